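"""Segmentation, agreement and separability metrics.

Pixel-wise metrics are computed one-vs-rest per class from a confusion
table: Matthews correlation coefficient (MCC), F-score, Cohen's kappa,
intersection over union, sensitivity, specificity, precision and accuracy.
ROC curves are swept over softmax scores of a stitched logit volume.
Inter-rater agreement uses ICC(2,1) — two-way random effects, absolute
agreement, single rater — with the F test of r = 0 against r > 0.
Cluster separability of an object-feature table is quantified by embedding
to 2-D with UMAP and cross-validating a K-nearest-neighbor classifier,
reporting Cohen's kappa per neighborhood size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["ConfusionCounts", "confusion", "metrics", "roc_auc", "icc",
           "separability"]


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest pixel counts for a single class."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self):
        return self.tp + self.fp + self.fn + self.tn


def confusion(pred, gt, class_value):
    """Pixel-wise one-vs-rest confusion counts for ``class_value``."""
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(
            f"prediction shape {pred.shape} != ground truth shape {gt.shape}"
        )
    p = pred == class_value
    g = gt == class_value
    return ConfusionCounts(
        tp=int(np.sum(p & g)),
        fp=int(np.sum(p & ~g)),
        fn=int(np.sum(~p & g)),
        tn=int(np.sum(~p & ~g)),
    )


def metrics(counts):
    """Standard closed-form metrics from confusion counts.

    Degenerate denominators yield 0 for the affected metric and set
    ``degenerate`` to True in the returned dict.
    """
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    n = counts.total
    degenerate = False

    def safe(num, den):
        nonlocal degenerate
        if den == 0:
            degenerate = True
            return 0.0
        return num / den

    mcc_den = np.sqrt(
        float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    mcc = safe(tp * tn - fp * fn, mcc_den)
    f_score = safe(2 * tp, 2 * tp + fp + fn)
    po = safe(tp + tn, n)
    pe = safe((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp), n * n)
    kappa = safe(po - pe, 1 - pe) if n else 0.0
    out = {
        "mcc": float(mcc),
        "f_score": float(f_score),
        "kappa": float(kappa),
        "iou": float(safe(tp, tp + fp + fn)),
        "sensitivity": float(safe(tp, tp + fn)),
        "specificity": float(safe(tn, tn + fp)),
        "precision": float(safe(tp, tp + fp)),
        "accuracy": float(safe(tp + tn, n)),
        "degenerate": degenerate,
    }
    return out


def roc_auc(scores, gt, class_value=1, from_volume_class=None):
    """ROC points and trapezoidal AUC for one class.

    ``scores`` is either a flat/2-D array of per-pixel scores for the class
    or a :class:`~wsiseg.inference.LogitVolume` (then
    ``from_volume_class`` selects the class channel; the sweep runs over
    softmax probabilities on covered pixels only). ``gt`` holds class
    labels on a compatible grid. Raises if the ground truth contains a
    single class.
    """
    if from_volume_class is not None:
        vol = scores
        probs = vol.softmax()[..., from_volume_class]
        keep = vol.counts > 0
        s = probs[keep].ravel()
        y = (np.asarray(gt)[keep].ravel() == class_value)
    else:
        s = np.asarray(scores, dtype=np.float64).ravel()
        y = (np.asarray(gt).ravel() == class_value)
    if s.shape != y.shape:
        raise ValueError("scores and ground truth sizes differ")
    if y.all() or not y.any():
        raise ValueError("ground truth contains a single class; ROC undefined")
    order = np.argsort(-s, kind="stable")
    y = y[order]
    s = s[order]
    distinct = np.r_[np.nonzero(np.diff(s))[0], y.size - 1]
    tps = np.cumsum(y)[distinct]
    fps = np.cumsum(~y)[distinct]
    tpr = np.r_[0.0, tps / tps[-1]]
    fpr = np.r_[0.0, fps / fps[-1]]
    auc = float(np.trapezoid(tpr, fpr))
    return {"fpr": fpr, "tpr": tpr,
            "thresholds": np.r_[np.inf, s[distinct]], "auc": auc}


def icc(matrix):
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``matrix`` is (n_targets, k_raters) with no missing cells. Returns the
    estimate, the F statistic and the p-value of the one-sided test of
    r = 0 vs r > 0 (F test on the target mean square). A zero-variance
    matrix across targets is flagged degenerate with ICC 0.
    """
    m = np.asarray(matrix, dtype=np.float64)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need >= 2 targets (rows) and >= 2 raters (columns)")
    if np.isnan(m).any():
        raise ValueError("rater matrix contains missing cells")
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)  # targets (rows)
    msc = ss_cols / (k - 1)  # raters (columns)
    mse = ss_err / ((n - 1) * (k - 1))  # residual
    den = msr + (k - 1) * mse + k * (msc - mse) / n
    if msr <= 0 or den <= 0:
        return {"icc": 0.0, "F": 0.0, "p_value": 1.0, "degenerate": True}
    value = (msr - mse) / den
    if mse <= 0:
        return {"icc": float(value), "F": np.inf, "p_value": 0.0,
                "degenerate": False}
    f_stat = msr / mse
    p = float(stats.f.sf(f_stat, n - 1, (n - 1) * (k - 1)))
    return {"icc": float(value), "F": float(f_stat), "p_value": p,
            "degenerate": False}


def separability(features, labels, k_list=None, folds=10, seed=0,
                 n_neighbors_umap=15):
    """UMAP + KNN class-separability score.

    Embeds the feature rows to 2-D with UMAP, then cross-validates a
    K-nearest-neighbor classifier on the embedding for each neighborhood
    size in ``k_list`` (default: odd 1..25), scoring Cohen's kappa on the
    pooled out-of-fold predictions. Returns ``{"kappa_per_k": {k: kappa},
    "best_k": k, "max_kappa": float, "embedding": (n, 2) array}``.

    Raises if any label group has fewer members than ``folds`` (stratified
    folds would be empty).
    """
    import umap
    from sklearn.metrics import cohen_kappa_score
    from sklearn.model_selection import StratifiedKFold, cross_val_predict
    from sklearn.neighbors import KNeighborsClassifier

    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two label groups")
    counts = np.unique(y, return_counts=True)[1]
    if counts.min() < folds:
        raise ValueError(
            f"smallest group has {counts.min()} members; needs >= {folds} "
            f"for {folds}-fold stratified CV"
        )
    if k_list is None:
        k_list = list(range(1, 26, 2))
    reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors_umap,
                        random_state=seed, n_jobs=1)
    emb = reducer.fit_transform(X)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    kappa_per_k = {}
    for k in k_list:
        pred = cross_val_predict(KNeighborsClassifier(n_neighbors=k), emb, y,
                                 cv=cv)
        kappa_per_k[int(k)] = float(cohen_kappa_score(y, pred))
    best_k = max(kappa_per_k, key=kappa_per_k.get)
    return {
        "kappa_per_k": kappa_per_k,
        "best_k": best_k,
        "max_kappa": kappa_per_k[best_k],
        "embedding": emb,
    }
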