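"""Patch-segmenter contract, reference model and minimal trainer.

Production deployments of whole-slide segmentation wrap a large encoder /
decoder network (the kind trained with an output stride of 16 and a decoder
output stride of 4). That architecture is out of scope here; instead this
module pins down the *contract* such a network must honor — logits at
``1 / decoder_output_stride`` of the input resolution — and provides a
deliberately tiny convolutional reference model with hand-written
forward/backward passes so the full pipeline (sampling, training, tiled
inference, evaluation) runs end to end on one CPU. Any external model can
participate by subclassing :class:`SegmenterContract`.

Training follows the conventional schedule for this family of models: SGD
with momentum 0.9 and a base learning rate of 1e-3 under polynomial decay
to zero. Pixels labelled with the sampler's ignore value are excluded from
the loss.
"""

from __future__ import annotations

import abc
import json
from dataclasses import dataclass, asdict

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "SegmenterContract",
    "TrainConfig",
    "lr_at_step",
    "ReferenceSegmenter",
    "ColorPrototypeSegmenter",
    "train_reference",
]


class SegmenterContract(abc.ABC):
    """A patch segmenter: RGB patch in, reduced-resolution logits out.

    For an ``(H, W, 3)`` input with H and W divisible by
    ``decoder_output_stride`` the output must be exactly
    ``(H / stride, W / stride, n_classes)``, and repeated calls on the same
    input with the same weights must return identical logits.
    """

    n_classes: int
    decoder_output_stride: int = 4

    @abc.abstractmethod
    def predict_logits(self, patch):
        """Return per-class logits for one RGB uint8 patch."""

    def _check_input(self, patch):
        patch = np.asarray(patch)
        s = self.decoder_output_stride
        if patch.ndim != 3 or patch.shape[2] != 3:
            raise ValueError("patch must be an (H, W, 3) RGB array")
        if patch.shape[0] % s or patch.shape[1] % s:
            raise ValueError(
                f"patch sides must be divisible by the decoder output "
                f"stride {s}; got {patch.shape[:2]}"
            )
        return patch


@dataclass(frozen=True)
class TrainConfig:
    """Trainer hyperparameters.

    ``steps`` defaults to 500 for the reference model (full-scale networks
    of this kind are trained for 50k-400k steps); ``batch_size`` defaults to
    2, the setting used when no large-batch hardware is available, with
    batch-normalisation training off by default for the same reason (the
    reference model has no batch-norm layers, so the flag is contract
    plumbing for wrapped networks).
    """

    steps: int = 500
    base_lr: float = 1e-3
    lr_power: float = 0.9
    momentum: float = 0.9
    batch_size: int = 2
    patch_size: int = 512
    train_batchnorm: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.base_lr <= 0:
            raise ValueError("base_lr must be positive")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must lie in [0, 1)")


def lr_at_step(cfg, step):
    """Polynomial-decay learning rate: ``base_lr * (1 - step/steps)^power``.

    Starts at ``base_lr`` and decays to exactly 0 at the final step.
    """
    if not 0 <= step <= cfg.steps:
        raise ValueError(f"step {step} outside [0, {cfg.steps}]")
    return cfg.base_lr * (1.0 - step / cfg.steps) ** cfg.lr_power


# -- numpy conv primitives --------------------------------------------------


def _conv3(x, w, b=0.0):
    """Same-padded 3x3 convolution; x (H, W, Cin), w (3, 3, Cin, Cout)."""
    xp = np.pad(x, ((1, 1), (1, 1), (0, 0)))
    cols = sliding_window_view(xp, (3, 3), axis=(0, 1))  # (H, W, Cin, 3, 3)
    return np.einsum("hwcij,ijco->hwo", cols, w, optimize=True) + b


def _conv3_grads(x, w, dy):
    """Gradients of :func:`_conv3` w.r.t. weights, bias and input."""
    xp = np.pad(x, ((1, 1), (1, 1), (0, 0)))
    cols = sliding_window_view(xp, (3, 3), axis=(0, 1))
    dw = np.einsum("hwcij,hwo->ijco", cols, dy, optimize=True)
    db = dy.sum(axis=(0, 1))
    w_rot = w[::-1, ::-1].transpose(0, 1, 3, 2)  # flip taps, swap channels
    dx = _conv3(dy, w_rot)
    return dw, db, dx


def _pool(x, s):
    h, w = x.shape[0] // s, x.shape[1] // s
    return x[: h * s, : w * s].reshape(h, s, w, s, -1).mean(axis=(1, 3))


class ReferenceSegmenter(SegmenterContract):
    """Tiny trainable convolutional patch segmenter.

    Architecture: fixed ``stride x stride`` average pooling (which realises
    the decoder output stride), input standardisation, then three trainable
    convolutions — 3x3 -> ReLU, 3x3 -> ReLU, 1x1 to class logits — with a
    skip connection feeding the pooled color directly into the classifier.
    It is intentionally small: enough capacity to segment color-separable
    structures, fast enough to train on one CPU in seconds.

    Follows the sklearn estimator idiom: hyperparameters are constructor
    arguments mirrored by ``get_params`` / ``set_params``; fitted state
    (weights, loss trace, class labels) lives in trailing-underscore
    attributes set by :meth:`fit`.
    """

    _PARAM_NAMES = ("n_classes", "hidden", "decoder_output_stride", "seed")

    def __init__(self, n_classes=3, hidden=16, decoder_output_stride=4,
                 seed=0):
        self.n_classes = n_classes
        self.hidden = hidden
        self.decoder_output_stride = decoder_output_stride
        self.seed = seed
        self._init_weights()

    # sklearn-style plumbing
    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in self._PARAM_NAMES}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self._PARAM_NAMES:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        self._init_weights()
        return self

    def _init_weights(self):
        rng = np.random.default_rng(self.seed)
        c, h = 3, self.hidden
        he = lambda fan_in, shape: rng.normal(
            0.0, np.sqrt(2.0 / fan_in), shape
        )
        self.weights_ = {
            "w1": he(9 * c, (3, 3, c, h)),
            "b1": np.zeros(h),
            "w2": he(9 * h, (3, 3, h, h)),
            "b2": np.zeros(h),
            # 1x1 classifier over [hidden features, pooled color skip]
            "w3": he(h + c, (h + c, self.n_classes)),
            "b3": np.zeros(self.n_classes),
        }

    # forward -----------------------------------------------------------
    @staticmethod
    def _standardize(patch):
        return (patch.astype(np.float64) - 128.0) / 40.0

    def _forward(self, patch):
        x = self._standardize(patch)
        p = _pool(x, self.decoder_output_stride)
        w = self.weights_
        a1 = _conv3(p, w["w1"], w["b1"])
        h1 = np.maximum(a1, 0.0)
        a2 = _conv3(h1, w["w2"], w["b2"])
        h2 = np.maximum(a2, 0.0)
        feats = np.concatenate([h2, p], axis=-1)
        logits = feats @ w["w3"] + w["b3"]
        return logits, (p, h1, h2, feats)

    def predict_logits(self, patch):
        patch = self._check_input(patch)
        logits, _ = self._forward(patch)
        return logits

    def predict(self, patch):
        """Argmax class map at ``1 / decoder_output_stride`` resolution."""
        return np.argmax(self.predict_logits(patch), axis=-1)

    # training ------------------------------------------------------------
    def _loss_and_grads(self, patch, label, ignore_label,
                        class_weights=None):
        logits, (p, h1, h2, feats) = self._forward(patch)
        s = self.decoder_output_stride
        off = s // 2
        lab = label[off::s, off::s][: logits.shape[0], : logits.shape[1]]
        valid = lab != ignore_label
        n_valid = int(valid.sum())
        if n_valid == 0:
            return 0.0, None
        z = logits - logits.max(axis=-1, keepdims=True)
        ez = np.exp(z)
        probs = ez / ez.sum(axis=-1, keepdims=True)
        idx = np.where(valid)
        targets = lab[valid]
        if class_weights is None:
            w = np.ones(targets.shape)
        else:
            w = np.asarray(class_weights)[targets]
        w_sum = w.sum()
        ll = np.log(probs[idx[0], idx[1], targets] + 1e-300)
        loss = -(w * ll).sum() / w_sum

        dlogits = probs.copy()
        dlogits[idx[0], idx[1], targets] -= 1.0
        dlogits[~valid] = 0.0
        dlogits[idx[0], idx[1]] *= (w / w_sum)[:, None]

        w = self.weights_
        dw3 = np.einsum("hwf,hwo->fo", feats, dlogits, optimize=True)
        db3 = dlogits.sum(axis=(0, 1))
        dfeats = dlogits @ w["w3"].T
        dh2 = dfeats[..., : self.hidden]
        da2 = dh2 * (h2 > 0)
        dw2, db2, dh1 = _conv3_grads(h1, w["w2"], da2)
        da1 = dh1 * (h1 > 0)
        dw1, db1, _ = _conv3_grads(p, w["w1"], da1)
        grads = {"w1": dw1, "b1": db1, "w2": dw2, "b2": db2,
                 "w3": dw3, "b3": db3}
        return loss, grads

    def fit(self, stream, cfg=None, ignore_label=255, class_names=None,
            balance_loss=True):
        """Train on an iterator of :class:`~wsiseg.sampling.PatchSample`.

        Runs ``cfg.steps`` optimiser steps of mini-batch SGD with momentum
        and polynomial learning-rate decay; ignore-labelled pixels
        contribute nothing to the loss. With ``balance_loss`` (default) the
        cross-entropy is inverse-frequency weighted per class, using label
        frequencies tracked over the stream — without it the large
        unannotated-background majority dominates the pixel loss and rare
        structure classes converge very slowly. Raises if the stream
        provides no annotated (non-ignore) pixels at all. Sets
        ``loss_trace_``, ``classes_`` and updated ``weights_``.
        """
        cfg = cfg or TrainConfig()
        it = iter(stream)
        velocity = {k: np.zeros_like(v) for k, v in self.weights_.items()}
        self.loss_trace_ = []
        self.classes_ = list(class_names) if class_names else None
        saw_pixels = False
        pix_counts = np.ones(self.n_classes)
        for step in range(cfg.steps):
            lr = lr_at_step(cfg, step)
            batch_loss = 0.0
            grad_acc = None
            n_used = 0
            for _ in range(cfg.batch_size):
                sample = next(it)
                if balance_loss:
                    lab = sample.label
                    keep = (lab != ignore_label) & (lab < self.n_classes)
                    pix_counts += np.bincount(
                        lab[keep].ravel(), minlength=self.n_classes
                    )
                    weights = pix_counts.sum() / (
                        self.n_classes * pix_counts
                    )
                else:
                    weights = None
                loss, grads = self._loss_and_grads(
                    sample.image, sample.label, ignore_label, weights
                )
                if grads is None:
                    continue
                saw_pixels = True
                batch_loss += loss
                n_used += 1
                if grad_acc is None:
                    grad_acc = grads
                else:
                    for k in grad_acc:
                        grad_acc[k] += grads[k]
            if n_used == 0:
                self.loss_trace_.append(np.nan)
                continue
            for k, w in self.weights_.items():
                g = grad_acc[k] / n_used
                velocity[k] = cfg.momentum * velocity[k] - lr * g
                w += velocity[k]
            self.loss_trace_.append(batch_loss / n_used)
        if not saw_pixels:
            raise ValueError("training stream contained no annotated pixels")
        return self

    def score(self, samples, ignore_label=255):
        """Mean pixel accuracy over patch samples (ignore pixels excluded)."""
        correct = total = 0
        s = self.decoder_output_stride
        off = s // 2
        for sample in samples:
            pred = self.predict(sample.image)
            lab = sample.label[off::s, off::s][: pred.shape[0], : pred.shape[1]]
            valid = lab != ignore_label
            correct += int((pred[valid] == lab[valid]).sum())
            total += int(valid.sum())
        return correct / total if total else 0.0

    # persistence ---------------------------------------------------------
    def save(self, path):
        meta = dict(self.get_params())
        meta["classes"] = getattr(self, "classes_", None)
        np.savez(path, meta=json.dumps(meta), **self.weights_)

    @classmethod
    def load(cls, path):
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            classes = meta.pop("classes", None)
            model = cls(**meta)
            model.weights_ = {
                k: np.array(data[k]) for k in model.weights_
            }
        if classes is not None:
            model.classes_ = classes
        return model


class ColorPrototypeSegmenter(SegmenterContract):
    """Analytic nearest-color segmenter honoring the contract.

    Each class is described by one or more RGB prototype colors; the logit
    of a class at a pooled pixel is the (scaled) negative squared distance
    to its nearest prototype. Useful as a deterministic stand-in model in
    stitching and export tests where no training is wanted.
    """

    def __init__(self, prototypes, decoder_output_stride=4, scale=0.01):
        self.prototypes = [np.atleast_2d(np.asarray(p, float))
                           for p in prototypes]
        self.n_classes = len(self.prototypes)
        self.decoder_output_stride = decoder_output_stride
        self.scale = scale

    def predict_logits(self, patch):
        patch = self._check_input(patch)
        p = _pool(patch.astype(np.float64), self.decoder_output_stride)
        logits = np.empty(p.shape[:2] + (self.n_classes,))
        for c, protos in enumerate(self.prototypes):
            d2 = ((p[..., None, :] - protos) ** 2).sum(axis=-1)
            logits[..., c] = -self.scale * d2.min(axis=-1)
        return logits


def train_reference(slide_docs, train_cfg=None, sampler_cfg=None,
                    model=None, tissue_downsample=32):
    """Train a :class:`ReferenceSegmenter` from annotated slides.

    ``slide_docs`` is a sequence of ``(SlidePyramid, AnnotationDocument)``
    pairs; patches are drawn round-robin-seeded from all slides through the
    class-balanced sampler. Returns the fitted model with ``classes_`` set
    to the annotated layer names (class 0 is unannotated background).
    """
    from .sampling import SamplerConfig, default_class_map, patch_stream
    from .slide import compute_tissue_mask

    if not slide_docs:
        raise ValueError("need at least one annotated slide")
    train_cfg = train_cfg or TrainConfig()
    sampler_cfg = sampler_cfg or SamplerConfig(
        patch_size=train_cfg.patch_size, rng_seed=train_cfg.seed
    )
    class_map = default_class_map(slide_docs[0][1], sampler_cfg)
    for _, doc in slide_docs[1:]:
        for name in default_class_map(doc, sampler_cfg):
            if name not in class_map:
                class_map[name] = max(class_map.values(), default=0) + 1
    n_classes = max(class_map.values()) + 1

    streams = []
    for i, (slide, doc) in enumerate(slide_docs):
        tissue = compute_tissue_mask(slide, tissue_downsample, cache_dir=None)
        cfg_i = SamplerConfig(
            **{**asdict(sampler_cfg), "rng_seed": sampler_cfg.rng_seed + i}
        )
        streams.append(patch_stream(slide, doc, tissue, cfg_i, class_map))

    def interleave():
        while True:
            for s in streams:
                yield next(s)

    if model is None:
        model = ReferenceSegmenter(n_classes=n_classes, seed=train_cfg.seed)
    elif model.n_classes != n_classes:
        raise ValueError(
            f"checkpoint has {model.n_classes} classes, data needs {n_classes}"
        )
    names = [None] * n_classes
    names[0] = "background"
    for name, v in class_map.items():
        names[v] = name
    model.fit(interleave(), train_cfg,
              ignore_label=sampler_cfg.ignore_label, class_names=names)
    return model
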