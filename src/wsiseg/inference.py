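"""Deterministic tiled whole-slide inference with logit averaging.

Prediction runs over an overlapping grid of large patches (defaults:
2000 px patches, 1000 px stride, read at downsample 2) restricted to tissue.
Each patch's logits are computed at ``1 / decoder_output_stride`` of the
patch resolution; a fixed rim (default 100 px in patch coordinates) is
trimmed from every prediction to suppress edge artifacts, except on sides
where the patch abuts the slide boundary (trimming there would leave a rim
of tissue unpredicted). Trimmed logits are accumulated into a slide-wide
volume and overlapping contributions are averaged unweighted, so under the
defaults the assembled class map sits at one-eighth of base resolution
(prediction downsample 2 x decoder output stride 4) and is never
up-sampled — contour and heatmap *coordinates* are up-sampled on export
instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .annotations import HeatmapLayer, mask_to_annotations

__all__ = [
    "InferenceConfig",
    "GridPlan",
    "LogitVolume",
    "plan_grid",
    "run_tiled_inference",
    "volume_to_mask",
    "export_contours",
    "export_heatmap",
    "StitchError",
]

log = logging.getLogger(__name__)


class StitchError(RuntimeError):
    """A patch prediction violated the segmenter contract."""


@dataclass(frozen=True)
class InferenceConfig:
    """Tiled-prediction parameters (pixel units are at the prediction
    downsample unless stated otherwise)."""

    patch_size: int = 2000
    stride: int = 1000
    prediction_downsample: float = 2.0
    border_trim: int = 100
    mode: str = "contours"  # or "heatmap"
    # edge-clamped origins are rounded up to this lattice so accumulation
    # stays aligned with the logit grid; must match the model's decoder
    # output stride (or a multiple of it)
    origin_align: int = 4

    def __post_init__(self):
        if self.stride > self.patch_size:
            raise ValueError("stride must not exceed patch_size")
        if self.stride < 1:
            raise ValueError("stride must be positive")
        if not 0 <= self.border_trim < self.patch_size / 2:
            raise ValueError("border_trim must lie in [0, patch_size/2)")
        if self.mode not in ("contours", "heatmap"):
            raise ValueError("mode must be 'contours' or 'heatmap'")


@dataclass
class GridPlan:
    """Row-major list of patch origins in prediction-downsample coords."""

    origins: list
    patch_size: int
    slide_id: str

    def __len__(self):
        return len(self.origins)


@dataclass
class LogitVolume:
    """Averaged per-class logit map for a whole slide.

    ``scale_factor`` is relative to base resolution
    (= prediction_downsample x decoder_output_stride). ``counts`` records
    how many trimmed patch predictions contributed to each output pixel;
    zero-count pixels hold logit 0 and are treated as background downstream.
    """

    logits: np.ndarray  # (H, W, C) float64, contribution means
    counts: np.ndarray  # (H, W) int
    scale_factor: float
    slide_id: str = "slide"

    @property
    def n_classes(self):
        return self.logits.shape[2]

    def softmax(self):
        z = self.logits - self.logits.max(axis=-1, keepdims=True)
        ez = np.exp(z)
        return ez / ez.sum(axis=-1, keepdims=True)


def _axis_origins(extent, patch, stride, align):
    """Stride-lattice origins covering [0, extent), clamped at the edge.

    The final origin is rounded up to a multiple of ``align`` so logit
    accumulation stays lattice-aligned; the patch may then overhang the
    slide edge, where reads are white-padded.
    """
    if extent <= patch:
        return [0]
    origins = list(range(0, extent - patch, stride))
    last = int(np.ceil((extent - patch) / align) * align)
    if not origins or origins[-1] != last:
        origins.append(last)
    return origins


def plan_grid(tissue, cfg, slide_dims=None, slide_id=None):
    """Enumerate tissue-intersecting patches of the overlapping grid.

    ``slide_dims`` is ``(base_width, base_height)``; by default it is
    reconstructed from the tissue-mask geometry. Origins lie on the stride
    lattice in prediction-downsample coordinates, clamped at slide edges,
    ordered row-major. Every tissue pixel is covered by at least one
    planned patch; patches not touching tissue are skipped. An empty
    tissue mask yields an empty plan.
    """
    ds = cfg.prediction_downsample
    mask = tissue.mask
    if slide_dims is None:
        slide_dims = (
            int(mask.shape[1] * tissue.downsample),
            int(mask.shape[0] * tissue.downsample),
        )
    W = int(slide_dims[0] / ds)
    H = int(slide_dims[1] / ds)
    sid = slide_id or tissue.source_slide_id
    if not mask.any():
        return GridPlan([], cfg.patch_size, sid)
    # tissue-mask pixels per prediction pixel
    ratio = tissue.downsample / ds
    origins = []
    for y in _axis_origins(H, cfg.patch_size, cfg.stride, cfg.origin_align):
        my0 = int(np.floor(y / ratio))
        my1 = int(np.ceil((y + cfg.patch_size) / ratio))
        for x in _axis_origins(W, cfg.patch_size, cfg.stride,
                               cfg.origin_align):
            mx0 = int(np.floor(x / ratio))
            mx1 = int(np.ceil((x + cfg.patch_size) / ratio))
            if mask[my0:my1, mx0:mx1].any():
                origins.append((x, y))
    return GridPlan(origins, cfg.patch_size, sid)


def _trim_bounds(origin, patch, trim, extent, stride_out):
    """Contributing logit-pixel range along one axis, after border trim.

    A logit pixel contributes when its full ``stride_out``-wide footprint
    lies at least ``trim`` patch pixels from the patch border; trimming is
    suppressed on sides abutting (or overhanging) the slide boundary.
    """
    t0 = trim if origin > 0 else 0
    t1 = trim if origin + patch < extent else 0
    c0 = int(np.ceil(t0 / stride_out))
    c1 = (patch - t1) // stride_out
    return c0, c1


def run_tiled_inference(slide, model, cfg, tissue, plan=None,
                        progress=True):
    """Predict every planned patch and stitch by unweighted logit averaging.

    Each output pixel of the returned :class:`LogitVolume` is the mean of
    all trimmed patch logits covering it; pixels no trimmed prediction
    reaches keep zero logits with ``counts == 0``. Raises
    :class:`StitchError` naming the patch if the model's output shape
    violates the segmenter contract.
    """
    ds = cfg.prediction_downsample
    os_ = model.decoder_output_stride
    if cfg.patch_size % os_ or cfg.stride % os_ or cfg.origin_align % os_:
        raise ValueError(
            f"patch_size, stride and origin_align must be divisible by "
            f"the decoder output stride {os_}"
        )
    if plan is None:
        plan = plan_grid(tissue, cfg, slide.dimensions, slide.slide_id)
    W = int(slide.base_width / ds)
    H = int(slide.base_height / ds)
    out_w, out_h = W // os_, H // os_
    n_classes = model.n_classes
    acc = np.zeros((out_h, out_w, n_classes), dtype=np.float64)
    counts = np.zeros((out_h, out_w), dtype=np.int64)
    patch_out = cfg.patch_size // os_

    for i, (x, y) in enumerate(plan.origins):
        rgb = slide.read_region(
            int(x * ds), int(y * ds),
            int(cfg.patch_size * ds), int(cfg.patch_size * ds), ds,
        )
        logits = np.asarray(model.predict_logits(rgb))
        if logits.shape != (patch_out, patch_out, n_classes):
            raise StitchError(
                f"patch at ({x}, {y}): model returned shape "
                f"{logits.shape}, contract requires "
                f"{(patch_out, patch_out, n_classes)}"
            )
        cx0, cx1 = _trim_bounds(x, cfg.patch_size, cfg.border_trim, W, os_)
        cy0, cy1 = _trim_bounds(y, cfg.patch_size, cfg.border_trim, H, os_)
        # clip to the volume extent (patches may overhang the slide edge)
        gx0, gy0 = x // os_ + cx0, y // os_ + cy0
        gx1 = min(x // os_ + cx1, out_w)
        gy1 = min(y // os_ + cy1, out_h)
        if gx1 <= gx0 or gy1 <= gy0:
            continue
        lx0, ly0 = gx0 - x // os_, gy0 - y // os_
        acc[gy0:gy1, gx0:gx1] += logits[
            ly0 : ly0 + (gy1 - gy0), lx0 : lx0 + (gx1 - gx0)
        ]
        counts[gy0:gy1, gx0:gx1] += 1
        if progress and (i + 1) % max(len(plan) // 10, 1) == 0:
            log.info("stitched %d/%d patches (%d%%)", i + 1, len(plan),
                     round(100 * (i + 1) / len(plan)))

    covered = counts > 0
    mean = np.zeros_like(acc)
    mean[covered] = acc[covered] / counts[covered, None]
    return LogitVolume(mean, counts, ds * os_, slide.slide_id)


def volume_to_mask(vol):
    """Per-pixel argmax class map at the volume's scale factor.

    Ties break toward the lower class index; pixels with zero
    contributions are labelled background (0). Under the defaults the mask
    sides are the base dimensions floor-divided by 8.
    """
    mask = np.argmax(vol.logits, axis=-1).astype(np.int32)
    mask[vol.counts == 0] = 0
    return mask, vol.scale_factor


def export_contours(mask, scale_factor, class_map=None, slide_id="slide"):
    """Vectorize a reduced-scale class map into base-coordinate contours.

    ``class_map`` maps class label -> mask integer (background 0 is never
    exported). Contour vertices are multiplied by ``scale_factor`` into
    base resolution.
    """
    return mask_to_annotations(mask, origin=(0, 0), scale=scale_factor,
                               class_map=class_map, slide_id=slide_id)


def export_heatmap(vol, class_index, class_label=None, threshold=0.05):
    """Sparse softmax-probability heatmap for one class.

    Keeps entries with probability >= ``threshold`` over the covered
    (tissue) region only; point coordinates are up-sampled to base
    resolution by the volume's scale factor. With ``threshold = 0`` the
    entry count equals the covered pixel count.
    """
    if not 0 <= class_index < vol.n_classes:
        raise ValueError(
            f"unknown class index {class_index}; volume has "
            f"{vol.n_classes} classes"
        )
    probs = vol.softmax()[..., class_index]
    keep = (vol.counts > 0) & (probs >= threshold)
    ys, xs = np.nonzero(keep)
    pts = np.column_stack([
        (xs + 0.5) * vol.scale_factor,
        (ys + 0.5) * vol.scale_factor,
        probs[ys, xs],
    ])
    label = class_label if class_label is not None else f"class_{class_index}"
    return HeatmapLayer(pts, label, vol.scale_factor)
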