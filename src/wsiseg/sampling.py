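"""On-the-fly training-patch extraction from annotated slides.

Patches are cut from the slide pyramid as they are requested rather than
pre-exported, with three stochastic choices per draw:

1. the downsample factor, cycled uniformly over a user list (default
   1, 2, 3, 4 relative to base resolution);
2. with probability ``background_prob`` (default 0.1) the patch location is
   unconstrained — it may land on glass background, which helps a trained
   network normalise to non-tissue input;
3. otherwise, when class balancing is on, the draw proactively counters
   uneven class abundance: a target class is chosen uniformly over the
   annotated classes and the patch is centered on a uniformly chosen
   polygon of that class, jittered by up to half a patch so the object
   appears at varied positions.

Pixels inside designated ignore-region polygons are written as
``ignore_label`` in the label raster; trainers exclude them from the loss,
and they play no role in the balancing statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import shapely

from .annotations import AnnotationDocument, rasterize

__all__ = ["SamplerConfig", "PatchSample", "sample_patch", "patch_stream",
           "apply_ignore_regions", "default_class_map"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SamplerConfig:
    """Patch-sampling parameters.

    ``patch_size`` is in output pixels at the sampled downsample (a patch at
    downsample d spans ``patch_size * d`` base pixels). ``ignore_layer``
    names the annotation layer treated as ignore regions.
    """

    patch_size: int = 512
    downsample_list: tuple = (1, 2, 3, 4)
    background_prob: float = 0.1
    ignore_label: int = 255
    balance: bool = True
    rng_seed: int = 0
    ignore_layer: str = "ignore"

    def __post_init__(self):
        if not 0.0 <= self.background_prob <= 1.0:
            raise ValueError("background_prob must lie in [0, 1]")
        if not self.downsample_list or any(d < 1 for d in self.downsample_list):
            raise ValueError("downsample_list must be non-empty with all >= 1")
        if self.patch_size < 1:
            raise ValueError("patch_size must be positive")


@dataclass
class PatchSample:
    """One training example with full provenance."""

    image: np.ndarray  # (patch, patch, 3) uint8
    label: np.ndarray  # (patch, patch) int, may contain ignore_label
    slide_id: str
    location: tuple  # base-resolution (x, y) of the patch origin
    downsample: float
    background_draw: bool = False
    target_class: str | None = None


def default_class_map(doc, cfg=None):
    """1-based integers in layer order, skipping the ignore layer."""
    ignore = cfg.ignore_layer if cfg is not None else "ignore"
    names = [n for n in doc.layers if n != ignore]
    return {n: i + 1 for i, n in enumerate(names)}


def apply_ignore_regions(label, doc, region, downsample, ignore_label,
                         ignore_layer="ignore"):
    """Overwrite pixels inside ignore polygons with ``ignore_label``.

    All other pixels are returned unchanged; with no ignore layer present
    this is the identity.
    """
    if ignore_layer not in doc.layers or not doc.layers[ignore_layer]:
        return label
    ignore_mask = rasterize(
        doc, region, downsample, {ignore_layer: 1}, layers=[ignore_layer]
    )
    out = label.copy()
    out[ignore_mask > 0] = ignore_label
    return out


def _clamp_origin(v, span, limit):
    return int(min(max(v, 0), max(limit - span, 0)))


def sample_patch(slide, doc, tissue, cfg, rng, class_map=None):
    """Draw one :class:`PatchSample` under the configured policy.

    The stochastic choices are made in a fixed order (downsample, branch,
    then location) so a seeded generator reproduces the stream bit-exactly.
    Classes with zero polygons are skipped from balancing with a logged
    warning. Every non-background balanced draw is centered near a polygon
    of its target class, so the patch contains at least one pixel of that
    class.
    """
    if class_map is None:
        class_map = default_class_map(doc, cfg)
    d = float(rng.choice(np.asarray(cfg.downsample_list, dtype=np.float64)))
    span = int(round(cfg.patch_size * d))  # patch extent in base pixels
    W, H = slide.base_width, slide.base_height

    background_draw = bool(rng.random() < cfg.background_prob)
    target = None
    if background_draw:
        # location unconstrained: may include non-tissue background
        x0 = int(rng.integers(0, max(W - span, 0) + 1))
        y0 = int(rng.integers(0, max(H - span, 0) + 1))
    elif cfg.balance:
        classes = [
            n for n in doc.layers
            if n != cfg.ignore_layer and n in class_map
        ]
        empty = [n for n in classes if not doc.layers[n]]
        for n in empty:
            log.warning("class %r has no polygons; skipped from balancing", n)
        classes = [n for n in classes if doc.layers[n]]
        if not classes:
            raise ValueError("no annotated classes available for balancing")
        target = classes[int(rng.integers(len(classes)))]
        polys = doc.layers[target]
        poly = polys[int(rng.integers(len(polys)))]
        pt = poly.to_shapely().representative_point()
        # jitter keeps the polygon's anchor strictly inside the patch
        jmax = (cfg.patch_size / 2 - 2) * d
        jx = rng.uniform(-jmax, jmax)
        jy = rng.uniform(-jmax, jmax)
        x0 = _clamp_origin(pt.x + jx - span / 2, span, W)
        y0 = _clamp_origin(pt.y + jy - span / 2, span, H)
    else:
        fg = np.flatnonzero(tissue.mask)
        if fg.size == 0:
            raise ValueError("tissue mask is empty; cannot sample tissue patch")
        idx = int(fg[int(rng.integers(fg.size))])
        my, mx = np.unravel_index(idx, tissue.mask.shape)
        cx = (mx + 0.5) * tissue.downsample
        cy = (my + 0.5) * tissue.downsample
        x0 = _clamp_origin(cx - span / 2, span, W)
        y0 = _clamp_origin(cy - span / 2, span, H)

    region = (x0, y0, span, span)
    image = slide.read_region(x0, y0, span, span, d)
    label = rasterize(doc, region, d, class_map,
                      layers=[n for n in doc.layers if n != cfg.ignore_layer])
    label = apply_ignore_regions(label, doc, region, d, cfg.ignore_label,
                                 cfg.ignore_layer)
    return PatchSample(
        image=image,
        label=label,
        slide_id=slide.slide_id,
        location=(x0, y0),
        downsample=d,
        background_draw=background_draw,
        target_class=target,
    )


def patch_stream(slide, doc, tissue, cfg, class_map=None, n=None):
    """Seeded infinite (or length-``n``) iterator of patch samples."""
    rng = np.random.default_rng(cfg.rng_seed)
    count = 0
    while n is None or count < n:
        yield sample_patch(slide, doc, tissue, cfg, rng, class_map)
        count += 1
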