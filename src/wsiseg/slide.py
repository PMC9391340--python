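"""Pyramidal whole-slide image abstraction and tissue-region masking.

A whole-slide image (WSI) is stored as a multi-resolution pyramid: a base
level at full scanner resolution plus progressively downsampled levels.
:class:`SlidePyramid` wraps either a tiled multi-resolution TIFF on disk or a
list of in-memory level arrays, and exposes a single ``read_region`` call in
base-resolution coordinates at an arbitrary downsample factor.

Coordinate convention (used by every public API in this package): 0-based,
half-open, ``x`` = column, ``y`` = row, all in base-resolution pixels.
Reads beyond the slide bounds are padded with white (255, 255, 255) so that
edge patches of an inference grid are always full size.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
from skimage.filters import gaussian
from skimage.morphology import remove_small_objects
from skimage.transform import resize

__all__ = [
    "SlidePyramid",
    "TissueMask",
    "TissueMaskConfig",
    "open_slide",
    "write_pyramidal_tiff",
    "compute_tissue_mask",
]

_WHITE = 255


class SlideReadError(IOError):
    """Raised when a slide file cannot be read."""


class SlidePyramid:
    """Multi-resolution RGB image with base-level pixel geometry.

    Parameters
    ----------
    levels : list of ndarray
        RGB uint8 arrays ordered from base resolution downward. Level
        downsample factors are inferred from the width ratio to the base
        level and must be strictly increasing from 1.
    slide_id : str
        Stable identifier, used in annotation documents and cache names.
    mpp : float, optional
        Microns per pixel at base resolution, if known.
    path : Path, optional
        Backing file, when the pyramid was opened from disk.
    """

    def __init__(self, levels, slide_id="slide", mpp=None, path=None):
        if not levels:
            raise ValueError("pyramid needs at least one level")
        self.levels = [np.ascontiguousarray(lv) for lv in levels]
        base = self.levels[0]
        if base.ndim != 3 or base.shape[2] != 3:
            raise ValueError("levels must be RGB (H, W, 3) arrays")
        self.base_height, self.base_width = base.shape[:2]
        self.downsamples = [self.base_width / lv.shape[1] for lv in self.levels]
        if any(b <= a for a, b in zip(self.downsamples, self.downsamples[1:])):
            raise ValueError("level downsamples must be strictly increasing")
        self.slide_id = slide_id
        self.mpp = mpp
        self.path = Path(path) if path is not None else None

    # -- geometry -----------------------------------------------------------

    @property
    def dimensions(self):
        """(width, height) of the base level in pixels."""
        return (self.base_width, self.base_height)

    def _best_level(self, downsample):
        """Largest-downsample level not exceeding the requested factor."""
        best = 0
        for i, d in enumerate(self.downsamples):
            if d <= downsample + 1e-9:
                best = i
        return best

    def read_region(self, x, y, w, h, downsample=1):
        """Read an RGB region given in base-resolution pixels.

        The returned raster has shape ``(round(h / downsample),
        round(w / downsample), 3)``; requesting ``w = n * downsample`` thus
        yields exactly ``n`` output columns. Portions of the request outside
        the slide are filled with white.
        """
        if w <= 0 or h <= 0:
            raise ValueError("region width/height must be positive")
        if downsample < 1:
            raise ValueError("downsample must be >= 1")
        out_w = int(round(w / downsample))
        out_h = int(round(h / downsample))
        li = self._best_level(downsample)
        ld = self.downsamples[li]
        level = self.levels[li]
        # region in level coordinates
        lx0 = int(np.floor(x / ld))
        ly0 = int(np.floor(y / ld))
        lw = int(round(w / ld))
        lh = int(round(h / ld))
        raw = np.full((lh, lw, 3), _WHITE, dtype=np.uint8)
        sx0, sy0 = max(lx0, 0), max(ly0, 0)
        sx1 = min(lx0 + lw, level.shape[1])
        sy1 = min(ly0 + lh, level.shape[0])
        if sx1 > sx0 and sy1 > sy0:
            raw[sy0 - ly0 : sy1 - ly0, sx0 - lx0 : sx1 - lx0] = level[
                sy0:sy1, sx0:sx1
            ]
        if (lh, lw) == (out_h, out_w):
            return raw
        scaled = resize(
            raw.astype(np.float64),
            (out_h, out_w, 3),
            order=1,
            anti_aliasing=(out_h < lh),
            preserve_range=True,
        )
        return np.clip(np.rint(scaled), 0, 255).astype(np.uint8)

    def thumbnail(self, downsample):
        """Whole-slide view at ``downsample`` with floor-divided dimensions."""
        w = (self.base_width // downsample) * downsample
        h = (self.base_height // downsample) * downsample
        return self.read_region(0, 0, w, h, downsample)

    def content_digest(self):
        """Hex digest of the base level bytes plus geometry (cache keying)."""
        h = hashlib.sha1()
        h.update(np.ascontiguousarray(self.levels[0]).tobytes())
        h.update(f"{self.base_width}x{self.base_height}".encode())
        return h.hexdigest()


def open_slide(path, slide_id=None, mpp=None):
    """Open a pyramidal TIFF, or a plain PNG/TIFF as a one-level pyramid."""
    path = Path(path)
    if not path.exists():
        raise SlideReadError(f"slide file not found: {path}")
    sid = slide_id or path.stem
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff", ".svs"):
            with tifffile.TiffFile(path) as tf:
                series = tf.series[0]
                levels = [np.asarray(lv.asarray()) for lv in series.levels]
        else:
            levels = [np.asarray(iio.imread(path))]
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise SlideReadError(f"cannot read slide {path}: {exc}") from exc
    levels = [lv[..., :3] if lv.ndim == 3 else np.stack([lv] * 3, -1) for lv in levels]
    return SlidePyramid(levels, slide_id=sid, mpp=mpp, path=path)


def write_pyramidal_tiff(path, levels, tile=(256, 256)):
    """Write level arrays as a tiled multi-resolution TIFF (SubIFD layout)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with tifffile.TiffWriter(path) as tw:
        tw.write(
            levels[0], tile=tile, photometric="rgb", subifds=len(levels) - 1
        )
        for lv in levels[1:]:
            tw.write(lv, tile=tile, photometric="rgb", subfiletype=1)
    return path


# -- tissue masking ---------------------------------------------------------


@dataclass(frozen=True)
class TissueMaskConfig:
    """Fast color-thresholding rule for tissue on a white background.

    A pixel is tissue when ``min(R, G, B)`` of the Gaussian-smoothed image
    falls below ``white_threshold``; connected components smaller than
    ``min_object_px`` (at the mask scale) are removed. Pure-white source
    pixels are never marked as tissue regardless of smoothing.
    """

    white_threshold: int = 228
    smooth_sigma: float = 1.0
    min_object_px: int = 100


@dataclass
class TissueMask:
    """Binary tissue raster at a fixed downsample of the base resolution."""

    mask: np.ndarray
    downsample: float
    source_slide_id: str

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def foreground_fraction(self):
        return float(self.mask.mean()) if self.mask.size else 0.0

    def save_png(self, path):
        iio.imwrite(Path(path), self.mask.astype(np.uint8) * 255)

    @classmethod
    def load_png(cls, path, downsample, source_slide_id):
        arr = np.asarray(iio.imread(Path(path)))
        if arr.ndim == 3:
            arr = arr[..., 0]
        return cls(arr > 0, downsample, source_slide_id)


def _cache_path(cache_dir, slide, downsample, cfg):
    key = hashlib.sha1(
        (
            f"{slide.content_digest()}|ds={downsample}|thr={cfg.white_threshold}"
            f"|sig={cfg.smooth_sigma}|min={cfg.min_object_px}"
        ).encode()
    ).hexdigest()[:16]
    return Path(cache_dir) / f"{slide.slide_id}_tissue_{key}.png"


def compute_tissue_mask(slide, downsample=32, config=None, cache_dir=None):
    """Threshold the tissue region of a slide, with a PNG cache.

    The mask has dimensions ``(base_height // downsample,
    base_width // downsample)``. Recomputation on the same slide and config
    is bit-identical; when ``cache_dir`` is given the mask is persisted
    there as a PNG under a content-addressed name and reloaded on
    subsequent calls. An all-background slide yields an empty mask, not an
    error.
    """
    cfg = config or TissueMaskConfig()
    cpath = None
    if cache_dir is not None:
        cpath = _cache_path(cache_dir, slide, downsample, cfg)
        if cpath.exists():
            return TissueMask.load_png(cpath, downsample, slide.slide_id)

    out_w = slide.base_width // downsample
    out_h = slide.base_height // downsample
    rgb = slide.read_region(0, 0, out_w * downsample, out_h * downsample, downsample)
    smoothed = gaussian(
        rgb.astype(np.float64) / 255.0, sigma=cfg.smooth_sigma,
        channel_axis=-1,
    )
    mask = smoothed.min(axis=-1) < cfg.white_threshold / 255.0
    mask &= rgb.min(axis=-1) < _WHITE  # never mark pure-white pixels
    if cfg.min_object_px > 1:
        # drop components with fewer than min_object_px pixels
        mask = remove_small_objects(mask, max_size=cfg.min_object_px - 1)
    tm = TissueMask(mask, float(downsample), slide.slide_id)
    if cpath is not None:
        os.makedirs(cpath.parent, exist_ok=True)
        tm.save_png(cpath)
    return tm
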