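"""Synthetic stained-slide generator used as the package's test fixture.

Emulates the geometry of a brightfield histology scan at desk scale: a white
scanner background, a few smooth pink tissue regions, and colored
elliptical target objects of two or more classes placed fully inside the
tissue. Every generated object carries a ground-truth polygon in
base-resolution coordinates, so the whole train / segment / convert /
evaluate pipeline can run without downloading a real whole-slide image.

Objects are drawn by rasterizing their ground-truth polygon with the same
fill rule the annotation module uses, so drawn pixel counts and rasterized
polygon areas agree by construction (up to the 64-gon approximation of the
ellipse). The same seed always yields bit-identical pixels, annotations and,
when a path is given, a byte-identical pyramidal TIFF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import ellipse as draw_ellipse

from .annotations import AnnotationDocument, Polygon, rasterize
from .slide import SlidePyramid, write_pyramidal_tiff

__all__ = ["ObjectClassSpec", "SyntheticSlideSpec", "generate_synthetic_slide",
           "GenerationError"]


class GenerationError(RuntimeError):
    """Objects could not be placed inside the tissue blobs."""


@dataclass(frozen=True)
class ObjectClassSpec:
    """One target class: `count` ellipses with semiaxes in `size_range` px."""

    name: str
    count: int
    size_range: tuple = (14, 32)
    color: tuple = (120, 70, 160)


@dataclass(frozen=True)
class SyntheticSlideSpec:
    """Recipe for one synthetic slide plus its ground truth.

    Defaults give a 1024 x 1024 px slide, three tissue blobs covering
    roughly half the area, and two color-separable object classes sized
    like downscaled glomeruli / tubular cross-sections.
    """

    base_size: tuple = (1024, 1024)  # (width, height) px
    classes: tuple = (
        ObjectClassSpec("glomerulus", 12, (16, 34), (118, 74, 162)),
        ObjectClassSpec("tubule", 16, (9, 20), (188, 92, 104)),
    )
    tissue_blobs: int = 3
    tissue_color: tuple = (234, 198, 210)
    background_color: tuple = (255, 255, 255)
    color_noise: int = 6
    n_levels: int = 3
    mpp: float = 0.25
    seed: int = 0
    min_separation: int = 4


def _ellipse_polygon(cx, cy, a, b, theta, n_vertices=64):
    phi = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    ex = a * np.cos(phi)
    ey = b * np.sin(phi)
    ct, st = np.cos(theta), np.sin(theta)
    xs = cx + ex * ct - ey * st
    ys = cy + ex * st + ey * ct
    return np.column_stack([xs, ys])


def _downscale2(img):
    h, w = img.shape[0] // 2 * 2, img.shape[1] // 2 * 2
    blocks = img[:h, :w].astype(np.float64).reshape(h // 2, 2, w // 2, 2, 3)
    return np.rint(blocks.mean(axis=(1, 3))).astype(np.uint8)


def generate_synthetic_slide(spec, path=None, max_tries=300):
    """Generate a pyramidal slide and its ground-truth annotations.

    Returns ``(SlidePyramid, AnnotationDocument)``; with ``path`` set the
    pyramid is also written as a tiled multi-resolution TIFF and the
    returned pyramid is backed by that file. Raises
    :class:`GenerationError` if an object cannot be placed fully inside a
    tissue blob (and clear of previously placed objects) after
    ``max_tries`` rejection-sampling attempts.
    """
    rng = np.random.default_rng(spec.seed)
    w, h = spec.base_size
    canvas = np.full((h, w, 3), spec.background_color, dtype=np.float64)

    # tissue blobs: large rotated ellipses
    tissue = np.zeros((h, w), dtype=bool)
    for _ in range(spec.tissue_blobs):
        cy = rng.uniform(0.25 * h, 0.75 * h)
        cx = rng.uniform(0.25 * w, 0.75 * w)
        ry = rng.uniform(0.16, 0.30) * h
        rx = rng.uniform(0.16, 0.30) * w
        theta = rng.uniform(0, np.pi)
        rr, cc = draw_ellipse(cy, cx, ry, rx, shape=(h, w), rotation=theta)
        tissue[rr, cc] = True
    canvas[tissue] = spec.tissue_color

    doc = AnnotationDocument(
        layers={c.name: [] for c in spec.classes},
        slide_id=f"synthetic-{spec.seed}",
        palette={c.name: c.color for c in spec.classes},
    )
    occupied = np.zeros((h, w), dtype=bool)
    sep = spec.min_separation
    for cls in spec.classes:
        lo, hi = cls.size_range
        for _ in range(cls.count):
            placed = False
            for _try in range(max_tries):
                a = rng.uniform(lo, hi)
                b = rng.uniform(lo, hi)
                theta = rng.uniform(0, np.pi)
                r = max(a, b) + 1
                cx = rng.uniform(r, w - r)
                cy = rng.uniform(r, h - r)
                verts = _ellipse_polygon(cx, cy, a, b, theta)
                poly = Polygon(verts, cls.name)
                bx0, by0, bx1, by1 = poly.bbox
                x0, y0 = int(np.floor(bx0)), int(np.floor(by0))
                ww = int(np.ceil(bx1)) - x0 + 1
                hh = int(np.ceil(by1)) - y0 + 1
                probe = AnnotationDocument(layers={cls.name: [poly]})
                sub = rasterize(probe, (x0, y0, ww, hh), 1,
                                {cls.name: 1}) > 0
                win_t = tissue[y0 : y0 + hh, x0 : x0 + ww]
                win_o = occupied[
                    max(y0 - sep, 0) : y0 + hh + sep,
                    max(x0 - sep, 0) : x0 + ww + sep,
                ]
                if win_t.shape != sub.shape:
                    continue
                if not np.all(win_t[sub]):
                    continue  # must lie entirely within a tissue blob
                if win_o.any():
                    continue  # keep objects well separated
                noise = rng.integers(
                    -spec.color_noise, spec.color_noise + 1, (hh, ww, 3)
                )
                region = canvas[y0 : y0 + hh, x0 : x0 + ww]
                region[sub] = np.clip(
                    np.asarray(cls.color, float) + noise, 0, 255
                )[sub]
                occupied[y0 : y0 + hh, x0 : x0 + ww] |= sub
                doc.layers[cls.name].append(poly)
                placed = True
                break
            if not placed:
                raise GenerationError(
                    f"could not place a {cls.name!r} object inside tissue "
                    f"after {max_tries} tries"
                )

    base = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    levels = [base]
    for _ in range(spec.n_levels - 1):
        levels.append(_downscale2(levels[-1]))
    if path is not None:
        write_pyramidal_tiff(path, levels)
    slide = SlidePyramid(levels, slide_id=doc.slide_id, mpp=spec.mpp,
                         path=path)
    return slide, doc
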