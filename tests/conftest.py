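"""Shared fixtures: all test data is generated programmatically."""

import numpy as np
import pytest

from wsiseg import (
    SlidePyramid,
    SyntheticSlideSpec,
    compute_tissue_mask,
    generate_synthetic_slide,
)

TISSUE_DOWNSAMPLE = 8  # mask scale suited to kilopixel fixture slides


@pytest.fixture(scope="session")
def spec():
    return SyntheticSlideSpec(seed=11)


@pytest.fixture(scope="session")
def slide_doc(spec):
    """One 1024 px synthetic slide with ground-truth annotations."""
    return generate_synthetic_slide(spec)


@pytest.fixture(scope="session")
def slide(slide_doc):
    return slide_doc[0]


@pytest.fixture(scope="session")
def doc(slide_doc):
    return slide_doc[1]


@pytest.fixture(scope="session")
def tissue(slide):
    return compute_tissue_mask(slide, TISSUE_DOWNSAMPLE, cache_dir=None)


@pytest.fixture()
def flat_slide():
    """256 px single-level slide entirely covered by mid-gray 'tissue'."""
    base = np.full((256, 256, 3), 180, dtype=np.uint8)
    return SlidePyramid([base], slide_id="flat")


def brute_force_point_in_polygon(vertices, x, y):
    """Independent even-odd ray-casting oracle for one point."""
    inside = False
    n = len(vertices)
    for i in range(n):
        x0, y0 = vertices[i]
        x1, y1 = vertices[(i + 1) % n]
        if (y0 > y) != (y1 > y):
            xi = x0 + (y - y0) * (x1 - x0) / (y1 - y0)
            if x < xi:
                inside = not inside
    return inside


def brute_force_stitch(slide, model, cfg, tissue):
    """Independent stitching accumulator: loop every planned patch, trim in
    patch coordinates, add each logit pixel individually, divide by the
    per-pixel coverage at the end."""
    from wsiseg import plan_grid

    ds = cfg.prediction_downsample
    os_ = model.decoder_output_stride
    W, H = int(slide.base_width / ds), int(slide.base_height / ds)
    out_w, out_h = W // os_, H // os_
    acc = np.zeros((out_h, out_w, model.n_classes))
    cnt = np.zeros((out_h, out_w), int)
    plan = plan_grid(tissue, cfg, slide.dimensions)
    for x, y in plan.origins:
        rgb = slide.read_region(int(x * ds), int(y * ds),
                                int(cfg.patch_size * ds),
                                int(cfg.patch_size * ds), ds)
        logits = model.predict_logits(rgb)
        t_left = cfg.border_trim if x > 0 else 0
        t_top = cfg.border_trim if y > 0 else 0
        t_right = cfg.border_trim if x + cfg.patch_size < W else 0
        t_bot = cfg.border_trim if y + cfg.patch_size < H else 0
        for ly in range(logits.shape[0]):
            py0, py1 = ly * os_, (ly + 1) * os_  # patch-coord footprint
            if py0 < t_top or py1 > cfg.patch_size - t_bot:
                continue
            for lx in range(logits.shape[1]):
                px0, px1 = lx * os_, (lx + 1) * os_
                if px0 < t_left or px1 > cfg.patch_size - t_right:
                    continue
                gy, gx = y // os_ + ly, x // os_ + lx
                if gy >= out_h or gx >= out_w:
                    continue
                acc[gy, gx] += logits[ly, lx]
                cnt[gy, gx] += 1
    out = np.zeros_like(acc)
    out[cnt > 0] = acc[cnt > 0] / cnt[cnt > 0, None]
    return out, cnt


def brute_force_rasterize(doc, region, downsample, class_map):
    """Per-pixel oracle: ray casting at pixel centers, later layers win."""
    x0, y0, w, h = region
    d = float(downsample)
    out_h, out_w = int(round(h / d)), int(round(w / d))
    mask = np.zeros((out_h, out_w), dtype=np.int32)
    for name, polys in doc.layers.items():
        if name not in class_map:
            continue
        for poly in polys:
            for i in range(out_h):
                for j in range(out_w):
                    cx = x0 + (j + 0.5) * d
                    cy = y0 + (i + 0.5) * d
                    if brute_force_point_in_polygon(poly.vertices, cx, cy):
                        mask[i, j] = class_map[name]
    return mask
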