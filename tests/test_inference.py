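"""Grid planning, logit-averaged stitching, mask assembly and exports."""

import numpy as np
import pytest

from wsiseg import (
    ColorPrototypeSegmenter,
    InferenceConfig,
    SlidePyramid,
    TissueMask,
    export_contours,
    export_heatmap,
    plan_grid,
    run_tiled_inference,
    volume_to_mask,
)
from wsiseg.inference import LogitVolume, StitchError, _axis_origins
from wsiseg.segmenter import SegmenterContract

from conftest import brute_force_stitch


class ConstantSegmenter(SegmenterContract):
    """Emits a constant logit vector everywhere; records calls."""

    def __init__(self, values, decoder_output_stride=4):
        self.values = np.asarray(values, float)
        self.n_classes = len(self.values)
        self.decoder_output_stride = decoder_output_stride
        self.calls = []

    def predict_logits(self, patch):
        patch = self._check_input(patch)
        s = self.decoder_output_stride
        self.calls.append(patch.shape)
        out = np.empty((patch.shape[0] // s, patch.shape[1] // s,
                        self.n_classes))
        out[:] = self.values
        return out


class PositionSegmenter(SegmenterContract):
    """Logit 0 = mean patch intensity: distinguishable per patch."""

    n_classes = 2
    decoder_output_stride = 4

    def predict_logits(self, patch):
        patch = self._check_input(patch)
        s = self.decoder_output_stride
        h, w = patch.shape[0] // s, patch.shape[1] // s
        out = np.zeros((h, w, 2))
        out[..., 0] = float(patch.mean())
        out[..., 1] = -float(patch.mean())
        return out


def _full_tissue(side_px, mask_ds=8):
    n = side_px // mask_ds
    return TissueMask(np.ones((n, n), bool), float(mask_ds), "t")


class TestPlanGrid:
    def test_tissue_fitting_one_patch(self):
        tissue = _full_tissue(256)
        cfg = InferenceConfig(patch_size=256, stride=128,
                              prediction_downsample=1, border_trim=16)
        plan = plan_grid(tissue, cfg, slide_dims=(256, 256))
        assert len(plan) == 1 and plan.origins == [(0, 0)]

    def test_empty_mask_gives_empty_plan(self):
        tissue = TissueMask(np.zeros((32, 32), bool), 8.0, "t")
        cfg = InferenceConfig(patch_size=256, stride=128)
        assert len(plan_grid(tissue, cfg, slide_dims=(256, 256))) == 0

    def test_lattice_enumeration_matches_brute_force(self):
        """3000 x 1000 tissue bbox, patch 2000, stride 1000: origins follow
        the clamped stride lattice; plan equals brute-force enumeration."""
        mask = np.zeros((500, 1000), bool)  # mask at ds 8 of an 8000x4000 pred plane
        mask[:125, :375] = True  # tissue bbox 3000 x 1000 at prediction scale
        tissue = TissueMask(mask, 8.0, "t")
        cfg = InferenceConfig(patch_size=2000, stride=1000,
                              prediction_downsample=1)
        plan = plan_grid(tissue, cfg, slide_dims=(8000, 4000))
        expected = []
        for y in _axis_origins(4000, 2000, 1000, cfg.origin_align):
            for x in _axis_origins(8000, 2000, 1000, cfg.origin_align):
                sub = mask[
                    int(np.floor(y / 8)) : int(np.ceil((y + 2000) / 8)),
                    int(np.floor(x / 8)) : int(np.ceil((x + 2000) / 8)),
                ]
                if sub.any():
                    expected.append((x, y))
        assert plan.origins == expected
        assert len(plan) > 1

    def test_every_tissue_pixel_covered(self, tissue, slide):
        cfg = InferenceConfig(patch_size=256, stride=128, border_trim=16)
        plan = plan_grid(tissue, cfg, slide.dimensions)
        ds = cfg.prediction_downsample
        covered = np.zeros_like(tissue.mask)
        ratio = tissue.downsample / ds
        for x, y in plan.origins:
            covered[
                int(np.floor(y / ratio)) : int(np.ceil((y + 256) / ratio)),
                int(np.floor(x / ratio)) : int(np.ceil((x + 256) / ratio)),
            ] = True
        assert np.all(covered[tissue.mask])


class TestStitching:
    def _slide(self, side=512):
        rng = np.random.default_rng(0)
        base = rng.integers(0, 255, (side, side, 3)).astype(np.uint8)
        return SlidePyramid([base], slide_id="s")

    def test_equal_logits_average_to_themselves(self):
        slide = self._slide(256)
        model = ConstantSegmenter([2.5, -1.0])
        cfg = InferenceConfig(patch_size=128, stride=64,
                              prediction_downsample=1, border_trim=0)
        vol = run_tiled_inference(slide, model, cfg, _full_tissue(256),
                                  progress=False)
        assert np.allclose(vol.logits[vol.counts > 0, 0], 2.5)
        assert (vol.counts >= 2).any()  # overlaps existed

    def test_overlap_unweighted_mean(self):
        """Patches emitting mean-intensity logits: overlap = plain mean."""
        slide = self._slide(384)
        model = PositionSegmenter()
        cfg = InferenceConfig(patch_size=256, stride=128,
                              prediction_downsample=1, border_trim=0)
        vol = run_tiled_inference(slide, model, cfg, _full_tissue(384),
                                  progress=False)
        # oracle: accumulate per-pixel from an independent pass
        means = {}
        for x, y in plan_grid(_full_tissue(384), cfg,
                              slide_dims=(384, 384)).origins:
            rgb = slide.read_region(x, y, 256, 256, 1)
            means[(x, y)] = float(rgb.mean())
        oracle = np.zeros(vol.logits.shape[:2])
        count = np.zeros(vol.logits.shape[:2], int)
        for (x, y), m in means.items():
            x0, y0 = x // 4, y // 4
            oracle[y0 : y0 + 64, x0 : x0 + 64] += m
            count[y0 : y0 + 64, x0 : x0 + 64] += 1
        oracle[count > 0] /= count[count > 0]
        assert np.allclose(vol.logits[..., 0], oracle, atol=1e-9)
        assert np.array_equal(vol.counts, count)

    def test_border_trim_oracle_equivalence(self):
        """Tiled stitching equals brute-force per-pixel mean of trimmed
        patch logits (the stitching oracle), including edge suppression."""
        slide = self._slide(512)
        model = PositionSegmenter()
        cfg = InferenceConfig(patch_size=256, stride=128,
                              prediction_downsample=1, border_trim=24)
        tissue = _full_tissue(512)
        vol = run_tiled_inference(slide, model, cfg, tissue, progress=False)
        oracle, counts = brute_force_stitch(slide, model, cfg, tissue)
        assert np.array_equal(vol.counts, counts)
        assert np.max(np.abs(vol.logits - oracle)) <= 1e-6

    def test_trimmed_patch_edge_receives_no_contribution(self):
        """Interior-patch logits within the trim never reach the volume."""
        slide = self._slide(512)
        cfg = InferenceConfig(patch_size=256, stride=128,
                              prediction_downsample=1, border_trim=32)
        model = ConstantSegmenter([1.0])
        vol = run_tiled_inference(slide, model, cfg, _full_tissue(512),
                                  progress=False)
        _, counts = brute_force_stitch(slide, model, cfg, _full_tissue(512))
        assert np.array_equal(vol.counts, counts)

    def test_contract_violation_names_patch(self):
        class Broken(SegmenterContract):
            n_classes = 2
            decoder_output_stride = 4

            def predict_logits(self, patch):
                return np.zeros((3, 3, 2))

        slide = self._slide(256)
        cfg = InferenceConfig(patch_size=128, stride=64,
                              prediction_downsample=1, border_trim=0)
        with pytest.raises(StitchError, match=r"\(0, 0\)"):
            run_tiled_inference(slide, Broken(), cfg, _full_tissue(256),
                                progress=False)


class TestMaskAndExports:
    def test_default_scales_give_one_eighth_mask(self, slide, tissue):
        """Prediction downsample 2 x decoder stride 4 -> mask = base / 8."""
        model = ConstantSegmenter([0.0, 1.0])
        cfg = InferenceConfig(patch_size=256, stride=128, border_trim=16)
        vol = run_tiled_inference(slide, model, cfg, tissue, progress=False)
        assert vol.scale_factor == 8.0
        mask, scale = volume_to_mask(vol)
        assert mask.shape == (slide.base_height // 8, slide.base_width // 8)
        assert scale == 8.0

    def test_single_class_volume_uniform_mask(self):
        vol = LogitVolume(np.zeros((8, 8, 1)), np.ones((8, 8), int), 8.0)
        mask, _ = volume_to_mask(vol)
        assert np.all(mask == 0)

    def test_tie_breaks_to_lower_class_index(self):
        logits = np.zeros((4, 4, 3))
        vol = LogitVolume(logits, np.ones((4, 4), int), 8.0)
        mask, _ = volume_to_mask(vol)
        assert np.all(mask == 0)
        logits2 = logits.copy()
        logits2[..., 1] = 5.0
        logits2[..., 2] = 5.0
        mask2, _ = volume_to_mask(LogitVolume(logits2, np.ones((4, 4), int),
                                              8.0))
        assert np.all(mask2 == 1)

    def test_uncovered_pixels_are_background(self):
        logits = np.full((4, 4, 2), -1.0)
        logits[..., 1] = 3.0  # argmax would be class 1 everywhere
        counts = np.zeros((4, 4), int)
        counts[0, 0] = 1
        mask, _ = volume_to_mask(LogitVolume(logits, counts, 8.0))
        assert mask[0, 0] == 1
        assert mask.sum() == 1

    def test_export_contours_upsamples_coordinates(self):
        mask = np.zeros((64, 64), int)
        mask[10:20, 30:40] = 1  # 10 x 10 blob at scale 8
        doc = export_contours(mask, 8.0, {"glomerulus": 1})
        (poly,) = doc.layers["glomerulus"]
        bx0, by0, bx1, by1 = poly.bbox
        assert bx1 - bx0 == pytest.approx(80, abs=8)
        assert by1 - by0 == pytest.approx(80, abs=8)
        assert bx0 == pytest.approx(240, abs=8)

    def test_export_contours_empty_mask(self):
        doc = export_contours(np.zeros((16, 16), int), 8.0)
        assert doc.n_polygons() == 0

    def test_heatmap_threshold_zero_keeps_whole_tissue_region(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(size=(16, 16, 3))
        counts = (rng.random((16, 16)) < 0.6).astype(int)
        vol = LogitVolume(logits, counts, 8.0)
        hm = export_heatmap(vol, 1, "glomerulus", threshold=0.0)
        assert len(hm.points) == int((counts > 0).sum())
        assert np.all((hm.points[:, 2] >= 0) & (hm.points[:, 2] <= 1))
        # coordinates are up-sampled by the scale factor
        assert hm.points[:, 0].max() <= 16 * 8

    def test_heatmap_unknown_class_raises(self):
        vol = LogitVolume(np.zeros((4, 4, 2)), np.ones((4, 4), int), 8.0)
        with pytest.raises(ValueError, match="unknown class"):
            export_heatmap(vol, 5)

    def test_heatmap_threshold_drops_low_probability(self):
        logits = np.zeros((4, 4, 2))
        logits[:2, :, 1] = 4.0  # prob ~0.98 in the top half, 0.5 below
        vol = LogitVolume(logits, np.ones((4, 4), int), 8.0)
        hm = export_heatmap(vol, 1, threshold=0.6)
        assert len(hm.points) == 8


def test_end_to_end_color_oracle_object_recall(slide_doc, spec, tissue):
    """Color-prototype segmentation recovers every well-separated object
    with no spurious detections (object-level precision = recall = 1)."""
    import shapely

    slide, doc = slide_doc
    protos = [[spec.tissue_color, spec.background_color]] + [
        [c.color] for c in spec.classes
    ]
    model = ColorPrototypeSegmenter(protos)
    cfg = InferenceConfig(patch_size=256, stride=128, border_trim=16)
    vol = run_tiled_inference(slide, model, cfg, tissue, progress=False)
    mask, scale = volume_to_mask(vol)
    cm = {c.name: i + 1 for i, c in enumerate(spec.classes)}
    pred = export_contours(mask, scale, cm, slide.slide_id)
    for name in cm:
        gts = [p.to_shapely() for p in doc.layers[name]]
        preds = [p.to_shapely() for p in pred.layers.get(name, [])]
        assert len(preds) == len(gts)
        matched = 0
        for g in gts:
            best = max(
                (g.intersection(q).area / g.union(q).area for q in preds),
                default=0.0,
            )
            if best >= 0.5:
                matched += 1
        assert matched == len(gts)
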