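"""Synthetic spine phantom: geometry truth, deformities, texture, mock detector."""

import numpy as np
import pytest

from spinemorph.errors import InvalidInputError, SizingError
from spinemorph.morphometry import VertebraMask, measure_heights
from spinemorph.phantom import (
    DeformityClass,
    PhantomSpec,
    apply_low_density_texture,
    cohort_spec,
    generate_spine,
    mock_detector,
    plan_truth,
    render_intensity,
    uniform_hlr_plan,
)


def column_heights_px(mask):
    """Independent oracle: per-column foreground pixel extents at the three
    Genant column centers (15/50/85% of the anterior-posterior extent)."""
    cols = np.flatnonzero(mask.any(axis=0))
    x0, x1 = cols[0], cols[-1]
    out = []
    for f in (0.15, 0.50, 0.85):
        x = int(round(x0 + f * (x1 - x0)))
        rows = np.flatnonzero(mask[:, x])
        out.append(rows[-1] - rows[0] + 1)
    return out


class TestGenerateSpine:
    def test_undeformed_posterior_column_height_matches_spec(self):
        spec = PhantomSpec(n_vertebrae=1, base_posterior_height_mm=15.0)
        labels, truth = generate_spine(spec)
        ha, hm, hp = column_heights_px(labels == 1)
        assert hp == 15
        assert truth.vertebrae[0].hlr == 0.0

    def test_wedge_truth_heights(self, wedge_phantom):
        labels, truth = wedge_phantom
        v = truth.vertebrae[0]
        assert v.ha_mm == pytest.approx(10.0)
        assert v.hp_mm == pytest.approx(15.0)
        assert v.hlr == pytest.approx(1.0 / 3.0)
        assert v.fractured

    def test_crush_reduces_all_columns_but_hlr_stays_zero(self):
        spec = PhantomSpec(
            n_vertebrae=5,
            deformity_plan=((2, DeformityClass.CRUSH, 0.30),),
        )
        labels, truth = generate_spine(spec)
        ha, hm, hp = column_heights_px(labels == 3)
        assert ha == hm == hp
        assert hp == pytest.approx(0.7 * 25, abs=1.0)
        v = truth.vertebrae[2]
        assert v.fractured and v.hlr == 0.0
        # measured Genant HLR misses the uniform collapse entirely
        vm = VertebraMask(labels == 3, (1.0, 1.0))
        mha, mhm, mhp = measure_heights(vm)
        assert max(0.0, 1 - min(mha, mhm) / mhp) < 0.05

    def test_labels_are_consecutive_and_boxes_disjoint(self, five_vertebra_phantom):
        labels, truth = five_vertebra_phantom
        assert sorted(np.unique(labels)) == [0, 1, 2, 3, 4, 5]
        boxes = [v.box_px for v in truth.vertebrae]
        for (_, _, _, y1), (_, y0b, _, _) in zip(boxes, boxes[1:]):
            assert y1 < y0b  # non-overlapping along the spine axis

    def test_fixed_seed_bit_identical(self):
        spec = cohort_spec(n_fractured=5, n_normal=20, seed=42)
        a, _ = generate_spine(spec)
        b, _ = generate_spine(spec)
        assert np.array_equal(a, b)

    def test_round_trip_heights_within_one_pixel(self):
        spec = PhantomSpec(n_vertebrae=3, base_posterior_height_mm=(18.0, 24.0, 30.0))
        labels, truth = generate_spine(spec)
        for v in truth.vertebrae:
            vm = VertebraMask(labels == v.label_id, truth.pixel_spacing_mm, v.name)
            ha, hm, hp = measure_heights(vm)
            assert abs(ha - v.ha_mm) <= 1.0
            assert abs(hm - v.hm_mm) <= 1.0
            assert abs(hp - v.hp_mm) <= 1.0

    def test_too_small_raster_names_offending_vertebra(self):
        with pytest.raises(SizingError, match="vertebra 0"):
            generate_spine(
                PhantomSpec(n_vertebrae=1, base_posterior_height_mm=2.0,
                            pixel_spacing_mm=(1.0, 1.0))
            )
        with pytest.raises(SizingError):
            generate_spine(PhantomSpec(body_width_mm=3.0))

    def test_invalid_plans_rejected(self):
        with pytest.raises(InvalidInputError):
            PhantomSpec(deformity_plan=((9, DeformityClass.WEDGE, 0.3),))
        with pytest.raises(InvalidInputError):
            PhantomSpec(
                deformity_plan=(
                    (1, DeformityClass.WEDGE, 0.3),
                    (1, DeformityClass.CRUSH, 0.2),
                )
            )
        with pytest.raises(InvalidInputError):
            PhantomSpec(deformity_plan=((0, DeformityClass.WEDGE, 1.2),))

    def test_plan_truth_matches_rasterized_truth(self):
        spec = cohort_spec(n_fractured=4, n_normal=12, seed=5)
        planned = plan_truth(spec)
        _, rasterized = generate_spine(spec)
        assert planned.image_shape == rasterized.image_shape
        for p, r in zip(planned.vertebrae, rasterized.vertebrae):
            assert p.hlr == pytest.approx(r.hlr)
            assert p.fractured == r.fractured


class TestLowDensityTexture:
    def test_zero_range_is_identity(self, wedge_phantom):
        labels, _ = wedge_phantom
        img = render_intensity(labels)
        out = apply_low_density_texture(img, labels > 0, (0.0, 0.0), seed=1)
        assert np.array_equal(out, img)

    def test_fixed_seed_reproducible(self, wedge_phantom):
        labels, _ = wedge_phantom
        img = render_intensity(labels)
        a = apply_low_density_texture(img, labels > 0, (100, 300), seed=9)
        b = apply_low_density_texture(img, labels > 0, (100, 300), seed=9)
        assert np.array_equal(a, b)

    def test_interior_darkens_rim_unchanged(self, wedge_phantom):
        from scipy import ndimage

        labels, _ = wedge_phantom
        mask = labels > 0
        img = render_intensity(labels)
        out = apply_low_density_texture(img, mask, (100, 300), seed=2, erosion_px=2)
        interior = ndimage.binary_erosion(mask, iterations=2)
        rim = mask & ~interior
        assert out[interior].mean() < img[interior].mean()
        assert np.array_equal(out[rim], img[rim])

    def test_empty_interior_warns_and_noops(self):
        img = np.full((6, 6), 100.0)
        mask = np.zeros((6, 6), dtype=bool)
        mask[3, 3] = True
        with pytest.warns(UserWarning):
            out = apply_low_density_texture(img, mask, (10, 20), seed=0, erosion_px=2)
        assert np.array_equal(out, img)


class TestMockDetector:
    def test_degenerate_targets_separate_perfectly(self):
        from spinemorph.pipeline import score_phantom

        spec = cohort_spec(n_fractured=10, n_normal=40, seed=8)
        truth = plan_truth(spec)
        scores = score_phantom(truth, sens_target=1.0, spec_target=1.0, seed=8)
        for v in truth.vertebrae:
            conf = scores[v.label_id].dl_confidence
            assert (conf >= 0.5) == v.fractured

    def test_calibration_at_scale(self):
        # 1000-vertebra phantom: empirical sensitivity at the 0.5 threshold
        # within +/-0.04 of the 0.83 target (binomial SE ~ 0.012 at n=1000)
        spec = cohort_spec(n_fractured=1000, n_normal=1000, seed=21)
        truth = plan_truth(spec)
        boxes = mock_detector(truth, sens_target=0.83, spec_target=0.96, seed=21)
        from spinemorph.detect_io import match_boxes

        scores, _ = match_boxes(boxes, truth.boxes_normalized())
        by_id = {s.vertebra_id: s.dl_confidence for s in scores}
        frac = [v.label_id for v in truth.vertebrae if v.fractured]
        norm = [v.label_id for v in truth.vertebrae if not v.fractured]
        sens = np.mean([by_id[i] >= 0.5 for i in frac])
        spc = np.mean([by_id[i] < 0.5 for i in norm])
        assert sens == pytest.approx(0.83, abs=0.04)
        assert spc == pytest.approx(0.96, abs=0.04)

    def test_same_seed_identical_scores(self):
        spec = cohort_spec(n_fractured=5, n_normal=20, seed=3)
        truth = plan_truth(spec)
        a = mock_detector(truth, 0.8, 0.95, seed=4)
        b = mock_detector(truth, 0.8, 0.95, seed=4)
        assert a == b

    def test_uniform_hlr_plan_covers_all_vertebrae(self):
        plan = uniform_hlr_plan(10, seed=0)
        assert sorted(p[0] for p in plan) == list(range(10))
        assert all(0.0 <= p[2] < 0.5 for p in plan)
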