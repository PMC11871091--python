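import numpy as np
import pytest

from hipseg.imaging_io import CTImage, LabelMask
from hipseg.quantify import (
    ahu,
    marrow_ratios,
    quantify_subject,
    select_reference_slice,
    tissue_area,
    tissue_volume,
)


def mask2d(classes, spacing=(1.0, 1.0), thickness=3.0):
    return LabelMask(np.asarray(classes, dtype=np.uint8), spacing, thickness)


class TestTissueArea:
    def test_unit_conversion(self):
        grid = np.zeros((20, 20), dtype=np.uint8)
        grid[:10, :10] = 5  # 100 pixels at 1x1 mm = 1 cm2
        assert tissue_area(mask2d(grid), 5) == pytest.approx(1.0)

    def test_empty_class_zero(self):
        assert tissue_area(mask2d(np.zeros((4, 4), dtype=np.uint8)), 3) == 0.0

    def test_scales_with_spacing_squared(self):
        grid = np.zeros((10, 10), dtype=np.uint8)
        grid[:5, :5] = 1
        a1 = tissue_area(mask2d(grid, spacing=(1.0, 1.0)), 1)
        a2 = tissue_area(mask2d(grid, spacing=(2.0, 2.0)), 1)
        assert a2 == pytest.approx(4.0 * a1)

    def test_rasterized_disc_near_analytic(self):
        # radius 20 mm at 0.5 mm pixels -> pi * 4 cm2
        n, r_mm, sp = 120, 20.0, 0.5
        rr, cc = np.ogrid[:n, :n]
        disc = ((rr - n / 2) ** 2 + (cc - n / 2) ** 2) * sp**2 <= r_mm**2
        grid = np.where(disc, 5, 0).astype(np.uint8)
        area = tissue_area(mask2d(grid, spacing=(sp, sp)), 5)
        assert area == pytest.approx(np.pi * 4.0, rel=0.02)


class TestTissueVolume:
    def test_constant_stack(self):
        # 10 cm2 per slice x 5 slices x 0.3 cm = 15 cm3
        sl = np.zeros((40, 40), dtype=np.uint8)
        sl[:25, :40] = 5  # 1000 px = 10 cm2
        stack = LabelMask(np.stack([sl] * 5), (1.0, 1.0), 3.0)
        assert tissue_volume(stack, 5) == pytest.approx(15.0)

    def test_zero_area_class(self):
        stack = LabelMask(np.zeros((5, 8, 8), dtype=np.uint8), (1.0, 1.0), 3.0)
        assert tissue_volume(stack, 4) == 0.0

    def test_varying_areas_match_bruteforce(self, rng):
        slices = rng.integers(0, 3, size=(5, 16, 16)).astype(np.uint8)
        stack = LabelMask(slices, (1.0, 1.0), 3.0)
        expected = sum(int((slices[k] == 1).sum()) / 100.0 for k in range(5)) * 0.3
        assert tissue_volume(stack, 1) == pytest.approx(expected)

    def test_window_exceeding_stack_raises(self):
        stack = LabelMask(np.zeros((3, 8, 8), dtype=np.uint8), (1.0, 1.0), 3.0)
        with pytest.raises(ValueError, match="window"):
            tissue_volume(stack, 1)


class TestAHU:
    def test_uniform_region(self):
        img = CTImage(np.full((8, 8), 50.0))
        grid = np.full((8, 8), 5, dtype=np.uint8)
        mean, per_h2 = ahu(img, mask2d(grid), 5)
        assert mean == pytest.approx(50.0)
        assert per_h2 is None

    def test_height_adjustment(self):
        img = CTImage(np.full((8, 8), 50.0))
        grid = np.full((8, 8), 5, dtype=np.uint8)
        _, per_h2 = ahu(img, mask2d(grid), 5, height_m=1.7)
        assert per_h2 == pytest.approx(50.0 / 2.89)

    def test_mixture_matches_weighted_mean(self, rng):
        vals = rng.normal(50, 10, size=(16, 16))
        grid = (rng.random((16, 16)) < 0.4).astype(np.uint8) * 5
        sel = grid == 5
        expected = vals[sel].sum() / sel.sum()
        mean, _ = ahu(CTImage(vals), mask2d(grid), 5)
        assert mean == pytest.approx(expected)

    def test_empty_class_raises(self):
        with pytest.raises(ValueError, match="empty"):
            ahu(CTImage(np.zeros((4, 4))), mask2d(np.zeros((4, 4), dtype=np.uint8)), 5)


class TestMarrowRatios:
    def test_known_ratio(self):
        grid = np.zeros((10, 10), dtype=np.uint8)
        grid[:6, :10] = 3  # HBM 60 px
        grid[6:8, :10] = 4  # MAT 20 px
        hbm, mat = marrow_ratios(mask2d(grid))
        assert hbm == pytest.approx(0.75)
        assert mat == pytest.approx(0.25)

    def test_all_hbm(self):
        grid = np.full((4, 4), 3, dtype=np.uint8)
        assert marrow_ratios(mask2d(grid)) == (1.0, 0.0)

    def test_empty_tbm_flagged(self):
        assert marrow_ratios(mask2d(np.zeros((4, 4), dtype=np.uint8))) == (None, None)

    def test_complements_sum_to_one(self, rng):
        for _ in range(50):
            grid = rng.integers(0, 8, size=(12, 12)).astype(np.uint8)
            hbm, mat = marrow_ratios(mask2d(grid))
            if hbm is not None:
                assert hbm + mat == pytest.approx(1.0, abs=1e-12)


class TestReferenceSlice:
    def _stack_with_peak(self, peak):
        slices = []
        for k in range(5):
            sl = np.zeros((16, 16), dtype=np.uint8)
            extent = 2 + 3 * (2 - abs(k - peak)) if abs(k - peak) <= 2 else 1
            sl[4 : 4 + extent, 10:14] = 1  # bone in the image-right half
            slices.append(sl)
        return LabelMask(np.stack(slices), (1.0, 1.0), 3.0)

    def test_peak_at_center(self):
        assert select_reference_slice(None, self._stack_with_peak(2)) == 2

    def test_constant_stack_ties_to_inferior(self):
        sl = np.zeros((16, 16), dtype=np.uint8)
        sl[4:8, 10:14] = 2
        stack = LabelMask(np.stack([sl] * 5), (1.0, 1.0), 3.0)
        assert select_reference_slice(None, stack) == 4

    def test_matches_bruteforce_argmax(self, rng):
        slices = (rng.random((7, 16, 16)) < 0.2).astype(np.uint8)
        stack = LabelMask(slices, (1.0, 1.0), 3.0)
        counts = [int(np.isin(slices[k][:, 8:], (1, 2)).sum()) for k in range(7)]
        expected = max(i for i, c in enumerate(counts) if c == max(counts))
        assert select_reference_slice(None, stack) == expected

    def test_no_bone_raises(self):
        stack = LabelMask(np.zeros((3, 8, 8), dtype=np.uint8), (1.0, 1.0), 3.0)
        with pytest.raises(ValueError, match="bone"):
            select_reference_slice(None, stack)


class TestQuantifySubject:
    def test_phantom_areas_match_label_counts(self, clean_sample):
        report = quantify_subject(
            clean_sample.image, clean_sample.labels, "S0000", height_m=clean_sample.height_m
        )
        ref = report.reference_index
        sp = clean_sample.labels.pixel_spacing
        for code in range(1, 8):
            n = int((clean_sample.labels.classes[ref] == code).sum())
            assert report.area_cm2[code] == pytest.approx(n * sp[0] * sp[1] / 100.0)

    def test_volume_of_constant_shape_stack(self, clean_config):
        from hipseg.phantom import generate_phantom
        import dataclasses

        cfg = dataclasses.replace(clean_config)
        s = generate_phantom(cfg, "S0042")
        report = quantify_subject(s.image, s.labels, "S0042")
        # SAT geometry is constant across slices -> volume = area x 5 x 0.3 cm
        assert report.volume_cm3[7] == pytest.approx(report.area_cm2[7] * 5 * 0.3)

    def test_ratios_sum_to_one(self, clean_sample):
        report = quantify_subject(clean_sample.image, clean_sample.labels, "S0000")
        assert report.hbm_over_tbm + report.mat_over_tbm == pytest.approx(1.0)
        assert report.tbm_area_cm2 == pytest.approx(
            report.area_cm2[3] + report.area_cm2[4]
        )

    def test_ahu_muscle_close_to_configured_mean(self, noisy_sample):
        report = quantify_subject(noisy_sample.image, noisy_sample.labels, "S0000")
        assert report.ahu_muscle == pytest.approx(50.0, abs=2.0)
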