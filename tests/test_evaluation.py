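import numpy as np
import pytest

from hipseg.evaluation import (
    OracleModel,
    aggregate,
    assd,
    cross_domain_eval,
    dsc,
    plan_cv,
    run_cv,
    sensitivity_specificity,
)
from hipseg.phantom import PhantomConfig, generate_cohort


# ---------------------------------------------------------------------------
# independent oracles (naive pixel loops / all-pairs distances)
# ---------------------------------------------------------------------------


def dsc_oracle(a, b, code):
    na = nb = inter = 0
    for x, y in zip(a.ravel(), b.ravel()):
        na += x == code
        nb += y == code
        inter += (x == code) and (y == code)
    if na + nb == 0:
        return None
    return 100.0 * 2.0 * inter / (na + nb)


def confusion_oracle(truth, pred, code):
    tp = fn = tn = fp = 0
    for t, p in zip(truth.ravel(), pred.ravel()):
        if t == code and p == code:
            tp += 1
        elif t == code:
            fn += 1
        elif p == code:
            fp += 1
        else:
            tn += 1
    sens = 100.0 * tp / (tp + fn) if tp + fn else None
    spec = 100.0 * tn / (tn + fp) if tn + fp else None
    return sens, spec


def boundary_oracle(mask):
    h, w = mask.shape
    pts = []
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            neighbors = []
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ii, jj = i + di, j + dj
                neighbors.append(mask[ii, jj] if 0 <= ii < h and 0 <= jj < w else False)
            if not all(neighbors):
                pts.append((i, j))
    return pts


def assd_oracle(a, b, code, spacing=(1.0, 1.0)):
    pa = boundary_oracle(a == code)
    pb = boundary_oracle(b == code)
    if not pa or not pb:
        return None

    def directed(src, dst):
        total = 0.0
        for i, j in src:
            best = min(
                np.hypot((i - ii) * spacing[0], (j - jj) * spacing[1]) for ii, jj in dst
            )
            total += best
        return total / len(src)

    return (directed(pa, pb) + directed(pb, pa)) / 2.0


def random_mask_pair(rng, size=16, n_classes=4):
    a = rng.integers(0, n_classes, size=(size, size)).astype(np.uint8)
    b = rng.integers(0, n_classes, size=(size, size)).astype(np.uint8)
    return a, b


# ---------------------------------------------------------------------------
# metric tests
# ---------------------------------------------------------------------------


class TestDSC:
    def test_identical_masks_100(self, rng):
        m = (rng.random((10, 10)) > 0.5).astype(np.uint8)
        m[0, 0] = 1
        assert dsc(m, m.copy(), 1) == 100.0

    def test_half_overlap(self):
        a = np.zeros((4, 4), dtype=np.uint8)
        b = np.zeros((4, 4), dtype=np.uint8)
        a[0, :4] = 1  # |A| = 4
        b[0, 2:4] = 1
        b[1, 0:2] = 1  # |B| = 4, overlap 2
        assert dsc(a, b, 1) == pytest.approx(50.0)

    def test_both_empty_undefined(self):
        z = np.zeros((4, 4), dtype=np.uint8)
        assert dsc(z, z, 3) is None

    def test_matches_oracle_exactly(self, rng):
        for _ in range(40):
            a, b = random_mask_pair(rng)
            for code in range(4):
                assert dsc(a, b, code) == dsc_oracle(a, b, code)

    def test_symmetry(self, rng):
        for _ in range(20):
            a, b = random_mask_pair(rng)
            assert dsc(a, b, 1) == dsc(b, a, 1)

    def test_bounded_by_100(self, rng):
        for _ in range(20):
            a, b = random_mask_pair(rng)
            v = dsc(a, b, 1)
            assert v is None or 0.0 <= v <= 100.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dsc(np.zeros((3, 3), dtype=np.uint8), np.zeros((4, 4), dtype=np.uint8), 1)


class TestASSD:
    def test_identical_masks_zero(self):
        m = np.zeros((8, 8), dtype=np.uint8)
        m[2:5, 2:5] = 1
        assert assd(m, m.copy(), 1) == 0.0

    def test_two_single_pixels(self):
        a = np.zeros((8, 8), dtype=np.uint8)
        b = np.zeros((8, 8), dtype=np.uint8)
        a[4, 1] = 1
        b[4, 4] = 1
        assert assd(a, b, 1, spacing=(1.0, 1.0)) == pytest.approx(3.0)

    def test_spacing_scales_distances(self):
        a = np.zeros((8, 8), dtype=np.uint8)
        b = np.zeros((8, 8), dtype=np.uint8)
        a[4, 1] = 1
        b[4, 4] = 1
        assert assd(a, b, 1, spacing=(1.0, 2.0)) == pytest.approx(6.0)

    def test_class_absent_undefined(self):
        m = np.zeros((4, 4), dtype=np.uint8)
        n = np.ones((4, 4), dtype=np.uint8)
        assert assd(m, n, 1) is None

    def test_matches_all_pairs_oracle(self, rng):
        for _ in range(25):
            a, b = random_mask_pair(rng, size=12, n_classes=3)
            for code in (1, 2):
                expected = assd_oracle(a, b, code)
                got = assd(a, b, code)
                if expected is None:
                    assert got is None
                else:
                    assert got == pytest.approx(expected, abs=1e-9)

    def test_symmetric(self, rng):
        for _ in range(10):
            a, b = random_mask_pair(rng, size=12)
            va, vb = assd(a, b, 1), assd(b, a, 1)
            if va is not None:
                assert va == pytest.approx(vb, abs=1e-12)


class TestSensitivitySpecificity:
    def test_perfect_prediction(self, rng):
        m = rng.integers(0, 3, size=(10, 10)).astype(np.uint8)
        for code in range(3):
            sens, spec = sensitivity_specificity(m, m.copy(), code)
            assert sens == 100.0 and spec == 100.0

    def test_known_counts(self):
        truth = np.zeros((1, 10), dtype=np.uint8)
        truth[0, :10] = 1  # 10 positives
        pred = np.zeros((1, 10), dtype=np.uint8)
        pred[0, :8] = 1  # TP=8, FN=2
        sens, spec = sensitivity_specificity(truth, pred, 1)
        assert sens == pytest.approx(80.0)
        assert spec is None  # no true negatives exist

    def test_matches_confusion_oracle(self, rng):
        for _ in range(40):
            a, b = random_mask_pair(rng)
            for code in range(4):
                assert sensitivity_specificity(a, b, code) == confusion_oracle(a, b, code)

    def test_asymmetric(self, rng):
        # sensitivity(truth, pred) generally != sensitivity(pred, truth)
        asym = 0
        for _ in range(20):
            a, b = random_mask_pair(rng)
            if sensitivity_specificity(a, b, 1)[0] != sensitivity_specificity(b, a, 1)[0]:
                asym += 1
        assert asym > 0


class TestAggregation:
    def test_undefined_excluded_and_flagged(self):
        per_image = {
            "a": {1: {"dsc": 80.0}},
            "b": {1: {"dsc": None}},
            "c": {1: {"dsc": 90.0}},
        }
        rep = aggregate(per_image)
        mean, sd, n = rep.summary[1]["dsc"]
        assert n == 2 and mean == pytest.approx(85.0) and sd == pytest.approx(5.0)
        assert ("b", 1, "dsc") in rep.undefined

    def test_counts_match_inputs(self, rng):
        per_image = {f"s{i}": {1: {"dsc": float(rng.uniform(0, 100))}} for i in range(7)}
        rep = aggregate(per_image)
        assert rep.summary[1]["dsc"][2] == 7


class TestCVPlan:
    def test_k10_on_100_subjects(self):
        ids = [f"S{i:04d}" for i in range(100)]
        plan = plan_cv(ids, k=10, seed=3)
        plan.validate()
        sizes = [len(plan.fold_subjects(f)) for f in range(10)]
        assert sizes == [10] * 10
        held_out = [s for f in range(10) for s in plan.fold_subjects(f)]
        assert sorted(held_out) == sorted(ids)  # each subject exactly once

    def test_k2_on_4(self):
        plan = plan_cv(["a", "b", "c", "d"], k=2, seed=0)
        assert sorted(len(plan.fold_subjects(f)) for f in range(2)) == [2, 2]

    def test_k_exceeds_n(self):
        with pytest.raises(ValueError):
            plan_cv(["a", "b"], k=3)

    def test_seed_reproducible(self):
        ids = [f"S{i}" for i in range(13)]
        assert plan_cv(ids, k=4, seed=9).assignment == plan_cv(ids, k=4, seed=9).assignment
        assert plan_cv(ids, k=4, seed=9).assignment != plan_cv(ids, k=4, seed=10).assignment


@pytest.fixture(scope="module")
def small_cohort():
    cfg = PhantomConfig(image_size=64, n_slices=1, noise_sigma=5.0, seed=5)
    return generate_cohort(cfg, 12)


class TestRunCV:
    def test_oracle_model_scores_100(self, small_cohort):
        pooled, folds, plan = run_cv(
            small_cohort, k=3, model_factory=OracleModel, with_assd=False, seed=0
        )
        assert len(folds) == 3
        for code in range(1, 8):
            mean, sd, n = pooled.summary[code]["dsc"]
            assert mean == 100.0 and sd == 0.0
        assert pooled.mean_dsc() == 100.0

    def test_every_subject_tested_once(self, small_cohort):
        _, _, plan = run_cv(small_cohort, k=4, model_factory=OracleModel, with_assd=False, seed=1)
        tested = [s for f in range(4) for s in plan.fold_subjects(f)]
        assert sorted(tested) == sorted(s.subject_id for s in small_cohort)


class TestCrossDomain:
    def test_report_structure_and_zero_shift(self):
        cfg = PhantomConfig(image_size=64, n_slices=1, noise_sigma=5.0, seed=6)
        from hipseg.phantom import DomainShift

        cfg = PhantomConfig(
            image_size=64, n_slices=1, noise_sigma=5.0, seed=6,
            domain_shift=DomainShift(hu_offset=0.0),
        )
        samples = generate_cohort(cfg, 8, domains=["A", "B"])
        result = cross_domain_eval(OracleModel(), samples, with_assd=False)
        assert set(result["reports"]) == {"A", "B"}
        for dom in ("A", "B"):
            assert result["reports"][dom].mean_dsc() == 100.0
        for code, delta in result["dsc_delta_vs_A"]["B"].items():
            assert delta == pytest.approx(0.0)

    def test_single_domain_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="two domains"):
            cross_domain_eval(OracleModel(), small_cohort)
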