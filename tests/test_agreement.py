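import numpy as np
import pytest
from scipy import stats

from conftest import make_mask

from edemaquant import (
    bland_altman,
    bland_altman_power,
    overlap_indices,
    paired_location_test,
    spearman_rho,
    summarize_grades,
)
from edemaquant.image_io import GridError


class TestBlandAltman:
    def test_identical_methods_collapse(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        with pytest.warns(UserWarning, match="zero variance"):
            ba = bland_altman(x, x)
        assert ba.bias == 0.0
        assert ba.loa_lower == ba.loa_upper == 0.0

    def test_hand_computed_triplet(self):
        """d = {-1, 0, 1}: bias 0, sd 1, LoA [-1.96, 1.96]."""
        ba = bland_altman(np.array([-1.0, 0.0, 1.0]), np.zeros(3))
        assert ba.bias == pytest.approx(0.0)
        assert ba.sd_diff == pytest.approx(1.0)
        assert ba.loa_lower == pytest.approx(-1.96)
        assert ba.loa_upper == pytest.approx(1.96)

    def test_large_cohort_recovery(self):
        """With bias -104 ml and SD 1040/1.96, LoA approach [-1144, 936]."""
        rng = np.random.default_rng(12345)
        n = 100_000
        sd = 1040.0 / 1.96
        d = rng.normal(-104.0, sd, n)
        ba = bland_altman(d, np.zeros(n))
        assert ba.bias == pytest.approx(-104.0, abs=3 * sd / np.sqrt(n))
        assert ba.loa_lower == pytest.approx(-1144.0, abs=15.0)
        assert ba.loa_upper == pytest.approx(936.0, abs=15.0)

    def test_loa_symmetry_invariant(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=(2, 40))
        ba = bland_altman(x, y)
        assert (ba.loa_lower + ba.loa_upper) / 2 == pytest.approx(ba.bias, rel=1e-12)
        assert ba.loa_upper - ba.bias == pytest.approx(1.96 * ba.sd_diff, rel=1e-12)

    def test_bias_ci_covers_truth(self):
        rng = np.random.default_rng(5)
        d = rng.normal(50.0, 10.0, 200)
        ba = bland_altman(d, np.zeros(200))
        assert ba.ci_bias[0] < 50.0 < ba.ci_bias[1]
        assert ba.ci_loa_lower[0] < ba.loa_lower < ba.ci_loa_lower[1]

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="3"):
            bland_altman([1.0, 2.0], [0.0, 0.0])

    def test_recovery_across_seeds(self):
        """bias and SD estimates stay within 3 standard errors of the truth
        in nearly all of 100 simulated cohorts."""
        n, bias, sd = 145, -104.0, 530.0
        se_bias = sd / np.sqrt(n)
        se_sd = sd / np.sqrt(2 * (n - 1))
        ok = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            d = rng.normal(bias, sd, n)
            ba = bland_altman(d, np.zeros(n))
            if abs(ba.bias - bias) < 3 * se_bias and abs(ba.sd_diff - sd) < 3 * se_sd:
                ok += 1
        assert ok >= 99


class TestSpearman:
    def test_monotone_limits(self):
        x = np.arange(10.0)
        assert spearman_rho(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert spearman_rho(x, -(x**3))[0] == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        """No ties: 1 - 6*sum(d^2)/(n(n^2-1)) with sum d^2 = 4 gives 0.8."""
        rho, _ = spearman_rho([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert rho == pytest.approx(1 - 24 / 120)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_matches_rank_then_pearson_oracle(self):
        """Average-rank + product-moment correlation, brute force."""
        rng = np.random.default_rng(77)
        for _ in range(300):
            n = int(rng.integers(4, 9))
            x = rng.integers(0, 5, n).astype(float)  # ties likely
            y = rng.integers(0, 5, n).astype(float)
            if np.unique(x).size == 1 or np.unique(y).size == 1:
                continue
            rx, ry = stats.rankdata(x), stats.rankdata(y)
            oracle = np.corrcoef(rx, ry)[0, 1]
            assert spearman_rho(x, y)[0] == pytest.approx(oracle, abs=1e-12)


class TestOverlap:
    def test_identical_masks(self):
        m = make_mask(np.pad(np.ones((2, 2, 2)), 1))
        res = overlap_indices(m, m)
        assert res.jaccard == 1.0 and res.dice == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4)); a[0] = 1
        b = np.zeros((4, 4, 4)); b[2] = 1
        res = overlap_indices(make_mask(a), make_mask(b))
        assert res.jaccard == 0.0 and res.dice == 0.0

    def test_counting_example(self):
        """|a|=|b|=100, overlap 80: Jaccard 80/120, Dice 0.8."""
        a = np.zeros((10, 10, 10)); b = np.zeros((10, 10, 10))
        a.ravel()[:100] = 1
        b.ravel()[20:120] = 1
        res = overlap_indices(make_mask(a), make_mask(b))
        assert res.intersection_voxels == 80 and res.union_voxels == 120
        assert res.jaccard == pytest.approx(2 / 3)
        assert res.dice == pytest.approx(0.8)

    def test_dice_jaccard_identity(self):
        """dice = 2J/(1+J) on random mask pairs, and J <= dice."""
        rng = np.random.default_rng(4)
        for _ in range(50):
            a = make_mask(rng.random((6, 6, 6)) > 0.5)
            b = make_mask(rng.random((6, 6, 6)) > 0.5)
            res = overlap_indices(a, b)
            assert res.dice == pytest.approx(2 * res.jaccard / (1 + res.jaccard), rel=1e-12)
            assert res.jaccard <= res.dice + 1e-15

    def test_both_empty_defined_as_one(self):
        e = make_mask(np.zeros((3, 3, 3)))
        with pytest.warns(UserWarning, match="empty"):
            res = overlap_indices(e, e)
        assert res.jaccard == res.dice == 1.0

    def test_incompatible_grids_rejected(self):
        with pytest.raises(GridError):
            overlap_indices(make_mask(np.ones((3, 3, 3))), make_mask(np.ones((3, 3, 4))))


class TestGradeSummary:
    def test_cohort_tallies(self):
        grades = [1] * 97 + [2] * 29 + [3] * 19
        s = summarize_grades(grades, n_expected=145)
        assert s.counts == {1: 97, 2: 29, 3: 19}
        assert s.percentages == {1: 67, 2: 20, 3: 13}
        assert sum(s.fractions.values()) == pytest.approx(1.0)

    def test_degenerate_single_grade(self):
        s = summarize_grades([1] * 10)
        assert s.percentages == {1: 100, 2: 0, 3: 0}

    def test_uniform_thirds(self):
        s = summarize_grades([1, 2, 3])
        assert s.percentages == {1: 33, 2: 33, 3: 33}
        assert s.fractions[1] == pytest.approx(1 / 3)

    def test_out_of_range_grade_rejected(self):
        with pytest.raises(ValueError, match="1,2,3"):
            summarize_grades([1, 4])


class TestPairedLocationTest:
    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="degenerate"):
            paired_location_test(x, x, method="t")
        _, p = paired_location_test(x, x, method="wilcoxon")
        assert p == 1.0

    def test_constant_shift_detected(self):
        """A deterministic nonzero shift is rejected with certainty; adding
        noise gives vanishing p at this n."""
        rng = np.random.default_rng(8)
        y = rng.normal(size=30)
        t, p = paired_location_test(y + 5.0, y, method="t")
        assert np.isinf(t) and p == 0.0
        _, p = paired_location_test(y + 5.0 + rng.normal(0, 0.5, 30), y, method="t")
        assert p < 1e-10

    def test_empirical_power_matches_noncentral_t(self):
        """Monte-Carlo power of the paired t test against the closed form."""
        n, shift, sd, reps, alpha = 145, 100.0, 500.0, 400, 0.05
        rng = np.random.default_rng(99)
        hits = 0
        for _ in range(reps):
            d = rng.normal(shift, sd, n)
            _, p = paired_location_test(d, np.zeros(n), method="t")
            hits += p < alpha
        ncp = shift / (sd / np.sqrt(n))
        tcrit = stats.t.ppf(1 - alpha / 2, n - 1)
        power = 1 - stats.nct.cdf(tcrit, n - 1, ncp) + stats.nct.cdf(-tcrit, n - 1, ncp)
        assert hits / reps == pytest.approx(power, abs=3 * np.sqrt(power * (1 - power) / reps))


class TestBlandAltmanPower:
    def test_vacuous_criterion(self):
        p = bland_altman_power(20, 0.0, 1.0, 1e9, reps=100, seed=0)
        assert p == 1.0

    def test_impossible_criterion(self):
        with pytest.warns(UserWarning, match="near zero"):
            p = bland_altman_power(20, 50.0, 10.0, 30.0, reps=100, seed=0)
        assert p == 0.0

    def test_seed_deterministic_and_reasonable(self):
        """The study-design inputs (n=145, 30 +/- 290 ml, limit 700 ml)
        give a reproducible, high power estimate."""
        p1 = bland_altman_power(145, 30.0, 290.0, 700.0, reps=400, seed=1)
        p2 = bland_altman_power(145, 30.0, 290.0, 700.0, reps=400, seed=1)
        assert p1 == p2
        assert 0.0 <= p1 <= 1.0
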