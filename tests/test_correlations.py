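"""Correlation battery: oracles, degenerate cases, and null calibration."""

import numpy as np
import pytest
from scipy import stats

from exonedge.correlations import (
    compare_dependent_correlations,
    distribution_shift_test,
    partial_spearman,
    proportion_shift_test,
    spearman,
)


def hand_spearman(x, y):
    """Average-rank rho computed from first principles."""
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    rx, ry = rx - rx.mean(), ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


class TestSpearman:
    def test_perfect_correlations(self):
        r = spearman(np.array([1, 2, 3]), np.array([3, 2, 1]))
        assert r.rho == pytest.approx(-1.0)
        assert spearman(np.arange(5), np.arange(5)).rho == pytest.approx(1.0)

    def test_ties_match_hand_ranking(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 5.0, 7.0, 8.0, 9.0])
        y = np.array([2.0, 1.0, 4.0, 4.0, 4.0, 6.0, 8.0, 7.0, 9.0, 9.0])
        r = spearman(x, y)
        assert r.rho == pytest.approx(hand_spearman(x, y))
        assert r.n == 10

    def test_nan_pairs_dropped(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        y = np.array([1.0, 2.0, 3.0, 4.0, np.nan])
        assert spearman(x, y).n == 3

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman(np.ones(5), np.arange(5))


class TestPartialSpearman:
    def test_identical_variables(self, rng):
        x = rng.normal(size=30)
        z = rng.normal(size=30)
        assert partial_spearman(x, x, z).rho == pytest.approx(1.0)

    def test_orthogonal_control_equals_plain(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        z = np.array([3.0, 1.0, 4.0, 2.0])  # rank-orthogonal to x
        r_partial = partial_spearman(x, x.copy(), z)
        r_plain = spearman(x, x.copy())
        assert r_partial.rho == pytest.approx(r_plain.rho)

    def test_shared_driver_removed(self, rng):
        z = np.linspace(0, 1, 200)
        x = z**2 + 0.02 * rng.normal(size=200)     # near-monotone in z
        y = np.exp(z) + 0.05 * rng.normal(size=200)
        assert spearman(x, y).rho > 0.9
        r = partial_spearman(x, y, z)
        assert abs(r.rho) < 0.35

    def test_independent_control_leaves_rho(self, rng):
        n = 2000
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        z = rng.normal(size=n)
        plain = spearman(x, y).rho
        part = partial_spearman(x, y, z).rho
        assert abs(plain - part) < 0.05

    def test_degenerate_control_rejected(self):
        x = np.arange(6.0)
        with pytest.raises(ValueError):
            partial_spearman(x, x[::-1].copy(), x.copy())


class TestDependentComparison:
    def test_equal_correlations_null(self):
        r = compare_dependent_correlations(0.4, 0.4, 0.5, 50)
        assert r.t_stat == 0.0 and r.p == 1.0
        assert r.df == 47

    def test_fisher_z_internal(self):
        assert np.arctanh(0.5) == pytest.approx(0.5493, abs=1e-4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            compare_dependent_correlations(1.0, 0.2, 0.3, 30)

    def test_null_calibration(self, rng):
        """Two noisy copies of one statistic vs a covariate: ~5% rejections."""
        n, reps, hits = 80, 400, 0
        for _ in range(reps):
            latent = rng.normal(size=n)
            x = 0.5 * latent + rng.normal(size=n)
            a = latent + 0.8 * rng.normal(size=n)
            b = latent + 0.8 * rng.normal(size=n)
            ra = spearman(x, a).rho
            rb = spearman(x, b).rho
            rab = spearman(a, b).rho
            hits += compare_dependent_correlations(ra, rb, rab, n).p < 0.05
        rate = hits / reps
        # binomial 95% band around 0.05 at 400 replicates, plus slack for
        # the Spearman-vs-Pearson variance mismatch of the z transform
        assert 0.01 <= rate <= 0.10


class TestProportionShift:
    def test_no_shift_is_zero(self):
        r = proportion_shift_test(10, 10, 100)
        assert r.chi2 == pytest.approx(0.0)

    def test_textbook_value(self):
        r = proportion_shift_test(10, 30, 100)
        assert r.chi2 == pytest.approx(12.5)
        assert r.p == pytest.approx(stats.chi2.sf(12.5, 1))

    def test_zero_margin_not_applicable(self):
        assert not proportion_shift_test(0, 0, 50).applicable

    def test_matches_scipy_contingency(self):
        r = proportion_shift_test(7, 19, 120)
        chi2, p, _, _ = stats.chi2_contingency(
            [[7, 113], [19, 101]], correction=False
        )
        assert r.chi2 == pytest.approx(chi2)
        assert r.p == pytest.approx(p)


class TestDistributionShift:
    def test_identical_groups_degenerate(self):
        h, p = distribution_shift_test([np.ones(5), np.ones(6)])
        assert h == 0.0 and p == 1.0

    def test_disjoint_ranges(self):
        h, p = distribution_shift_test([np.arange(20), np.arange(100, 120)])
        assert p < 0.001

    def test_three_group_hand_computation(self):
        groups = [np.array([1.0, 3.0, 5.0]), np.array([2.0, 4.0, 6.0]),
                  np.array([7.0, 8.0, 9.0])]
        flat = np.concatenate(groups)
        ranks = stats.rankdata(flat)
        n = flat.size
        start, h = 0, 0.0
        for g in groups:
            r = ranks[start : start + g.size]
            h += g.size * (r.mean() - (n + 1) / 2) ** 2
            start += g.size
        h *= 12 / (n * (n + 1))  # no ties in this toy
        got_h, _ = distribution_shift_test(groups)
        assert got_h == pytest.approx(h)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            distribution_shift_test([np.array([1.0]), np.array([2.0, 3.0])])
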