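"""Permutation ANOVA, bootstrap CIs and variance components against
independent oracles (exhaustive enumeration, closed forms, scipy)."""

from itertools import permutations

import numpy as np
import pytest
from scipy import stats

from aquatherm.errors import DesignError, ParameterError, SampleSizeError
from aquatherm.resampling import (
    PermutationSpec,
    bootstrap_ci,
    factorial_permutation,
    permutation_anova,
    variance_explained,
)


def one_way_f(values, codes, k):
    """Plain one-way F, the deterministic part of the pseudo-F."""
    values = np.asarray(values, float)
    grand = values.mean()
    ssb = sum(
        (codes == g).sum() * (values[codes == g].mean() - grand) ** 2
        for g in range(k)
    )
    ssw = sum(((values[codes == g] - values[codes == g].mean()) ** 2).sum()
              for g in range(k))
    return (ssb / (k - 1)) / (ssw / (len(values) - k))


def exhaustive_p(values, codes, k):
    """Fraction of all distinct label arrangements with F >= observed."""
    obs = one_way_f(values, codes, k)
    seen, count, total = set(), 0, 0
    for perm in permutations(range(len(values))):
        arrangement = tuple(codes[list(perm)])
        if arrangement in seen:
            continue
        seen.add(arrangement)
        total += 1
        if one_way_f(values, np.array(arrangement), k) >= obs - 1e-12:
            count += 1
    return count / total


class TestPermutationAnova:
    def test_identical_group_means_p_near_one(self):
        v = np.r_[np.arange(10.0), np.arange(10.0)]
        g = ["a"] * 10 + ["b"] * 10
        res = permutation_anova(v, g, PermutationSpec(n_perm=999, seed=0))
        assert res.p_value > 0.5
        assert res.observed == pytest.approx(0.0, abs=1e-12)

    def test_matches_exhaustive_enumeration(self):
        v = np.array([1.0, 2.0, 101.0, 102.0])
        g = np.array(["a", "a", "b", "b"])
        truth = exhaustive_p(v, np.array([0, 0, 1, 1]), 2)  # = 2/6
        assert truth == pytest.approx(1 / 3)
        res = permutation_anova(v, g, PermutationSpec(n_perm=4999, seed=1))
        # sampled add-one p agrees with enumeration within binomial MC error
        se = np.sqrt(truth * (1 - truth) / 4999)
        assert res.p_value == pytest.approx(truth, abs=4 * se + 1e-3)

    def test_exhaustive_agreement_on_random_small_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            n = int(rng.integers(6, 9))
            codes = np.array([0] * (n // 2) + [1] * (n - n // 2))
            v = rng.normal(size=n)
            truth = exhaustive_p(v, codes, 2)
            g = np.where(codes == 0, "a", "b")
            res = permutation_anova(v, g, PermutationSpec(n_perm=2999, seed=int(rng.integers(1000))))
            se = np.sqrt(truth * (1 - truth) / 2999)
            assert res.p_value == pytest.approx(truth, abs=4 * se + 2e-3)

    def test_default_n_perm_is_9999(self):
        assert PermutationSpec().n_perm == 9999

    def test_add_one_rule_bounds(self):
        v = np.array([0.0, 0.1, 10.0, 10.1])
        res = permutation_anova(v, ["a", "a", "b", "b"], PermutationSpec(n_perm=99, seed=0))
        assert 0 < res.p_value <= 1
        assert res.p_value >= 1 / 100  # add-one floor

    def test_individual_unit_collapses_repeated_measures(self):
        # two records per individual; group signal only between individuals
        v = np.array([1.0, 1.0, 2.0, 2.0, 11.0, 11.0, 12.0, 12.0])
        g = ["a"] * 4 + ["b"] * 4
        ind = ["i1", "i1", "i2", "i2", "i3", "i3", "i4", "i4"]
        res = permutation_anova(
            v, g, PermutationSpec(n_perm=999, seed=0, unit="individual"),
            individuals=ind,
        )
        assert res.df_between == 1 and res.df_within == 2  # 4 individuals, 2 groups

    def test_small_group_rejected(self):
        with pytest.raises(DesignError):
            permutation_anova([1.0, 2.0, 3.0], ["a", "b", "b"], PermutationSpec(n_perm=9))

    def test_type_one_error_controlled(self):
        # 500 null datasets, alpha 0.05, n_perm 499
        rng = np.random.default_rng(123)
        rejections = 0
        for _ in range(500):
            v = rng.normal(size=16)
            g = ["a"] * 8 + ["b"] * 8
            res = permutation_anova(
                v, g, PermutationSpec(n_perm=499, seed=int(rng.integers(2**31 - 1)))
            )
            rejections += res.p_value <= 0.05
        assert rejections / 500 == pytest.approx(0.05, abs=0.02)


class TestFactorial:
    def simulate(self, seed, interaction=0.0, n_rep=4):
        rng = np.random.default_rng(seed)
        rows = []
        for a in range(2):
            for b in range(4):
                for _ in range(n_rep):
                    y = 0.5 * a + 0.3 * b + interaction * a * b + rng.normal()
                    rows.append((y, f"A{a}", f"B{b}"))
        y, fa, fb = zip(*rows)
        return np.array(y), np.array(fa), np.array(fb)

    def test_null_interaction_type_one_control(self):
        rng = np.random.default_rng(42)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            y, fa, fb = self.simulate(int(rng.integers(2**31 - 1)))
            res = factorial_permutation(
                y, fa, fb, PermutationSpec(n_perm=199, seed=int(rng.integers(2**31 - 1)))
            )
            rejections += res["interaction"].p_value <= 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.04)

    def test_strong_interaction_detected(self):
        y, fa, fb = self.simulate(0, interaction=3.0, n_rep=6)
        res = factorial_permutation(y, fa, fb, PermutationSpec(n_perm=999, seed=5))
        assert res["interaction"].p_value < 0.05

    def test_main_effect_detected(self):
        y, fa, fb = self.simulate(1, n_rep=8)
        y = y + 5.0 * (fa == "A1")
        res = factorial_permutation(y, fa, fb, PermutationSpec(n_perm=999, seed=6))
        assert res["a"].p_value < 0.05

    def test_single_factor_delegates_to_one_way(self):
        y = np.array([1.0, 2.0, 11.0, 12.0])
        res = factorial_permutation(
            y, ["a", "a", "b", "b"], None,
            PermutationSpec(n_perm=99, seed=0, unit="record"),
        )
        assert set(res) == {"a"} and res["a"].statistic_name == "pseudo-F"

    def test_empty_cell_rejected(self):
        y = np.arange(6.0)
        fa = ["A0", "A0", "A0", "A1", "A1", "A1"]
        fb = ["B0", "B0", "B1", "B0", "B0", "B0"]  # (A1, B1) empty
        with pytest.raises(DesignError):
            factorial_permutation(y, fa, fb, PermutationSpec(n_perm=9))


class TestBootstrap:
    def test_constant_vector_degenerate_interval(self):
        ci = bootstrap_ci([5.0] * 10, n_boot=200, seed=0)
        assert ci.lower == ci.point == ci.upper == 5.0

    def test_matches_analytic_normal_interval(self):
        rng = np.random.default_rng(8)
        x = rng.normal(10.0, 2.0, size=10000)
        ci = bootstrap_ci(x, n_boot=2000, seed=9)
        se = x.std(ddof=1) / np.sqrt(len(x))
        assert ci.lower == pytest.approx(x.mean() - 1.96 * se, abs=0.6 * se)
        assert ci.upper == pytest.approx(x.mean() + 1.96 * se, abs=0.6 * se)

    def test_seed_determinism(self):
        x = np.random.default_rng(1).normal(size=50)
        a = bootstrap_ci(x, n_boot=500, seed=77)
        b = bootstrap_ci(x, n_boot=500, seed=77)
        assert (a.lower, a.upper) == (b.lower, b.upper)

    def test_custom_statistic(self):
        x = np.arange(1.0, 101.0)
        ci = bootstrap_ci(x, statistic=np.median, n_boot=500, seed=3)
        assert ci.point == pytest.approx(np.median(x))
        assert ci.lower <= ci.point <= ci.upper

    def test_too_few_values(self):
        with pytest.raises(SampleSizeError):
            bootstrap_ci([1.0])

    def test_coverage_of_normal_mean(self):
        # 500 replicates of n=30 samples; 95% interval should cover ~95%
        rng = np.random.default_rng(321)
        covered = 0
        for _ in range(500):
            x = rng.normal(0.0, 1.0, size=30)
            ci = bootstrap_ci(x, n_boot=999, seed=int(rng.integers(2**31 - 1)))
            covered += ci.lower <= 0.0 <= ci.upper
        assert covered / 500 == pytest.approx(0.95, abs=0.03)


class TestVarianceExplained:
    def test_between_only_variation_is_total(self):
        vc = variance_explained([1, 1, 1, 5, 5, 5], ["a"] * 3 + ["b"] * 3)
        assert vc.pct_between_individuals == pytest.approx(100.0)

    def test_degenerate_zero_variance_flagged(self):
        vc = variance_explained([2.0] * 6, ["a"] * 3 + ["b"] * 3)
        assert vc.undefined and np.isnan(vc.pct_between_individuals)

    def test_hand_decomposition_fifty_percent(self):
        vc = variance_explained([0.0, 2.0, 2.0, 4.0], ["a", "a", "b", "b"])
        assert vc.pct_between_individuals == pytest.approx(50.0)
        assert vc.ss_between == pytest.approx(4.0)
        assert vc.ss_total == pytest.approx(8.0)

    def test_single_individual_rejected(self):
        with pytest.raises(DesignError):
            variance_explained([1.0, 2.0], ["a", "a"])

    def test_agrees_with_scipy_f_oneway_decomposition(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=40) + np.repeat(rng.normal(size=8), 5)
        ids = np.repeat([f"i{j}" for j in range(8)], 5)
        vc = variance_explained(vals, ids)
        groups = [vals[ids == f"i{j}"] for j in range(8)]
        f, _ = stats.f_oneway(*groups)
        # convert scipy's F back to an SSB/SST share
        dfb, dfw = 7, 32
        share = (f * dfb) / (f * dfb + dfw) * 100
        assert vc.pct_between_individuals == pytest.approx(share)
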