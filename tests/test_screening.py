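"""Assay statistics: DoS, proportion tests, stability, responsiveness,
Z', hit calling, and the group-comparison battery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from meascreen.screening import (
    assess_stability,
    call_hits,
    compare_groups,
    dos,
    log_spike_count,
    percent_responsive,
    prop_test,
    responsiveness,
    zprime,
)


class TestDos:
    def test_symmetry_and_arithmetic(self):
        assert dos(2, 2) == 0.0
        assert dos(1, 3) == pytest.approx(0.5)

    def test_mfr_reduction_example(self):
        # gap-junction blocker means: 1.61 Hz pre, 1.24 Hz post
        assert dos(1.61, 1.24) == pytest.approx(-0.130, abs=5e-4)

    def test_undefined_at_double_zero(self):
        assert np.isnan(dos(0.0, 0.0))

    @given(
        pre=st.floats(0, 1e6, allow_nan=False),
        post=st.floats(0, 1e6, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_antisymmetric_and_bounded(self, pre, post):
        if pre + post == 0:
            return
        v = dos(pre, post)
        assert -1.0 <= v <= 1.0
        assert v == pytest.approx(-dos(post, pre), abs=1e-12)


class TestPropTest:
    def test_equal_proportions(self):
        z, p = prop_test(10, 64, 10, 64)
        assert z == 0.0
        assert p == 1.0

    def test_large_difference_significant(self):
        _, p = prop_test(22, 64, 3, 64)
        assert p < 0.001

    @pytest.mark.parametrize(
        "x1,n1,x2,n2",
        [(0, 10, 10, 10), (5, 20, 15, 20), (30, 100, 45, 120), (1, 8, 7, 9)],
    )
    def test_matches_chi_square_oracle(self, x1, n1, x2, n2):
        z, p = prop_test(x1, n1, x2, n2)
        table = np.array([[x1, n1 - x1], [x2, n2 - x2]])
        chi2, p_chi, _, _ = stats.chi2_contingency(table, correction=False)
        assert z**2 == pytest.approx(chi2, abs=1e-9)
        assert p == pytest.approx(p_chi, abs=1e-6)

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError):
            prop_test(0, 0, 1, 10)


class TestStability:
    def test_identical_recordings_stable(self):
        wmfr = np.array([1.0, 2.0, 3.0, 4.0])
        v = assess_stability(
            [(100, 128)] * 3, [wmfr, wmfr.copy(), wmfr.copy()]
        )
        assert v.stable
        assert all(p == 1.0 for p in v.prop_p_values)
        assert v.kw_p_value == 1.0

    def test_aey_jump_unstable(self):
        v = assess_stability(
            [(int(0.9 * 768), 768), (int(0.3 * 768), 768), (int(0.3 * 768), 768)],
            [np.ones(48)] * 3,
        )
        assert not v.stable

    def test_same_distribution_usually_stable(self):
        rng = np.random.default_rng(0)
        stable = 0
        n_rep = 40
        for _ in range(n_rep):
            counts = [(int(rng.binomial(768, 0.9)), 768) for _ in range(3)]
            wmfrs = [rng.lognormal(1.0, 0.3, 48) for _ in range(3)]
            if assess_stability(counts, wmfrs).stable:
                stable += 1
        # 4 tests at alpha 0.05 each: joint pass rate ~0.82+; demand >= 60%
        assert stable / n_rep >= 0.6

    def test_mismatched_sets_rejected(self):
        with pytest.raises(ValueError, match="mismatched"):
            assess_stability(
                [(10, 64), (10, 128), (10, 64)], [np.ones(4)] * 3
            )

    def test_requires_three(self):
        with pytest.raises(ValueError, match="3"):
            assess_stability([(1, 10)] * 2, [np.ones(3)] * 2)


class TestResponsiveness:
    def test_boundary_inclusive(self):
        base = np.sort(np.concatenate(
            [np.linspace(i * 30 + 1, i * 30 + 29, 10) for i in range(10)]
        ))
        treat = np.sort(np.concatenate(
            [np.linspace(1, 29, 20)]  # one bin with exactly 2x
            + [np.linspace(i * 30 + 1, i * 30 + 29, 10) for i in range(1, 10)]
        ))
        assert responsiveness(base, treat, 300.0, 300.0)

    def test_below_double_not_responsive(self):
        base = np.sort(np.concatenate(
            [np.linspace(i * 30 + 1, i * 30 + 29, 10) for i in range(10)]
        ))
        treat = np.sort(np.concatenate(
            [np.linspace(1, 29, 19)]
            + [np.linspace(i * 30 + 1, i * 30 + 29, 10) for i in range(1, 10)]
        ))
        assert not responsiveness(base, treat, 300.0, 300.0)

    def test_null_rate_matches_binned_poisson_oracle(self):
        # chemical mode false-positive rate on unchanged Poisson firing
        rng = np.random.default_rng(1)
        lam = 3.0 * 30
        flags = []
        for _ in range(400):
            base = np.sort(rng.uniform(0, 300, rng.poisson(lam * 10)))
            treat = np.sort(rng.uniform(0, 300, rng.poisson(lam * 10)))
            flags.append(responsiveness(base, treat, 300.0, 300.0))
        measured = np.mean(flags)
        oracle = []
        for _ in range(4000):
            base_mean = rng.poisson(lam, 10).mean()
            treat_bins = rng.poisson(lam, 10)
            oracle.append(treat_bins.max() >= 2 * max(base_mean, 1.0))
        expected = np.mean(oracle)
        se = np.sqrt(max(expected * (1 - expected), 1e-4) / 400)
        assert abs(measured - expected) <= max(3 * se, 0.02)

    def test_percent_over_group(self):
        silent = np.empty(0)
        burst = np.sort(np.random.default_rng(2).uniform(0, 30, 200))
        pairs = [(silent, burst), (silent, silent)]
        assert percent_responsive(pairs, 300.0, 300.0) == 50.0

    def test_zero_length_epoch_rejected(self):
        with pytest.raises(ValueError, match="bin"):
            responsiveness(np.empty(0), np.empty(0), 10.0, 10.0)


class TestZprime:
    def test_perfect_separation(self):
        assert zprime([1.0, 1.0, 1.0], [4.0, 4.0, 4.0]) == 1.0

    def test_closed_form_example(self):
        # arms with mu/sd (2.0, 0.2) and (4.1, 0.67): 1 - 3*0.87/2.1
        rng = np.random.default_rng(3)
        low = 2.0 + 0.2 * rng.standard_normal(100000)
        high = 4.1 + 0.67 * rng.standard_normal(100000)
        v = zprime(low, high)
        assert v == pytest.approx(1 - 3 * (0.2 + 0.67) / 2.1, abs=0.01)
        assert v == pytest.approx(-0.243, abs=0.02)

    def test_monotone_decreasing_in_sd(self):
        rng = np.random.default_rng(4)
        vals = []
        for sd in (0.1, 0.2, 0.4):
            low = 2.0 + sd * rng.standard_normal(5000)
            high = 4.0 + 0.1 * rng.standard_normal(5000)
            vals.append(zprime(low, high))
        assert vals[0] > vals[1] > vals[2]

    def test_arm_swap_invariance(self):
        rng = np.random.default_rng(5)
        low = 2.0 + 0.2 * rng.standard_normal(50)
        high = 4.0 + 0.3 * rng.standard_normal(50)
        assert zprime(low, high) == pytest.approx(zprime(high, low))

    def test_never_exceeds_one(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            low = rng.normal(2, 0.5, 8)
            high = rng.normal(4, 0.5, 8)
            assert zprime(low, high) <= 1.0

    def test_equal_means_flagged(self):
        assert zprime([1.0, 1.0], [1.0, 1.0]) == float("-inf")

    def test_monte_carlo_at_true_056(self):
        # Arms designed for true Z' = 0.56 (Delta = 2.1 dex, sigma
        # 0.154/arm): mean estimate at n=4 wells/arm over 100 seeds
        # within +-0.1.
        delta, sig = 2.1, 0.44 * 2.1 / 6.0
        true_z = 1 - 3 * (2 * sig) / delta
        assert true_z == pytest.approx(0.56)
        ests = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            low = 2.0 + sig * rng.standard_normal(4)
            high = 2.0 + delta + sig * rng.standard_normal(4)
            ests.append(zprime(low, high))
        assert abs(np.mean(ests) - 0.56) <= 0.1


class TestHitCalling:
    def test_at_reference_not_a_hit(self):
        table, _ = call_hits(np.array([4.0, 4.1, 4.2]), {"c": 4.1})
        assert not table.iloc[0]["hit"]

    def test_arithmetic_example(self):
        # reference median 4.1, MAD 0.1 -> 3x MAD band is +-0.3
        table, thr = call_hits(np.array([4.0, 4.1, 4.2]), {"c": 3.7})
        assert thr.median_ref == pytest.approx(4.1)
        assert thr.mad_ref == pytest.approx(0.1)
        row = table.iloc[0]
        assert row["hit"]
        assert row["direction"] == "down"

    def test_vehicle_like_compound_within_wide_band(self):
        # vehicle at 4.2 vs baseline centered 4.1 with MAD ~0.45: n.s.
        rng = np.random.default_rng(7)
        ref = 4.1 + 0.67 * rng.standard_normal(200)
        table, thr = call_hits(ref, {"vehicle": 4.2})
        assert thr.mad_ref == pytest.approx(0.45, abs=0.08)
        assert not table.iloc[0]["hit"]

    def test_translation_invariance_exact(self):
        rng = np.random.default_rng(8)
        ref = rng.normal(4, 0.2, 24)
        means = {f"c{i}": rng.normal(4, 0.5) for i in range(10)}
        t1, _ = call_hits(ref, means)
        shifted = {k: v + 1.75 for k, v in means.items()}
        t2, _ = call_hits(ref + 1.75, shifted)
        assert list(t1["hit"]) == list(t2["hit"])
        assert list(t1["direction"]) == list(t2["direction"])

    def test_false_hit_rate_matches_monte_carlo_oracle(self):
        # Null compounds (4-well means from the reference Gaussian):
        # empirical false-hit rate vs direct Monte-Carlo of the 3xMAD
        # rule, within binomial error.
        rng = np.random.default_rng(9)
        n_ref, n_wells, n_trials = 24, 4, 800
        hits = 0
        for _ in range(n_trials):
            ref = rng.standard_normal(n_ref)
            mean = rng.standard_normal(n_wells).mean()
            med = np.median(ref)
            mad = np.median(np.abs(ref - med))
            hits += abs(mean - med) > 3 * mad
        oracle_rate = hits / n_trials

        rng = np.random.default_rng(10)
        flagged = total = 0
        for _ in range(n_trials):
            ref = rng.standard_normal(n_ref)
            means = {"null": rng.standard_normal(n_wells).mean()}
            table, _ = call_hits(ref, means)
            flagged += int(table.iloc[0]["hit"])
            total += 1
        rate = flagged / total
        se = np.sqrt(max(oracle_rate * (1 - oracle_rate), 1e-3) / n_trials)
        assert abs(rate - oracle_rate) <= 4 * se

    def test_zero_mad_rejected(self):
        with pytest.raises(ValueError, match="MAD"):
            call_hits(np.array([4.0, 4.0, 4.0]), {"c": 3.0})

    def test_log_spike_count_definition(self):
        assert log_spike_count(0) == 0.0
        assert log_spike_count(9999) == pytest.approx(4.0, abs=1e-4)


class TestCompareGroups:
    def test_identical_groups_p_one(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        rep = compare_groups({"a": g, "b": g.copy(), "c": g.copy()})
        assert rep["p_value"] == 1.0
        assert not rep["significant"]

    def test_separated_gaussians_significant(self):
        rng = np.random.default_rng(11)
        wins = 0
        for _ in range(40):
            a = rng.normal(0, 1, 8)
            b = rng.normal(3, 1, 8)
            rep = compare_groups({"a": a, "b": b})
            wins += rep["significant"]
        assert wins / 40 >= 0.95

    def test_heavy_tails_select_nonparametric(self):
        rng = np.random.default_rng(12)
        nonpar = 0
        for _ in range(30):
            a = rng.standard_cauchy(12)
            b = rng.standard_cauchy(12) + 1
            rep = compare_groups({"a": a, "b": b})
            nonpar += rep["test"] == "kruskal-wallis"
        assert nonpar / 30 > 0.5

    def test_constant_group_forces_nonparametric(self):
        rep = compare_groups(
            {"a": np.array([1.0, 1.0, 1.0]), "b": np.array([1.0, 2.0, 3.0])}
        )
        assert rep["test"] == "kruskal-wallis"

    def test_posthoc_table_present(self):
        rng = np.random.default_rng(13)
        rep = compare_groups(
            {g: rng.normal(i, 1, 10) for i, g in enumerate("abc")}
        )
        assert len(rep["posthoc"]) == 3
        assert {"group_a", "group_b", "p_adj"} <= set(rep["posthoc"].columns)
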