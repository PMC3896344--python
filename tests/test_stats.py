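"""Mann-Whitney/BH machinery against enumeration and library oracles, and
the comparison pipeline on constructed synthetic cohorts."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from spikedwt import (RunConfig, SignificanceConfig, SyntheticCohort,
                      bh_adjusted, biphasic_profile, compare_coefficients,
                      excited_profile, fdr_bh, mann_whitney_u, marginal_tier,
                      merge_intervals, shuffle_control, simulate_cohort,
                      significant_duration, with_tail)
from spikedwt.pipeline import trial_power_maps


def exact_mwu_p(x, y):
    """Brute-force enumeration oracle: two-sided p over all C(n, nx)
    assignments of the pooled ranks (tie-free data only)."""
    pooled = np.concatenate([x, y])
    ranks = pooled.argsort().argsort() + 1
    nx = len(x)
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    us = np.array([sum(c) - nx * (nx + 1) / 2
                   for c in itertools.combinations(ranks, nx)])
    p = 2 * min(np.mean(us <= u_obs), np.mean(us >= u_obs))
    return min(p, 1.0)


class TestMannWhitney:
    def test_fully_separated_small_samples(self):
        # 20 arrangements of C(6,3); U=0 is one extreme tail
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_samples_degenerate(self):
        u, p = mann_whitney_u([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == 1.0
        assert u == 4.5

    @pytest.mark.parametrize("nx, ny", [(3, 5), (4, 4), (8, 8), (2, 7)])
    def test_matches_enumeration_oracle(self, nx, ny):
        rng = np.random.default_rng(nx * 100 + ny)
        for _ in range(5):
            x = rng.normal(size=nx)
            y = rng.normal(0.5, size=ny)
            _, p = mann_whitney_u(x, y)
            assert p == pytest.approx(exact_mwu_p(x, y), abs=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestFDR:
    def test_hand_worked_step_up(self):
        res = fdr_bh([0.01, 0.02, 0.06, 0.9], q=0.1)
        assert res.n_rejected == 3 and res.crit_p == 0.06
        np.testing.assert_array_equal(res.rejected, [True, True, True, False])

    def test_nothing_significant(self):
        res = fdr_bh([1.0, 1.0, 1.0], q=0.1)
        assert res.n_rejected == 0 and res.crit_p == 0.0

    def test_single_p_reduces_to_raw_threshold(self):
        res = fdr_bh([0.04], q=0.05)
        assert res.n_rejected == 1 and res.crit_p == 0.04

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([], q=0.1)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_statsmodels_bh(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(2, 200)) ** rng.uniform(0.5, 3)
        q = rng.uniform(0.01, 0.3)
        rej_sm, adj_sm, *_ = multipletests(p, alpha=q, method="fdr_bh")
        np.testing.assert_array_equal(fdr_bh(p, q).rejected, rej_sm)
        np.testing.assert_allclose(bh_adjusted(p), adj_sm, atol=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_rejections_monotone_in_q(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=64) ** 2
        q1, q2 = sorted(rng.uniform(0.01, 0.5, size=2))
        r1, r2 = fdr_bh(p, q1).rejected, fdr_bh(p, q2).rejected
        assert np.all(r2[r1])  # rejected at q1 => rejected at q2

    def test_min_q_grid_agrees_with_explicit_scan(self):
        cfg = SignificanceConfig()
        rng = np.random.default_rng(12)
        p = rng.uniform(size=40) ** 3
        from spikedwt.stats import _min_q_on_grid
        got = _min_q_on_grid(bh_adjusted(p), cfg)
        grid = np.round(np.arange(1, 26) * cfg.q_grid_step, 10)
        for i in range(p.size):
            scan = [q for q in grid if fdr_bh(p, q).rejected[i]]
            expect = min(scan) if scan else np.nan
            assert got[i] == pytest.approx(expect, abs=1e-12, nan_ok=True)


def test_merge_intervals_sorts_and_joins_touching():
    assert merge_intervals([(10, 20), (0, 5), (5, 8), (19, 30)]) == \
        [(0, 8), (10, 30)]


def _cohort_maps(profiles, n_trials, seed, period="response"):
    cohort = SyntheticCohort(profiles=profiles, n_trials=n_trials, seed=seed)
    grouped = simulate_cohort(cohort)
    cfg = RunConfig()
    keys = sorted(profiles)
    return tuple(trial_power_maps(grouped[k], cfg, period) for k in keys)


class TestCompareCoefficients:
    def test_group_against_itself_never_rejects(self):
        (maps_a, _) = _cohort_maps({"a": biphasic_profile(),
                                    "b": biphasic_profile()}, 10, 3)
        res = compare_coefficients(maps_a, maps_a, SignificanceConfig())
        assert res.n_primary == 0
        assert (res.table["p"] >= 0.9).all()

    def test_latency_difference_localized_and_control_clean(self):
        profiles = {"early": biphasic_profile(latency_ms=175.0),
                    "late": biphasic_profile(latency_ms=300.0)}
        maps_a, maps_b = _cohort_maps(profiles, 20, 99)
        res = compare_coefficients(maps_a, maps_b, SignificanceConfig())
        assert res.n_primary > 0
        ivs = res.intervals("significant")
        assert any(a < 300.0 and b > 175.0 for a, b in ivs), \
            "no primary interval intersects the shifted-onset range"
        ctrl_a, ctrl_b = _cohort_maps(profiles, 20, 99, period="control")
        ctrl = compare_coefficients(ctrl_a, ctrl_b, SignificanceConfig())
        assert ctrl.n_primary == 0

    def test_post_stimulus_tail_detected_after_offset(self):
        # elevated rate 500-900 ms after offset (offset at 500 ms): the
        # envelopes agree before 1000 ms, so rejections must sit after it
        base = excited_profile(latency_ms=175.0)
        profiles = {"plain": base, "tail": with_tail(base, 1000.0, 1400.0, 25.0)}
        # FDR at q=0.10 tolerates ~10% false discoveries among rejections,
        # so confinement is asserted on average over replicates, not for
        # every rejected coefficient of a single realization
        late_fracs = []
        for seed in range(1, 6):
            maps_a, maps_b = _cohort_maps(profiles, 20, seed)
            res = compare_coefficients(maps_a, maps_b, SignificanceConfig())
            assert res.n_primary > 0
            sig = res.table[res.table["tier"] == "significant"]
            assert (sig["t_start_ms"] >= 1000.0).any()
            late_fracs.append((sig["t_end_ms"] > 900.0).mean())
        assert np.mean(late_fracs) >= 0.85

    def test_mismatched_geometry_rejected(self):
        maps_a, maps_b = _cohort_maps({"a": biphasic_profile(),
                                       "b": biphasic_profile()}, 5, 1)
        small = RunConfig(n_bins=64)
        cohort = SyntheticCohort(profiles={"a": biphasic_profile(),
                                           "b": biphasic_profile()},
                                 n_trials=5, seed=1)
        grouped = simulate_cohort(cohort)
        maps_small = trial_power_maps(grouped["b"], small)
        with pytest.raises(ValueError):
            compare_coefficients(maps_a, maps_small, SignificanceConfig())

    def test_single_trial_group_rejected(self):
        maps_a, maps_b = _cohort_maps({"a": biphasic_profile(),
                                       "b": biphasic_profile()}, 5, 2)
        with pytest.raises(ValueError):
            compare_coefficients(maps_a[:1], maps_b, SignificanceConfig())


class TestMarginalTier:
    """Tier assignment driven by hand-built results (p-values injected)."""

    @staticmethod
    def _result_with(p_target, p_control, seed=0):
        maps_a, maps_b = _cohort_maps({"a": biphasic_profile(),
                                       "b": biphasic_profile()}, 4, seed)
        cfg = SignificanceConfig()
        res = compare_coefficients(maps_a, maps_b, cfg)
        ctrl = compare_coefficients(maps_a, maps_b, cfg)
        t = res.table.copy()
        t["p"] = 1.0
        for idx, p in p_target.items():
            t.loc[idx, "p"] = p
        t["min_q"] = np.where(t["p"] < 1, np.ceil(bh_adjusted(t["p"].to_numpy())
                                                  / 0.01) * 0.01, np.nan)
        fdr = fdr_bh(t["p"].to_numpy(), cfg.q_primary)
        t["tier"] = np.where(fdr.rejected, "significant", "none")
        tc = ctrl.table.copy()
        tc["p"] = 1.0
        for idx, p in p_control.items():
            tc.loc[idx, "p"] = p
        import dataclasses
        return (dataclasses.replace(res, table=t, crit_p=fdr.crit_p),
                dataclasses.replace(ctrl, table=tc), cfg)

    def test_clean_control_marginal_assigned(self):
        # min_q = 0.22-ish coefficient, clean control, uncovered window
        res, ctrl, cfg = self._result_with({5: 0.22 / 128}, {})
        out = marginal_tier(res, ctrl, cfg)
        assert out.table.loc[5, "tier"] == "marginal"
        assert out.control_clean is True

    def test_primary_takes_precedence_over_marginal(self):
        res, ctrl, cfg = self._result_with({5: 0.08 / 128}, {})
        out = marginal_tier(res, ctrl, cfg)
        assert out.table.loc[5, "tier"] == "significant"
        assert "marginal" not in set(out.table.loc[[5], "tier"])

    def test_control_rejection_blocks_marginal(self):
        res, ctrl, cfg = self._result_with({5: 0.22 / 128}, {40: 1e-6})
        out = marginal_tier(res, ctrl, cfg)
        assert out.table.loc[5, "tier"] == "none"
        assert out.control_clean is False

    def test_window_inside_primary_interval_blocks_marginal(self):
        # rows 0..63 are level-1 windows; a primary level-5 coefficient
        # covering [0, 175] ms shadows the level-1 window at index 1
        res, ctrl, cfg = self._result_with({120: 1e-5, 0: 0.21 / 128}, {})
        out = marginal_tier(res, ctrl, cfg)
        assert out.table.loc[120, "tier"] == "significant"
        assert out.table.loc[0, "tier"] == "none"

    def test_missing_control_rejected(self):
        res, ctrl, cfg = self._result_with({}, {})
        with pytest.raises(ValueError):
            marginal_tier(res, None, cfg)

    def test_tiers_are_exclusive(self):
        res, ctrl, cfg = self._result_with({5: 0.22 / 128, 9: 1e-5}, {})
        out = marginal_tier(res, ctrl, cfg)
        tiers = out.table["tier"]
        assert not ((tiers == "significant") & (tiers == "marginal")).any()
        assert set(tiers) <= {"significant", "marginal", "none"}


class TestShuffleControl:
    def test_exchangeable_data_rarely_rejects(self):
        maps_a, maps_b = _cohort_maps({"a": biphasic_profile(),
                                       "b": biphasic_profile()}, 12, 17)
        cfg = SignificanceConfig(n_shuffles=40, seed=5)
        counts = shuffle_control(maps_a, maps_b, cfg)
        assert counts.shape == (40,)
        assert np.mean(counts >= 1) <= 0.15

    def test_zero_shuffles_rejected(self):
        maps_a, maps_b = _cohort_maps({"a": biphasic_profile(),
                                       "b": biphasic_profile()}, 4, 1)
        with pytest.raises(ValueError):
            shuffle_control(maps_a, maps_b,
                            SignificanceConfig(n_shuffles=0, seed=1))

    def test_fixed_seed_reproduces_counts(self):
        maps_a, maps_b = _cohort_maps({"a": biphasic_profile(),
                                       "b": biphasic_profile()}, 6, 2)
        cfg = SignificanceConfig(n_shuffles=10, seed=9)
        np.testing.assert_array_equal(shuffle_control(maps_a, maps_b, cfg),
                                      shuffle_control(maps_a, maps_b, cfg))


def test_significant_duration_sums_merged_tiers():
    profiles = {"early": biphasic_profile(latency_ms=175.0),
                "late": biphasic_profile(latency_ms=300.0)}
    maps_a, maps_b = _cohort_maps(profiles, 20, 4)
    res = compare_coefficients(maps_a, maps_b, SignificanceConfig())
    total = significant_duration(res)
    assert total == pytest.approx(sum(b - a for a, b in res.intervals("significant")))
    assert total > 0
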