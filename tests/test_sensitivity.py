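"""Threshold search, one-/two-way sweeps, beta fitting, and PSA machinery."""

import numpy as np
import pytest
from scipy import stats

from cbtcea import (
    ConfigError,
    find_threshold,
    fit_beta,
    one_way,
    run_psa,
    sample_parameters,
    two_way,
)

COST_ONLY_KEYS = (
    "wage_psych", "li_sessions", "hi_sessions", "platform_cost_icbt",
    "time_fraction_icbt", "outpatient_monthly", "hosp_cost_episode",
    "labor_participation", "unemployment", "student_wage", "hours_per_month",
)


class TestFitBeta:
    def test_method_of_moments_oracle(self):
        alpha, beta = fit_beta(0.633, 0.506, 0.760)
        sd = (0.760 - 0.506) / 3.92
        common = 0.633 *0.367 / sd**2 - 1
        assert alpha == pytest.approx(0.633 * common)
        assert beta == pytest.approx(0.367 * common)
        assert alpha == pytest.approx(34.39, abs=0.01)
        assert beta == pytest.approx(19.94, abs=0.01)

    def test_fitted_mean_matches_input(self):
        for mean, lo, hi in [(0.633, 0.506, 0.760), (0.053, 0.042, 0.064),
                             (0.0044, 0.0035, 0.0053)]:
            a, b = fit_beta(mean, lo, hi)
            assert a / (a + b) == pytest.approx(mean, abs=1e-12)

    def test_symmetric_mean_gives_equal_shapes(self):
        a, b = fit_beta(0.5, 0.3, 0.7)
        assert a == pytest.approx(b)

    def test_infeasible_variance_raises(self):
        with pytest.raises(ConfigError, match="beta fit failed"):
            fit_beta(0.01, 0.0, 1.0)  # variance too large for the mean

    def test_sampled_mean_within_three_se(self):
        a, b = fit_beta(0.633, 0.506, 0.760)
        rng = np.random.default_rng(11)
        draws = rng.beta(a, b, 100_000)
        se = stats.beta.std(a, b) / np.sqrt(draws.size)
        assert abs(draws.mean() - 0.633) < 3 * se


class TestFindThreshold:
    def test_uptake_ratio_identities(self, params, cfg):
        """dQALY crosses zero exactly where the effective-uptake products of
        the two arms coincide: 1/0.99 for acceptance, 1/1.19 for adherence."""
        thr = find_threshold(params, cfg, "rr_accept_icbt")
        assert thr == pytest.approx(1 / 0.99, abs=1e-4)
        thr = find_threshold(params, cfg, "rr_adhere_icbt")
        assert thr == pytest.approx(1 / 1.19, abs=1e-4)

    def test_no_sign_change_returns_none(self, params, cfg):
        assert find_threshold(params, cfg, "recovery_licbt") is None

    def test_root_bracketing_precision(self, params, cfg):
        thr = find_threshold(params, cfg, "rr_accept_icbt", xtol=1e-6)
        from cbtcea.sensitivity import _objective

        assert abs(_objective(params, cfg, "rr_accept_icbt", thr,
                              "delta_qaly_zero", 46070)) < 1e-7


class TestOneWay:
    def test_thresholds_on_influential_ratios(self, params, cfg):
        res = one_way(params, cfg, "rr_accept_icbt")
        assert res.threshold == pytest.approx(1.0101, abs=1e-3)
        res = one_way(params, cfg, "rr_adhere_icbt")
        assert res.threshold == pytest.approx(0.8403, abs=1e-3)

    @pytest.mark.parametrize("key", COST_ONLY_KEYS)
    def test_cost_parameters_never_move_delta_qaly(self, params, cfg, key):
        base_dq = None
        res = one_way(params, cfg, key)
        for r in (res.low_result, res.high_result):
            if base_dq is None:
                base_dq = r.delta_qaly
            assert abs(r.delta_qaly - base_dq) < 1e-15
        assert res.threshold is None

    def test_degenerate_parameter_flagged(self, params, cfg):
        res = one_way(params, cfg, "utility_age")
        assert res.degenerate
        assert res.threshold is None

    def test_base_between_endpoints_for_monotone_response(self, params, cfg):
        from cbtcea import base_case

        _, _, ce = base_case(params, cfg)
        res = one_way(params, cfg, "rr_accept_icbt")
        lo, hi = sorted([res.low_result.delta_qaly, res.high_result.delta_qaly])
        assert lo <= ce.delta_qaly <= hi


class TestTwoWay:
    def test_base_case_corner_prefers_icbt(self, params, cfg):
        res = two_way(params, cfg, "rr_accept_icbt", (1.18, 1.20),
                      "rr_adhere_icbt", (0.98, 1.0), grid_n=3)
        assert res.icbt_preferred.all()

    def test_frontier_brackets_preference_flip(self, params, cfg):
        res = two_way(params, cfg, "rr_accept_icbt", None,
                      "rr_adhere_icbt", (0.84, 0.86), grid_n=5)
        f = res.frontier[0]  # at adherence ratio 0.84
        assert 1.0 < f < 1.2
        # cells on either side of the frontier disagree
        below = res.values1 < f - 1e-9
        above = res.values1 > f + 1e-9
        assert not res.icbt_preferred[0][below].any()
        assert res.icbt_preferred[0][above].all()


class TestSampling:
    def test_same_seed_identical_draw(self, params):
        a = sample_parameters(params, np.random.default_rng(5))
        b = sample_parameters(params, np.random.default_rng(5))
        assert a.specs == b.specs

    def test_fixed_parameters_unchanged(self, params):
        drawn = sample_parameters(params, np.random.default_rng(5))
        for key in ("utility_age", "discount_annual", "horizon_cycles", "wtp",
                    "li_session_hours", "hi_session_hours"):
            assert drawn.specs[key].base == params.specs[key].base

    def test_draws_respect_ranges(self, params):
        rng = np.random.default_rng(6)
        for _ in range(50):
            drawn = sample_parameters(params, rng)
            for key, spec in params.specs.items():
                v = drawn.specs[key].base
                if spec.family == "triangular":
                    assert spec.low <= v <= spec.high
                elif spec.family == "beta":
                    assert 0.0 <= v <= 1.0

    def test_empirical_means_match_distributions(self, params):
        rng = np.random.default_rng(7)
        n = 20_000
        keys = ("accept_fcbt", "rr_adhere_icbt", "outpatient_monthly")
        sums = dict.fromkeys(keys, 0.0)
        for _ in range(n):
            drawn = sample_parameters(params, rng)
            for k in keys:
                sums[k] += drawn.specs[k].base
        # beta keeps the base value as its mean; triangular mean is
        # (low + base + high) / 3
        expect = {
            "accept_fcbt": 0.633,
            "rr_adhere_icbt": (0.84 + 0.99 + 1.0) / 3,
            "outpatient_monthly": (185 + 220 + 348) / 3,
        }
        sds = {"accept_fcbt": (0.760 - 0.506) / 3.92,
               "rr_adhere_icbt": 0.034, "outpatient_monthly": 34.0}
        for k in keys:
            se = sds[k] / np.sqrt(n)
            assert abs(sums[k] / n - expect[k]) < 4 * se


class TestRunPSA:
    def test_fixed_seed_bitwise_reproducible(self, params, cfg):
        a = run_psa(params, cfg, n_draws=200, seed=42)
        b = run_psa(params, cfg, n_draws=200, seed=42)
        for fld in ("cost_icbt", "qaly_icbt", "cost_fcbt", "qaly_fcbt",
                    "ceac_icbt"):
            assert np.array_equal(getattr(a, fld), getattr(b, fld))

    def test_ceac_complement_sums_to_one(self, params, cfg):
        res = run_psa(params, cfg, n_draws=300, seed=9)
        for w, p_i in zip(res.wtp_grid, res.ceac_icbt):
            nmb = w * res.delta_qaly - res.delta_cost
            p_f = np.mean(nmb <= 0)  # ties go to the comparator
            assert p_i + p_f == pytest.approx(1.0)
            assert 0.0 <= p_i <= 1.0

    def test_single_draw_degenerates(self, params, cfg):
        res = run_psa(params, cfg, n_draws=1, seed=3)
        m, lo, hi = res.mean_ci(res.delta_cost)
        assert m == lo == hi
        assert set(np.unique(res.ceac_icbt)) <= {0.0, 1.0}

    def test_mean_ci_shrinks_with_n(self, params, cfg):
        res = run_psa(params, cfg, n_draws=400, seed=4)
        m, lo, hi = res.mean_ci(res.delta_qaly)
        half = res.mean_ci(res.delta_qaly[:100])
        assert (hi - lo) < (half[2] - half[1])
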