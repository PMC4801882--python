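"""Tests for LHS sampling, filtering, likelihood, fitting and profiling."""
import math

import numpy as np
import pandas as pd
import pytest

import bcellkin as bk
from bcellkin.inference import _gaussian_lnl
from bcellkin.synthetic import totals_ranges_dict


@pytest.fixture(scope="module")
def control_ranges():
    return bk.ParameterRanges.from_ci(bk.table1_ci("control"))


@pytest.fixture(scope="module")
def control_data(small_cohort):
    return small_cohort[small_cohort["group"] == "control"]


class TestLHS:
    def test_one_value_per_stratum(self):
        r = bk.ParameterRanges(sampled={"mu_i": (0.0, 1.0)}, fixed={})
        _, mat = bk.lhs_matrix(r, 4, seed=0)
        strata = np.floor(mat[:, 0] * 4).astype(int)
        assert sorted(strata) == [0, 1, 2, 3]

    def test_degenerate_range_collapses(self):
        r = bk.ParameterRanges(sampled={"mu_i": (0.3, 0.3)}, fixed={})
        _, mat = bk.lhs_matrix(r, 5, seed=0)
        assert np.all(mat == 0.3)

    def test_deterministic_given_seed(self, control_ranges):
        _, a = bk.lhs_matrix(control_ranges, 50, seed=42)
        _, b = bk.lhs_matrix(control_ranges, 50, seed=42)
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("seed", range(10))
    def test_stratum_occupancy_all_dimensions(self, control_ranges, seed):
        n = 16
        names, mat = bk.lhs_matrix(control_ranges, n, seed=seed)
        for j, name in enumerate(names):
            lo, hi = control_ranges.sampled[name]
            if hi == lo:
                continue
            strata = np.floor((mat[:, j] - lo) / (hi - lo) * n).astype(int)
            strata = np.clip(strata, 0, n - 1)  # right endpoint
            assert sorted(strata) == list(range(n))

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            bk.ParameterRanges(sampled={"mu_i": (0.5, 0.1)})

    def test_candidates_respect_bounds_after_completion(self, control_ranges):
        cands = bk.lhs_sample(control_ranges, 20, seed=1, on_infeasible="drop")
        for c in cands:
            for name, (lo, hi) in control_ranges.sampled.items():
                assert lo <= getattr(c, name) <= hi
            assert c.S >= 0 and c.K > 0


class TestSteadyStateFilter:
    def test_unbounded_ranges_pass_everything(self, control_ranges):
        cands = bk.lhs_sample(control_ranges, 30, seed=0, on_infeasible="drop")
        ranges = {s: (0.0, math.inf) for s in bk.MEASURED_SUBSETS}
        filt = bk.steady_state_filter(cands, ranges)
        assert filt.n_passing == len(cands)

    def test_impossible_range_passes_nothing(self, control_ranges):
        cands = bk.lhs_sample(control_ranges, 10, seed=0, on_infeasible="drop")
        filt = bk.steady_state_filter(cands, {"immature": (0.0, 0.0)})
        assert filt.n_passing == 0

    def test_upper_below_lower_rejected(self, control_ranges):
        cands = bk.lhs_sample(control_ranges, 2, seed=0, on_infeasible="drop")
        with pytest.raises(ValueError):
            bk.steady_state_filter(cands, {"immature": (1.0, 0.5)})

    def test_passing_candidates_verified_by_independent_integration(
        self, control_params
    ):
        ranges = totals_ranges_dict(bk.generate_totals_ranges(control_params, 0.5))
        pr = bk.ParameterRanges.from_ci(bk.table1_ci("control"))
        cands = bk.lhs_sample(pr, 400, seed=3, on_infeasible="drop")
        filt = bk.steady_state_filter(cands, ranges)
        assert filt.n_passing > 0
        for cand in filt.passing[:5]:
            ss = bk.find_steady_state(cand)  # independent of the filter's path
            for subset, (lo, hi) in ranges.items():
                v = getattr(ss, subset)
                assert lo * 0.999 <= v <= hi * 1.001


class TestLogLikelihood:
    def _exact_data(self, params, design):
        pred = bk.predicted_fractions(params, design)
        rows = []
        for (day, subset), mu in pred.items():
            for m in range(3):
                rows.append(
                    {
                        "mouse_id": f"c_d{day:g}_m{m}",
                        "group": design.group,
                        "day": day,
                        "subset": subset,
                        "labeled_fraction": mu,
                    }
                )
        return pd.DataFrame(rows)

    def test_zero_residuals_closed_form(self, control_params, designs):
        data = self._exact_data(control_params, designs["control"])
        sd = 0.05
        lnl = bk.log_likelihood(
            control_params, data, designs["control"], bk.NoiseModel(sd=sd)
        )
        n = len(data)
        assert lnl == pytest.approx(-n * math.log(sd * math.sqrt(2 * math.pi)), rel=1e-9)

    def test_moving_one_datum_decreases_lnl(self, control_params, designs):
        data = self._exact_data(control_params, designs["control"])
        noise = bk.NoiseModel(sd=0.03)
        base = bk.log_likelihood(control_params, data, designs["control"], noise)
        prev = base
        for shift in (0.01, 0.02, 0.05, 0.1):
            shifted = data.copy()
            shifted.loc[0, "labeled_fraction"] = np.clip(
                shifted.loc[0, "labeled_fraction"] + shift, 0, 1
            )
            lnl = bk.log_likelihood(control_params, shifted, designs["control"], noise)
            assert lnl < prev
            prev = lnl

    def test_matches_brute_force_row_sum(self, control_params, designs, control_data):
        sd = 0.04
        lnl = bk.log_likelihood(
            control_params, control_data, designs["control"], bk.NoiseModel(sd=sd)
        )
        pred = bk.predicted_fractions(control_params, designs["control"])
        brute = 0.0
        for row in control_data.itertuples(index=False):
            mu = pred[(row.day, row.subset)]
            r = row.labeled_fraction - mu
            brute += -0.5 * math.log(2 * math.pi * sd**2) - r**2 / (2 * sd**2)
        assert lnl == pytest.approx(brute, rel=1e-12)

    def test_invariant_under_row_permutation(self, control_params, designs, control_data):
        perm = control_data.sample(frac=1.0, random_state=5)
        a = bk.log_likelihood(control_params, control_data, designs["control"])
        b = bk.log_likelihood(control_params, perm, designs["control"])
        assert a == pytest.approx(b, rel=1e-12)

    def test_failed_simulation_gives_minus_inf(self, designs, control_data):
        # S = 0 empties the system: predictions are undefined (NaN fractions)
        p = bk.table1_parameters("control").replace(S=0.0)
        lnl = bk.log_likelihood(p, control_data, designs["control"])
        assert lnl == -math.inf


class TestFitMLE:
    def test_single_candidate_is_returned(self, designs, control_data):
        r = bk.ParameterRanges.from_ci(bk.table1_ci("control"))
        fit = bk.fit_mle(control_data, r, 1, seed=0, design=designs["control"])
        assert fit.n_candidates == 1
        assert fit.params is not None

    def test_noise_free_data_prefers_truth(self, control_params, designs):
        pred = bk.predicted_fractions(control_params, designs["control"])
        rows = [
            {"mouse_id": f"m{day:g}{subset}", "group": "control", "day": day,
             "subset": subset, "labeled_fraction": mu}
            for (day, subset), mu in pred.items()
        ]
        data = pd.DataFrame(rows)
        r = bk.ParameterRanges.from_ci(bk.table1_ci("control"))
        cands = bk.lhs_sample(r, 30, seed=2, on_infeasible="drop")
        noise = bk.NoiseModel(sd=0.03)
        lnl_truth = bk.log_likelihood(control_params, data, designs["control"], noise)
        fit = bk.fit_mle(data, r, 30, seed=2, design=designs["control"], noise=noise)
        assert fit.log_likelihood >= max(
            bk.log_likelihood(c, data, designs["control"], noise) for c in cands
        ) - 1e-9
        assert lnl_truth >= fit.log_likelihood  # truth is the global optimum

    def test_deterministic_given_seed(self, designs, control_data):
        r = bk.ParameterRanges.from_ci(bk.table1_ci("control"))
        f1 = bk.fit_mle(control_data, r, 40, seed=9, design=designs["control"])
        f2 = bk.fit_mle(control_data, r, 40, seed=9, design=designs["control"])
        assert f1.params == f2.params
        assert f1.log_likelihood == f2.log_likelihood

    def test_zero_passing_candidates_is_explicit_failure(self, designs, control_data):
        r = bk.ParameterRanges.from_ci(bk.table1_ci("control"))
        with pytest.raises(bk.FitError):
            bk.fit_mle(
                control_data, r, 5, seed=0, design=designs["control"],
                total_ranges={"immature": (0.0, 0.0)},
            )


class TestProfileLikelihood:
    def test_cutoff_is_chi2_quantile(self):
        assert round(bk.likelihood_ratio_cutoff(0.05), 2) == 3.84

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            bk.likelihood_ratio_cutoff(1.5)

    def test_quadratic_loglik_recovers_wald_interval(self):
        # Gaussian mean with known sd: profile CI must equal mu_hat +/- 1.96 se
        mu_hat, se = 0.4, 0.05
        def loglik(values):
            return -0.5 * ((values["mu"] - mu_hat) / se) ** 2
        r = bk.ParameterRanges(sampled={"mu": (0.0, 1.0)}, fixed={})
        ci = bk.profile_ci_from_loglik(
            loglik, r, {"mu": mu_hat}, 0.0, "mu", grid_size=801, seed=0,
            n_draws=1, n_rounds=1,
        )
        half = 1.959964 * se
        assert ci.lower == pytest.approx(mu_hat - half, abs=2e-3)
        assert ci.upper == pytest.approx(mu_hat + half, abs=2e-3)
        assert not ci.censored_lower and not ci.censored_upper

    def test_best_fit_inside_interval(self, control_params, designs, control_data):
        r = bk.ParameterRanges.from_ci(bk.table1_ci("control"))
        fit = bk.fit_mle(control_data, r, 60, seed=4, design=designs["control"])
        ci = bk.profile_likelihood_ci(
            "mu_i", fit, control_data, r, designs["control"],
            grid_size=7, n_draws=20, n_rounds=1, seed=0,
        )
        assert ci.lower <= fit.params.mu_i <= ci.upper

    def test_ci_narrows_with_less_noisy_data(self, control_params, designs):
        widths = {}
        for sd in (0.06, 0.015):
            spec = bk.CohortSpec(
                params={"control": control_params},
                designs={"control": designs["control"]},
                noise_sd=sd,
                seed=12,
            )
            data = bk.generate_cohort(spec)
            r = bk.ParameterRanges.from_ci(bk.table1_ci("control"))
            fit = bk.fit_mle(data, r, 80, seed=4, design=designs["control"],
                             noise=bk.NoiseModel(sd=sd))
            ci = bk.profile_likelihood_ci(
                "gamma", fit, data, r, designs["control"],
                noise=bk.NoiseModel(sd=sd),
                grid_size=9, n_draws=25, n_rounds=1, seed=0,
            )
            widths[sd] = ci.upper - ci.lower
        assert widths[0.015] <= widths[0.06] + 1e-9


def test_gaussian_lnl_profiled_matches_explicit_maximum():
    rng = np.random.default_rng(0)
    resid = rng.normal(0, 0.05, size=40)
    profiled = _gaussian_lnl(resid, None)
    sds = np.linspace(0.001, 0.3, 4000)
    grid_max = max(_gaussian_lnl(resid, s) for s in sds)
    assert profiled >= grid_max - 1e-6
    assert profiled == pytest.approx(grid_max, abs=1e-3)
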