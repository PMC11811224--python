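"""Monte Carlo engine: fitting, sampling, simulation, percentile conventions."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from aquarisk import (
    FLUORIDE,
    NITRATE,
    ContaminantSpec,
    DistributionSpec,
    ScenarioSpec,
    default_scenario,
    edi,
    fit_lognormal,
    hazard_quotient,
    percentile,
    sample,
    simulate_hi,
    simulate_hq,
)
from aquarisk.errors import (
    EmptyInputError,
    FittingError,
    SamplingError,
    ValidationError,
)


def _rng(seed=0):
    return np.random.default_rng(seed)


class TestFitLognormal:
    def test_identical_values_give_zero_spread(self):
        fit = fit_lognormal([2.5, 2.5, 2.5])
        assert fit.p1 == pytest.approx(math.log(2.5), rel=1e-12)
        assert fit.p2 == 0.0

    def test_parameter_recovery_on_large_sample(self):
        draws = _rng(11).lognormal(-1.2, 0.5, size=10_000)
        fit = fit_lognormal(draws)
        assert fit.p1 == pytest.approx(-1.2, abs=0.02)
        assert fit.p2 == pytest.approx(0.5, abs=0.02)

    def test_fixture_panel_fits_without_clamping(self, fluoride_panel):
        fit = fit_lognormal(fluoride_panel.measured, floor=0.005)
        assert fit.n_clamped == 0
        assert math.isfinite(fit.p1) and fit.p2 > 0

    def test_floor_clamps_and_counts(self):
        fit = fit_lognormal([0.001, 0.002, 1.0, 2.0], floor=0.005)
        assert fit.n_clamped == 2
        # the two sub-floor values entered the fit as ln(0.005)
        logs = [math.log(0.005), math.log(0.005), 0.0, math.log(2.0)]
        assert fit.p1 == pytest.approx(np.mean(logs), rel=1e-9)

    def test_too_few_values_rejected(self):
        with pytest.raises(FittingError):
            fit_lognormal([1.0])


class TestSample:
    def test_point_spec_is_constant(self):
        out = sample(DistributionSpec.point(2.5), 4, _rng())
        assert out.tolist() == [2.5, 2.5, 2.5, 2.5]

    def test_truncated_normal_mean_unaffected_by_distant_bound(self):
        # truncation at 0 is 7.5 SDs below the mean: negligible mass removed
        out = sample(DistributionSpec.normal(7.5, 1.0, lower=0.0), 10_000, _rng(1))
        assert out.mean() == pytest.approx(7.5, abs=0.05)

    def test_lognormal_mean_matches_closed_form(self):
        out = sample(DistributionSpec.lognormal(0.0, 0.5), 10_000, _rng(2))
        assert out.mean() == pytest.approx(math.exp(0.125), abs=0.03)

    def test_truncation_bounds_are_inclusive_and_respected(self):
        spec = DistributionSpec.normal(0.0, 1.0, lower=-0.5, upper=0.5)
        out = sample(spec, 5_000, _rng(3))
        assert np.all(out >= -0.5) and np.all(out <= 0.5)

    def test_negligible_mass_raises(self):
        with pytest.raises(SamplingError):
            sample(DistributionSpec.normal(0.0, 1.0, lower=20.0), 100, _rng(4))

    def test_truncated_sample_distribution_matches_truncnorm_oracle(self):
        # scipy's truncnorm is the independent reference for the rejection sampler
        spec = DistributionSpec.normal(10.0, 2.0, lower=8.0, upper=15.0)
        out = sample(spec, 20_000, _rng(5))
        a, b = (8.0 - 10.0) / 2.0, (15.0 - 10.0) / 2.0
        ks = stats.kstest(out, stats.truncnorm(a, b, loc=10.0, scale=2.0).cdf)
        assert ks.pvalue > 0.01


class TestPercentile:
    def test_median_of_odd_length(self):
        assert percentile(np.array([1.0, 2, 3, 4, 5]), 0.5) == 3.0

    def test_interpolated_rank_convention(self):
        # rank 1 + 3*0.95 = 3.85 -> 3 + 0.85*(4-3)
        assert percentile(np.array([1.0, 2, 3, 4]), 0.95) == pytest.approx(3.85, rel=1e-12)

    def test_constant_trials_return_the_constant(self):
        assert percentile(np.full(10, 7.0), 0.123) == 7.0

    @pytest.mark.parametrize("q", [0.0, 1.0, -0.1, 1.5])
    def test_probability_outside_open_interval_rejected(self, q):
        with pytest.raises(ValidationError):
            percentile(np.array([1.0, 2.0]), q)

    def test_empty_trials_rejected(self):
        with pytest.raises(EmptyInputError):
            percentile(np.array([]), 0.5)

    def test_monotone_in_probability(self):
        trials = _rng(6).lognormal(0, 1, 500)
        qs = np.linspace(0.01, 0.99, 25)
        values = [percentile(trials, q) for q in qs]
        assert all(a <= b for a, b in zip(values, values[1:]))


def _point_scenario(profile, c, n_trials=100, seed=1):
    return ScenarioSpec(
        contaminant=FLUORIDE,
        group=profile.group,
        c_dist=DistributionSpec.point(c),
        ir_dist=DistributionSpec.point(profile.ir),
        bw_dist=DistributionSpec.point(profile.bw),
        ef=profile.ef,
        ed=profile.ed,
        at=profile.at,
        n_trials=n_trials,
        seed=seed,
    )


class TestSimulateHq:
    def test_point_distributions_collapse_to_deterministic(self, profile_map):
        infants = profile_map["infants"]
        result = simulate_hq(_point_scenario(infants, 0.45))
        det = hazard_quotient(edi(0.45, infants), FLUORIDE.rfd)
        assert np.all(result.trials == det)
        assert result.mean == det and result.sd == 0.0
        assert all(v == det for v in result.percentiles.values())
        assert det == pytest.approx(0.70, abs=1e-12)

    def test_fixed_seed_is_bitwise_reproducible(self, fluoride_panel, profile_map):
        scenario = default_scenario(fluoride_panel, profile_map["children"], seed=99)
        a, b = simulate_hq(scenario), simulate_hq(scenario)
        assert np.array_equal(a.trials, b.trials)
        assert a.percentiles == b.percentiles

    def test_lognormal_concentration_mean_matches_closed_form(self, profile_map):
        infants = profile_map["infants"]
        p1, p2 = -1.2, 0.5
        scenario = ScenarioSpec(
            contaminant=FLUORIDE,
            group="infants",
            c_dist=DistributionSpec.lognormal(p1, p2),
            ir_dist=DistributionSpec.point(infants.ir),
            bw_dist=DistributionSpec.point(infants.bw),
            ef=infants.ef,
            ed=infants.ed,
            at=infants.at,
            n_trials=50_000,
            seed=3,
        )
        result = simulate_hq(scenario)
        expected = math.exp(p1 + p2**2 / 2) * infants.ir / (infants.bw * FLUORIDE.rfd)
        se = result.sd / math.sqrt(result.n_trials)
        assert abs(result.mean - expected) < 3 * se

    def test_mean_matches_independence_factorisation(self, profile_map):
        """E[HQ] = E[C] * E[IR] * E[1/BW] / RfD for independent inputs.

        E[1/BW] over the truncated normal comes from numeric integration —
        an oracle fully independent of the sampling path.
        """
        infants = profile_map["infants"]
        c_dist = DistributionSpec.lognormal(-1.2, 0.6)
        ir_dist = DistributionSpec.lognormal(math.log(infants.ir), 0.25)
        bw_dist = DistributionSpec.normal(infants.bw, 0.15 * infants.bw, lower=0.2 * infants.bw)
        scenario = ScenarioSpec(
            contaminant=FLUORIDE,
            group="infants",
            c_dist=c_dist,
            ir_dist=ir_dist,
            bw_dist=bw_dist,
            ef=infants.ef,
            ed=infants.ed,
            at=infants.at,
            n_trials=100_000,
            seed=4,
        )
        result = simulate_hq(scenario)

        a = (bw_dist.lower - bw_dist.p1) / bw_dist.p2
        tn = stats.truncnorm(a, np.inf, loc=bw_dist.p1, scale=bw_dist.p2)
        e_inv_bw, _ = integrate.quad(lambda x: tn.pdf(x) / x, bw_dist.lower, np.inf)
        expected = c_dist.analytic_mean() * ir_dist.analytic_mean() * e_inv_bw / FLUORIDE.rfd
        se = result.sd / math.sqrt(result.n_trials)
        assert abs(result.mean - expected) < 3 * se

    def test_default_scenarios_rank_infants_highest_at_p95(
        self, fluoride_panel, nitrate_panel, profile_map
    ):
        for panel in (fluoride_panel, nitrate_panel):
            p95 = {
                g: simulate_hq(default_scenario(panel, profile_map[g], seed=8)).percentiles[95.0]
                for g in ("infants", "children", "teenagers", "adults")
            }
            assert p95["infants"] == max(p95.values())


class TestSimulateHi:
    def test_point_scenarios_collapse_to_deterministic_sum(self, profile_map):
        infants = profile_map["infants"]
        f = _point_scenario(infants, 0.45)
        n = ScenarioSpec(
            contaminant=NITRATE,
            group=infants.group,
            c_dist=DistributionSpec.point(2.91),
            ir_dist=DistributionSpec.point(infants.ir),
            bw_dist=DistributionSpec.point(infants.bw),
            ef=infants.ef,
            ed=infants.ed,
            at=infants.at,
            n_trials=100,
            seed=1,
        )
        sim = simulate_hi([f, n])
        det = hazard_quotient(edi(0.45, infants), 0.06) + hazard_quotient(
            edi(2.91, infants), 1.6
        )
        assert np.all(sim.hi.trials == det)

    def test_hi_trials_are_elementwise_sum_of_components(
        self, fluoride_panel, nitrate_panel, profile_map
    ):
        children = profile_map["children"]
        scenarios = [
            default_scenario(p, children, n_trials=2_000, seed=5)
            for p in (fluoride_panel, nitrate_panel)
        ]
        sim = simulate_hi(scenarios)
        total = sum(r.trials for r in sim.per_contaminant.values())
        assert np.array_equal(sim.hi.trials, total)

    def test_ir_and_bw_draws_are_shared_within_a_trial(self, profile_map):
        # With point concentrations, the two HQ trial vectors differ only by
        # the constant C/RfD factor — which requires identical IR/BW draws.
        infants = profile_map["infants"]
        common = dict(
            ir_dist=DistributionSpec.lognormal(math.log(infants.ir), 0.25),
            bw_dist=DistributionSpec.normal(infants.bw, 1.0, lower=1.0),
            ef=infants.ef,
            ed=infants.ed,
            at=infants.at,
            n_trials=500,
            seed=6,
            group="infants",
        )
        f = ScenarioSpec(contaminant=FLUORIDE, c_dist=DistributionSpec.point(0.3), **common)
        n = ScenarioSpec(contaminant=NITRATE, c_dist=DistributionSpec.point(2.0), **common)
        sim = simulate_hi([f, n])
        ratio = sim.per_contaminant["fluoride"].trials / sim.per_contaminant["nitrate"].trials
        expected = (0.3 / FLUORIDE.rfd) / (2.0 / NITRATE.rfd)
        assert np.allclose(ratio, expected, rtol=1e-12)

    def test_two_identical_scenarios_double_the_mean(self, profile_map):
        infants = profile_map["infants"]
        make = lambda spec: ScenarioSpec(
            contaminant=spec,
            group="infants",
            c_dist=DistributionSpec.lognormal(-1.0, 0.5),
            ir_dist=DistributionSpec.point(infants.ir),
            bw_dist=DistributionSpec.point(infants.bw),
            ef=infants.ef,
            ed=infants.ed,
            at=infants.at,
            n_trials=20_000,
            seed=7,
        )
        f = make(ContaminantSpec("a", rfd=0.06))
        n = make(ContaminantSpec("b", rfd=0.06))
        sim = simulate_hi([f, n])
        single = simulate_hq(f)
        # the two estimates use independent draws, so their errors add
        se_hi = sim.hi.sd / math.sqrt(sim.hi.n_trials)
        se_single = single.sd / math.sqrt(single.n_trials)
        assert abs(sim.hi.mean - 2 * single.mean) < 3 * math.hypot(se_hi, 2 * se_single)

    def test_mismatched_groups_rejected(self, fluoride_panel, nitrate_panel, profile_map):
        a = default_scenario(fluoride_panel, profile_map["infants"], seed=1)
        b = default_scenario(nitrate_panel, profile_map["adults"], seed=1)
        with pytest.raises(ValidationError, match="group"):
            simulate_hi([a, b])
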