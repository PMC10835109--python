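import itertools

import numpy as np
import pandas as pd
import pytest

from aqadapt.exposure_health import (
    HealthEconParams,
    breakeven_concentration,
    daily_benefits_vector,
    daily_cost,
    equivalent_annual_mean,
    psi,
)
from aqadapt.strategies import (
    SocialLearningParams,
    delta_utility,
    fit_social_learning,
    forced_strategy,
    no_adaptation,
    rational_strategy,
    run_social_learning,
    social_learning_step,
    threshold_strategy,
)
from aqadapt.synthetic_data import generate_daily_pm

from .conftest import constant_series, make_profile


def brute_force_best_net_benefit(values, profile, params):
    """Exhaustive search over all adaptation-day subsets of a toy year."""
    n = len(values)
    b = daily_benefits_vector(values, profile, params)
    c = daily_cost(params.phi(profile), 1.0, profile.outdoor_time)
    best = 0.0
    for k in range(n + 1):
        for days in itertools.combinations(range(n), k):
            nb = sum(b[d] - c for d in days)
            best = max(best, nb)
    return best


class TestThresholdStrategy:
    def test_no_alerts_zero_everything(self, profile, params):
        o = threshold_strategy(constant_series(10.0), profile, params, 100, 0.2)
        assert o.n_adapt_days == 0
        assert o.annual_benefit == o.annual_cost == 0.0

    def test_zero_compliance_zero_popweighted(self, profile, params):
        s = generate_daily_pm(30.0, 12.0, 0.5, 0.5, seed=3)
        o = threshold_strategy(s, profile, params, 100, 0.0)
        assert o.popweighted_net_benefit == 0.0
        assert o.annual_benefit > 0  # per-complier values unaffected

    def test_popweighted_scales_linearly_with_compliance(self, profile, params):
        s = generate_daily_pm(30.0, 12.0, 0.5, 0.5, seed=3)
        half = threshold_strategy(s, profile, params, 100, 0.5)
        full = threshold_strategy(s, profile, params, 100, 1.0)
        assert full.popweighted_net_benefit == pytest.approx(2 * half.popweighted_net_benefit)
        assert full.annual_net_benefit == pytest.approx(half.annual_net_benefit)

    def test_invalid_compliance_rejected(self, profile, params):
        with pytest.raises(ValueError):
            threshold_strategy(constant_series(10.0), profile, params, 100, 1.5)


class TestRationalStrategy:
    def test_all_days_below_breakeven_empty_set(self, profile, params):
        pm_star = breakeven_concentration(profile, params)
        s = constant_series(min(0.9 * pm_star, 100.0))
        o = rational_strategy(s, profile, params)
        assert o.n_adapt_days == 0

    def test_constant_above_breakeven_selects_all_days(self, params):
        p = make_profile(baseline_mortality_rate=0.02, hourly_wage=5.0)
        pm_star = breakeven_concentration(p, params)
        assert pm_star < 150  # stays inside the AQI table's physical range
        o = rational_strategy(constant_series(pm_star * 1.1), p, params)
        assert o.n_adapt_days == 365
        assert o.annual_net_benefit > 0

    def test_greedy_matches_exhaustive_on_toy_years(self, params):
        """Greedy day selection attains the exhaustive-subset maximum."""
        rng = np.random.default_rng(7)
        p = make_profile()
        pm_star = breakeven_concentration(p, params, n_days=10)
        for _ in range(25):
            v = rng.gamma(2.0, pm_star / 2, size=10)
            o = rational_strategy(v, p, params)
            best = brute_force_best_net_benefit(v, p, params)
            assert o.annual_net_benefit == pytest.approx(best, rel=1e-9, abs=1e-9)

    def test_selected_set_is_breakeven_threshold_set(self, params):
        rng = np.random.default_rng(11)
        p = make_profile()
        pm_star = breakeven_concentration(p, params)
        v = rng.gamma(2.0, pm_star / 2, size=365)
        o = rational_strategy(v, p, params)
        assert set(o.adapt_days) == set(np.nonzero(v >= pm_star)[0].tolist())

    def test_equal_concentration_ties_nb_invariant(self, params):
        """Ties at the selection boundary cannot change total net benefit."""
        p = make_profile(baseline_mortality_rate=0.02, hourly_wage=5.0)
        pm_star = breakeven_concentration(p, params)
        v = np.full(365, 1.0)
        v[10] = v[20] = v[30] = pm_star  # exactly break-even: NB = 0 each
        o = rational_strategy(v, p, params)
        assert o.annual_net_benefit == pytest.approx(0.0, abs=1e-6)

    def test_dominates_threshold_on_shared_inputs(self, params):
        rng = np.random.default_rng(13)
        for i in range(10):
            p = make_profile(
                infiltration_factor=float(rng.uniform(0.05, 0.5)),
                hourly_wage=float(rng.uniform(10, 50)),
                baseline_mortality_rate=float(rng.uniform(0.004, 0.02)),
            )
            s = generate_daily_pm(rng.uniform(15, 40), 8.0, 0.5, 0.5, seed=100 + i)
            rat = rational_strategy(s, p, params)
            for thr in (100, 150):
                for comp in (0.2, 1.0):
                    t = threshold_strategy(s, p, params, thr, comp)
                    assert rat.annual_net_benefit >= t.annual_net_benefit - 1e-9
                    assert rat.popweighted_net_benefit >= t.popweighted_net_benefit - 1e-9


class TestForcedStrategy:
    def test_target_at_mean_is_empty(self, profile, params):
        s = constant_series(10.0)
        o = forced_strategy(s, 10.0, profile, params)
        assert o.n_adapt_days == 0
        assert o.feasible

    def test_constant_series_analytic_day_count(self, params):
        # psi = 0.5 via FINF = 1/3, Tout = 12: 24*(1/3)/(12+12/3) = 8/16
        p = make_profile(infiltration_factor=1 / 3, outdoor_time=12.0)
        assert psi(1 / 3, 12.0) == pytest.approx(0.5)
        o = forced_strategy(constant_series(10.0), 9.5, p, params)
        assert o.n_adapt_days == int(np.ceil(365 * (10 - 9.5) / (10 * 0.5))) == 37

    def test_psi_one_is_infeasible_with_all_days(self, params):
        p = make_profile(infiltration_factor=1.0)
        o = forced_strategy(constant_series(10.0), 9.0, p, params)
        assert not o.feasible
        assert o.n_adapt_days == 365

    def test_exposure_contract_overshoot_at_most_one_day(self, profile, params):
        """When feasible, the equivalent mean lands within one day's increment."""
        rng = np.random.default_rng(5)
        ps = psi(profile.infiltration_factor, profile.outdoor_time)
        for i in range(20):
            s = generate_daily_pm(rng.uniform(10, 30), 6.0, 0.5, 0.5, seed=200 + i)
            max_gap = 0.9 * s.annual_mean * (1 - ps)  # keep the target reachable
            target = s.annual_mean - rng.uniform(0.2, min(2.0, max_gap))
            o = forced_strategy(s, target, profile, params)
            assert o.feasible
            eq = o.pm_equivalent
            assert eq <= target + 1e-9
            max_inc = (1 - ps) * s.values.max() / 365
            assert target - eq <= max_inc + 1e-9

    def test_costs_accrue_even_when_net_negative(self, profile, params):
        s = generate_daily_pm(21.5, 8.0, 0.5, 0.4, seed=9)
        o = forced_strategy(s, s.annual_mean - 1.2, profile, params)
        assert o.annual_cost > 0
        assert o.annual_cost == pytest.approx(
            o.n_adapt_days * daily_cost(profile.hourly_wage, 1.0, profile.outdoor_time)
        )

    def test_negative_target_rejected(self, profile, params):
        with pytest.raises(ValueError):
            forced_strategy(constant_series(10.0), -1.0, profile, params)


class TestOutcomeInvariants:
    def test_no_adaptation_outcome(self, profile, params):
        o = no_adaptation(constant_series(10.0), profile, params)
        assert o.annual_net_benefit == 0.0
        assert o.pm_equivalent == pytest.approx(10.0)

    def test_mitigation_never_increases_rational_benefit(self, params):
        from aqadapt.synthetic_data import apply_mitigation_shift

        rng = np.random.default_rng(17)
        for i in range(10):
            p = make_profile(infiltration_factor=float(rng.uniform(0.05, 0.5)))
            s = generate_daily_pm(rng.uniform(15, 35), 8.0, 0.5, 0.5, seed=300 + i)
            mit = apply_mitigation_shift(s, 1.2)
            o_ref = rational_strategy(s, p, params)
            o_mit = rational_strategy(mit, p, params)
            assert o_mit.annual_benefit <= o_ref.annual_benefit + 1e-9
            assert o_mit.annual_net_benefit <= o_ref.annual_net_benefit + 1e-9


class TestDeltaUtility:
    def test_balanced_and_neutral_is_zero(self):
        assert delta_utility(0.5, 10.0, 10.0, r0=5.0, delta_r=0.7) == pytest.approx(0.0)

    def test_normalization(self):
        assert delta_utility(0.1, 15.0, 10.0, r0=5.0, delta_r=0.0) == pytest.approx(1.0)

    def test_full_anti_adaptation_norm(self):
        assert delta_utility(0.0, 10.0, 10.0, r0=1.0, delta_r=1.0) == pytest.approx(-1.0)

    def test_invalid_r0_rejected(self):
        with pytest.raises(ValueError):
            delta_utility(0.5, 1.0, 1.0, r0=0.0, delta_r=0.1)


class TestSocialLearningStep:
    def test_boundaries_are_fixed_points(self):
        assert social_learning_step(0.0, 0.5, 10.0) == 0.0
        assert social_learning_step(1.0, 0.5, -10.0) == 1.0

    def test_neutral_utility_is_fixed(self):
        assert social_learning_step(0.5, 0.1, 0.0) == 0.5

    def test_hand_evaluated_update(self):
        assert social_learning_step(0.5, 0.1, 2.0) == pytest.approx(0.55)

    def test_sign_of_move_matches_utility(self):
        assert social_learning_step(0.3, 0.1, 1.0) > 0.3
        assert social_learning_step(0.3, 0.1, -1.0) < 0.3

    def test_clipped_to_unit_interval(self):
        assert social_learning_step(0.5, 10.0, 10.0) == 1.0
        assert social_learning_step(0.5, 10.0, -10.0) == 0.0


def sl_params(**kw) -> SocialLearningParams:
    regions = ("Northeast", "Midwest", "South", "West")
    base = dict(
        kappa={r: 1.0 for r in regions},
        delta={r: 0.3 for r in regions},
        xi={r: 0.5 for r in regions},
        r0=200.0,
        aqi_threshold=100,
    )
    base.update(kw)
    return SocialLearningParams(**base)


class TestRunSocialLearning:
    def test_clean_air_low_initial_share_decays(self, params):
        """No alerts -> no risk signal; with x below 1/2 the norm pushes down."""
        p = make_profile()
        series = {p.cell_id: constant_series(5.0)}
        traj, _ = run_social_learning(series, [p], sl_params(), params, 8, initial_x=0.3)
        xs = traj[traj["cell"] == p.cell_id].sort_values("quarter")["x"].to_numpy()
        assert np.all(np.diff(xs) <= 1e-12)

    def test_costly_polluted_quarters_decay_without_norm(self, params):
        """Alerts present but cost far above perceived benefit: x declines."""
        p = make_profile(hourly_wage=500.0)  # cost dwarfs health benefit
        series = {p.cell_id: generate_daily_pm(30.0, 12.0, 0.5, 0.5, seed=2, cell_id=p.cell_id)}
        sp = sl_params(delta={r: 0.0 for r in ("Northeast", "Midwest", "South", "West")})
        traj, _ = run_social_learning(series, [p], sp, params, 8, initial_x=0.5)
        xs = traj[traj["cell"] == p.cell_id].sort_values("quarter")["x"].to_numpy()
        assert xs[-1] < xs[0]
        assert np.all(np.diff(xs) <= 1e-12)

    def test_norm_lock_in_near_full_adoption(self, params):
        """Strong social norms hold adoption near 1 even when costs exceed risk."""
        p = make_profile(hourly_wage=100.0)
        series = {p.cell_id: generate_daily_pm(30.0, 12.0, 0.5, 0.5, seed=2, cell_id=p.cell_id)}
        sp = sl_params(delta={r: 5.0 for r in ("Northeast", "Midwest", "South", "West")})
        traj, _ = run_social_learning(series, [p], sp, params, 12, initial_x=0.97)
        xs = traj[traj["cell"] == p.cell_id]["x"].to_numpy()
        assert xs[-1] > 0.9

    def test_larger_population_moves_faster(self, params):
        pa = make_profile(cell_id="c0000", adult_population=1e5)
        pb = make_profile(cell_id="c0001", adult_population=9e5)
        s = generate_daily_pm(30.0, 12.0, 0.5, 0.5, seed=2)
        series = {
            "c0000": s.replace_values(s.values),
            "c0001": s.replace_values(s.values),
        }
        traj, _ = run_social_learning(series, [pa, pb], sl_params(), params, 1, initial_x=0.3)
        q1 = traj[traj["quarter"] == 1].set_index("cell")["x"]
        move_a = abs(q1["c0000"] - 0.3)
        move_b = abs(q1["c0001"] - 0.3)
        assert move_b > move_a

    def test_trajectories_stay_in_unit_interval(self, params):
        p = make_profile()
        series = {p.cell_id: generate_daily_pm(40.0, 15.0, 0.5, 0.6, seed=4, cell_id=p.cell_id)}
        sp = sl_params(kappa={r: 15.0 for r in ("Northeast", "Midwest", "South", "West")})
        traj, _ = run_social_learning(series, [p], sp, params, 20, initial_x=0.4)
        assert traj["x"].between(0.0, 1.0).all()

    def test_outcome_accounts_realized_compliance(self, params):
        p = make_profile()
        series = {p.cell_id: generate_daily_pm(30.0, 12.0, 0.5, 0.5, seed=2, cell_id=p.cell_id)}
        traj, outcomes = run_social_learning(series, [p], sl_params(), params, 4, initial_x=0.2)
        o = outcomes[p.cell_id]
        assert 0.0 <= o.compliance <= 1.0
        assert o.pm_equivalent <= o.pm_unadapted + 1e-9
        assert o.popweighted_net_benefit == pytest.approx(
            o.compliance * o.annual_net_benefit)


def simulate_fit_dataset(true_params, r0=200.0, n_quarters=24, x0=0.15, noise=0.0, seed=0):
    """Generate region-level adoption trajectories from the model itself."""
    rng = np.random.default_rng(seed)
    regions = sorted(true_params)
    risk, cost_driver, rows = {}, {}, []
    for region in regions:
        kappa, delta_r, xi_r = true_params[region]
        # seasonally varying drivers: strong winter risk, varying alert load
        q = np.arange(n_quarters)
        risk[region] = 260.0 + 180.0 * np.cos(2 * np.pi * q / 4) + 30.0 * np.cos(2 * np.pi * q / 8)
        cost_driver[region] = 300.0 + 150.0 * np.cos(2 * np.pi * q / 4 + 0.7)
        x = x0
        rows.append({"region": region, "quarter": 0, "x": x0})
        for t in range(n_quarters):
            du = (risk[region][t] - xi_r * cost_driver[region][t]) / r0 \
                + delta_r * (2 * x - 1)
            x = float(np.clip(x + kappa * x * (1 - x) * du, 0.0, 1.0))
            rows.append({"region": region, "quarter": t + 1,
                         "x": float(np.clip(x + noise * rng.standard_normal(), 0.0, 1.0))})
    return pd.DataFrame(rows), risk, cost_driver


TRUE_SL = {
    "Northeast": (0.6, 0.25, 0.45),
    "Midwest": (0.9, 0.15, 0.60),
    "South": (0.45, 0.35, 0.30),
    "West": (0.75, 0.20, 0.50),
}


class TestFitSocialLearning:
    def test_noiseless_parameter_recovery(self):
        obs, risk, cost = simulate_fit_dataset(TRUE_SL)
        fits = fit_social_learning(obs, risk, cost, r0=200.0, seed=1)
        for region, (k, d, x) in TRUE_SL.items():
            f = fits[region]
            assert f.kappa == pytest.approx(k, rel=0.05)
            assert f.delta == pytest.approx(d, rel=0.05)
            assert f.xi == pytest.approx(x, rel=0.05)
            assert f.adj_r2 > 0.9

    def test_constant_trajectory_flagged_non_identifiable(self):
        obs, risk, cost = simulate_fit_dataset(TRUE_SL)
        region = "Northeast"
        obs.loc[obs["region"] == region, "x"] = 0.0  # fixed point: any kappa fits
        fits = fit_social_learning(obs, risk, cost, r0=200.0, seed=1)
        assert not fits[region].identifiable
        for other in ("Midwest", "South", "West"):
            assert fits[other].identifiable

    def test_noise_degrades_fit_quality(self):
        obs0, risk, cost = simulate_fit_dataset(TRUE_SL, noise=0.0)
        obs1, _, _ = simulate_fit_dataset(TRUE_SL, noise=0.02, seed=3)
        clean = fit_social_learning(obs0, risk, cost, r0=200.0, seed=1)
        noisy = fit_social_learning(obs1, risk, cost, r0=200.0, seed=1)
        for region in TRUE_SL:
            assert noisy[region].adj_r2 < clean[region].adj_r2

    def test_too_few_quarters_rejected(self):
        obs, risk, cost = simulate_fit_dataset(TRUE_SL, n_quarters=4)
        with pytest.raises(ValueError, match="quarters"):
            fit_social_learning(obs, risk, cost, r0=200.0)
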