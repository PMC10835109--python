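"""Adaptation decision models: Threshold, Rational actor, Forced, Social Learning.

Each strategy selects, for one cell-year, the set of days on which (some of)
the population stays indoors, and accounts the resulting annual benefits and
costs per complying person plus population-weighted variants.

* Threshold — comply with air-quality alerts at an AQI threshold (100 or
  150), with a configurable compliance fraction (default 20%, the current US
  rate).
* Rational actor — with perfect information, adapt on every day whose
  marginal net benefit is non-negative.  Because the benefit chain is linear
  in concentration, the optimal set is exactly the days above a break-even
  concentration, found by a greedy scan of days sorted by decreasing
  pollution.
* Forced — keep adding days in decreasing-pollution order, regardless of net
  benefit, until the equivalent annual-mean exposure reaches a mitigation
  target (e.g. the mitigated scenario's annual mean).
* Social Learning — a replicator-dynamics model in which the adopter share
  x of each cell's population grows or shrinks each quarter in proportion to
  x(1−x) times the utility difference between adapting and not adapting,
  which mixes perceived health risk, adaptation cost, and social norms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import aqi_alerts
from .exposure_health import (
    HealthEconParams,
    annual_ledger,
    annual_mean,
    daily_benefits_vector,
    daily_cost,
    equivalent_annual_mean,
    psi,
)
from .synthetic_data import DailySeries, GridCellProfile

__all__ = [
    "AdaptationOutcome",
    "SocialLearningParams",
    "SocialLearningState",
    "threshold_strategy",
    "rational_strategy",
    "forced_strategy",
    "no_adaptation",
    "delta_utility",
    "social_learning_step",
    "run_social_learning",
    "fit_social_learning",
    "QUARTER_SLICES",
]

# Quarter boundaries for a fixed 365-day year (91, 91, 91, 92 days).
QUARTER_SLICES = ((0, 91), (91, 182), (182, 273), (273, 365))


@dataclass(frozen=True)
class AdaptationOutcome:
    """Result of one strategy applied to one cell-year.

    ``annual_benefit``/``annual_cost``/``annual_net_benefit`` are USD per
    complying person per year; ``popweighted_*`` scale them by the compliance
    fraction, i.e. they are per capita over the whole cell population.
    ``pm_equivalent`` is the complier's post-adaptation equivalent annual
    mean.  ``feasible`` is False only for Forced runs that cannot reach their
    exposure target even adapting every day.
    """

    cell_id: str
    strategy: str
    adapt_days: tuple
    compliance: float
    annual_benefit: float
    annual_cost: float
    annual_net_benefit: float
    pm_equivalent: float
    pm_unadapted: float
    feasible: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.compliance <= 1.0:
            raise ValueError(f"compliance must lie in [0, 1], got {self.compliance}")
        nb = self.annual_benefit - self.annual_cost
        if abs(nb - self.annual_net_benefit) > 1e-6 * max(1.0, abs(nb)):
            raise ValueError("annual_net_benefit must equal benefit - cost")
        if self.pm_equivalent > self.pm_unadapted + 1e-9:
            raise ValueError("pm_equivalent cannot exceed the unadapted annual mean")

    @property
    def n_adapt_days(self) -> int:
        return len(self.adapt_days)

    @property
    def popweighted_benefit(self) -> float:
        return self.compliance * self.annual_benefit

    @property
    def popweighted_cost(self) -> float:
        return self.compliance * self.annual_cost

    @property
    def popweighted_net_benefit(self) -> float:
        return self.compliance * self.annual_net_benefit

    @property
    def pm_population_mean(self) -> float:
        """Cell-mean exposure: compliers at pm_equivalent, the rest unadapted."""
        return self.compliance * self.pm_equivalent + (1.0 - self.compliance) * self.pm_unadapted


def _outcome(series, days, profile, params, strategy, compliance=1.0, feasible=True):
    _, totals = annual_ledger(series, days, profile, params)
    return AdaptationOutcome(
        cell_id=profile.cell_id,
        strategy=strategy,
        adapt_days=tuple(int(d) for d in sorted(days)),
        compliance=float(compliance),
        annual_benefit=totals["benefit"],
        annual_cost=totals["cost"],
        annual_net_benefit=totals["net_benefit"],
        pm_equivalent=totals["pm_equivalent"],
        pm_unadapted=annual_mean(series),
        feasible=feasible,
    )


def no_adaptation(series, profile: GridCellProfile, params: HealthEconParams) -> AdaptationOutcome:
    """Baseline outcome with no adaptation at all (zero benefit, zero cost)."""
    return _outcome(series, (), profile, params, "none", compliance=0.0)


def threshold_strategy(
    series,
    profile: GridCellProfile,
    params: HealthEconParams,
    aqi_threshold: float = 100,
    compliance: float = 0.2,
) -> AdaptationOutcome:
    """Comply with air-quality alerts: adapt exactly on alert days.

    Benefits and costs per complier use the full outdoor time (xi = 1); the
    population-weighted values scale linearly with the compliance fraction.
    """
    if not 0.0 <= compliance <= 1.0:
        raise ValueError(f"compliance must lie in [0, 1], got {compliance}")
    days = aqi_alerts.alert_days(series, aqi_threshold)
    return _outcome(series, days, profile, params.with_(xi=1.0),
                    f"threshold{int(aqi_threshold)}", compliance=compliance)


def rational_strategy(series, profile: GridCellProfile, params: HealthEconParams) -> AdaptationOutcome:
    """Perfect-information actor: adapt on every day with net benefit >= 0.

    Days are scanned in order of decreasing concentration (ties broken by day
    index); selection stops at the first day whose marginal net benefit is
    negative.  Linearity of the benefit chain makes this greedy set the
    global maximizer of total net benefit over all day subsets.
    """
    p = params.with_(xi=1.0)
    v = series.values if isinstance(series, DailySeries) else np.asarray(series, dtype=float)
    n = len(v)
    b = daily_benefits_vector(v, profile, p)
    c = daily_cost(p.phi(profile), p.xi, profile.outdoor_time)
    nb = b - c
    order = np.lexsort((np.arange(n), -v))
    nb_sorted = nb[order]
    neg = np.nonzero(nb_sorted < 0)[0]
    k = int(neg[0]) if neg.size else n
    days = np.sort(order[:k])
    return _outcome(v, days, profile, p, "rational", compliance=1.0)


def forced_strategy(
    series,
    target_annual_mean: float,
    profile: GridCellProfile,
    params: HealthEconParams,
) -> AdaptationOutcome:
    """Adapt — irrationally if need be — until exposure reaches a target.

    Days are added in decreasing-concentration order until the equivalent
    annual mean is at or below ``target_annual_mean`` (slight overshoot at
    daily granularity) or every day is used; in the latter case the outcome
    is flagged infeasible.  Benefits and costs accrue for all selected days
    regardless of sign.
    """
    if target_annual_mean < 0:
        raise ValueError(f"target_annual_mean must be >= 0, got {target_annual_mean}")
    p = params.with_(xi=1.0)
    v = series.values if isinstance(series, DailySeries) else np.asarray(series, dtype=float)
    n = len(v)
    ps = psi(profile.infiltration_factor, profile.outdoor_time)
    base_mean = v.mean()
    if base_mean <= target_annual_mean:
        return _outcome(v, (), profile, p, "forced", compliance=1.0)
    order = np.lexsort((np.arange(n), -v))
    # mean after adapting the k most polluted days
    reduction = (1.0 - ps) * np.cumsum(v[order]) / n
    means_after = base_mean - reduction
    hit = np.nonzero(means_after <= target_annual_mean + 1e-12)[0]
    if hit.size:
        k = int(hit[0]) + 1
        feasible = True
    else:
        k = n
        feasible = False
    days = np.sort(order[:k])
    return _outcome(v, days, profile, p, "forced", compliance=1.0, feasible=feasible)


# ---------------------------------------------------------------------------
# Social learning (replicator dynamics)
# ---------------------------------------------------------------------------


def identity_norm(x):
    """Linear predominant-norm function omega(x) = x."""
    return x


def smoothstep_norm(x):
    """Smoothed-step alternative norm function, 3x² − 2x³."""
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


@dataclass
class SocialLearningParams:
    """Region-level behavioural parameters of the social-learning model.

    kappa : learning rate per census region (>0).
    delta : social-norm weight per region.
    xi : fitted fraction of outdoor time given up per region, in (0, 1].
    r0 : utility normalization constant (>0).
    risk_multiplier : scales the objective quarterly health benefit into
        perceived risk (1 = perceived equals objective).
    omega : predominant-norm function on adopter share.
    aqi_threshold : alert threshold the adopters comply with.
    """

    kappa: Mapping[str, float]
    delta: Mapping[str, float]
    xi: Mapping[str, float]
    r0: float = 100.0
    risk_multiplier: float = 1.0
    omega: Callable = identity_norm
    aqi_threshold: float = 100.0

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValueError(f"r0 must be > 0, got {self.r0}")
        for r, k in self.kappa.items():
            if k <= 0:
                raise ValueError(f"kappa must be > 0 (region {r!r}: {k})")
        for r, x in self.xi.items():
            if not 0 < x <= 1:
                raise ValueError(f"xi must lie in (0, 1] (region {r!r}: {x})")


@dataclass
class SocialLearningState:
    """Adopter proportions per cell at one quarterly time step."""

    quarter: int
    x: Mapping[str, float]

    def __post_init__(self) -> None:
        for c, v in self.x.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"adopter share must lie in [0, 1] (cell {c!r}: {v})")


def delta_utility(x, perceived_risk, cost, r0: float, delta_r: float,
                  omega: Callable = identity_norm):
    """Utility difference between adapting and not adapting.

    (R − C)/R0 + delta_r·(2·omega(x) − 1): positive when the perceived health
    risk avoided outweighs the cost, shifted by the prevailing social norm
    (anti-adaptation below omega(x)=1/2, pro-adaptation above).
    """
    if r0 <= 0:
        raise ValueError(f"r0 must be > 0, got {r0}")
    return (np.asarray(perceived_risk, dtype=float) - np.asarray(cost, dtype=float)) / r0 \
        + delta_r * (2.0 * omega(np.asarray(x, dtype=float)) - 1.0)


def social_learning_step(x, kappa_sigma, delta_u):
    """One replicator-dynamics update, clipped to [0, 1].

    x' = clip(x + kappa·sigma·x·(1−x)·deltaU).  The boundaries x=0 and x=1
    are fixed points; for interior x the sign of the move equals the sign of
    the utility difference.
    """
    x = np.asarray(x, dtype=float)
    out = x + np.asarray(kappa_sigma, dtype=float) * x * (1.0 - x) * np.asarray(delta_u, dtype=float)
    return np.clip(out, 0.0, 1.0)


def _quarter_indicators(values: np.ndarray, aqi_threshold: float):
    """Per quarter: boolean mask of alert days within the quarter."""
    alerts = np.zeros(len(values), dtype=bool)
    alerts[aqi_alerts.alert_days(values, aqi_threshold)] = True
    return [alerts[a:b] for a, b in QUARTER_SLICES]


def run_social_learning(
    series_by_cell: Mapping[str, "DailySeries | np.ndarray"],
    profiles: Sequence[GridCellProfile],
    sl: SocialLearningParams,
    params: HealthEconParams,
    horizon_quarters: int,
    initial_x: float | Mapping[str, float] = 0.2,
):
    """Run the quarterly social-learning dynamics over a repeating year.

    Each quarter, the adopter fraction x of a cell complies with that
    quarter's alerts; perceived risk is the quarter's summed single-day
    health benefits over alert days (times ``risk_multiplier``) and cost is
    the quarter's summed adaptation cost with the region's fitted xi.  Cell
    population (normalized to mean 1 across cells) scales the learning rate:
    denser cells spread information faster.

    Returns ``(trajectory, outcomes)``: a tidy frame (quarter, cell, region,
    x, delta_u) including the initial state at quarter 0, and per-cell
    AdaptationOutcome for the final simulated year using that year's realized
    compliance per quarter.
    """
    prof = {p.cell_id: p for p in profiles}
    cells = [p.cell_id for p in profiles]
    pops = np.array([prof[c].adult_population for c in cells], dtype=float)
    sigma = pops / pops.mean() if pops.mean() > 0 else np.ones_like(pops)

    # Pre-compute per-cell quarterly drivers (year repeats cyclically).
    risk_q, costdrv_q, ben_q, cost_unit_q, alert_sets = {}, {}, {}, {}, {}
    for c in cells:
        p = prof[c]
        s = series_by_cell[c]
        v = s.values if isinstance(s, DailySeries) else np.asarray(s, dtype=float)
        b_all = daily_benefits_vector(v, p, params)
        masks = _quarter_indicators(v, sl.aqi_threshold)
        xi_r = sl.xi[p.census_region]
        phi = params.phi(p)
        risk_q[c] = [sl.risk_multiplier * float(b_all[a:b][m].sum())
                     for (a, b), m in zip(QUARTER_SLICES, masks)]
        costdrv_q[c] = [float(m.sum()) * phi * p.outdoor_time for m in masks]
        ben_q[c] = [float(b_all[a:b][m].sum()) for (a, b), m in zip(QUARTER_SLICES, masks)]
        cost_unit_q[c] = [float(m.sum()) * daily_cost(phi, xi_r, p.outdoor_time) for m in masks]
        alert_sets[c] = [np.arange(a, b)[m] for (a, b), m in zip(QUARTER_SLICES, masks)]

    if isinstance(initial_x, Mapping):
        x = np.array([float(initial_x[c]) for c in cells])
    else:
        x = np.full(len(cells), float(initial_x))
    if np.any((x < 0) | (x > 1)):
        raise ValueError("initial_x must lie in [0, 1]")

    rows = [
        {"quarter": 0, "cell": c, "region": prof[c].census_region, "x": float(x[i]), "delta_u": np.nan}
        for i, c in enumerate(cells)
    ]
    x_hist = [x.copy()]
    for t in range(horizon_quarters):
        q = t % 4
        du = np.empty(len(cells))
        for i, c in enumerate(cells):
            region = prof[c].census_region
            xi_r = sl.xi[region]
            du[i] = delta_utility(
                x[i], risk_q[c][q], xi_r * costdrv_q[c][q], sl.r0, sl.delta[region], sl.omega
            )
        kappa = np.array([sl.kappa[prof[c].census_region] for c in cells])
        x = social_learning_step(x, kappa * sigma, du)
        x_hist.append(x.copy())
        rows.extend(
            {"quarter": t + 1, "cell": c, "region": prof[c].census_region,
             "x": float(x[i]), "delta_u": float(du[i])}
            for i, c in enumerate(cells)
        )
    trajectory = pd.DataFrame(rows)

    # Annual outcome over the last 4 simulated quarters (or fewer at short
    # horizons): per quarter, the realized adopter fraction complies.
    last = min(4, horizon_quarters)
    outcomes = {}
    for i, c in enumerate(cells):
        p = prof[c]
        ps = psi(p.infiltration_factor, p.outdoor_time)
        s = series_by_cell[c]
        v = s.values if isinstance(s, DailySeries) else np.asarray(s, dtype=float)
        benefit = cost = 0.0
        adapted_reduction = 0.0
        mean_x = 0.0
        all_days: list = []
        for j in range(last):
            t = horizon_quarters - last + j
            q = t % 4
            xq = float(x_hist[t][i])  # share in force during quarter t
            benefit += xq * ben_q[c][q]
            cost += xq * cost_unit_q[c][q]
            days = alert_sets[c][q]
            all_days.extend(int(d) for d in days)
            adapted_reduction += xq * (1.0 - ps) * v[days].sum() / len(v)
            mean_x += xq / max(last, 1)
        pm_unadapted = float(v.mean())
        outcomes[c] = AdaptationOutcome(
            cell_id=c,
            strategy="social",
            adapt_days=tuple(sorted(all_days)),
            compliance=mean_x,
            annual_benefit=benefit / mean_x if mean_x > 0 else 0.0,
            annual_cost=cost / mean_x if mean_x > 0 else 0.0,
            annual_net_benefit=(benefit - cost) / mean_x if mean_x > 0 else 0.0,
            pm_equivalent=pm_unadapted - (adapted_reduction / mean_x if mean_x > 0 else 0.0),
            pm_unadapted=pm_unadapted,
        )
    return trajectory, outcomes


# ---------------------------------------------------------------------------
# Fitting the social-learning model to observed adoption trajectories
# ---------------------------------------------------------------------------


@dataclass
class SocialLearningFit:
    """Fitted parameters and goodness of fit for one region."""

    region: str
    kappa: float
    delta: float
    xi: float
    r0: float
    adj_r2: float
    sse: float
    converged: bool
    identifiable: bool = True


def _simulate_region(theta, r0, risk, cost_driver, x0, n_steps, omega):
    kappa, delta_r, xi_r = theta
    x = float(x0)
    out = np.empty(n_steps)
    for t in range(n_steps):
        du = (risk[t] - xi_r * cost_driver[t]) / r0 + delta_r * (2.0 * omega(x) - 1.0)
        x = float(np.clip(x + kappa * x * (1.0 - x) * du, 0.0, 1.0))
        out[t] = x
    return out


def fit_social_learning(
    observed: pd.DataFrame,
    risk: Mapping[str, np.ndarray],
    cost_driver: Mapping[str, np.ndarray],
    r0: float,
    omega: Callable = identity_norm,
    n_starts: int = 8,
    seed: int = 0,
    bounds=((1e-3, 0.0, 1e-3), (20.0, 5.0, 1.0)),
) -> dict:
    """Fit (kappa, delta, xi) per region to observed quarterly adopter shares.

    ``observed`` is tidy (region, quarter, x) with quarters 0..T; the model
    is simulated forward from the observed initial share and compared to
    quarters 1..T by least squares.  ``risk`` and ``cost_driver`` give the
    per-quarter perceived-risk and pre-xi cost series per region (the fitted
    xi multiplies the cost driver).  R0 is held fixed: it divides the same
    utility term kappa multiplies, so the pair is not jointly identifiable
    from trajectories alone.  Multi-start local least squares with a fixed
    seed keeps the fit deterministic; non-convergence returns the best-found
    parameters flagged ``converged=False``.  A constant observed trajectory
    is flagged non-identifiable (any kappa fits a fixed point).
    """
    regions = sorted(observed["region"].unique())
    if len(regions) < 2:
        raise ValueError("need at least 2 regions to fit")
    rng = np.random.default_rng(seed)
    lo = np.asarray(bounds[0], dtype=float)
    hi = np.asarray(bounds[1], dtype=float)
    fits = {}
    for region in regions:
        grp = observed[observed["region"] == region].sort_values("quarter")
        xs = grp["x"].to_numpy(dtype=float)
        if len(xs) < 9:
            raise ValueError(f"need >= 8 quarters of observations (region {region!r})")
        x0, target = xs[0], xs[1:]
        n_steps = len(target)
        R = np.asarray(risk[region], dtype=float)
        D = np.asarray(cost_driver[region], dtype=float)
        if len(R) < n_steps or len(D) < n_steps:
            raise ValueError(f"driver series shorter than observations (region {region!r})")

        identifiable = bool(np.var(xs) > 1e-12)

        def resid(theta):
            return _simulate_region(theta, r0, R, D, x0, n_steps, omega) - target

        best = None
        starts = lo + (hi - lo) * rng.random((n_starts, 3))
        starts[0] = np.array([1.0, 0.3, 0.5])  # one deterministic mid-range start
        for s0 in starts:
            try:
                res = least_squares(resid, s0, bounds=(lo, hi), method="trf")
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            raise RuntimeError(f"all optimizer starts failed for region {region!r}")
        sse = float(2.0 * best.cost)
        sst = float(((target - target.mean()) ** 2).sum())
        n, p = n_steps, 3
        r2 = 1.0 - sse / sst if sst > 0 else (1.0 if sse < 1e-12 else 0.0)
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1) if n > p + 1 else r2
        fits[region] = SocialLearningFit(
            region=region,
            kappa=float(best.x[0]),
            delta=float(best.x[1]),
            xi=float(best.x[2]),
            r0=float(r0),
            adj_r2=float(adj),
            sse=sse,
            converged=bool(best.success),
            identifiable=identifiable,
        )
    return fits


def outcomes_to_frame(outcomes: Mapping[str, AdaptationOutcome],
                      scenario: str = "", year_label: str = "") -> pd.DataFrame:
    """Tidy table of strategy outcomes, one row per cell."""
    rows = []
    for c, o in outcomes.items():
        rows.append(
            {
                "cell_id": c,
                "scenario": scenario,
                "epoch": year_label,
                "strategy": o.strategy,
                "adapt_day_count": o.n_adapt_days,
                "compliance": o.compliance,
                "benefit": o.annual_benefit,
                "cost": o.annual_cost,
                "net_benefit": o.annual_net_benefit,
                "popweighted_benefit": o.popweighted_benefit,
                "popweighted_cost": o.popweighted_cost,
                "popweighted_net_benefit": o.popweighted_net_benefit,
                "pm_equivalent": o.pm_equivalent,
                "pm_unadapted": o.pm_unadapted,
                "feasible": o.feasible,
            }
        )
    return pd.DataFrame(rows)
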