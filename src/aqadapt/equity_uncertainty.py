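"""Population-weighted aggregation, Monte-Carlo uncertainty, sensitivity sweeps.

National summaries are population-weighted means over grid cells.  Health and
valuation uncertainty is propagated by Monte Carlo over the relative risk
(normal on ln RR) and the VSL (lognormal), holding each strategy's
adaptation-day sets fixed at their central-estimate values, and reporting
empirical 2.5th/97.5th percentile intervals — percentile rather than
normal-approximation intervals because the lognormal VSL makes the benefit
distribution right-skewed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exposure_health import HealthEconParams
from .strategies import (
    AdaptationOutcome,
    forced_strategy,
    no_adaptation,
    rational_strategy,
    threshold_strategy,
)
from .synthetic_data import GridCellProfile

__all__ = [
    "McConfig",
    "CiResult",
    "popweighted_mean",
    "draw_rr_vsl",
    "monte_carlo_ci",
    "benefit_hook",
    "build_summary_table",
    "summary_to_text",
    "sensitivity_sweep",
]


@dataclass(frozen=True)
class McConfig:
    """Monte-Carlo settings for health/valuation uncertainty.

    rr_ci: 95% interval of the relative risk; ln(RR) is sampled normally with
    sd = (ln hi − ln lo)/(2·1.96), truncated to RR > 1.  vsl_sd is the
    arithmetic standard deviation of the lognormal VSL draw (0 gives a point
    mass).  ``vsl_mean``/``vsl_sd`` of ``None`` default to the central VSL
    and 0.6× that value.
    """

    n_draws: int = 5000
    seed: int = 0
    rr_central: float = 1.14
    rr_ci: tuple = (1.07, 1.22)
    vsl_mean: float | None = None
    vsl_sd: float | None = None

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError(f"n_draws must be >= 1, got {self.n_draws}")
        lo, hi = self.rr_ci
        if not (0 < lo <= self.rr_central <= hi):
            raise ValueError(f"rr_ci must bracket rr_central, got {self.rr_ci}")


@dataclass(frozen=True)
class CiResult:
    mean: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.mean + 1e-9 and self.mean <= self.ci_high + 1e-9):
            raise ValueError("interval must contain the mean")


def popweighted_mean(values, weights) -> float:
    """Population-weighted mean: sum(w·v)/sum(w)."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape:
        raise ValueError("values and weights must have the same shape")
    if np.any(w < 0):
        raise ValueError("weights must be >= 0")
    tw = w.sum()
    if tw <= 0:
        raise ValueError("total weight must be > 0")
    return float((w * v).sum() / tw)


def draw_rr_vsl(mc: McConfig, params: HealthEconParams, n: int | None = None,
                rng: np.random.Generator | None = None):
    """Sample (rr, vsl) draw vectors according to the MC configuration."""
    n = n if n is not None else mc.n_draws
    rng = rng if rng is not None else np.random.default_rng(mc.seed)
    lo, hi = mc.rr_ci
    if hi > lo:
        sd_log = (np.log(hi) - np.log(lo)) / (2.0 * 1.959963984540054)
        rr = np.exp(np.log(mc.rr_central) + sd_log * rng.standard_normal(n))
        rr = np.maximum(rr, 1.0 + 1e-9)  # truncate: RR must exceed 1
    else:
        rr = np.full(n, mc.rr_central)
    vmean = mc.vsl_mean if mc.vsl_mean is not None else params.vsl
    vsd = mc.vsl_sd if mc.vsl_sd is not None else 0.6 * vmean
    if vsd > 0:
        sigma2 = np.log1p((vsd / vmean) ** 2)
        mu = np.log(vmean) - sigma2 / 2.0
        vsl = np.exp(mu + np.sqrt(sigma2) * rng.standard_normal(n))
    else:
        vsl = np.full(n, vmean)
    return rr, vsl


def monte_carlo_ci(hook: Callable, mc: McConfig, params: HealthEconParams | None = None) -> CiResult:
    """Mean and 95% percentile interval of ``hook(rr, vsl)`` over MC draws.

    ``hook`` recomputes the per-capita quantity for vectors of (rr, vsl)
    draws, with adaptation-day sets held fixed.  Deterministic for a fixed
    seed; degenerate (point-mass) draw distributions give a zero-width
    interval.
    """
    params = params or HealthEconParams()
    rr, vsl = draw_rr_vsl(mc, params)
    vals = np.asarray(hook(rr, vsl), dtype=float)
    if vals.shape != rr.shape:
        raise ValueError("hook must return one value per draw")
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return CiResult(mean=float(vals.mean()), ci_low=float(lo), ci_high=float(hi))


def benefit_hook(outcomes: Mapping[str, AdaptationOutcome],
                 profiles: Sequence[GridCellProfile],
                 params: HealthEconParams) -> Callable:
    """Hook recomputing the national per-capita adaptation benefit per draw.

    Exploits linearity: with day sets frozen, the population-weighted benefit
    is vsl · (rr−1)/rr · K where K aggregates each cell's fixed exposure
    reduction, baseline mortality and compliance.
    """
    prof = {p.cell_id: p for p in profiles}
    w = np.array([prof[c].adult_population for c in outcomes], dtype=float)
    k = np.array(
        [
            prof[c].baseline_mortality_rate
            * (o.pm_unadapted - o.pm_equivalent)
            * o.compliance
            / params.rr_reference_increment
            for c, o in outcomes.items()
        ]
    )
    k_national = float((w * k).sum() / w.sum())

    def hook(rr, vsl):
        rr = np.asarray(rr, dtype=float)
        vsl = np.asarray(vsl, dtype=float)
        return vsl * ((rr - 1.0) / rr) * k_national

    return hook


def _mitigation_benefit_cells(outcomes_ref, outcomes_mit, profiles, params,
                              rr=None, vsl=None):
    """Per-capita mitigation benefit per cell given the row's adaptation.

    The exposed concentration under each scenario is the cell-population mean
    (compliers at the adapted equivalent mean, the rest at the unadapted
    mean); adaptation therefore shrinks the REF−mitigated exposure gap — the
    adapters staying inside gain less from cleaner outdoor air.
    """
    rr = rr if rr is not None else params.rr
    vsl = vsl if vsl is not None else params.vsl
    prof = {p.cell_id: p for p in profiles}
    cells = list(outcomes_ref)
    gap = np.array(
        [outcomes_ref[c].pm_population_mean - outcomes_mit[c].pm_population_mean for c in cells]
    )
    y0 = np.array([prof[c].baseline_mortality_rate for c in cells])
    af = (np.asarray(rr) - 1.0) / np.asarray(rr)
    return np.asarray(vsl) * y0 * af * gap / params.rr_reference_increment


STRATEGY_RUNNERS = {
    "none": lambda s, p, hp, kw: no_adaptation(s, p, hp),
    "threshold100": lambda s, p, hp, kw: threshold_strategy(s, p, hp, 100, kw.get("compliance", 0.2)),
    "threshold150": lambda s, p, hp, kw: threshold_strategy(s, p, hp, 150, kw.get("compliance", 0.2)),
    "threshold100_full": lambda s, p, hp, kw: threshold_strategy(s, p, hp, 100, 1.0),
    "threshold150_full": lambda s, p, hp, kw: threshold_strategy(s, p, hp, 150, 1.0),
    "rational": lambda s, p, hp, kw: rational_strategy(s, p, hp),
    "forced": lambda s, p, hp, kw: forced_strategy(s, kw["target"][p.cell_id], p, hp),
}


def run_strategies_on_ensemble(ensemble, profiles, params, strategy: str, **kw) -> dict:
    """Apply one strategy to every (cell, replicate); replicate-mean outcomes.

    Returns cell_id → AdaptationOutcome whose dollar figures and exposure
    means are averaged over replicates (day sets are taken from the first
    replicate for bookkeeping).
    """
    runner = STRATEGY_RUNNERS[strategy]
    prof = {p.cell_id: p for p in profiles}
    out = {}
    for c in ensemble.cells:
        per_rep = [runner(ensemble.series[c][r], prof[c], params, kw) for r in ensemble.replicates]
        o0 = per_rep[0]
        out[c] = replace(
            o0,
            annual_benefit=float(np.mean([o.annual_benefit for o in per_rep])),
            annual_cost=float(np.mean([o.annual_cost for o in per_rep])),
            annual_net_benefit=float(np.mean([o.annual_net_benefit for o in per_rep])),
            pm_equivalent=float(np.mean([o.pm_equivalent for o in per_rep])),
            pm_unadapted=float(np.mean([o.pm_unadapted for o in per_rep])),
            feasible=all(o.feasible for o in per_rep),
        )
    return out


def build_summary_table(
    outcomes: Mapping[tuple, Mapping[str, AdaptationOutcome]],
    profiles: Sequence[GridCellProfile],
    params: HealthEconParams,
    mc: McConfig,
    mitigation_pairs: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """National summary crossing mitigation level × adaptation strategy.

    ``outcomes`` maps (mitigation_label, strategy_label) → per-cell outcomes.
    Adaptation benefit carries a 95% Monte-Carlo interval; the mitigation
    benefit of a row under a mitigated scenario is the population-weighted
    mortality-burden difference between the reference and mitigated exposures
    for that row's (partially adapting) population.  ``mitigation_pairs``
    maps a mitigated scenario label to its reference label (default: any
    scenario named "P37" pairs with "REF").
    """
    if mitigation_pairs is None:
        mitigation_pairs = {"P37": "REF"}
    prof = {p.cell_id: p for p in profiles}
    rows = []
    for (mit, strat), oc in outcomes.items():
        cells = list(oc)
        w = np.array([prof[c].adult_population for c in cells])
        ben = popweighted_mean([oc[c].popweighted_benefit for c in cells], w)
        cost = popweighted_mean([oc[c].popweighted_cost for c in cells], w)
        nb = popweighted_mean([oc[c].popweighted_net_benefit for c in cells], w)
        if ben > 0:
            ci = monte_carlo_ci(benefit_hook(oc, profiles, params), mc, params)
            ci_low, ci_high = ci.ci_low, ci.ci_high
        else:
            ci_low = ci_high = 0.0
        mit_ben = mit_lo = mit_hi = 0.0
        ref_label = mitigation_pairs.get(mit)
        if ref_label is not None and (ref_label, strat) in outcomes:
            oc_ref = outcomes[(ref_label, strat)]
            central = _mitigation_benefit_cells(oc_ref, oc, profiles, params)
            mit_ben = popweighted_mean(central, w)
            rr_d, vsl_d = draw_rr_vsl(mc, params)
            gap = popweighted_mean(
                [
                    prof[c].baseline_mortality_rate
                    * (oc_ref[c].pm_population_mean - oc[c].pm_population_mean)
                    / params.rr_reference_increment
                    for c in cells
                ],
                w,
            )
            draws = vsl_d * ((rr_d - 1.0) / rr_d) * gap
            mit_lo, mit_hi = (float(x) for x in np.percentile(draws, [2.5, 97.5]))
        rows.append(
            {
                "mitigation": mit,
                "strategy": strat,
                "adaptation_benefit": ben,
                "benefit_ci_low": ci_low,
                "benefit_ci_high": ci_high,
                "adaptation_cost": cost,
                "adaptation_net_benefit": nb,
                "mitigation_benefit": mit_ben,
                "mitigation_ci_low": mit_lo,
                "mitigation_ci_high": mit_hi,
            }
        )
    return pd.DataFrame(rows)


def summary_to_text(table: pd.DataFrame) -> str:
    """Human-readable summary with CIs in parentheses (per-capita 2020 USD)."""
    if table.empty:
        return "(no summary rows)\n"
    lines = [
        f"{'Mitigation':<12}{'Strategy':<18}{'Adapt. cost':>12}"
        f"{'Adapt. benefit (95% CI)':>34}{'Net benefit':>13}{'Mitig. benefit (95% CI)':>34}"
    ]
    for _, r in table.iterrows():
        ben = f"${r.adaptation_benefit:,.0f} (${r.benefit_ci_low:,.0f}, ${r.benefit_ci_high:,.0f})"
        mit = f"${r.mitigation_benefit:,.0f} (${r.mitigation_ci_low:,.0f}, ${r.mitigation_ci_high:,.0f})"
        lines.append(
            f"{r.mitigation:<12}{r.strategy:<18}{'$' + format(r.adaptation_cost, ',.0f'):>12}"
            f"{ben:>34}{'$' + format(r.adaptation_net_benefit, ',.0f'):>13}{mit:>34}"
        )
    return "\n".join(lines) + "\n"


def sensitivity_sweep(
    variable: str,
    grid: Sequence[float],
    series_by_cell: Mapping[str, np.ndarray],
    profiles: Sequence[GridCellProfile],
    params: HealthEconParams,
    strategy: str = "rational",
) -> pd.DataFrame:
    """One-at-a-time sweep of population-weighted rational net benefits.

    ``variable`` is one of 'tout', 'phi', 'finf', 'annual_mean'; all cells are
    set to each grid value in turn (for 'annual_mean', every series is
    rescaled to that national mean, preserving relative spatial and daily
    patterns).  Net benefits fall with phi and FINF and rise with Tout and
    concentration.
    """
    if variable not in ("tout", "phi", "finf", "annual_mean"):
        raise ValueError(f"unknown sweep variable {variable!r}")
    if strategy != "rational":
        raise ValueError("sensitivity sweep is defined for the rational strategy")
    w = np.array([p.adult_population for p in profiles])
    rows = []
    base_means = {c: float(np.mean(np.asarray(v, dtype=float)))
                  for c, v in series_by_cell.items()}
    national = np.mean(list(base_means.values()))
    for val in grid:
        hp = params
        nbs, bens, costs = [], [], []
        for p in profiles:
            prof = p
            v = np.asarray(series_by_cell[p.cell_id], dtype=float)
            if variable == "tout":
                prof = _with(p, outdoor_time=float(val))
            elif variable == "finf":
                prof = _with(p, infiltration_factor=float(val))
            elif variable == "phi":
                hp = params.with_(hourly_cost=float(val))
            elif variable == "annual_mean":
                v = v * (float(val) / national)
            o = rational_strategy(v, prof, hp)
            nbs.append(o.annual_net_benefit)
            bens.append(o.annual_benefit)
            costs.append(o.annual_cost)
        rows.append(
            {
                "variable": variable,
                "value": float(val),
                "net_benefit": popweighted_mean(nbs, w),
                "benefit": popweighted_mean(bens, w),
                "cost": popweighted_mean(costs, w),
            }
        )
    return pd.DataFrame(rows)


def _with(profile: GridCellProfile, **kw) -> GridCellProfile:
    from dataclasses import replace as dc_replace

    return dc_replace(profile, **kw)
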