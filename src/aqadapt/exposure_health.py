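"""Exposure, mortality and monetization chain for adaptation accounting.

A person who adapts on a day spends all 24 h indoors, where only a fraction
FINF of outdoor PM2.5 is present; on a normal day they spend Tout hours
outdoors.  The ratio of exposures,

    psi = 24·FINF / (Tout + (24 − Tout)·FINF),

scales that day's outdoor concentration in the annual exposure average.  The
resulting drop in equivalent annual-mean concentration lowers all-cause
mortality through a linearized concentration–response function with relative
risk RR per 10 µg/m³,

    delta_I = Y0 · (RR − 1)/RR · delta_PM / 10,

which is monetized at the value of a statistical life (VSL).  The cost of
adapting a day is the value of outdoor time given up, phi·xi·Tout.  Because
the whole chain is linear in concentration, a day's marginal benefit against
the no-adaptation baseline equals its contribution to any adaptation-day set.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .synthetic_data import DailySeries, GridCellProfile

__all__ = [
    "HealthEconParams",
    "ExposureResult",
    "psi",
    "annual_mean",
    "equivalent_annual_mean",
    "single_day_delta_pm",
    "delta_incidence",
    "daily_benefit",
    "daily_cost",
    "daily_benefits_vector",
    "breakeven_concentration",
    "annual_ledger",
    "exposure_result",
]


@dataclass(frozen=True)
class HealthEconParams:
    """Health and economic valuation parameters.

    vsl_2008_usd : EPA central VSL in 2008 USD (7.9 million).
    vsl_inflation_factor : CPI-based 2008→2020 USD factor.
    rr : relative risk of all-cause premature mortality per
        ``rr_reference_increment`` (10 µg/m³) of annual-mean PM2.5.
    xi : fraction of outdoor time given up when adapting, in (0, 1].
    hourly_cost : USD/h; ``None`` means use each cell's mean hourly wage.
    cr_form : "linear" applies the attributable fraction (RR−1)/RR scaled
        linearly by delta_PM/10; "loglinear" uses the BenMAP-style
        1 − exp(−beta·delta_PM) with beta = ln(RR)/10.
    """

    vsl_2008_usd: float = 7.9e6
    vsl_inflation_factor: float = 1.27
    rr: float = 1.14
    rr_reference_increment: float = 10.0
    xi: float = 1.0
    hourly_cost: float | None = None
    cr_form: str = "linear"

    def __post_init__(self) -> None:
        if self.vsl_2008_usd <= 0 or self.vsl_inflation_factor <= 0:
            raise ValueError("VSL and inflation factor must be > 0")
        if self.rr <= 1:
            raise ValueError(f"rr must be > 1, got {self.rr}")
        if not 0 < self.xi <= 1:
            raise ValueError(f"xi must lie in (0, 1], got {self.xi}")
        if self.cr_form not in ("linear", "loglinear"):
            raise ValueError(f"cr_form must be 'linear' or 'loglinear', got {self.cr_form!r}")

    @property
    def vsl(self) -> float:
        """Central VSL in 2020 USD."""
        return self.vsl_2008_usd * self.vsl_inflation_factor

    def with_(self, **kw) -> "HealthEconParams":
        return replace(self, **kw)

    def phi(self, profile: GridCellProfile) -> float:
        """Hourly adaptation cost for a cell (its wage unless overridden)."""
        return self.hourly_cost if self.hourly_cost is not None else profile.hourly_wage


@dataclass(frozen=True)
class ExposureResult:
    """Annual exposure summary for one cell-year and adaptation-day set."""

    psi: float
    pm_annual_unadapted: float
    pm_annual_adapted: float

    def __post_init__(self) -> None:
        if self.pm_annual_adapted > self.pm_annual_unadapted + 1e-9:
            raise ValueError("adapted annual mean cannot exceed unadapted annual mean")

    @property
    def delta_pm(self) -> float:
        return self.pm_annual_unadapted - self.pm_annual_adapted


def psi(finf: float, tout: float) -> float:
    """Exposure ratio of an all-indoors day to a normal day with ``tout`` h outside.

    Lies in [FINF, 1]; equals 1 when indoor air equals outdoor air (FINF=1)
    and 0 when the building blocks everything (FINF=0).
    """
    if not 0.0 <= finf <= 1.0:
        raise ValueError(f"finf must lie in [0, 1], got {finf}")
    if not 0.0 < tout <= 24.0:
        denom = tout + (24.0 - tout) * finf
        if denom == 0:
            raise ValueError("psi undefined for tout=0 with finf=0")
        raise ValueError(f"tout must lie in (0, 24], got {tout}")
    return 24.0 * finf / (tout + (24.0 - tout) * finf)


def _values(series) -> np.ndarray:
    return series.values if isinstance(series, DailySeries) else np.asarray(series, dtype=float)


def annual_mean(series) -> float:
    """Plain annual mean concentration (sum over days / number of days)."""
    return float(_values(series).mean())


def equivalent_annual_mean(series, adapt_days: Iterable[int], psi_ratio: float) -> float:
    """Annual-mean outdoor-equivalent concentration after adapting on a day set.

    Each adapted day contributes ``psi`` times its outdoor concentration; all
    other days contribute in full.  With an empty set this is the plain annual
    mean; with every day adapted it is ``psi`` times the annual mean.
    Accepts arrays of any length for toy-year analyses (denominator adapts).
    """
    v = _values(series)
    n = len(v)
    days = np.asarray(sorted(set(int(d) for d in adapt_days)), dtype=int)
    if days.size and (days.min() < 0 or days.max() >= n):
        raise ValueError(f"adaptation day index out of range [0, {n})")
    total = v.sum()
    adapted_sum = v[days].sum() if days.size else 0.0
    return float((total - (1.0 - psi_ratio) * adapted_sum) / n)


def single_day_delta_pm(pm_day: float, psi_ratio: float, n_days: int = 365):
    """Drop in equivalent annual mean from adapting one day: (1−psi)·PM_d/n."""
    return (1.0 - psi_ratio) * np.asarray(pm_day, dtype=float) / n_days


def delta_incidence(y0: float, rr: float, delta_pm, increment: float = 10.0,
                    form: str = "linear"):
    """Change in premature-mortality incidence (deaths/person/year).

    ``linear`` (default): Y0 · (RR−1)/RR · delta_PM/increment.
    ``loglinear``: Y0 · (1 − exp(−ln(RR)/increment · delta_PM)).
    """
    if y0 <= 0:
        raise ValueError(f"y0 must be > 0, got {y0}")
    if rr <= 0:
        raise ValueError(f"rr must be > 0, got {rr}")
    d = np.asarray(delta_pm, dtype=float)
    if np.any(d < 0):
        raise ValueError("delta_pm must be >= 0")
    if form == "linear":
        out = y0 * ((rr - 1.0) / rr) * (d / increment)
    elif form == "loglinear":
        beta = np.log(rr) / increment
        out = y0 * (1.0 - np.exp(-beta * d))
    else:
        raise ValueError(f"form must be 'linear' or 'loglinear', got {form!r}")
    return float(out) if np.isscalar(delta_pm) else out


def daily_benefit(vsl: float, delta_i):
    """Monetized benefit of an incidence change: VSL × delta_I (USD/person/yr)."""
    out = vsl * np.asarray(delta_i, dtype=float)
    return float(out) if np.isscalar(delta_i) else out


def daily_cost(phi: float, xi: float, tout: float) -> float:
    """Cost of adapting one day: value of outdoor time given up, phi·xi·Tout."""
    return phi * xi * tout


def daily_benefits_vector(values: np.ndarray, profile: GridCellProfile,
                          params: HealthEconParams) -> np.ndarray:
    """Single-day adaptation benefit for every day of a series (USD/person/yr)."""
    v = np.asarray(values, dtype=float)
    ps = psi(profile.infiltration_factor, profile.outdoor_time)
    dpm = single_day_delta_pm(v, ps, n_days=len(v))
    di = delta_incidence(profile.baseline_mortality_rate, params.rr, dpm,
                         increment=params.rr_reference_increment, form=params.cr_form)
    return daily_benefit(params.vsl, di)


def breakeven_concentration(profile: GridCellProfile, params: HealthEconParams,
                            n_days: int = 365) -> float:
    """Daily concentration PM* at which one day's net benefit is zero.

    From the linear chain: PM* = C_d · n · increment · RR /
    (VSL · Y0 · (RR−1) · (1−psi)).  Days above PM* have positive net benefit;
    infinite when psi = 1 (adapting cannot change exposure).
    """
    ps = psi(profile.infiltration_factor, profile.outdoor_time)
    if ps >= 1.0:
        return float("inf")
    c_d = daily_cost(params.phi(profile), params.xi, profile.outdoor_time)
    return (
        c_d * n_days * params.rr_reference_increment * params.rr
        / (params.vsl * profile.baseline_mortality_rate * (params.rr - 1.0) * (1.0 - ps))
    )


def annual_ledger(series, adapt_days: Iterable[int], profile: GridCellProfile,
                  params: HealthEconParams):
    """Per-day benefit/cost/net-benefit ledger plus annual totals.

    Each adapted day's benefit is its single-day marginal benefit against the
    no-adaptation baseline (exact for the linear chain); non-adaptation days
    carry zeros.  Returns ``(ledger_frame, totals_dict)``; totals sum over
    adaptation days only and include the post-adaptation equivalent annual
    mean.
    """
    v = _values(series)
    n = len(v)
    days = np.asarray(sorted(set(int(d) for d in adapt_days)), dtype=int)
    if days.size and (days.min() < 0 or days.max() >= n):
        raise ValueError(f"adaptation day index out of range [0, {n})")
    ps = psi(profile.infiltration_factor, profile.outdoor_time)
    adapted = np.zeros(n, dtype=bool)
    adapted[days] = True

    benefit = np.zeros(n)
    cost = np.zeros(n)
    dinc = np.zeros(n)
    if days.size:
        b_all = daily_benefits_vector(v, profile, params)
        dpm = single_day_delta_pm(v, ps, n_days=n)
        di = delta_incidence(profile.baseline_mortality_rate, params.rr, dpm,
                             increment=params.rr_reference_increment, form=params.cr_form)
        c_d = daily_cost(params.phi(profile), params.xi, profile.outdoor_time)
        benefit[adapted] = b_all[adapted]
        cost[adapted] = c_d
        dinc[adapted] = np.asarray(di)[adapted]

    ledger = pd.DataFrame(
        {
            "day": np.arange(n),
            "pm": v,
            "adapted": adapted,
            "benefit": benefit,
            "cost": cost,
            "net_benefit": benefit - cost,
            "delta_incidence": dinc,
        }
    )
    totals = {
        "benefit": float(benefit.sum()),
        "cost": float(cost.sum()),
        "net_benefit": float((benefit - cost).sum()),
        "pm_equivalent": equivalent_annual_mean(v, days, ps),
        "n_adapt_days": int(days.size),
    }
    return ledger, totals


def exposure_result(series, adapt_days: Iterable[int], profile: GridCellProfile) -> ExposureResult:
    """Exposure summary (psi, unadapted and adapted annual means) for a day set."""
    ps = psi(profile.infiltration_factor, profile.outdoor_time)
    return ExposureResult(
        psi=ps,
        pm_annual_unadapted=annual_mean(series),
        pm_annual_adapted=equivalent_annual_mean(series, adapt_days, ps),
    )
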