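"""AQI conversion, alert-day detection, and alert-day statistics.

The US EPA Air Quality Index maps a pollutant concentration onto a 0–500
index by piecewise-linear interpolation between published breakpoints.  Air
quality alerts are issued when the AQI exceeds a threshold: 100 for sensitive
groups, 150 for the general population; for 24-h mean PM2.5 these correspond
to 35.4 and 55.4 µg/m³.  This module counts alert days per cell-year (ADY)
and the extra alert days relative to a start-of-century baseline (EADY), and
builds population-weighted cumulative distributions of those statistics by
race, income or housing-leakage group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence
import math
import warnings

import numpy as np
import pandas as pd

from .synthetic_data import DailySeries, GridCellProfile

__all__ = [
    "AqiBreakpointTable",
    "AlertStats",
    "EPA_PM25_BREAKPOINTS",
    "pm_to_aqi",
    "aqi_to_pm",
    "alert_days",
    "ady",
    "eady",
    "alert_stats",
    "subgroup_cdf",
]


@dataclass(frozen=True)
class AqiBreakpointTable:
    """Ordered contiguous (conc_low, conc_high, aqi_low, aqi_high) segments."""

    segments: tuple

    def __post_init__(self) -> None:
        segs = tuple(tuple(float(x) for x in s) for s in self.segments)
        object.__setattr__(self, "segments", segs)
        prev = None
        for cl, ch, al, ah in segs:
            if not (cl < ch and al < ah):
                raise ValueError(f"breakpoint segment not increasing: {(cl, ch, al, ah)}")
            if prev is not None:
                pc, pa = prev
                # contiguity at EPA reporting resolution (0.1 µg/m³, 1 AQI unit)
                if not (math.isclose(cl - pc, 0.1, abs_tol=1e-9) and al == pa + 1):
                    raise ValueError(
                        f"segments not contiguous: previous ends ({pc}, {pa}), next starts ({cl}, {al})"
                    )
            prev = (ch, ah)

    @property
    def conc_max(self) -> float:
        return self.segments[-1][1]

    @property
    def aqi_max(self) -> float:
        return self.segments[-1][3]


# 2012-vintage EPA PM2.5 breakpoints (24-h mean, µg/m³); the 35.4 → 100 and
# 55.4 → 150 knots are the alert thresholds used throughout.
EPA_PM25_BREAKPOINTS = AqiBreakpointTable(
    segments=(
        (0.0, 12.0, 0, 50),
        (12.1, 35.4, 51, 100),
        (35.5, 55.4, 101, 150),
        (55.5, 150.4, 151, 200),
        (150.5, 250.4, 201, 300),
        (250.5, 350.4, 301, 400),
        (350.5, 500.4, 401, 500),
    )
)


def pm_to_aqi(conc, table: AqiBreakpointTable = EPA_PM25_BREAKPOINTS):
    """Convert 24-h mean PM2.5 (µg/m³) to the integer AQI sub-index.

    Follows EPA convention: the concentration is truncated to 0.1 µg/m³,
    linearly interpolated within its breakpoint segment, and rounded to the
    nearest integer.  Concentrations above the table maximum are clamped to
    the top AQI with a warning.  Accepts scalars or arrays.
    """
    arr = np.asarray(conc, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    if np.any(arr < 0):
        raise ValueError("concentration must be >= 0")
    trunc = np.floor(arr * 10.0 + 1e-9) / 10.0
    out = np.empty_like(trunc)
    over = trunc > table.conc_max
    if np.any(over):
        warnings.warn(
            "concentration above AQI table maximum; clamping to top index",
            UserWarning,
            stacklevel=2,
        )
        out[over] = table.aqi_max
    rest = ~over
    t = trunc[rest]
    res = np.empty_like(t)
    done = np.zeros(t.shape, dtype=bool)
    for cl, ch, al, ah in table.segments:
        m = ~done & (t <= ch + 1e-12)
        res[m] = al + (ah - al) * (t[m] - cl) / (ch - cl)
        done |= m
    res = np.clip(res, 0.0, None)
    out[rest] = np.rint(res)
    out = out.astype(int)
    return int(out[0]) if scalar else out


def aqi_to_pm(aqi, table: AqiBreakpointTable = EPA_PM25_BREAKPOINTS):
    """Invert the AQI map: index value back to PM2.5 concentration (µg/m³)."""
    arr = np.asarray(aqi, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    if np.any(arr < 0) or np.any(arr > table.aqi_max):
        raise ValueError(f"AQI must lie in [0, {table.aqi_max}]")
    out = np.empty_like(arr)
    done = np.zeros(arr.shape, dtype=bool)
    for cl, ch, al, ah in table.segments:
        m = ~done & (arr <= ah + 1e-12)
        out[m] = cl + (ch - cl) * (arr[m] - al) / (ah - al)
        done |= m
    out = np.clip(out, 0.0, None)
    out = np.round(out, 1)
    return float(out[0]) if scalar else out


def alert_days(
    series: DailySeries | np.ndarray,
    aqi_threshold: float = 100,
    table: AqiBreakpointTable = EPA_PM25_BREAKPOINTS,
) -> np.ndarray:
    """Day indices (0-based) whose integer AQI strictly exceeds the threshold."""
    values = series.values if isinstance(series, DailySeries) else np.asarray(series, dtype=float)
    idx = pm_to_aqi(values, table=table)
    return np.nonzero(idx > aqi_threshold)[0]


def ady(series: DailySeries, aqi_threshold: float = 100,
        table: AqiBreakpointTable = EPA_PM25_BREAKPOINTS) -> int:
    """Alert days per year for one cell-year."""
    return int(len(alert_days(series, aqi_threshold, table)))


@dataclass(frozen=True)
class AlertStats:
    """Alert-day statistics for one cell under one scenario-epoch."""

    cell_id: str
    scenario: str
    year_label: str
    ady: float
    eady: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.ady <= 365:
            raise ValueError(f"ady must lie in [0, 365], got {self.ady}")


def eady(baseline: AlertStats, future: AlertStats) -> float:
    """Extra alert days per year of ``future`` relative to ``baseline``."""
    if baseline.cell_id != future.cell_id:
        raise ValueError(
            f"EADY compares the same cell; got {baseline.cell_id!r} vs {future.cell_id!r}"
        )
    return float(future.ady - baseline.ady)


def alert_stats(
    ensemble,
    aqi_threshold: float = 100,
    baseline: dict | None = None,
    table: AqiBreakpointTable = EPA_PM25_BREAKPOINTS,
) -> dict:
    """Per-cell AlertStats for an ensemble; ADY averaged over replicates.

    ``baseline`` maps cell_id → start-of-century AlertStats; when given, EADY
    is filled in against it.
    """
    out = {}
    for c in ensemble.cells:
        mean_ady = float(
            np.mean([ady(ensemble.series[c][r], aqi_threshold, table) for r in ensemble.replicates])
        )
        e = None
        if baseline is not None:
            e = mean_ady - baseline[c].ady
        out[c] = AlertStats(
            cell_id=c, scenario=ensemble.scenario, year_label=ensemble.year_label,
            ady=mean_ady, eady=e,
        )
    return out


def _group_weights(profile: GridCellProfile, grouping: str) -> dict:
    if grouping == "race":
        return {g: profile.adult_population * s for g, s in profile.race_shares.items()}
    if grouping == "income":
        return {profile.income_group: profile.adult_population}
    if grouping == "leakage":
        return {profile.leakage_class: profile.adult_population}
    raise ValueError(f"grouping must be 'race', 'income' or 'leakage', got {grouping!r}")


def subgroup_cdf(
    stats: Iterable[AlertStats],
    profiles: Sequence[GridCellProfile],
    grouping: str,
    metric: str = "eady",
) -> pd.DataFrame:
    """Population-weighted cumulative distribution of ADY/EADY per subgroup.

    Each cell contributes to every group it houses, weighted by that group's
    population in the cell.  Returns a tidy frame (group, value, cdf) where
    ``cdf`` at a value v is the weighted fraction of the group's population
    living in cells with metric ≤ v; within each group the CDF is
    non-decreasing and ends at 1.
    """
    prof_by_cell = {p.cell_id: p for p in profiles}
    rows = []
    for st in stats:
        val = getattr(st, metric)
        if val is None:
            raise ValueError(f"metric {metric!r} not populated for cell {st.cell_id}")
        for g, w in _group_weights(prof_by_cell[st.cell_id], grouping).items():
            rows.append((g, float(val), float(w)))
    df = pd.DataFrame(rows, columns=["group", "value", "weight"])
    out = []
    for g, grp in df.groupby("group"):
        grp = grp.sort_values("value")
        agg = grp.groupby("value", as_index=False)["weight"].sum()
        total = agg["weight"].sum()
        if total <= 0:
            continue
        agg["cdf"] = agg["weight"].cumsum() / total
        agg["group"] = g
        out.append(agg[["group", "value", "cdf"]])
    return pd.concat(out, ignore_index=True)
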