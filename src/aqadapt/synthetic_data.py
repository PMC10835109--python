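"""Synthetic gridded PM2.5 scenarios and socio-demographic grid profiles.

The analysis downstream (alert counting, benefit/cost accounting, adaptation
strategies) only assumes that each grid cell carries a 365-day series of 24-h
mean outdoor PM2.5 concentrations plus static demographic attributes.  This
module generates both with the statistical structure of real data — seasonal
cycle, day-to-day autocorrelation, right-skewed daily distributions, and
correlated demographics (leakier housing in lower-income cells) — so the whole
pipeline is testable without any external download.

Daily concentrations are modelled as a seasonal sinusoid modulated by
lognormal AR(1) multiplicative noise, then rescaled so the annual mean hits
its target exactly.  A "mitigation" scenario is derived from a reference
scenario by lowering each cell's annual mean by a fixed shift (default
1.2 µg/m³), applied proportionally across days so the daily pattern is
preserved and no day goes negative.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "ConfigurationError",
    "Dist",
    "DemographyConfig",
    "GridCellProfile",
    "DailySeries",
    "ScenarioEnsemble",
    "generate_grid",
    "generate_daily_pm",
    "apply_mitigation_shift",
    "write_scenario",
    "read_scenario",
    "profiles_to_frame",
    "CENSUS_REGIONS",
    "RACE_GROUPS",
]

N_DAYS = 365  # fixed year length; leap days out of scope

CENSUS_REGIONS = ("Northeast", "Midwest", "South", "West")
RACE_GROUPS = ("White", "Black", "Asian", "Native", "Other")


class ConfigurationError(ValueError):
    """Raised when a generator configuration is invalid; names the field."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridCellProfile:
    """Static attributes of one grid cell.

    Attributes
    ----------
    adult_population : persons aged 25–99.
    hourly_wage : mean hourly wage, USD(2020)/h; the default hourly
        adaptation cost for the cell.
    baseline_mortality_rate : all-cause deaths/person/year (Y0).
    infiltration_factor : fraction of outdoor PM2.5 present indoors (FINF).
    outdoor_time : hours/day normally spent outdoors (Tout).
    race_shares : population fraction per race group; sums to 1.
    income_group : "above" or "below" national median income.
    leakage_class : "leakier" or "tighter" than average housing.
    census_region : one of the four US census regions.
    """

    cell_id: str
    lat: float
    lon: float
    adult_population: float
    hourly_wage: float
    baseline_mortality_rate: float
    infiltration_factor: float
    outdoor_time: float
    race_shares: Mapping[str, float]
    income_group: str
    leakage_class: str
    census_region: str

    def __post_init__(self) -> None:
        if self.adult_population < 0:
            raise ValueError(f"adult_population must be >= 0, got {self.adult_population}")
        if self.baseline_mortality_rate <= 0:
            raise ValueError(f"baseline_mortality_rate must be > 0, got {self.baseline_mortality_rate}")
        if not 0.0 <= self.infiltration_factor <= 1.0:
            raise ValueError(f"infiltration_factor must lie in [0, 1], got {self.infiltration_factor}")
        if not 0.0 < self.outdoor_time <= 24.0:
            raise ValueError(f"outdoor_time must lie in (0, 24], got {self.outdoor_time}")
        total = float(sum(self.race_shares.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"race_shares must sum to 1 (got {total})")
        if self.income_group not in ("above", "below"):
            raise ValueError(f"income_group must be 'above' or 'below', got {self.income_group!r}")
        if self.leakage_class not in ("leakier", "tighter"):
            raise ValueError(f"leakage_class must be 'leakier' or 'tighter', got {self.leakage_class!r}")
        if self.census_region not in CENSUS_REGIONS:
            raise ValueError(f"census_region must be one of {CENSUS_REGIONS}, got {self.census_region!r}")


@dataclass(frozen=True)
class DailySeries:
    """One cell-year of 365 daily 24-h mean PM2.5 values (µg/m³)."""

    cell_id: str
    scenario: str
    year_label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (N_DAYS,):
            raise ValueError(f"DailySeries requires exactly {N_DAYS} days, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("DailySeries values must be finite")
        if np.any(v < 0):
            raise ValueError("DailySeries values must be >= 0")

    @property
    def annual_mean(self) -> float:
        return float(self.values.mean())

    def replace_values(self, values: np.ndarray, scenario: str | None = None) -> "DailySeries":
        return DailySeries(
            cell_id=self.cell_id,
            scenario=scenario if scenario is not None else self.scenario,
            year_label=self.year_label,
            values=np.asarray(values, dtype=float),
        )


@dataclass
class ScenarioEnsemble:
    """A set of DailySeries keyed by (cell, replicate) for one scenario."""

    scenario: str
    year_label: str
    series: dict  # cell_id -> {replicate index -> DailySeries}
    replicate_seeds: tuple = ()
    config_hash: str = ""

    def __post_init__(self) -> None:
        if not self.series:
            raise ValueError("ScenarioEnsemble requires at least one cell")
        rep_sets = {tuple(sorted(reps)) for reps in (d.keys() for d in self.series.values())}
        if len(rep_sets) != 1:
            raise ValueError("all cells must share the same replicate set")
        if len(next(iter(rep_sets))) < 1:
            raise ValueError("replicate count must be >= 1")

    @property
    def cells(self) -> list:
        return sorted(self.series)

    @property
    def replicates(self) -> list:
        return sorted(next(iter(self.series.values())))

    def get(self, cell_id: str, replicate: int = 0) -> DailySeries:
        return self.series[cell_id][replicate]


# ---------------------------------------------------------------------------
# Distribution helper
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Dist:
    """A named 1-D sampling distribution.

    kinds: "constant" (value), "lognormal" (mean, sd — arithmetic moments),
    "normal" (mean, sd, optional lo/hi clip), "uniform" (lo, hi).
    """

    kind: str
    params: Mapping[str, float]

    def validate(self, name: str) -> None:
        p = self.params
        try:
            if self.kind == "constant":
                float(p["value"])
            elif self.kind == "lognormal":
                if not (p["mean"] > 0 and p["sd"] >= 0):
                    raise ValueError
            elif self.kind == "normal":
                if not p["sd"] >= 0:
                    raise ValueError
            elif self.kind == "uniform":
                if not p["lo"] <= p["hi"]:
                    raise ValueError
            else:
                raise KeyError(self.kind)
        except (KeyError, ValueError, TypeError) as exc:
            raise ConfigurationError(
                f"invalid distribution for field '{name}': kind={self.kind!r} params={dict(p)!r}"
            ) from exc

    @property
    def mean(self) -> float:
        if self.kind == "constant":
            return float(self.params["value"])
        if self.kind in ("lognormal", "normal"):
            return float(self.params["mean"])
        return 0.5 * (self.params["lo"] + self.params["hi"])

    @property
    def sd(self) -> float:
        if self.kind == "constant":
            return 0.0
        if self.kind in ("lognormal", "normal"):
            return float(self.params["sd"])
        return (self.params["hi"] - self.params["lo"]) / math.sqrt(12.0)

    def sample_from_normal(self, z: np.ndarray) -> np.ndarray:
        """Transform standard-normal draws into draws from this distribution.

        Going through a normal score keeps Gaussian-copula rank correlations
        between fields intact.
        """
        p = self.params
        if self.kind == "constant":
            return np.full_like(z, float(p["value"]))
        if self.kind == "lognormal":
            mean, sd = float(p["mean"]), float(p["sd"])
            if sd == 0:
                return np.full_like(z, mean)
            sigma2 = math.log1p((sd / mean) ** 2)
            mu = math.log(mean) - sigma2 / 2.0
            return np.exp(mu + math.sqrt(sigma2) * z)
        if self.kind == "normal":
            out = float(p["mean"]) + float(p["sd"]) * z
            lo = p.get("lo", -np.inf)
            hi = p.get("hi", np.inf)
            return np.clip(out, lo, hi)
        if self.kind == "uniform":
            from scipy.stats import norm

            u = norm.cdf(z)
            return p["lo"] + (p["hi"] - p["lo"]) * u
        raise ConfigurationError(f"unknown distribution kind {self.kind!r}")


# ---------------------------------------------------------------------------
# Demography configuration
# ---------------------------------------------------------------------------


def _default_race_alphas() -> dict:
    # Dirichlet concentration per region; South has a higher Black share,
    # West higher Asian/Other, loosely echoing US census patterns.
    return {
        "Northeast": {"White": 14.0, "Black": 2.4, "Asian": 1.6, "Native": 0.1, "Other": 1.9},
        "Midwest": {"White": 16.0, "Black": 2.0, "Asian": 0.7, "Native": 0.2, "Other": 1.1},
        "South": {"White": 12.0, "Black": 4.0, "Asian": 0.7, "Native": 0.3, "Other": 3.0},
        "West": {"White": 13.0, "Black": 1.0, "Asian": 2.4, "Native": 0.4, "Other": 3.2},
    }


@dataclass
class DemographyConfig:
    """Distributions and correlation structure for :func:`generate_grid`.

    Defaults emulate contiguous-US magnitudes: mean wage ≈ $27/h (2020 USD),
    adult all-cause baseline mortality ≈ 0.9%/yr, infiltration factors around
    0.15 (tighter housing) and 0.35 (leakier housing), 1 h/day outdoors.
    ``income_leakage_rank_corr`` < 0 makes leakier housing more likely in
    lower-income cells.
    """

    wage: Dist = field(default_factory=lambda: Dist("lognormal", {"mean": 27.0, "sd": 8.0}))
    mortality: Dist = field(default_factory=lambda: Dist("lognormal", {"mean": 0.009, "sd": 0.002}))
    adult_population: Dist = field(
        default_factory=lambda: Dist("lognormal", {"mean": 6.0e5, "sd": 4.0e5})
    )
    finf_tighter: Dist = field(
        default_factory=lambda: Dist("normal", {"mean": 0.15, "sd": 0.03, "lo": 0.01, "hi": 0.95})
    )
    finf_leakier: Dist = field(
        default_factory=lambda: Dist("normal", {"mean": 0.35, "sd": 0.07, "lo": 0.01, "hi": 0.95})
    )
    outdoor_time: Dist = field(default_factory=lambda: Dist("constant", {"value": 1.0}))
    income_leakage_rank_corr: float = -0.5
    p_leakier: float = 0.5
    region_probs: Mapping[str, float] = field(
        default_factory=lambda: {"Northeast": 0.18, "Midwest": 0.21, "South": 0.38, "West": 0.23}
    )
    race_alphas: Mapping[str, Mapping[str, float]] = field(default_factory=_default_race_alphas)

    def validate(self) -> None:
        for name in ("wage", "mortality", "adult_population", "finf_tighter", "finf_leakier", "outdoor_time"):
            getattr(self, name).validate(name)
        if not -1.0 < self.income_leakage_rank_corr < 1.0:
            raise ConfigurationError(
                f"income_leakage_rank_corr must lie in (-1, 1), got {self.income_leakage_rank_corr}"
            )
        if not 0.0 <= self.p_leakier <= 1.0:
            raise ConfigurationError(f"p_leakier must lie in [0, 1], got {self.p_leakier}")
        tot = sum(self.region_probs.values())
        if abs(tot - 1.0) > 1e-9:
            raise ConfigurationError(f"region_probs must sum to 1, got {tot}")


def config_hash(obj) -> str:
    """Stable short hash of a (nested dataclass / dict) configuration."""
    if hasattr(obj, "__dataclass_fields__"):
        obj = asdict(obj)
    text = repr(_canonical(obj))
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def _canonical(x):
    if isinstance(x, Mapping):
        return tuple(sorted((k, _canonical(v)) for k, v in x.items()))
    if isinstance(x, (list, tuple)):
        return tuple(_canonical(v) for v in x)
    if isinstance(x, np.ndarray):
        return tuple(x.tolist())
    return x


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def generate_grid(
    n_cells: int,
    seed: int,
    config: DemographyConfig | None = None,
) -> list:
    """Generate ``n_cells`` grid-cell profiles, deterministic in ``seed``.

    Income group is assigned by the cell's wage relative to the configured
    median wage; housing-leakage class is drawn through a Gaussian copula
    correlated with the wage score, so a negative
    ``income_leakage_rank_corr`` places leakier housing preferentially in
    lower-wage cells.
    """
    if n_cells < 1:
        raise ValueError(f"n_cells must be >= 1, got {n_cells}")
    cfg = config or DemographyConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)

    rho = cfg.income_leakage_rank_corr
    # z_w drives wage/income, z_l drives the leakage score; a negative rank
    # correlation pairs low wage with leakier housing.
    z = rng.multivariate_normal([0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=n_cells)
    z_w, z_l = z[:, 0], z[:, 1]

    from scipy.stats import norm

    wages = cfg.wage.sample_from_normal(z_w)
    # lognormal median = exp(mu); for constant/normal fall back to mean
    median_wage = _dist_median(cfg.wage)
    income_group = np.where(wages > median_wage, "above", "below")
    leak_cut = norm.ppf(1.0 - cfg.p_leakier)
    leakier = z_l > leak_cut

    finf = np.where(
        leakier,
        cfg.finf_leakier.sample_from_normal(rng.standard_normal(n_cells)),
        cfg.finf_tighter.sample_from_normal(rng.standard_normal(n_cells)),
    )
    y0 = cfg.mortality.sample_from_normal(rng.standard_normal(n_cells))
    pop = cfg.adult_population.sample_from_normal(rng.standard_normal(n_cells))
    tout = cfg.outdoor_time.sample_from_normal(rng.standard_normal(n_cells))

    regions = rng.choice(
        list(cfg.region_probs), size=n_cells, p=list(cfg.region_probs.values())
    )
    lats = rng.uniform(25.0, 49.0, size=n_cells)
    lons = rng.uniform(-124.0, -67.0, size=n_cells)

    profiles = []
    for i in range(n_cells):
        alphas = cfg.race_alphas[regions[i]]
        shares = rng.dirichlet(list(alphas.values()))
        shares = shares / shares.sum()
        race_shares = dict(zip(alphas.keys(), shares.tolist()))
        profiles.append(
            GridCellProfile(
                cell_id=f"c{i:04d}",
                lat=float(lats[i]),
                lon=float(lons[i]),
                adult_population=float(pop[i]),
                hourly_wage=float(wages[i]),
                baseline_mortality_rate=float(y0[i]),
                infiltration_factor=float(finf[i]),
                outdoor_time=float(tout[i]),
                race_shares=race_shares,
                income_group=str(income_group[i]),
                leakage_class="leakier" if leakier[i] else "tighter",
                census_region=str(regions[i]),
            )
        )
    return profiles


def _dist_median(dist: Dist) -> float:
    if dist.kind == "lognormal":
        mean, sd = dist.params["mean"], dist.params["sd"]
        if sd == 0:
            return float(mean)
        sigma2 = math.log1p((sd / mean) ** 2)
        return float(mean * math.exp(-sigma2 / 2.0))
    return dist.mean


def generate_daily_pm(
    annual_mean: float,
    seasonal_amplitude: float = 0.0,
    ar1_coefficient: float = 0.0,
    noise_cv: float = 0.0,
    seed: int = 0,
    cell_id: str = "c0000",
    scenario: str = "REF",
    year_label: str = "end",
    peak_day: int = 14,
) -> DailySeries:
    """Simulate one cell-year of daily 24-h mean PM2.5.

    Model: ``base_t = annual_mean + A·cos(2π(t − peak_day)/365)`` (clipped at
    0) times stationary lognormal AR(1) multiplicative noise with coefficient
    of variation ``noise_cv`` and lag-1 log-scale autocorrelation
    ``ar1_coefficient``; the result is rescaled so the sample annual mean
    equals ``annual_mean`` exactly.  The product is right-skewed and
    autocorrelated, like real PM2.5.
    """
    if annual_mean <= 0:
        raise ValueError(f"annual_mean must be > 0, got {annual_mean}")
    if not 0.0 <= ar1_coefficient < 1.0:
        raise ValueError(f"ar1_coefficient must lie in [0, 1), got {ar1_coefficient}")
    if noise_cv < 0:
        raise ValueError(f"noise_cv must be >= 0, got {noise_cv}")

    t = np.arange(N_DAYS)
    base = annual_mean + seasonal_amplitude * np.cos(2.0 * np.pi * (t - peak_day) / N_DAYS)
    base = np.clip(base, 0.0, None)

    if noise_cv == 0.0:
        noise = np.ones(N_DAYS)
    else:
        rng = np.random.default_rng(seed)
        sigma2 = math.log1p(noise_cv**2)
        s = math.sqrt(sigma2)
        zv = np.empty(N_DAYS)
        zv[0] = rng.standard_normal() * s
        innov_sd = s * math.sqrt(1.0 - ar1_coefficient**2)
        eps = rng.standard_normal(N_DAYS - 1) * innov_sd
        for i in range(1, N_DAYS):
            zv[i] = ar1_coefficient * zv[i - 1] + eps[i - 1]
        noise = np.exp(zv - sigma2 / 2.0)

    values = np.clip(base * noise, 0.0, None)
    m = values.mean()
    if m <= 0:
        raise ValueError("degenerate simulation: zero mean before rescaling")
    values = values * (annual_mean / m)
    return DailySeries(cell_id=cell_id, scenario=scenario, year_label=year_label, values=values)


def apply_mitigation_shift(series: DailySeries, delta: float, scenario: str | None = None) -> DailySeries:
    """Lower a series' annual mean by ``delta`` µg/m³, preserving the daily pattern.

    The shift is applied proportionally (each day scaled by
    ``(mean − delta)/mean``), so daily values stay non-negative and the
    annual-mean identity holds exactly.  If ``delta`` exceeds the annual mean
    the result is an all-zero series and a warning is emitted.
    """
    if delta < 0:
        raise ValueError(f"delta must be >= 0, got {delta}")
    label = scenario if scenario is not None else f"{series.scenario}-mitigated"
    m = series.annual_mean
    if delta == 0:
        return series.replace_values(series.values.copy(), scenario=label)
    if delta > m:
        warnings.warn(
            f"mitigation delta {delta} exceeds annual mean {m:.4g}; returning all-zero series",
            UserWarning,
            stacklevel=2,
        )
        return series.replace_values(np.zeros(N_DAYS), scenario=label)
    return series.replace_values(series.values * ((m - delta) / m), scenario=label)


# ---------------------------------------------------------------------------
# Scenario I/O (NetCDF via xarray's scipy backend; CSV fallback)
# ---------------------------------------------------------------------------


def _ensemble_to_dataset(ensemble: ScenarioEnsemble) -> xr.Dataset:
    cells = ensemble.cells
    reps = ensemble.replicates
    data = np.empty((len(reps), len(cells), N_DAYS))
    for j, c in enumerate(cells):
        for i, r in enumerate(reps):
            data[i, j, :] = ensemble.series[c][r].values
    ds = xr.Dataset(
        {"pm25": (("replicate", "cell", "day"), data)},
        coords={
            "replicate": np.asarray(reps),
            "cell": np.asarray(cells, dtype="U16"),
            "day": np.arange(N_DAYS),
        },
        attrs={
            "scenario": ensemble.scenario,
            "year_label": ensemble.year_label,
            "replicate_seeds": ",".join(str(s) for s in ensemble.replicate_seeds),
            "config_hash": ensemble.config_hash,
        },
    )
    ds["pm25"].attrs["units"] = "ug m-3"
    return ds


def write_scenario(path, ensemble: ScenarioEnsemble) -> None:
    """Write an ensemble to NetCDF (``.nc``) or long-format CSV (``.csv``)."""
    path = str(path)
    if path.endswith(".csv"):
        rows = []
        for c in ensemble.cells:
            for r in ensemble.replicates:
                v = ensemble.series[c][r].values
                rows.append(
                    pd.DataFrame(
                        {
                            "cell": c,
                            "replicate": r,
                            "day": np.arange(N_DAYS),
                            "pm25": v,
                        }
                    )
                )
        df = pd.concat(rows, ignore_index=True)
        with open(path, "w") as fh:
            fh.write(f"# scenario={ensemble.scenario} year_label={ensemble.year_label}\n")
            fh.write(
                f"# replicate_seeds={','.join(str(s) for s in ensemble.replicate_seeds)}"
                f" config_hash={ensemble.config_hash}\n"
            )
            df.to_csv(fh, index=False, float_format="%.9g")
    else:
        _ensemble_to_dataset(ensemble).to_netcdf(path, engine="scipy")


class ScenarioParseError(ValueError):
    """Raised when a stored scenario file violates the series invariants."""


def read_scenario(path) -> ScenarioEnsemble:
    """Read a scenario ensemble written by :func:`write_scenario`."""
    path = str(path)
    if path.endswith(".csv"):
        header = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                for tok in line[1:].split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        header[k] = v
        df = pd.read_csv(path, comment="#")
        scenario = header.get("scenario", "unknown")
        year_label = header.get("year_label", "unknown")
        seeds = tuple(
            int(s) for s in header.get("replicate_seeds", "").split(",") if s.strip()
        )
        chash = header.get("config_hash", "")
        series: dict = {}
        for (c, r), grp in df.groupby(["cell", "replicate"]):
            vals = grp.sort_values("day")["pm25"].to_numpy()
            _check_stored(vals, f"cell={c} replicate={r}")
            series.setdefault(str(c), {})[int(r)] = DailySeries(
                cell_id=str(c), scenario=scenario, year_label=year_label, values=vals
            )
        return ScenarioEnsemble(
            scenario=scenario, year_label=year_label, series=series,
            replicate_seeds=seeds, config_hash=chash,
        )

    try:
        ds = xr.open_dataset(path, engine="scipy")
    except Exception as exc:  # pragma: no cover - backend specific
        raise ScenarioParseError(f"cannot parse scenario file {path!r}: {exc}") from exc
    with ds:
        if "pm25" not in ds:
            raise ScenarioParseError(f"variable 'pm25' missing from {path!r}")
        pm = ds["pm25"]
        if pm.sizes.get("day") != N_DAYS:
            raise ScenarioParseError(
                f"day dimension must have length {N_DAYS}, got {pm.sizes.get('day')}"
            )
        data = pm.transpose("replicate", "cell", "day").to_numpy()
        if np.any(data < 0):
            raise ScenarioParseError("negative concentration found in stored scenario")
        scenario = ds.attrs.get("scenario", "unknown")
        year_label = ds.attrs.get("year_label", "unknown")
        seeds = tuple(
            int(s) for s in str(ds.attrs.get("replicate_seeds", "")).split(",") if s.strip()
        )
        chash = ds.attrs.get("config_hash", "")
        cells = [str(c) for c in ds["cell"].values]
        reps = [int(r) for r in ds["replicate"].values]
    series = {
        c: {
            r: DailySeries(cell_id=c, scenario=scenario, year_label=year_label,
                           values=data[i, j, :])
            for i, r in enumerate(reps)
        }
        for j, c in enumerate(cells)
    }
    return ScenarioEnsemble(
        scenario=scenario, year_label=year_label, series=series,
        replicate_seeds=seeds, config_hash=chash,
    )


def _check_stored(vals: np.ndarray, where: str) -> None:
    if len(vals) != N_DAYS:
        raise ScenarioParseError(f"{where}: expected {N_DAYS} days, found {len(vals)}")
    if np.any(vals < 0):
        raise ScenarioParseError(f"{where}: negative concentration in stored scenario")


def profiles_to_frame(profiles: Sequence[GridCellProfile]) -> pd.DataFrame:
    """Tabulate profiles, one row per cell (race shares as share_<group> columns)."""
    rows = []
    for p in profiles:
        row = {
            "cell_id": p.cell_id,
            "lat": p.lat,
            "lon": p.lon,
            "adult_population": p.adult_population,
            "hourly_wage": p.hourly_wage,
            "baseline_mortality_rate": p.baseline_mortality_rate,
            "infiltration_factor": p.infiltration_factor,
            "outdoor_time": p.outdoor_time,
            "income_group": p.income_group,
            "leakage_class": p.leakage_class,
            "census_region": p.census_region,
        }
        for g, s in p.race_shares.items():
            row[f"share_{g}"] = s
        rows.append(row)
    return pd.DataFrame(rows)
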