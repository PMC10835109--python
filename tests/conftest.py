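import numpy as np
import pytest

from aqadapt.cli import build_ensembles, health_params
from aqadapt.config import RunConfig
from aqadapt.exposure_health import HealthEconParams
from aqadapt.synthetic_data import (
    DailySeries,
    DemographyConfig,
    GridCellProfile,
    generate_grid,
)


def make_profile(**kw) -> GridCellProfile:
    base = dict(
        cell_id="c0000",
        lat=40.0,
        lon=-95.0,
        adult_population=5e5,
        hourly_wage=27.0,
        baseline_mortality_rate=0.009,
        infiltration_factor=0.2,
        outdoor_time=1.0,
        race_shares={"White": 0.6, "Black": 0.2, "Asian": 0.1, "Native": 0.02, "Other": 0.08},
        income_group="above",
        leakage_class="tighter",
        census_region="Midwest",
    )
    base.update(kw)
    return GridCellProfile(**base)


def constant_series(value: float, **kw) -> DailySeries:
    base = dict(cell_id="c0000", scenario="REF", year_label="end")
    base.update(kw)
    return DailySeries(values=np.full(365, float(value)), **base)


@pytest.fixture
def profile() -> GridCellProfile:
    return make_profile()


@pytest.fixture
def params() -> HealthEconParams:
    return HealthEconParams()


@pytest.fixture(scope="session")
def national_run():
    """Fixed synthetic national ensemble: 50 cells, 5 replicates, fixed seed.

    Emulates end-of-century reference conditions (national-mean anchor
    21.5 µg/m³) plus its mitigated counterpart (1.2 µg/m³ lower).
    """
    cfg = RunConfig(n_cells=50, n_replicates=5, seed=42, epoch_means={"end": 21.5})
    profiles = generate_grid(cfg.n_cells, cfg.child_seed("grid"), DemographyConfig())
    ensembles = build_ensembles(cfg, profiles)
    return {
        "cfg": cfg,
        "profiles": profiles,
        "params": health_params(cfg),
        "ref": ensembles[("REF", "end")],
        "mit": ensembles[("P37", "end")],
    }
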