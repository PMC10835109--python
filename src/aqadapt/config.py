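"""Run configuration: one YAML file drives the whole pipeline.

Every random operation derives its seed deterministically from the master
seed plus a stable component tag, so a fixed config reproduces byte-identical
outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .synthetic_data import config_hash

__all__ = ["RunConfig", "derive_seed", "load_config", "save_config"]


def derive_seed(master_seed: int, tag: str) -> int:
    """Deterministic child seed from (master seed, component tag), < 2^31."""
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, zlib.crc32(tag.encode())])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class RunConfig:
    """Pipeline settings; defaults are the package's study conditions.

    ``epoch_means`` anchor the national-mean PM2.5 per epoch under the
    reference scenario; ``mitigation_delta`` is the annual-mean reduction the
    mitigated scenario achieves (µg/m³).  ``mean_spread`` is the relative
    cell-to-cell spread of annual means around the epoch anchor.
    """

    seed: int = 42
    n_cells: int = 50
    n_replicates: int = 5
    epoch_means: dict = field(default_factory=lambda: {"start": 12.0, "end": 21.5})
    mitigation_delta: float = 1.2
    mean_spread: float = 0.35
    seasonal_amplitude_ratio: float = 0.4
    ar1: float = 0.6
    noise_cv: float = 0.4
    strategies: list = field(
        default_factory=lambda: [
            "none",
            "threshold100",
            "threshold150",
            "threshold100_full",
            "threshold150_full",
            "rational",
            "forced",
        ]
    )
    compliance: float = 0.2
    vsl_2008_usd: float = 7.9e6
    vsl_inflation_factor: float = 1.27
    rr: float = 1.14
    xi: float = 1.0
    mc_draws: int = 2000
    out_dir: str = "aqadapt_out"

    def __post_init__(self) -> None:
        required = {
            "seed", "n_cells", "n_replicates", "epoch_means", "mitigation_delta",
        }
        for name in required:
            if getattr(self, name) is None:
                raise ValueError(f"config field '{name}' is required")
        if self.n_cells < 1 or self.n_replicates < 1:
            raise ValueError("n_cells and n_replicates must be >= 1")

    @property
    def hash(self) -> str:
        return config_hash(asdict(self))

    def child_seed(self, tag: str) -> int:
        return derive_seed(self.seed, tag)


def load_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    return RunConfig(**data)


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=True))
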