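"""Run configuration: a flat key-value file mirroring the simulation
parameter table, plus helpers to resolve a configuration into concrete
Hamiltonian and filopodia parameters for each model preset."""

from __future__ import annotations

import dataclasses
import math
import tomllib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .models import MODELS, adhesion_matrix, pulling_mask_table
from .params import CPMParams, FilopodiaParams, default_j_table

__all__ = ["SimConfig", "load_config", "save_config"]


@dataclass
class SimConfig:
    """Flat simulation configuration.

    Field names follow the standard parameter table (temperature,
    target_area, ...).  Model-specific fields: ``offset``/``slope``
    parameterize the differential-adhesion gradient;
    ``j_cross`` is the cross-type interfacial energy J(1, 2) of the
    two-type models; ``lambda_f`` the filopodial pulling force.
    """

    model: str = "ce_one_type"
    temperature: float = 50.0
    target_area: float = 100.0
    target_length: float = 10.0
    lambda_area: float = 5.0
    lambda_length: float = 5.0
    mcs: int = 100_000
    n_cells: int = 200
    theta_max: float = 45.0
    r_max: float = 2.0
    n_max: int = 3
    t_interval: int = 20
    w: float = 0.99
    lambda_f: float = 15.0
    repolarization_mode: str = "vicsek"
    j_cell_medium: float = 10.0
    j_cell_cell: float = 10.0
    j_cross: float = 6.0
    offset: float = 25.0
    slope: float = 2.5
    type2_fraction: float = 0.5
    seed: int = 0
    snapshot_interval: int = 0
    lattice_size: int = 0  # 0 -> automatic
    growth_mcs: int = 100

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; "
                             f"choose one of {MODELS}")

    # -- derived quantities --------------------------------------------
    def resolved_lattice_size(self) -> int:
        """Side length of the (square) lattice including the frame.

        Defaults to 400 for 200 cells of target area 100 and scales
        with the square root of the total tissue area.
        """
        if self.lattice_size:
            return self.lattice_size
        return int(round(400.0 * math.sqrt(
            (self.n_cells / 200.0) * (self.target_area / 100.0))))

    def n_types(self) -> int:
        if self.model == "diff_adhesion":
            return 10
        return 1 if self.model == "ce_one_type" else 2

    def j_table(self) -> np.ndarray:
        if self.model == "diff_adhesion":
            return adhesion_matrix(self.offset, self.slope)
        if self.model == "ce_one_type":
            return default_j_table(1, self.j_cell_medium, self.j_cell_cell)
        return default_j_table(2, self.j_cell_medium, self.j_cell_cell,
                               j_cross=self.j_cross)

    def cpm_params(self) -> CPMParams:
        return CPMParams(temperature=self.temperature,
                         lambda_area=self.lambda_area,
                         lambda_length=self.lambda_length,
                         target_area=self.target_area,
                         target_length=self.target_length,
                         J=self.j_table())

    def uses_pulling(self) -> bool:
        return self.model != "diff_adhesion" and self.lambda_f != 0.0

    def filopodia_params(self) -> FilopodiaParams:
        return FilopodiaParams(theta_max=self.theta_max, r_max=self.r_max,
                               n_max=self.n_max, t_interval=self.t_interval,
                               w=self.w, lambda_f=self.lambda_f,
                               repolarization_mode=self.repolarization_mode)

    def pulling_table(self) -> np.ndarray | None:
        if self.model in ("diff_adhesion", "ce_one_type"):
            return None
        variant = self.model.removeprefix("ce_")
        return pulling_mask_table(variant, self.n_types())

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


_FIELDS = {f.name: f.type for f in dataclasses.fields(SimConfig)}


def load_config(path: str | Path) -> SimConfig:
    """Read a flat key-value (TOML) configuration file."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    unknown = set(raw) - set(_FIELDS)
    if unknown:
        raise ValueError(
            f"unknown configuration keys {sorted(unknown)}; "
            f"valid keys are {sorted(_FIELDS)}")
    return SimConfig(**raw)


def save_config(config: SimConfig, path: str | Path) -> None:
    """Write the configuration as a flat TOML file."""
    lines = []
    for f in dataclasses.fields(SimConfig):
        v = getattr(config, f.name)
        if isinstance(v, str):
            lines.append(f'{f.name} = "{v}"')
        elif isinstance(v, bool):
            lines.append(f"{f.name} = {str(v).lower()}")
        else:
            lines.append(f"{f.name} = {v}")
    Path(path).write_text("\n".join(lines) + "\n")
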