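"""Records and configuration I/O.

Records are plain CSV with the exact header
``sire_id,dam_id,progeny_order,phenotype`` (comma separator, '.' decimal,
UTF-8).  Writing canonicalizes row order to sire-major, dam-minor, ascending
progeny order; reading validates the nesting and progeny-order contracts and
round-trips phenotypes at full precision.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from .exceptions import RecordsError
from .model import _frame_to_arrays
from .simulate import FullSibRecords, RECORD_COLUMNS


def read_records(path) -> FullSibRecords:
    """Read and validate a records CSV."""
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise RecordsError(f"empty input file: {path}") from exc
    if list(df.columns) != list(RECORD_COLUMNS):
        raise RecordsError(
            f"{path}: header must be exactly {','.join(RECORD_COLUMNS)}, "
            f"got {','.join(map(str, df.columns))}"
        )
    y, design, _, _ = _frame_to_arrays(df)
    canonical = df.sort_values(
        ["sire_id", "dam_id", "progeny_order"], kind="mergesort"
    ).reset_index(drop=True)
    canonical["phenotype"] = y
    return FullSibRecords(data=canonical, design=design)


def write_records(records: FullSibRecords, path) -> None:
    """Write records CSV in canonical order at full float precision."""
    df = records.data.loc[:, list(RECORD_COLUMNS)].sort_values(
        ["sire_id", "dam_id", "progeny_order"], kind="mergesort"
    )
    df.to_csv(path, index=False)


# -- run configuration -----------------------------------------------------


class SimulationSection(BaseModel):
    """Simulator settings of a run configuration."""

    model_config = ConfigDict(extra="forbid")

    n_sires: int = 25
    dams_per_sire: int = 5
    progeny_per_dam: int = 4
    mu: float = 0.0
    sigma_s2: float = 0.125
    sigma_d2: float = 0.125
    sigma_e2: float = 0.75
    ar_order: int = 0
    rho1: float = 0.0
    rho2: float = 0.0
    ar_scope: str = "dam"
    seed: int = 0

    @field_validator("ar_scope")
    @classmethod
    def _scope(cls, v: str) -> str:
        if v not in ("dam", "sire"):
            raise ValueError("ar_scope must be 'dam' or 'sire'")
        return v


class StudySection(BaseModel):
    """Monte Carlo grid settings of a run configuration."""

    model_config = ConfigDict(extra="forbid")

    ar_order: int = 1
    rho_specs: list[tuple[float, float]] = [
        (r, 0.0) for r in (-1.0, -0.7, -0.5, -0.3, 0.0, 0.3, 0.5, 0.7, 1.0)
    ]
    sample_sizes: list[int] = [100, 500]
    h2_values: list[float] = [0.1, 0.5]
    methods: list[str] = ["anova", "ml", "reml", "minque0"]
    replicates: int = 500
    dams_per_sire: int = 5
    progeny_per_dam: int = 4
    ar_scope: str = "dam"


class RunConfig(BaseModel):
    """Versioned, schema-validated run configuration (YAML on disk).

    Parsing rejects unknown keys and round-trips losslessly.
    """

    model_config = ConfigDict(extra="forbid")

    schema_version: int = 1
    simulation: Optional[SimulationSection] = None
    study: Optional[StudySection] = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)
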