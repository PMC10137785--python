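"""Monte Carlo bias/MSE study harness.

For each grid cell (method x AR spec x sample size x parametric
heritability) the harness simulates R replicate datasets, fits the requested
estimator, and summarizes each heritability ratio by its replicate mean and
its mean squared deviation from the parametric value (the study's "MSE").

Seeding: each cell derives an independent seed stream from
``(master_seed, crc32(cell key))``, so a cell's result does not depend on
which other cells run or in what order.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .ar import ARErrorSpec
from .components import VarianceComponents
from .design import design_for_total
from .exceptions import CellError
from .model import FullSibModel
from .simulate import SimulationConfig, simulate_full_sib

logger = logging.getLogger(__name__)

ESTIMANDS = ("hs2", "hd2", "hsd2")

#: AR(1) coefficients tabulated by the study
AR1_RHO_GRID: tuple[float, ...] = (-1.0, -0.7, -0.5, -0.3, 0.0, 0.3, 0.5, 0.7, 1.0)
#: AR(2) coefficient pairs tabulated by the study
AR2_PAIRS: tuple[tuple[float, float], ...] = (
    (-1.0, -1.0), (-1.0, -0.5), (0.0, -0.5), (0.0, 0.5), (1.0, 0.5),
)


@dataclass(frozen=True)
class CellSpec:
    """Coordinates of one Monte Carlo cell."""

    method: str
    n_total: int
    h2: float
    ar: ARErrorSpec = field(default_factory=ARErrorSpec.independent)
    dams_per_sire: int = 5
    progeny_per_dam: int = 4
    ar_scope: str = "dam"
    mu: float = 10.0

    def key(self) -> str:
        return (
            f"{self.method}|{self.n_total}|{self.h2!r}|{self.ar.order}"
            f"|{self.ar.rho1!r}|{self.ar.rho2!r}|{self.dams_per_sire}"
            f"|{self.progeny_per_dam}|{self.ar_scope}"
        )


@dataclass(frozen=True)
class MCCellResult:
    """Replicate summaries for one cell."""

    spec: CellSpec
    n_replicates: int
    n_ok: int
    n_failed: int
    seed: int
    mean: dict[str, float]
    mse: dict[str, float]
    se: dict[str, float]  # Monte Carlo standard error of the mean

    def rows(self) -> list[dict[str, object]]:
        out = []
        for est in ESTIMANDS:
            out.append(
                {
                    "rho1": self.spec.ar.rho1,
                    "rho2": self.spec.ar.rho2,
                    "ar_order": self.spec.ar.order,
                    "n_total": self.spec.n_total,
                    "h2_param": self.spec.h2,
                    "method": self.spec.method,
                    "estimand": est,
                    "mean": self.mean[est],
                    "mse": self.mse[est],
                    "se": self.se[est],
                    "n_ok": self.n_ok,
                }
            )
        return out


@dataclass(frozen=True)
class StudyGrid:
    """Full factorial study layout."""

    rho_specs: tuple[ARErrorSpec, ...] = tuple(
        ARErrorSpec.ar1(r) for r in AR1_RHO_GRID
    )
    sample_sizes: tuple[int, ...] = (100, 500)
    h2_values: tuple[float, ...] = (0.1, 0.5)
    methods: tuple[str, ...] = ("anova", "ml", "reml", "minque0")
    replicates: int = 500
    seed: int = 0
    dams_per_sire: int = 5
    progeny_per_dam: int = 4
    ar_scope: str = "dam"

    def cells(self) -> list[CellSpec]:
        return [
            CellSpec(
                method=m,
                n_total=n,
                h2=h2,
                ar=ar,
                dams_per_sire=self.dams_per_sire,
                progeny_per_dam=self.progeny_per_dam,
                ar_scope=self.ar_scope,
            )
            for ar in self.rho_specs
            for n in self.sample_sizes
            for h2 in self.h2_values
            for m in self.methods
        ]


def ar2_grid(**kwargs) -> StudyGrid:
    """Study grid over the tabulated AR(2) pairs."""
    return StudyGrid(
        rho_specs=tuple(ARErrorSpec.ar2(r1, r2) for r1, r2 in AR2_PAIRS), **kwargs
    )


def _replicate_seed(master_seed: int, cell_key: str, rep: int) -> int:
    crc = zlib.crc32(cell_key.encode())
    ss = np.random.SeedSequence((int(master_seed), crc, rep))
    return int(ss.generate_state(1)[0] % 2**31)


def run_cell(spec: CellSpec, replicates: int, master_seed: int) -> MCCellResult:
    """Simulate/estimate ``replicates`` times and summarize.

    Unconverged or failed replicates are counted and excluded from the
    summaries; a cell where every replicate fails raises :class:`CellError`.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    design = design_for_total(spec.n_total, spec.dams_per_sire, spec.progeny_per_dam)
    vc = VarianceComponents.from_h2(spec.h2)
    estimates = {est: [] for est in ESTIMANDS}
    n_failed = 0
    for rep in range(replicates):
        config = SimulationConfig(
            design=design,
            vc=vc,
            mu=spec.mu,
            ar=spec.ar,
            ar_scope=spec.ar_scope,
            seed=_replicate_seed(master_seed, spec.key(), rep),
        )
        try:
            records = simulate_full_sib(config)
            res = FullSibModel.from_records(records, validate=False).fit(spec.method)
            if not res.converged:
                raise RuntimeError("fit did not converge")
            h = res.heritability.as_dict()
        except Exception as exc:  # noqa: BLE001 - replicate failures are data
            logger.warning("replicate %d of cell %s failed: %s", rep, spec.key(), exc)
            n_failed += 1
            continue
        for est in ESTIMANDS:
            estimates[est].append(h[est])
    n_ok = replicates - n_failed
    if n_ok == 0:
        raise CellError(f"all {replicates} replicates failed for cell {spec.key()}")
    mean, mse, se = {}, {}, {}
    for est in ESTIMANDS:
        vals = np.asarray(estimates[est])
        mean[est] = float(vals.mean())
        mse[est] = float(((vals - spec.h2) ** 2).mean())
        se[est] = float(vals.std(ddof=0) / np.sqrt(n_ok))
    return MCCellResult(
        spec=spec,
        n_replicates=replicates,
        n_ok=n_ok,
        n_failed=n_failed,
        seed=master_seed,
        mean=mean,
        mse=mse,
        se=se,
    )


def run_grid(grid: StudyGrid) -> pd.DataFrame:
    """Run every cell; long-format output, one row per (cell x estimand).

    Per-cell failures are logged and skipped; the grid continues.
    """
    rows: list[dict[str, object]] = []
    for spec in grid.cells():
        try:
            result = run_cell(spec, grid.replicates, grid.seed)
        except CellError as exc:
            logger.error("cell failed entirely: %s", exc)
            continue
        rows.extend(result.rows())
    columns = [
        "rho1", "rho2", "ar_order", "n_total", "h2_param",
        "method", "estimand", "mean", "mse", "se", "n_ok",
    ]
    return pd.DataFrame(rows, columns=columns)
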