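"""Full-sib phenotype simulator.

Records follow the two-level nested random model

    y_ijk = mu + sigma_s a_i + sigma_d a_ij + e_ijk,

with ``a_i`` (sire) and ``a_ij`` (dam within sire) independent standard
normal deviates and ``e_ij.`` an autoregressive error series along progeny
order (see :mod:`fullsib.ar`).  By default the AR series restarts within each
dam family (``ar_scope="dam"``: progeny of different dams are conditionally
independent given the sire); ``ar_scope="sire"`` instead runs one series
across all progeny of a sire in dam-major order, which correlates full-sib
families of the same sire and is what biases the sire variance component.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ar import ARErrorSpec, ar_error_series
from .components import VarianceComponents
from .design import NestedDesign

RECORD_COLUMNS = ("sire_id", "dam_id", "progeny_order", "phenotype")


@dataclass(frozen=True)
class FullSibRecords:
    """Phenotype records plus the design that generated (or fits) them.

    ``data`` has columns sire_id, dam_id, progeny_order, phenotype in
    canonical sire-major, dam-minor, progeny-order-ascending row order.
    Progeny order is meaningful: the AR error process runs along it.
    Dam ids are unique across sires (nested classification).
    """

    data: pd.DataFrame
    design: NestedDesign

    def __len__(self) -> int:
        return len(self.data)

    @property
    def phenotype(self) -> np.ndarray:
        return self.data["phenotype"].to_numpy()


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to reproduce one simulated dataset."""

    design: NestedDesign
    vc: VarianceComponents
    mu: float = 0.0
    ar: ARErrorSpec = field(default_factory=ARErrorSpec.independent)
    ar_scope: str = "dam"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ar_scope not in ("dam", "sire"):
            raise ValueError("ar_scope must be 'dam' or 'sire'")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def design_id_columns(design: NestedDesign) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Canonical (sire_id, dam_id, progeny_order) columns, ids starting at 1."""
    sizes = design.family_sizes
    dams_per_sire = design.dams_per_sire
    sire_of_dam = np.repeat(np.arange(design.n_sires) + 1, dams_per_sire)
    sire_id = np.repeat(sire_of_dam, sizes)
    dam_id = np.repeat(np.arange(design.n_dams) + 1, sizes)
    order = np.concatenate([np.arange(1, n + 1) for n in sizes])
    return sire_id, dam_id, order


def simulate_full_sib(config: SimulationConfig) -> FullSibRecords:
    """Generate one full-sib dataset; byte-identical under a fixed seed."""
    rng = np.random.default_rng(config.seed)
    design = config.design
    vc = config.vc
    sd_s, sd_d = np.sqrt(vc.sigma_s2), np.sqrt(vc.sigma_d2)

    a_i = rng.standard_normal(design.n_sires)
    a_ij = rng.standard_normal(design.n_dams)

    sizes = design.family_sizes
    if config.ar_scope == "sire":
        per_sire = design.n_per_sire
        if (per_sire == per_sire[0]).all():
            errors = ar_error_series(
                int(per_sire[0]), vc.sigma_e2, config.ar, rng,
                n_series=design.n_sires,
            ).ravel()
        else:
            errors = np.concatenate(
                [
                    ar_error_series(int(n), vc.sigma_e2, config.ar, rng)[0]
                    for n in per_sire
                ]
            )
    else:
        if (sizes == sizes[0]).all():
            errors = ar_error_series(
                int(sizes[0]), vc.sigma_e2, config.ar, rng,
                n_series=design.n_dams,
            ).ravel()
        else:
            errors = np.concatenate(
                [ar_error_series(int(n), vc.sigma_e2, config.ar, rng)[0] for n in sizes]
            )

    sire_id, dam_id, order = design_id_columns(design)
    y = (
        config.mu
        + sd_s * np.repeat(a_i, design.n_per_sire)
        + sd_d * np.repeat(a_ij, sizes)
        + errors
    )
    data = pd.DataFrame(
        {
            "sire_id": sire_id,
            "dam_id": dam_id,
            "progeny_order": order,
            "phenotype": y,
        }
    )
    return FullSibRecords(data=data, design=design)
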