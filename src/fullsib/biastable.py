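"""Analytic bias table: expected mean squares and heritabilities under AR(1).

With errors AR(1)-correlated along a within-family series of length
``n_within``, every ``sigma_e2`` in the expected mean squares acquires the
geometric factor ``Q(rho) = 1 + rho + ... + rho^{n_within-1}``, while the
sire and dam increments of E(MSB) and E(MSA) are untouched.  A naive analyst
who back-solves components from the usual independent-error expectations
therefore works with an error component ``Q * sigma_e2`` and a fixed pair of
genetic components, and the implied heritabilities drift with rho: as rho
rises toward 1, E(MSE) grows without the genetic increments following, so
every heritability ratio collapses toward 0; as rho falls toward -1 (even
series length), E(MSE) vanishes and the sire+dam heritability is pinned at
its maximum 2.

The default configuration reproduces a worked numeric example: within-family
series length 122, error variance 0.15, dam and sire mean-square increments
1.28 and 0.4509, and naive genetic components (0.01, 0.249513).  These six
constants are a fixture inferred from the example's printed rows, not a
design with recoverable family counts (the implied mean-square divisors are
non-integer).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .components import heritability_from_components
from .ems import geometric_q

CSV_HEADER = ("r", "Q", "E_MSE", "E_MSB", "E_MSA", "hs2", "hd2", "hsd2")


@dataclass(frozen=True)
class BiasTableConfig:
    """Constants defining one analytic bias table."""

    n_within: int = 122
    sigma_e2: float = 0.15
    dam_increment: float = 1.28
    sire_increment: float = 0.4509
    sigma_s2_naive: float = 0.01
    sigma_d2_naive: float = 0.249513


REFERENCE_CONFIG = BiasTableConfig()

DEFAULT_RHO_GRID: tuple[float, ...] = tuple(np.round(np.arange(-10, 11) / 10.0, 1))


@dataclass(frozen=True)
class BiasTableRow:
    """One rho row: Q, the three expected mean squares, and the
    heritabilities implied by the naive component back-solve."""

    rho: float
    q: float
    emse: float
    emsb: float
    emsa: float
    hs2: float
    hd2: float
    hsd2: float


def bias_table(
    rho_grid: Sequence[float] | None = None,
    config: BiasTableConfig = REFERENCE_CONFIG,
) -> list[BiasTableRow]:
    """Analytic table over a rho grid.

    For each rho: ``Q = geometric_q(rho, n_within)``,
    ``E(MSE) = Q sigma_e2``, ``E(MSB) = E(MSE) + dam_increment``,
    ``E(MSA) = E(MSB) + sire_increment`` and the heritabilities of the naive
    components ``(sigma_s2_naive, sigma_d2_naive, Q sigma_e2)``.
    """
    if rho_grid is None:
        rho_grid = DEFAULT_RHO_GRID
    rows = []
    for rho in rho_grid:
        q = geometric_q(rho, config.n_within)
        emse = q * config.sigma_e2
        emsb = emse + config.dam_increment
        emsa = emsb + config.sire_increment
        h = heritability_from_components(
            config.sigma_s2_naive, config.sigma_d2_naive, emse
        )
        rows.append(
            BiasTableRow(
                rho=float(rho), q=q, emse=emse, emsb=emsb, emsa=emsa,
                hs2=h.hs2, hd2=h.hd2, hsd2=h.hsd2,
            )
        )
    return rows


def bias_table_frame(
    rho_grid: Sequence[float] | None = None,
    config: BiasTableConfig = REFERENCE_CONFIG,
) -> pd.DataFrame:
    rows = bias_table(rho_grid, config)
    return pd.DataFrame(
        {
            "r": [r.rho for r in rows],
            "Q": [r.q for r in rows],
            "E_MSE": [r.emse for r in rows],
            "E_MSB": [r.emsb for r in rows],
            "E_MSA": [r.emsa for r in rows],
            "hs2": [r.hs2 for r in rows],
            "hd2": [r.hd2 for r in rows],
            "hsd2": [r.hsd2 for r in rows],
        }
    )


def write_bias_table(
    path,
    rho_grid: Sequence[float] | None = None,
    config: BiasTableConfig = REFERENCE_CONFIG,
) -> None:
    """Write the table as CSV with header ``r,Q,E_MSE,E_MSB,E_MSA,hs2,hd2,hsd2``."""
    frame = bias_table_frame(rho_grid, config)
    frame.to_csv(path, index=False, quoting=csv.QUOTE_MINIMAL)


def plot_bias_curves(rows: Iterable[BiasTableRow] | None = None, ax=None):
    """Optional figure: the three heritability curves against rho."""
    import matplotlib.pyplot as plt

    if rows is None:
        rows = bias_table()
    rows = list(rows)
    if ax is None:
        _, ax = plt.subplots()
    rho = [r.rho for r in rows]
    for attr, label in (("hs2", "$h^2_s$"), ("hd2", "$h^2_d$"), ("hsd2", "$h^2_{s+d}$")):
        ax.plot(rho, [getattr(r, attr) for r in rows], marker="o", ms=3, label=label)
    ax.set_xlabel(r"error autocorrelation $\rho$")
    ax.set_ylabel("implied heritability")
    ax.legend()
    return ax
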