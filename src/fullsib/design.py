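"""Nested sire/dam family structures.

The two-level nested (full-sib) layout groups progeny by dam within sire:
sire i has dams j = 1..d_i, and dam (i, j) has n_ij progeny.  All counts and
degrees of freedom used elsewhere derive from this structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidDesignError


@dataclass(frozen=True)
class NestedDesign:
    """Family structure of a full-sib experiment.

    Parameters
    ----------
    n_progeny
        ``n_progeny[i][j]`` is the number of progeny of dam *j* of sire *i*.
        Ragged (unbalanced) structures are allowed.
    """

    n_progeny: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        try:
            norm = tuple(tuple(int(n) for n in sire) for sire in self.n_progeny)
        except (TypeError, ValueError) as exc:
            raise InvalidDesignError(f"non-integer progeny counts: {exc}") from exc
        object.__setattr__(self, "n_progeny", norm)
        if len(norm) < 2:
            raise InvalidDesignError("a nested design needs at least 2 sires")
        for i, sire in enumerate(norm):
            if len(sire) < 1:
                raise InvalidDesignError(f"sire {i} has no dams")
            for j, n in enumerate(sire):
                if n < 1:
                    raise InvalidDesignError(
                        f"dam {j} of sire {i} has progeny count {n} < 1"
                    )

    # -- derived counts ----------------------------------------------------

    @property
    def n_sires(self) -> int:
        """Number of sires *s*."""
        return len(self.n_progeny)

    @property
    def n_dams(self) -> int:
        """Total number of dams *D* across sires."""
        return sum(len(sire) for sire in self.n_progeny)

    @property
    def n_total(self) -> int:
        """Total number of progeny records *N*."""
        return sum(sum(sire) for sire in self.n_progeny)

    @property
    def n_per_sire(self) -> np.ndarray:
        """Progeny per sire, ``n_i. = sum_j n_ij``."""
        return np.array([sum(sire) for sire in self.n_progeny])

    @property
    def dams_per_sire(self) -> np.ndarray:
        return np.array([len(sire) for sire in self.n_progeny])

    @property
    def family_sizes(self) -> np.ndarray:
        """Flat vector of within-dam family sizes n_ij (dam-major order)."""
        return np.array([n for sire in self.n_progeny for n in sire])

    def is_balanced(self) -> bool:
        """True when every sire has the same number of dams and every dam the
        same number of progeny."""
        d = self.dams_per_sire
        n = self.family_sizes
        return bool((d == d[0]).all() and (n == n[0]).all())

    def common_family_size(self) -> int | None:
        """The shared n_ij if all within-dam families are equal, else None."""
        n = self.family_sizes
        return int(n[0]) if (n == n[0]).all() else None

    # -- constructors ------------------------------------------------------

    @classmethod
    def balanced(
        cls, n_sires: int, dams_per_sire: int, progeny_per_dam: int
    ) -> "NestedDesign":
        if min(n_sires, dams_per_sire, progeny_per_dam) < 1:
            raise InvalidDesignError("all balanced-design counts must be >= 1")
        return cls(tuple((progeny_per_dam,) * dams_per_sire for _ in range(n_sires)))


def design_for_total(
    total_n: int, dams_per_sire: int, progeny_per_dam: int
) -> NestedDesign:
    """Balanced design with a prescribed total number of progeny.

    The sire count is ``total_n / (dams_per_sire * progeny_per_dam)``; the
    total must divide exactly.
    """
    per_sire = dams_per_sire * progeny_per_dam
    if per_sire < 1 or total_n < 1:
        raise InvalidDesignError("counts must be positive")
    if total_n % per_sire:
        raise InvalidDesignError(
            f"total {total_n} is not divisible by dams_per_sire * progeny_per_dam "
            f"= {per_sire}"
        )
    return NestedDesign.balanced(total_n // per_sire, dams_per_sire, progeny_per_dam)
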