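"""Variance components and full-sib heritability ratios.

In the two-level nested random model the phenotypic variance splits as
``sigma_p2 = sigma_s2 + sigma_d2 + sigma_e2``.  The sire component equals the
paternal half-sib covariance, the dam component the excess of the full-sib
over the half-sib covariance, so heritability can be formed three ways:

* sire component:      ``hs2  = 4 sigma_s2 / sigma_p2``
* dam component:       ``hd2  = 4 sigma_d2 / sigma_p2``
* sire+dam (2t'):      ``hsd2 = 2 (sigma_s2 + sigma_d2) / sigma_p2``

``hs2 + hd2 == 2 * hsd2`` identically.  Estimated components may be negative
(raw ANOVA / MINQUE0 solutions), so estimated heritabilities may fall outside
[0, 1]; nothing here truncates.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import UndefinedHeritabilityError


@dataclass(frozen=True)
class VarianceComponents:
    """True (non-negative) variance components, in squared phenotype units."""

    sigma_s2: float
    sigma_d2: float
    sigma_e2: float

    def __post_init__(self) -> None:
        if min(self.sigma_s2, self.sigma_d2, self.sigma_e2) < 0:
            raise ValueError("true variance components must be non-negative")
        if self.sigma_p2 <= 0:
            raise ValueError("phenotypic variance must be positive")

    @property
    def sigma_p2(self) -> float:
        return self.sigma_s2 + self.sigma_d2 + self.sigma_e2

    @classmethod
    def from_h2(cls, h2: float, sigma_p2: float = 1.0) -> "VarianceComponents":
        """Components for a parametric heritability with an equal sire/dam
        split and unit (or given) phenotypic variance:
        ``sigma_s2 = sigma_d2 = h2/4 * sigma_p2``."""
        if not 0 <= h2 <= 2:
            raise ValueError("parametric h2 must lie in [0, 2]")
        g = h2 / 4.0 * sigma_p2
        return cls(g, g, sigma_p2 - 2 * g)


@dataclass(frozen=True)
class ComponentEstimates:
    """Estimated variance components; any field may be negative."""

    sigma_s2: float
    sigma_d2: float
    sigma_e2: float
    method: str = "anova"

    @property
    def sigma_p2(self) -> float:
        return self.sigma_s2 + self.sigma_d2 + self.sigma_e2

    def heritability(self) -> "HeritabilityTriple":
        return heritability_from_components(
            self.sigma_s2, self.sigma_d2, self.sigma_e2
        )


@dataclass(frozen=True)
class HeritabilityTriple:
    """The three full-sib heritability ratios (dimensionless)."""

    hs2: float
    hd2: float
    hsd2: float

    def as_dict(self) -> dict[str, float]:
        return {"hs2": self.hs2, "hd2": self.hd2, "hsd2": self.hsd2}


def heritability_from_components(
    sigma_s2: float, sigma_d2: float, sigma_e2: float
) -> HeritabilityTriple:
    """Heritability ratios from (possibly negative) component estimates.

    Raises
    ------
    UndefinedHeritabilityError
        If the three components sum to zero.
    """
    sigma_p2 = sigma_s2 + sigma_d2 + sigma_e2
    if sigma_p2 == 0:
        raise UndefinedHeritabilityError("zero phenotypic variance")
    return HeritabilityTriple(
        hs2=4.0 * sigma_s2 / sigma_p2,
        hd2=4.0 * sigma_d2 / sigma_p2,
        hsd2=2.0 * (sigma_s2 + sigma_d2) / sigma_p2,
    )
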