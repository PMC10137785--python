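"""Autoregressive within-family error processes.

Errors along the progeny sequence of a family follow AR(1),
``e_k = rho e_{k-1} + eta_k``, or AR(2),
``e_k = rho1 e_{k-1} + rho2 e_{k-2} + eta_k``.  For stationary coefficients
the innovations are scaled so the *marginal* error variance is exactly
``sigma_e2`` (for AR(1): ``Var(eta) = sigma_e2 (1 - rho^2)``, giving
``Corr(e_k, e_l) = rho^{|k-l|}``).  Boundary and non-stationary parameter
values are still simulable via explicit degenerate / drifting constructions,
since the study grids tabulate them; such runs log a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

_warned: set[tuple] = set()


def _warn_once(key: tuple, msg: str, *args) -> None:
    # one warning per distinct degenerate/non-stationary spec, not per family
    if key not in _warned:
        _warned.add(key)
        logger.warning(msg, *args)


@dataclass(frozen=True)
class ARErrorSpec:
    """Order and coefficients of the within-family error process."""

    order: int = 0
    rho1: float = 0.0
    rho2: float = 0.0

    def __post_init__(self) -> None:
        if self.order not in (0, 1, 2):
            raise ValueError(f"AR order must be 0, 1 or 2, got {self.order}")
        if self.order == 0 and (self.rho1 != 0.0 or self.rho2 != 0.0):
            raise ValueError("order-0 spec must have rho1 = rho2 = 0")
        if self.order == 1:
            if self.rho2 != 0.0:
                raise ValueError("order-1 spec must have rho2 = 0")
            if abs(self.rho1) > 1:
                raise ValueError("|rho1| > 1 is not supported for AR(1)")

    @property
    def stationary(self) -> bool:
        if self.order == 0:
            return True
        if self.order == 1:
            return abs(self.rho1) < 1
        return (
            self.rho1 + self.rho2 < 1
            and self.rho2 - self.rho1 < 1
            and abs(self.rho2) < 1
        )

    @classmethod
    def independent(cls) -> "ARErrorSpec":
        return cls(0)

    @classmethod
    def ar1(cls, rho: float) -> "ARErrorSpec":
        return cls(1, rho)

    @classmethod
    def ar2(cls, rho1: float, rho2: float) -> "ARErrorSpec":
        return cls(2, rho1, rho2)


def _ar2_innovation_variance(rho1: float, rho2: float, sigma_e2: float) -> float:
    # Yule-Walker: choose Var(eta) so the stationary marginal variance is
    # sigma_e2:  gamma0 = Var(eta) (1-rho2) / ((1+rho2) ((1-rho2)^2 - rho1^2))
    return sigma_e2 * (1 + rho2) * ((1 - rho2) ** 2 - rho1**2) / (1 - rho2)


def ar_error_series(
    n: int,
    sigma_e2: float,
    spec: ARErrorSpec,
    rng: np.random.Generator,
    n_series: int = 1,
) -> np.ndarray:
    """Draw ``n_series`` independent error series of length ``n``.

    Returns an array of shape ``(n_series, n)``.  Stationary specs have exact
    marginal variance ``sigma_e2`` at every position; the AR(1) boundary
    ``rho = +-1`` uses the degenerate construction ``e_k = (+-1)^{k-1} e_1``,
    and non-stationary AR(2) pairs use the plain recursion started from
    ``e_1, e_2 ~ N(0, sigma_e2)`` with unit-variance-scaled innovations
    (marginal variance drifts; a warning is logged).
    """
    if n < 1:
        raise ValueError("series length must be >= 1")
    if sigma_e2 < 0:
        raise ValueError("sigma_e2 must be non-negative")
    sd = np.sqrt(sigma_e2)
    out = np.empty((n_series, n))

    if spec.order == 0 or (spec.order == 1 and spec.rho1 == 0.0):
        return rng.standard_normal((n_series, n)) * sd

    if spec.order == 1:
        rho = spec.rho1
        out[:, 0] = rng.standard_normal(n_series) * sd
        if abs(rho) == 1.0:
            _warn_once(
                ("ar1-boundary", rho),
                "AR(1) boundary rho=%+g: degenerate alternating/constant errors",
                rho,
            )
            signs = rho ** np.arange(n)
            return out[:, :1] * signs[None, :]
        sd_in = np.sqrt(sigma_e2 * (1 - rho**2))
        innov = rng.standard_normal((n_series, n - 1)) * sd_in
        for k in range(1, n):
            out[:, k] = rho * out[:, k - 1] + innov[:, k - 1]
        return out

    rho1, rho2 = spec.rho1, spec.rho2
    if spec.stationary:
        var_eta = _ar2_innovation_variance(rho1, rho2, sigma_e2)
        r1 = rho1 / (1 - rho2)  # lag-1 autocorrelation
        # exact stationary start: (e1, e2) bivariate normal
        z = rng.standard_normal((n_series, 2))
        out[:, 0] = z[:, 0] * sd
        if n > 1:
            out[:, 1] = sd * (r1 * z[:, 0] + np.sqrt(max(1 - r1**2, 0.0)) * z[:, 1])
        sd_eta = np.sqrt(max(var_eta, 0.0))
    else:
        _warn_once(
            ("ar2-nonstationary", rho1, rho2),
            "non-stationary AR(2) pair (%g, %g): marginal variance drifts",
            rho1,
            rho2,
        )
        out[:, 0] = rng.standard_normal(n_series) * sd
        if n > 1:
            out[:, 1] = rng.standard_normal(n_series) * sd
        sd_eta = sd
    if n > 2:
        innov = rng.standard_normal((n_series, n - 2)) * sd_eta
        for k in range(2, n):
            out[:, k] = rho1 * out[:, k - 1] + rho2 * out[:, k - 2] + innov[:, k - 2]
    return out


def ar_covariance(n: int, sigma_e2: float, spec: ARErrorSpec) -> np.ndarray:
    """Exact covariance matrix of :func:`ar_error_series` output.

    For stationary specs this is the stationary autocovariance
    (AR(1): ``sigma_e2 rho^{|k-l|}``); for the degenerate and drifting
    constructions the covariance is propagated through the same recursion the
    sampler uses, so it matches the simulated process, not a stationary
    idealization.
    """
    if n < 1:
        raise ValueError("series length must be >= 1")
    if spec.order == 0 or (spec.order == 1 and spec.rho1 == 0.0):
        return sigma_e2 * np.eye(n)
    if spec.order == 1:
        rho = spec.rho1
        k = np.arange(n)
        lag = np.abs(k[:, None] - k[None, :])
        # holds for |rho| < 1 (stationary) and the degenerate |rho| = 1 case
        return sigma_e2 * (rho**lag).astype(float)
    rho1, rho2 = spec.rho1, spec.rho2
    cov = np.zeros((n, n))
    if spec.stationary:
        # stationary autocorrelations by Yule-Walker recursion
        r = np.empty(n)
        r[0] = 1.0
        if n > 1:
            r[1] = rho1 / (1 - rho2)
        for h in range(2, n):
            r[h] = rho1 * r[h - 1] + rho2 * r[h - 2]
        k = np.arange(n)
        lag = np.abs(k[:, None] - k[None, :])
        return sigma_e2 * r[lag]
    # drifting construction: forward-propagate the covariance
    var_eta = sigma_e2
    cov[0, 0] = sigma_e2
    if n > 1:
        cov[1, 1] = sigma_e2
    for k in range(2, n):
        for l in range(k):
            cov[k, l] = rho1 * cov[k - 1, l] + rho2 * cov[k - 2, l]
            cov[l, k] = cov[k, l]
        cov[k, k] = (
            rho1**2 * cov[k - 1, k - 1]
            + rho2**2 * cov[k - 2, k - 2]
            + 2 * rho1 * rho2 * cov[k - 1, k - 2]
            + var_eta
        )
    return cov
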