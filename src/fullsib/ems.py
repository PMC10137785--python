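"""Expected mean squares for the nested full-sib ANOVA.

The hierarchical ANOVA of a full-sib experiment has three strata: between
sires (mean square MSA), between dams within sires (MSB) and within dams
(MSE).  With independent errors the balanced expectations are the classic

    E(MSA) = sigma_e2 + n sigma_d2 + n d sigma_s2
    E(MSB) = sigma_e2 + n sigma_d2
    E(MSE) = sigma_e2

With AR(1)-correlated errors along the within-dam progeny sequence every
``sigma_e2`` acquires the geometric correction factor

    Q = 1 + rho + rho^2 + ... + rho^{n_ij - 1},

so the analytic expectations become ``E(MSE) = Q sigma_e2``,
``E(MSB) = Q sigma_e2 + lambda1 sigma_d2`` and
``E(MSA) = Q sigma_e2 + lambda2 sigma_s2 + lambda3 sigma_d2``, where the
lambdas are the usual unbalanced nested-design coefficients (Henderson's
method I).  This module also carries an exact generative counterpart
(:func:`generative_expected_mean_squares`) that computes the true E(MS) under
the simulation model for any AR spec, which the analytic ``Q`` formulas
approximate; the two coincide at ``rho = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ar import ARErrorSpec, ar_covariance
from .components import ComponentEstimates, VarianceComponents
from .design import NestedDesign
from .exceptions import (
    DegreesOfFreedomError,
    InvalidDesignError,
    UnsupportedConfigurationError,
)


def geometric_q(rho: float, n_within: int) -> float:
    """Finite geometric sum ``sum_{k=0}^{n_within-1} rho^k``.

    Closed form ``(1 - rho^n) / (1 - rho)`` for ``rho != 1`` and ``n_within``
    at ``rho = 1``; exact at both boundaries (``rho = -1`` gives 0 for even
    ``n_within``, 1 for odd).
    """
    n = int(n_within)
    if n < 1:
        raise InvalidDesignError("within-family series length must be >= 1")
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    if rho == 1.0:
        return float(n)
    return float((1.0 - rho**n) / (1.0 - rho))


@dataclass(frozen=True)
class EmsCoefficients:
    """Coefficients of the analytic expected mean squares.

    ``lambda1`` multiplies sigma_d2 in E(MSB); ``lambda2`` multiplies
    sigma_s2 and ``lambda3`` sigma_d2 in E(MSA); ``q`` multiplies sigma_e2
    everywhere (1 for independent errors).
    """

    lambda1: float
    lambda2: float
    lambda3: float
    q: float = 1.0


def nested_design_coefficients(
    design: NestedDesign, as_printed: bool = False
) -> EmsCoefficients:
    """Unbalanced nested-ANOVA coefficients of the variance components.

    With ``n_i. = sum_j n_ij`` and N, D, s the progeny/dam/sire totals:

        lambda1 = [N - sum_ij n_ij^2 / n_i.] / (D - s)
        lambda2 = [N - sum_i n_i.^2 / N] / (s - 1)
        lambda3 = [sum_ij n_ij^2 / n_i. - sum_ij n_ij^2 / N] / (s - 1)

    In a balanced design (d dams/sire, n progeny/dam) these reduce exactly to
    ``(n, n d, n)``.  ``as_printed=True`` instead reproduces a published
    variant verbatim: lambda1 with denominator ``sum_i (n_i. - 1)`` and the
    sire/dam attachments in E(MSA) swapped.  That variant does **not** reduce
    to the balanced pattern and is kept only for comparison.
    """
    s = design.n_sires
    D = design.n_dams
    N = design.n_total
    if s < 2:
        raise DegreesOfFreedomError("need at least 2 sires")
    if not as_printed and design.is_balanced():
        # exact closed form; also covers the one-dam-per-sire layout, where
        # the general lambda1 ratio is the 0/0 limit of this value
        n = int(design.family_sizes[0])
        d_per = int(design.dams_per_sire[0])
        return EmsCoefficients(lambda1=float(n), lambda2=float(n * d_per), lambda3=float(n))
    if D <= s:
        raise DegreesOfFreedomError("need more dams than sires (dam stratum df)")
    n_i = design.n_per_sire.astype(float)
    nij2_over_ni = sum(
        sum(n**2 for n in sire) / sum(sire) for sire in design.n_progeny
    )
    sum_nij2 = float((design.family_sizes.astype(float) ** 2).sum())
    sum_ni2 = float((n_i**2).sum())

    term_d = N - nij2_over_ni
    term_s = N - sum_ni2 / N
    term_sd = nij2_over_ni - sum_nij2 / N
    if as_printed:
        lambda1 = term_d / (N - s)  # printed denominator sum_i (n_i. - 1)
        lambda2 = term_sd / (s - 1)  # printed attachment: this on sigma_s2
        lambda3 = term_s / (s - 1)
    else:
        lambda1 = term_d / (D - s)
        lambda2 = term_s / (s - 1)
        lambda3 = term_sd / (s - 1)
    return EmsCoefficients(lambda1=lambda1, lambda2=lambda2, lambda3=lambda3)


def expected_mean_squares(
    design: NestedDesign, vc: VarianceComponents, rho: float = 0.0
) -> tuple[float, float, float]:
    """Analytic ``(E(MSA), E(MSB), E(MSE))`` under AR(1)-correlated errors.

    The Q correction uses a single within-dam family size, so a nonzero
    ``rho`` requires a common ``n_ij``.
    """
    if rho != 0.0:
        n_common = design.common_family_size()
        if n_common is None:
            raise UnsupportedConfigurationError(
                "Q is defined for a common within-dam family size; "
                "got unbalanced n_ij with rho != 0"
            )
        q = geometric_q(rho, n_common)
    else:
        q = 1.0
    lam = nested_design_coefficients(design)
    emse = q * vc.sigma_e2
    emsb = emse + lam.lambda1 * vc.sigma_d2
    emsa = emse + lam.lambda2 * vc.sigma_s2 + lam.lambda3 * vc.sigma_d2
    return emsa, emsb, emse


def naive_components_from_ms(
    msa: float,
    msb: float,
    mse: float,
    c_dam: float,
    c_sire: float,
    method: str = "naive-ems",
) -> ComponentEstimates:
    """Back-solve components from the three mean squares using the
    independent-errors expectations (``sigma_e2 = MSE``,
    ``sigma_d2 = (MSB - MSE)/c_dam``, ``sigma_s2 = (MSA - MSB)/c_sire``).

    Negative solutions are preserved; applying this to correlated data is
    precisely the biased procedure whose consequences the analytic bias table
    quantifies.
    """
    if c_dam <= 0 or c_sire <= 0:
        raise ValueError("mean-square divisors must be positive")
    return ComponentEstimates(
        sigma_s2=(msa - msb) / c_sire,
        sigma_d2=(msb - mse) / c_dam,
        sigma_e2=mse,
        method=method,
    )


def intraclass_sampling_variance(t: float, design: NestedDesign) -> float:
    """Approximate sampling variance of an intraclass correlation estimate.

    Swiger-type large-sample approximation for a one-way layout of F equal
    families of size k (here: full-sib families, i.e. dams):

        Var(t) ~= 2 (N-1) (1-t)^2 [1 + (k-1) t]^2 / (k^2 (N-F) (F-1))

    Used for reporting a standard error alongside ``t' = 0.5 * hsd2``.
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError("t must lie in [0, 1]")
    k = design.common_family_size()
    if k is None:
        raise UnsupportedConfigurationError(
            "intraclass sampling variance approximation needs equal family sizes"
        )
    F = design.n_dams
    N = design.n_total
    if F < 2 or N <= F:
        raise DegreesOfFreedomError("need F >= 2 families and N > F records")
    return (
        2.0 * (N - 1) * (1 - t) ** 2 * (1 + (k - 1) * t) ** 2
        / (k**2 * (N - F) * (F - 1))
    )


def generative_expected_mean_squares(
    design: NestedDesign,
    vc: VarianceComponents,
    ar: ARErrorSpec | None = None,
    ar_scope: str = "dam",
) -> tuple[float, float, float]:
    """Exact ``(E(MSA), E(MSB), E(MSE))`` under the simulation model.

    Unlike :func:`expected_mean_squares` this carries the error covariance
    through the actual mean-square quadratic forms, so it is exact for any
    AR spec, any scope ("dam": the AR series restarts in each dam family;
    "sire": one series runs across all progeny of a sire) and any design.
    """
    if ar is None:
        ar = ARErrorSpec.independent()
    if ar_scope not in ("dam", "sire"):
        raise ValueError("ar_scope must be 'dam' or 'sire'")
    s = design.n_sires
    D = design.n_dams
    N = design.n_total
    if D <= s or N <= D:
        raise DegreesOfFreedomError("every stratum needs positive df")

    sse = 0.0
    # per-sire: dam-mean covariance (genetic + error parts), sire-mean var
    sire_mean_var = np.empty(s)
    ssb = 0.0
    for i, sire in enumerate(design.n_progeny):
        n_i = sum(sire)
        d_i = len(sire)
        if ar_scope == "sire":
            C = ar_covariance(n_i, vc.sigma_e2, ar)
        else:
            C = np.zeros((n_i, n_i))
            off = 0
            for n in sire:
                C[off : off + n, off : off + n] = ar_covariance(n, vc.sigma_e2, ar)
                off += n
        # E(SSE) contribution: within-dam deviations kill sire+dam effects
        off = 0
        for n in sire:
            blk = C[off : off + n, off : off + n]
            sse += blk.trace() - blk.sum() / n
            off += n
        # dam-mean covariance within the sire (error part)
        nvec = np.array(sire, dtype=float)
        edges = np.concatenate(([0], np.cumsum(sire))).astype(int)
        G_err = np.empty((d_i, d_i))
        for a in range(d_i):
            for b in range(d_i):
                G_err[a, b] = (
                    C[edges[a] : edges[a + 1], edges[b] : edges[b + 1]].sum()
                    / (nvec[a] * nvec[b])
                )
        G = vc.sigma_s2 + vc.sigma_d2 * np.eye(d_i) + G_err
        w = nvec / n_i  # weights of dam means in the sire mean
        var_sire_mean = float(w @ G @ w)
        sire_mean_var[i] = var_sire_mean
        # E sum_j n_ij (ybar_ij - ybar_i.)^2
        for a in range(d_i):
            ssb += nvec[a] * (G[a, a] - 2 * (G[a] @ w) + var_sire_mean)

    n_i_all = design.n_per_sire.astype(float)
    grand_var = float((n_i_all**2 * sire_mean_var).sum()) / N**2
    ssa = 0.0
    for i in range(s):
        cov_ig = n_i_all[i] * sire_mean_var[i] / N  # sires independent
        ssa += n_i_all[i] * (sire_mean_var[i] - 2 * cov_ig + grand_var)
    return ssa / (s - 1), ssb / (D - s), sse / (N - D)
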