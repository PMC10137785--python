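"""Two-level nested random-effects model and its four estimators.

``FullSibModel`` is built from phenotype records (a DataFrame, a CSV file or
a simulated :class:`~fullsib.simulate.FullSibRecords`) and ``fit`` returns a
:class:`FullSibResults` carrying the variance-component estimates, the
heritability ratios, likelihood information and a ``summary()`` table.

All four estimators fit the *independent-error* working model

    y = mu 1 + Z_s u_s + Z_d u_d + eps,
    V = sigma_s2 Z_s Z_s' + sigma_d2 Z_d Z_d' + sigma_e2 I.

Applying this working model to data whose errors are actually autocorrelated
is deliberate: quantifying the resulting bias is the point of the study
harness built on top.

Estimators
----------
* ``anova``   - Henderson's method I: equate the three nested mean squares to
  their expectations; raw (possibly negative) solutions are preserved.
* ``ml`` / ``reml`` - Gaussian (restricted) maximum likelihood with the
  components constrained non-negative.  Balanced designs use the exact
  separable-likelihood solution whenever it is interior; otherwise a
  bound-constrained quasi-Newton search (two deterministic starts).
* ``minque0`` - MINQUE with zero priors for the random effects (the MIVQUE0
  convention): solve ``S theta = q`` with ``S_ab = tr(M V_a M V_b)``,
  ``q_a = y' M V_a M y`` and ``M = I - 11'/N``; negatives preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

from .components import ComponentEstimates, HeritabilityTriple, heritability_from_components
from .design import NestedDesign
from .ems import intraclass_sampling_variance, nested_design_coefficients
from .exceptions import DegreesOfFreedomError, RankDeficiencyError, RecordsError
from .simulate import FullSibRecords, RECORD_COLUMNS

METHODS = ("anova", "ml", "reml", "minque0")

_REL_TOL = 1e-8  # relative convergence tolerance on the deviance


@dataclass(frozen=True)
class AnovaDecomposition:
    """Hierarchical sums of squares of the nested classification."""

    ss_sires: float
    ss_dams_within: float
    ss_within: float
    df_sires: int
    df_dams: int
    df_within: int

    @property
    def ms_sires(self) -> float:
        return self.ss_sires / self.df_sires

    @property
    def ms_dams(self) -> float:
        return self.ss_dams_within / self.df_dams

    @property
    def ms_within(self) -> float:
        return self.ss_within / self.df_within

    @property
    def total_ss(self) -> float:
        return self.ss_sires + self.ss_dams_within + self.ss_within

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source": ["sires", "dams within sires", "within dams"],
                "df": [self.df_sires, self.df_dams, self.df_within],
                "ss": [self.ss_sires, self.ss_dams_within, self.ss_within],
                "ms": [self.ms_sires, self.ms_dams, self.ms_within],
            }
        )


def _frame_to_arrays(data: pd.DataFrame) -> tuple[np.ndarray, NestedDesign, np.ndarray, np.ndarray]:
    """Validate a records frame and return (y, design, sire_codes, dam_codes)."""
    missing = [c for c in RECORD_COLUMNS if c not in data.columns]
    if missing:
        raise RecordsError(f"missing column(s): {', '.join(missing)}")
    if len(data) == 0:
        raise RecordsError("empty input: no phenotype records")
    df = data.loc[:, list(RECORD_COLUMNS)].copy()
    y = pd.to_numeric(df["phenotype"], errors="coerce")
    if y.isna().any():
        rows = df.index[y.isna()].tolist()[:5]
        raise RecordsError(f"non-numeric phenotype at row(s) {rows}")
    df["phenotype"] = y.astype(float)
    df = df.sort_values(
        ["sire_id", "dam_id", "progeny_order"], kind="mergesort"
    ).reset_index(drop=True)

    sires_of_dam = df.groupby("dam_id")["sire_id"].nunique()
    shared = sires_of_dam[sires_of_dam > 1]
    if len(shared):
        raise RecordsError(
            f"dam id(s) {shared.index.tolist()} appear under more than one sire; "
            "dams must be nested within sires"
        )
    counts: list[list[int]] = []
    for sire_id, sire_df in df.groupby("sire_id", sort=True):
        sire_counts = []
        for dam_id, dam_df in sire_df.groupby("dam_id", sort=True):
            order = dam_df["progeny_order"].to_numpy()
            expected = np.arange(1, len(order) + 1)
            if not np.array_equal(order, expected):
                raise RecordsError(
                    f"progeny_order of dam {dam_id} (sire {sire_id}) is "
                    f"{order.tolist()}; must run 1..{len(order)} without gaps "
                    "or duplicates"
                )
            sire_counts.append(len(order))
        counts.append(sire_counts)
    design = NestedDesign(tuple(tuple(c) for c in counts))
    sire_codes = np.repeat(np.arange(design.n_sires), design.n_per_sire)
    dam_codes = np.repeat(np.arange(design.n_dams), design.family_sizes)
    return df["phenotype"].to_numpy(), design, sire_codes, dam_codes


class FullSibModel:
    """Nested sire/dam random-effects model bound to one dataset."""

    def __init__(self, data: pd.DataFrame):
        y, design, sire_codes, dam_codes = _frame_to_arrays(data)
        self._init_arrays(y, design, sire_codes, dam_codes)

    def _init_arrays(self, y, design, sire_codes, dam_codes) -> None:
        self.endog = y
        self.design = design
        self._sire_codes = sire_codes
        self._dam_codes = dam_codes
        self._anova: AnovaDecomposition | None = None

    @classmethod
    def from_records(cls, records: FullSibRecords, validate: bool = True) -> "FullSibModel":
        """Build from simulator output.  ``validate=False`` trusts the
        canonical row order the simulator guarantees (fast path)."""
        if validate:
            return cls(records.data)
        obj = cls.__new__(cls)
        design = records.design
        obj._init_arrays(
            records.data["phenotype"].to_numpy(),
            design,
            np.repeat(np.arange(design.n_sires), design.n_per_sire),
            np.repeat(np.arange(design.n_dams), design.family_sizes),
        )
        return obj

    @classmethod
    def from_csv(cls, path) -> "FullSibModel":
        from .io import read_records

        return cls.from_records(read_records(path), validate=False)

    @property
    def nobs(self) -> int:
        return self.endog.size

    # -- ANOVA decomposition ----------------------------------------------

    def anova_decomposition(self) -> AnovaDecomposition:
        if self._anova is None:
            self._anova = self._decompose()
        return self._anova

    def _decompose(self) -> AnovaDecomposition:
        d = self.design
        s, D, N = d.n_sires, d.n_dams, d.n_total
        if D <= s or N <= D:
            raise DegreesOfFreedomError(
                f"degenerate strata: s={s}, D={D}, N={N} leave no df"
            )
        z = self.endog - self.endog.mean()
        n_dam = d.family_sizes.astype(float)
        n_sire = d.n_per_sire.astype(float)
        dam_sums = np.bincount(self._dam_codes, weights=z, minlength=D)
        sire_sums = np.bincount(self._sire_codes, weights=z, minlength=s)
        dam_means = dam_sums / n_dam
        sire_means = sire_sums / n_sire
        ss_sires = float(n_sire @ sire_means**2)
        ss_dams = float(
            n_dam @ (dam_means - sire_means[np.repeat(np.arange(s), d.dams_per_sire)]) ** 2
        )
        ss_within = float(z @ z - n_dam @ dam_means**2)
        return AnovaDecomposition(
            ss_sires=ss_sires,
            ss_dams_within=ss_dams,
            ss_within=max(ss_within, 0.0),
            df_sires=s - 1,
            df_dams=D - s,
            df_within=N - D,
        )

    # -- estimators --------------------------------------------------------

    def fit(self, method: str = "reml") -> "FullSibResults":
        method = method.lower()
        if method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {method!r}")
        if method == "anova":
            return self._fit_anova()
        if method == "minque0":
            return self._fit_minque0()
        return self._fit_likelihood(reml=(method == "reml"))

    def _fit_anova(self) -> "FullSibResults":
        an = self.anova_decomposition()
        lam = nested_design_coefficients(self.design)
        k1, k2, k3 = lam.lambda1, lam.lambda3, lam.lambda2
        sigma_e2 = an.ms_within
        sigma_d2 = (an.ms_dams - an.ms_within) / k1
        sigma_s2 = (
            an.ms_sires - an.ms_dams * (k2 / k1) - an.ms_within * (1 - k2 / k1)
        ) / k3
        est = ComponentEstimates(sigma_s2, sigma_d2, sigma_e2, method="anova")
        return FullSibResults(self, est, converged=True)

    def _fit_minque0(self) -> "FullSibResults":
        d = self.design
        N = float(d.n_total)
        n_dam = d.family_sizes.astype(float)
        n_sire = d.n_per_sire.astype(float)
        # per-observation values of V_a 1 (row sums of Z_s Z_s', Z_d Z_d', I)
        u_s = np.repeat(n_sire, d.n_per_sire)
        u_d = np.repeat(n_dam, d.family_sizes)
        u_e = np.ones(int(N))
        us = [u_s, u_d, u_e]
        tr = np.array(
            [
                [float((n_sire**2).sum()), float((n_dam**2).sum()), N],
                [float((n_dam**2).sum()), float((n_dam**2).sum()), N],
                [N, N, N],
            ]
        )
        ones = np.array([float((n_sire**2).sum()), float((n_dam**2).sum()), N])
        S = np.empty((3, 3))
        for a in range(3):
            for b in range(3):
                S[a, b] = (
                    tr[a, b]
                    - 2.0 / N * float(us[a] @ us[b])
                    + ones[a] * ones[b] / N**2
                )
        z = self.endog - self.endog.mean()
        dam_sums = np.bincount(self._dam_codes, weights=z, minlength=d.n_dams)
        sire_sums = np.bincount(self._sire_codes, weights=z, minlength=d.n_sires)
        q = np.array([float(sire_sums @ sire_sums), float(dam_sums @ dam_sums), float(z @ z)])
        if np.linalg.cond(S) > 1e12:
            raise RankDeficiencyError(
                f"singular MINQUE0 equations for design s={d.n_sires}, "
                f"D={d.n_dams}, N={d.n_total}"
            )
        theta = np.linalg.solve(S, q)
        est = ComponentEstimates(*map(float, theta), method="minque0")
        return FullSibResults(self, est, converged=True)

    # -- (RE)ML ------------------------------------------------------------

    def _fit_likelihood(self, reml: bool) -> "FullSibResults":
        an = self.anova_decomposition()
        scale = max(an.total_ss / (self.nobs - 1), 0.0)
        method = "reml" if reml else "ml"
        if scale == 0.0:
            est = ComponentEstimates(0.0, 0.0, 0.0, method=method)
            return FullSibResults(
                self, est, converged=False, message="degenerate data: zero variance"
            )
        if self.design.is_balanced():
            theta, ll, converged, nit = self._balanced_likelihood_fit(reml, scale)
        else:
            theta, ll, converged, nit = self._general_likelihood_fit(reml, scale)
        est = ComponentEstimates(*map(float, theta), method=method)
        return FullSibResults(self, est, converged=converged, loglik=ll, n_iter=nit)

    def _balanced_deviance_parts(self, reml: bool):
        an = self.anova_decomposition()
        d = self.design
        n = int(d.family_sizes[0])
        nd = n * int(d.dams_per_sire[0])
        s, D, N = d.n_sires, d.n_dams, d.n_total
        dfs = np.array([s if not reml else s - 1, D - s, N - D], dtype=float)
        ss = np.array([an.ss_sires, an.ss_dams_within, an.ss_within])
        const = (
            (N - 1) * np.log(2 * np.pi) + np.log(N)
            if reml
            else N * np.log(2 * np.pi)
        )
        return n, nd, dfs, ss, const

    def _balanced_likelihood_fit(self, reml: bool, scale: float):
        n, nd, dfs, ss, const = self._balanced_deviance_parts(reml)
        an = self.anova_decomposition()
        eps = 1e-12 * scale

        def lambdas(theta):
            ss2, sd2, se2 = theta
            return np.array([se2 + n * sd2 + nd * ss2, se2 + n * sd2, se2])

        def neg2ll(theta):
            lam = lambdas(theta)
            if np.any(lam <= 0):
                return np.inf
            return const + float(dfs @ np.log(lam) + ss @ (1.0 / lam))

        # exact interior solution: the deviance separates across the three
        # eigenvalue blocks; each term df log(lam) + SS/lam is minimized at
        # lam = SS/df, feasible iff the implied components are non-negative.
        lam_hat = ss / dfs
        se2 = lam_hat[2]
        sd2 = (lam_hat[1] - lam_hat[2]) / n
        ss2 = (lam_hat[0] - lam_hat[1]) / nd
        if se2 > 0 and sd2 >= 0 and ss2 >= 0:
            theta = np.array([ss2, sd2, se2])
            return theta, -0.5 * neg2ll(theta), True, 0

        start_anova = np.maximum(
            [
                (an.ms_sires - an.ms_dams) / nd,
                (an.ms_dams - an.ms_within) / n,
                an.ms_within,
            ],
            [0.0, 0.0, eps],
        )
        return self._optimize(neg2ll, start_anova, scale, eps)

    def _general_neg2ll(self, reml: bool):
        """Build the -2 log-likelihood evaluator for arbitrary designs
        (per-sire dense blocks; the grand mean is profiled out)."""
        d = self.design
        y = self.endog
        N = d.n_total
        sire_slices = np.concatenate(([0], np.cumsum(d.n_per_sire)))
        dam_blocks = [list(sire) for sire in d.n_progeny]
        const = (N - 1) * np.log(2 * np.pi) if reml else N * np.log(2 * np.pi)

        def neg2ll(theta):
            ss2, sd2, se2 = theta
            if se2 <= 0 or ss2 < 0 or sd2 < 0:
                return np.inf
            logdet = 0.0
            xtvx = 0.0
            xtvy = 0.0
            factors = []
            for i in range(d.n_sires):
                ni = sire_slices[i + 1] - sire_slices[i]
                V = np.full((ni, ni), ss2)
                off = 0
                for nij in dam_blocks[i]:
                    V[off : off + nij, off : off + nij] += sd2
                    off += nij
                V[np.diag_indices(ni)] += se2
                try:
                    c, low = cho_factor(V, lower=True)
                except np.linalg.LinAlgError:
                    return np.inf
                logdet += 2.0 * np.log(np.diag(c)).sum()
                yi = y[sire_slices[i] : sire_slices[i + 1]]
                sol = cho_solve((c, low), np.column_stack([yi, np.ones(ni)]))
                xtvy += float(sol[:, 1] @ yi)
                xtvx += float(sol[:, 1].sum())
                factors.append((c, low, yi, sol))
            mu = xtvy / xtvx
            quad = 0.0
            for c, low, yi, sol in factors:
                r = yi - mu
                quad += float(r @ (sol[:, 0] - mu * sol[:, 1]))
            out = const + logdet + quad
            if reml:
                out += np.log(xtvx)
            return out

        return neg2ll

    def _general_likelihood_fit(self, reml: bool, scale: float):
        eps = 1e-12 * scale
        neg2ll = self._general_neg2ll(reml)
        an = self.anova_decomposition()
        d = self.design
        lam = nested_design_coefficients(d)
        start_anova = np.maximum(
            [
                (an.ms_sires - an.ms_dams * lam.lambda3 / lam.lambda1
                 - an.ms_within * (1 - lam.lambda3 / lam.lambda1)) / lam.lambda2,
                (an.ms_dams - an.ms_within) / lam.lambda1,
                an.ms_within,
            ],
            [0.0, 0.0, eps],
        )
        return self._optimize(neg2ll, start_anova, scale, eps)

    @staticmethod
    def _optimize(neg2ll, start_anova, scale, eps):
        starts = [np.asarray(start_anova, dtype=float),
                  np.array([scale / 3, scale / 3, scale / 3])]
        bounds = [(0.0, None), (0.0, None), (eps, None)]
        best = None
        nit = 0
        for x0 in starts:
            res = optimize.minimize(
                neg2ll,
                x0,
                method="L-BFGS-B",
                bounds=bounds,
                options={"ftol": _REL_TOL, "gtol": 1e-10, "maxiter": 500},
            )
            nit += res.nit
            if best is None or res.fun < best.fun:
                best = res
        theta = np.asarray(best.x)
        return theta, -0.5 * float(best.fun), bool(best.success), nit

    # -- convenience -------------------------------------------------------

    def loglike(self, sigma_s2: float, sigma_d2: float, sigma_e2: float,
                reml: bool = True) -> float:
        """Profile (restricted) log-likelihood at given components; the grand
        mean is profiled out."""
        if self.design.is_balanced():
            n, nd, dfs, ss, const = self._balanced_deviance_parts(reml)
            lam = np.array(
                [sigma_e2 + n * sigma_d2 + nd * sigma_s2,
                 sigma_e2 + n * sigma_d2, sigma_e2]
            )
            if np.any(lam <= 0):
                return -np.inf
            return -0.5 * (const + float(dfs @ np.log(lam) + ss @ (1.0 / lam)))
        val = self._general_neg2ll(reml)(np.array([sigma_s2, sigma_d2, sigma_e2]))
        return -0.5 * val if np.isfinite(val) else -np.inf


class FullSibResults:
    """Estimation results for one dataset and one method."""

    def __init__(
        self,
        model: FullSibModel,
        params: ComponentEstimates,
        converged: bool,
        loglik: float | None = None,
        n_iter: int = 0,
        message: str = "",
    ):
        self.model = model
        self.params = params
        self.method = params.method
        self.converged = converged
        self.loglik = loglik
        self.n_iter = n_iter
        self.message = message
        try:
            self.heritability: HeritabilityTriple = params.heritability()
        except Exception:  # zero phenotypic variance (degenerate data)
            self.heritability = HeritabilityTriple(np.nan, np.nan, np.nan)

    @property
    def anova(self) -> AnovaDecomposition:
        return self.model.anova_decomposition()

    @property
    def intraclass_correlation(self) -> float:
        """Full-sib intraclass correlation t' = (sigma_s2+sigma_d2)/sigma_p2."""
        return 0.5 * self.heritability.hsd2

    def sampling_variance_t(self) -> float:
        """Approximate sampling variance of t' (equal family sizes only)."""
        t = min(max(self.intraclass_correlation, 0.0), 1.0)
        return intraclass_sampling_variance(t, self.model.design)

    def as_row(self) -> dict[str, object]:
        h = self.heritability
        return {
            "method": self.method,
            "sigma_s2": self.params.sigma_s2,
            "sigma_d2": self.params.sigma_d2,
            "sigma_e2": self.params.sigma_e2,
            "hs2": h.hs2,
            "hd2": h.hd2,
            "hsd2": h.hsd2,
            "converged": self.converged,
            "loglik": self.loglik if self.loglik is not None else "",
        }

    def summary(self) -> str:
        d = self.model.design
        h = self.heritability
        an = self.anova
        lines = [
            "Full-sib nested variance-component fit",
            "=" * 54,
            f"method:        {self.method.upper():>10}    converged: {self.converged}",
            f"records:       {d.n_total:>10}    sires: {d.n_sires}  dams: {d.n_dams}",
        ]
        if self.loglik is not None:
            lines.append(f"log-likelihood: {self.loglik:>12.4f}    iterations: {self.n_iter}")
        lines += [
            "-" * 54,
            f"{'component':<14}{'estimate':>12}",
            f"{'sigma_s2':<14}{self.params.sigma_s2:>12.6f}",
            f"{'sigma_d2':<14}{self.params.sigma_d2:>12.6f}",
            f"{'sigma_e2':<14}{self.params.sigma_e2:>12.6f}",
            "-" * 54,
            f"{'h2 (sire)':<14}{h.hs2:>12.6f}",
            f"{'h2 (dam)':<14}{h.hd2:>12.6f}",
            f"{'h2 (sire+dam)':<14}{h.hsd2:>12.6f}",
            f"{'t-prime':<14}{self.intraclass_correlation:>12.6f}",
            "-" * 54,
            "ANOVA: "
            + "  ".join(
                f"MS_{k}={v:.5f}"
                for k, v in (
                    ("sires", an.ms_sires),
                    ("dams", an.ms_dams),
                    ("within", an.ms_within),
                )
            ),
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<FullSibResults {self.method} sigma_s2={self.params.sigma_s2:.4g} "
            f"sigma_d2={self.params.sigma_d2:.4g} sigma_e2={self.params.sigma_e2:.4g}>"
        )


def anova_decompose(records: FullSibRecords) -> AnovaDecomposition:
    """Hierarchical sums of squares of a records set."""
    return FullSibModel.from_records(records, validate=False).anova_decomposition()


def estimate_heritability(records: FullSibRecords, method: str) -> HeritabilityTriple:
    """Fit the chosen estimator and return the heritability triple."""
    return FullSibModel.from_records(records, validate=False).fit(method).heritability
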