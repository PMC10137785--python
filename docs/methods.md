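# Methods

## Model

Phenotypes follow the two-level nested random model
`y_ijk = mu + s_i + d_ij + e_ijk` with `s_i ~ N(0, sigma_s2)` (sires,
i = 1..s), `d_ij ~ N(0, sigma_d2)` (dams nested in sires, j = 1..d_i) and
residuals `e_ijk` along progeny order k = 1..n_ij.  Sires are independent;
dams are independent given the sire.  All genetic interpretation is through
the sib covariances: sigma_s2 = COV(half sibs),
sigma_s2 + sigma_d2 = COV(full sibs), so

    hs2 = 4 sigma_s2 / sigma_p2,  hd2 = 4 sigma_d2 / sigma_p2,
    hsd2 = 2 (sigma_s2 + sigma_d2) / sigma_p2 = 2 t',

with the exact identity hs2 + hd2 = 2 hsd2.  The dam component absorbs
dominance and common-environment variance, which is why the three ratios
differ in real data; the package computes all three and never truncates an
estimated ratio.

## Error processes

`ARErrorSpec` describes the residual series along progeny order:

* order 0 — i.i.d. `N(0, sigma_e2)`.
* order 1 — `e_k = rho e_{k-1} + eta_k`.  For |rho| < 1 the innovation
  variance is `sigma_e2 (1 - rho^2)`, chosen so the *marginal* variance is
  exactly sigma_e2 at every k and `Corr(e_k, e_l) = rho^{|k-l|}`, matching
  the model assumption `E(e_ijk^2) = sigma_e2`.  At the boundary rho = ±1
  the process degenerates to `e_k = (±1)^{k-1} e_1`.
* order 2 — `e_k = rho1 e_{k-1} + rho2 e_{k-2} + eta_k`.  Stationary pairs
  (rho1 + rho2 < 1, rho2 − rho1 < 1, |rho2| < 1) start from the exact
  stationary bivariate normal for (e_1, e_2) with lag-1 correlation
  rho1/(1 − rho2), innovations Yule–Walker-scaled so the marginal variance
  is sigma_e2.  Non-stationary pairs (the study tabulates e.g. (1, 0.5))
  are generated by the plain recursion from `e_1, e_2 ~ N(0, sigma_e2)`
  with `eta ~ N(0, sigma_e2)`; the marginal variance then drifts, and a
  warning is logged once per spec.

`ar_covariance` returns the exact covariance of whichever construction the
sampler uses (stationary autocovariance, alternating-sign matrix, or the
forward-propagated drifting covariance), so analytic expectations can be
formed for every simulable regime.

**Correlation scope.** Two conventions exist for where the series runs, and
the package supports both.  `ar_scope="dam"` (default) restarts the series
in every dam family: full sibs are serially correlated, but dam families
remain conditionally independent given the sire.  `ar_scope="sire"` runs a
single series across all of a sire's progeny in dam-major order, so
adjacent dam families are also correlated.  The choice matters for which
estimator is biased: under dam scope the error correlation leaves
E(MSA) − E(MSB) = n d sigma_s2 intact (dams stay independent), so the ANOVA
sire component — and hence hs2 — is essentially unbiased, while hd2 and
hsd2 are strongly biased (up for rho > 0, down for rho < 0).  Under sire
scope the cross-dam correlation contaminates the sire line as well, and hs2
is overestimated for rho > 0 and underestimated for rho < 0.  Both facts
are verified against exact generative expectations in the tests.

## Expected mean squares under AR(1)

For the nested ANOVA (sums of squares between sires / dams within sires /
within dams, with df s − 1, D − s, N − D), the analytic expectations under
AR(1) errors along a common within-dam family size n are

    E(MSE) = Q sigma_e2
    E(MSB) = Q sigma_e2 + lambda1 sigma_d2
    E(MSA) = Q sigma_e2 + lambda2 sigma_s2 + lambda3 sigma_d2
    Q      = 1 + rho + ... + rho^{n-1} = (1 - rho^n)/(1 - rho)

with the standard unbalanced nested-design coefficients

    lambda1 = [N - sum_ij n_ij^2 / n_i.] / (D - s)
    lambda2 = [N - sum_i n_i.^2 / N] / (s - 1)
    lambda3 = [sum_ij n_ij^2 / n_i. - sum_ij n_ij^2 / N] / (s - 1)

which reduce to (n, nd, n) in the balanced case.  A published variant of
these formulas attaches the lambda2/lambda3 terms to the opposite
components and divides lambda1 by sum_i(n_i. − 1) instead of D − s; that
variant does not reduce to the balanced pattern and is available verbatim
under `as_printed=True` for comparison only.  Because Q is defined through
a single n_ij, `expected_mean_squares` refuses unbalanced family sizes when
rho ≠ 0 rather than inventing an averaging rule.

Two caveats are deliberate.  First, `E(MSE) = Q sigma_e2` is the source
formula, not the exact expectation of the within-dam mean square under the
generative model (the exact value is `n (sigma_e2 − var(ebar)) / (n − 1)`,
which *decreases* in rho; the Q form instead grows toward n sigma_e2 as
rho → 1).  The package therefore also provides
`generative_expected_mean_squares`, which carries the exact error
covariance through the three quadratic forms for any AR spec, scope and
design; it coincides with the analytic formulas at rho = 0 and is validated
against Monte Carlo in the tests.  Second, the bias table below uses the Q
form, as the analytic construction it reproduces does.

## The analytic bias table

`bias_table` tabulates, per rho: Q, E(MSE) = Q sigma_e2,
E(MSB) = E(MSE) + dam increment, E(MSA) = E(MSB) + sire increment, and the
heritabilities of the fixed naive components
(sigma_s2_hat, sigma_d2_hat, Q sigma_e2).  The default configuration —
n_within = 122, sigma_e2 = 0.15, increments 1.28 and 0.4509, naive
components (0.01, 0.249513) — reproduces a published worked example; the
six constants are stored as an explicit fixture because the nested design
behind them is not recoverable (the implied mean-square divisors,
1.28/0.249513 ≈ 5.13 and 0.4509/0.01 ≈ 45.1, are not integer products of
any family layout).  Within that construction E(MSE) is strictly
increasing and hsd2 strictly decreasing in rho; at rho = −1 (even series
length) Q = 0 kills the error term and pins hsd2 at its maximum 2 for any
positive components, and as rho → 1 all three ratios collapse toward 0.

## Estimators

All four estimators fit the independent-error working model
`V = sigma_s2 Z_s Z_s' + sigma_d2 Z_d Z_d' + sigma_e2 I` — applying them to
correlated data is the studied misuse, so no AR-aware likelihood is fitted.

* **ANOVA (Henderson I).**  Equate the three nested mean squares to their
  expectations and solve; negative solutions are reported as-is (they are
  the source of the negative printed heritabilities the study discusses).
* **ML / REML.**  Gaussian likelihood with the grand mean profiled out;
  REML maximizes the residual likelihood
  −½[log|V| + log(1'V⁻¹1) + y'Py] (+ constant).  Components are
  constrained non-negative, matching standard variance-component software.
  Balanced designs use the eigenvalue factorization of V — the deviance
  separates over the three strata with eigenvalues
  (sigma_e2, sigma_e2 + n sigma_d2, sigma_e2 + n sigma_d2 + n d sigma_s2)
  and stratum sums of squares — so the interior optimum is available in
  closed form (REML: the ANOVA solution exactly; ML: the same with the
  sire stratum divided by s instead of s − 1, the classic ML shrinkage).
  If the closed-form candidate violates a constraint, or the design is
  unbalanced (per-sire block Cholesky likelihood), a bound-constrained
  L-BFGS-B search runs from two deterministic starts (ANOVA truncated at
  zero, and equal thirds of the total variance), relative deviance
  tolerance 1e−8.  Non-convergence and degenerate (zero-variance) data are
  flagged, never silently returned.  The boundary constraint is on the
  variance scale rather than a log parameterization precisely so that
  exact zeros — which occur with appreciable probability when true
  components are small — are representable.
* **MINQUE0 (MIVQUE0 convention: zero priors for the random effects,
  identity weighting).**  Solve S theta = q with
  S_ab = tr(M V_a M V_b), q_a = y'M V_a M y, M = I − 11'/N.  All traces
  and quadratic forms reduce to group counts and group sums, so the solve
  is O(D); the reduction is verified against a dense matrix construction
  in the tests.  Negative solutions preserved; a singular S raises with
  design diagnostics.

Consequences worth knowing: on balanced data MINQUE0 coincides with ANOVA,
and REML coincides with ANOVA whenever the ANOVA solution is interior.
Because ML/REML truncate at zero, they are *upward*-biased for components
whose sampling distribution straddles zero — at h2 = 0.1 with 25 sires
roughly a third of replicates hit the boundary and the replicate-mean REML
hsd2 sits near 0.112 rather than 0.10.  That is a property of constrained
likelihood estimation, not an implementation artifact; the unconstrained
ANOVA estimator is mean-unbiased in the same setting.

An approximate sampling variance for the full-sib intraclass correlation
t' is reported for balanced designs via the Swiger-type formula
`2 (N−1)(1−t)^2 [1+(k−1)t]^2 / (k^2 (N−F)(F−1))` with F dam families of
size k; it is informational only.

## Simulator defaults and the Monte Carlo harness

The study conditions are: parametric heritabilities {0.1, 0.5} mapped to
components by an equal sire/dam split at unit phenotypic variance
(sigma_s2 = sigma_d2 = h2/4, sigma_e2 = 1 − h2/2 — the split is a modelling
choice, no dominance is simulated); total sample sizes {100, 500} arranged
as 5 dams per sire x 4 progeny per dam (s = 5 or 25), a conventional
full-sib layout that keeps all three strata informative; AR(1) coefficients
{−1, −0.7, −0.5, −0.3, 0, 0.3, 0.5, 0.7, 1}; AR(2) pairs
{(−1,−1), (−1,−0.5), (0,−0.5), (0,0.5), (1,0.5)}; methods = all four;
default R = 500 replicates per cell.  Each cell derives its seed stream as
SeedSequence(master, crc32(cell key), replicate), so results are
reproducible cell-by-cell and independent of grid composition.  Cell
summaries are the replicate mean and MSE = mean((h_hat − h2)^2) per ratio,
plus the Monte Carlo standard error of the mean; MSE = bias² + variance
holds exactly with the population-variance convention.  Unconverged or
failed replicates are logged, counted and excluded.

What the generator does **not** emulate: dominance or epistatic variance,
common-litter environments, selection, assortative mating, unbalanced field
structures, non-normal phenotypes, or correlation structures other than AR
along progeny order.  Passing tests therefore demonstrate estimator
behavior under the stated Gaussian AR conditions, not robustness of
heritability estimation in real populations.

## Numerical choices and problem sizes

Closed-form Q uses `(1 − rho^n)/(1 − rho)` with exact handling of rho = 1
(Q = n) and rho = −1 (0 or 1 by parity).  ANOVA sums of squares are
computed on mean-centered data via group bincounts; the within-dam SS is
clamped at zero against cancellation.  The MINQUE0 solve refuses condition
numbers above 1e12.  Records CSV I/O pins the dialect (comma, '.' decimal,
UTF-8, exact header `sire_id,dam_id,progeny_order,phenotype`), re-reads
floats with round-trip precision, canonicalizes row order sire-major, and
validates nesting (a dam under two sires is an error) and progeny-order
contiguity (1..n_ij per dam) with row-level messages.

Test and validation problem sizes were chosen to make each statistical
assertion sharp at three Monte Carlo standard errors while keeping the
default suite in the minutes range: 10^4 replicates for the expected-mean-
square oracle on the 10x5x4 design, R = 500 per cell for estimator
recovery and bias-direction checks at P = 500, 1.5–4 x 10^3 replicates for
unbiasedness oracles on small designs, and 2 x 10^5-point series for AR
autocorrelation checks.

## Known limitations

* The analytic Q-corrected E(MSE) diverges from the exact generative
  expectation as |rho| grows (see above); both quantities are exposed.
* The AR(2) regime has no analytic EMS here; it is simulation-only.
* ML/REML standard errors of the components are not reported (the study
  summarizes uncertainty through Monte Carlo replication instead).
* The intraclass sampling-variance formula assumes equal family sizes and
  one-way structure; it is approximate for the nested design.
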