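"""Frequentist multi-trait association tests for a single SNP.

Two families of tests are implemented behind a common interface:

* summary-statistic tests, operating on per-trait univariate GWAS results
  (effect, SE, Wald z, p) plus the trait correlation matrix: min-P
  (Sidak-corrected minimum p with the Nyholt effective number of tests),
  TATES (extended Simes over correlated trait p-values), and the
  cross-phenotype meta-analysis statistics S_Hom and S_Het;
* individual-level tests, operating on the genotype/phenotype matrix
  directly: MANOVA (Wilks' lambda), canonical correlation analysis (CCA,
  as in mv-PLINK), Combined-PC (summed chi-squares of PC-on-SNP
  regressions), and MultiPhen (proportional-odds ordinal regression of
  genotype on all traits, likelihood-ratio tested).

With a single SNP predictor MANOVA and CCA are algebraically identical
(Wilks' lambda = 1 - rho^2); they are implemented through different
numerical routes and their agreement is used as a cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize, stats

from ._exceptions import (
    ConvergenceError,
    DegenerateInputError,
    MatrixStructureError,
    ParameterError,
)
from .datagen import GenoPhenoDataset, _mvn_factor

__all__ = [
    "TestResult",
    "UnivariateSummary",
    "NullContext",
    "METHOD_NAMES",
    "univariate_scan",
    "nyholt_meff",
    "pvalue_correlation",
    "minp_test",
    "tates_test",
    "shom_test",
    "shet_test",
    "ShetNull",
    "manova_test",
    "cca_test",
    "combined_pc_test",
    "multiphen_test",
    "build_context",
    "run_method",
    "write_summary",
    "read_summary",
]

_PMIN = 1e-300  # floor keeping p-values inside (0, 1]


@dataclass(frozen=True)
class TestResult:
    """Outcome of one association test on one dataset."""

    method: str
    statistic: float
    df: float | None
    pvalue: float

    def __post_init__(self):
        if not np.isfinite(self.statistic):
            raise ParameterError(f"{self.method}: non-finite statistic")
        if not (0.0 < self.pvalue <= 1.0):
            raise ParameterError(f"{self.method}: p-value {self.pvalue} outside (0, 1]")


@dataclass
class UnivariateSummary:
    """Per-trait univariate GWAS results for one SNP.

    ``trait_corr`` is the phenotype correlation matrix used by the
    summary-statistic tests to adjust for trait dependence; in a single
    fully-overlapping cohort it also equals the null correlation of the
    Wald statistics.
    """

    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    trait_corr: np.ndarray
    n: int | None = None

    @property
    def n_traits(self) -> int:
        return self.z.shape[0]


# ---------------------------------------------------------------------------
# univariate scan
# ---------------------------------------------------------------------------

def univariate_scan(data: GenoPhenoDataset) -> UnivariateSummary:
    """Per-trait regression of each phenotype on the genotype.

    Quantitative traits use closed-form simple linear regression;
    case/control traits use logistic regression.  Two-sided p-values come
    from the standard-normal reference for the Wald statistic.
    """
    g = np.asarray(data.genotypes, dtype=float)
    n, k = data.phenotypes.shape
    if n <= k + 2:
        raise ParameterError(f"need n > K + 2 (n={n}, K={k})")
    x = g - g.mean()
    sxx = float(x @ x)
    if sxx <= 0.0:
        raise DegenerateInputError("genotype column is constant")

    beta = np.empty(k)
    se = np.empty(k)
    quant = ~data.binary
    if quant.any():
        yq = data.phenotypes[:, quant]
        yc = yq - yq.mean(axis=0)
        b = (x @ yc) / sxx
        resid = yc - np.outer(x, b)
        sigma2 = np.einsum("ij,ij->j", resid, resid) / (n - 2)
        beta[quant] = b
        se[quant] = np.sqrt(sigma2 / sxx)
    for j in np.flatnonzero(data.binary):
        beta[j], se[j] = _logistic_wald(data.phenotypes[:, j], g)

    z = beta / se
    p = np.maximum(2.0 * stats.norm.sf(np.abs(z)), _PMIN)
    corr = np.corrcoef(data.phenotypes, rowvar=False)
    corr = np.atleast_2d(corr)
    return UnivariateSummary(beta=beta, se=se, z=z, p=p, trait_corr=corr, n=n)


def _logistic_wald(y: np.ndarray, g: np.ndarray) -> tuple[float, float]:
    """Slope and SE from logistic regression of a 0/1 trait on genotype."""
    import statsmodels.api as sm

    if y.min() == y.max():
        raise DegenerateInputError("binary trait has a single level")
    x = sm.add_constant(g)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(y, x).fit(disp=0, maxiter=100)
    return float(fit.params[1]), float(fit.bse[1])


# ---------------------------------------------------------------------------
# min-P and TATES
# ---------------------------------------------------------------------------

def nyholt_meff(c) -> float:
    """Effective number of independent tests from the trait correlations.

    ``Meff = 1 + (K - 1) (1 - Var(lambda) / K)`` where ``lambda`` are the
    eigenvalues of the correlation matrix and Var uses divisor K - 1.
    Equals K for independent traits and 1 when all are perfectly
    correlated.
    """
    c = np.atleast_2d(np.asarray(c, dtype=float))
    k = c.shape[0]
    if k == 1:
        return 1.0
    lam = np.linalg.eigvalsh(c)
    meff = 1.0 + (k - 1.0) * (1.0 - lam.var(ddof=1) / k)
    return float(np.clip(meff, 1.0, k))


def minp_test(summary: UnivariateSummary, meff: float | None = None) -> TestResult:
    """Sidak-adjusted minimum univariate p-value.

    The minimum of the K trait p-values is corrected for the Nyholt
    effective number of tests implied by the phenotype correlation matrix:
    ``p_adj = 1 - (1 - p_min)^Meff``.
    """
    if meff is None:
        meff = nyholt_meff(summary.trait_corr)
    p_min = float(summary.p.min())
    p_adj = -np.expm1(meff * np.log1p(-min(p_min, 1.0 - 1e-16)))
    return TestResult("minP", statistic=p_min, df=None,
                      pvalue=float(np.clip(p_adj, _PMIN, 1.0)))


_PCORR_CACHE: dict = {}


def pvalue_correlation(trait_corr, n_draws: int = 10_000, seed: int = 271_828) -> np.ndarray:
    """Correlation matrix of univariate p-values under the global null.

    Estimated by seeded Monte Carlo: draw ``n_draws`` null Wald vectors
    from MVN(0, trait_corr), map to two-sided p-values, and take their
    sample correlation.  Cached per (matrix, n_draws, seed) so repeated
    tests on the same correlation structure pay the cost once.
    """
    c = np.atleast_2d(np.asarray(trait_corr, dtype=float))
    key = (np.round(c, 12).tobytes(), c.shape[0], int(n_draws), int(seed))
    hit = _PCORR_CACHE.get(key)
    if hit is not None:
        return hit
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_draws, c.shape[0])) @ _mvn_factor(c).T
    p = 2.0 * stats.norm.sf(np.abs(z))
    out = np.atleast_2d(np.corrcoef(p, rowvar=False))
    _PCORR_CACHE[key] = out
    return out


def tates_test(summary: UnivariateSummary, pcorr: np.ndarray | None = None) -> TestResult:
    """Trait-based extended Simes test over correlated p-values.

    Sort the trait p-values ascending and take
    ``p_TATES = min_j  me_total * p_(j) / me_j`` where ``me_j`` is the
    effective number of p-values (Nyholt on the p-value correlation
    submatrix) among the j most significant traits.  For independent
    traits this reduces to the Simes procedure.
    """
    k = summary.n_traits
    if k == 1:
        return TestResult("TATES", statistic=float(summary.p[0]), df=None,
                          pvalue=float(summary.p[0]))
    if pcorr is None:
        pcorr = pvalue_correlation(summary.trait_corr)
    order = np.argsort(summary.p)
    me = np.empty(k)
    for j in range(1, k + 1):
        idx = order[:j]
        me[j - 1] = nyholt_meff(pcorr[np.ix_(idx, idx)])
    p_sorted = summary.p[order]
    p_tates = float(np.min(me[-1] * p_sorted / me))
    return TestResult("TATES", statistic=float(summary.p.min()), df=None,
                      pvalue=float(np.clip(p_tates, _PMIN, 1.0)))


# ---------------------------------------------------------------------------
# S_Hom / S_Het cross-phenotype meta-analysis
# ---------------------------------------------------------------------------

def _solve_ones_quadratic(r: np.ndarray, t: np.ndarray) -> float:
    """(1' R^-1 T)^2 / (1' R^-1 1), the homogeneity meta-analysis form."""
    try:
        cho = linalg.cho_factor(r)
    except linalg.LinAlgError as exc:
        raise MatrixStructureError(f"singular correlation matrix: {exc}") from exc
    a = linalg.cho_solve(cho, np.ones(r.shape[0]))
    denom = float(a.sum())
    if denom <= 0.0:
        raise MatrixStructureError("correlation matrix is not positive definite")
    return float((a @ t) ** 2 / denom)


def shom_test(summary: UnivariateSummary, null_corr: np.ndarray | None = None) -> TestResult:
    """Homogeneous cross-phenotype meta-analysis of Wald statistics.

    ``S_Hom = (1' R^-1 T)^2 / (1' R^-1 1)`` with T the per-trait Wald
    statistics and R their null correlation matrix (the trait correlation
    matrix in a single fully-overlapping cohort); chi-square with 1 df.
    Optimal when the SNP effect is homogeneous across traits; opposite
    effects cancel.
    """
    r = summary.trait_corr if null_corr is None else np.asarray(null_corr, dtype=float)
    s = _solve_ones_quadratic(r, summary.z)
    return TestResult("SHom", statistic=s, df=1.0,
                      pvalue=float(max(stats.chi2.sf(s, 1), _PMIN)))


def _shet_statistic(t: np.ndarray, r: np.ndarray) -> float:
    """Maximum of the homogeneity form over |T|-threshold trait subsets.

    The included-trait set only changes at observed |T| values, so the
    threshold grid reduces to the nested top-m subsets by |T|
    (m = 1..K; m = K reproduces the all-trait statistic, so S_Het is
    always at least the tau = 0 value).
    """
    order = np.argsort(-np.abs(t))
    best = -np.inf
    for m in range(1, t.shape[0] + 1):
        idx = np.sort(order[:m])
        best = max(best, _solve_ones_quadratic(r[np.ix_(idx, idx)], t[idx]))
    return best


@dataclass(frozen=True)
class ShetNull:
    """Moment-matched Gamma fit to the null distribution of S_Het."""

    shape: float
    scale: float
    n_sims: int

    def sf(self, s: float) -> float:
        return float(stats.gamma.sf(s, a=self.shape, scale=self.scale))

    @classmethod
    def fit(cls, r: np.ndarray, n_sims: int = 100_000, seed: int = 1) -> "ShetNull":
        """Fit from seeded draws of S_Het under T ~ MVN(0, R).

        Draws are grouped by the identity of the top-m trait subset so the
        quadratic form is evaluated once per distinct subset, vectorized
        over the draws that share it.
        """
        if n_sims < 1_000:
            warnings.warn("fewer than 1000 null simulations gives an unstable "
                          "Gamma fit", stacklevel=2)
        r = np.atleast_2d(np.asarray(r, dtype=float))
        k = r.shape[0]
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((int(n_sims), k)) @ _mvn_factor(r).T
        order = np.argsort(-np.abs(z), axis=1)
        masks = np.cumsum(2 ** order, axis=1)          # (n_sims, K) subset codes
        best = np.full(int(n_sims), -np.inf)
        for m in range(k):
            codes = masks[:, m]
            for code in np.unique(codes):
                idx = np.flatnonzero((int(code) >> np.arange(k)) & 1)
                rows = codes == code
                cho = linalg.cho_factor(r[np.ix_(idx, idx)])
                a = linalg.cho_solve(cho, np.ones(idx.size))
                s = (z[np.ix_(rows, idx)] @ a) ** 2 / a.sum()
                best[rows] = np.maximum(best[rows], s)
        mean, var = float(best.mean()), float(best.var(ddof=1))
        return cls(shape=mean**2 / var, scale=var / mean, n_sims=int(n_sims))


_SHET_CACHE: dict = {}


def fit_shet_null(r, n_sims: int = 100_000, seed: int = 1) -> ShetNull:
    """Cached :meth:`ShetNull.fit` keyed by the correlation matrix."""
    r = np.atleast_2d(np.asarray(r, dtype=float))
    key = (np.round(r, 12).tobytes(), r.shape[0], int(n_sims), int(seed))
    hit = _SHET_CACHE.get(key)
    if hit is None:
        hit = _SHET_CACHE[key] = ShetNull.fit(r, n_sims, seed)
    return hit


def shet_test(summary: UnivariateSummary, null_corr: np.ndarray | None = None,
              null: ShetNull | None = None, null_sims: int = 100_000,
              seed: int = 1) -> TestResult:
    """Subset-searching cross-phenotype meta-analysis.

    Recomputes the S_Hom form over all |T|-threshold subsets of traits and
    takes the maximum; because the maximum has no standard reference
    distribution, the p-value comes from a Gamma distribution
    moment-matched to seeded null simulations of the same statistic.
    A pre-fitted ``null`` (see :func:`fit_shet_null`) avoids refitting per
    call.
    """
    if summary.n_traits == 1:
        s = float(summary.z[0] ** 2)
        return TestResult("SHet", statistic=s, df=1.0,
                          pvalue=float(max(stats.chi2.sf(s, 1), _PMIN)))
    r = summary.trait_corr if null_corr is None else np.asarray(null_corr, dtype=float)
    s = _shet_statistic(summary.z, r)
    if null is None:
        null = fit_shet_null(r, n_sims=null_sims, seed=seed)
    return TestResult("SHet", statistic=s, df=None,
                      pvalue=float(np.clip(null.sf(s), _PMIN, 1.0)))


# ---------------------------------------------------------------------------
# individual-level tests
# ---------------------------------------------------------------------------

def _check_individual(data: GenoPhenoDataset):
    n, k = data.phenotypes.shape
    if n <= k + 2:
        raise ParameterError(f"need n > K + 2 (n={n}, K={k})")
    g = np.asarray(data.genotypes, dtype=float)
    if np.ptp(g) == 0.0:
        raise DegenerateInputError("genotype column is constant")
    return g, n, k


def manova_test(data: GenoPhenoDataset) -> TestResult:
    """One-way MANOVA of the trait matrix on additive genotype.

    Wilks' lambda from the multivariate regression of Y on G; with a
    single predictor the exact transform
    ``F = (1 - L)/L * (n - K - 1)/K`` has an F(K, n-K-1) reference.
    Equivalent to a reversed multiple regression with the SNP as outcome.
    Binary traits, when present, enter as their 0/1 values.
    """
    g, n, k = _check_individual(data)
    x = np.column_stack([np.ones(n), g])
    y = data.phenotypes
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    e = resid.T @ resid                       # error SSCP under the full model
    yc = y - y.mean(axis=0)
    e0 = yc.T @ yc                            # error SSCP under intercept only
    sign, logdet_e = np.linalg.slogdet(e)
    sign0, logdet_e0 = np.linalg.slogdet(e0)
    if sign <= 0 or sign0 <= 0:
        raise DegenerateInputError("rank-deficient phenotype matrix")
    wilks = float(np.exp(logdet_e - logdet_e0))
    df2 = n - k - 1
    f = (1.0 - wilks) / wilks * df2 / k
    return TestResult("MANOVA", statistic=f, df=float(k),
                      pvalue=float(max(stats.f.sf(f, k, df2), _PMIN)))


def cca_test(data: GenoPhenoDataset) -> TestResult:
    """Canonical correlation of the SNP with the trait set (mv-PLINK test).

    With one variable on the genotype side the first canonical correlation
    is the multiple correlation of G on Y,
    ``rho^2 = S_gy' S_yy^-1 S_gy / S_gg``, tested with the exact
    ``F = (n - K - 1)/K * rho^2 / (1 - rho^2)`` on (K, n-K-1) df.
    Algebraically identical to MANOVA for a single SNP.
    """
    g, n, k = _check_individual(data)
    gc = g - g.mean()
    yc = data.phenotypes - data.phenotypes.mean(axis=0)
    s_yy = yc.T @ yc
    s_gy = yc.T @ gc
    s_gg = float(gc @ gc)
    try:
        rho2 = float(s_gy @ linalg.solve(s_yy, s_gy, assume_a="pos")) / s_gg
    except linalg.LinAlgError as exc:
        raise DegenerateInputError(f"rank-deficient phenotype matrix: {exc}") from exc
    rho2 = min(max(rho2, 0.0), 1.0 - 1e-15)
    df2 = n - k - 1
    f = df2 / k * rho2 / (1.0 - rho2)
    return TestResult("CCA", statistic=f, df=float(k),
                      pvalue=float(max(stats.f.sf(f, k, df2), _PMIN)))


def combined_pc_test(data: GenoPhenoDataset) -> TestResult:
    """Sum of chi-squares from regressing each phenotype PC on the SNP.

    PCA is run on the standardized trait matrix; each of the K principal
    components is regressed on genotype, and the K squared Wald statistics
    are summed.  Orthogonality of the PCs makes the component tests
    independent, giving a chi-square reference with K df.
    """
    g, n, k = _check_individual(data)
    y = data.phenotypes
    sd = y.std(axis=0, ddof=1)
    if np.any(sd == 0.0):
        raise DegenerateInputError("zero-variance trait")
    ys = (y - y.mean(axis=0)) / sd
    corr = (ys.T @ ys) / (n - 1)
    _, vec = np.linalg.eigh(corr)
    pcs = ys @ vec
    xc = g - g.mean()
    sxx = float(xc @ xc)
    b = (xc @ pcs) / sxx
    resid = pcs - np.outer(xc, b)             # PCs are already centered
    sigma2 = np.einsum("ij,ij->j", resid, resid) / (n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z2 = np.where(sigma2 > 0, b**2 * sxx / sigma2, 0.0)
    stat = float(z2.sum())
    return TestResult("CombinedPC", statistic=stat, df=float(k),
                      pvalue=float(max(stats.chi2.sf(stat, k), _PMIN)))


# ---------------------------------------------------------------------------
# MultiPhen: proportional-odds reversed regression
# ---------------------------------------------------------------------------

def _ordinal_negll_grad(theta, x, codes, n_cuts):
    """Negative log-likelihood and gradient of the proportional-odds model.

    Cumulative logits P(G <= j) = sigmoid(a_j - x b).  Non-monotone
    cutpoints yield +inf, which line searches back away from.
    """
    a = theta[:n_cuts]
    b = theta[n_cuts:]
    if n_cuts > 1 and np.any(np.diff(a) <= 0):
        return np.inf, np.zeros_like(theta)
    eta = a[None, :] - (x @ b)[:, None]
    gam = 1.0 / (1.0 + np.exp(-eta))
    n = x.shape[0]
    upper = np.concatenate([gam, np.ones((n, 1))], axis=1)
    lower = np.concatenate([np.zeros((n, 1)), gam], axis=1)
    rows = np.arange(n)
    pi = upper[rows, codes] - lower[rows, codes]
    if np.any(pi <= 0.0):
        return np.inf, np.zeros_like(theta)
    ll = float(np.log(pi).sum())

    w = gam * (1.0 - gam)                      # sigmoid derivative at each cut
    w_up = np.concatenate([w, np.zeros((n, 1))], axis=1)[rows, codes]
    w_lo = np.concatenate([np.zeros((n, 1)), w], axis=1)[rows, codes]
    inv_pi = 1.0 / pi
    # d ll / d a_j: +w_j/pi where code == j, -w_j/pi where code == j + 1
    ga = np.zeros(n_cuts)
    for j in range(n_cuts):
        ga[j] = float((w_up * inv_pi)[codes == j].sum()
                      - (w_lo * inv_pi)[codes == j + 1].sum())
    gb = -x.T @ ((w_up - w_lo) * inv_pi)
    return -ll, -np.concatenate([ga, gb])


def multiphen_test(data: GenoPhenoDataset, max_iter: int = 100,
                   tol: float = 1e-8) -> TestResult:
    """Reversed ordinal regression: genotype outcome, traits as predictors.

    A proportional-odds logistic model of G in {0, 1, 2} on all K
    phenotypes jointly is compared with the intercept-only model by a
    likelihood-ratio test, chi-square with K df.  Approximately equivalent
    to MANOVA/CCA for common SNPs.

    Raises
    ------
    ConvergenceError
        If the optimizer fails; the error carries the iteration count
        (no silent fallback model is fitted).
    """
    g, n, k = _check_individual(data)
    levels, codes = np.unique(data.genotypes, return_inverse=True)
    if levels.size < 2:
        raise DegenerateInputError("genotype has a single observed level")
    x = data.phenotypes - data.phenotypes.mean(axis=0)
    n_cuts = levels.size - 1

    counts = np.bincount(codes, minlength=levels.size).astype(float)
    ll_null = float((counts * np.log(counts / n)).sum())
    cum = np.cumsum(counts)[:-1] / n
    a0 = np.log(cum / (1.0 - cum))             # null MLE for the cutpoints
    theta0 = np.concatenate([a0, np.zeros(k)])

    res = optimize.minimize(
        _ordinal_negll_grad, theta0, args=(x, codes, n_cuts), jac=True,
        method="BFGS", options={"maxiter": max_iter, "gtol": tol * n},
    )
    grad_ok = np.max(np.abs(res.jac)) < 1e-3 * n
    if not (res.success or grad_ok):
        raise ConvergenceError(
            f"ordinal regression did not converge: {res.message}", n_iter=res.nit
        )
    lrt = max(2.0 * (-res.fun - ll_null), 0.0)
    return TestResult("MultiPhen", statistic=lrt, df=float(k),
                      pvalue=float(max(stats.chi2.sf(lrt, k), _PMIN)))


# ---------------------------------------------------------------------------
# registry and per-scenario context
# ---------------------------------------------------------------------------

METHOD_NAMES = ("minP", "TATES", "SHom", "SHet", "MANOVA", "CCA",
                "CombinedPC", "MultiPhen")

_SUMMARY_METHODS = frozenset({"minP", "TATES", "SHom", "SHet"})


@dataclass
class NullContext:
    """Per-correlation-matrix quantities shared across replicates.

    Both the TATES p-value correlation matrix and the S_Het null Gamma fit
    depend only on the trait correlation structure, so a replicate engine
    computes them once per scenario point (from the generating matrix) and
    reuses them for every replicate.
    """

    corr: np.ndarray
    pcorr: np.ndarray | None = None
    shet_null: ShetNull | None = None


def build_context(corr, pcorr_draws: int = 10_000, shet_sims: int = 100_000,
                  seed: int = 1, methods=METHOD_NAMES) -> NullContext:
    """Precompute the cached null quantities for one correlation matrix."""
    corr = np.atleast_2d(np.asarray(corr, dtype=float))
    ctx = NullContext(corr=corr)
    if "TATES" in methods and corr.shape[0] > 1:
        ctx.pcorr = pvalue_correlation(corr, n_draws=pcorr_draws, seed=seed)
    if "SHet" in methods and corr.shape[0] > 1:
        ctx.shet_null = fit_shet_null(corr, n_sims=shet_sims, seed=seed)
    return ctx


def needs_summary(methods) -> bool:
    return any(m in _SUMMARY_METHODS for m in methods)


def run_method(name: str, data: GenoPhenoDataset,
               summary: UnivariateSummary | None = None,
               ctx: NullContext | None = None) -> TestResult:
    """Dispatch one named test on a dataset (summary computed if needed)."""
    if name not in METHOD_NAMES:
        raise ParameterError(f"unknown method {name!r}; choose from {METHOD_NAMES}")
    if name in _SUMMARY_METHODS and summary is None:
        summary = univariate_scan(data)
    if name == "minP":
        return minp_test(summary)
    if name == "TATES":
        return tates_test(summary, pcorr=None if ctx is None else ctx.pcorr)
    if name == "SHom":
        return shom_test(summary)
    if name == "SHet":
        return shet_test(summary, null=None if ctx is None else ctx.shet_null)
    if name == "MANOVA":
        return manova_test(data)
    if name == "CCA":
        return cca_test(data)
    if name == "CombinedPC":
        return combined_pc_test(data)
    return multiphen_test(data)


# ---------------------------------------------------------------------------
# summary-statistic I/O
# ---------------------------------------------------------------------------

def write_summary(summary: UnivariateSummary, path, trait_names=None) -> None:
    """Write per-trait results as TSV (columns: trait, beta, se, z, p)."""
    import pandas as pd

    names = trait_names or [f"P{i + 1}" for i in range(summary.n_traits)]
    pd.DataFrame({"trait": names, "beta": summary.beta, "se": summary.se,
                  "z": summary.z, "p": summary.p}).to_csv(path, sep="\t", index=False)


def read_summary(path, trait_corr) -> UnivariateSummary:
    """Read a summary TSV; the trait correlation matrix is supplied separately."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return UnivariateSummary(
        beta=df["beta"].to_numpy(), se=df["se"].to_numpy(),
        z=df["z"].to_numpy(), p=df["p"].to_numpy(),
        trait_corr=np.atleast_2d(np.asarray(trait_corr, dtype=float)),
    )
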