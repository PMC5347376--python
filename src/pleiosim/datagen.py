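"""Single-SNP multivariate genotype-phenotype simulation.

The generating model relates one biallelic SNP to ``K`` correlated
quantitative traits.  Genotypes ``G in {0, 1, 2}`` count minor alleles and
are drawn under Hardy-Weinberg equilibrium with genotype probabilities
``{p^2, 2pq, q^2}`` (``q`` = minor allele frequency, ``p = 1 - q``).
Phenotypes follow the additive model

    Y_k = f(v_k) * G + eps_k,      eps ~ MVN(0, c)

where ``v_k`` is the fraction of phenotypic variance explained by the SNP
on trait ``k`` and ``c`` is the residual correlation matrix with unit
diagonal.  The per-allele coefficient is

    f(v) = sqrt( ve / (2 p q) ),   ve = v / (1 - v)

so that, with residual variance 1 and Var(G) = 2pq, the SNP explains
exactly ``v`` of the variance of ``Y_k``.  Because effect sizes in GWAS
are tiny, ``c`` is also approximately the observed phenotypic correlation
matrix.

The module additionally supports mediated (indirect) effects on a trait
pair and case/control traits generated by a liability-threshold model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from ._exceptions import MatrixStructureError, ParameterError

__all__ = [
    "PSD_TOL",
    "GenoPhenoDataset",
    "IndirectEffectSpec",
    "LiabilityConfig",
    "hwe_genotype_probs",
    "sample_genotypes",
    "transformed_variance",
    "variance_to_coefficient",
    "coefficient_to_variance",
    "validate_effect_vector",
    "validate_correlation",
    "is_positive_definite",
    "equicorrelation",
    "simulate_dataset",
    "simulate_indirect",
    "liability_dichotomize",
    "dichotomize_dataset",
    "write_dataset",
]

#: smallest eigenvalue above which a correlation matrix counts as positive
#: definite; matrices failing this are rejected, never repaired
PSD_TOL = 1e-8


# ---------------------------------------------------------------------------
# parameter validation
# ---------------------------------------------------------------------------

def _check_maf(maf: float) -> float:
    maf = float(maf)
    if not (0.0 < maf <= 0.5) or not np.isfinite(maf):
        raise ParameterError(f"minor allele frequency must be in (0, 0.5], got {maf}")
    return maf


def validate_effect_vector(v) -> np.ndarray:
    """Validate a vector of per-trait variance fractions.

    Each entry is the fraction of a trait's variance explained by the SNP
    and must be finite, ``>= 0`` and ``< 1``.
    """
    v = np.atleast_1d(np.asarray(v, dtype=float))
    if v.ndim != 1 or v.size < 1:
        raise ParameterError("effect vector must be one-dimensional and non-empty")
    if not np.all(np.isfinite(v)) or np.any(v < 0) or np.any(v >= 1):
        raise ParameterError("variance fractions must be finite and in [0, 1)")
    return v


def validate_correlation(c, tol: float = PSD_TOL) -> np.ndarray:
    """Validate a correlation matrix: symmetric, unit diagonal, PSD.

    Raises
    ------
    MatrixStructureError
        If the matrix is non-symmetric, has a non-unit diagonal,
        off-diagonals outside [-1, 1], or an eigenvalue below ``-tol``.
    """
    c = np.atleast_2d(np.asarray(c, dtype=float))
    if c.shape[0] != c.shape[1]:
        raise MatrixStructureError(f"correlation matrix must be square, got {c.shape}")
    if not np.allclose(c, c.T, atol=1e-10):
        raise MatrixStructureError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(c), 1.0, atol=1e-10):
        raise MatrixStructureError("correlation matrix must have unit diagonal")
    if np.any(np.abs(c) > 1 + 1e-10):
        raise MatrixStructureError("correlations must lie in [-1, 1]")
    if np.linalg.eigvalsh(c)[0] < -tol:
        raise MatrixStructureError("correlation matrix is not positive semi-definite")
    return c


def is_positive_definite(c, tol: float = PSD_TOL) -> bool:
    """True iff the smallest eigenvalue of symmetric ``c`` exceeds ``tol``."""
    c = np.atleast_2d(np.asarray(c, dtype=float))
    if c.shape[0] != c.shape[1] or not np.allclose(c, c.T, atol=1e-10):
        raise MatrixStructureError("input must be a symmetric square matrix")
    return bool(np.linalg.eigvalsh(c)[0] > tol)


def equicorrelation(k: int, r: float) -> np.ndarray:
    """K x K matrix with unit diagonal and constant off-diagonal ``r``."""
    c = np.full((k, k), float(r))
    np.fill_diagonal(c, 1.0)
    return c


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def hwe_genotype_probs(maf: float) -> tuple[float, float, float]:
    """Hardy-Weinberg genotype probabilities ``(p^2, 2pq, q^2)``.

    ``q`` is the minor allele frequency and genotypes count minor alleles,
    so the first entry is the major-homozygote probability.
    """
    q = _check_maf(maf)
    p = 1.0 - q
    return (p * p, 2.0 * p * q, q * q)


def sample_genotypes(n: int, maf: float, seed=None) -> np.ndarray:
    """Draw ``n`` genotypes from the HWE trinomial.

    ``seed`` may be an int or a ``numpy.random.Generator``; a fixed seed
    gives a bit-identical vector.
    """
    if n < 1:
        raise ParameterError(f"sample size must be >= 1, got {n}")
    probs = hwe_genotype_probs(maf)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    u = rng.random(int(n))
    cuts = np.cumsum(probs[:2])
    return np.searchsorted(cuts, u).astype(np.int8)


# ---------------------------------------------------------------------------
# variance <-> coefficient transforms
# ---------------------------------------------------------------------------

def transformed_variance(v: float) -> float:
    """Variance explained rescaled against unit residual variance.

    ``ve = v / (1 - v)``: a SNP explaining 0.5% of phenotypic variance has
    ``ve = 0.005 / 0.995 = 0.005025`` since the residual error variance is 1.
    """
    v = float(v)
    if not (0.0 <= v < 1.0) or not np.isfinite(v):
        raise ParameterError(f"variance fraction must be in [0, 1), got {v}")
    return v / (1.0 - v)


def variance_to_coefficient(v: float, maf: float) -> float:
    """Per-allele regression coefficient giving variance explained ``v``.

    Under the additive model with Var(G) = 2pq and residual variance 1,
    ``f(v) = sqrt(ve / (2 p q))`` with ``ve = v / (1 - v)``.  ``f(0) = 0``
    and ``f`` is strictly increasing in ``v``.
    """
    q = _check_maf(maf)
    ve = transformed_variance(v)
    return float(np.sqrt(ve / (2.0 * (1.0 - q) * q)))


def coefficient_to_variance(beta: float, maf: float) -> float:
    """Inverse of :func:`variance_to_coefficient` (sign of ``beta`` ignored)."""
    q = _check_maf(maf)
    ve = float(beta) ** 2 * 2.0 * (1.0 - q) * q
    return ve / (1.0 + ve)


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------

@dataclass
class GenoPhenoDataset:
    """One simulated cohort: ``n`` genotypes plus an ``n x K`` trait matrix.

    ``binary`` flags the columns that hold case/control status (0/1) after
    liability-threshold dichotomization; quantitative columns are on the
    unit-residual-variance scale of the generating model.  The generating
    parameters travel with the data for provenance.
    """

    genotypes: np.ndarray          # (n,) int8, minor-allele counts
    phenotypes: np.ndarray         # (n, K) float, or 0/1 in binary columns
    maf: float
    effects: np.ndarray            # per-trait variance fractions v
    correlation: np.ndarray        # residual correlation matrix c
    seed: int | None = None
    binary: np.ndarray = field(default=None)  # (K,) bool mask

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes)
        self.phenotypes = np.atleast_2d(np.asarray(self.phenotypes, dtype=float))
        if self.phenotypes.shape[0] != self.genotypes.shape[0]:
            raise ParameterError("genotype and phenotype row counts disagree")
        if self.binary is None:
            self.binary = np.zeros(self.n_traits, dtype=bool)
        else:
            self.binary = np.asarray(self.binary, dtype=bool)
        self.effects = np.asarray(self.effects, dtype=float)
        if self.effects.shape[0] != self.n_traits:
            raise ParameterError("effect vector length does not match trait count")

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_traits(self) -> int:
        return self.phenotypes.shape[1]


def _mvn_factor(c: np.ndarray) -> np.ndarray:
    """Square root of a PSD matrix via eigendecomposition (handles singular c)."""
    w, vec = np.linalg.eigh(c)
    w = np.clip(w, 0.0, None)
    return vec * np.sqrt(w)


def simulate_dataset(v, c, n: int, maf: float = 0.3, seed=None) -> GenoPhenoDataset:
    """Simulate genotypes and ``K`` correlated quantitative traits.

    Parameters
    ----------
    v : array-like of shape (K,)
        Fraction of each trait's variance explained by the SNP.
    c : array-like of shape (K, K)
        Residual correlation matrix (unit diagonal, PSD).
    n : int
        Number of individuals.
    maf : float
        Minor allele frequency in (0, 0.5].
    seed : int or Generator, optional
        Source of randomness; a fixed int gives bit-identical output.
    """
    v = validate_effect_vector(v)
    c = validate_correlation(c)
    if c.shape[0] != v.shape[0]:
        raise ParameterError(
            f"effect vector length {v.shape[0]} does not match correlation "
            f"dimension {c.shape[0]}"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    g = sample_genotypes(n, maf, rng)
    coefs = np.array([variance_to_coefficient(vk, maf) for vk in v])
    eps = rng.standard_normal((int(n), v.shape[0])) @ _mvn_factor(c).T
    y = g[:, None] * coefs[None, :] + eps
    return GenoPhenoDataset(
        genotypes=g, phenotypes=y, maf=float(maf), effects=v, correlation=c,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
    )


# ---------------------------------------------------------------------------
# indirect (mediated) effects
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IndirectEffectSpec:
    """Mediated effect across a trait pair.

    The SNP explains ``v`` of the variance of trait 1, and trait 1 in turn
    explains ``v_prime`` of the variance of trait 2; the SNP touches trait 2
    only through that path.  ``residual_corr`` correlates the two residual
    terms beyond the mediated path (default 0).
    """

    v: float
    v_prime: float
    residual_corr: float = 0.0

    def __post_init__(self):
        for name in ("v", "v_prime"):
            x = getattr(self, name)
            if not (0.0 <= x < 1.0):
                raise ParameterError(f"{name} must be in [0, 1), got {x}")
        if not (-1.0 <= self.residual_corr <= 1.0):
            raise ParameterError("residual_corr must be in [-1, 1]")


def simulate_indirect(spec: IndirectEffectSpec, n: int, maf: float = 0.3,
                      seed=None) -> GenoPhenoDataset:
    """Simulate a trait pair where the SNP effect on trait 2 is mediated.

        Y1 = f(v) G + eps1
        Y2 = g(v') Y1 + eps2

    ``g(v')`` is the coefficient under which Y1 explains ``v'`` of the
    variance of Y2; it uses the theoretical Var(Y1) = 1 + f(v)^2 * 2pq, so
    the variance of Y2 attributable to the SNP is exactly ``v * v'``.
    """
    if not isinstance(spec, IndirectEffectSpec):
        spec = IndirectEffectSpec(*spec)
    q = _check_maf(maf)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    g = sample_genotypes(n, maf, rng)
    f_coef = variance_to_coefficient(spec.v, maf)
    var_y1 = 1.0 + f_coef**2 * 2.0 * (1.0 - q) * q
    # analogue of f(v): predictor is Y1 instead of G
    g_coef = float(np.sqrt(transformed_variance(spec.v_prime) / var_y1))
    c = equicorrelation(2, spec.residual_corr)
    eps = rng.standard_normal((int(n), 2)) @ _mvn_factor(c).T
    y1 = f_coef * g + eps[:, 0]
    y2 = g_coef * y1 + eps[:, 1]
    return GenoPhenoDataset(
        genotypes=g, phenotypes=np.column_stack([y1, y2]), maf=float(maf),
        effects=np.array([spec.v, spec.v * spec.v_prime]), correlation=c,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
    )


# ---------------------------------------------------------------------------
# liability-threshold case/control model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LiabilityConfig:
    """Which traits to dichotomize and at what disease prevalence.

    ``prevalence[k]`` applies to the k-th masked trait if ``mask`` is given,
    otherwise one prevalence per trait.  Each prevalence must lie strictly
    inside (0, 1).
    """

    prevalence: tuple
    mask: tuple | None = None

    def __post_init__(self):
        prev = np.atleast_1d(np.asarray(self.prevalence, dtype=float))
        if np.any(prev <= 0.0) or np.any(prev >= 1.0):
            raise ParameterError("each prevalence must lie strictly in (0, 1)")
        object.__setattr__(self, "prevalence", tuple(prev.tolist()))
        if self.mask is not None:
            object.__setattr__(self, "mask", tuple(bool(m) for m in self.mask))


def liability_dichotomize(y: np.ndarray, config: LiabilityConfig,
                          loc=0.0, scale=1.0) -> np.ndarray:
    """Threshold continuous liabilities into case/control status.

    Column ``k`` becomes 1 (case) where the liability exceeds the upper
    ``prevalence[k]`` quantile of its generating normal ``N(loc, scale^2)``.
    ``loc``/``scale`` may be scalars or per-column vectors; defaults assume
    standard-normal marginals.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    mask = np.ones(y.shape[1], dtype=bool) if config.mask is None \
        else np.asarray(config.mask, dtype=bool)
    prev = np.asarray(config.prevalence, dtype=float)
    if prev.size != mask.sum():
        raise ParameterError("one prevalence required per dichotomized trait")
    loc = np.broadcast_to(np.asarray(loc, dtype=float), (y.shape[1],))
    scale = np.broadcast_to(np.asarray(scale, dtype=float), (y.shape[1],))
    out = y.copy()
    thresholds = loc[mask] + scale[mask] * stats.norm.isf(prev)
    out[:, mask] = (y[:, mask] > thresholds[None, :]).astype(float)
    return out


def dichotomize_dataset(data: GenoPhenoDataset, config: LiabilityConfig) -> GenoPhenoDataset:
    """Apply the liability threshold to a simulated dataset.

    Thresholds come from the theoretical marginal of each simulated trait
    (normal with mean f(v)*2q*p... strictly, mean f(v)*E[G] and variance
    1 + f(v)^2*2pq), so the expected case fraction equals the configured
    prevalence without reference to the realized sample.
    """
    q = data.maf
    coefs = np.array([variance_to_coefficient(vk, q) for vk in data.effects])
    mean = coefs * 2.0 * q                      # E[G] = 2q under HWE
    sd = np.sqrt(1.0 + coefs**2 * 2.0 * (1.0 - q) * q)
    y = liability_dichotomize(data.phenotypes, config, loc=mean, scale=sd)
    mask = np.ones(data.n_traits, dtype=bool) if config.mask is None \
        else np.asarray(config.mask, dtype=bool)
    binary = data.binary | mask
    return replace(data, phenotypes=y, binary=binary)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def write_dataset(data: GenoPhenoDataset, path, plink_binary_coding: bool = True) -> None:
    """Write a dataset as whitespace-delimited text with a header.

    Columns: FID IID G P1..PK.  Binary traits are coded 1/2
    (control/case) when ``plink_binary_coding`` is true, matching PLINK
    phenotype-file conventions; 0/1 otherwise.
    """
    import pandas as pd

    y = data.phenotypes.copy()
    if plink_binary_coding and data.binary.any():
        y[:, data.binary] = y[:, data.binary] + 1.0
    cols = {
        "FID": np.arange(1, data.n + 1),
        "IID": np.arange(1, data.n + 1),
        "G": data.genotypes.astype(int),
    }
    for k in range(data.n_traits):
        col = y[:, k]
        cols[f"P{k + 1}"] = col.astype(int) if data.binary[k] else col
    pd.DataFrame(cols).to_csv(path, sep=" ", index=False)
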