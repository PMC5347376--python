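"""Scenario families exploring the genetic-effect / trait-correlation space.

Four families of (effect vector, correlation matrix) combinations cover the
model space systematically:

* **S1** — structured grid: a canonical library of effect vectors crossed
  with equicorrelation matrices over r = -0.9 .. 0.9 in steps of 0.1
  (non-positive-definite grid points are dropped).
* **S2** — effects and pairwise correlations sampled uniformly, with
  rejection until the correlation matrix is positive definite.
* **S3** — correlations chosen to reflect the effect pattern: 0.6 for a
  trait pair with equal effects, 0.2 for unequal nonzero effects, 0.05
  when exactly one of the pair is affected.
* **S4a** — pairwise correlations drawn i.i.d. from a user-supplied
  Gaussian mixture (e.g. fitted to a real cohort's trait correlations),
  rejecting non-PD matrices.
* **S4b** — effect vectors derived from published per-SNP regression
  coefficients, rescaled so the largest per-SNP effect explains a target
  variance fraction while preserving relative effect sizes.

For two traits the canonical effect vectors are v1 = (0.5%, 0.5%),
v2 = (0.5%, 0.1%), v3 = (0.5%, 0); for K >= 4 traits (K divisible by 4)
ten vectors assign one of {0.5%, 0.1%, 0} to each quarter of the traits.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._exceptions import MatrixStructureError, ParameterError, SamplingError
from .datagen import (
    PSD_TOL,
    equicorrelation,
    is_positive_definite,
    validate_effect_vector,
    variance_to_coefficient,
    coefficient_to_variance,
)

__all__ = [
    "TWO_TRAIT_VECTORS",
    "QUARTER_VALUES",
    "EffectVectorLibrary",
    "S1Point",
    "BetaTable",
    "CorrelationMixture",
    "effect_vector_library",
    "table2_vectors",
    "s1_grid",
    "s2_sample",
    "s3_correlations",
    "s4a_sample",
    "s4b_transform",
    "cap_snps_per_trait",
    "enumerate_trait_subsets",
    "read_beta_table",
]

# canonical per-quarter variance fractions for K >= 4 (rows v1..v10)
QUARTER_VALUES: dict[str, tuple[float, float, float, float]] = {
    "v1": (0.005, 0.005, 0.005, 0.005),
    "v2": (0.005, 0.005, 0.005, 0.0),
    "v3": (0.005, 0.005, 0.0, 0.0),
    "v4": (0.005, 0.0, 0.0, 0.0),
    "v5": (0.005, 0.005, 0.005, 0.001),
    "v6": (0.005, 0.005, 0.001, 0.001),
    "v7": (0.005, 0.001, 0.001, 0.001),
    "v8": (0.005, 0.005, 0.001, 0.0),
    "v9": (0.005, 0.001, 0.001, 0.0),
    "v10": (0.005, 0.001, 0.0, 0.0),
}

# the three qualitatively different vectors for a trait pair
TWO_TRAIT_VECTORS: dict[str, tuple[float, float]] = {
    "v1": (0.005, 0.005),
    "v2": (0.005, 0.001),
    "v3": (0.005, 0.0),
}


@dataclass(frozen=True)
class EffectVectorLibrary:
    """Ordered, named effect vectors for a given trait count."""

    k: int
    vectors: dict  # name -> np.ndarray of variance fractions

    def __iter__(self):
        return iter(self.vectors.items())

    def __getitem__(self, name: str) -> np.ndarray:
        return self.vectors[name]


def table2_vectors(k: int) -> EffectVectorLibrary:
    """The ten canonical effect vectors for ``k >= 4`` traits.

    Each vector assigns its four quarter-values to consecutive blocks of
    ``k/4`` traits, e.g. for k = 8 the vector v5 puts 0.5% on six traits
    and 0.1% on two.
    """
    if k < 4 or k % 4 != 0:
        raise ParameterError(f"quarter construction requires K divisible by 4, got {k}")
    block = k // 4
    vectors = {
        name: np.repeat(np.asarray(quarters, dtype=float), block)
        for name, quarters in QUARTER_VALUES.items()
    }
    return EffectVectorLibrary(k=k, vectors=vectors)


def effect_vector_library(k: int) -> EffectVectorLibrary:
    """Canonical effect vectors: v1-v3 for two traits, v1-v10 for K >= 4."""
    if k == 2:
        vectors = {n: np.asarray(v, dtype=float) for n, v in TWO_TRAIT_VECTORS.items()}
        return EffectVectorLibrary(k=2, vectors=vectors)
    return table2_vectors(k)


# ---------------------------------------------------------------------------
# S1: structured grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class S1Point:
    """One grid point: a named effect vector with an equicorrelation matrix."""

    vector_name: str
    r: float
    v: np.ndarray
    c: np.ndarray

    @property
    def point_id(self) -> str:
        return f"{self.vector_name}@r={self.r:+.1f}"


def correlation_grid(r_min: float = -0.9, r_max: float = 0.9,
                     step: float = 0.1) -> np.ndarray:
    """Inclusive grid of correlations, robust to floating-point drift."""
    if step <= 0:
        raise ParameterError(f"grid step must be positive, got {step}")
    n_steps = int(round((r_max - r_min) / step))
    return np.round(r_min + step * np.arange(n_steps + 1), 10)


def s1_grid(k: int, r_min: float = -0.9, r_max: float = 0.9, step: float = 0.1,
            vectors: EffectVectorLibrary | None = None) -> list[S1Point]:
    """Cross the canonical effect-vector library with the correlation grid.

    Grid points whose equicorrelation matrix is not positive definite are
    silently dropped: for K traits the smallest eigenvalue is
    ``1 + (K-1) r``, so e.g. for K = 4 correlations below -1/3 vanish and
    the grid starts at -0.3.
    """
    if vectors is None:
        vectors = effect_vector_library(k)
    points = []
    for r in correlation_grid(r_min, r_max, step):
        c = equicorrelation(k, r)
        if not is_positive_definite(c):
            continue
        for name, v in vectors:
            points.append(S1Point(vector_name=name, r=float(r), v=v, c=c))
    return points


# ---------------------------------------------------------------------------
# S2: uniform sampling
# ---------------------------------------------------------------------------

def _fill_offdiagonal(k: int, values: np.ndarray) -> np.ndarray:
    c = np.eye(k)
    iu = np.triu_indices(k, 1)
    c[iu] = values
    c[(iu[1], iu[0])] = values
    return c


def s2_sample(k: int, seed=None, v_max: float = 0.005,
              max_tries: int = 100_000) -> tuple[np.ndarray, np.ndarray]:
    """Sample an effect vector and a PD correlation matrix uniformly.

    Effects are uniform on [0, ``v_max``] (default 0-0.5% variance
    explained); pairwise correlations are uniform on (-1, 1), rejection
    sampled until the matrix is positive definite.
    """
    if k < 2:
        raise ParameterError("at least two traits required")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    v = rng.uniform(0.0, v_max, size=k)
    n_pairs = k * (k - 1) // 2
    for _ in range(int(max_tries)):
        c = _fill_offdiagonal(k, rng.uniform(-1.0, 1.0, size=n_pairs))
        if is_positive_definite(c):
            return v, c
    raise SamplingError(
        f"no positive-definite correlation matrix in {max_tries} tries (K={k})"
    )


# ---------------------------------------------------------------------------
# S3: correlations reflecting effects
# ---------------------------------------------------------------------------

def s3_correlations(v, equal: float = 0.6, different: float = 0.2,
                    single: float = 0.05, both_zero: float | None = None) -> np.ndarray:
    """Correlation matrix whose entries reflect the effect pattern.

    For each trait pair: ``equal`` (0.6) when both effects match,
    ``different`` (0.2) when both are nonzero but unequal, and ``single``
    (0.05) when exactly one trait is affected.  Pairs where neither trait
    is affected have equal (zero) effects and take ``both_zero``, which
    defaults to ``equal``.

    Raises
    ------
    MatrixStructureError
        If the resulting matrix is not positive definite (surfaced, never
        silently repaired).
    """
    v = validate_effect_vector(v)
    if both_zero is None:
        both_zero = equal
    k = v.shape[0]
    c = np.eye(k)
    for s, t in itertools.combinations(range(k), 2):
        if v[s] == 0.0 and v[t] == 0.0:
            r = both_zero
        elif v[s] == 0.0 or v[t] == 0.0:
            r = single
        elif v[s] == v[t]:
            r = equal
        else:
            r = different
        c[s, t] = c[t, s] = r
    if not is_positive_definite(c):
        raise MatrixStructureError("effect-reflecting correlation matrix is not PD")
    return c


# ---------------------------------------------------------------------------
# S4a: mixture-sampled correlations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationMixture:
    """Univariate Gaussian mixture over pairwise trait correlations.

    Typically fitted to the observed correlations of a real cohort; the
    fitted parameters are supplied by the user.
    """

    weights: tuple
    means: tuple
    sds: tuple

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        m = np.asarray(self.means, dtype=float)
        s = np.asarray(self.sds, dtype=float)
        if not (w.shape == m.shape == s.shape) or w.ndim != 1:
            raise ParameterError("weights, means and sds must have equal length")
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ParameterError("mixture weights must be non-negative and sum to 1")
        if np.any(s <= 0):
            raise ParameterError("mixture standard deviations must be positive")
        object.__setattr__(self, "weights", tuple(w.tolist()))
        object.__setattr__(self, "means", tuple(m.tolist()))
        object.__setattr__(self, "sds", tuple(s.tolist()))

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        """Draw correlations from the mixture truncated to (-1, 1)."""
        w = np.asarray(self.weights)
        m = np.asarray(self.means)
        s = np.asarray(self.sds)
        out = np.empty(size)
        todo = np.arange(size)
        while todo.size:                       # resample out-of-range draws
            comp = rng.choice(w.size, size=todo.size, p=w)
            draw = rng.normal(m[comp], s[comp])
            ok = np.abs(draw) < 1.0
            out[todo[ok]] = draw[ok]
            todo = todo[~ok]
        return out


def s4a_sample(k: int, mixture: CorrelationMixture, seed=None,
               max_tries: int = 100_000) -> np.ndarray:
    """Sample a PD correlation matrix with mixture-distributed off-diagonals."""
    if k < 2:
        raise ParameterError("at least two traits required")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_pairs = k * (k - 1) // 2
    for _ in range(int(max_tries)):
        c = _fill_offdiagonal(k, mixture.sample(n_pairs, rng))
        if is_positive_definite(c):
            return c
    raise SamplingError(
        f"no positive-definite correlation matrix in {max_tries} tries (K={k})"
    )


# ---------------------------------------------------------------------------
# S4b: effects from published GWAS coefficients
# ---------------------------------------------------------------------------

@dataclass
class BetaTable:
    """Published per-SNP, per-trait regression coefficients.

    ``betas`` has one row per SNP and one column per trait (trait units per
    allele).  ``index_trait`` names the trait whose GWAS reported the SNP;
    ``maf`` is optional per-SNP allele frequency.
    """

    betas: pd.DataFrame                       # index = SNP ids
    index_trait: pd.Series                    # per SNP
    maf: pd.Series | None = None

    def __post_init__(self):
        if (self.betas.abs().sum(axis=1) == 0).any():
            raise ParameterError("every SNP row must have at least one nonzero beta")

    @property
    def traits(self) -> list[str]:
        return list(self.betas.columns)

    def __len__(self) -> int:
        return len(self.betas)


def read_beta_table(path) -> BetaTable:
    """Read a tab-separated beta table.

    Expected columns: ``snp``, ``index_trait``, optional ``maf``, then one
    column per trait.
    """
    df = pd.read_csv(path, sep="\t")
    df = df.set_index("snp")
    index_trait = df.pop("index_trait")
    maf = df.pop("maf") if "maf" in df.columns else None
    return BetaTable(betas=df.astype(float), index_trait=index_trait, maf=maf)


def write_beta_table(table: BetaTable, path) -> None:
    df = table.betas.copy()
    df.insert(0, "index_trait", table.index_trait)
    if table.maf is not None:
        df.insert(1, "maf", table.maf)
    df.index.name = "snp"
    df.to_csv(path, sep="\t")


def cap_snps_per_trait(table: BetaTable, cap: int = 20) -> BetaTable:
    """Retain at most ``cap`` SNPs per index trait.

    Keeps the SNPs with the largest absolute coefficient on their index
    trait; ties break deterministically by row order.  Prevents bias toward
    traits with many published associations.
    """
    keep = []
    for trait, group in table.index_trait.groupby(table.index_trait, sort=False):
        snps = group.index
        if len(snps) <= cap:
            keep.extend(snps)
            continue
        strength = table.betas.loc[snps, trait].abs()
        # stable sort so equal strengths keep their original order
        order = strength.sort_values(ascending=False, kind="stable").index[:cap]
        keep.extend([s for s in snps if s in set(order)])
    keep = [s for s in table.betas.index if s in set(keep)]
    return BetaTable(
        betas=table.betas.loc[keep],
        index_trait=table.index_trait.loc[keep],
        maf=None if table.maf is None else table.maf.loc[keep],
    )


def s4b_transform(table: BetaTable, target_max_v: float = 0.005,
                  maf: float = 0.3) -> pd.DataFrame:
    """Rescale published betas into simulation effect vectors.

    Each SNP row is multiplied by ``d_i = beta*(target_max_v, maf) /
    max_k |beta_ik|`` where ``beta*`` is the coefficient explaining
    ``target_max_v`` of phenotypic variance.  The scaled coefficients are
    converted back to variance fractions, so the per-row maximum equals
    ``target_max_v`` exactly and relative coefficient sizes are preserved.
    When the table carries per-SNP allele frequencies they are used in
    place of ``maf``.

    Returns a DataFrame of variance fractions (rows = SNPs, columns =
    traits).
    """
    if not (0.0 < target_max_v < 1.0):
        raise ParameterError(f"target_max_v must be in (0, 1), got {target_max_v}")
    rows = {}
    for snp, beta in table.betas.iterrows():
        snp_maf = maf if table.maf is None else float(table.maf.loc[snp])
        b = beta.to_numpy(dtype=float)
        b_max = np.abs(b).max()
        d = variance_to_coefficient(target_max_v, snp_maf) / b_max
        rows[snp] = [coefficient_to_variance(bi * d, snp_maf) for bi in b]
    return pd.DataFrame.from_dict(rows, orient="index", columns=table.traits)


def enumerate_trait_subsets(k_total: int, k_sub: int) -> list[tuple[int, ...]]:
    """All C(k_total, k_sub) trait-index subsets in lexicographic order."""
    if not (1 <= k_sub <= k_total):
        raise ParameterError("subset size must satisfy 1 <= k_sub <= k_total")
    return list(itertools.combinations(range(k_total), k_sub))
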