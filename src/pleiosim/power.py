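"""Replicate engine: Monte-Carlo power and type-I error estimation.

For each scenario point (an effect vector paired with a correlation
matrix) the engine simulates R independent cohorts, applies the selected
association tests, and reports the proportion of replicates significant
at the configured threshold together with a Wilson 95% interval.  Power
at the conventional genome-wide threshold (P < 5e-8) with 10,000
replicates of 5,000 individuals is the reference protocol; desk-scale
runs use laxer thresholds and fewer replicates.

Replicate r always uses seed ``base_seed + r``, so results are identical
for a fixed specification regardless of execution order or worker count,
and scenario points share common random numbers.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from ._exceptions import ConfigError, ParameterError, PleiosimError
from . import scenarios as _scen
from .datagen import simulate_dataset, validate_correlation, validate_effect_vector
from .methods import (
    METHOD_NAMES,
    build_context,
    needs_summary,
    run_method,
    univariate_scan,
)

__all__ = [
    "ScenarioPoint",
    "ScenarioSpec",
    "PowerEstimate",
    "BenchmarkResult",
    "build_points",
    "run_replicates",
    "estimate_type1",
    "power_curve",
    "summarize",
    "read_results",
]

#: genome-wide significance, the reference threshold
GENOME_WIDE_ALPHA = 5e-8


@dataclass(frozen=True)
class ScenarioPoint:
    """One (effect vector, correlation matrix) combination to benchmark."""

    point_id: str
    v: np.ndarray
    c: np.ndarray
    r: float | None = None      # common correlation, when the point is equicorrelated


@dataclass(frozen=True)
class ScenarioSpec:
    """Complete description of one benchmarking run.

    ``scenario`` selects the family (S1, S2, S3, S4a, S4b or "custom" with
    explicit points); family-specific parameters live in ``params``:
    grid bounds/step and vector names for S1/S3, draw count for S2/S4a,
    mixture parameters for S4a, beta-table path for S4b.
    """

    scenario: str
    k: int
    n: int = 5_000
    maf: float = 0.3
    n_replicates: int = 10_000
    alpha: float = GENOME_WIDE_ALPHA
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.scenario not in ("S1", "S2", "S3", "S4a", "S4b", "custom"):
            raise ConfigError(f"unknown scenario {self.scenario!r}")
        if self.n < 1 or self.n_replicates < 1:
            raise ConfigError("n and n_replicates must be positive")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError("alpha must be in (0, 1)")
        if self.seed < 0:
            raise ConfigError("seed must be non-negative")


@dataclass(frozen=True)
class PowerEstimate:
    """Power (or type-I error) of one method at one scenario point."""

    method: str
    point_id: str
    n_replicates: int
    n_significant: int
    n_failed: int
    alpha: float
    r: float | None = None

    @property
    def power(self) -> float:
        n_ok = self.n_replicates - self.n_failed
        return self.n_significant / n_ok if n_ok else float("nan")

    @property
    def ci(self) -> tuple[float, float]:
        """Wilson 95% interval for the rejection proportion."""
        n_ok = self.n_replicates - self.n_failed
        if n_ok == 0:
            return (float("nan"), float("nan"))
        lo, hi = proportion_confint(self.n_significant, n_ok, alpha=0.05,
                                    method="wilson")
        return (float(lo), float(hi))


@dataclass
class BenchmarkResult:
    """All estimates from one run, with provenance."""

    spec: ScenarioSpec
    estimates: list      # of PowerEstimate
    seed: int
    runtime_s: float = 0.0
    failures: dict = field(default_factory=dict)   # (method, point_id) -> count

    def get(self, method: str, point_id: str) -> PowerEstimate:
        for est in self.estimates:
            if est.method == method and est.point_id == point_id:
                return est
        raise KeyError((method, point_id))


# ---------------------------------------------------------------------------
# scenario points
# ---------------------------------------------------------------------------

def build_points(spec: ScenarioSpec) -> list[ScenarioPoint]:
    """Expand a specification into concrete scenario points."""
    p = dict(spec.params)
    if spec.scenario == "custom":
        return list(p["points"])
    if spec.scenario == "S1":
        grid = _scen.s1_grid(spec.k, p.get("r_min", -0.9), p.get("r_max", 0.9),
                             p.get("step", 0.1))
        names = p.get("vectors")
        if names is not None:
            grid = [pt for pt in grid if pt.vector_name in set(names)]
        return [ScenarioPoint(pt.point_id, pt.v, pt.c, r=pt.r) for pt in grid]
    if spec.scenario == "S2":
        n_draws = int(p.get("n_points", 1))
        out = []
        for i in range(n_draws):
            v, c = _scen.s2_sample(spec.k, seed=spec.seed + 900_000 + i)
            out.append(ScenarioPoint(f"S2#{i}", v, c))
        return out
    if spec.scenario == "S3":
        lib = _scen.effect_vector_library(spec.k)
        names = p.get("vectors", list(lib.vectors))
        return [ScenarioPoint(f"S3:{name}", lib[name], _scen.s3_correlations(lib[name]))
                for name in names]
    if spec.scenario == "S4a":
        mix = p["mixture"]
        if not isinstance(mix, _scen.CorrelationMixture):
            mix = _scen.CorrelationMixture(**mix)
        lib = _scen.effect_vector_library(spec.k)
        names = p.get("vectors", list(lib.vectors))
        out = []
        for i, name in enumerate(names):
            c = _scen.s4a_sample(spec.k, mix, seed=spec.seed + 800_000 + i)
            out.append(ScenarioPoint(f"S4a:{name}", lib[name], c))
        return out
    # S4b: effect vectors from a beta table; correlations supplied or identity
    table = p.get("beta_table")
    if table is None:
        table = _scen.read_beta_table(p["beta_table_path"])
    table = _scen.cap_snps_per_trait(table, p.get("cap", 20))
    effects = _scen.s4b_transform(table, p.get("target_max_v", 0.005), spec.maf)
    corr = p.get("correlation")
    subset = p.get("subset")
    out = []
    for snp, row in effects.iterrows():
        v = row.to_numpy()
        c = np.eye(v.size) if corr is None else np.asarray(corr, dtype=float)
        if subset is not None:
            v = v[list(subset)]
            c = c[np.ix_(list(subset), list(subset))]
        out.append(ScenarioPoint(f"S4b:{snp}", v, c))
    return out


# ---------------------------------------------------------------------------
# engine
# ---------------------------------------------------------------------------

def _replicate_chunk(v, c, n, maf, alpha, methods, seeds, ctx, want_summary):
    """Run one contiguous block of replicates; returns (sig, fail) counts.

    Each replicate's seed is passed in explicitly, so the result depends
    only on the seed list, not on which worker executes the block.
    """
    n_sig = dict.fromkeys(methods, 0)
    n_fail = dict.fromkeys(methods, 0)
    for seed in seeds:
        data = simulate_dataset(v, c, n, maf, seed=seed)
        summary = univariate_scan(data) if want_summary else None
        for m in methods:
            try:
                res = run_method(m, data, summary=summary, ctx=ctx)
            except PleiosimError:
                n_fail[m] += 1
                continue
            if res.pvalue < alpha:
                n_sig[m] += 1
    return n_sig, n_fail


def run_replicates(spec: ScenarioSpec, methods=METHOD_NAMES,
                   points: list[ScenarioPoint] | None = None,
                   progress=None, n_jobs: int = 1) -> BenchmarkResult:
    """Estimate power for each method at each scenario point.

    Per-replicate method failures are recorded and excluded from the
    denominator (never silently dropped); the failure counts travel with
    the result.  ``progress`` may be a callable ``(point_id, i, total)``.
    With ``n_jobs > 1`` replicate blocks run in parallel workers; because
    every replicate seed derives from its index, the result is identical
    for any worker count.
    """
    methods = list(methods)
    unknown = [m for m in methods if m not in METHOD_NAMES]
    if unknown:
        raise ConfigError(f"unknown method(s) {unknown}; choose from {METHOD_NAMES}")
    if points is None:
        points = build_points(spec)
    t0 = time.perf_counter()
    want_summary = needs_summary(methods)
    estimates: list[PowerEstimate] = []
    failures: dict = {}
    for ip, point in enumerate(points):
        v = validate_effect_vector(point.v)
        c = validate_correlation(point.c)
        ctx = build_context(c, seed=spec.seed + 1, methods=methods)
        seeds = [spec.seed + rep for rep in range(spec.n_replicates)]
        args = (v, c, spec.n, spec.maf, spec.alpha, methods)
        if n_jobs > 1:
            from joblib import Parallel, delayed

            blocks = np.array_split(np.asarray(seeds), n_jobs * 4)
            parts = Parallel(n_jobs=n_jobs)(
                delayed(_replicate_chunk)(*args, list(b), ctx, want_summary)
                for b in blocks if b.size)
        else:
            parts = [_replicate_chunk(*args, seeds, ctx, want_summary)]
        n_sig = dict.fromkeys(methods, 0)
        n_fail = dict.fromkeys(methods, 0)
        for sig, fail in parts:
            for m in methods:
                n_sig[m] += sig[m]
                n_fail[m] += fail[m]
        for m in methods:
            estimates.append(PowerEstimate(
                method=m, point_id=point.point_id,
                n_replicates=spec.n_replicates, n_significant=n_sig[m],
                n_failed=n_fail[m], alpha=spec.alpha, r=point.r,
            ))
            if n_fail[m]:
                failures[(m, point.point_id)] = n_fail[m]
        if progress is not None:
            progress(point.point_id, ip + 1, len(points))
    return BenchmarkResult(spec=spec, estimates=estimates, seed=spec.seed,
                           runtime_s=time.perf_counter() - t0, failures=failures)


def estimate_type1(spec: ScenarioSpec, methods=METHOD_NAMES,
                   alpha: float | None = None,
                   points: list[ScenarioPoint] | None = None,
                   progress=None) -> BenchmarkResult:
    """Rejection rate under the complete null (all effects forced to zero)."""
    if alpha is not None:
        spec = replace(spec, alpha=alpha)
    if points is None:
        points = build_points(spec)
    null_points = [ScenarioPoint(pt.point_id, np.zeros_like(np.asarray(pt.v, dtype=float)),
                                 pt.c, r=pt.r) for pt in points]
    return run_replicates(spec, methods, points=null_points, progress=progress)


def power_curve(result: BenchmarkResult, method: str) -> list[tuple[float, PowerEstimate]]:
    """Power of one method ordered along the correlation grid.

    Only meaningful for S1-style results where each point carries a common
    correlation ``r``.
    """
    series = [(est.r, est) for est in result.estimates
              if est.method == method and est.r is not None]
    if not series:
        raise ConfigError(f"no grid estimates for method {method!r} "
                          "(is this an S1-style result?)")
    return sorted(series, key=lambda t: t[0])


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def summarize(result: BenchmarkResult, wide: bool = False) -> pd.DataFrame:
    """Long-format table of estimates (or a method-by-point power pivot)."""
    if not result.estimates:
        raise ParameterError("empty benchmark result")
    rows = []
    for est in result.estimates:
        lo, hi = est.ci
        rows.append({
            "method": est.method, "point_id": est.point_id, "r": est.r,
            "n": result.spec.n, "n_replicates": est.n_replicates,
            "n_significant": est.n_significant, "n_failed": est.n_failed,
            "power": est.power, "ci_lo": lo, "ci_hi": hi, "alpha": est.alpha,
        })
    df = pd.DataFrame(rows)
    if wide:
        return df.pivot(index="point_id", columns="method", values="power")
    return df


def read_results(path) -> pd.DataFrame:
    """Read a results TSV written by :func:`summarize` + ``to_csv``."""
    return pd.read_csv(path, sep="\t")
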