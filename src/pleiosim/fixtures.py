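"""Deterministic toy fixtures: a synthetic beta table and tiny datasets.

The bundled beta table (``data/toy_betas.tsv``) is a synthetic stand-in
for published GWAS coefficients: 20 SNPs by 12 metabolic-style traits
with a sparse block structure (each SNP loads on its index trait plus a
few neighbours).  It exists so the real-data-informed scenario (S4b) can
be exercised end to end without downloading any GWAS results; users
supply real tables themselves.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import scenarios as _scen
from .datagen import (
    LiabilityConfig,
    dichotomize_dataset,
    equicorrelation,
    simulate_dataset,
    write_dataset,
)

__all__ = ["toy_beta_table", "bundled_beta_table_path", "make_fixtures"]

_TRAITS = ["height", "bmi", "sbp", "dbp", "tg", "hdl", "ldl", "tc",
           "glucose", "insulin", "homa_b", "homa_ir"]


def toy_beta_table(seed: int = 7, n_snps: int = 20) -> _scen.BetaTable:
    """Synthetic per-SNP, per-trait coefficients with known structure.

    Each SNP has a dominant coefficient on its index trait and smaller
    spillover effects on up to three following traits; signs alternate.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    k = len(_TRAITS)
    betas = np.zeros((n_snps, k))
    index_trait = []
    for i in range(n_snps):
        t = i % k
        index_trait.append(_TRAITS[t])
        betas[i, t] = (0.05 + 0.1 * rng.random()) * (-1 if i % 3 == 0 else 1)
        for off in range(1, 1 + int(rng.integers(0, 4))):
            betas[i, (t + off) % k] = betas[i, t] * rng.uniform(0.1, 0.8)
    df = pd.DataFrame(np.round(betas, 6), columns=_TRAITS,
                      index=[f"rs{1000 + i}" for i in range(n_snps)])
    return _scen.BetaTable(
        betas=df,
        index_trait=pd.Series(index_trait, index=df.index),
        maf=pd.Series(np.round(rng.uniform(0.05, 0.5, n_snps), 3), index=df.index),
    )


def bundled_beta_table_path() -> Path:
    """Path of the beta table shipped with the package."""
    return Path(__file__).parent / "data" / "toy_betas.tsv"


def make_fixtures(seed: int = 7, outdir="fixtures") -> dict:
    """Write the toy beta table plus one tiny dataset per scenario family.

    Returns a mapping of fixture name to path.  Byte-stable across runs
    for a fixed seed: every dataset seed is derived from ``seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}

    table = toy_beta_table(seed)
    path = outdir / "toy_betas.tsv"
    _scen.write_beta_table(table, path)
    written["beta_table"] = path

    lib2 = _scen.effect_vector_library(2)

    # S1-style: two traits, equicorrelation 0.5
    ds = simulate_dataset(lib2["v1"], equicorrelation(2, 0.5), n=200, maf=0.3,
                          seed=seed)
    write_dataset(ds, outdir / "s1_pair.txt")
    written["s1_pair"] = outdir / "s1_pair.txt"

    # S2-style: sampled effects and correlations, 4 traits
    v, c = _scen.s2_sample(4, seed=seed)
    write_dataset(simulate_dataset(v, c, n=200, maf=0.3, seed=seed + 1),
                  outdir / "s2_sampled.txt")
    written["s2_sampled"] = outdir / "s2_sampled.txt"

    # S3-style: correlations reflect the v8 pattern on 4 traits
    lib4 = _scen.effect_vector_library(4)
    c3 = _scen.s3_correlations(lib4["v8"])
    write_dataset(simulate_dataset(lib4["v8"], c3, n=200, maf=0.3, seed=seed + 2),
                  outdir / "s3_reflect.txt")
    written["s3_reflect"] = outdir / "s3_reflect.txt"

    # case/control pair under the liability threshold model
    ds_cc = simulate_dataset(lib2["v1"], np.eye(2), n=200, maf=0.3, seed=seed + 3)
    ds_cc = dichotomize_dataset(ds_cc, LiabilityConfig(prevalence=(0.2, 0.2)))
    write_dataset(ds_cc, outdir / "case_control_pair.txt")
    written["case_control"] = outdir / "case_control_pair.txt"

    return written
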