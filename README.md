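# pleiosim

Simulation of multivariate genotype–phenotype data and benchmarking of
multi-trait GWAS methods.

Genome-wide association studies increasingly test one genetic variant
against many correlated phenotypes at once, but the competing
multi-trait tests differ in subtle, scenario-dependent ways.  `pleiosim`
is a simulation framework for exploring exactly that: it generates
single-SNP cohorts with controlled per-trait variance explained and
residual correlation structure, and measures the statistical power and
type-I error of eight frequentist multi-trait association tests by
Monte-Carlo replication.  It is aimed at methodologists benchmarking new
multivariate tests and at study designers asking which existing test to
use for a given trait panel.

## The model

Genotypes `G ∈ {0,1,2}` follow Hardy–Weinberg equilibrium in proportions
`{p², 2pq, q²}` (`q` = minor allele frequency).  Phenotypes follow

    Y_k = f(v_k)·G + ε_k,    ε ~ MVN(0, c),
    f(v) = sqrt(ve / 2pq),   ve = v/(1 − v),

so the SNP explains exactly the fraction `v_k` of trait k's variance and
`c` is (approximately) the phenotypic correlation matrix.  Mediated
effects on a trait pair and liability-threshold case/control traits are
also supported.  Four scenario families (structured grids, uniform
sampling, effect-reflecting correlations, real-data-informed effects)
cover the effect/correlation model space; see `docs/methods.md`.

Implemented tests: min-P, TATES, S_Hom, S_Het (summary-statistic based)
and MANOVA, CCA, Combined-PC, MultiPhen (individual-level).

## Worked example

```python
import pleiosim as ps

data = ps.simulate_dataset([0.005]*4, ps.equicorrelation(4, 0.3),
                           n=5_000, maf=0.3, seed=42)
summary = ps.univariate_scan(data)
for name in ps.METHOD_NAMES:
    res = ps.run_method(name, data, summary=summary)
    print(f"{name:>10s}  p = {res.pvalue:.3e}")
```

prints

```
      minP  p = 3.955e-08
     TATES  p = 4.229e-08
      SHom  p = 3.006e-12
      SHet  p = 4.674e-13
    MANOVA  p = 7.982e-11
       CCA  p = 7.982e-11
CombinedPC  p = 7.170e-11
 MultiPhen  p = 1.256e-10
```

All eight tests detect the (strongly pleiotropic) simulated signal; the
meta-analytic S_Hom/S_Het profit most from four homogeneous effects,
MANOVA and CCA agree to machine precision, and min-P/TATES — which only
correct the best univariate result — trail the joint tests.  The
`examples/` directory contains short narrative scripts for dataset
simulation, testing, power curves and the scenario generators; power
runs are driven either from Python (`pleiosim.power.run_replicates`) or
from the thin CLI:

```bash
pleiosim simulate --k 2 --n 5000 --seed 1 --out cohort.txt
pleiosim benchmark --config config.yaml
```

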