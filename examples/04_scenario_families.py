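"""Tour of the scenario generators: S2, S3 and the real-data route S4b.

Prints one sampled uniform scenario, the correlation matrix that reflects
a mixed effect vector, and the effect vectors obtained by rescaling the
bundled (synthetic) GWAS beta table so each SNP's largest effect explains
exactly 0.5% of variance.
"""

import numpy as np

import pleiosim as ps
from pleiosim.fixtures import bundled_beta_table_path

# S2: uniform effects in [0, 0.5%], uniform correlations rejected to PD
v, c = ps.s2_sample(4, seed=1)
print("S2 sampled effects (% variance):", np.round(100 * v, 3))
print("S2 sampled correlations (PD guaranteed):")
print(np.round(c, 2))

# S3: correlations mirror the effect pattern (0.6 equal / 0.2 unequal / 0.05 single)
v8 = ps.effect_vector_library(4)["v8"]
print("\nS3 effect vector v8 (% variance):", 100 * v8)
print("S3 reflecting correlations:")
print(ps.s3_correlations(v8))

# S4b: published betas -> effect vectors with max 0.5% variance per SNP
table = ps.read_beta_table(bundled_beta_table_path())
table = ps.cap_snps_per_trait(table, cap=20)
effects = ps.s4b_transform(table, target_max_v=0.005, maf=0.3)
print(f"\nS4b: {len(effects)} SNPs x {effects.shape[1]} traits; "
      f"per-SNP max variance fraction = {np.round(effects.max(axis=1), 10).unique()}")
print("first SNP's effect vector (% variance):")
print((100 * effects.iloc[0]).round(4).to_string())
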