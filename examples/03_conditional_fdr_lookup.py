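"""Conditional FDR: 2-D lookup table, per-SNP assignment, power gain.

Builds the conditional-FDR lookup for trait 1 given trait 2, assigns each
SNP its cFDR by bilinear interpolation at its own p-value pair, and compares
the number of declarations (cFDR < 0.01) with the unconditional FDR at the
same threshold.
"""

import numpy as np

from condfdr import SimConfig, simulate_panel, build_lookup, interpolate_fdr
from condfdr.cfdr import uncond_fdr_vector

cfg = SimConfig(n_snps=100_000, seed=3)
t1, t2, _, truth = simulate_panel(cfg)
p1, p2 = t1["P"].to_numpy(), t2["P"].to_numpy()

lookup = build_lookup(p1, p2, trait="trait2")
print(f"lookup grid: {lookup.fdr.shape[0]} x {lookup.fdr.shape[1]} nodes; "
      f"FDR at origin (p1 = p2 = 1): {lookup.fdr[0, 0]:.0f}")

cfdr = interpolate_fdr(lookup, p1, p2)
uncond = uncond_fdr_vector(p1)
nonnull = truth["component"].isin(["t1", "pleio"]).to_numpy()

dec_c, dec_u = cfdr < 0.01, uncond < 0.01
print(f"declared at cFDR < 0.01:        {dec_c.sum():4d} "
      f"({(dec_c & nonnull).sum()} truly associated)")
print(f"declared at uncond. FDR < 0.01: {dec_u.sum():4d} "
      f"({(dec_u & nonnull).sum()} truly associated)")
# conditioning on the pleiotropic trait recovers extra true associations at
# the same nominal FDR threshold -- the power gain the method is built for.
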