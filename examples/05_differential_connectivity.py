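"""Modular differential connectivity on a proteomics-like Braak contrast.

Simulates a protein module whose intra-module correlation drops from 0.6 in
non-AD samples (Braak 0-2) to 0.2 in AD samples (Braak 5-6), then measures
the mean difference in Fisher-z-transformed correlations (case minus
control) with a label-permutation null. Also runs the per-protein t-test
with Storey q-values.
"""
import numpy as np

from olnet import GeneModule, feature_ttest_qvalue, modular_differential_connectivity, simulate_proteomics

module = GeneModule("yellow", frozenset(f"P{i:03d}" for i in range(30)))
expr = simulate_proteomics(module, n_per_group=100, r_control=0.6, r_case=0.2, seed=8)
meta = expr.sample_meta
ad = list(meta.index[meta["group"] == "5-6"])
ctrl = list(meta.index[meta["group"] == "0-2"])

result = modular_differential_connectivity(expr, module, ad, ctrl, n_perm=10_000, seed=8)
target = np.arctanh(0.2) - np.arctanh(0.6)
print(f"MDC = {result.mdc_value:.3f} (population value {target:.3f}), "
      f"empirical p = {result.permutation_p:.4f} at {result.n_permutations} permutations")
# A negative MDC means loss of coordinated expression in the AD group.

ttab = feature_ttest_qvalue(expr, ad, ctrl)
n_hits = int((ttab["q"] < 0.05).sum())
print(f"per-protein t-tests: {n_hits} proteins at q < 0.05 "
      f"(pi0 estimate {ttab['pi0'].iloc[0]:.2f})")
# Connectivity changes without mean-level changes: MDC is significant while
# individual protein abundances stay flat, as the correlation structure --
# not the means -- differs between groups.
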