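"""Gene-set statistics: Fisher enrichment, cell-type annotation, and the
exact multi-set intersection test.

The Fisher test asks whether a module overlaps a marker set more than
expected by chance in a declared universe; the multi-set test generalizes
this to the m-way intersection of several sets, computed exactly by
iterated hypergeometric conditioning.
"""
import numpy as np

from olnet import GeneModule, GeneSet, celltype_annotation, fisher_enrichment, multiset_intersection_test

rng = np.random.default_rng(7)
universe = [f"g{i:04d}" for i in range(5000)]

# a module drawn half from an oligodendrocyte-like marker set
markers = {
    "oligodendrocyte": frozenset(universe[:150]),
    "neuron": frozenset(universe[200:400]),
    "microglia": frozenset(universe[500:650]),
}
module_members = frozenset(rng.choice(universe[:150], 40, replace=False)) | frozenset(
    rng.choice(universe[1000:], 40, replace=False)
)
module = GeneModule("turquoise", module_members)

res = fisher_enrichment(module.members, markers["oligodendrocyte"], universe)
print(f"module vs OL markers: overlap {res.overlap}, FE = {res.fold_enrichment:.2f}, "
      f"p = {res.p_value:.2e}")
# FE ~ 17 here: the module holds 50% marker genes vs 3% expected by chance.

matrix, best = celltype_annotation(
    [module], [GeneSet(k, v) for k, v in markers.items()], universe, min_module_size=50
)
print(f"annotation call: {best['turquoise']} "
      f"(-log10 adjusted p = {matrix.loc['turquoise', best['turquoise']]:.1f})")

# three DEG-like sets sharing a planted 25-gene core
core = set(universe[:25])
sets = [
    GeneSet(f"signature_{i}", frozenset(core | set(rng.choice(universe[100:], 75, replace=False))))
    for i in range(3)
]
r = multiset_intersection_test(sets, universe=universe)
print(f"3-way intersection: observed {r.overlap}, expected {r.expected:.3f}, "
      f"FE = {r.fold_enrichment:.0f}, exact p = {r.p_value:.2e}")
# The observed 25-gene core vastly exceeds the ~0.004 genes expected for
# independent sets of these sizes, hence the astronomically small p.
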