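"""Dendrograms and split networks from allelic profiles.

UPGMA produces an ultrametric dendrogram over STs (cut into k groups to
define phylogroups); split decomposition finds all weighted bipartitions
supported by the distance matrix — incompatible split pairs draw as
parallelograms and signal recombination.
"""
from mlstkit import (cut_tree, distance_from_profiles, has_reticulation,
                     simulate_dataset, split_decomposition, upgma)

dataset = simulate_dataset(mode="clonal", n_isolates=50, seed=9)
dm = distance_from_profiles(dataset.table)

tree = upgma(dm)
groups = cut_tree(tree, 2)
print("UPGMA 2-cut phylogroups:")
for label, group in zip("AB", groups):
    print(f"  group {label}: {len(group)} STs: {', '.join(group)}")

system = split_decomposition(dm)
retic, pairs = has_reticulation(system)
print(f"\nsplit decomposition: {len(system.splits)} splits, "
      f"residual {system.residual:.4f}")
print(f"reticulate signal: {retic} ({len(pairs)} incompatible pairs)")

# A 2-founder clonal population separates into two phylogroups; the
# combined split graph may still carry incompatible splits where
# homoplasy (parallel single-locus changes) mimics recombination.
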