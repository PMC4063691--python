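"""Clonal complexes and the minimum-spanning tree of sequence types.

STs sharing at least 5 of 8 alleles with a group's central genotype are
pooled into a clonal complex; each complex's founder is the ST with the
most single-locus variants. A Prim minimum-spanning tree links STs by
the number of differing loci (1-2 strong, 3-5 intermediate, >=6 weak).
"""
from mlstkit import group_sts, minimum_spanning_tree, simulate_dataset

dataset = simulate_dataset(mode="clonal", n_isolates=50, seed=5)
result = group_sts(dataset.table, threshold=5)

print(f"{result.n_complexes} groups "
      f"({len(result.multi_st_groups)} multi-ST complexes, "
      f"{len(result.singletons)} singletons)")
for idx, group in enumerate(result.groups):
    print(f"  group {idx + 1}: founder ST{result.founders[idx]}, "
          f"{len(group)} STs, "
          f"{result.group_isolate_count(group)} isolates: "
          + ", ".join(f"ST{st}" for st in group))

tree = minimum_spanning_tree(dataset.table)
print("\nMST edges (ST -- ST, differing loci, relationship):")
for u, v, data in sorted(tree.edges(data=True)):
    print(f"  ST{u:<3} -- ST{v:<3}  w={data['weight']}  "
          f"{data['relationship']}")

# Founder STs sit at the centre of 'stars' of single-locus variants
# (weight-1 edges); distant singletons attach through weak edges.
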