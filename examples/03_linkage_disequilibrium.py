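"""Clonality testing with the index of association.

I_A = V_O/V_E - 1 compares the observed variance of the pairwise
locus-mismatch count with its expectation under free recombination;
I_A^S = I_A/(l-1) standardises it by the number of loci. Both are ~0 in
a panmictic population and positive in a clonal one. Significance comes
from permuting each locus column independently.
"""
from mlstkit import permutation_test, simulate_dataset

for mode in ("clonal", "panmictic"):
    dataset = simulate_dataset(mode=mode, n_isolates=50, seed=3)
    res = permutation_test(dataset.table, n_permutations=999, seed=3)
    print(f"{mode:>10}:  V_O={res.v_o:.4f}  V_E={res.v_e:.4f}  "
          f"I_A={res.ia:.4f}  I_A^S={res.ia_s:.4f}  p={res.p_value:.4f}")

# The clonal population shows inflated V_O (alleles travel together on
# clonal frames), hence I_A >> 0 with a small p; the panmictic
# population sits near I_A = 0 with a non-significant p.
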