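"""Linkage-disequilibrium (clonality) testing on allelic profiles.

For every unordered pair of isolates let K be the number of loci at which
their allele numbers differ. Under linkage equilibrium (free
recombination) the variance of K matches the sum of per-locus
heterozygosity terms; clonal populations show inflated variance. The
index of association is

    I_A = V_O / V_E - 1,

with V_O the variance of the observed mismatch distribution (population
variance over all n(n-1)/2 pairs — the mismatch distribution is a
complete distribution, not a sample) and

    V_E = sum_j h_j (1 - h_j),    h_j = (n/(n-1)) (1 - sum_i p_ij^2)

the expectation under independence, using the unbiased per-locus
diversity h_j. The LIAN standardisation I_A^S = I_A / (l - 1) removes the
dependence on the number of loci l. Significance comes from a Monte-Carlo
null that permutes each locus column independently (destroying
between-locus association while preserving allele frequencies).
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .errors import FormatError, NoVariationError
from .scheme import ProfileTable


@dataclass
class LinkageResult:
    n_isolates: int
    n_loci: int
    v_o: float
    v_e: float
    ia: float
    ia_s: float
    p_value: float | None = None
    n_permutations: int | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "n_isolates": self.n_isolates, "n_loci": self.n_loci,
            "V_O": self.v_o, "V_E": self.v_e,
            "I_A": self.ia, "I_A_S": self.ia_s,
            "p_value": self.p_value, "n_permutations": self.n_permutations,
            "seed": self.seed,
        }


def _as_matrix(profiles) -> np.ndarray:
    if isinstance(profiles, ProfileTable):
        mat = np.asarray([p.alleles for p in profiles.profiles], dtype=np.int64)
    else:
        mat = np.asarray(profiles, dtype=np.int64)
    if mat.ndim != 2:
        raise FormatError("profiles must form an isolates x loci matrix")
    return mat


def mismatch_distribution(profiles) -> Counter:
    """Histogram of K (differing-locus count) over all unordered pairs."""
    mat = _as_matrix(profiles)
    n = mat.shape[0]
    if n < 2:
        raise FormatError("need at least 2 profiles")
    diff = (mat[:, None, :] != mat[None, :, :]).sum(axis=2)
    iu = np.triu_indices(n, k=1)
    return Counter(diff[iu].tolist())


def _matching_pairs(column: np.ndarray) -> int:
    _, counts = np.unique(column, return_counts=True)
    return int((counts * (counts - 1) // 2).sum())


def _vo(mat: np.ndarray) -> float:
    """Population variance of the pairwise mismatch count, computed from
    per-locus and per-locus-pair match counts in O(l^2 n)."""
    n, l = mat.shape
    pairs = n * (n - 1) // 2
    d = np.empty(l)
    for j in range(l):
        d[j] = pairs - _matching_pairs(mat[:, j])
    sum_k = d.sum()
    sum_k2 = d.sum()  # diagonal terms: indicator squared = indicator
    scale = mat.max() + 1
    for j in range(l):
        for k in range(j + 1, l):
            m_jk = _matching_pairs(mat[:, j] * scale + mat[:, k])
            both_diff = pairs - (pairs - d[j]) - (pairs - d[k]) + m_jk
            sum_k2 += 2 * both_diff
    mean = sum_k / pairs
    return float(sum_k2 / pairs - mean * mean)


def _ve(mat: np.ndarray, unbiased: bool = True) -> float:
    n, _ = mat.shape
    ve = 0.0
    for j in range(mat.shape[1]):
        _, counts = np.unique(mat[:, j], return_counts=True)
        p = counts / n
        h = 1.0 - float((p * p).sum())
        if unbiased:
            h *= n / (n - 1)
        ve += h * (1.0 - h)
    return ve


def index_of_association(profiles, unbiased_ve: bool = True
                         ) -> LinkageResult:
    """Point estimates V_O, V_E, I_A and I_A^S.

    ``unbiased_ve=False`` drops the n/(n-1) correction from the per-locus
    diversities (an estimator variant some programs use).
    """
    mat = _as_matrix(profiles)
    n, l = mat.shape
    if n < 3:
        raise FormatError("index of association needs >= 3 isolates")
    if l < 2:
        raise FormatError("index of association needs >= 2 loci")
    v_e = _ve(mat, unbiased=unbiased_ve)
    if v_e == 0.0:
        raise NoVariationError("all loci are monomorphic; I_A undefined")
    v_o = _vo(mat)
    ia = v_o / v_e - 1.0
    return LinkageResult(n_isolates=n, n_loci=l, v_o=v_o, v_e=v_e,
                         ia=ia, ia_s=ia / (l - 1))


def permutation_test(profiles, n_permutations: int = 1000,
                     seed: int | None = None,
                     unbiased_ve: bool = True) -> LinkageResult:
    """Monte-Carlo test of linkage equilibrium.

    Each permutation independently shuffles every locus column across
    isolates; p = (1 + #{permuted V_O >= observed V_O}) /
    (1 + n_permutations), never exactly zero. ``seed`` is required for a
    reproducible run.
    """
    if seed is None:
        raise ValueError("permutation_test requires an explicit seed")
    mat = _as_matrix(profiles)
    result = index_of_association(mat, unbiased_ve=unbiased_ve)
    rng = np.random.default_rng(seed)
    observed = result.v_o
    exceed = 0
    # canonical row order: the null draws then depend only on the multiset
    # of profiles, making the p-value exactly relabelling-invariant
    work = mat[np.lexsort(mat.T[::-1])].copy()
    for _ in range(n_permutations):
        for j in range(work.shape[1]):
            rng.shuffle(work[:, j])
        if _vo(work) >= observed - 1e-12:
            exceed += 1
    result.p_value = (1 + exceed) / (1 + n_permutations)
    result.n_permutations = n_permutations
    result.seed = seed
    return result
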