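"""Split decomposition (Bandelt-Dress d-splits) of a distance matrix.

A split is a bipartition A|B of the taxon set; its isolation index is

    alpha(A|B) = 1/2 min_{i,j in A; k,l in B}
        [ max(d(i,k)+d(j,l), d(i,l)+d(j,k), d(i,j)+d(k,l))
          - d(i,j) - d(k,l) ]

(i = j and k = l allowed). The d-splits of a metric are the splits with
alpha > 0; for an additive (tree) metric they are exactly the tree's
edges with alpha equal to the branch length. A pair of incompatible
splits (all four intersection cells non-empty) draws as a parallelogram
in a split network and signals reticulate signal, e.g. recombination.

Enumeration is exhaustive over all 2^(n-1)-1 splits for small taxon sets
and uses the incremental Bandelt-Dress construction (extend the split
system taxon by taxon, pruning splits whose index drops to 0) above
that; the two agree on their overlap range.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from skbio import DistanceMatrix

from .errors import FormatError

BRUTE_FORCE_MAX = 12
TAXON_CAP = 60
_TOL = 1e-9


@dataclass(frozen=True)
class Split:
    side_a: frozenset[str]
    side_b: frozenset[str]
    weight: float   # isolation index alpha

    @property
    def is_trivial(self) -> bool:
        return min(len(self.side_a), len(self.side_b)) < 2

    def key(self) -> frozenset:
        """Orientation-free identity of the bipartition."""
        return frozenset((self.side_a, self.side_b))


@dataclass
class SplitSystem:
    taxa: tuple[str, ...]
    splits: list[Split] = field(default_factory=list)
    residual: float = 0.0

    @property
    def nontrivial(self) -> list[Split]:
        return [s for s in self.splits if not s.is_trivial]


def _as_matrix(dm) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(dm, DistanceMatrix):
        return np.asarray(dm.data, dtype=float), tuple(dm.ids)
    arr = np.asarray(dm, dtype=float)
    return arr, tuple(str(i) for i in range(arr.shape[0]))


def _alpha(a_idx: np.ndarray, b_idx: np.ndarray, d: np.ndarray) -> float:
    """Vectorised isolation index over index arrays a_idx | b_idx."""
    dA = d[np.ix_(a_idx, a_idx)]
    dB = d[np.ix_(b_idx, b_idx)]
    dAB = d[np.ix_(a_idx, b_idx)]
    x1 = dAB[:, None, :, None] + dAB[None, :, None, :]   # d(i,k)+d(j,l)
    x2 = dAB[:, None, None, :] + dAB[None, :, :, None]   # d(i,l)+d(j,k)
    x3 = dA[:, :, None, None] + dB[None, None, :, :]     # d(i,j)+d(k,l)
    val = np.maximum(x1, np.maximum(x2, x3)) - x3
    return 0.5 * float(val.min())


def isolation_index(side_a, side_b, dm) -> float:
    """Isolation index of the bipartition ``side_a | side_b``."""
    d, taxa = _as_matrix(dm)
    index = {t: i for i, t in enumerate(taxa)}
    a = sorted(set(side_a))
    b = sorted(set(side_b))
    if not a or not b or set(a) & set(b) or set(a) | set(b) != set(taxa):
        raise FormatError("sides must be a non-empty bipartition of taxa")
    return _alpha(np.array([index[t] for t in a]),
                  np.array([index[t] for t in b]), d)


def _brute_force_splits(d: np.ndarray, taxa) -> list[Split]:
    n = len(taxa)
    idx = np.arange(n)
    splits = []
    for mask in range(2 ** (n - 1)):  # mask 0 = trivial split of taxon 0
        in_a = [0] + [i for i in range(1, n) if mask >> (i - 1) & 1]
        in_b = [i for i in range(1, n) if not (mask >> (i - 1) & 1)]
        if not in_b:
            continue
        alpha = _alpha(idx[in_a], idx[in_b], d)
        if alpha > _TOL:
            splits.append(Split(frozenset(taxa[i] for i in in_a),
                                frozenset(taxa[i] for i in in_b), alpha))
    return splits


def _incremental_splits(d: np.ndarray, taxa) -> list[Split]:
    # Extend the d-split system one taxon at a time. Every d-split of the
    # enlarged set restricts to a split of index >= alpha on the subset,
    # so extending all surviving splits (plus the new trivial split)
    # covers all candidates; pruning alpha = 0 splits is safe because the
    # isolation index is monotone non-increasing under taxon addition.
    n = len(taxa)
    systems = [(frozenset([0]), frozenset([1]))]
    for m in range(2, n):
        prev = systems
        candidates = set()
        for a, b in prev:
            candidates.add((a | {m}, b))
            candidates.add((a, b | {m}))
        candidates.add((frozenset([m]),
                        frozenset(range(m))))
        systems = []
        for a, b in candidates:
            alpha = _alpha(np.fromiter(a, int), np.fromiter(b, int), d)
            if alpha > _TOL:
                systems.append((a, b))
    out = []
    for a, b in systems:
        alpha = _alpha(np.fromiter(a, int), np.fromiter(b, int), d)
        out.append(Split(frozenset(taxa[i] for i in a),
                         frozenset(taxa[i] for i in b), alpha))
    return out


def split_metric_pair(splits: list[Split], x: str, y: str) -> float:
    """Distance between two taxa induced by the split system."""
    total = 0.0
    for s in splits:
        if (x in s.side_a) != (y in s.side_a):
            total += s.weight
    return total


def split_decomposition(dm, method: str = "auto") -> SplitSystem:
    """All d-splits (alpha > 0) of a metric, sorted by descending alpha.

    ``method``: "brute" (exhaustive, <= 12 taxa), "incremental"
    (Bandelt-Dress taxon-by-taxon construction) or "auto". Taxon sets
    above 60 are rejected — collapse isolates to distinct STs or alleles
    first.
    """
    d, taxa = _as_matrix(dm)
    n = len(taxa)
    if n < 2:
        raise FormatError("need at least 2 taxa")
    if n > TAXON_CAP:
        raise FormatError(
            f"{n} taxa exceeds the {TAXON_CAP}-taxon cap; collapse to "
            f"distinct STs/alleles first")
    if method == "auto":
        method = "brute" if n <= BRUTE_FORCE_MAX else "incremental"
    if method == "brute":
        if n > 16:
            raise FormatError("brute-force enumeration capped at 16 taxa")
        splits = _brute_force_splits(d, taxa)
    elif method == "incremental":
        splits = (_brute_force_splits(d, taxa) if n == 2
                  else _incremental_splits(d, taxa))
    else:
        raise ValueError(f"unknown method {method!r}")
    splits.sort(key=lambda s: (-s.weight,
                               min(sorted(s.side_a), sorted(s.side_b))))
    total_d = 0.0
    total_s = 0.0
    for i, j in combinations(range(n), 2):
        total_d += d[i, j]
        total_s += split_metric_pair(splits, taxa[i], taxa[j])
    residual = 0.0 if total_d == 0 else max(0.0, 1.0 - total_s / total_d)
    return SplitSystem(taxa=taxa, splits=splits, residual=residual)


def splits_compatible(s: Split, t: Split) -> bool:
    """Two splits are compatible iff some intersection cell of their
    bipartitions is empty."""
    for x in (s.side_a, s.side_b):
        for y in (t.side_a, t.side_b):
            if not (x & y):
                return True
    return False


def has_reticulation(system: SplitSystem
                     ) -> tuple[bool, list[tuple[Split, Split]]]:
    """True iff some pair of non-trivial splits is incompatible; the
    incompatible pairs are returned."""
    pairs = [(s, t) for s, t in combinations(system.nontrivial, 2)
             if not splits_compatible(s, t)]
    return bool(pairs), pairs


def is_weakly_compatible(system: SplitSystem) -> bool:
    """Weak compatibility of the emitted system (Bandelt-Dress): no three
    splits pairwise cut a common 4-point configuration.

    Checked directly from the definition: three splits are weakly
    compatible unless taxa x, y1, y2, y3 exist with split i putting
    {x, y_i} on one side and the other two y's on the other, for all
    three splits simultaneously."""
    from itertools import product
    splits = system.splits
    for s1, s2, s3 in combinations(splits, 3):
        for a1, a2, a3 in product((s1.side_a, s1.side_b),
                                  (s2.side_a, s2.side_b),
                                  (s3.side_a, s3.side_b)):
            b1 = s1.side_b if a1 is s1.side_a else s1.side_a
            b2 = s2.side_b if a2 is s2.side_a else s2.side_a
            b3 = s3.side_b if a3 is s3.side_a else s3.side_a
            if (a1 & a2 & a3) and (a1 & b2 & b3) and (b1 & a2 & b3) \
                    and (b1 & b2 & a3):
                return False
    return True


def write_splits_nexus(system: SplitSystem, path) -> None:
    """Nexus file with Taxa and st_splits blocks (SplitsTree-compatible)."""
    taxa = list(system.taxa)
    index = {t: i + 1 for i, t in enumerate(taxa)}
    lines = ["#NEXUS", "", "BEGIN Taxa;",
             f"DIMENSIONS ntax={len(taxa)};", "TAXLABELS"]
    for i, t in enumerate(taxa, 1):
        lines.append(f"[{i}] '{t}'")
    lines += [";", "END;", "", "BEGIN Splits;",
              f"DIMENSIONS ntax={len(taxa)} nsplits={len(system.splits)};",
              "FORMAT labels=no weights=yes;", "MATRIX"]
    for i, s in enumerate(system.splits, 1):
        side = s.side_a if taxa[0] in s.side_a else s.side_b
        members = " ".join(str(index[t]) for t in
                           sorted(side, key=lambda t: index[t]))
        lines.append(f"[{i}, size={min(len(s.side_a), len(s.side_b))}]"
                     f"\t{s.weight:.6f}\t{members},")
    lines += [";", "END;"]
    with open(path, "w") as handle:
        handle.write("\n".join(lines) + "\n")
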