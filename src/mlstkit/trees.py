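"""Distance-based phylogeny over allelic profiles or concatenated
sequences: UPGMA (ultrametric dendrogram), neighbour joining, and group
extraction by tree cutting.

Distance matrices are :class:`skbio.DistanceMatrix`; trees are
:class:`skbio.TreeNode` with branch lengths, serialisable as Newick.
Both agglomerations use a deterministic tie-break (lexicographically
smallest label pair) so repeated runs are byte-identical.
"""
from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .errors import FormatError
from .scheme import ProfileTable, Scheme


def distance_from_profiles(table: ProfileTable, by: str = "st"
                           ) -> DistanceMatrix:
    """Proportion of mismatched loci (Hamming / l).

    ``by="st"`` uses distinct STs as taxa (labels ``ST<n>``);
    ``by="isolate"`` uses isolates.
    """
    if by == "st":
        vectors = table.distinct_sts()
        labels = [f"ST{st}" for st in vectors]
        rows = [vectors[st] for st in sorted(vectors)]
    elif by == "isolate":
        labels = [p.isolate_id for p in table.profiles]
        rows = [p.alleles for p in table.profiles]
    else:
        raise ValueError(f"unknown taxon mode {by!r}")
    mat = np.asarray(rows, dtype=np.int64)
    if mat.shape[0] < 2:
        raise FormatError("need at least 2 taxa")
    dist = (mat[:, None, :] != mat[None, :, :]).mean(axis=2)
    return DistanceMatrix(dist, ids=labels)


def distance_from_concatenates(
        sequences_by_locus: dict[str, dict[str, str]],
        scheme: Scheme | None = None) -> DistanceMatrix:
    """p-distance on per-taxon concatenated locus alignments.

    ``sequences_by_locus`` maps locus -> {taxon -> sequence}; loci are
    concatenated in scheme order (or input dict order when no scheme is
    given). Every taxon must carry every locus.
    """
    locus_order = (scheme.locus_names if scheme is not None
                   else tuple(sequences_by_locus))
    taxa = sorted(sequences_by_locus[locus_order[0]])
    concat = {}
    for taxon in taxa:
        parts = []
        for locus in locus_order:
            table = sequences_by_locus[locus]
            if taxon not in table:
                raise FormatError(f"taxon {taxon} missing locus {locus}")
            parts.append(table[taxon].upper())
        concat[taxon] = "".join(parts)
    lengths = {len(s) for s in concat.values()}
    if len(lengths) > 1:
        raise FormatError("concatenates have unequal lengths")
    arr = np.frombuffer("".join(concat[t] for t in taxa).encode(),
                        dtype="S1").reshape(len(taxa), -1)
    dist = (arr[:, None, :] != arr[None, :, :]).mean(axis=2)
    return DistanceMatrix(dist, ids=taxa)


def _dm_to_dict(dm: DistanceMatrix):
    ids = list(dm.ids)
    d = {}
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i < j:
                d[frozenset((a, b))] = float(dm[i, j])
    return ids, d


def upgma(dm: DistanceMatrix) -> TreeNode:
    """Average-linkage (UPGMA) dendrogram; node heights are d/2 so the
    result is ultrametric. Ties are broken by the lexicographically
    smallest (representative-label) cluster pair."""
    ids, dist = _dm_to_dict(dm)
    if len(ids) < 2:
        raise FormatError("need at least 2 taxa")
    clusters = {name: (TreeNode(name=name), 1, 0.0) for name in ids}
    # representative label of a cluster = its smallest leaf label
    while len(clusters) > 1:
        best = None
        for a, b in combinations(sorted(clusters), 2):
            key = (dist[frozenset((a, b))], a, b)
            if best is None or key < best:
                best = key
        d, a, b = best
        node_a, size_a, h_a = clusters.pop(a)
        node_b, size_b, h_b = clusters.pop(b)
        height = d / 2.0
        node_a.length = height - h_a
        node_b.length = height - h_b
        parent = TreeNode(children=[node_a, node_b])
        rep = min(a, b)
        for other in clusters:
            key_o = frozenset((rep, other))
            dist[key_o] = (size_a * dist.pop(frozenset((a, other)))
                           + size_b * dist.pop(frozenset((b, other)))) \
                / (size_a + size_b)
        dist.pop(frozenset((a, b)), None)
        clusters[rep] = (parent, size_a + size_b, height)
    root, _, _ = clusters.popitem()[1]
    root.length = None
    return root


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbour joining with the standard Q criterion.

    Negative branch lengths are clamped to 0 with a warning. The result
    is returned as a TreeNode whose root is the final trifurcation (or
    the 2/3-taxon degenerate forms)."""
    ids, dist = _dm_to_dict(dm)
    if len(ids) < 2:
        raise FormatError("need at least 2 taxa")

    def clamp(x):
        if x < 0:
            warnings.warn(f"negative branch length {x:.6g} clamped to 0",
                          stacklevel=2)
            return 0.0
        return x

    nodes = {name: TreeNode(name=name) for name in ids}
    active = sorted(ids)
    if len(active) == 2:
        a, b = active
        nodes[a].length = clamp(dist[frozenset((a, b))])
        nodes[b].length = 0.0
        return TreeNode(children=[nodes[a], nodes[b]])
    counter = 0
    while len(active) > 3:
        r = len(active)
        totals = {a: sum(dist[frozenset((a, b))]
                         for b in active if b != a) for a in active}
        best = None
        for a, b in combinations(active, 2):
            q = (r - 2) * dist[frozenset((a, b))] - totals[a] - totals[b]
            key = (q, a, b)
            if best is None or key < best:
                best = key
        _, a, b = best
        d_ab = dist[frozenset((a, b))]
        la = 0.5 * d_ab + (totals[a] - totals[b]) / (2.0 * (r - 2))
        lb = d_ab - la
        nodes[a].length = clamp(la)
        nodes[b].length = clamp(lb)
        new_name = f"_nj{counter}"
        counter += 1
        nodes[new_name] = TreeNode(children=[nodes[a], nodes[b]])
        for c in active:
            if c in (a, b):
                continue
            d_new = 0.5 * (dist.pop(frozenset((a, c)))
                           + dist.pop(frozenset((b, c))) - d_ab)
            dist[frozenset((new_name, c))] = d_new
        dist.pop(frozenset((a, b)), None)
        active = sorted(c for c in active if c not in (a, b))
        active.append(new_name)
        active.sort()
    a, b, c = active
    d_ab = dist[frozenset((a, b))]
    d_ac = dist[frozenset((a, c))]
    d_bc = dist[frozenset((b, c))]
    nodes[a].length = clamp(0.5 * (d_ab + d_ac - d_bc))
    nodes[b].length = clamp(0.5 * (d_ab + d_bc - d_ac))
    nodes[c].length = clamp(0.5 * (d_ac + d_bc - d_ab))
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    for node in root.traverse():
        if not node.is_tip() and node is not root:
            node.name = None
    return root


def is_ultrametric(tree: TreeNode, tol: float = 1e-9) -> bool:
    """All root-to-leaf path lengths equal within ``tol``."""
    depths = [tip.accumulate_to_ancestor(tree) for tip in tree.tips()]
    return max(depths) - min(depths) <= tol


def _node_height(node: TreeNode) -> float:
    tip = next(node.tips(), None)
    if tip is None:
        return 0.0
    return tip.accumulate_to_ancestor(node)


def cut_tree(tree: TreeNode, k: int) -> list[list[str]]:
    """Cut an (ultrametric) dendrogram into ``k`` leaf groups by removing
    the k-1 highest internal nodes; deterministic under height ties
    (smallest leaf-label set first). Groups are returned sorted by size
    (descending) then by smallest member."""
    leaves = [tip.name for tip in tree.tips()]
    n = len(leaves)
    if not (1 <= k <= n):
        raise FormatError(f"k={k} outside 1..{n}")
    cut: set[int] = set()
    internal = {id(node): node for node in tree.traverse()
                if not node.is_tip()}

    def cuttable():
        for node in internal.values():
            if id(node) in cut:
                continue
            parent = node.parent
            if parent is None or id(parent) in cut:
                yield node

    for _ in range(k - 1):
        candidates = list(cuttable())
        if not candidates:
            break
        best = max(candidates,
                   key=lambda nd: (_node_height(nd),
                                   [t.name for t in nd.tips()]))
        cut.add(id(best))

    groups: list[list[str]] = []

    def collect(node):
        if node.is_tip():
            groups.append([node.name])
        elif id(node) in cut:
            for child in node.children:
                collect(child)
        else:
            groups.append(sorted(t.name for t in node.tips()))

    collect(tree)
    return sorted(groups, key=lambda g: (-len(g), g[0]))


def write_newick(tree: TreeNode, path) -> None:
    """Newick with branch lengths at 6 decimal places."""
    text = _newick(tree) + ";\n"
    with open(path, "w") as handle:
        handle.write(text)


def _newick(node: TreeNode) -> str:
    if node.is_tip():
        base = node.name or ""
    else:
        base = "(" + ",".join(_newick(c) for c in node.children) + ")"
        if node.name:
            base += node.name
    if node.length is not None:
        base += f":{node.length:.6f}"
    return base
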