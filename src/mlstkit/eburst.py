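"""Clonal-complex inference on sequence types.

Implements eBURST-style grouping and founder prediction plus a Prim
minimum-spanning tree over allelic profiles.

Grouping rule (the "shared-allele threshold" rule): starting from the
full ST set, the candidate central genotype is the unassigned ST with the
most single-locus variants (SLVs) among unassigned STs (ties broken by
double-locus variant count, isolate frequency, then lowest ST number);
every unassigned ST sharing at least ``threshold`` identical alleles with
that centre joins its group. Groups whose centres themselves share the
threshold are merged. The classic eBURST default (join when an SLV of any
group member) is available as ``rule="slv"``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .errors import FormatError
from .scheme import ProfileTable


def profile_distance(a, b) -> int:
    """Hamming distance between two allele-number vectors."""
    va = tuple(a.alleles) if hasattr(a, "alleles") else tuple(a)
    vb = tuple(b.alleles) if hasattr(b, "alleles") else tuple(b)
    if len(va) != len(vb):
        raise FormatError("profiles compare different numbers of loci")
    return sum(1 for x, y in zip(va, vb) if x != y)


def _st_inputs(table: ProfileTable):
    st_vectors = table.distinct_sts()
    if not st_vectors:
        raise FormatError("profile table defines no STs")
    freqs = table.st_counts()
    for st in st_vectors:
        freqs.setdefault(st, 0)
    return st_vectors, freqs


def variant_counts(st_vectors: dict[int, tuple[int, ...]]
                   ) -> tuple[dict[int, int], dict[int, int],
                              list[tuple[int, int]]]:
    """Per-ST SLV and DLV counts plus the SLV edge list."""
    sts = sorted(st_vectors)
    slv = {st: 0 for st in sts}
    dlv = {st: 0 for st in sts}
    edges = []
    for i, a in enumerate(sts):
        for b in sts[i + 1:]:
            d = profile_distance(st_vectors[a], st_vectors[b])
            if d == 1:
                slv[a] += 1
                slv[b] += 1
                edges.append((a, b))
            elif d == 2:
                dlv[a] += 1
                dlv[b] += 1
    return slv, dlv, edges


def _founder_key(st, slv, dlv, freq):
    # maximise SLVs, then DLVs, then isolate frequency; lowest ST wins ties
    return (-slv[st], -dlv[st], -freq.get(st, 0), st)


@dataclass
class CCResult:
    groups: list[list[int]]                 # sorted ST lists, largest first
    founders: dict[int, int] = field(default_factory=dict)  # group idx -> ST
    slv_graph: list[tuple[int, int]] = field(default_factory=list)
    slv_counts: dict[int, int] = field(default_factory=dict)
    dlv_counts: dict[int, int] = field(default_factory=dict)
    st_frequencies: dict[int, int] = field(default_factory=dict)

    @property
    def multi_st_groups(self) -> list[list[int]]:
        return [g for g in self.groups if len(g) > 1]

    @property
    def singletons(self) -> list[int]:
        return sorted(st for g in self.groups if len(g) == 1 for st in g)

    @property
    def n_complexes(self) -> int:
        """Total group count: multi-ST complexes plus singletons."""
        return len(self.groups)

    def group_isolate_count(self, group: list[int]) -> int:
        return sum(self.st_frequencies.get(st, 0) for st in group)


def group_sts(table: ProfileTable, threshold: int = 5,
              rule: str = "central") -> CCResult:
    """Partition STs into clonal complexes and singletons.

    ``threshold`` is the number of identical alleles an ST must share
    with the group's central genotype (``rule="central"``) or with at
    least one group member at l-1 loci (``rule="slv"``, classic eBURST).
    """
    st_vectors, freqs = _st_inputs(table)
    n_loci = len(next(iter(st_vectors.values())))
    if not (1 <= threshold <= n_loci):
        raise FormatError(
            f"threshold {threshold} outside 1..{n_loci}")
    slv, dlv, edges = variant_counts(st_vectors)

    if rule == "slv":
        graph = nx.Graph()
        graph.add_nodes_from(st_vectors)
        graph.add_edges_from(
            (a, b) for a, b in edges)
        raw_groups = [sorted(c) for c in nx.connected_components(graph)]
        centers = {}
    elif rule == "central":
        max_dist = n_loci - threshold
        unassigned = set(st_vectors)
        raw_groups = []
        centers = {}
        while unassigned:
            sub_slv = {st: 0 for st in unassigned}
            sub_dlv = {st: 0 for st in unassigned}
            members = sorted(unassigned)
            for i, a in enumerate(members):
                for b in members[i + 1:]:
                    d = profile_distance(st_vectors[a], st_vectors[b])
                    if d == 1:
                        sub_slv[a] += 1
                        sub_slv[b] += 1
                    elif d == 2:
                        sub_dlv[a] += 1
                        sub_dlv[b] += 1
            center = min(unassigned,
                         key=lambda st: _founder_key(st, sub_slv, sub_dlv,
                                                     freqs))
            group = [st for st in unassigned
                     if profile_distance(st_vectors[st],
                                         st_vectors[center]) <= max_dist]
            centers[len(raw_groups)] = center
            raw_groups.append(sorted(group))
            unassigned -= set(group)
        # merge groups whose centres share the threshold
        merge = nx.Graph()
        merge.add_nodes_from(range(len(raw_groups)))
        for i in range(len(raw_groups)):
            for j in range(i + 1, len(raw_groups)):
                if profile_distance(st_vectors[centers[i]],
                                    st_vectors[centers[j]]) <= max_dist:
                    merge.add_edge(i, j)
        merged = []
        for comp in nx.connected_components(merge):
            merged.append(sorted(st for i in comp for st in raw_groups[i]))
        raw_groups = merged
    else:
        raise ValueError(f"unknown rule {rule!r}")

    def group_order(g):
        return (-sum(freqs.get(st, 0) for st in g), -len(g), g[0])

    groups = sorted(raw_groups, key=group_order)
    result = CCResult(groups=groups, slv_graph=edges, slv_counts=slv,
                      dlv_counts=dlv, st_frequencies=freqs)
    for idx, group in enumerate(groups):
        result.founders[idx] = predict_founder(group, st_vectors, freqs)
    return result


def predict_founder(group: list[int],
                    st_vectors: dict[int, tuple[int, ...]],
                    frequencies: dict[int, int]) -> int:
    """Predicted primary founder of one group.

    The ST with the most SLVs within the group; ties broken by DLV count,
    then isolate frequency, then lowest ST number.
    """
    if not group:
        raise FormatError("empty group")
    sub = {st: st_vectors[st] for st in group}
    slv, dlv, _ = variant_counts(sub)
    return min(group, key=lambda st: _founder_key(st, slv, dlv, frequencies))


DEFAULT_EDGE_CLASSES = ((2, "strong"), (5, "intermediate"))


def classify_edge(weight: int, classes=DEFAULT_EDGE_CLASSES) -> str:
    """Map an edge weight (differing-locus count) to a relationship
    class; defaults: 1-2 strong, 3-5 intermediate, >=6 weak."""
    for upper, label in classes:
        if weight <= upper:
            return label
    return "weak"


def minimum_spanning_tree(table: ProfileTable,
                          edge_classes=DEFAULT_EDGE_CLASSES) -> nx.Graph:
    """Prim minimum-spanning tree over the distinct STs.

    The complete graph is weighted by :func:`profile_distance`. The start
    node and every tie are resolved deterministically: higher isolate
    frequency first, then lower ST number. Nodes carry ``count``,
    ``region_counts`` and ``source_counts`` attributes; edges carry
    ``weight`` and ``relationship``.
    """
    st_vectors, freqs = _st_inputs(table)
    sts = sorted(st_vectors)
    tree = nx.Graph()
    region_tallies: dict[int, dict[str, int]] = {st: {} for st in sts}
    source_tallies: dict[int, dict[str, int]] = {st: {} for st in sts}
    for prof in table.profiles:
        if prof.st is None:
            continue
        if prof.region:
            t = region_tallies[prof.st]
            t[prof.region] = t.get(prof.region, 0) + 1
        if prof.source:
            t = source_tallies[prof.st]
            t[prof.source] = t.get(prof.source, 0) + 1
    for st in sts:
        tree.add_node(st, count=freqs.get(st, 0),
                      region_counts=region_tallies[st],
                      source_counts=source_tallies[st])
    if len(sts) == 1:
        return tree
    start = min(sts, key=lambda st: (-freqs.get(st, 0), st))
    in_tree = {start}
    while len(in_tree) < len(sts):
        best = None
        for v in sts:
            if v in in_tree:
                continue
            for u in sorted(in_tree):
                w = profile_distance(st_vectors[u], st_vectors[v])
                key = (w, -freqs.get(v, 0), v, u)
                if best is None or key < best[0]:
                    best = (key, u, v, w)
        _, u, v, w = best
        tree.add_edge(u, v, weight=w,
                      relationship=classify_edge(w, edge_classes))
        in_tree.add(v)
    return tree


def write_mst_dot(tree: nx.Graph, path) -> None:
    """Plain DOT rendering of an MST (weights and relationship classes
    as edge labels, isolate counts as node labels)."""
    lines = ["graph mst {"]
    for node, data in sorted(tree.nodes(data=True)):
        lines.append(
            f'  "ST{node}" [label="ST{node} (n={data.get("count", 0)})"];')
    for u, v, data in sorted(tree.edges(data=True)):
        lines.append(
            f'  "ST{u}" -- "ST{v}" [label="{data["weight"]}", '
            f'relationship="{data["relationship"]}"];')
    lines.append("}")
    with open(path, "w") as handle:
        handle.write("\n".join(lines) + "\n")
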