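"""Independent brute-force oracles used by the test suite.

Everything here is written directly from definitions (exact rational
arithmetic, exhaustive enumeration) and shares no code with the package
implementation paths it checks.
"""
from __future__ import annotations

from fractions import Fraction
from itertools import combinations, permutations

from Bio.Data.CodonTable import unambiguous_dna_by_id

_TABLE = unambiguous_dna_by_id[1]
AA = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    AA[_stop] = "*"
BASES = "ACGT"


def ng86_sites(codon: str) -> tuple[Fraction, Fraction]:
    """(nonsynonymous, synonymous) site counts of one codon: at each
    position, the synonymous fraction of the 3 possible changes; a change
    creating a stop codon is nonsynonymous."""
    syn = Fraction(0)
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1:]
            if AA[mutant] != "*" and AA[mutant] == AA[codon]:
                syn += Fraction(1, 3)
    return Fraction(3) - syn, syn


def ng86_codon_differences(c1: str, c2: str) -> tuple[Fraction, Fraction]:
    """(nonsyn, syn) step counts averaged over minimal mutational
    pathways; pathways through a stop codon are dropped unless all are."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return Fraction(0), Fraction(0)
    results = []
    for order in permutations(diff):
        cur, nd, sd, blocked = c1, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if AA[nxt] == "*" and nxt != c2:
                blocked = True
            if AA[nxt] == AA[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        results.append((nd, sd, blocked))
    usable = [(n, s) for n, s, b in results if not b] \
        or [(n, s) for n, s, _ in results]
    k = len(usable)
    return (Fraction(sum(n for n, _ in usable), k),
            Fraction(sum(s for _, s in usable), k))


def ng86_pair_exact(a: str, b: str):
    """Exact pre-correction NG86 quantities (n_sites, s_sites, nd, sd)."""
    n_sites = s_sites = nd = sd = Fraction(0)
    for i in range(0, len(a), 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        if AA[ca] == "*" or AA[cb] == "*":
            continue
        na, sa = ng86_sites(ca)
        nb, sb = ng86_sites(cb)
        n_sites += (na + nb) / 2
        s_sites += (sa + sb) / 2
        dn, ds = ng86_codon_differences(ca, cb)
        nd += dn
        sd += ds
    return n_sites, s_sites, nd, sd


def pair_mismatch_variance(rows) -> tuple[Fraction, Fraction]:
    """(mean, population variance) of the differing-locus count over all
    unordered pairs, by direct enumeration."""
    ks = [sum(1 for x, y in zip(a, b) if x != y)
          for a, b in combinations(rows, 2)]
    n = len(ks)
    mean = Fraction(sum(ks), n)
    var = sum((Fraction(k) - mean) ** 2 for k in ks) / n
    return mean, var


def ia_exact(rows) -> Fraction:
    """I_A = V_O/V_E - 1 with unbiased per-locus diversity, exactly."""
    n = len(rows)
    _, v_o = pair_mismatch_variance(rows)
    v_e = Fraction(0)
    for j in range(len(rows[0])):
        col = [r[j] for r in rows]
        h = Fraction(n, n - 1) * (
            1 - sum(Fraction(col.count(v), n) ** 2 for v in set(col)))
        v_e += h * (1 - h)
    return v_o / v_e - 1


def minimum_spanning_weight(dist: dict[tuple[int, int], int],
                            nodes: list[int]) -> int:
    """Exhaustive minimum spanning-tree weight over all edge subsets of
    size n-1 that connect the node set."""
    edges = [(dist[a, b] if (a, b) in dist else dist[b, a], a, b)
             for a, b in combinations(nodes, 2)]
    best = None
    n = len(nodes)
    for subset in combinations(edges, n - 1):
        parent = {v: v for v in nodes}

        def find(v):
            while parent[v] != v:
                parent[v] = parent[parent[v]]
                v = parent[v]
            return v

        ok = True
        for _, a, b in subset:
            ra, rb = find(a), find(b)
            if ra == rb:
                ok = False
                break
            parent[ra] = rb
        if ok:
            w = sum(e[0] for e in subset)
            if best is None or w < best:
                best = w
    return best


def tree_metric(n_taxa: int, rng):
    """Random additive (tree) metric: a random binary tree topology with
    positive branch lengths; returns (distance matrix as dict of
    frozensets, list of edge splits with weights)."""
    import itertools
    taxa = [f"t{i}" for i in range(n_taxa)]
    # random binary tree by sequential attachment
    adj = {}

    def connect(a, b, w):
        adj.setdefault(a, {})[b] = w
        adj.setdefault(b, {})[a] = w

    next_id = itertools.count(1)
    leaf_of = {}
    leaf_of[taxa[0]] = 0
    leaf_of[taxa[1]] = next(next_id)
    connect(leaf_of[taxa[0]], leaf_of[taxa[1]],
            float(rng.uniform(0.1, 1.0)))
    for t in taxa[2:]:
        all_edges = [(a, b) for a in adj for b in adj[a] if a < b]
        a, b = all_edges[rng.integers(len(all_edges))]
        w = adj[a].pop(b)
        adj[b].pop(a)
        mid = next(next_id)
        f = float(rng.uniform(0.2, 0.8))
        connect(a, mid, w * f)
        connect(mid, b, w * (1 - f))
        leaf = next(next_id)
        leaf_of[t] = leaf
        connect(mid, leaf, float(rng.uniform(0.1, 1.0)))

    # all-pairs distances by BFS/DFS accumulation
    def dists_from(start):
        out = {start: 0.0}
        stack = [start]
        while stack:
            v = stack.pop()
            for u, w in adj[v].items():
                if u not in out:
                    out[u] = out[v] + w
                    stack.append(u)
        return out

    dmat = {}
    for x, y in combinations(taxa, 2):
        dmat[frozenset((x, y))] = dists_from(leaf_of[x])[leaf_of[y]]

    # edge splits: removing an edge bipartitions the leaves
    splits = []
    leaf_ids = {v: t for t, v in leaf_of.items()}

    def reachable(start, banned):
        seen = {start}
        stack = [start]
        while stack:
            v = stack.pop()
            for u in adj[v]:
                if u not in seen and (v, u) != banned and (u, v) != banned:
                    seen.add(u)
                    stack.append(u)
        return seen

    for a in adj:
        for b in adj[a]:
            if a < b:
                side = {leaf_ids[v] for v in reachable(a, (a, b))
                        if v in leaf_ids}
                other = set(taxa) - side
                if side and other:
                    splits.append((frozenset(side), frozenset(other),
                                   adj[a][b]))
    # deduplicate bipartitions (sum weights of parallel path edges: none
    # in a tree, but identical bipartitions arise from edges adjacent to
    # degree-2 nodes)
    merged = {}
    for sa, sb, w in splits:
        key = frozenset((sa, sb))
        merged[key] = merged.get(key, 0.0) + w
    out = [(min(k, key=sorted), max(k, key=sorted), w)
           for k, w in merged.items()]
    return taxa, dmat, out
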