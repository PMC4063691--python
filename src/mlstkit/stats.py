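"""Per-locus diversity and selection statistics.

Covers the quantities usually tabulated when a typing scheme is
characterised: polymorphic (segregating) sites, SNP totals, GC content,
and Nei-Gojobori (1986) synonymous/nonsynonymous substitution rates with
the Jukes-Cantor multiple-hit correction.

NG86 conventions used here (they change digits, so they are spelled out):

* per-codon site counting — at each codon position the synonymous site
  fraction is (number of the 3 possible single-base changes that preserve
  the amino acid)/3; changes creating a stop codon count as nonsynonymous;
* codons differing at several positions are scored by averaging the
  synonymous/nonsynonymous step counts over all minimal mutational
  pathways; pathways passing through a stop codon are excluded unless
  every pathway is blocked (then all are used);
* site counts are averaged over the two sequences of a pair;
* p_N and p_S are corrected with Jukes-Cantor d = -(3/4) ln(1 - (4/3) p).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations, permutations

from .errors import (AmbiguityError, FormatError, MlstError, NoVariationError,
                     SaturationError)
from .scheme import UNAMBIGUOUS_DNA

_BASES = "ACGT"

_CODON_AA: dict[str, str] = {}


def _build_code():
    from Bio.Data.CodonTable import unambiguous_dna_by_id
    table = unambiguous_dna_by_id[1]  # standard genetic code
    _CODON_AA.update(table.forward_table)
    for codon in table.stop_codons:
        _CODON_AA[codon] = "*"


_build_code()


def _check_sequences(sequences, minimum=1):
    seqs = [s.upper() for s in sequences]
    if len(seqs) < minimum:
        raise FormatError(f"need at least {minimum} sequence(s)")
    if len({len(s) for s in seqs}) > 1:
        raise FormatError("sequences have unequal lengths "
                          "(indels are unsupported)")
    for s in seqs:
        bad = set(s) - UNAMBIGUOUS_DNA
        if bad:
            raise AmbiguityError(
                f"sequence contains non-ACGT character(s) {sorted(bad)}")
    return seqs


def count_polymorphic_sites(sequences) -> int:
    """Number of alignment columns holding >= 2 distinct residues."""
    seqs = _check_sequences(sequences, minimum=2)
    return sum(1 for column in zip(*seqs) if len(set(column)) > 1)


def total_snps(polymorphic_site_counts) -> int:
    """Scheme-wide SNP total: sum of per-locus polymorphic-site counts."""
    return int(sum(polymorphic_site_counts))


def gc_content(sequences) -> float:
    """Percentage of G+C pooled over all input sequences."""
    seqs = _check_sequences(sequences, minimum=1)
    gc = sum(s.count("G") + s.count("C") for s in seqs)
    total = sum(len(s) for s in seqs)
    if total == 0:
        raise FormatError("empty sequences")
    return 100.0 * gc / total


def _codon_site_counts(codon: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) site counts of one codon."""
    aa = _CODON_AA[codon]
    syn = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1:]
            if _CODON_AA[mutant] == aa:  # stop targets are nonsynonymous
                syn += 1.0 / 3.0
    return 3.0 - syn, syn


def _codon_path_counts(c1: str, c2: str) -> tuple[float, float]:
    """(nonsyn, syn) observed differences between two codons, averaged
    over minimal mutational pathways."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff):
        cur = c1
        nd = sd = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if _CODON_AA[nxt] == "*" and nxt != c2:
                blocked = True
            if _CODON_AA[nxt] == _CODON_AA[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((nd, sd, blocked))
    usable = [(nd, sd) for nd, sd, blocked in paths if not blocked]
    if not usable:
        usable = [(nd, sd) for nd, sd, _ in paths]
    n = len(usable)
    return (sum(p[0] for p in usable) / n, sum(p[1] for p in usable) / n)


def jukes_cantor(p: float) -> float:
    """Multiple-hit correction d = -(3/4) ln(1 - (4/3) p)."""
    if p == 0:
        return 0.0
    if p >= 0.75:
        raise SaturationError(
            f"proportion of differences {p:.4f} >= 3/4; "
            f"Jukes-Cantor distance undefined")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass
class NGPair:
    """Raw and corrected quantities of one NG86 pairwise comparison."""

    n_sites: float      # nonsynonymous sites (pair average)
    s_sites: float      # synonymous sites (pair average)
    nd: float           # observed nonsynonymous differences
    sd: float           # observed synonymous differences
    pn: float
    ps: float
    dn: float
    ds: float


def nei_gojobori_pair(seq_a: str, seq_b: str, correction: bool = True
                      ) -> NGPair:
    """NG86 pairwise dN/dS between two in-frame coding sequences.

    Codons containing an in-frame stop in either sequence are skipped
    with a warning. Raises :class:`SaturationError` when a Jukes-Cantor
    argument is out of range and :class:`MlstError` when no synonymous
    sites remain.
    """
    a, b = _check_sequences([seq_a, seq_b], minimum=2)
    if len(a) % 3 != 0:
        raise FormatError(f"length {len(a)} is not a multiple of 3")
    n_sites = s_sites = nd = sd = 0.0
    for i in range(0, len(a), 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        if _CODON_AA[ca] == "*" or _CODON_AA[cb] == "*":
            warnings.warn(
                f"in-frame stop codon at position {i + 1}; codon skipped",
                stacklevel=2)
            continue
        na, sa = _codon_site_counts(ca)
        nb, sb = _codon_site_counts(cb)
        n_sites += (na + nb) / 2.0
        s_sites += (sa + sb) / 2.0
        cn, cs = _codon_path_counts(ca, cb)
        nd += cn
        sd += cs
    if s_sites == 0:
        raise MlstError("zero synonymous sites; dS undefined")
    pn = nd / n_sites
    ps = sd / s_sites
    dn = jukes_cantor(pn) if correction else pn
    ds = jukes_cantor(ps) if correction else ps
    return NGPair(n_sites, s_sites, nd, sd, pn, ps, dn, ds)


def locus_dn_ds(sequences, weighting: str = "by_allele",
                frame_offset: int = 0
                ) -> tuple[float, float, float | None]:
    """Mean pairwise (dN, dS, dN/dS) for one locus.

    ``by_allele`` (default) averages over unordered pairs of *distinct*
    sequences — an allelic-variation summary; ``by_isolate`` averages over
    all isolate pairs. The ratio is reported as 0.0 when dN = 0 and as
    None ("undefined") when dS = 0 with dN > 0. ``frame_offset`` drops
    leading bases so that codon 1 starts at the fragment's reading frame;
    trailing partial codons are dropped.
    """
    if weighting not in ("by_allele", "by_isolate"):
        raise ValueError(f"unknown weighting {weighting!r}")
    seqs = _check_sequences(sequences, minimum=1)
    trimmed_len = (len(seqs[0]) - frame_offset) // 3 * 3
    seqs = [s[frame_offset:frame_offset + trimmed_len] for s in seqs]
    if weighting == "by_allele":
        seen = set()
        units = [s for s in seqs if not (s in seen or seen.add(s))]
    else:
        units = seqs
    pairs = list(combinations(units, 2))
    informative = [p for p in pairs if p[0] != p[1]]
    if not informative:
        return 0.0, 0.0, 0.0
    dn_sum = ds_sum = 0.0
    for x, y in informative:
        res = nei_gojobori_pair(x, y)
        dn_sum += res.dn
        ds_sum += res.ds
    dn = dn_sum / len(pairs)
    ds = ds_sum / len(pairs)
    if dn == 0.0:
        return dn, ds, 0.0
    if ds == 0.0:
        return dn, ds, None
    return dn, ds, dn / ds


@dataclass
class LocusStats:
    locus: str
    n_sequences: int
    n_alleles: int
    fragment_length: int
    polymorphic_sites: int
    gc_percent: float
    dn: float
    ds: float
    dn_ds: float | None   # None renders as "undefined"


def summarize_loci(sequences_by_locus: dict[str, list[tuple[str, str]]],
                   weighting: str = "by_allele",
                   frame_offsets: dict[str, int] | None = None
                   ) -> list[LocusStats]:
    """Per-locus summary over a shared isolate set.

    ``sequences_by_locus`` maps locus name -> [(isolate_id, sequence)].
    Locus order of the output follows the input dict order.
    """
    frame_offsets = frame_offsets or {}
    out = []
    for locus, records in sequences_by_locus.items():
        seqs = [seq.upper() for _, seq in records]
        if not seqs:
            raise FormatError(f"locus {locus}: no sequences")
        poly = count_polymorphic_sites(seqs) if len(seqs) > 1 else 0
        dn, ds, ratio = locus_dn_ds(seqs, weighting=weighting,
                                    frame_offset=frame_offsets.get(locus, 0))
        out.append(LocusStats(
            locus=locus,
            n_sequences=len(seqs),
            n_alleles=len(set(seqs)),
            fragment_length=len(seqs[0]),
            polymorphic_sites=poly,
            gc_percent=gc_content(seqs),
            dn=dn, ds=ds, dn_ds=ratio))
    return out


def stats_table_tsv(stats: list[LocusStats]) -> str:
    """Render locus summaries as a TSV table (one row per locus)."""
    header = ("locus\tn_sequences\tn_alleles\tfragment_length\t"
              "polymorphic_sites\tgc_percent\tdN\tdS\tdN_dS")
    lines = [header]
    for s in stats:
        ratio = "undefined" if s.dn_ds is None else f"{s.dn_ds:.4f}"
        lines.append("\t".join([
            s.locus, str(s.n_sequences), str(s.n_alleles),
            str(s.fragment_length), str(s.polymorphic_sites),
            f"{s.gc_percent:.2f}", f"{s.dn:.4f}", f"{s.ds:.4f}", ratio]))
    return "\n".join(lines) + "\n"
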