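"""In-silico typing: primer trimming, allele assignment, ST assignment.

The trimming step is the computational analogue of the PCR/sequencing
step: it locates the scheme primer pair in a finished sequence (either
orientation), removes the primer sites (sequencing-primer regions are
unreliable) and returns the internal fragment in the scheme's forward
orientation. Allele and ST numbers are assigned by exact sequence /
exact vector identity, in first-encounter order over the input.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .errors import (AmbiguityError, FormatError, FragmentLengthError,
                     MlstError, NovelAlleleError, NovelSTError,
                     PrimerNotFoundError)
from .io import reverse_complement
from .scheme import (UNAMBIGUOUS_DNA, AlleleDatabase, AllelicProfile, Locus,
                     ProfileTable, Scheme)

_IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def _mismatches(primer: str, window: str) -> int:
    n = 0
    for p, b in zip(primer, window):
        if b not in _IUPAC_SETS.get(p, p):
            n += 1
    return n


def _best_site(sequence: str, primer: str, budget: int) -> int | None:
    """Leftmost start of the best (fewest-mismatch) primer occurrence
    within the budget, or None."""
    best_pos, best_mm = None, budget + 1
    span = len(primer)
    for start in range(len(sequence) - span + 1):
        mm = _mismatches(primer, sequence[start:start + span])
        if mm < best_mm:
            best_pos, best_mm = start, mm
            if mm == 0:
                break
    return best_pos if best_mm <= budget else None


def trim_to_locus(sequence: str, locus: Locus,
                  max_primer_mismatches: int = 1,
                  length_tolerance: float = 0.10,
                  keep_primers: bool = False) -> str:
    """Extract the typed fragment between the locus primers.

    Both orientations of ``sequence`` are searched; the result is always
    in the scheme's forward orientation. Expected fragment length is
    ``amplicon_length - len(fwd) - len(rev)`` (or ``amplicon_length`` with
    ``keep_primers``); a relative deviation above ``length_tolerance``
    raises :class:`FragmentLengthError`.
    """
    seq = sequence.upper().replace("U", "T")
    fwd = locus.forward_primer
    rev_rc = reverse_complement(locus.reverse_primer)
    fragment = None
    for oriented in (seq, reverse_complement(seq)):
        fstart = _best_site(oriented, fwd, max_primer_mismatches)
        if fstart is None:
            continue
        tail = oriented[fstart + len(fwd):]
        # rightmost reverse-primer site -> maximal internal fragment
        rstart = None
        for cand in range(len(tail) - len(rev_rc), -1, -1):
            if _mismatches(rev_rc, tail[cand:cand + len(rev_rc)]) \
                    <= max_primer_mismatches:
                rstart = cand
                break
        if rstart is None:
            continue
        if keep_primers:
            fragment = oriented[fstart:fstart + len(fwd)] \
                + tail[:rstart + len(rev_rc)]
        else:
            fragment = tail[:rstart]
        break
    if fragment is None:
        raise PrimerNotFoundError(
            f"locus {locus.name}: primer not located within "
            f"{max_primer_mismatches} mismatch(es) in either orientation")
    expected = locus.amplicon_length
    if not keep_primers:
        expected -= len(locus.forward_primer) + len(locus.reverse_primer)
    if abs(len(fragment) - expected) > length_tolerance * expected:
        raise FragmentLengthError(
            f"locus {locus.name}: fragment length anomaly — got "
            f"{len(fragment)}, expected {expected} "
            f"(tolerance {length_tolerance:.0%})")
    return fragment


def assign_allele(fragment: str, locus: str, db: AlleleDatabase,
                  mode: str = "open") -> int:
    """Exact-match allele number for ``fragment`` at ``locus``.

    ``open``: unseen sequences are appended under the next free number.
    ``closed``: unseen sequences raise :class:`NovelAlleleError` and the
    database is left untouched. Ambiguity codes and length conflicts are
    hard errors — alleles are exact-sequence identities.
    """
    if mode not in ("open", "closed"):
        raise ValueError(f"mode must be 'open' or 'closed', got {mode!r}")
    seq = fragment.upper()
    bad = set(seq) - UNAMBIGUOUS_DNA
    if bad:
        raise AmbiguityError(
            f"locus {locus}: fragment contains ambiguous/invalid "
            f"character(s) {sorted(bad)}")
    length = db.allele_length(locus)
    if length is not None and len(seq) != length:
        raise FragmentLengthError(
            f"locus {locus}: length conflict — fragment is {len(seq)} bp, "
            f"alleles are {length} bp (indels are out of model)")
    number = db.lookup(locus, seq)
    if number is not None:
        return number
    if mode == "closed":
        raise NovelAlleleError(locus, seq)
    return db.add(locus, seq)


def assign_sts(profiles: list[AllelicProfile],
               st_definitions: dict[tuple[int, ...], int] | None = None,
               mode: str = "open") -> ProfileTable:
    """Assign STs to complete allelic profiles.

    Identical allele vectors always share an ST. In ``open`` mode novel
    vectors receive the next free ST number in first-encounter (input)
    order; in ``closed`` mode they raise :class:`NovelSTError`.
    """
    if mode not in ("open", "closed"):
        raise ValueError(f"mode must be 'open' or 'closed', got {mode!r}")
    defs = dict(st_definitions) if st_definitions else {}
    next_st = max(defs.values(), default=0) + 1
    lengths = {len(p.alleles) for p in profiles}
    if len(lengths) > 1:
        raise FormatError(f"inconsistent profile lengths {sorted(lengths)}")
    out = []
    for prof in profiles:
        vec = prof.alleles
        st = defs.get(vec)
        if st is None:
            if mode == "closed":
                raise NovelSTError(vec)
            st = next_st
            defs[vec] = st
            next_st += 1
        out.append(AllelicProfile(prof.isolate_id, vec, st=st,
                                  region=prof.region, source=prof.source))
    n_loci = len(out[0].alleles) if out else len(next(iter(defs), ()))
    table = ProfileTable(locus_names=tuple(f"locus{i+1}"
                                           for i in range(n_loci)),
                         profiles=out, st_definitions=defs)
    return table


@dataclass
class TypingOutcome:
    isolate_id: str
    locus: str
    status: str          # matched | novel | failed
    allele: int | None = None
    reason: str | None = None


@dataclass
class TypingReport:
    outcomes: list[TypingOutcome] = field(default_factory=list)
    failed_isolates: list[str] = field(default_factory=list)

    def to_tsv(self) -> str:
        lines = ["isolate\tlocus\tstatus\tallele\treason"]
        for o in self.outcomes:
            lines.append("\t".join([
                o.isolate_id, o.locus, o.status,
                "" if o.allele is None else str(o.allele), o.reason or ""]))
        return "\n".join(lines) + "\n"


def type_batch(sequences_by_locus: dict[str, list[tuple[str, str]]],
               scheme: Scheme,
               db: AlleleDatabase | None = None,
               st_definitions: dict[tuple[int, ...], int] | None = None,
               mode: str = "open",
               max_primer_mismatches: int = 1,
               trim: bool = True,
               length_tolerance: float = 0.10
               ) -> tuple[ProfileTable, TypingReport]:
    """Type a batch of isolates end to end.

    ``sequences_by_locus`` maps locus name -> [(isolate_id, sequence)].
    Isolates failing at any locus (missing, primer not located, novel
    allele in closed mode, ...) are excluded from the returned table and
    listed in the report; failures are never fatal for the batch.
    """
    if db is None:
        db = AlleleDatabase(scheme.locus_names)
    report = TypingReport()
    per_isolate: dict[str, dict[str, int]] = {}
    order: list[str] = []
    for locus_name in scheme.locus_names:
        for iso, _ in sequences_by_locus.get(locus_name, []):
            if iso not in per_isolate:
                per_isolate[iso] = {}
                order.append(iso)
    for locus in scheme.loci:
        seen = {iso: seq for iso, seq in
                sequences_by_locus.get(locus.name, [])}
        for iso in order:
            if iso not in seen:
                report.outcomes.append(TypingOutcome(
                    iso, locus.name, "failed", reason="missing sequence"))
                continue
            try:
                frag = seen[iso]
                if trim:
                    frag = trim_to_locus(
                        frag, locus,
                        max_primer_mismatches=max_primer_mismatches,
                        length_tolerance=length_tolerance)
                known = db.lookup(locus.name, frag.upper())
                allele = assign_allele(frag, locus.name, db, mode=mode)
                status = "matched" if known is not None else "novel"
                report.outcomes.append(TypingOutcome(
                    iso, locus.name, status, allele=allele))
                per_isolate[iso][locus.name] = allele
            except MlstError as exc:
                report.outcomes.append(TypingOutcome(
                    iso, locus.name, "failed", reason=str(exc)))
    complete, failed = [], []
    for iso in order:
        calls = per_isolate[iso]
        if len(calls) == scheme.n_loci:
            complete.append(AllelicProfile(
                iso, tuple(calls[n] for n in scheme.locus_names)))
        else:
            failed.append(iso)
    report.failed_isolates = failed
    table = assign_sts(complete, st_definitions, mode=mode)
    table.locus_names = scheme.locus_names
    return table, report
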