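"""Core MLST domain types.

A *scheme* is an ordered set of housekeeping-gene loci, each with a primer
pair and an expected amplicon size. Unique fragment sequences per locus are
numbered *alleles*; the vector of allele numbers across all loci is an
*allelic profile*; each unique profile is a *sequence type* (ST).

The locus order declared by the scheme is authoritative: it fixes the
column order of every profile table written or read by this package.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .errors import FormatError

IUPAC_DNA = set("ACGTRYSWKMBDHVN")
UNAMBIGUOUS_DNA = set("ACGT")


@dataclass(frozen=True)
class Locus:
    """One scheme locus: a gene fragment amplified by a primer pair.

    ``reference_span`` is a 1-based inclusive genome coordinate pair kept
    for documentation; it never enters any computation.
    """

    name: str
    forward_primer: str
    reverse_primer: str
    amplicon_length: int
    reference_span: tuple[int, int] | None = None

    def __post_init__(self):
        if not self.name:
            raise FormatError("locus name must be non-empty")
        for label, primer in (("forward", self.forward_primer),
                              ("reverse", self.reverse_primer)):
            if not primer:
                raise FormatError(f"locus {self.name}: {label} primer empty")
            bad = set(primer) - IUPAC_DNA
            if bad:
                raise FormatError(
                    f"locus {self.name}: non-IUPAC character(s) "
                    f"{sorted(bad)} in {label} primer")
        if self.amplicon_length <= 0:
            raise FormatError(
                f"locus {self.name}: amplicon_length must be positive")


@dataclass(frozen=True)
class Scheme:
    """Ordered, named collection of loci; order defines profile columns."""

    name: str
    loci: tuple[Locus, ...]

    def __post_init__(self):
        if len(self.loci) < 2:
            raise FormatError("a scheme needs at least 2 loci")
        names = [loc.name for loc in self.loci]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise FormatError(f"duplicate locus name(s): {dup}")

    @property
    def locus_names(self) -> tuple[str, ...]:
        return tuple(loc.name for loc in self.loci)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def locus(self, name: str) -> Locus:
        for loc in self.loci:
            if loc.name == name:
                return loc
        raise KeyError(name)


class AlleleDatabase:
    """Per-locus numbered unique sequences.

    Within a locus all sequences are distinct, equal-length (alleles are
    exact, indel-free identities) and numbered 1..k without gaps. Numbers
    read from file are authoritative and never reassigned.
    """

    def __init__(self, loci: tuple[str, ...] | list[str]):
        self.loci = tuple(loci)
        self._alleles: dict[str, dict[int, str]] = {n: {} for n in self.loci}
        self._index: dict[str, dict[str, int]] = {n: {} for n in self.loci}

    def alleles(self, locus: str) -> dict[int, str]:
        return dict(self._alleles[locus])

    def n_alleles(self, locus: str) -> int:
        return len(self._alleles[locus])

    def allele_length(self, locus: str) -> int | None:
        table = self._alleles[locus]
        if not table:
            return None
        return len(next(iter(table.values())))

    def sequence(self, locus: str, number: int) -> str:
        return self._alleles[locus][number]

    def lookup(self, locus: str, sequence: str) -> int | None:
        """Exact-match allele number, or None."""
        return self._index[locus].get(sequence)

    def add(self, locus: str, sequence: str, number: int | None = None) -> int:
        """Register a sequence under ``number`` (default: next free)."""
        seq = sequence.upper()
        bad = set(seq) - UNAMBIGUOUS_DNA
        if bad:
            raise FormatError(
                f"locus {locus}: allele sequence contains non-ACGT "
                f"character(s) {sorted(bad)}")
        table = self._alleles[locus]
        length = self.allele_length(locus)
        if length is not None and len(seq) != length:
            raise FormatError(
                f"locus {locus}: allele length {len(seq)} conflicts with "
                f"established length {length}")
        if seq in self._index[locus]:
            raise FormatError(
                f"locus {locus}: duplicate allele sequence "
                f"(already number {self._index[locus][seq]})")
        if number is None:
            number = len(table) + 1
        if number in table:
            raise FormatError(f"locus {locus}: allele number {number} reused")
        table[number] = seq
        self._index[locus][seq] = number
        return number

    def validate(self) -> None:
        """Check the 1..k-without-gaps numbering invariant."""
        for locus, table in self._alleles.items():
            if table and sorted(table) != list(range(1, len(table) + 1)):
                raise FormatError(
                    f"locus {locus}: allele numbers {sorted(table)} do not "
                    f"form 1..{len(table)}")


@dataclass
class AllelicProfile:
    """One isolate's allele-number vector (scheme locus order) plus
    optional ST and provenance metadata."""

    isolate_id: str
    alleles: tuple[int, ...]
    st: int | None = None
    region: str | None = None
    source: str | None = None

    def __post_init__(self):
        self.alleles = tuple(int(a) for a in self.alleles)
        if any(a < 1 for a in self.alleles):
            raise FormatError(
                f"isolate {self.isolate_id}: allele numbers must be >= 1")


@dataclass
class ProfileTable:
    """Profiles of a set of isolates plus the allele-vector -> ST map."""

    locus_names: tuple[str, ...]
    profiles: list[AllelicProfile] = field(default_factory=list)
    st_definitions: dict[tuple[int, ...], int] = field(default_factory=dict)

    def __post_init__(self):
        self.locus_names = tuple(self.locus_names)
        for prof in self.profiles:
            if len(prof.alleles) != len(self.locus_names):
                raise FormatError(
                    f"isolate {prof.isolate_id}: {len(prof.alleles)} alleles "
                    f"for {len(self.locus_names)} loci")

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    def __len__(self) -> int:
        return len(self.profiles)

    def st_of(self, alleles: tuple[int, ...]) -> int | None:
        return self.st_definitions.get(tuple(alleles))

    def st_counts(self) -> dict[int, int]:
        """ST -> number of isolates."""
        counts: dict[int, int] = {}
        for prof in self.profiles:
            if prof.st is None:
                continue
            counts[prof.st] = counts.get(prof.st, 0) + 1
        return counts

    def distinct_sts(self) -> dict[int, tuple[int, ...]]:
        """ST -> allele vector, sorted by ST number."""
        return {st: vec for vec, st in
                sorted(self.st_definitions.items(), key=lambda kv: kv[1])}

    def validate(self) -> None:
        sts = sorted(set(self.st_definitions.values()))
        if len(sts) != len(self.st_definitions):
            raise FormatError("two allele vectors map to the same ST")
        if sts and sts != list(range(1, len(sts) + 1)):
            raise FormatError(f"ST numbers {sts} do not form 1..{len(sts)}")
        for prof in self.profiles:
            if prof.st is not None:
                defined = self.st_definitions.get(prof.alleles)
                if defined != prof.st:
                    raise FormatError(
                        f"isolate {prof.isolate_id}: ST {prof.st} conflicts "
                        f"with definition {defined}")
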