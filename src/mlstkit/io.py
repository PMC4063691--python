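"""Readers and writers for schemes, FASTA files and profile tables.

Formats
-------
* Scheme config: YAML with a ``name`` key and a ``loci`` list of per-locus
  blocks (name, primers, amplicon_length, optional reference_span).
* Allele databases: one FASTA per locus, records named ``locus_number``
  (PubMLST convention, e.g. ``recA_1``).
* Profile tables: tab-separated, header
  ``isolate<TAB>locus1..locusL<TAB>ST[<TAB>region<TAB>source]``; column
  order must match the scheme's declared locus order. ST-definition tables
  (``ST<TAB>locus1..locusL``) are supported for PubMLST interchange.
"""
from __future__ import annotations

import warnings
from importlib import resources
from pathlib import Path

import yaml
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import FormatError
from .scheme import (IUPAC_DNA, UNAMBIGUOUS_DNA, AlleleDatabase,
                     AllelicProfile, Locus, ProfileTable, Scheme)


def read_scheme(path: str | Path) -> Scheme:
    """Load a scheme config file.

    Raises :class:`FormatError` (naming the locus) on missing fields,
    duplicate locus names or non-IUPAC primer characters.
    """
    with open(path) as handle:
        doc = yaml.safe_load(handle)
    if not isinstance(doc, dict) or "loci" not in doc:
        raise FormatError(f"{path}: scheme config needs a 'loci' list")
    loci = []
    for block in doc["loci"]:
        name = block.get("name")
        if not name:
            raise FormatError(f"{path}: locus block without a name")
        for key in ("forward_primer", "reverse_primer", "amplicon_length"):
            if key not in block:
                raise FormatError(f"{path}: locus {name} missing '{key}'")
        span = block.get("reference_span")
        loci.append(Locus(
            name=str(name),
            forward_primer=str(block["forward_primer"]).upper(),
            reverse_primer=str(block["reverse_primer"]).upper(),
            amplicon_length=int(block["amplicon_length"]),
            reference_span=tuple(span) if span else None,
        ))
    return Scheme(name=str(doc.get("name", Path(path).stem)),
                  loci=tuple(loci))


def load_default_scheme() -> Scheme:
    """The bundled eight-locus *Leuconostoc lactis* scheme
    (carB, groEL, murC, pheS, pyrG, recA, rpoB, uvrC)."""
    ref = resources.files("mlstkit") / "data" / "leuconostoc_lactis.yaml"
    with resources.as_file(ref) as path:
        return read_scheme(path)


def write_scheme(scheme: Scheme, path: str | Path) -> None:
    doc = {"name": scheme.name, "loci": []}
    for loc in scheme.loci:
        block = {
            "name": loc.name,
            "forward_primer": loc.forward_primer,
            "reverse_primer": loc.reverse_primer,
            "amplicon_length": loc.amplicon_length,
        }
        if loc.reference_span:
            block["reference_span"] = list(loc.reference_span)
        doc["loci"].append(block)
    with open(path, "w") as handle:
        yaml.safe_dump(doc, handle, sort_keys=False)


def read_locus_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read per-isolate sequences for one locus.

    Isolate id = first whitespace-delimited header token. Sequences are
    uppercased and U is mapped to T. IUPAC ambiguity codes are accepted
    with a warning; anything else is an error naming the record.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        residues = set(seq)
        bad = residues - IUPAC_DNA
        if bad:
            raise FormatError(
                f"{path}: record {rec.id} contains non-nucleotide "
                f"character(s) {sorted(bad)}")
        if residues - UNAMBIGUOUS_DNA:
            warnings.warn(
                f"{path}: record {rec.id} contains IUPAC ambiguity codes; "
                f"it cannot be allele-assigned", stacklevel=2)
        records.append((rec.id, seq))
    if not records:
        raise FormatError(f"{path}: empty FASTA")
    return records


def write_locus_fasta(records: list[tuple[str, str]], path: str | Path,
                      width: int = 70) -> None:
    with open(path, "w") as handle:
        for name, seq in records:
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i:i + width] + "\n")


def read_allele_fasta(path: str | Path, locus: str,
                      db: AlleleDatabase) -> AlleleDatabase:
    """Load numbered alleles (``locus_number`` headers) into ``db``.

    Numbers from the file are authoritative; the 1..k invariant is checked
    after loading.
    """
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        try:
            prefix, number = name.rsplit("_", 1)
            number = int(number)
        except ValueError:
            raise FormatError(
                f"{path}: allele header '{name}' is not locus_number") from None
        if prefix != locus:
            raise FormatError(
                f"{path}: allele {name} does not belong to locus {locus}")
        db.add(locus, str(rec.seq).upper().replace("U", "T"), number=number)
    db.validate()
    return db


def write_allele_fasta(db: AlleleDatabase, locus: str,
                       path: str | Path) -> None:
    records = [(f"{locus}_{num}", seq)
               for num, seq in sorted(db.alleles(locus).items())]
    write_locus_fasta(records, path)


def _check_locus_header(columns: list[str], locus_names, path, first: str):
    expected = [first, *locus_names]
    if columns[:len(expected)] != expected:
        raise FormatError(
            f"{path}: header columns {columns[:len(expected)]} do not match "
            f"scheme locus order {expected}")


def read_profiles_tsv(path: str | Path,
                      scheme: Scheme | None = None) -> ProfileTable:
    """Read an isolate profile table.

    Columns: ``isolate``, one per locus, ``ST``, optional ``region`` and
    ``source``. When ``scheme`` is given the locus columns must appear in
    the scheme's declared order.
    """
    with open(path) as handle:
        lines = handle.read().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty profile table")
    header = lines[0].split("\t")
    if header[0] != "isolate" or "ST" not in header:
        raise FormatError(
            f"{path}: header must start with 'isolate' and contain 'ST'")
    st_col = header.index("ST")
    locus_names = tuple(header[1:st_col])
    if scheme is not None:
        _check_locus_header(header, scheme.locus_names, path, "isolate")
        locus_names = scheme.locus_names
    extras = header[st_col + 1:]
    table = ProfileTable(locus_names=locus_names)
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < st_col + 1:
            raise FormatError(f"{path}:{lineno}: expected at least "
                              f"{st_col + 1} columns, got {len(fields)}")
        try:
            alleles = tuple(int(x) for x in fields[1:st_col])
            st = int(fields[st_col])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer value "
                              f"({exc})") from None
        meta = dict(zip(extras, fields[st_col + 1:]))
        prof = AllelicProfile(isolate_id=fields[0], alleles=alleles, st=st,
                              region=meta.get("region") or None,
                              source=meta.get("source") or None)
        existing = table.st_definitions.get(alleles)
        if existing is None:
            table.st_definitions[alleles] = st
        elif existing != st:
            raise FormatError(
                f"{path}:{lineno}: allele vector already defined as "
                f"ST {existing}, not {st}")
        table.profiles.append(prof)
    table.validate()
    return table


def write_profiles_tsv(table: ProfileTable, path: str | Path) -> None:
    has_meta = any(p.region or p.source for p in table.profiles)
    with open(path, "w") as handle:
        header = ["isolate", *table.locus_names, "ST"]
        if has_meta:
            header += ["region", "source"]
        handle.write("\t".join(header) + "\n")
        for prof in table.profiles:
            row = [prof.isolate_id,
                   *(str(a) for a in prof.alleles),
                   "" if prof.st is None else str(prof.st)]
            if has_meta:
                row += [prof.region or "", prof.source or ""]
            handle.write("\t".join(row) + "\n")


def read_st_definitions_tsv(path: str | Path,
                            scheme: Scheme | None = None
                            ) -> tuple[tuple[str, ...],
                                       dict[tuple[int, ...], int]]:
    """PubMLST-style ST definition table: ``ST<TAB>locus1..locusL``."""
    with open(path) as handle:
        lines = handle.read().splitlines()
    header = lines[0].split("\t")
    if header[0] != "ST":
        raise FormatError(f"{path}: first column must be 'ST'")
    locus_names = tuple(c for c in header[1:] if c != "clonal_complex")
    if scheme is not None and locus_names != scheme.locus_names:
        raise FormatError(
            f"{path}: locus columns {locus_names} do not match scheme "
            f"order {scheme.locus_names}")
    defs: dict[tuple[int, ...], int] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        try:
            st = int(fields[0])
            vec = tuple(int(x) for x in fields[1:1 + len(locus_names)])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer value "
                              f"({exc})") from None
        defs[vec] = st
    return locus_names, defs


def write_st_definitions_tsv(locus_names, st_definitions,
                             path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("\t".join(["ST", *locus_names]) + "\n")
        for vec, st in sorted(st_definitions.items(), key=lambda kv: kv[1]):
            handle.write("\t".join([str(st), *(str(a) for a in vec)]) + "\n")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
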