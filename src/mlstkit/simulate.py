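"""Synthetic scheme, allele and population generator.

Provides ground truth for every analysis module without external data.
The defaults mirror the study conditions this toolkit is built around: an
eight-locus housekeeping scheme, ~500-700 bp in-frame fragments at
43-48% GC, 50 isolates, a handful of alleles per locus with 3-9
segregating sites, mutations dominated by synonymous changes (strong
purifying selection), and either a clonal population (founders plus
single-locus-variant descendants, the eBURST "star" pattern) or a
panmictic one (independent allele draws per locus, linkage equilibrium
by construction).

Everything is bit-reproducible given (parameters, seed).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .calling import assign_sts
from .errors import FormatError
from .io import (reverse_complement, write_locus_fasta, write_profiles_tsv,
                 write_scheme)
from .scheme import AlleleDatabase, AllelicProfile, Locus, ProfileTable, Scheme
from .stats import _CODON_AA

_BASES = "ACGT"


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)


def _random_dna(rng, length: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return "".join(rng.choice(list(_BASES), size=length, p=p))


def _random_coding(rng, length: int, gc: float) -> str:
    """In-frame fragment with no internal stop codons."""
    if length % 3 != 0:
        raise FormatError(f"fragment length {length} not divisible by 3")
    codons = []
    for _ in range(length // 3):
        while True:
            codon = _random_dna(rng, 3, gc)
            if _CODON_AA[codon] != "*":
                codons.append(codon)
                break
    return "".join(codons)


@dataclass
class SimScheme:
    scheme: Scheme
    references: dict[str, str]      # locus -> reference fragment (frame 1)

    def amplicon(self, locus_name: str, fragment: str | None = None) -> str:
        """Embed a fragment between the locus primers."""
        loc = self.scheme.locus(locus_name)
        frag = self.references[locus_name] if fragment is None else fragment
        return loc.forward_primer + frag \
            + reverse_complement(loc.reverse_primer)


def gen_scheme(n_loci: int = 8, fragment_lengths=510,
               gc_target: float = 0.45, seed=0) -> SimScheme:
    """Random scheme: in-frame reference fragments at the requested GC,
    flanked by synthesized 18-22 bp primers so trimming round-trips."""
    rng = _rng(seed)
    if isinstance(fragment_lengths, int):
        fragment_lengths = [fragment_lengths] * n_loci
    if len(fragment_lengths) != n_loci:
        raise FormatError("need one fragment length per locus")
    loci = []
    refs = {}
    for i, frag_len in enumerate(fragment_lengths):
        name = f"locus{i + 1:02d}"
        fragment = _random_coding(rng, frag_len, gc_target)
        fwd = _random_dna(rng, int(rng.integers(18, 23)), 0.5)
        rev = _random_dna(rng, int(rng.integers(18, 23)), 0.5)
        loci.append(Locus(name=name, forward_primer=fwd, reverse_primer=rev,
                          amplicon_length=len(fwd) + frag_len + len(rev)))
        refs[name] = fragment
    return SimScheme(scheme=Scheme(name="synthetic", loci=tuple(loci)),
                     references=refs)


def _mutation_effect(codon: str, pos: int, alt: str) -> str | None:
    """'syn'/'nonsyn' for a single-base change, None if it creates a stop."""
    mutant = codon[:pos] + alt + codon[pos + 1:]
    if _CODON_AA[mutant] == "*":
        return None
    return "syn" if _CODON_AA[mutant] == _CODON_AA[codon] else "nonsyn"


def gen_alleles(reference: str, n_alleles: int, n_sites: int,
                synonymous_fraction: float = 0.9, seed=0
                ) -> tuple[list[str], dict]:
    """Allele set with exactly ``n_sites`` planted segregating sites.

    Each site is a single-base change in its own codon; its effect is
    drawn synonymous with probability ``synonymous_fraction`` (rejection
    sampling over positions/bases for the requested effect). Allele 1 is
    the reference; every other allele carries a distinct non-empty subset
    of the sites, and every site segregates. The truth table records site
    positions, bases and effects.
    """
    rng = _rng(seed)
    if n_alleles < 2:
        raise FormatError(
            "n_alleles must be >= 2: a single allele cannot carry "
            "segregating sites")
    if n_sites < 1:
        raise FormatError("n_sites must be >= 1")
    if 2 ** n_sites - 1 < n_alleles - 1:
        raise FormatError(
            f"{n_sites} sites support at most {2 ** n_sites} distinct "
            f"alleles, {n_alleles} requested")
    n_codons = len(reference) // 3
    if n_sites > n_codons:
        raise FormatError("more sites than codons (one site per codon)")
    sites = []
    used_codons: set[int] = set()
    for _ in range(n_sites):
        want_syn = rng.random() < synonymous_fraction
        for _attempt in range(10000):
            ci = int(rng.integers(n_codons))
            if ci in used_codons:
                continue
            codon = reference[3 * ci:3 * ci + 3]
            pos = int(rng.integers(3))
            alt = _BASES[int(rng.integers(4))]
            if alt == codon[pos]:
                continue
            effect = _mutation_effect(codon, pos, alt)
            if effect is None:
                continue
            if (effect == "syn") == want_syn:
                used_codons.add(ci)
                sites.append({"position": 3 * ci + pos,
                              "ref": codon[pos], "alt": alt,
                              "effect": effect})
                break
        else:
            raise FormatError(
                "could not place a mutation with the requested effect")
    sites.sort(key=lambda s: s["position"])
    # distinct non-empty site subsets covering every site
    for _attempt in range(10000):
        masks = set()
        while len(masks) < n_alleles - 1:
            mask = int(rng.integers(1, 2 ** n_sites))
            masks.add(mask)
        combined = 0
        for m in masks:
            combined |= m
        if combined == 2 ** n_sites - 1:
            break
    else:
        raise FormatError("could not cover all sites with allele subsets")
    alleles = [reference]
    ordered_masks = sorted(masks)
    for mask in ordered_masks:
        seq = list(reference)
        for bit, site in enumerate(sites):
            if mask >> bit & 1:
                seq[site["position"]] = site["alt"]
        alleles.append("".join(seq))
    truth = {"sites": sites,
             "n_sites": n_sites,
             "allele_masks": [0] + ordered_masks,
             "n_synonymous": sum(s["effect"] == "syn" for s in sites)}
    return alleles, truth


@dataclass
class SimDataset:
    sim_scheme: SimScheme
    db: AlleleDatabase
    table: ProfileTable
    truth: dict
    sequences_by_locus: dict[str, list[tuple[str, str]]] = \
        field(default_factory=dict)

    @property
    def scheme(self) -> Scheme:
        return self.sim_scheme.scheme


def gen_population(mode: str, n_isolates: int, db: AlleleDatabase,
                   scheme: Scheme, seed=0, n_founders: int = 2,
                   descent_p: float = 0.5, max_depth: int | None = None
                   ) -> tuple[ProfileTable, dict]:
    """Allelic profiles under a clonal or panmictic model.

    clonal: ``n_founders`` founders maximally separated (distinct alleles
    at every locus); each isolate descends from a founder through a
    geometric(``descent_p``) number of single-locus allele changes
    (depth 0 = the founder itself), yielding founder-centred SLV stars;
    ``max_depth`` caps the depth (e.g. at the clonal-complex radius so
    every descendant stays groupable with its founder).
    panmictic: every locus drawn independently and uniformly from its
    allele set — linkage equilibrium by construction.
    """
    rng = _rng(seed)
    locus_names = scheme.locus_names
    k = {name: db.n_alleles(name) for name in locus_names}
    if any(v < 1 for v in k.values()):
        raise FormatError("every locus needs at least one allele")
    profiles: list[AllelicProfile] = []
    truth: dict = {"mode": mode}
    if n_isolates == 0:
        table = assign_sts([], {})
        table.locus_names = locus_names
        return table, truth
    if mode == "panmictic":
        for i in range(n_isolates):
            vec = tuple(int(rng.integers(1, k[name] + 1))
                        for name in locus_names)
            profiles.append(AllelicProfile(f"iso{i + 1:04d}", vec))
    elif mode == "clonal":
        if any(v < n_founders for v in k.values()):
            raise FormatError(
                f"clonal mode with {n_founders} founders needs >= "
                f"{n_founders} alleles at every locus")
        founders = []
        perms = {name: rng.permutation(k[name]) + 1 for name in locus_names}
        for f in range(n_founders):
            founders.append(tuple(int(perms[name][f])
                                  for name in locus_names))
        assignment = []
        depths = []
        for i in range(n_isolates):
            f = int(rng.integers(n_founders))
            depth = int(rng.geometric(descent_p)) - 1
            if max_depth is not None:
                depth = min(depth, max_depth)
            vec = list(founders[f])
            for _ in range(depth):
                j = int(rng.integers(len(locus_names)))
                if k[locus_names[j]] < 2:
                    continue
                while True:
                    new = int(rng.integers(1, k[locus_names[j]] + 1))
                    if new != vec[j]:
                        vec[j] = new
                        break
            assignment.append(f)
            depths.append(depth)
            profiles.append(AllelicProfile(f"iso{i + 1:04d}", tuple(vec)))
        truth["founders"] = [list(f) for f in founders]
        truth["founder_of_isolate"] = assignment
        truth["depths"] = depths
    else:
        raise ValueError(f"unknown mode {mode!r}")
    table = assign_sts(profiles, {})
    table.locus_names = locus_names
    truth["n_sts"] = len(table.st_definitions)
    return table, truth


def simulate_dataset(mode: str = "clonal", n_isolates: int = 50,
                     n_loci: int = 8, fragment_lengths=510,
                     n_alleles=None, n_sites=None,
                     synonymous_fraction: float = 0.9,
                     gc_target: float = 0.45, seed: int = 0,
                     n_founders: int = 2, descent_p: float = 0.5
                     ) -> SimDataset:
    """Full synthetic dataset: scheme + allele databases + population +
    per-isolate amplicon sequences (primers attached), with truth labels.

    ``n_alleles``/``n_sites`` may be ints or per-locus lists; defaults
    draw 3-8 alleles and 3-9 sites per locus.
    """
    rng = _rng(seed)
    sim = gen_scheme(n_loci=n_loci, fragment_lengths=fragment_lengths,
                     gc_target=gc_target, seed=rng)
    scheme = sim.scheme
    db = AlleleDatabase(scheme.locus_names)
    allele_truth = {}
    for name in scheme.locus_names:
        ka = (n_alleles if isinstance(n_alleles, int)
              else n_alleles[name] if n_alleles else int(rng.integers(3, 9)))
        ks = (n_sites if isinstance(n_sites, int)
              else n_sites[name] if n_sites else int(rng.integers(3, 10)))
        alleles, truth = gen_alleles(sim.references[name], ka, ks,
                                     synonymous_fraction, seed=rng)
        for seq in alleles:
            db.add(name, seq)
        allele_truth[name] = truth
    table, pop_truth = gen_population(mode, n_isolates, db, scheme,
                                      seed=rng, n_founders=n_founders,
                                      descent_p=descent_p)
    sequences = {name: [] for name in scheme.locus_names}
    for prof in table.profiles:
        for j, name in enumerate(scheme.locus_names):
            frag = db.sequence(name, prof.alleles[j])
            sequences[name].append((prof.isolate_id, sim.amplicon(name, frag)))
    truth = {"alleles": allele_truth, "population": pop_truth,
             "n_sts": pop_truth.get("n_sts", 0)}
    return SimDataset(sim_scheme=sim, db=db, table=table, truth=truth,
                      sequences_by_locus=sequences)


def write_dataset(dataset: SimDataset, out_dir: str | Path) -> None:
    """Emit scheme config, per-locus FASTAs, profiles.tsv and truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_scheme(dataset.scheme, out / "scheme.yaml")
    for name, records in dataset.sequences_by_locus.items():
        write_locus_fasta(records, out / f"{name}.fasta")
    write_profiles_tsv(dataset.table, out / "profiles.tsv")
    with open(out / "truth.json", "w") as handle:
        json.dump(dataset.truth, handle, indent=2, sort_keys=True)
        handle.write("\n")
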