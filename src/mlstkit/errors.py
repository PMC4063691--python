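"""Exception hierarchy.

All data-level failures raise :class:`MlstError` subclasses so callers (and
the CLI) can distinguish bad input (exit code 1) from usage errors (exit
code 2).
"""


class MlstError(Exception):
    """Base class for all mlstkit data errors."""


class FormatError(MlstError):
    """Malformed scheme/FASTA/profile input; message names the offending
    locus, record or line."""


class PrimerNotFoundError(MlstError):
    """Neither orientation of the query contains the primer pair within the
    mismatch budget ("primer not located")."""


class FragmentLengthError(MlstError):
    """Trimmed fragment length deviates from the scheme expectation by more
    than the tolerance ("fragment length anomaly"), or an allele candidate
    does not match the established allele length ("length conflict")."""


class AmbiguityError(MlstError):
    """IUPAC ambiguity code encountered where an exact A/C/G/T sequence is
    required (allele assignment, site counting)."""


class NovelAlleleError(MlstError):
    """Closed-mode allele lookup found no exact match."""

    def __init__(self, locus: str, sequence: str):
        super().__init__(f"novel allele at locus {locus}")
        self.locus = locus
        self.sequence = sequence


class NovelSTError(MlstError):
    """Closed-mode ST lookup found no matching allelic profile."""

    def __init__(self, alleles: tuple):
        super().__init__(f"novel ST for allele vector {alleles}")
        self.alleles = alleles


class SaturationError(MlstError):
    """Jukes-Cantor correction undefined (proportion of differences >= 3/4)."""


class NoVariationError(MlstError):
    """Statistic undefined because every locus is monomorphic."""
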