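"""Core domain types shared by every analysis stage.

All coordinates use a single internal convention: 0-based, half-open
``[start, end)`` intervals, the BED convention.  GFF3 input (1-based,
inclusive) is converted on read and back on write; nothing downstream
ever sees 1-based coordinates.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

PLUS = "+"
MINUS = "-"
UNSTRANDED = "."

#: Transposable-element family vocabulary and the element class each family
#: belongs to.  Retroelements transpose through an RNA intermediate; DNA
#: elements move directly.
TE_FAMILY_CLASS: dict[str, str] = {
    "Copia": "retroelement",
    "Gypsy": "retroelement",
    "LINE": "retroelement",
    "SINE": "retroelement",
    "hAT": "DNA element",
    "En-Spm": "DNA element",
    "MITE": "DNA element",
    "Mutator": "DNA element",
    "Helitron": "DNA element",
    "Unclassified": "DNA element",
}

#: Default aliases mapping RepeatMasker/Repbase class/family strings onto the
#: ten-family vocabulary above.  Matching is case-insensitive on the last
#: path component ("LTR/Gypsy" -> "Gypsy").
TE_FAMILY_ALIASES: dict[str, str] = {
    "copia": "Copia",
    "ltr/copia": "Copia",
    "gypsy": "Gypsy",
    "ltr/gypsy": "Gypsy",
    "line": "LINE",
    "sine": "SINE",
    "hat": "hAT",
    "dna/hat": "hAT",
    "en-spm": "En-Spm",
    "enspm": "En-Spm",
    "cmc-enspm": "En-Spm",
    "dna/en-spm": "En-Spm",
    "mite": "MITE",
    "mutator": "Mutator",
    "mudr": "Mutator",
    "dna/mudr": "Mutator",
    "helitron": "Helitron",
    "rc/helitron": "Helitron",
    "unclassified": "Unclassified",
    "unknown": "Unclassified",
}


class ParseError(ValueError):
    """Raised when an input file does not conform to its declared dialect."""


class ConfigurationError(ValueError):
    """Raised for invalid parameter combinations."""


class DataError(ValueError):
    """Raised when inputs are mutually inconsistent (e.g. unknown chromosome)."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = UNSTRANDED

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in (PLUS, MINUS, UNSTRANDED):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Any-overlap (>= 1 bp) under half-open arithmetic.

        Intervals that merely touch (``self.end == other.start``) do NOT
        overlap; this keeps all region counts bit-stable.
        """
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        """True if ``other`` lies fully inside this interval."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def expanded(self, flank: int) -> "GenomicInterval":
        """The interval enlarged by ``flank`` bp on both sides (clipped at 0)."""
        if flank < 0:
            raise ConfigurationError("flank must be non-negative")
        return GenomicInterval(
            self.chrom, max(0, self.start - flank), self.end + flank, self.strand
        )


@dataclass
class GeneModel:
    """A gene locus with its TE-relatedness flag and optional annotations."""

    gene_id: str
    interval: GenomicInterval
    is_te_related: bool = False
    tf_family: Optional[str] = None
    expression: Optional[float] = None

    def __post_init__(self) -> None:
        if self.expression is not None:
            e = float(self.expression)
            if e != e or e in (float("inf"), float("-inf")):
                raise ValueError(f"expression for {self.gene_id} must be finite")

    @property
    def length(self) -> int:
        return len(self.interval)


@dataclass
class TEFeature:
    """One annotated transposable-element copy."""

    te_id: str
    interval: GenomicInterval
    family: str
    te_class: str = ""

    def __post_init__(self) -> None:
        expected = TE_FAMILY_CLASS.get(self.family)
        if expected is None:
            # family outside the default vocabulary: an explicit class is
            # required (the vocabulary is configurable, the class is not)
            if self.te_class not in ("retroelement", "DNA element"):
                raise ValueError(
                    f"unknown TE family {self.family!r} requires an explicit "
                    "te_class of 'retroelement' or 'DNA element'"
                )
        elif not self.te_class:
            self.te_class = expected
        elif self.te_class != expected:
            raise ValueError(
                f"te_class {self.te_class!r} inconsistent with family "
                f"{self.family!r} (expected {expected!r})"
            )


@dataclass
class Peak(object):
    """An enriched interval called from one ChIP sample.

    ``summit`` is a 0-based offset within the interval; ``tag_count`` is the
    number of sequence tags supporting the peak (0 if the caller's output
    did not carry one).
    """

    sample: str
    interval: GenomicInterval
    summit: Optional[int] = None
    tag_count: int = 0
    score: Optional[float] = None
    peak_id: str = ""

    def __post_init__(self) -> None:
        if self.summit is not None and not (0 <= self.summit < len(self.interval)):
            raise ValueError(
                f"summit {self.summit} outside [0, {len(self.interval)})"
            )
        if self.tag_count < 0:
            raise ValueError("tag_count must be non-negative")


@dataclass(frozen=True)
class ReadTag:
    """A mapped sequencing tag, reduced to its 5' position and strand."""

    chrom: str
    five_prime_pos: int
    strand: str
    length: int

    def __post_init__(self) -> None:
        if self.five_prime_pos < 0:
            raise ValueError("five_prime_pos must be >= 0")
        if self.length <= 0:
            raise ValueError("length must be positive")
        if self.strand not in (PLUS, MINUS):
            raise ValueError(f"read strand must be + or -, got {self.strand!r}")


@dataclass
class CategoryMap:
    """gene_id -> set of category labels, with the size of the gene universe.

    ``universe_size`` is the total number of genes N from which selections are
    drawn; it may exceed the number of mapped genes when the map covers only
    part of the universe.
    """

    mapping: dict[str, set[str]] = field(default_factory=dict)
    universe_size: int = 0

    def __post_init__(self) -> None:
        if self.universe_size <= 0:
            raise ValueError("universe_size must be positive")
        if self.universe_size < len(self.mapping):
            raise ValueError(
                f"universe_size {self.universe_size} smaller than number of "
                f"mapped genes {len(self.mapping)}"
            )

    def category_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for cats in self.mapping.values():
            for c in cats:
                sizes[c] = sizes.get(c, 0) + 1
        return sizes

    def genes_in(self, category: str) -> set[str]:
        return {g for g, cats in self.mapping.items() if category in cats}


def normalize_te_family(raw: str, aliases: Optional[dict[str, str]] = None) -> str:
    """Map a RepeatMasker class/family string onto the family vocabulary.

    Tries the full string, then the part after the last '/', case-insensitive.
    Unrecognised names fall back to ``Unclassified``.
    """
    table = TE_FAMILY_ALIASES if aliases is None else aliases
    for key in (raw.lower(), raw.lower().split("/")[-1]):
        if key in table:
            return table[key]
    if raw in TE_FAMILY_CLASS:
        return raw
    return "Unclassified"
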