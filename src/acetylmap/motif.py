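"""Inverted-repeat motif scanning and telomere-repeat read screening.

The binding motif is modelled as a conserved half site (IUPAC consensus,
default GATGGGCCGA) followed, after a short spacer, by its own reverse
complement on the same strand — an inverted repeat.  The scanner reports
every position where the half site matches with at most ``max_mismatch``
mismatches per half and the reverse-complement half follows within the
allowed spacer range; overlapping hits are all reported, and a hit is
described canonically with its leading half on the forward strand (the same
inverted repeat read from the other strand is the identical footprint, not
a second hit).  ``N`` never matches anything.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .enrich import EnrichmentResult, hypergeom_upper_tail
from .model import DataError, GeneModel, GenomicInterval, ParseError

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifSpec:
    """Inverted-repeat consensus: half site, mismatch budget and spacer."""

    half_site: str = "GATGGGCCGA"
    max_mismatch: int = 1
    spacer_min: int = 0
    spacer_max: int = 11
    total_window: int = 31

    def __post_init__(self) -> None:
        hs = self.half_site.upper()
        if not hs or any(b not in IUPAC for b in hs):
            raise ValueError(f"half_site {self.half_site!r} is not IUPAC")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        if not 0 <= self.spacer_min <= self.spacer_max:
            raise ValueError("need 0 <= spacer_min <= spacer_max")
        if 2 * len(hs) + self.spacer_min > self.total_window:
            raise ValueError("half sites plus minimum spacer exceed the window")
        object.__setattr__(self, "half_site", hs)


@dataclass(frozen=True)
class MotifHit:
    """One inverted-repeat occurrence; footprint = 2*|half| + spacer."""

    chrom: str
    start: int
    end: int
    strand: str
    mismatch_lead: int
    mismatch_trail: int
    spacer: int

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)


def _encode(sequence: str) -> np.ndarray:
    seq = sequence.upper()
    codes = np.empty(len(seq), dtype=np.int8)
    for i, base in enumerate(seq):
        code = _BASE_CODE.get(base)
        if code is None:
            raise ParseError(f"non-nucleotide character {base!r} at position {i}")
        codes[i] = code
    return codes


def _mismatch_counts(codes: np.ndarray, pattern: str) -> np.ndarray:
    """Mismatches of ``pattern`` at every start position (IUPAC-aware).

    Positions too close to the end get a count of len(pattern)+1 so they can
    never qualify.  An ``N`` in the sequence matches nothing.
    """
    L = len(pattern)
    n_starts = len(codes) - L + 1
    if n_starts <= 0:
        return np.empty(0, dtype=np.int32)
    mm = np.zeros(n_starts, dtype=np.int32)
    for j, sym in enumerate(pattern):
        allowed = np.zeros(5, dtype=bool)
        for b in IUPAC[sym]:
            allowed[_BASE_CODE[b]] = True
        # index 4 == N stays False: N never matches
        mm += ~allowed[codes[j: j + n_starts]]
    return mm


def scan_inverted_repeat(
    sequence: str, spec: MotifSpec = MotifSpec(), chrom: str = "seq"
) -> list[MotifHit]:
    """All inverted-repeat occurrences of ``spec`` in ``sequence``.

    Reports every (position, spacer) combination whose leading half matches
    the consensus and whose trailing half matches its reverse complement,
    each within the mismatch budget.  Overlapping hits are all kept.
    """
    if not sequence:
        return []
    codes = _encode(sequence)
    half = spec.half_site
    L = len(half)
    mm_lead = _mismatch_counts(codes, half)
    mm_trail = _mismatch_counts(codes, reverse_complement(half))
    lead_ok = np.where(mm_lead <= spec.max_mismatch)[0]
    hits: list[MotifHit] = []
    for s1 in lead_ok:
        for spacer in range(spec.spacer_min, spec.spacer_max + 1):
            s2 = s1 + L + spacer
            if s2 >= mm_trail.size:
                break
            if mm_trail[s2] <= spec.max_mismatch:
                hits.append(
                    MotifHit(
                        chrom=chrom,
                        start=int(s1),
                        end=int(s2 + L),
                        strand="+",
                        mismatch_lead=int(mm_lead[s1]),
                        mismatch_trail=int(mm_trail[s2]),
                        spacer=spacer,
                    )
                )
    return hits


def genes_with_motif(
    genome: Mapping[str, str],
    genes: Sequence[GeneModel],
    spec: MotifSpec = MotifSpec(),
    flank: int = 2000,
) -> set[str]:
    """IDs of genes with >= 1 inverted-repeat hit in body +/- flank.

    ``genome`` maps chromosome name -> sequence (a pyfaidx.Fasta works via
    ``str(fasta[chrom])`` upstream).  Each chromosome is scanned once and
    hits are assigned to genes by interval overlap; gene windows are clipped
    to chromosome bounds.
    """
    hits_by_chrom: dict[str, np.ndarray] = {}
    for chrom, seq in genome.items():
        hits = scan_inverted_repeat(str(seq), spec, chrom=chrom)
        hits_by_chrom[chrom] = np.asarray(
            sorted((h.start, h.end) for h in hits), dtype=np.int64
        ).reshape(-1, 2)
    out: set[str] = set()
    for g in genes:
        iv = g.interval
        if iv.chrom not in hits_by_chrom:
            raise DataError(f"chromosome {iv.chrom!r} absent from the genome")
        hits = hits_by_chrom[iv.chrom]
        if hits.size == 0:
            continue
        lo = max(0, iv.start - flank)
        hi = min(len(genome[iv.chrom]), iv.end + flank)
        if bool(np.any((hits[:, 0] < hi) & (hits[:, 1] > lo))):
            out.add(g.gene_id)
    return out


def motif_enrichment(
    bound_genes: Iterable[str],
    motif_genes: Iterable[str],
    universe_size: int,
) -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment of motif genes among bound genes."""
    bound = set(bound_genes)
    motif = set(motif_genes)
    if not bound:
        raise ValueError("empty bound-gene set")
    k = len(bound & motif)
    r = EnrichmentResult(
        category="inverted_repeat",
        k=k,
        n=len(bound),
        K=len(motif),
        N=universe_size,
        method="hypergeometric",
        p=hypergeom_upper_tail(k, len(bound), len(motif), universe_size),
    )
    r.q = r.p
    return r


def count_reads_with_repeat(
    reads: Iterable[str], unit: str = "TTTAGGG", min_copies: int = 2
) -> int:
    """Reads containing >= min_copies tandem copies of ``unit`` on either
    strand (telomere-repeat screen)."""
    if not unit:
        raise ValueError("unit must be non-empty")
    needle = unit.upper() * min_copies
    needle_rc = reverse_complement(needle)
    count = 0
    for read in reads:
        r = read.upper()
        if needle in r or needle_rc in r:
            count += 1
    return count
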