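"""Peak-to-gene assignment and the genic/TE partitions derived from it.

A gene is "marked" in a sample when at least one peak overlaps its extended
region (gene body plus a symmetric flank, 2 kb by default) by >= 1 bp under
half-open arithmetic — intervals that merely touch do not overlap.  A
transposable element is marked only when a peak fully CONTAINS it; the
asymmetry between any-overlap for genes and containment for TEs is the
deliberate marking rule, not an accident.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .model import ConfigurationError, GeneModel, Peak, TEFeature


@dataclass
class MarkAssignment:
    """Result of assigning one sample's peaks to genes."""

    sample: str
    gene_peaks: dict[str, list[Peak]] = field(default_factory=dict)
    intergenic_peaks: list[Peak] = field(default_factory=list)
    n_peaks: int = 0

    @property
    def marked_genes(self) -> set[str]:
        return {g for g, ps in self.gene_peaks.items() if ps}

    @property
    def genic_peak_count(self) -> int:
        return self.n_peaks - len(self.intergenic_peaks)


def assign_peaks_to_genes(
    peaks: Sequence[Peak], genes: Sequence[GeneModel], flank: int = 2000
) -> MarkAssignment:
    """Assign each peak to every gene whose extended region it overlaps.

    The extended region of gene g is [g.start - flank, g.end + flank); a
    peak overlapping several extended genes is assigned to all of them, and
    peaks overlapping none are labelled intergenic.  The flank is applied on
    both sides regardless of strand.
    """
    if flank < 0:
        raise ConfigurationError("flank must be non-negative")
    sample = peaks[0].sample if peaks else ""
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        iv = g.interval
        trees.setdefault(iv.chrom, IntervalTree()).addi(
            iv.start - flank, iv.end + flank, g.gene_id
        )
    assignment = MarkAssignment(sample=sample, n_peaks=len(peaks))
    assignment.gene_peaks = {g.gene_id: [] for g in genes}
    for p in peaks:
        tree = trees.get(p.interval.chrom)
        hits = tree.overlap(p.interval.start, p.interval.end) if tree else set()
        if not hits:
            assignment.intergenic_peaks.append(p)
            continue
        for hit in hits:
            assignment.gene_peaks[hit.data].append(p)
    return assignment


def summarize_peak_context(
    assignment: MarkAssignment, genes: Sequence[GeneModel]
) -> dict:
    """Counts and fractions for the genic/intergenic and TE/non-TE partitions.

    A marked gene that is TE-related and another that is not may share a
    peak; such a peak contributes to both gene categories (double-counted by
    construction), while the genic/intergenic peak partition is exact.
    """
    n_peaks = assignment.n_peaks
    n_genic = assignment.genic_peak_count
    marked = assignment.marked_genes
    te_genes = [g for g in genes if g.is_te_related]
    non_te = [g for g in genes if not g.is_te_related]
    marked_te = sum(1 for g in te_genes if g.gene_id in marked)
    marked_non_te = sum(1 for g in non_te if g.gene_id in marked)
    return {
        "sample": assignment.sample,
        "n_peaks": n_peaks,
        "genic_peaks": n_genic,
        "intergenic_peaks": len(assignment.intergenic_peaks),
        "genic_fraction": n_genic / n_peaks if n_peaks else 0.0,
        "n_genes": len(genes),
        "marked_genes": len(marked),
        "te_genes_total": len(te_genes),
        "te_genes_marked": marked_te,
        "te_genes_marked_fraction": marked_te / len(te_genes) if te_genes else 0.0,
        "non_te_genes_total": len(non_te),
        "non_te_genes_marked": marked_non_te,
        "non_te_genes_marked_fraction": (
            marked_non_te / len(non_te) if non_te else 0.0
        ),
    }


def overlap_gene_sets(sets: Mapping[str, Iterable[str]]) -> dict[str, int]:
    """Counts for every intersection/difference region of 2 or 3 named sets.

    Region keys are '&'-joined sorted membership patterns like ``"A"``,
    ``"A&B"``; the regions partition the union of the sets.
    """
    names = list(sets)
    if not 2 <= len(names) <= 3:
        raise ValueError("overlap_gene_sets supports 2 or 3 sets")
    materialized = {name: set(s) for name, s in sets.items()}
    regions: dict[str, int] = {}
    union = set().union(*materialized.values())
    for element in union:
        key = "&".join(sorted(n for n in names if element in materialized[n]))
        regions[key] = regions.get(key, 0) + 1
    # report zero counts for empty regions so the table shape is stable
    from itertools import combinations

    for r in range(1, len(names) + 1):
        for combo in combinations(sorted(names), r):
            regions.setdefault("&".join(combo), 0)
    return regions


def te_peak_containment(
    tes: Sequence[TEFeature], peaks: Sequence[Peak]
) -> set[str]:
    """IDs of TEs lying fully inside some peak (strict containment).

    A TE partially overlapped by a peak is NOT marked.
    """
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        iv = p.interval
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, p)
    marked: set[str] = set()
    for te in tes:
        tree = trees.get(te.interval.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(te.interval.start, te.interval.end):
            if hit.begin <= te.interval.start and te.interval.end <= hit.end:
                marked.add(te.te_id)
                break
    return marked
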