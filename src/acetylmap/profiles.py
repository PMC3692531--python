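"""Metagene tag-density profiles over gene bodies and flanks.

Each gene body is rescaled to a fixed number of intervals (20 by default)
with the upstream and downstream 2-kb flanks split either into 20 scaled
intervals or into fixed 100-bp intervals.  A tag contributes to the interval
containing its assignment point (5' position, optionally shifted by half the
fragment extension toward 3').  Minus-strand genes are mirrored so interval
1 is always 5'-most.  Two normalisations are offered: tag count divided by
interval length ("per_bp", averaged over genes), or additionally divided by
the total tag count of the sample ("per_bp_per_total").
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import ConfigurationError, GeneModel, ReadTag

log = logging.getLogger(__name__)


@dataclass
class ProfileMatrix:
    """Average tag densities over the upstream/body/downstream layout."""

    stratum: str
    region_labels: list[str]  # "up"/"body"/"down" per interval
    density: np.ndarray  # mean over genes of count / interval bp
    n_genes: int
    n_skipped: int
    total_tags: int
    normalization: str
    # per-gene raw counts and interval lengths, kept for downstream selection
    counts: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    interval_bp: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    gene_ids: list[str] = field(default_factory=list)


def _assignment_points(tags: Sequence[ReadTag], fragment_extension: int):
    """Sorted per-chromosome arrays of tag assignment points.

    The assignment point is the 5' position shifted by fragment_extension/2
    toward the 3' end of the read.
    """
    shift = fragment_extension // 2
    by_chrom: dict[str, list[int]] = {}
    for t in tags:
        pos = t.five_prime_pos + shift if t.strand == "+" else t.five_prime_pos - shift
        by_chrom.setdefault(t.chrom, []).append(pos)
    return {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in by_chrom.items()}


def _edges(start: int, length: int, n: int) -> np.ndarray:
    """n half-open interval edges over [start, start+length); the last
    (3'-most) interval absorbs the remainder of the integer division."""
    width = length // n
    edges = start + width * np.arange(n + 1, dtype=np.int64)
    edges[-1] = start + length
    return edges


def _flank_layout(flank_bp: int, flank_mode: str) -> int:
    if flank_mode == "scaled_20":
        return 20
    if flank_mode == "fixed_100bp":
        n = flank_bp // 100
        if n < 1:
            raise ConfigurationError("flank too short for 100-bp intervals")
        return n
    raise ConfigurationError(f"unknown flank_mode {flank_mode!r}")


def metagene_profile(
    tags: Sequence[ReadTag],
    genes: Sequence[GeneModel],
    body_intervals: int = 20,
    flank_bp: int = 2000,
    flank_mode: str = "scaled_20",
    normalization: str = "per_bp",
    fragment_extension: int = 0,
    stratum: str = "all",
) -> ProfileMatrix:
    """Average tag density over upstream flank, scaled gene body and
    downstream flank.

    Genes shorter than ``body_intervals`` bp cannot host one tag boundary per
    interval and are skipped (counted in ``n_skipped``).
    """
    if body_intervals < 1:
        raise ConfigurationError("body_intervals must be >= 1")
    if not genes:
        raise ConfigurationError("genes must be non-empty")
    if normalization not in ("per_bp", "per_bp_per_total"):
        raise ConfigurationError(f"unknown normalization {normalization!r}")
    n_flank = _flank_layout(flank_bp, flank_mode)
    n_cols = n_flank + body_intervals + n_flank
    points = _assignment_points(tags, fragment_extension)

    kept: list[GeneModel] = []
    counts_rows: list[np.ndarray] = []
    bp_rows: list[np.ndarray] = []
    for g in genes:
        iv = g.interval
        if len(iv) < body_intervals:
            continue
        # widths in GENE orientation (5'->3'), remainder always on the
        # 3'-most interval of each region
        widths = np.concatenate(
            [
                np.diff(_edges(0, flank_bp, n_flank)),
                np.diff(_edges(0, len(iv), body_intervals)),
                np.diff(_edges(0, flank_bp, n_flank)),
            ]
        )
        if iv.strand == "-":
            # genome-space edges run left-to-right = 3'->5' for a - gene
            genome_widths = widths[::-1]
        else:
            genome_widths = widths
        edges = iv.start - flank_bp + np.concatenate(
            [[0], np.cumsum(genome_widths)]
        )
        pos = points.get(iv.chrom)
        if pos is None:
            row = np.zeros(n_cols, dtype=np.int64)
        else:
            row = np.diff(np.searchsorted(pos, edges))
        if iv.strand == "-":  # mirror so interval 1 is 5'-most
            row = row[::-1].copy()
        kept.append(g)
        counts_rows.append(row)
        bp_rows.append(widths)

    n_skipped = len(genes) - len(kept)
    if n_skipped:
        log.warning(
            "%d gene(s) shorter than %d bp skipped in metagene profile",
            n_skipped,
            body_intervals,
        )
    if not kept:
        raise ConfigurationError("no gene long enough for the requested layout")
    counts = np.vstack(counts_rows)
    interval_bp = np.vstack(bp_rows)
    density = (counts / interval_bp).mean(axis=0)
    if normalization == "per_bp_per_total":
        total = max(1, len(tags))
        density = density / total
    labels = ["up"] * n_flank + ["body"] * body_intervals + ["down"] * n_flank
    return ProfileMatrix(
        stratum=stratum,
        region_labels=labels,
        density=density,
        n_genes=len(kept),
        n_skipped=n_skipped,
        total_tags=len(tags),
        normalization=normalization,
        counts=counts,
        interval_bp=interval_bp,
        gene_ids=[g.gene_id for g in kept],
    )


def stratify_by_length(
    genes: Sequence[GeneModel], breaks: Sequence[int] = (1500, 5000, 10000)
) -> dict[str, list[GeneModel]]:
    """Partition genes by body length at the given break points.

    A gene exactly on a break falls in the lower bin (closed upper bound);
    default breaks separate the <=1.5 kb, 1.5-5 kb, 5-10 kb and >10 kb size
    classes used when examining TSS enrichment.
    """
    bks = list(breaks)
    if any(b2 <= b1 for b1, b2 in zip(bks, bks[1:])):
        raise ConfigurationError("breaks must be strictly increasing")
    labels = [f"<={bks[0]}bp"]
    labels += [f"{lo + 1}-{hi}bp" for lo, hi in zip(bks, bks[1:])]
    labels += [f">{bks[-1]}bp"]
    strata: dict[str, list[GeneModel]] = {lab: [] for lab in labels}
    for g in genes:
        idx = int(np.searchsorted(bks, g.length, side="left"))
        if idx < len(bks) and g.length == bks[idx]:
            pass  # exactly on a break: lower bin via side="left"
        strata[labels[idx]].append(g)
    return strata


def gene_tag_density(
    tags: Sequence[ReadTag],
    genes: Sequence[GeneModel],
    flank: int = 0,
    fragment_extension: int = 0,
) -> dict[str, float]:
    """Per-gene tag density: assignment points in [start - flank, end + flank)
    divided by that region's length."""
    points = _assignment_points(tags, fragment_extension)
    out: dict[str, float] = {}
    for g in genes:
        iv = g.interval
        pos = points.get(iv.chrom)
        lo, hi = iv.start - flank, iv.end + flank
        n = 0 if pos is None else int(
            np.searchsorted(pos, hi) - np.searchsorted(pos, lo)
        )
        out[g.gene_id] = n / (hi - lo)
    return out


def expression_tier_density(
    genes: Sequence[GeneModel],
    densities: dict[str, float],
    n_tiers: int = 3,
) -> list[dict]:
    """Mean tag density per expression tier.

    Genes with an expression value are ranked (ascending) and cut into
    ``n_tiers`` equal-size tiers — ties broken by gene_id order, remainder
    genes going to the lower tiers — and the mean density of each tier is
    returned, low to high.
    """
    expressed = [g for g in genes if g.expression is not None]
    if len(expressed) < n_tiers:
        raise ConfigurationError(
            f"need >= {n_tiers} genes with expression, got {len(expressed)}"
        )
    values = {g.expression for g in expressed}
    if len(values) == 1:
        log.warning("all expression values identical; tiers are arbitrary")
    ranked = sorted(expressed, key=lambda g: (g.expression, g.gene_id))
    base, rem = divmod(len(ranked), n_tiers)
    tiers = []
    offset = 0
    for t in range(n_tiers):
        size = base + (1 if t < rem else 0)
        members = ranked[offset: offset + size]
        offset += size
        tiers.append(
            {
                "tier": t + 1,
                "n_genes": size,
                "mean_expression": float(np.mean([g.expression for g in members])),
                "mean_density": float(
                    np.mean([densities.get(g.gene_id, 0.0) for g in members])
                ),
            }
        )
    return tiers


def select_three_prime_peak_genes(
    tags: Sequence[ReadTag],
    genes: Sequence[GeneModel],
    body_intervals: int = 20,
    last_k: int = 2,
    ratio_cutoff: float = 1.5,
    fragment_extension: int = 0,
) -> set[str]:
    """Genes whose 3'-end tag density stands out against their own body.

    A gene is selected when its mean density over the last ``last_k`` body
    intervals exceeds ``ratio_cutoff`` times its mean density over the middle
    intervals (excluding the first and last ``last_k``).
    """
    if body_intervals <= 2 * last_k:
        raise ConfigurationError("body_intervals must exceed 2 * last_k")
    profile = metagene_profile(
        tags,
        genes,
        body_intervals=body_intervals,
        flank_bp=max(100, body_intervals),
        flank_mode="fixed_100bp",
        fragment_extension=fragment_extension,
    )
    labels = np.asarray(profile.region_labels)
    body_cols = np.where(labels == "body")[0]
    last_cols = body_cols[-last_k:]
    mid_cols = body_cols[last_k:-last_k]
    dens = profile.counts / profile.interval_bp
    selected: set[str] = set()
    for i, gene_id in enumerate(profile.gene_ids):
        last_mean = dens[i, last_cols].mean()
        mid_mean = dens[i, mid_cols].mean()
        if last_mean > ratio_cutoff * mid_mean and last_mean > 0:
            selected.add(gene_id)
    return selected
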