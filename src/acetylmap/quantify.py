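"""Per-gene signal quantification, differential-marking calls, ChIP-qPCR
arithmetic and strand cross-correlation quality metrics.

Signals are tag counts over the gene's extended region scaled to
tags-per-million, so fold changes between libraries of different depth are
meaningful.  The QC block computes the classic strand cross-correlation
curve: the Pearson correlation between plus- and minus-strand 5'-position
coverage as a function of shift peaks at the library's fragment length, and
the normalized (NSC) and relative (RSC) coefficients summarise how far that
peak rises above background and above the read-length phantom position.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .model import ConfigurationError, DataError, GeneModel, ReadTag
from .profiles import _assignment_points


@dataclass
class SignalTable:
    """feature_id -> per-sample normalized tag count."""

    samples: list[str]
    values: dict[str, dict[str, float]]  # gene_id -> sample -> signal
    scaling_factors: dict[str, float]  # sample -> 1e6 / total tags


@dataclass
class QcMetrics:
    shifts: np.ndarray
    cc: np.ndarray
    fragment_length: int
    nsc: float
    rsc: float
    n_tags: int


def gene_signal(
    tags_by_sample: Mapping[str, Sequence[ReadTag]],
    genes: Sequence[GeneModel],
    flank: int = 2000,
    fragment_extension: int = 0,
) -> SignalTable:
    """Tags-per-million falling in each gene's body +/- flank, per sample."""
    samples = list(tags_by_sample)
    for s in samples:
        if not tags_by_sample[s]:
            raise DataError(f"sample {s!r} has no tags")
    values: dict[str, dict[str, float]] = {g.gene_id: {} for g in genes}
    scaling: dict[str, float] = {}
    for s in samples:
        tags = tags_by_sample[s]
        factor = 1e6 / len(tags)
        scaling[s] = factor
        points = _assignment_points(tags, fragment_extension)
        for g in genes:
            iv = g.interval
            pos = points.get(iv.chrom)
            n = 0 if pos is None else int(
                np.searchsorted(pos, iv.end + flank)
                - np.searchsorted(pos, iv.start - flank)
            )
            values[g.gene_id][s] = n * factor
    return SignalTable(samples=samples, values=values, scaling_factors=scaling)


def fold_change_classification(
    signal_a: Mapping[str, float],
    signal_b: Mapping[str, float],
    cutoff: float = 2.0,
    pseudocount: float = 1.0,
) -> dict[str, tuple[str, float]]:
    """Classify each feature as increased/decreased/unchanged in b vs a.

    fold = (b + pseudocount) / (a + pseudocount); increased iff fold >
    cutoff, decreased iff fold < 1/cutoff.
    """
    if cutoff <= 1:
        raise ConfigurationError("cutoff must exceed 1")
    if pseudocount < 0:
        raise ConfigurationError("pseudocount must be >= 0")
    out: dict[str, tuple[str, float]] = {}
    for fid in signal_a:
        a = signal_a[fid]
        b = signal_b.get(fid, 0.0)
        if pseudocount == 0 and a == 0:
            raise ZeroDivisionError(
                f"undefined ratio for {fid!r}: zero signal with zero pseudocount"
            )
        fold = (b + pseudocount) / (a + pseudocount)
        if fold > cutoff:
            cls = "increased"
        elif fold < 1.0 / cutoff:
            cls = "decreased"
        else:
            cls = "unchanged"
        out[fid] = (cls, fold)
    return out


def qpcr_enrichment(ct_input: float, ct_chip: float) -> float:
    """ChIP-qPCR fold enrichment: 2^(Ct_input - Ct_ChIP)."""
    if not (np.isfinite(ct_input) and np.isfinite(ct_chip)):
        raise ValueError("Ct values must be finite")
    return float(2.0 ** (ct_input - ct_chip))


def cross_correlation_qc(
    tags: Sequence[ReadTag],
    max_shift: int = 500,
    read_length: int | None = None,
    min_tags_per_chrom: int = 100,
    bin_size: int = 1,
) -> QcMetrics:
    """Strand cross-correlation curve with NSC and RSC.

    cc(shift) is the Pearson correlation of the plus-strand 5' coverage
    vector with the minus-strand coverage displaced by ``shift``, combined
    across chromosomes carrying at least ``min_tags_per_chrom`` tags
    (weighted by tag count).  The fragment-length estimate is the argmax
    over shifts greater than the read length; the background is the minimum
    cc over the declared range.  NSC = cc_max / cc_background and
    RSC = (cc_max - cc_background) / (cc(read length) - cc_background).
    """
    if not tags:
        raise DataError("no tags for QC")
    if read_length is None:
        read_length = int(round(float(np.median([t.length for t in tags]))))
    if max_shift <= read_length:
        raise ConfigurationError("max_shift must exceed the read length")
    plus: dict[str, list[int]] = {}
    minus: dict[str, list[int]] = {}
    for t in tags:
        (plus if t.strand == "+" else minus).setdefault(t.chrom, []).append(
            t.five_prime_pos
        )
    if not plus or not minus:
        raise DataError("cross-correlation undefined with single-strand input")

    shifts = np.arange(0, max_shift + 1)
    weighted = np.zeros(shifts.size)
    weight_total = 0.0
    for chrom in set(plus) & set(minus):
        p_pos = np.asarray(plus[chrom])
        m_pos = np.asarray(minus[chrom])
        n_chrom = p_pos.size + m_pos.size
        if n_chrom < min_tags_per_chrom:
            continue
        length = int(max(p_pos.max(), m_pos.max())) + 1
        n_bins = length // bin_size + 1
        p_cov = np.bincount(p_pos // bin_size, minlength=n_bins).astype(float)
        m_cov = np.bincount(m_pos // bin_size, minlength=n_bins).astype(float)
        cc = np.empty(shifts.size)
        for i, shift in enumerate(shifts):
            sb = shift // bin_size
            a = p_cov[: n_bins - sb] if sb else p_cov
            b = m_cov[sb:]
            if a.std() == 0 or b.std() == 0:
                cc[i] = 0.0
            else:
                cc[i] = float(np.corrcoef(a, b)[0, 1])
        weighted += n_chrom * cc
        weight_total += n_chrom
    if weight_total == 0:
        raise DataError(
            f"no chromosome carries >= {min_tags_per_chrom} tags; QC unstable"
        )
    cc = weighted / weight_total
    search = shifts > read_length
    frag = int(shifts[search][np.argmax(cc[search])])
    cc_max = float(cc[search].max())
    cc_bg = float(cc.min())
    cc_read = float(cc[shifts == read_length][0])
    nsc = cc_max / cc_bg if cc_bg > 0 else float("inf")
    denom = cc_read - cc_bg
    rsc = (cc_max - cc_bg) / denom if denom != 0 else float("inf")
    return QcMetrics(
        shifts=shifts,
        cc=cc,
        fragment_length=frag,
        nsc=nsc,
        rsc=rsc,
        n_tags=len(tags),
    )
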