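"""Synthetic miniature dataset with the statistical structure the analysis
assumes: a small genome, non-overlapping genes, TE copies drawn from named
families, gene categories, expression values, and ChIP tags for a
three-sample design (an acetylation mark in wild type and in a knock-down
line, plus one protein-binding sample).

Tag placement is a Poisson mixture: a uniform background process over the
genome plus, for each feature truly marked in a sample, a focal process over
its placement window — TSS +/- 500 bp for the acetylation samples, the whole
gene body for the binding sample.  Read strands flank the fragment centre at
+/- fragment_length/2, so the strand cross-correlation QC recovers the
configured fragment length.  Every output is a pure function of the
configuration, including the seed; truth tables are emitted alongside the
data so recovery tests can assert against what was injected without the
pipeline ever seeing it.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .model import (
    CategoryMap,
    ConfigurationError,
    GeneModel,
    GenomicInterval,
    Peak,
    ReadTag,
    TEFeature,
)

SAMPLES = ("H3K9ac-WT", "H3K9ac-RNAi", "SRT1")

DEFAULT_TE_COUNTS = {
    "Copia": 30, "Gypsy": 60, "LINE": 60, "SINE": 20, "hAT": 25,
    "En-Spm": 30, "MITE": 80, "Mutator": 50, "Helitron": 20,
    "Unclassified": 25,
}

CATEGORY_VOCAB = (
    "metabolism", "transcription", "stress_response", "development",
    "transport", "signaling", "unknown",
)

TF_FAMILIES = ("MYB", "WRKY", "bZIP", "AP2")


@dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults emulate the study design at desk
    scale (three samples, ~45% of non-TE genes vs ~8% of TE-related genes
    acetylated, 93% wild-type/knock-down overlap, 200-bp fragments)."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 1_200_000
    n_genes: int = 200
    gene_length_range: tuple[int, int] = (1000, 5000)
    te_family_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_TE_COUNTS)
    )
    te_gene_fraction: float = 0.285
    tf_fraction: float = 0.10
    mark_prob_non_te: float = 0.45
    mark_prob_te_gene: float = 0.08
    mark_flip_prob: float = 0.05  # WT->RNAi mark-status disagreement
    bind_prob: float = 0.10  # binding-sample target fraction
    enriched_categories: list[tuple[str, float]] = field(
        default_factory=lambda: [("stress_response", 6.0)]
    )
    te_mark_prob: float = 0.05
    te_enriched_families: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"H3K9ac-RNAi": {"LINE": 8.0}, "SRT1": {"Mutator": 8.0}}
    )
    mark_architecture: dict[str, str] = field(
        default_factory=lambda: {
            "H3K9ac-WT": "tss_enriched",
            "H3K9ac-RNAi": "tss_enriched",
            "SRT1": "body_enriched",
        }
    )
    background_rate: float = 0.01  # tags per bp
    peak_rate: float = 0.5  # tags per bp over the placement window
    te_peak_rate: Optional[float] = None  # defaults to peak_rate
    tss_window: int = 500
    fold_change_targets: list[tuple[str, float]] = field(
        default_factory=lambda: [("stress_response", 3.0)]
    )
    # differential genes are a small minority of the library in the study
    # design; cap how many genes a category descriptor recruits
    fold_target_max_genes: int = 5
    motif_half_site: str = "GATGGGCCGA"
    motif_spacer: int = 5
    motif_target_fraction: float = 0.5  # of truly bound genes
    read_length: int = 36
    fragment_length: int = 200
    # intergenic spacing large enough that a 2-kb flank cannot reach the
    # focal tag window of a neighbouring gene's promoter
    min_gene_gap: int = 4000
    generate_sequence: bool = True

    def __post_init__(self) -> None:
        if self.background_rate < 0 or self.peak_rate < 0:
            raise ConfigurationError("rates must be non-negative")
        for _desc, fold in self.fold_change_targets:
            if fold < 1:
                raise ConfigurationError("fold-change targets require fold >= 1")


@dataclass
class SyntheticTruth:
    """What was injected, for recovery tests only."""

    marked_genes: dict[str, set[str]]  # sample -> gene ids
    gene_fold: dict[str, float]  # RNAi/WT fold for fold-target genes
    marked_tes: dict[str, set[str]]  # sample -> te ids
    enriched_categories: dict[str, set[str]]  # sample -> categories
    motif_genes: set[str]
    fragment_length: int


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    genes: list[GeneModel]
    tes: list[TEFeature]
    categories: CategoryMap
    genome: dict[str, str]
    chrom_lengths: dict[str, int]
    truth: SyntheticTruth


def _boosted_prob(base: float, multiplier: float) -> float:
    odds = base / (1 - base) * multiplier
    return odds / (1 + odds)


def _resolve_gene_set(
    descriptor, genes: Sequence[GeneModel], categories: CategoryMap
) -> set[str]:
    """A fold/motif target descriptor: a category name or an explicit list."""
    if isinstance(descriptor, str):
        members = categories.genes_in(descriptor)
        if not members:
            raise ConfigurationError(f"no gene carries category {descriptor!r}")
        return members
    return set(descriptor)


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate annotation, genome, categories, expression and truth labels."""
    rng = np.random.default_rng([config.seed, 0])
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    chrom_lengths = {c: config.chrom_length for c in chroms}

    genes = _place_genes(config, rng, chroms)
    tes = _place_tes(config, rng, genes, chrom_lengths)
    categories = _assign_categories(config, rng, genes)
    truth = _draw_truth(config, rng, genes, tes, categories)
    _assign_expression(rng, genes, truth)
    genome = (
        _draw_genome(config, rng, chrom_lengths, genes, truth)
        if config.generate_sequence
        else {}
    )
    return SyntheticDataset(
        config=config,
        genes=genes,
        tes=tes,
        categories=categories,
        genome=genome,
        chrom_lengths=chrom_lengths,
        truth=truth,
    )


def generate_annotation(config: SyntheticConfig):
    """(genes, tes, categories, genome) — see generate_dataset for the full
    bundle including truth."""
    ds = generate_dataset(config)
    return ds.genes, ds.tes, ds.categories, ds.genome


def _place_genes(config, rng, chroms) -> list[GeneModel]:
    lo, hi = config.gene_length_range
    per_chrom = np.full(len(chroms), config.n_genes // len(chroms))
    per_chrom[: config.n_genes % len(chroms)] += 1
    genes: list[GeneModel] = []
    idx = 0
    for chrom, n in zip(chroms, per_chrom):
        n = int(n)
        lengths = rng.integers(lo, hi + 1, size=n)
        needed = int(lengths.sum()) + (n + 1) * config.min_gene_gap
        if needed > config.chrom_length:
            raise ConfigurationError(
                f"cannot pack {n} genes into {chrom}: need >= {needed} bp, "
                f"have {config.chrom_length}"
            )
        slack = config.chrom_length - int(lengths.sum()) - (n + 1) * config.min_gene_gap
        # exponential weights give realistically dispersed intergenic gaps
        # (some near-minimal, some large) instead of near-uniform spacing
        w = rng.exponential(size=n + 1)
        extra = np.floor(slack * w / w.sum()).astype(np.int64)
        pos = 0
        for i in range(n):
            pos += config.min_gene_gap + int(extra[i])
            start = pos
            end = start + int(lengths[i])
            pos = end
            idx += 1
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(
                    gene_id=f"gene_{idx:05d}",
                    interval=GenomicInterval(chrom, start, end, strand),
                    is_te_related=bool(rng.random() < config.te_gene_fraction),
                )
            )
    return genes


def _place_tes(config, rng, genes, chrom_lengths) -> list[TEFeature]:
    # intergenic gaps per chromosome, shrunk by a buffer on both sides so a
    # marked TE's tag footprint cannot reach into a neighbouring gene's
    # 2-kb flank; TEs may overlap each other but never gene bodies
    buffer = 2600
    gaps: list[tuple[str, int, int]] = []
    for chrom, length in chrom_lengths.items():
        bounds = sorted(
            (g.interval.start, g.interval.end)
            for g in genes
            if g.interval.chrom == chrom
        )
        prev = 0
        for s, e in bounds:
            if (s - buffer) - (prev + buffer) >= 500:
                gaps.append((chrom, prev + buffer, s - buffer))
            prev = e
        if (length - buffer) - (prev + buffer) >= 500:
            gaps.append((chrom, prev + buffer, length - buffer))
    if not gaps:
        raise ConfigurationError("no intergenic space left for TE placement")
    gap_lens = np.array([e - s for _, s, e in gaps], dtype=float)
    gap_p = gap_lens / gap_lens.sum()
    tes: list[TEFeature] = []
    idx = 0
    for family in sorted(config.te_family_counts):
        for _ in range(config.te_family_counts[family]):
            idx += 1
            te_len = int(rng.integers(100, 401))
            for _attempt in range(100):
                gi = int(rng.choice(len(gaps), p=gap_p))
                chrom, gs, ge = gaps[gi]
                if ge - gs <= te_len:
                    continue
                start = int(rng.integers(gs, ge - te_len))
                tes.append(
                    TEFeature(
                        te_id=f"te_{idx:05d}",
                        interval=GenomicInterval(chrom, start, start + te_len),
                        family=family,
                    )
                )
                break
            else:
                raise ConfigurationError(
                    "could not place a TE copy; enlarge the genome"
                )
    return tes


def _assign_categories(config, rng, genes) -> CategoryMap:
    # balanced assignment (a shuffled round-robin) so every category is
    # populated whenever n_genes >= len(vocabulary)
    labels = [CATEGORY_VOCAB[i % len(CATEGORY_VOCAB)] for i in range(len(genes))]
    rng.shuffle(labels)
    mapping: dict[str, set[str]] = {}
    for g, cat in zip(genes, labels):
        mapping[g.gene_id] = {cat}
        if rng.random() < config.tf_fraction:
            g.tf_family = TF_FAMILIES[int(rng.integers(len(TF_FAMILIES)))]
            mapping[g.gene_id].add("TF")
    return CategoryMap(mapping=mapping, universe_size=len(genes))


def _draw_truth(config, rng, genes, tes, categories) -> SyntheticTruth:
    marked: dict[str, set[str]] = {s: set() for s in SAMPLES}
    enriched_cats = {cat for cat, _m in config.enriched_categories}
    boost = dict(config.enriched_categories)
    fold_targets: dict[str, float] = {}
    for desc, fold in config.fold_change_targets:
        members = sorted(_resolve_gene_set(desc, genes, categories))
        for gid in members[: config.fold_target_max_genes]:
            fold_targets[gid] = max(fold_targets.get(gid, 1.0), fold)

    for g in genes:
        base = config.mark_prob_te_gene if g.is_te_related else config.mark_prob_non_te
        wt = rng.random() < base
        rnai = wt if rng.random() >= config.mark_flip_prob else not wt
        if g.gene_id in fold_targets:
            wt = rnai = True  # fold targets marked in both, rate scaled in B
        if wt:
            marked["H3K9ac-WT"].add(g.gene_id)
        if rnai:
            marked["H3K9ac-RNAi"].add(g.gene_id)
        p_bind = config.bind_prob
        cats = categories.mapping.get(g.gene_id, set())
        for cat in cats & enriched_cats:
            p_bind = _boosted_prob(config.bind_prob, boost[cat])
        if rng.random() < p_bind:
            marked["SRT1"].add(g.gene_id)

    # base TE mark status is shared across samples (the marked-TE complement
    # barely changes between conditions); a per-sample family boost shifts
    # the COMPOSITION of the marked set toward that family while holding the
    # expected total constant, so library sizes stay comparable
    p0 = config.te_mark_prob
    fam_counts: dict[str, int] = {}
    for te in tes:
        fam_counts[te.family] = fam_counts.get(te.family, 0) + 1
    removal_prob: dict[str, float] = {}
    for sample, boosts in config.te_enriched_families.items():
        added = sum(
            fam_counts.get(f, 0) * (_boosted_prob(p0, m) - p0)
            for f, m in boosts.items()
        )
        pool = sum(
            n * p0 for f, n in fam_counts.items() if f not in boosts
        )
        removal_prob[sample] = min(0.95, added / pool) if pool > 0 else 0.0
    marked_tes: dict[str, set[str]] = {s: set() for s in SAMPLES}
    for te in tes:
        base = rng.random() < p0
        for sample in SAMPLES:
            boosts = config.te_enriched_families.get(sample, {})
            mult = boosts.get(te.family)
            if base:
                if mult is None and boosts and rng.random() < removal_prob[sample]:
                    continue  # rebalanced away in this sample
                marked_tes[sample].add(te.te_id)
            elif mult:
                p_boost = _boosted_prob(p0, mult)
                if rng.random() < (p_boost - p0) / (1 - p0):
                    marked_tes[sample].add(te.te_id)

    by_id = {g.gene_id: g for g in genes}
    bound_non_te = sorted(
        gid for gid in marked["SRT1"] if not by_id[gid].is_te_related
    )
    n_motif = int(round(config.motif_target_fraction * len(bound_non_te)))
    motif_genes = set(bound_non_te[:n_motif])

    return SyntheticTruth(
        marked_genes=marked,
        gene_fold=fold_targets,
        marked_tes=marked_tes,
        enriched_categories={"SRT1": enriched_cats},
        motif_genes=motif_genes,
        fragment_length=config.fragment_length,
    )


def _assign_expression(rng, genes, truth) -> None:
    # log2 microarray scale, coupled to wild-type marking so the
    # expression-tier comparison has signal to recover
    marked_wt = truth.marked_genes["H3K9ac-WT"]
    for g in genes:
        bonus = 2.0 if g.gene_id in marked_wt else 0.0
        g.expression = float(4.0 + bonus + rng.normal(0.0, 1.0))


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _draw_genome(config, rng, chrom_lengths, genes, truth) -> dict[str, str]:
    from .motif import reverse_complement

    genome: dict[str, str] = {}
    arrays: dict[str, np.ndarray] = {}
    for chrom, length in chrom_lengths.items():
        arrays[chrom] = _BASES[rng.integers(0, 4, size=length)]
    insert = (
        config.motif_half_site
        + "".join(
            "ACGT"[int(b)] for b in rng.integers(0, 4, size=config.motif_spacer)
        )
        + reverse_complement(config.motif_half_site)
    )
    ins = np.frombuffer(insert.encode(), dtype=np.uint8)
    for g in genes:
        if g.gene_id not in truth.motif_genes:
            continue
        iv = g.interval
        mid = (iv.start + iv.end) // 2
        arrays[iv.chrom][mid: mid + ins.size] = ins[: config.chrom_length - mid]
    for chrom, arr in arrays.items():
        genome[chrom] = arr.tobytes().decode("ascii")
    return genome


# ---------------------------------------------------------------------------
# tag simulation


def _placement_window(gene: GeneModel, architecture: str, tss_window: int):
    iv = gene.interval
    if architecture == "tss_enriched":
        tss = iv.start if iv.strand != "-" else iv.end - 1
        return max(0, tss - tss_window), tss + tss_window
    if architecture == "body_enriched":
        return iv.start, iv.end
    if architecture == "uniform":
        return iv.start, iv.end
    raise ConfigurationError(f"unknown mark architecture {architecture!r}")


def simulate_chip_tags(
    dataset: SyntheticDataset, sample: str, seed: Optional[int] = None
) -> list[ReadTag]:
    """Draw one sample's tags from the Poisson mixture.

    Fragment centres come from a uniform background process plus focal
    processes over the placement windows of truly marked genes and TEs;
    each centre becomes a plus- or minus-strand read whose 5' end sits at
    centre -/+ fragment_length/2.
    """
    if sample not in SAMPLES:
        raise ConfigurationError(f"unknown sample {sample!r}; expected {SAMPLES}")
    config = dataset.config
    rng = np.random.default_rng(
        [config.seed if seed is None else seed, SAMPLES.index(sample) + 1]
    )
    centers: list[np.ndarray] = []
    chrom_of: list[np.ndarray] = []
    chroms = list(dataset.chrom_lengths)
    for ci, chrom in enumerate(chroms):
        length = dataset.chrom_lengths[chrom]
        n_bg = rng.poisson(config.background_rate * length)
        if n_bg:
            centers.append(rng.integers(0, length, size=n_bg))
            chrom_of.append(np.full(n_bg, ci))
    architecture = config.mark_architecture[sample]
    for g in dataset.genes:
        if g.gene_id not in dataset.truth.marked_genes[sample]:
            continue
        lo, hi = _placement_window(g, architecture, config.tss_window)
        rate = config.peak_rate
        if sample == "H3K9ac-RNAi" and g.gene_id in dataset.truth.gene_fold:
            rate *= dataset.truth.gene_fold[g.gene_id]
        n = rng.poisson(rate * (hi - lo))
        if n:
            centers.append(rng.integers(lo, hi, size=n))
            chrom_of.append(np.full(n, chroms.index(g.interval.chrom)))
    pad = config.fragment_length
    for te in dataset.tes:
        if te.te_id not in dataset.truth.marked_tes[sample]:
            continue
        iv = te.interval
        lo, hi = max(0, iv.start - pad), iv.end + pad
        te_rate = config.te_peak_rate if config.te_peak_rate is not None else config.peak_rate
        n = rng.poisson(te_rate * (hi - lo))
        if n:
            centers.append(rng.integers(lo, hi, size=n))
            chrom_of.append(np.full(n, chroms.index(iv.chrom)))
    if not centers:
        return []
    center = np.concatenate(centers)
    cidx = np.concatenate(chrom_of)
    # each fragment end is sequenced independently with probability 1/2, so
    # the expected tag yield equals the configured rate while fragments kept
    # on both strands anchor the cross-correlation peak at fragment_length
    keep_plus = rng.random(center.size) < 0.5
    keep_minus = rng.random(center.size) < 0.5
    half = config.fragment_length // 2
    tags: list[ReadTag] = []
    for i in range(center.size):
        chrom = chroms[int(cidx[i])]
        length = dataset.chrom_lengths[chrom]
        if keep_plus[i]:
            # keep the whole read inside the chromosome
            pos = int(np.clip(center[i] - half, 0, length - config.read_length))
            tags.append(ReadTag(chrom, pos, "+", config.read_length))
        if keep_minus[i]:
            pos = int(
                np.clip(center[i] + half, config.read_length - 1, length - 1)
            )
            tags.append(ReadTag(chrom, pos, "-", config.read_length))
    tags.sort(key=lambda t: (t.chrom, t.five_prime_pos, t.strand))
    return tags


# ---------------------------------------------------------------------------
# naive window peak caller (plumbing so end-to-end synthetic tests run)


def call_peaks_window(
    tags: Sequence[ReadTag],
    control_tags: Optional[Sequence[ReadTag]] = None,
    window: int = 400,
    step: int = 200,
    fold_cutoff: float = 5.0,
    chrom_lengths: Optional[dict[str, int]] = None,
    sample: str = "",
) -> list[Peak]:
    """Sliding-window enrichment caller.

    A window qualifies when its tag count exceeds ``fold_cutoff`` times the
    expected background count (global tag rate, or the control-matched rate
    when control tags are given); overlapping/adjacent qualifying windows
    merge into one peak whose summit is the centre of its densest window.
    """
    if not (window >= step > 0):
        raise ConfigurationError("require window >= step > 0")
    if not tags:
        return []
    by_chrom: dict[str, np.ndarray] = {}
    for t in tags:
        by_chrom.setdefault(t.chrom, []).append(t.five_prime_pos)  # type: ignore
    by_chrom = {c: np.sort(np.asarray(v)) for c, v in by_chrom.items()}
    if chrom_lengths is None:
        chrom_lengths = {c: int(v.max()) + 1 for c, v in by_chrom.items()}
    genome_len = sum(chrom_lengths.values())
    rate = len(tags) / genome_len
    ctrl_by_chrom = None
    ctrl_scale = None
    if control_tags:
        ctrl_by_chrom = {}
        for t in control_tags:
            ctrl_by_chrom.setdefault(t.chrom, []).append(t.five_prime_pos)
        ctrl_by_chrom = {c: np.sort(np.asarray(v)) for c, v in ctrl_by_chrom.items()}
        ctrl_scale = len(tags) / len(control_tags)
    peaks: list[Peak] = []
    for chrom in sorted(by_chrom):
        pos = by_chrom[chrom]
        length = chrom_lengths.get(chrom, int(pos.max()) + 1)
        starts = np.arange(0, max(1, length - window + step), step)
        counts = np.searchsorted(pos, starts + window) - np.searchsorted(pos, starts)
        if ctrl_by_chrom is not None:
            cpos = ctrl_by_chrom.get(chrom, np.empty(0, dtype=int))
            expected = (
                np.searchsorted(cpos, starts + window) - np.searchsorted(cpos, starts)
            ) * ctrl_scale
            expected = np.maximum(expected, rate * window * 0.1)
        else:
            expected = np.full(starts.size, rate * window)
        qualified = counts > fold_cutoff * expected
        i = 0
        while i < starts.size:
            if not qualified[i]:
                i += 1
                continue
            j = i
            while j + 1 < starts.size and qualified[j + 1] and starts[j + 1] <= starts[j] + window:
                j += 1
            span_start = int(starts[i])
            span_end = int(min(starts[j] + window, length))
            block = slice(i, j + 1)
            best = i + int(np.argmax(counts[block]))
            summit = int(starts[best] + window // 2 - span_start)
            summit = min(max(summit, 0), span_end - span_start - 1)
            n_in = int(np.searchsorted(pos, span_end) - np.searchsorted(pos, span_start))
            peaks.append(
                Peak(
                    sample=sample,
                    interval=GenomicInterval(chrom, span_start, span_end),
                    summit=summit,
                    tag_count=n_in,
                    peak_id=f"{sample or 'peak'}_{len(peaks) + 1}",
                )
            )
            i = j + 1
    return peaks


# ---------------------------------------------------------------------------
# fixture writing


def write_fixture(dataset: SyntheticDataset, outdir) -> dict[str, Path]:
    """Write the full fixture directory: genome.fa, genes.gff3, tes.out,
    tags_<sample>.bed, expression.tsv, categories.tsv, truth.tsv and a
    manifest recording the configuration."""
    import yaml

    from . import io as amio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    fa = outdir / "genome.fa"
    with open(fa, "w") as fh:
        for chrom, seq in dataset.genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i: i + 60] + "\n")
    paths["genome"] = fa

    amio.write_gff3(dataset.genes, outdir / "genes.gff3")
    paths["genes"] = outdir / "genes.gff3"
    amio.write_repeatmasker(dataset.tes, outdir / "tes.out")
    paths["tes"] = outdir / "tes.out"

    for sample in SAMPLES:
        tags = simulate_chip_tags(dataset, sample)
        p = outdir / f"tags_{sample}.bed"
        amio.write_bed(tags, p)
        paths[f"tags_{sample}"] = p

    with open(outdir / "expression.tsv", "w") as fh:
        fh.write("#gene_id\texpression\n")
        for g in dataset.genes:
            fh.write(f"{g.gene_id}\t{g.expression:.6f}\n")
    paths["expression"] = outdir / "expression.tsv"

    with open(outdir / "categories.tsv", "w") as fh:
        fh.write("#gene_id\tcategory\n")
        for gid in sorted(dataset.categories.mapping):
            for cat in sorted(dataset.categories.mapping[gid]):
                fh.write(f"{gid}\t{cat}\n")
    paths["categories"] = outdir / "categories.tsv"

    truth = dataset.truth
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("#kind\tsample\tfeature_id\tvalue\n")
        for sample in SAMPLES:
            for gid in sorted(truth.marked_genes[sample]):
                fh.write(f"marked_gene\t{sample}\t{gid}\t1\n")
            for tid in sorted(truth.marked_tes[sample]):
                fh.write(f"marked_te\t{sample}\t{tid}\t1\n")
        for gid in sorted(truth.gene_fold):
            fh.write(f"gene_fold\tH3K9ac-RNAi\t{gid}\t{truth.gene_fold[gid]}\n")
        for gid in sorted(truth.motif_genes):
            fh.write(f"motif_gene\t.\t{gid}\t1\n")
        fh.write(f"fragment_length\t.\t.\t{truth.fragment_length}\n")
    paths["truth"] = outdir / "truth.tsv"

    manifest = dataclasses.asdict(dataset.config)
    manifest["samples"] = list(SAMPLES)
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    paths["manifest"] = outdir / "manifest.yaml"
    return paths
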