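"""End-to-end orchestration: from a YAML config describing the input files
to the full report directory — QC, peak context, marked-gene sets and their
overlaps, metagene profiles, fold-change classes, category- and TE-family
enrichment tables, and the motif scan.

Every stage output is a pure function of (inputs, parameters, seed):
rerunning with the same config byte-reproduces all tables.
"""
from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import annotate, enrich, io as amio, motif, profiles, quantify
from .model import ConfigurationError

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    genes: str = ""
    genes_format: str = "gff3"
    tes: str = ""
    peaks: dict[str, str] = field(default_factory=dict)  # sample -> path
    peaks_format: str = "bed"
    tags: dict[str, str] = field(default_factory=dict)  # sample -> path
    genome: str = ""
    expression: str = ""
    categories: str = ""
    outdir: str = "report"
    seed: int = 0
    flank: int = 2000
    body_intervals: int = 20
    fold_cutoff: float = 2.0
    fdr_cutoff: float = 0.05
    te_p_cutoff: float = 0.01
    small_count_threshold: int = 100
    fragment_extension: int = 0
    motif_half_site: str = "GATGGGCCGA"
    motif_max_mismatch: int = 1
    motif_spacer_min: int = 0
    motif_spacer_max: int = 11
    universe_size: Optional[int] = None
    # external caller parameters recorded for provenance only; peak calling
    # is consumed, not performed, by the pipeline
    external_caller: dict = field(
        default_factory=lambda: {
            "software": "MACS 1.4",
            "bandwidth_bp": 300,
            "mfold": 32,
            "p_value": 1.0e-5,
        }
    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if not self.genes:
            raise ConfigurationError("config requires a gene annotation path")
        required = [self.genes]
        required += list(self.peaks.values()) + list(self.tags.values())
        for opt in (self.tes, self.genome, self.expression, self.categories):
            if opt:
                required.append(opt)
        missing = [p for p in required if not Path(p).exists()]
        if missing:
            raise ConfigurationError(f"missing input file(s): {missing}")
        if self.genome == "" and self.motif_half_site:
            # motif stage silently skipped without a genome unless peaks were
            # the only request; an explicit genome-less motif ask is an error
            pass
        if self.flank < 0 or self.fold_cutoff <= 1 or not 0 < self.fdr_cutoff < 1:
            raise ConfigurationError("parameter out of documented range")


def _config_hash(config: PipelineConfig) -> str:
    from dataclasses import asdict

    return hashlib.sha256(
        yaml.safe_dump(asdict(config), sort_keys=True).encode()
    ).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write the report directory; returns its path."""
    config.validate()
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        log.info("stage %-18s at %6.1fs", name, time.time() - t0)

    stage("load")
    genes = amio.read_annotations(config.genes, config.genes_format)
    tes = amio.read_annotations(config.tes, "repeatmasker_out") if config.tes else []
    peaks = {
        s: amio.read_peaks(p, config.peaks_format, sample=s)
        for s, p in config.peaks.items()
    }
    tags = {s: amio.read_tags(p) for s, p in config.tags.items()}
    if config.expression:
        expr = amio.read_expression(config.expression)
        for g in genes:
            if g.gene_id in expr:
                g.expression = expr[g.gene_id]
    universe = config.universe_size or len(genes)
    category_map = (
        amio.read_category_map(config.categories, universe_size=universe)
        if config.categories
        else None
    )

    stage("qc")
    qc_rows = []
    for s, ts in tags.items():
        try:
            m = quantify.cross_correlation_qc(ts)
            qc_rows.append(
                {
                    "sample": s,
                    "n_tags": m.n_tags,
                    "fragment_length": m.fragment_length,
                    "NSC": f"{m.nsc:.4f}",
                    "RSC": f"{m.rsc:.4f}",
                }
            )
        except Exception as exc:  # QC failure should not kill annotation
            qc_rows.append(
                {
                    "sample": s,
                    "n_tags": len(ts),
                    "fragment_length": "NA",
                    "NSC": "NA",
                    "RSC": f"error:{exc}",
                }
            )
    amio.write_table(
        qc_rows,
        outdir / "qc_report.tsv",
        ["sample", "n_tags", "fragment_length", "NSC", "RSC"],
    )

    stage("annotate")
    assignments = {
        s: annotate.assign_peaks_to_genes(ps, genes, flank=config.flank)
        for s, ps in peaks.items()
    }
    context_rows = [
        annotate.summarize_peak_context(a, genes) for a in assignments.values()
    ]
    if context_rows:
        amio.write_table(
            context_rows, outdir / "peak_context.tsv", list(context_rows[0])
        )
    marked_rows = []
    for s, a in assignments.items():
        for gid in sorted(a.marked_genes):
            ps = a.gene_peaks[gid]
            marked_rows.append(
                {
                    "gene_id": gid,
                    "sample": s,
                    "n_peaks": len(ps),
                    "peak_ids": ",".join(p.peak_id for p in ps),
                }
            )
    amio.write_table(
        marked_rows,
        outdir / "marked_genes.tsv",
        ["gene_id", "sample", "n_peaks", "peak_ids"],
    )
    if len(assignments) >= 2:
        sets = {s: a.marked_genes for s, a in assignments.items()}
        if len(sets) > 3:
            sets = dict(list(sets.items())[:3])
        regions = annotate.overlap_gene_sets(sets)
        amio.write_table(
            [{"region": k, "n_genes": v} for k, v in sorted(regions.items())],
            outdir / "venn_regions.tsv",
            ["region", "n_genes"],
        )

    stage("profiles")
    profile_rows = []
    strata = profiles.stratify_by_length(genes)
    for s, ts in tags.items():
        for stratum, members in strata.items():
            if not members:
                continue
            try:
                pm = profiles.metagene_profile(
                    ts,
                    members,
                    body_intervals=config.body_intervals,
                    flank_bp=config.flank,
                    fragment_extension=config.fragment_extension,
                    stratum=stratum,
                )
            except ConfigurationError:
                continue
            for i, (lab, d) in enumerate(zip(pm.region_labels, pm.density)):
                profile_rows.append(
                    {
                        "sample": s,
                        "stratum": stratum,
                        "region": lab,
                        "interval": i + 1,
                        "density": f"{d:.6g}",
                    }
                )
    amio.write_table(
        profile_rows,
        outdir / "metagene_profiles.tsv",
        ["sample", "stratum", "region", "interval", "density"],
    )

    stage("quantify")
    fold_classes: dict[str, tuple[str, float]] = {}
    if {"H3K9ac-WT", "H3K9ac-RNAi"} <= set(tags):
        table = quantify.gene_signal(tags, genes, flank=config.flank)
        fold_classes = quantify.fold_change_classification(
            {g: v["H3K9ac-WT"] for g, v in table.values.items()},
            {g: v["H3K9ac-RNAi"] for g, v in table.values.items()},
            cutoff=config.fold_cutoff,
        )
        rows = []
        for gid in sorted(table.values):
            cls, fold = fold_classes[gid]
            row = {"gene_id": gid, "class": cls, "fold": f"{fold:.4f}"}
            for s in table.samples:
                row[s] = f"{table.values[gid][s]:.4f}"
            rows.append(row)
        amio.write_table(
            rows,
            outdir / "signal_fold.tsv",
            ["gene_id"] + table.samples + ["fold", "class"],
        )

    stage("enrichment")
    if category_map is not None:
        enr_rows = []
        selections: dict[str, set[str]] = {
            f"marked:{s}": a.marked_genes for s, a in assignments.items()
        }
        if fold_classes:
            selections["increased:H3K9ac-RNAi"] = {
                g for g, (cls, _f) in fold_classes.items() if cls == "increased"
            }
        for name, sel in selections.items():
            if not sel:
                continue
            for r in enrich.category_enrichment(
                sel,
                category_map,
                method="hypergeometric",
                fdr_cutoff=config.fdr_cutoff,
                sample=name,
            ):
                enr_rows.append(_enrichment_row(r))
        amio.write_table(
            enr_rows, outdir / "category_enrichment.tsv", _ENRICH_COLS
        )

    if tes and peaks:
        marked_tes = {}
        for s, ps in peaks.items():
            contained = annotate.te_peak_containment(tes, ps)
            marked_tes[s] = [te for te in tes if te.te_id in contained]
        te_rows = [
            _enrichment_row(r)
            for r in enrich.te_family_enrichment(
                marked_tes,
                tes,
                small_count_threshold=config.small_count_threshold,
                p_cutoff=config.te_p_cutoff,
            )
        ]
        amio.write_table(te_rows, outdir / "te_family_enrichment.tsv", _ENRICH_COLS)

    stage("motif")
    if config.genome:
        import pyfaidx

        fasta = pyfaidx.Fasta(config.genome)
        genome = {name: str(fasta[name]) for name in fasta.keys()}
        spec = motif.MotifSpec(
            half_site=config.motif_half_site,
            max_mismatch=config.motif_max_mismatch,
            spacer_min=config.motif_spacer_min,
            spacer_max=config.motif_spacer_max,
        )
        hits = []
        for chrom, seq in genome.items():
            hits.extend(motif.scan_inverted_repeat(seq, spec, chrom=chrom))
        with open(outdir / "motif_hits.bed", "w") as fh:
            for h in hits:
                fh.write(
                    f"{h.chrom}\t{h.start}\t{h.end}\t"
                    f"spacer{h.spacer}_mm{h.mismatch_lead}+{h.mismatch_trail}\t0\t+\n"
                )
        motif_genes = motif.genes_with_motif(genome, genes, spec, flank=config.flank)
        with open(outdir / "motif_genes.tsv", "w") as fh:
            fh.write("#gene_id\n")
            for gid in sorted(motif_genes):
                fh.write(gid + "\n")
        motif_rows = []
        for s, a in assignments.items():
            if not a.marked_genes:
                continue
            r = motif.motif_enrichment(a.marked_genes, motif_genes, universe)
            r.sample = s
            motif_rows.append(_enrichment_row(r))
        amio.write_table(motif_rows, outdir / "motif_enrichment.tsv", _ENRICH_COLS)

    stage("manifest")
    from dataclasses import asdict

    manifest = {
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "n_genes": len(genes),
        "n_tes": len(tes),
        "samples": sorted(set(peaks) | set(tags)),
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    stage("done")
    return outdir


_ENRICH_COLS = [
    "sample", "category", "k", "n", "K", "N", "method", "p", "q", "significant",
]


def _enrichment_row(r: enrich.EnrichmentResult) -> dict:
    return {
        "sample": r.sample,
        "category": r.category,
        "k": r.k,
        "n": r.n,
        "K": r.K,
        "N": r.N,
        "method": r.method,
        "p": f"{r.p:.6g}",
        "q": f"{r.q:.6g}",
        "significant": int(r.significant),
    }
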