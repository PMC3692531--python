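"""Metagene profile arithmetic, stratification, expression tiers and the
3'-peak gene selector."""
import numpy as np
import pytest

from acetylmap.model import ConfigurationError, GeneModel, GenomicInterval, ReadTag
from acetylmap.profiles import (
    expression_tier_density,
    gene_tag_density,
    metagene_profile,
    select_three_prime_peak_genes,
    stratify_by_length,
)


def gene(gid, start, end, strand="+", chrom="chr1", expr=None):
    return GeneModel(gid, GenomicInterval(chrom, start, end, strand), expression=expr)


def tags_at(positions, chrom="chr1", strand="+"):
    return [ReadTag(chrom, p, strand, 36) for p in positions]


class TestMetagene:
    def test_single_tag_lands_in_first_interval(self):
        g = gene("g", 0, 2000)
        pm = metagene_profile(tags_at([40]), [g], body_intervals=20, flank_bp=2000)
        body = pm.density[np.asarray(pm.region_labels) == "body"]
        assert body[0] == pytest.approx(1 / 100)  # 100-bp interval, 1 tag
        assert body[1:].sum() == 0

    def test_minus_strand_gene_is_mirrored(self):
        g = gene("g", 0, 2000, strand="-")
        pm = metagene_profile(tags_at([1960]), [g], body_intervals=20, flank_bp=2000)
        body = pm.density[np.asarray(pm.region_labels) == "body"]
        assert body[0] == pytest.approx(1 / 100)

    def test_uniform_coverage_gives_flat_profile(self):
        g = gene("g", 10_000, 14_000)
        # one tag every 10 bp across the extended region
        positions = range(10_000 - 2000, 14_000 + 2000, 10)
        pm = metagene_profile(tags_at(positions), [g], flank_bp=2000)
        assert pm.density == pytest.approx(np.full(pm.density.size, 0.1), rel=0.05)

    def test_count_conservation(self, small_dataset, wt_tags):
        """Raw interval counts over a gene sum to the number of tag
        assignment points in its extended region."""
        genes = small_dataset.genes[:20]
        pm = metagene_profile(wt_tags, genes, flank_bp=2000)
        pos = {}
        for t in wt_tags:
            pos.setdefault(t.chrom, []).append(t.five_prime_pos)
        pos = {c: np.sort(np.asarray(v)) for c, v in pos.items()}
        for i, gid in enumerate(pm.gene_ids):
            g = next(x for x in genes if x.gene_id == gid)
            iv = g.interval
            p = pos.get(iv.chrom, np.empty(0))
            expected = int(
                np.searchsorted(p, iv.end + 2000) - np.searchsorted(p, iv.start - 2000)
            )
            assert int(pm.counts[i].sum()) == expected

    def test_strand_mirror_invariance(self, small_dataset, wt_tags):
        """Reversing every gene's strand and reflecting tag positions about
        the chromosome midpoint leaves the profile unchanged."""
        genes = [g for g in small_dataset.genes if g.interval.start > 3000][:15]
        L = small_dataset.chrom_lengths["chr1"]
        pm = metagene_profile(wt_tags, genes, flank_bp=2000)
        flip = {"+": "-", "-": "+"}
        rgenes = [
            GeneModel(
                g.gene_id,
                GenomicInterval(
                    g.interval.chrom,
                    L - g.interval.end,
                    L - g.interval.start,
                    flip[g.interval.strand],
                ),
            )
            for g in genes
        ]
        rtags = [
            ReadTag(t.chrom, L - 1 - t.five_prime_pos, flip[t.strand], t.length)
            for t in wt_tags
        ]
        pm_r = metagene_profile(rtags, rgenes, flank_bp=2000)
        assert pm_r.density == pytest.approx(pm.density, rel=1e-12)

    def test_interval_assignment_agrees_with_per_position_scan(self):
        """Oracle: brute-force per-position counting on short genes."""
        rng = np.random.default_rng(2)
        g = gene("g", 5000, 6700)  # 1700 bp body: uneven interval widths
        positions = sorted(int(p) for p in rng.integers(3000, 8700, size=400))
        pm = metagene_profile(tags_at(positions), [g], body_intervals=20, flank_bp=2000)
        # brute force: walk the layout edges position by position
        widths = pm.interval_bp[0]
        edges = np.concatenate([[3000], 3000 + np.cumsum(widths)])
        brute = [
            sum(1 for p in positions if lo <= p < hi)
            for lo, hi in zip(edges[:-1], edges[1:])
        ]
        assert pm.counts[0].tolist() == brute

    def test_fragment_extension_shifts_assignment_point(self):
        g = gene("g", 0, 2000)
        # 5' at 95: unshifted -> interval 1; extension 200 shifts to 195 ->
        # still interval 1; extension 400 shifts to 295 -> interval 3
        pm0 = metagene_profile(tags_at([95]), [g], flank_bp=2000, fragment_extension=0)
        pm4 = metagene_profile(tags_at([95]), [g], flank_bp=2000, fragment_extension=400)
        body0 = pm0.counts[0][np.asarray(pm0.region_labels) == "body"]
        body4 = pm4.counts[0][np.asarray(pm4.region_labels) == "body"]
        assert body0[0] == 1 and body4[2] == 1

    def test_short_genes_skipped_with_warning(self):
        long_g = gene("long", 0, 2000)
        short_g = gene("short", 10_000, 10_010)
        pm = metagene_profile(tags_at([40]), [long_g, short_g], body_intervals=20)
        assert pm.n_genes == 1 and pm.n_skipped == 1

    def test_per_total_normalization(self):
        g = gene("g", 0, 2000)
        pm = metagene_profile(
            tags_at([40, 50]), [g], flank_bp=2000,
            flank_mode="fixed_100bp", normalization="per_bp_per_total",
        )
        body = pm.density[np.asarray(pm.region_labels) == "body"]
        assert body[0] == pytest.approx(2 / 100 / 2)


class TestStratify:
    def test_break_boundary_goes_to_lower_bin(self):
        strata = stratify_by_length([gene("g", 0, 1500)], breaks=[1500])
        assert [g.gene_id for g in strata["<=1500bp"]] == ["g"]

    def test_single_break_two_strata(self):
        genes = [gene("a", 0, 1000), gene("b", 0, 3000)]
        strata = stratify_by_length(genes, breaks=[1500])
        assert len(strata) == 2
        assert sum(len(v) for v in strata.values()) == 2

    def test_partition_of_random_genes(self):
        rng = np.random.default_rng(0)
        genes = [
            gene(f"g{i}", 0, int(l))
            for i, l in enumerate(rng.integers(200, 20_000, size=50))
        ]
        strata = stratify_by_length(genes)
        assert sum(len(v) for v in strata.values()) == 50

    def test_unsorted_breaks_rejected(self):
        with pytest.raises(ConfigurationError):
            stratify_by_length([], breaks=[5000, 1500])


class TestExpressionTiers:
    def test_enumerated_three_genes(self):
        genes = [
            gene("a", 0, 100, expr=1.0),
            gene("b", 0, 100, expr=2.0),
            gene("c", 0, 100, expr=3.0),
        ]
        dens = {"a": 0.1, "b": 0.2, "c": 0.3}
        tiers = expression_tier_density(genes, dens, n_tiers=3)
        assert [t["mean_density"] for t in tiers] == pytest.approx([0.1, 0.2, 0.3])

    def test_constant_density_equal_tiers(self):
        genes = [gene(f"g{i}", 0, 100, expr=float(i)) for i in range(9)]
        dens = {g.gene_id: 0.5 for g in genes}
        tiers = expression_tier_density(genes, dens)
        assert all(t["mean_density"] == pytest.approx(0.5) for t in tiers)

    def test_density_expression_coupling_recovered(self, small_dataset, wt_tags):
        """With acetylation coupled to expression in the generator, tier mean
        densities increase from low to high expression."""
        dens = gene_tag_density(wt_tags, small_dataset.genes, flank=0)
        tiers = expression_tier_density(small_dataset.genes, dens, n_tiers=3)
        means = [t["mean_density"] for t in tiers]
        assert means[0] < means[2]

    def test_too_few_genes_rejected(self):
        with pytest.raises(ConfigurationError):
            expression_tier_density([gene("a", 0, 10, expr=1.0)], {}, n_tiers=3)


class TestThreePrimeSelection:
    def test_flat_gene_not_selected(self):
        g = gene("g", 0, 2000)
        tags = tags_at(range(0, 2000, 20))
        assert select_three_prime_peak_genes(tags, [g]) == set()

    def test_all_tags_in_last_interval_selected(self):
        g = gene("g", 0, 2000)
        tags = tags_at([1950, 1960, 1970])
        assert select_three_prime_peak_genes(tags, [g]) == {"g"}

    def test_injected_three_prime_bump_recovered(self):
        """Genes given a 2x tag bump over their last body tenth are selected
        at ratio cutoff 1.5 in >= 90% of cases."""
        rng = np.random.default_rng(9)
        genes, tags = [], []
        for i in range(40):
            start = i * 10_000
            g = gene(f"g{i}", start, start + 4000)
            genes.append(g)
            # uniform body at rate 0.1/bp, 3' 10% at 0.3/bp (3x)
            n_body = rng.poisson(0.1 * 3600)
            tags += tags_at(start + rng.integers(0, 3600, size=n_body))
            n_tail = rng.poisson(0.3 * 400)
            tags += tags_at(start + 3600 + rng.integers(0, 400, size=n_tail))
        selected = select_three_prime_peak_genes(tags, genes, ratio_cutoff=1.5)
        assert len(selected) >= 36

    def test_degenerate_layout_rejected(self):
        with pytest.raises(ConfigurationError):
            select_three_prime_peak_genes([], [gene("g", 0, 100)], body_intervals=4, last_k=2)
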