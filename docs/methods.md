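# Methods

## Coordinate conventions and marking rules

All intervals are 0-based half-open internally; GFF3 and RepeatMasker
(1-based inclusive) are converted on read and write. Overlap requires at
least one shared base: intervals that merely touch do not overlap, which
keeps every count bit-stable. Two deliberately different marking rules
coexist:

- a **gene** is marked when a peak overlaps its body extended by a
  symmetric flank (default 2000 bp, applied on both sides regardless of
  strand — the genic region definition is strand-free);
- a **transposable element** is marked only when a peak fully contains it.

A peak overlapping several extended genes marks all of them; a peak
touching both a TE-related and a non-TE gene is tabulated in both gene
categories (the double count is inherent to the partition, and noted in
the context summary rather than silently resolved).

## Enrichment statistics

`hypergeom_upper_tail(k, n, K, N)` returns P(X ≥ k) — the
observation-inclusive upper tail — via log-space summation of exact pmf
terms (gammaln + logsumexp), accurate far below the double-precision
underflow limit of direct summation. The one-sided Fisher exact test on
[[a, b], [c, d]] is the same number with k=a, n=a+b, K=a+c, N=a+b+c+d;
the test-suite enforces the identity against scipy's independent Fisher
implementation on 1000 random tables and against exhaustive pmf summation
for N ≤ 60.

Category enrichment uses the hypergeometric tail (or Pearson's
chi-squared without continuity correction, the procedure GO-style tools
apply to flat category maps) followed by Benjamini–Hochberg adjustment at
FDR 0.05; chi-squared being two-sided, significance is additionally
restricted to the over-representation direction. TE-family enrichment
tests each family against the all-family TE universe with n equal to the
total marked copies across every family; the method is recorded as Fisher
below 100 marked copies and hypergeometric above — the two are numerically
identical, the label preserves the historical procedure split —
and significance is called at p < 0.01 without multiplicity correction.

### Tail conventions and irreproducible published cells

The published survey tables this package can re-derive mix two tail
conventions: spot-checking every printed cell shows the wild-type and
RNAi TE rows follow the strict tail P(X > k) (an off-by-one relative to
the inclusive tail), while the increase and Fisher-labelled rows follow
P(X ≥ k); the transcription-factor table and the motif p-value match
neither convention exactly. This implementation uses the inclusive tail
everywhere, because it is the definition of the one-sided Fisher test and
the only choice under which the Fisher/hypergeometric identity holds.
Consequently `scripts/acceptance.py` reproduces the inclusive-tail cells
exactly and deviates from the strict-tail cells by their off-by-one pmf
term; a few published cells (e.g. a total-retroelement binding p of
7.67e-12 where both conventions give ≈1e-21, and an increase-row SINE
value an order of magnitude from either tail) are irreproducible under
any single consistent construction and are treated as defects of the
source tables, not fitted.

## Metagene profiles

Gene bodies are split into `body_intervals` (default 20) equal intervals,
the integer-division remainder going to the 3′-most interval *in gene
orientation*; flanks are split into 20 scaled intervals or fixed 100-bp
intervals. A tag contributes to the interval containing its assignment
point — the 5′ position, optionally shifted by `fragment_extension/2`
toward 3′ (default extension 0, i.e. raw 5′ counting; the upstream
protocol's fragment extension is unknown, so it is a flag). Minus-strand
genes are mirrored so interval 1 is always 5′-most; the remainder rule in
gene orientation is what makes the profile exactly invariant under
genome reflection, a property the suite asserts. Densities are averaged
per gene and then across genes (not pooled; pooling would weight
high-coverage genes more — the per-gene average matches the
equal-gene-weight reading of a metagene curve), and the second
normalisation mode additionally divides by the sample's total tag count.
Genes shorter than `body_intervals` bp are skipped and counted, mirroring
the separate treatment short genes receive in length-stratified analyses.
Expression tiers are equal-size rank tiers (ties broken by gene id,
remainder to lower tiers).

## Signal, fold change and QC

Per-gene signal is the count of tag assignment points in body ± flank,
scaled to tags-per-million so library depth cancels. Fold change between
samples is (b + pseudocount)/(a + pseudocount) with pseudocount 1.0
(zero-signal genes are otherwise undefined), classified at the 2-fold
cutoff; the classification is exactly antisymmetric under sample swap.
The paper-level ambiguity of peak-level vs gene-level ratios is resolved
gene-level, the variant compatible with a per-gene signal table.

Strand cross-correlation: per chromosome with ≥ 100 tags, the Pearson
correlation between the plus-strand 5′-coverage vector and the
minus-strand vector displaced by each shift (1-bp bins by default),
combined across chromosomes weighted by tag count. Fragment length is the
argmax over shifts beyond the read length; background is the curve
minimum over the declared range; NSC = cc_max/cc_bg and
RSC = (cc_max − cc_bg)/(cc(read length) − cc_bg). On displacement-free
input the curve is flat and the metrics are uninformative by design.

## Motif scanning

The inverted repeat is parameterised as an IUPAC half site (default
`GATGGGCCGA`), a per-half mismatch budget (default 1 — the half site is
described as highly conserved, the rest of the discovered 31-bp motif is
not printed anywhere and so cannot be matched exactly), and a spacer range
whose default (0–11) lets the footprint reach the reported 31 bp. Every
(position, spacer) combination is reported; `N` matches nothing; a hit is
described canonically with the leading half on the forward strand, since
the mirror-strand description is the same genomic footprint. The
genome-scan-level published numbers (1209 motif genes, 55/1824 bound)
enter the enrichment checks as printed counts, so the scanner's thresholds
do not influence those statistics.

## Synthetic data generator

The generator emulates the study design at desk scale: two
TSS-architecture acetylation samples (wild type and knock-down) and one
body-architecture binding sample, on a uniform-base genome carrying
non-overlapping genes and intergenic TE copies from the ten-family
vocabulary. Defaults: 200 genes of 1–5 kb on 2 × 1.2 Mb chromosomes,
45%/8% marking of non-TE/TE-related genes, 5% wild-type–knock-down mark
disagreement, 10% binding-target fraction, background 0.01 and focal
0.5 tags/bp, 200-bp fragments, 36-bp reads. Tag placement is a Poisson
mixture — background over the genome plus a focal process over TSS ± 500
bp or the gene body — chosen over read-resampling because closed-form
expectations make recovery tests exact. Each fragment's two ends are
candidate reads retained independently with probability ½, so the
expected yield equals the configured rate while the fragments kept on
both strands pin the cross-correlation peak at the configured fragment
length (a single global fragment length, so QC has one known answer).

Three generator choices keep the miniature's statistics faithful to a
genome-scale experiment rather than to a toy:

- intergenic gaps are at least 4 kb and exponentially dispersed, and TEs
  are placed with a 2.6-kb buffer from gene bodies, so a 2-kb flank can
  never capture a neighbouring feature's focal tags (in a real genome the
  differential signal of one locus does not sit inside another's flank);
- fold-change injection recruits at most a handful of genes
  (`fold_target_max_genes`, default 5), keeping the differential tag mass
  a small fraction of the library as in the real survey — otherwise
  per-million scaling visibly compresses the very fold it should measure;
- a TE-family boost shifts the *composition* of the marked-TE set toward
  the boosted family while holding the expected total constant (the
  published marked-TE totals barely differ between conditions), so
  library sizes stay comparable across samples.

Truth tables (per-sample marked genes and TEs, injected folds, enriched
categories, motif-bearing genes, fragment length) are written beside the
data; recovery tests consume truth, the pipeline never does. The
generator does not model sequencing error, mappability, duplicates or
diploidy, and its uniform-base genome has none of the repeat structure of
a real one — passing recovery tests therefore demonstrates correctness of
the downstream arithmetic under the stated statistical model, not
robustness to alignment artefacts.

The naive sliding-window peak caller (windows whose count exceeds a fold
cutoff times the expected background, merged when overlapping; summit at
the densest window's centre) exists so end-to-end synthetic runs need no
external caller; it is plumbing, not a contribution, and real analyses
should keep consuming externally called peaks.

## Problem sizes used by the test-suite and acceptance script

The session fixture is one 1.4-Mb chromosome with 150 genes (~45k tags
per sample); the 100-seed recovery check runs at the 1000-gene,
annotation-only scale where category and TE-family recovery have ample
power (≥ 95/100 seeds with ≤ 10% neutral false positives); the published
statistics are recomputed over the full printed universes (56 798 genes,
301 830 TE copies), which the exact engine handles in milliseconds.

## Known limitations

Chromosome names are compared as exact strings (no "chr" normalisation —
silent renaming hides input errors). The RepeatMasker reader keeps only
coordinates and the normalised family. The cross-correlation background
uses the curve minimum, which on very sparse toy inputs can sit near zero
and inflate NSC; chromosomes with < 100 tags are excluded for this
reason. GO hierarchies are consumed as flat category maps — no ontology
propagation. All tests are one-sided by design; depletion is out of
scope.
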