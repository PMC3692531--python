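"""Reference contingency counts from a genome-scale rice survey of H3K9
acetylation and OsSRT1 binding (MSU6.0 gene annotation: 56798 loci of which
1728 are transcription-factor genes; RepeatMasker TE annotation: 301830
copies).  These printed counts are inputs: the enrichment engines recompute
every test statistic from them at run time.

The retroelement table reports Copia, Gypsy, a "total LTR" column that also
covers minor LTR families, LINE and SINE; the minor-LTR family ("LTR_other")
is derived here as total LTR minus Copia minus Gypsy so the copy counts sum
exactly to the published class totals (84929 retroelements, 216901 DNA
elements).
"""
from __future__ import annotations

from .model import CategoryMap, TEFeature, GenomicInterval

GENE_UNIVERSE = 56_798
TF_GENES = 1_728
MOTIF_GENES = 1_209

#: selection label -> (selection size n, TF genes in the selection k)
TF_SELECTIONS: dict[str, tuple[int, int]] = {
    "h3k9ac_increased_rnai": (3688, 182),
    "srt1_binding": (1824, 73),
    "srt1_binding_with_h3k9ac": (755, 34),
    "srt1_binding_with_h3k9ac_increase": (157, 9),
}

#: motif-bearing genes among binding targets: (bound n, motif-bearing k)
MOTIF_SELECTION: tuple[int, int] = (1824, 55)

#: genome-wide TE copy numbers per family
TE_UNIVERSE_COUNTS: dict[str, int] = {
    "Copia": 12_562,
    "Gypsy": 54_330,
    "LTR_other": 3_106,  # total LTR 69998 minus Copia minus Gypsy
    "LINE": 6_627,
    "SINE": 8_304,
    "hAT": 10_714,
    "En-Spm": 29_433,
    "MITE": 108_347,
    "Mutator": 41_408,
    "Helitron": 11_766,
    "Unclassified": 15_233,
}

#: marked-TE counts per family for each survey row; row totals are
#: 12442 (WT), 11918 (RNAi), 4162 (increase) and 985 (binding)
TE_MARKED_COUNTS: dict[str, dict[str, int]] = {
    "H3K9ac-WT": {
        "Copia": 222, "Gypsy": 690, "LTR_other": 62, "LINE": 289, "SINE": 378,
        "hAT": 497, "En-Spm": 746, "MITE": 5720, "Mutator": 3000,
        "Helitron": 220, "Unclassified": 618,
    },
    "H3K9ac-RNAi": {
        "Copia": 232, "Gypsy": 739, "LTR_other": 61, "LINE": 316, "SINE": 312,
        "hAT": 486, "En-Spm": 737, "MITE": 5480, "Mutator": 2722,
        "Helitron": 217, "Unclassified": 616,
    },
    "H3K9ac-increase": {
        "Copia": 89, "Gypsy": 277, "LTR_other": 17, "LINE": 126, "SINE": 97,
        "hAT": 162, "En-Spm": 286, "MITE": 2043, "Mutator": 739,
        "Helitron": 89, "Unclassified": 237,
    },
    "SRT1": {
        "Copia": 50, "Gypsy": 287, "LTR_other": 13, "LINE": 44, "SINE": 22,
        "hAT": 29, "En-Spm": 111, "MITE": 220, "Mutator": 166,
        "Helitron": 23, "Unclassified": 20,
    },
}

_RETRO = {"Copia", "Gypsy", "LTR_other", "LINE", "SINE"}


def tf_category_map() -> CategoryMap:
    """CategoryMap with one 'TF' category of the published size over the
    published gene universe."""
    mapping = {f"LOC_TF{i:05d}": {"TF"} for i in range(TF_GENES)}
    return CategoryMap(mapping=mapping, universe_size=GENE_UNIVERSE)


def tf_selection(n: int, k: int) -> list[str]:
    """A gene selection of size n containing exactly k TF genes."""
    sel = [f"LOC_TF{i:05d}" for i in range(k)]
    sel += [f"LOC_Os{i:06d}" for i in range(n - k)]
    return sel


def build_te_universe() -> list[TEFeature]:
    """One TEFeature per annotated copy (coordinates are placeholders; only
    family identity enters the counting)."""
    iv = GenomicInterval("chr1", 0, 1)
    tes: list[TEFeature] = []
    i = 0
    for family, count in TE_UNIVERSE_COUNTS.items():
        te_class = "retroelement" if family in _RETRO else "DNA element"
        for _ in range(count):
            i += 1
            tes.append(
                TEFeature(te_id=f"te{i}", interval=iv, family=family, te_class=te_class)
            )
    return tes


def marked_te_sets(universe: list[TEFeature]) -> dict[str, list[TEFeature]]:
    """Per-row marked-TE lists drawn from the universe with the published
    per-family counts."""
    by_family: dict[str, list[TEFeature]] = {}
    for te in universe:
        by_family.setdefault(te.family, []).append(te)
    rows: dict[str, list[TEFeature]] = {}
    for row, counts in TE_MARKED_COUNTS.items():
        rows[row] = [
            te for family, k in counts.items() for te in by_family[family][:k]
        ]
    return rows
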