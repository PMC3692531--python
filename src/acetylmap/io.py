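"""Readers and writers for the standard formats the pipeline touches.

Supported inputs: GFF3 and BED for gene models, RepeatMasker ``.out`` (or
BED with a family column) for transposable elements, BED or MACS-style tab
text for peaks, BED6 for mapped tags, two-column tab text for expression
values and gene->category maps.  Everything is converted to the internal
0-based half-open convention on read (GFF3 and RepeatMasker are 1-based
inclusive on disk).

All table outputs are tab-separated with a header line beginning ``#``.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Union

from .model import (
    CategoryMap,
    GeneModel,
    GenomicInterval,
    ParseError,
    ConfigurationError,
    Peak,
    ReadTag,
    TEFeature,
    normalize_te_family,
    UNSTRANDED,
)

log = logging.getLogger(__name__)

PathLike = Union[str, Path]


def _lines(path: PathLike):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            yield lineno, line


def _parse_int(value: str, what: str, path: PathLike, lineno: int) -> int:
    try:
        return int(value)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: non-integer {what} {value!r}") from None


def _interval(
    chrom: str, start: int, end: int, strand: str, path: PathLike, lineno: int
) -> GenomicInterval:
    try:
        return GenomicInterval(chrom, start, end, strand)
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: {exc}") from None


# ---------------------------------------------------------------------------
# annotations


def read_annotations(path: PathLike, format: str):
    """Read gene models or TE features.

    ``format`` is one of ``gff3``, ``bed12``, ``bed6`` (genes) or
    ``repeatmasker_out`` (TEs).  Coordinates are converted to 0-based
    half-open; a GFF3/RepeatMasker start ``s`` becomes internal ``s - 1``.
    """
    if format == "gff3":
        return _read_gff3_genes(path)
    if format in ("bed6", "bed12"):
        return _read_bed_genes(path)
    if format == "repeatmasker_out":
        return _read_repeatmasker(path)
    raise ConfigurationError(f"unknown annotation format {format!r}")


def _gff3_attributes(field: str) -> dict[str, str]:
    attrs = {}
    for part in field.split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            attrs[k.strip()] = v.strip()
    return attrs


def _read_gff3_genes(path: PathLike) -> list[GeneModel]:
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for lineno, line in _lines(path):
        if line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 9:
            raise ParseError(f"{path}:{lineno}: GFF3 needs 9 columns, got {len(cols)}")
        chrom, _source, ftype, start, end, _score, strand, _phase, attr = cols[:9]
        if ftype != "gene":
            continue
        s = _parse_int(start, "start", path, lineno)
        e = _parse_int(end, "end", path, lineno)
        if strand not in ("+", "-"):
            strand = UNSTRANDED
        iv = _interval(chrom, s - 1, e, strand, path, lineno)
        attrs = _gff3_attributes(attr)
        gene_id = attrs.get("ID") or attrs.get("Name")
        if not gene_id:
            raise ParseError(f"{path}:{lineno}: gene record without ID attribute")
        if gene_id in seen:
            raise ParseError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        expr = attrs.get("expression")
        genes.append(
            GeneModel(
                gene_id=gene_id,
                interval=iv,
                is_te_related=attrs.get("is_te_related", "0") in ("1", "true", "True"),
                tf_family=attrs.get("tf_family") or None,
                expression=float(expr) if expr is not None else None,
            )
        )
    return genes


def _read_bed_genes(path: PathLike) -> list[GeneModel]:
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for lineno, line in _lines(path):
        if line.startswith(("#", "track", "browser")):
            continue
        cols = line.split("\t")
        if len(cols) < 3:
            raise ParseError(f"{path}:{lineno}: BED needs >= 3 columns")
        chrom = cols[0]
        s = _parse_int(cols[1], "start", path, lineno)
        e = _parse_int(cols[2], "end", path, lineno)
        name = cols[3] if len(cols) > 3 else f"feature_{lineno}"
        strand = cols[5] if len(cols) > 5 and cols[5] in ("+", "-") else UNSTRANDED
        if name in seen:
            raise ParseError(f"{path}:{lineno}: duplicate gene_id {name!r}")
        seen.add(name)
        genes.append(GeneModel(gene_id=name, interval=_interval(chrom, s, e, strand, path, lineno)))
    return genes


def _read_repeatmasker(path: PathLike) -> list[TEFeature]:
    """Parse RepeatMasker ``.out``: keep chrom, coordinates and family only.

    Family strings are normalised to the ten-family vocabulary via the alias
    table ("LTR/Gypsy" -> Gypsy).  Coordinates on disk are 1-based inclusive.
    """
    tes: list[TEFeature] = []
    for lineno, line in _lines(path):
        stripped = line.strip()
        low = stripped.lower()
        if low.startswith(("sw", "score")) or not stripped[0].isdigit():
            continue  # the two header lines
        cols = stripped.split()
        if len(cols) < 11:
            raise ParseError(f"{path}:{lineno}: RepeatMasker row needs >= 11 columns")
        chrom = cols[4]
        s = _parse_int(cols[5], "start", path, lineno)
        e = _parse_int(cols[6], "end", path, lineno)
        family = normalize_te_family(cols[10])
        iv = _interval(chrom, s - 1, e, UNSTRANDED, path, lineno)
        tes.append(TEFeature(te_id=f"te_{len(tes) + 1}", interval=iv, family=family))
    return tes


# ---------------------------------------------------------------------------
# peaks


def read_peaks(path: PathLike, format: str, sample: str) -> list[Peak]:
    """Read peak calls; ``format`` is ``bed`` or ``macs_tab``.

    ``sample`` labels every peak.  ``tag_count`` is taken from the
    score/pileup column when present, else 0.
    """
    if format == "bed":
        peaks = _read_bed_peaks(path, sample)
    elif format == "macs_tab":
        peaks = _read_macs_peaks(path, sample)
    else:
        raise ConfigurationError(f"unknown peak format {format!r}")
    if not peaks:
        log.warning("no peaks read from %s", path)
    return peaks


def _read_bed_peaks(path: PathLike, sample: str) -> list[Peak]:
    peaks: list[Peak] = []
    for lineno, line in _lines(path):
        if line.startswith(("#", "track", "browser")):
            continue
        cols = line.split("\t")
        if len(cols) < 3:
            raise ParseError(f"{path}:{lineno}: BED needs >= 3 columns")
        iv = _interval(
            cols[0],
            _parse_int(cols[1], "start", path, lineno),
            _parse_int(cols[2], "end", path, lineno),
            UNSTRANDED,
            path,
            lineno,
        )
        name = cols[3] if len(cols) > 3 else f"{sample}_peak_{len(peaks) + 1}"
        tag_count = 0
        if len(cols) > 4:
            try:
                tag_count = int(float(cols[4]))
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric score {cols[4]!r}")
        peaks.append(Peak(sample=sample, interval=iv, tag_count=tag_count, peak_id=name))
    return peaks


def _read_macs_peaks(path: PathLike, sample: str) -> list[Peak]:
    """MACS-style tab text: chrom, start (1-based), end, length, summit
    (1-based offset), tags, ... ; header lines start with '#' or 'chr'."""
    peaks: list[Peak] = []
    for lineno, line in _lines(path):
        if line.startswith("#") or line.lower().startswith("chr\t"):
            continue
        cols = line.split("\t")
        if len(cols) < 6:
            raise ParseError(f"{path}:{lineno}: MACS row needs >= 6 columns")
        s = _parse_int(cols[1], "start", path, lineno)
        iv = _interval(
            cols[0], s - 1, _parse_int(cols[2], "end", path, lineno),
            UNSTRANDED, path, lineno,
        )
        summit = _parse_int(cols[4], "summit", path, lineno) - 1
        tags = _parse_int(cols[5], "tags", path, lineno)
        peaks.append(
            Peak(
                sample=sample,
                interval=iv,
                summit=summit if 0 <= summit < len(iv) else None,
                tag_count=tags,
                peak_id=f"{sample}_peak_{len(peaks) + 1}",
            )
        )
    return peaks


# ---------------------------------------------------------------------------
# tags


def read_tags(path: PathLike) -> list[ReadTag]:
    """Read mapped tags from BED6; the strand column is required.

    The 5' position is ``start`` on the + strand and ``end - 1`` on the -
    strand; ``length = end - start``.
    """
    tags: list[ReadTag] = []
    for lineno, line in _lines(path):
        if line.startswith(("#", "track", "browser")):
            continue
        cols = line.split("\t")
        if len(cols) < 6:
            raise ParseError(
                f"{path}:{lineno}: tag BED needs 6 columns (strand required)"
            )
        s = _parse_int(cols[1], "start", path, lineno)
        e = _parse_int(cols[2], "end", path, lineno)
        strand = cols[5]
        if strand not in ("+", "-"):
            raise ParseError(f"{path}:{lineno}: invalid strand {strand!r}")
        if not 0 <= s < e:
            raise ParseError(f"{path}:{lineno}: require 0 <= start < end")
        tags.append(
            ReadTag(
                chrom=cols[0],
                five_prime_pos=s if strand == "+" else e - 1,
                strand=strand,
                length=e - s,
            )
        )
    return tags


# ---------------------------------------------------------------------------
# simple tables


def read_expression(path: PathLike) -> dict[str, float]:
    """Two-column tab text: gene_id <TAB> value (log2 microarray scale)."""
    out: dict[str, float] = {}
    for lineno, line in _lines(path):
        if line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 2:
            raise ParseError(f"{path}:{lineno}: expected gene_id<TAB>value")
        try:
            out[cols[0]] = float(cols[1])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-numeric value {cols[1]!r}")
    return out


def read_category_map(path: PathLike, universe_size: int) -> CategoryMap:
    """Two-column tab text: gene_id <TAB> category (one pair per line)."""
    mapping: dict[str, set[str]] = {}
    for lineno, line in _lines(path):
        if line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 2:
            raise ParseError(f"{path}:{lineno}: expected gene_id<TAB>category")
        mapping.setdefault(cols[0], set()).add(cols[1])
    return CategoryMap(mapping=mapping, universe_size=universe_size)


# ---------------------------------------------------------------------------
# writers


def write_bed(features: Iterable, path: PathLike) -> None:
    """Write GeneModel, TEFeature, Peak or ReadTag records as BED6."""
    with open(path, "w") as fh:
        for f in features:
            if isinstance(f, ReadTag):
                if f.strand == "+":
                    s, e = f.five_prime_pos, f.five_prime_pos + f.length
                else:
                    s, e = f.five_prime_pos - f.length + 1, f.five_prime_pos + 1
                fh.write(f"{f.chrom}\t{s}\t{e}\ttag\t0\t{f.strand}\n")
                continue
            iv = f.interval
            name = getattr(f, "gene_id", None) or getattr(f, "te_id", None) or getattr(
                f, "peak_id", ""
            ) or "feature"
            score = getattr(f, "tag_count", 0)
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


def write_gff3(genes: Iterable[GeneModel], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            attrs = [f"ID={g.gene_id}", f"is_te_related={int(g.is_te_related)}"]
            if g.tf_family:
                attrs.append(f"tf_family={g.tf_family}")
            if g.expression is not None:
                attrs.append(f"expression={g.expression:.6g}")
            fh.write(
                f"{iv.chrom}\tacetylmap\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand if iv.strand != '.' else '+'}\t.\t{';'.join(attrs)}\n"
            )


def write_repeatmasker(tes: Iterable[TEFeature], path: PathLike) -> None:
    """Write a minimal RepeatMasker-style ``.out`` (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write(
            "   SW  perc perc perc  query      position in query    matching"
            "       repeat              position in  repeat\n"
            "score  div. del. ins.  sequence    begin     end    (left)   "
            "repeat class/family         begin  end (left)   ID\n"
        )
        for i, t in enumerate(tes, start=1):
            iv = t.interval
            fh.write(
                f"  225  10.0  0.0  0.0  {iv.chrom}  {iv.start + 1}  {iv.end}  (0)  +  "
                f"{t.te_id}  {t.family}  1  {len(iv)}  (0)  {i}\n"
            )


def write_table(rows: Iterable[dict], path: PathLike, columns: list[str]) -> None:
    """Tab-separated table with a '#'-prefixed header line."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in columns) + "\n")
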