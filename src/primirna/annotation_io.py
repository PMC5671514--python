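"""GFF3 and GTF reading/writing.

Both formats are 9-column tab-separated with 1-based inclusive
coordinates; they differ only in the attribute syntax of column 9
(GFF3: ``key=value;``, GTF: ``key "value";``). Coordinates are taken
verbatim. Records whose type is not covered by the caller's biotype map
are counted and skipped, never guessed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from .features import Biotype, FeatureSet, GeneFeature
from .intervals import GenomicInterval

log = logging.getLogger(__name__)

#: GFF3 attribute characters that must be percent-escaped for round-tripping.
_GFF3_ESCAPES = {"%": "%25", ";": "%3B", "=": "%3D", ",": "%2C", "\t": "%09", "\n": "%0A"}

#: Types written by :func:`write_gff3`, mapping back onto themselves so the
#: package's own output files re-read without configuration.
OWN_TYPES: dict[str, Biotype] = {bt.value: bt for bt in Biotype}

#: A reasonable default for Araport11-style annotations; the hairpin
#: record type is a user decision (``miRNA`` vs ``miRNA_primary_transcript``),
#: so both map to hairpins here and callers can override.
ARAPORT_LIKE_TYPES: dict[str, Biotype] = {
    "miRNA": Biotype.PRE_MIRNA,
    "miRNA_primary_transcript": Biotype.PRE_MIRNA,
    "gene": Biotype.PROTEIN_CODING,
    "protein_coding_gene": Biotype.PROTEIN_CODING,
    "ncRNA": Biotype.NON_CODING,
    "lnc_RNA": Biotype.NON_CODING,
    "ncRNA_gene": Biotype.NON_CODING,
    **OWN_TYPES,
}


class AnnotationParseError(ValueError):
    """Malformed GFF3/GTF content; the message names the offending line."""


def _escape(value: str) -> str:
    for raw, esc in _GFF3_ESCAPES.items():
        value = value.replace(raw, esc)
    return value


def _unescape(value: str) -> str:
    for raw, esc in _GFF3_ESCAPES.items():
        value = value.replace(esc, raw)
    return value


def _parse_gff3_attributes(col9: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in col9.strip().split(";"):
        chunk = chunk.strip()
        if not chunk or chunk == ".":
            continue
        if "=" not in chunk:
            raise AnnotationParseError(f"line {lineno}: malformed GFF3 attribute {chunk!r}")
        key, value = chunk.split("=", 1)
        attrs[_unescape(key)] = _unescape(value)
    return attrs


def _parse_gtf_attributes(col9: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in col9.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            raise AnnotationParseError(f"line {lineno}: malformed GTF attribute {chunk!r}")
        key, value = chunk.split(" ", 1)
        attrs[key] = value.strip().strip('"')
    return attrs


def _split_columns(line: str, lineno: int) -> list[str]:
    cols = line.rstrip("\n").split("\t")
    if len(cols) != 9:
        raise AnnotationParseError(
            f"line {lineno}: expected 9 tab-separated columns, got {len(cols)}"
        )
    return cols


def _parse_coords(cols: list[str], lineno: int) -> GenomicInterval:
    try:
        start, end = int(cols[3]), int(cols[4])
    except ValueError:
        raise AnnotationParseError(
            f"line {lineno}: non-integer coordinates {cols[3]!r}/{cols[4]!r}"
        ) from None
    if start < 1 or end < start:
        raise AnnotationParseError(
            f"line {lineno}: invalid interval [{start}, {end}] (need 1 <= start <= end)"
        )
    strand = cols[6] if cols[6] in ("+", "-") else "."
    return GenomicInterval(cols[0], start, end, strand)


def read_gff3(
    path: str | Path,
    biotype_map: Mapping[str, Biotype] | None = None,
) -> FeatureSet:
    """Read a GFF3 file into a :class:`FeatureSet`.

    ``biotype_map`` maps GFF3 column-3 types onto package biotypes
    (default: :data:`ARAPORT_LIKE_TYPES`). Records with unmapped types
    are skipped; the skipped-per-type tally is logged. A record's id is
    its ``ID`` attribute, falling back to ``Name``; duplicate ids raise.
    """
    biotype_map = dict(biotype_map if biotype_map is not None else ARAPORT_LIKE_TYPES)
    if not biotype_map:
        raise ValueError("biotype_map must cover at least one GFF3 type")
    fs = FeatureSet()
    skipped: dict[str, int] = {}
    anon = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = _split_columns(line, lineno)
            ftype = cols[2]
            if ftype not in biotype_map:
                skipped[ftype] = skipped.get(ftype, 0) + 1
                continue
            interval = _parse_coords(cols, lineno)
            attrs = _parse_gff3_attributes(cols[8], lineno)
            fid = attrs.get("ID") or attrs.get("Name")
            if fid is None:
                anon += 1
                fid = f"{ftype}_{lineno}"
            fs.add(GeneFeature(fid, interval, biotype_map[ftype], attrs))
    if skipped:
        log.info("read_gff3(%s): skipped unmapped types %s", path, skipped)
    return fs


def write_gff3(fs: FeatureSet, path: str | Path, *, source: str = "primirna") -> None:
    """Write a FeatureSet as GFF3, one record per feature, sorted by
    (chrom, start, id). Round-trips through :func:`read_gff3` with the
    default type map."""
    if len(fs) == 0:
        raise ValueError("refusing to write an empty FeatureSet")
    feats = sorted(fs, key=lambda f: (f.interval.chrom, f.interval.start, f.id))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in feats:
            attrs = dict(f.attributes)
            attrs["ID"] = f.id
            col9 = ";".join(f"{_escape(k)}={_escape(v)}" for k, v in attrs.items())
            fh.write(
                "\t".join(
                    [
                        f.interval.chrom,
                        source,
                        f.biotype.value,
                        str(f.interval.start),
                        str(f.interval.end),
                        ".",
                        f.interval.strand,
                        ".",
                        col9,
                    ]
                )
                + "\n"
            )


def write_gtf(fs: FeatureSet, path: str | Path, *, source: str = "primirna") -> None:
    """Write transcript-model features as GTF (one transcript line plus
    its exon lines, from the ``exons`` attribute or the full span)."""
    feats = sorted(
        (f for f in fs if f.biotype is Biotype.TRANSCRIPT_MODEL),
        key=lambda f: (f.interval.chrom, f.interval.start, f.id),
    )
    with open(path, "w") as fh:
        for f in feats:
            gene_id = f.attributes.get("gene_id", f.id)
            attrs = f'gene_id "{gene_id}"; transcript_id "{f.id}";'
            exons = f.attributes.get("exons", f"{f.interval.start}-{f.interval.end}")
            rows = [("transcript", f.interval.start, f.interval.end)]
            rows += [
                ("exon", int(s), int(e))
                for s, e in (chunk.split("-") for chunk in exons.split(","))
            ]
            for ftype, s, e in rows:
                fh.write(
                    "\t".join(
                        [
                            f.interval.chrom,
                            source,
                            ftype,
                            str(s),
                            str(e),
                            ".",
                            f.interval.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def read_gtf_transcripts(path: str | Path) -> FeatureSet:
    """Read assembled transcript models from a GTF file.

    Produces one ``transcript_model`` feature per ``transcript_id``,
    spanning from the first exon start to the last exon end; the exon
    structure is retained in the ``exons`` attribute as
    ``"start-end,start-end,..."``.
    """
    spans: dict[str, list] = {}  # tid -> [chrom, strand, [(s,e), ...], gene_id]
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = _split_columns(line, lineno)
            if cols[2] not in ("exon", "transcript"):
                continue
            interval = _parse_coords(cols, lineno)
            attrs = _parse_gtf_attributes(cols[8], lineno)
            tid = attrs.get("transcript_id")
            if tid is None:
                raise AnnotationParseError(
                    f"line {lineno}: {cols[2]} record without transcript_id"
                )
            if tid not in spans:
                spans[tid] = [interval.chrom, interval.strand, [], attrs.get("gene_id", tid)]
                order.append(tid)
            rec = spans[tid]
            if interval.chrom != rec[0]:
                raise AnnotationParseError(
                    f"line {lineno}: transcript {tid} spans multiple chromosomes"
                )
            if cols[2] == "exon":
                rec[2].append((interval.start, interval.end))
            elif not rec[2]:
                # remember the transcript line's span for exonless entries
                rec[2].append((interval.start, interval.end))
    fs = FeatureSet()
    for tid in order:
        chrom, strand, exons, gene_id = spans[tid]
        exons.sort()
        iv = GenomicInterval(chrom, exons[0][0], max(e for _, e in exons), strand)
        attrs = {
            "transcript_id": tid,
            "gene_id": gene_id,
            "exons": ",".join(f"{s}-{e}" for s, e in exons),
        }
        fs.add(GeneFeature(tid, iv, Biotype.TRANSCRIPT_MODEL, attrs))
    return fs
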