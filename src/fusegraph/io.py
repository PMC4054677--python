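"""Readers and writers for caller outputs, gene models, and the fusion report.

Structural-rearrangement (GSR) calls arrive as tabular text in one of three
dialects: a generic seven-column TSV, a BreakDancer-style row, or a
CREST-style soft-clip row.  Fusion candidates arrive as a generic TSV of
gene pairs with two genomic positions.  Gene models are read from BED12
(0-based half-open, converted to 1-based inclusive at ingest) or GTF
(1-based inclusive, parsed through gffutils).

Every reader is total over its grammar: each line yields a record, a logged
filtered drop, or a line-numbered error.  Chromosome names lose an optional
``chr`` prefix at ingest, and caller scores of 0 are clamped to 1 because
score 0 is reserved for null (reference) edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .core import (
    BreakEnd,
    Breakpoint,
    BreakpointPath,
    GenomicPosition,
    format_path,
    natural_chrom_key,
    strip_chr,
)

logger = logging.getLogger("fusegraph")

__all__ = [
    "GeneModel",
    "FusionCandidate",
    "ValidatedFusion",
    "FormatError",
    "read_gsr_generic",
    "read_gsr_breakdancer",
    "read_gsr_crest",
    "read_fusions_generic",
    "read_gene_models",
    "write_gene_models_bed12",
    "write_report",
    "DEFAULT_MIN_SPAN",
]

#: Minimum intra-chromosomal span (bp) kept at GSR ingest.  Short local
#: events are overwhelmingly alignment artifacts at typical insert sizes.
DEFAULT_MIN_SPAN = 1000


class FormatError(ValueError):
    """A line of an input file violates its declared grammar."""


@dataclass(frozen=True)
class GeneModel:
    """A flattened gene: id, strand, 1-based inclusive span, optional exons."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")
        if self.exons is not None:
            prev = None
            for s, e in self.exons:
                if s < self.start or e > self.end or s > e:
                    raise ValueError(f"gene {self.gene_id}: exon ({s},{e}) outside span")
                if prev is not None and s <= prev:
                    raise ValueError(f"gene {self.gene_id}: exons overlap or unsorted")
                prev = e

    def contains(self, pos: GenomicPosition, pad: int = 0) -> bool:
        return pos.chrom == self.chrom and self.start - pad <= pos.pos <= self.end + pad

    @property
    def tx_start(self) -> int:
        """First transcribed base (5' end in transcription order)."""
        return self.start if self.strand == "+" else self.end

    @property
    def tx_end(self) -> int:
        """Last transcribed base (3' end in transcription order)."""
        return self.end if self.strand == "+" else self.start


@dataclass(frozen=True)
class FusionCandidate:
    """A putative fusion: 5' gene, 3' gene, and the two transcript-side positions."""

    gene5: str
    gene3: str
    x: GenomicPosition
    y: GenomicPosition
    source: str = ""

    @property
    def pair(self) -> str:
        return f"{self.gene5}>{self.gene3}"


@dataclass(frozen=True)
class ValidatedFusion:
    """A fusion candidate with at least one supporting genomic allele."""

    candidate: FusionCandidate
    alleles: tuple  # of BreakpointPath
    anchors: tuple = ()  # of (x0 BreakEnd, y0 BreakEnd) per allele
    sources: tuple = ()  # caller tags of merged redundant candidates


# --------------------------------------------------------------------------
# GSR readers
# --------------------------------------------------------------------------


def _data_lines(path) -> Iterable[tuple]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def _mk_end(chrom: str, pos: str, strand: str, path, lineno: int) -> BreakEnd:
    if strand not in ("+", "-"):
        raise FormatError(f"{path}:{lineno}: bad strand token {strand!r}")
    try:
        p = int(pos)
    except ValueError:
        raise FormatError(f"{path}:{lineno}: non-integer position {pos!r}") from None
    try:
        return BreakEnd(GenomicPosition(strip_chr(chrom), p), strand)
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: {exc}") from exc


def _keep_span(b: Breakpoint, min_span: int, path, lineno: int) -> bool:
    if b.in_end.chrom == b.out_end.chrom:
        span = abs(b.in_end.pos - b.out_end.pos)
        if span < min_span:
            logger.info(
                "%s:%d: dropped intra-chromosomal call spanning %d bp (< %d)",
                path, lineno, span, min_span,
            )
            return False
    return True


def _clamp_score(score: int) -> int:
    # score 0 is the null-edge sentinel; a caller call with 0 reads keeps
    # minimal support rather than masquerading as a reference adjacency
    return max(score, 1)


def read_gsr_generic(path, min_span: int = DEFAULT_MIN_SPAN) -> list:
    """Read the generic GSR TSV: chrom1 pos1 strand1 chrom2 pos2 strand2 score."""
    out = []
    for lineno, cols in _data_lines(path):
        if len(cols) != 7:
            raise FormatError(f"{path}:{lineno}: expected 7 columns, got {len(cols)}")
        in_end = _mk_end(cols[0], cols[1], cols[2], path, lineno)
        out_end = _mk_end(cols[3], cols[4], cols[5], path, lineno)
        try:
            score = int(cols[6])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-integer score {cols[6]!r}") from None
        if score < 0:
            raise FormatError(f"{path}:{lineno}: negative score {score}")
        b = Breakpoint(in_end, out_end, _clamp_score(score))
        if _keep_span(b, min_span, path, lineno):
            out.append(b)
    return out


def _majority_strand(orientation: str, path, lineno: int) -> str:
    """Majority strand of a BreakDancer orientation token such as ``34+12-``."""
    import re

    m = re.fullmatch(r"(\d+)\+(\d+)-", orientation)
    if not m:
        raise FormatError(
            f"{path}:{lineno}: malformed orientation token {orientation!r}"
        )
    fwd, rev = int(m.group(1)), int(m.group(2))
    return "+" if fwd >= rev else "-"


def read_gsr_breakdancer(path, min_span: int = DEFAULT_MIN_SPAN) -> list:
    """Adapter for BreakDancer-style rows.

    Columns: chr1 pos1 orientation1 chr2 pos2 orientation2 type size score
    num_reads.  The in-end strand is the majority strand at the first end;
    the out-end strand is the flip of the majority at the second end (reads
    there point back toward the junction).  num_reads becomes the score.
    """
    out = []
    for lineno, cols in _data_lines(path):
        if len(cols) < 10:
            raise FormatError(f"{path}:{lineno}: expected 10 columns, got {len(cols)}")
        s1 = _majority_strand(cols[2], path, lineno)
        s2 = _majority_strand(cols[5], path, lineno)
        in_end = _mk_end(cols[0], cols[1], s1, path, lineno)
        out_end = _mk_end(cols[3], cols[4], "+" if s2 == "-" else "-", path, lineno)
        try:
            num_reads = int(cols[9])
        except ValueError:
            raise FormatError(
                f"{path}:{lineno}: non-integer read count {cols[9]!r}"
            ) from None
        b = Breakpoint(in_end, out_end, _clamp_score(num_reads))
        if _keep_span(b, min_span, path, lineno):
            out.append(b)
    return out


def read_gsr_crest(path, min_span: int = DEFAULT_MIN_SPAN) -> list:
    """Best-effort adapter for CREST-style soft-clip rows.

    Columns: chrom1 pos1 strand1 softclip1 chrom2 pos2 strand2 softclip2
    [type ...].  Strands are taken as written; the score is the larger of
    the two soft-clip counts.
    """
    out = []
    for lineno, cols in _data_lines(path):
        if len(cols) < 8:
            raise FormatError(f"{path}:{lineno}: expected >= 8 columns, got {len(cols)}")
        in_end = _mk_end(cols[0], cols[1], cols[2], path, lineno)
        out_end = _mk_end(cols[4], cols[5], cols[6], path, lineno)
        try:
            score = max(int(cols[3]), int(cols[7]))
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-integer soft-clip count") from None
        b = Breakpoint(in_end, out_end, _clamp_score(score))
        if _keep_span(b, min_span, path, lineno):
            out.append(b)
    return out


# --------------------------------------------------------------------------
# fusion candidates
# --------------------------------------------------------------------------


def read_fusions_generic(
    path,
    genes: Optional[Sequence[GeneModel]] = None,
    dedupe: bool = False,
) -> list:
    """Read the fusion TSV: gene5 chrom5 pos5 gene3 chrom3 pos3 source.

    When gene models are supplied, candidates naming unknown genes or whose
    positions fall outside the named gene's span are retained with a logged
    warning; the search skips them later with a reason.
    """
    by_id = {g.gene_id: g for g in genes} if genes else {}
    out = []
    seen = set()
    for lineno, cols in _data_lines(path):
        if len(cols) != 7:
            raise FormatError(f"{path}:{lineno}: expected 7 columns, got {len(cols)}")
        try:
            x = GenomicPosition(strip_chr(cols[1]), int(cols[2]))
            y = GenomicPosition(strip_chr(cols[4]), int(cols[5]))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        cand = FusionCandidate(cols[0], cols[3], x, y, cols[6])
        if dedupe:
            key = (cand.gene5, cand.gene3, x, y)
            if key in seen:
                continue
            seen.add(key)
        if by_id:
            for gid, pos in ((cand.gene5, x), (cand.gene3, y)):
                g = by_id.get(gid)
                if g is None:
                    logger.warning("%s:%d: unknown gene id %r", path, lineno, gid)
                elif not g.contains(pos):
                    logger.warning(
                        "%s:%d: position %s outside span of gene %s",
                        path, lineno, pos, gid,
                    )
        out.append(cand)
    return out


# --------------------------------------------------------------------------
# gene models
# --------------------------------------------------------------------------


def _flatten(records: dict) -> list:
    """Union the span and merge exons of multi-transcript gene records."""
    models = []
    for gid, (chrom, strand, spans, exons) in records.items():
        start = min(s for s, _ in spans)
        end = max(e for _, e in spans)
        merged = None
        if exons:
            merged = []
            for s, e in sorted(exons):
                if merged and s <= merged[-1][1] + 1:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            merged = tuple(merged)
        models.append(GeneModel(gid, chrom, strand, start, end, merged))
    models.sort(key=lambda g: (natural_chrom_key(g.chrom), g.start, g.gene_id))
    return models


def _read_bed12(path) -> list:
    records: dict = {}
    for lineno, cols in _data_lines(path):
        if len(cols) < 6:
            raise FormatError(f"{path}:{lineno}: expected >= 6 BED columns")
        chrom = strip_chr(cols[0])
        try:
            start0, end0 = int(cols[1]), int(cols[2])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-integer BED coordinates") from None
        name, strand = cols[3], cols[5]
        if strand not in ("+", "-"):
            raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
        start, end = start0 + 1, end0  # 0-based half-open -> 1-based inclusive
        exons = []
        if len(cols) >= 12:
            try:
                n_blocks = int(cols[9])
                sizes = [int(v) for v in cols[10].rstrip(",").split(",")]
                offsets = [int(v) for v in cols[11].rstrip(",").split(",")]
            except ValueError:
                raise FormatError(f"{path}:{lineno}: malformed BED12 blocks") from None
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise FormatError(
                    f"{path}:{lineno}: blockCount {n_blocks} does not match block lists"
                )
            for size, off in zip(sizes, offsets):
                exons.append((start0 + off + 1, start0 + off + size))
        rec = records.setdefault(name, (chrom, strand, [], []))
        rec[2].append((start, end))
        rec[3].extend(exons)
    return _flatten(records)


def _read_gtf(path) -> list:
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    records: dict = {}
    for feat in db.all_features():
        if feat.featuretype not in ("gene", "exon"):
            continue
        gid = feat.attributes.get("gene_id", [feat.id])[0]
        chrom = strip_chr(feat.seqid)
        rec = records.setdefault(gid, (chrom, feat.strand, [], []))
        if feat.featuretype == "gene":
            rec[2].append((feat.start, feat.end))
        else:
            rec[3].append((feat.start, feat.end))
    # exon-only genes still need a span
    for gid, (chrom, strand, spans, exons) in records.items():
        if not spans and exons:
            spans.append((min(s for s, _ in exons), max(e for _, e in exons)))
    return _flatten(records)


def read_gene_models(path, format: str = "bed12") -> list:
    """Read gene models from BED12 or GTF into flattened per-gene records."""
    if format == "bed12":
        return _read_bed12(path)
    if format == "gtf":
        return _read_gtf(path)
    raise ValueError(f"unknown gene-model format {format!r}")


def write_gene_models_bed12(models: Sequence[GeneModel], path) -> None:
    """Write flattened gene models back out as BED12 (0-based half-open)."""
    with open(path, "w") as fh:
        for g in models:
            exons = g.exons or ((g.start, g.end),)
            sizes = ",".join(str(e - s + 1) for s, e in exons) + ","
            offsets = ",".join(str(s - g.start) for s, _ in exons) + ","
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        g.chrom, g.start - 1, g.end, g.gene_id, 0, g.strand,
                        g.start - 1, g.end, 0, len(exons), sizes, offsets,
                    )
                )
                + "\n"
            )


# --------------------------------------------------------------------------
# report
# --------------------------------------------------------------------------

REPORT_COLUMNS = ("fusion", "n_alleles", "paths", "anchors", "sources")


def write_report(fusions: Sequence[ValidatedFusion], path) -> None:
    """Write the validated-fusion report as a '#'-headed TSV.

    One row per validated fusion; multiple supporting alleles are joined
    with ';' in the paths column, with per-allele anchor pairs alongside.
    """
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(REPORT_COLUMNS) + "\n")
        for vf in fusions:
            paths = ";".join(format_path(p) for p in vf.alleles)
            anchors = ";".join(f"{a}..{b}" for a, b in vf.anchors)
            sources = ",".join(dict.fromkeys(vf.sources)) or vf.candidate.source
            fh.write(
                "\t".join(
                    (
                        vf.candidate.pair,
                        str(len(vf.alleles)),
                        paths,
                        anchors,
                        sources,
                    )
                )
                + "\n"
            )
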