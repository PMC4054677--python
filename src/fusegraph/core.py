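"""Breakpoint domain types and the breakpoint-string codec.

A *breakpoint* is a novel adjacency between two DNA break-ends: an in-end
(the endpoint of the segment entering the junction) and an out-end (the
start of the segment exiting it).  Each break-end is a reference coordinate
plus a strand: ``+`` means the attached segment runs with increasing
coordinates, ``-`` with decreasing coordinates.  A confidence score ``f``
(typically a supporting-read count) is attached to the junction; ``f == 0``
is reserved for *null* edges, i.e. reference adjacencies whose intervening
sequence matches the reference genome.

The text encoding glues the pieces together with no whitespace::

    5:139807117+65|5:141217466-
    chrom:pos  strand score | chrom:pos strand

A breakpoint string is strand-symmetric: swapping the two ends and flipping
both strands describes the same double-stranded junction (``x+3|y+`` is
identical to ``y-3|x-``).  ``canonicalize`` picks a deterministic
representative of that pair so breakpoints can be used as undirected,
hashable edge keys.

A *breakpoint path* chains edges whose interior ends coincide; it encodes
one derivative allele.  Paths serialize as overlapping edge strings, e.g.
``20:46795673-17|20:33925625-0|20:33923847-18|20:33679982-``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Iterator

__all__ = [
    "GenomicPosition",
    "BreakEnd",
    "Breakpoint",
    "BreakpointClass",
    "BreakpointPath",
    "BreakpointParseError",
    "parse_breakpoint_string",
    "format_breakpoint_string",
    "reverse_complement",
    "canonicalize",
    "classify",
    "parse_path",
    "format_path",
    "path_reverse_complement",
    "count_unique_breakpoints",
    "merge_null_runs",
    "trim_terminal_nulls",
    "normalize_path",
    "canonical_path_key",
    "natural_chrom_key",
    "strip_chr",
]

_STRAND_FLIP = {"+": "-", "-": "+"}
_STRAND_ORD = {"+": 0, "-": 1}


class BreakpointParseError(ValueError):
    """Raised when a breakpoint or path string does not match the grammar."""


def strip_chr(chrom: str) -> str:
    """Drop an optional ``chr`` prefix; chromosome names are otherwise opaque."""
    return chrom[3:] if chrom.lower().startswith("chr") and len(chrom) > 3 else chrom


def natural_chrom_key(chrom: str) -> tuple:
    """Sort key placing numeric chromosome tokens in numeric order (2 < 10 < X)."""
    parts = re.split(r"(\d+)", chrom)
    return tuple((0, int(p)) if p.isdigit() else (1, p) for p in parts if p)


@dataclass(frozen=True, order=False)
class GenomicPosition:
    chrom: str
    pos: int

    def __post_init__(self) -> None:
        if not self.chrom or ":" in self.chrom or "|" in self.chrom:
            raise ValueError(f"invalid chromosome name {self.chrom!r}")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")

    def sort_key(self) -> tuple:
        return (natural_chrom_key(self.chrom), self.pos)

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}"


@dataclass(frozen=True)
class BreakEnd:
    position: GenomicPosition
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def chrom(self) -> str:
        return self.position.chrom

    @property
    def pos(self) -> int:
        return self.position.pos

    def flipped(self) -> "BreakEnd":
        return BreakEnd(self.position, _STRAND_FLIP[self.strand])

    def sort_key(self) -> tuple:
        return (*self.position.sort_key(), _STRAND_ORD[self.strand])

    def __str__(self) -> str:
        return f"{self.position}{self.strand}"


@dataclass(frozen=True)
class Breakpoint:
    """An undirected novel adjacency (score > 0) or reference run (score == 0)."""

    in_end: BreakEnd
    out_end: BreakEnd
    score: int

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError(f"score must be non-negative, got {self.score}")
        if self.score == 0:
            a, b = self.in_end, self.out_end
            if a.chrom != b.chrom or a.strand != b.strand:
                raise ValueError(
                    f"null edge must stay on one chromosome and strand: {a}|{b}"
                )
            ahead = b.pos >= a.pos if a.strand == "+" else b.pos <= a.pos
            if not ahead:
                raise ValueError(
                    f"null edge must walk the reference in the strand direction: {a}0|{b}"
                )

    @property
    def is_null(self) -> bool:
        return self.score == 0

    def __str__(self) -> str:
        return format_breakpoint_string(self)


class BreakpointClass(Enum):
    NULL = "null"
    JUMP = "jump"
    INVERSE = "inverse"
    REPEAT = "repeat"
    INTER_CHROMOSOMAL = "inter_chromosomal"

    def __str__(self) -> str:  # convenient for CLI printing
        return self.value


# --------------------------------------------------------------------------
# codec
# --------------------------------------------------------------------------

_BP_RE = re.compile(
    r"^(?P<c1>[^:|\s]+):(?P<p1>\d+)(?P<s1>[+-])(?P<f>\d+)"
    r"\|(?P<c2>[^:|\s]+):(?P<p2>\d+)(?P<s2>[+-])$"
)
_END_SCORE_RE = re.compile(r"^(?P<c>[^:|\s]+):(?P<p>\d+)(?P<s>[+-])(?P<f>\d+)$")
_END_RE = re.compile(r"^(?P<c>[^:|\s]+):(?P<p>\d+)(?P<s>[+-])$")


def _diagnose(s: str) -> str:
    """Name the offending field of a malformed breakpoint string."""
    if "|" not in s:
        return "missing '|' separator"
    left, _, right = s.partition("|")
    if not _END_SCORE_RE.match(left):
        if re.match(r"^[^:|\s]+:-\d+", left):
            return f"negative position in in-end {left!r}"
        if re.match(r"^[^:|\s]+:\d+[+-]$", left):
            return f"missing score in in-end {left!r}"
        return f"malformed in-end token {left!r}"
    if not _END_RE.match(right):
        if re.match(r"^[^:|\s]+:-\d+", right):
            return f"negative position in out-end {right!r}"
        return f"malformed out-end token {right!r}"
    return "malformed breakpoint string"


def parse_breakpoint_string(s: str) -> Breakpoint:
    """Parse ``chrom:pos{+,-}score|chrom:pos{+,-}`` into a :class:`Breakpoint`."""
    m = _BP_RE.match(s)
    if not m:
        raise BreakpointParseError(f"cannot parse breakpoint {s!r}: {_diagnose(s)}")
    try:
        in_end = BreakEnd(GenomicPosition(m["c1"], int(m["p1"])), m["s1"])
        out_end = BreakEnd(GenomicPosition(m["c2"], int(m["p2"])), m["s2"])
        return Breakpoint(in_end, out_end, int(m["f"]))
    except ValueError as exc:
        raise BreakpointParseError(f"cannot parse breakpoint {s!r}: {exc}") from exc


def format_breakpoint_string(b: Breakpoint) -> str:
    return f"{b.in_end}{b.score}|{b.out_end}"


def reverse_complement(b: Breakpoint) -> Breakpoint:
    """Swap the two ends and flip both strands; the score is preserved."""
    return Breakpoint(b.out_end.flipped(), b.in_end.flipped(), b.score)


def _bp_sort_key(b: Breakpoint) -> tuple:
    return (*b.in_end.sort_key(), *b.out_end.sort_key())


def canonicalize(b: Breakpoint) -> Breakpoint:
    """Deterministic representative of {b, reverse_complement(b)}.

    Ordering: in-chrom (natural sort), in-pos, in-strand ('+' < '-'), then
    the out-end fields.  The convention itself is arbitrary; only the
    equivalence of a breakpoint with its reverse complement is meaningful.
    """
    rc = reverse_complement(b)
    return b if _bp_sort_key(b) <= _bp_sort_key(rc) else rc


def classify(b: Breakpoint) -> BreakpointClass:
    """Classify a breakpoint: null, jump, inverse, repeat, or inter-chromosomal.

    Intra-chromosomal novel edges split by strand geometry: *inverse* joins
    opposite strands (inversion / fold-back), *jump* skips ahead in the
    direction of travel (deletion-like), *repeat* connects back to an
    upstream position on the same strand (tandem-duplication-like).
    """
    if b.score == 0:
        return BreakpointClass.NULL
    a, o = b.in_end, b.out_end
    if a.chrom != o.chrom:
        return BreakpointClass.INTER_CHROMOSOMAL
    if a.strand != o.strand:
        return BreakpointClass.INVERSE
    ahead = o.pos > a.pos if a.strand == "+" else o.pos < a.pos
    return BreakpointClass.JUMP if ahead else BreakpointClass.REPEAT


# --------------------------------------------------------------------------
# paths
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class BreakpointPath:
    """An ordered chain of breakpoints encoding one derivative allele.

    Consecutive edges must share their boundary break-end exactly (the
    out-end of edge *i* equals the in-end of edge *i+1*, position and
    strand).  The empty path is legal and represents a fusion whose two
    anchors coincide.
    """

    edges: tuple

    def __init__(self, edges: Iterable[Breakpoint]):
        object.__setattr__(self, "edges", tuple(edges))
        for i in range(len(self.edges) - 1):
            if self.edges[i].out_end != self.edges[i + 1].in_end:
                raise ValueError(
                    f"path boundary mismatch at junction {i}: "
                    f"{self.edges[i].out_end} != {self.edges[i + 1].in_end}"
                )

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self) -> Iterator[Breakpoint]:
        return iter(self.edges)

    @property
    def novel_edges(self) -> tuple:
        return tuple(e for e in self.edges if e.score > 0)

    @property
    def total_score(self) -> int:
        return sum(e.score for e in self.edges)

    def __str__(self) -> str:
        return format_path(self)


def parse_path(s: str) -> BreakpointPath:
    """Parse a serialized breakpoint path (a chain of overlapping edge strings)."""
    tokens = s.split("|")
    if len(tokens) < 2:
        raise BreakpointParseError(f"cannot parse path {s!r}: missing '|' separator")
    ends = []
    scores = []
    for i, tok in enumerate(tokens):
        last = i == len(tokens) - 1
        m = (_END_RE if last else _END_SCORE_RE).match(tok)
        if not m:
            kind = "terminal end" if last else "scored end"
            raise BreakpointParseError(
                f"cannot parse path {s!r}: malformed {kind} token {tok!r} at index {i}"
            )
        try:
            ends.append(BreakEnd(GenomicPosition(m["c"], int(m["p"])), m["s"]))
        except ValueError as exc:
            raise BreakpointParseError(
                f"cannot parse path {s!r}: bad token {tok!r} at index {i}: {exc}"
            ) from exc
        if not last:
            scores.append(int(m["f"]))
    try:
        edges = [
            Breakpoint(ends[i], ends[i + 1], scores[i]) for i in range(len(scores))
        ]
    except ValueError as exc:
        raise BreakpointParseError(f"cannot parse path {s!r}: {exc}") from exc
    return BreakpointPath(edges)


def format_path(p: BreakpointPath) -> str:
    if not p.edges:
        return ""
    parts = [f"{e.in_end}{e.score}" for e in p.edges]
    parts.append(str(p.edges[-1].out_end))
    return "|".join(parts)


def path_reverse_complement(p: BreakpointPath) -> BreakpointPath:
    """Reverse the edge order and reverse-complement every edge (involution)."""
    return BreakpointPath(reverse_complement(e) for e in reversed(p.edges))


def count_unique_breakpoints(p: BreakpointPath) -> int:
    """Distinct canonical forms among the score>0 edges of a path.

    A path may traverse the same physical breakpoint twice in opposite
    orientations (inverted duplication); such traversals collapse to one
    canonical breakpoint here.
    """
    return len({canonicalize(e) for e in p.edges if e.score > 0})


def merge_null_runs(p: BreakpointPath) -> BreakpointPath:
    """Collapse maximal runs of consecutive null edges into single null edges.

    Reported paths write a reference run as one null edge even when interior
    breakpoint nodes subdivide it in the graph.
    """
    merged = []
    for e in p.edges:
        if e.is_null and merged and merged[-1].is_null:
            merged[-1] = Breakpoint(merged[-1].in_end, e.out_end, 0)
        else:
            merged.append(e)
    return BreakpointPath(merged)


def trim_terminal_nulls(p: BreakpointPath) -> BreakpointPath:
    """Drop leading and trailing null edges (uninformative reference runs)."""
    edges = list(p.edges)
    while edges and edges[0].is_null:
        edges.pop(0)
    while edges and edges[-1].is_null:
        edges.pop()
    return BreakpointPath(edges)


def normalize_path(p: BreakpointPath) -> BreakpointPath:
    """Reporting form of a traversal: trim terminal nulls, merge null runs."""
    return merge_null_runs(trim_terminal_nulls(p))


def canonical_path_key(p: BreakpointPath) -> str:
    """Orientation-independent identity of a path (min of the two serializations)."""
    fwd = format_path(p)
    rev = format_path(path_reverse_complement(p))
    return min(fwd, rev)
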