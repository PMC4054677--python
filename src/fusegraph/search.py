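"""Transcriptome-guided allele search.

A fusion candidate supplies two genomic positions: ``x``, the last
transcribed base of the 5' partner at the RNA junction, and ``y``, the
first transcribed base of the 3' partner.  Because of splicing, the
genomic breakpoints responsible for the fusion need not sit at the RNA
junction; the search first *anchors* the candidate to graph nodes — ``x0``,
the nearest node carrying a novel edge at or beyond ``x`` in the 5' gene's
transcription direction, and ``y0``, the nearest such node between the 3'
gene's transcription start side and ``y`` — then enumerates every
breakpoint path from ``x0`` to ``y0``.

The enumeration is a breadth-first expansion over (position, strand)
states: each extension appends one traversable edge (strand continuity is
enforced by the graph's neighbors contract), a path is emitted when it
reaches ``y0`` arriving on the 3' gene's transcription strand, and a branch
is abandoned when it runs out of edges or exceeds the configured limits.
The bare recursion does not terminate on cyclic graphs, so explicit bounds
are imposed: a cap on novel edges per path, a per-edge reuse cap (>= 2 is
required to traverse inverted duplications, whose alleles cross the same
physical breakpoint twice in opposite orientations), and a cap on emitted
paths per fusion.
"""

from __future__ import annotations

import logging
from collections import Counter, deque
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .core import (
    BreakEnd,
    Breakpoint,
    BreakpointPath,
    canonical_path_key,
    canonicalize,
    format_breakpoint_string,
    normalize_path,
)
from .graph import BreakpointGraph, neighbors
from .io import FusionCandidate, GeneModel, ValidatedFusion

logger = logging.getLogger("fusegraph")

__all__ = [
    "SearchLimits",
    "AnchorPair",
    "AlleleList",
    "find_anchors",
    "enumerate_alleles",
    "validate_fusions",
]

#: Hard cap on BFS expansions per anchor pair, guarding pathological graphs.
_MAX_EXPANSIONS = 200_000


@dataclass(frozen=True)
class SearchLimits:
    """Termination bounds for the path enumeration.

    max_novel_edges: most novel (score>0) edges a single path may contain.
    max_edge_reuse: times one canonical edge may be traversed in a path;
        2 keeps inverted-duplication alleles reachable while guaranteeing
        termination on cycles.
    max_paths_per_fusion: emitted paths per anchor pair before truncation.
    """

    max_novel_edges: int = 8
    max_edge_reuse: int = 2
    max_paths_per_fusion: int = 50

    def __post_init__(self) -> None:
        for name in ("max_novel_edges", "max_edge_reuse", "max_paths_per_fusion"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass(frozen=True)
class AnchorPair:
    """Start and target break-ends of one search run.

    ``x0`` carries the 5' gene's transcription strand (the walk departs in
    that direction); ``y0`` carries the 3' gene's strand (the walk must
    arrive moving in that direction).
    """

    x0: BreakEnd
    y0: BreakEnd


class AlleleList(list):
    """List of BreakpointPath with a truncation flag."""

    truncated: bool = False


def _downstream_candidates(
    nodes_with_edges: Sequence, pos: int, strand: str
) -> list:
    """Novel-edge nodes at or beyond ``pos`` in the strand's direction, nearest first."""
    if strand == "+":
        return [n for n in nodes_with_edges if n.pos >= pos]
    return sorted(
        (n for n in nodes_with_edges if n.pos <= pos),
        key=lambda n: -n.pos,
    )


def _upstream_candidates(nodes_with_edges: Sequence, pos: int, strand: str) -> list:
    """Novel-edge nodes between the gene's 5' side and ``pos``, nearest first."""
    if strand == "+":
        return sorted(
            (n for n in nodes_with_edges if n.pos <= pos),
            key=lambda n: -n.pos,
        )
    return [n for n in nodes_with_edges if n.pos >= pos]


def find_anchors(
    f: FusionCandidate,
    bg: BreakpointGraph,
    genes: Optional[dict] = None,
    anchor_depth: int = 3,
    strict_nearest: bool = False,
) -> list:
    """Candidate (x0, y0) anchor pairs for a fusion, nearest pairs first.

    Returns an empty list — with a logged reason — when either gene is
    unknown, a fusion position falls outside its (padded) gene span, or a
    gene contains no novel-edge node on the required side.  Beyond the
    strict nearest node, up to ``anchor_depth`` candidates per side are
    combined, because caller-position jitter otherwise silently kills true
    fusions.
    """
    genes = genes if genes is not None else bg.genes
    depth = 1 if strict_nearest else anchor_depth
    g5, g3 = genes.get(f.gene5), genes.get(f.gene3)
    if g5 is None or g3 is None:
        missing = f.gene5 if g5 is None else f.gene3
        logger.info("fusion %s skipped: unknown gene %s", f.pair, missing)
        return []
    pad = bg.gene_pad
    if not g5.contains(f.x, pad) or not g3.contains(f.y, pad):
        logger.info("fusion %s skipped: position outside gene span", f.pair)
        return []
    x_cands = _downstream_candidates(bg.novel_nodes_in_gene(g5), f.x.pos, g5.strand)
    y_cands = _upstream_candidates(bg.novel_nodes_in_gene(g3), f.y.pos, g3.strand)
    if not x_cands:
        logger.info("fusion %s skipped: no breakpoint beyond x in %s", f.pair, f.gene5)
        return []
    if not y_cands:
        logger.info("fusion %s skipped: no breakpoint before y in %s", f.pair, f.gene3)
        return []
    pairs = []
    for ix, xn in enumerate(x_cands[:depth]):
        for iy, yn in enumerate(y_cands[:depth]):
            pairs.append(
                (
                    ix + iy,
                    ix,
                    AnchorPair(BreakEnd(xn, g5.strand), BreakEnd(yn, g3.strand)),
                )
            )
    pairs.sort(key=lambda t: (t[0], t[1]))
    return [p for _, _, p in pairs]


def enumerate_alleles(
    anchor: AnchorPair, bg: BreakpointGraph, limits: SearchLimits = SearchLimits()
) -> AlleleList:
    """Breadth-first enumeration of breakpoint paths from x0 to y0.

    Emitted paths are normalized to reporting form (terminal null edges
    trimmed, null runs merged), deduplicated under path reverse complement,
    and sorted simplest-first: ascending novel-edge count, then descending
    total score.
    """
    out = AlleleList()
    if not bg.g.has_node(anchor.x0.position):
        return out
    seen_keys: set = set()

    def emit(edges: tuple) -> None:
        path = normalize_path(BreakpointPath(edges))
        key = canonical_path_key(path)
        if key not in seen_keys:
            seen_keys.add(key)
            out.append(path)

    if anchor.x0 == anchor.y0:
        emit(())

    queue = deque()
    queue.append((anchor.x0, (), 0, Counter()))
    expansions = 0
    while queue:
        if len(out) >= limits.max_paths_per_fusion:
            out.truncated = True
            logger.warning("path enumeration truncated at %d paths", len(out))
            break
        cur, edges, n_novel, usage = queue.popleft()
        for bp, nxt in neighbors(bg, cur.position, cur.strand):
            expansions += 1
            if expansions > _MAX_EXPANSIONS:
                out.truncated = True
                logger.warning("path enumeration truncated: expansion cap reached")
                queue.clear()
                break
            key = format_breakpoint_string(canonicalize(bp))
            if usage[key] + 1 > limits.max_edge_reuse:
                continue
            novel = n_novel + (1 if bp.score > 0 else 0)
            if novel > limits.max_novel_edges:
                continue
            new_edges = edges + (bp,)
            if nxt == anchor.y0:
                emit(new_edges)
                continue  # a path terminates on hitting y0
            new_usage = usage.copy()
            new_usage[key] += 1
            queue.append((nxt, new_edges, novel, new_usage))

    out.sort(
        key=lambda p: (
            len(p.novel_edges),
            -p.total_score,
            canonical_path_key(p),
        )
    )
    return out


def validate_fusions(
    fusions: Sequence[FusionCandidate],
    bg: BreakpointGraph,
    genes: Optional[dict] = None,
    limits: SearchLimits = SearchLimits(),
    merge_window: int = 10,
    anchor_depth: int = 3,
    strict_nearest: bool = False,
) -> list:
    """Anchor and search every candidate; keep those with >= 1 supporting allele.

    Redundant candidates — same gene pair with both positions within
    ``merge_window`` bp — are merged before searching and report together,
    pooling their caller tags.  Alleles found from different anchor pairs
    are pooled per candidate and deduplicated under reverse complement.
    """
    genes = genes if genes is not None else bg.genes

    merged: list = []
    for cand in fusions:
        for rep in merged:
            if (
                rep[0].gene5 == cand.gene5
                and rep[0].gene3 == cand.gene3
                and rep[0].x.chrom == cand.x.chrom
                and rep[0].y.chrom == cand.y.chrom
                and abs(rep[0].x.pos - cand.x.pos) <= merge_window
                and abs(rep[0].y.pos - cand.y.pos) <= merge_window
            ):
                rep[1].append(cand.source)
                break
        else:
            merged.append((cand, [cand.source]))

    validated = []
    for cand, sources in merged:
        anchors = find_anchors(
            cand, bg, genes, anchor_depth=anchor_depth, strict_nearest=strict_nearest
        )
        alleles: list = []
        allele_anchors: list = []
        seen: set = set()
        for pair in anchors:
            for path in enumerate_alleles(pair, bg, limits):
                key = canonical_path_key(path)
                if key not in seen:
                    seen.add(key)
                    alleles.append(path)
                    allele_anchors.append((pair.x0, pair.y0))
        if not alleles:
            if anchors:
                logger.info("fusion %s: no supporting allele found", cand.pair)
            continue
        order = sorted(
            range(len(alleles)),
            key=lambda i: (
                len(alleles[i].novel_edges),
                -alleles[i].total_score,
                canonical_path_key(alleles[i]),
            ),
        )
        validated.append(
            ValidatedFusion(
                candidate=cand,
                alleles=tuple(alleles[i] for i in order),
                anchors=tuple(allele_anchors[i] for i in order),
                sources=tuple(sources),
            )
        )
    validated.sort(key=lambda vf: (vf.candidate.pair, vf.candidate.x.sort_key()))
    return validated
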