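"""Gene-aware breakpoint multigraph.

Nodes are genomic positions: every break-end of a novel adjacency, plus the
two terminal bases of every gene span.  Novel edges are inserted verbatim
(canonicalized, parallel edges kept — a node can carry multiple edges, one
per allele in a polyploid genome).  Null (reference) edges chain the
breakpoint ends lying inside each gene span in genomic order, so reference
traversal is confined to expressed regions; no null edge crosses a gene
boundary, which removes read-through artifacts by construction.  The
inter-gene connection can be restored explicitly when read-through events
are of interest.

Edges are undirected: traversal from either side reorients an edge through
its reverse complement, so strand semantics stay consistent whichever end
the walk arrives from.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import networkx as nx
from intervaltree import IntervalTree

from .core import (
    BreakEnd,
    Breakpoint,
    GenomicPosition,
    canonicalize,
    format_breakpoint_string,
    reverse_complement,
)
from .io import GeneModel

logger = logging.getLogger("fusegraph")

__all__ = ["BreakpointGraph", "build_graph", "neighbors", "restore_read_through"]


class BreakpointGraph:
    """Multigraph over break-end positions with novel and null edges."""

    def __init__(self) -> None:
        self.g = nx.MultiGraph()
        self.gene_index: dict = {}  # chrom -> IntervalTree of GeneModel
        self.genes: dict = {}  # gene_id -> GeneModel
        self.gene_pad: int = 0
        self._null_pairs: set = set()
        self.terminal_nodes: set = set()

    # -- construction -----------------------------------------------------

    def add_novel(self, b: Breakpoint) -> None:
        c = canonicalize(b)
        u, v = c.in_end.position, c.out_end.position
        self.g.add_node(u)
        self.g.add_node(v)
        self.g.add_edge(u, v, bp=c)

    def add_null(self, lo: GenomicPosition, hi: GenomicPosition) -> bool:
        """Insert the reference adjacency lo->hi ('+' orientation); idempotent."""
        key = (lo, hi)
        if key in self._null_pairs:
            return False
        self._null_pairs.add(key)
        b = Breakpoint(BreakEnd(lo, "+"), BreakEnd(hi, "+"), 0)
        self.g.add_edge(lo, hi, bp=canonicalize(b))
        return True

    # -- queries ----------------------------------------------------------

    def has_node(self, pos: GenomicPosition) -> bool:
        return self.g.has_node(pos)

    @property
    def nodes(self):
        return self.g.nodes

    def edge_data(self) -> Iterable[Breakpoint]:
        for _, _, data in self.g.edges(data=True):
            yield data["bp"]

    def novel_edges(self) -> list:
        return [b for b in self.edge_data() if b.score > 0]

    def null_edge_count(self) -> int:
        return sum(1 for b in self.edge_data() if b.is_null)

    def genes_at(self, pos: GenomicPosition) -> list:
        tree = self.gene_index.get(pos.chrom)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.at(pos.pos)), key=lambda g: g.gene_id)

    def novel_nodes_in_gene(self, gene: GeneModel) -> list:
        """Positions inside the (padded) gene span carrying >=1 novel edge."""
        out = []
        lo, hi = gene.start - self.gene_pad, gene.end + self.gene_pad
        for node in self.g.nodes:
            if node.chrom != gene.chrom or not lo <= node.pos <= hi:
                continue
            if any(
                data["bp"].score > 0
                for _, _, data in self.g.edges(node, data=True)
            ):
                out.append(node)
        return sorted(out, key=lambda n: n.pos)

    def to_dot(self) -> str:
        """DOT dump with breakpoint strings as edge labels (debug aid)."""
        lines = ["graph breakpoints {"]
        for node in sorted(self.g.nodes, key=lambda n: n.sort_key()):
            lines.append(f'  "{node}";')
        for _, _, data in sorted(
            self.g.edges(data=True),
            key=lambda t: format_breakpoint_string(t[2]["bp"]),
        ):
            b = data["bp"]
            style = ' style=dashed' if b.is_null else ""
            lines.append(
                f'  "{b.in_end.position}" -- "{b.out_end.position}"'
                f' [label="{format_breakpoint_string(b)}"{style}];'
            )
        lines.append("}")
        return "\n".join(lines) + "\n"


def build_graph(
    gsr: Sequence[Breakpoint],
    genes: Sequence[GeneModel],
    gene_pad: int = 0,
) -> BreakpointGraph:
    """Assemble the breakpoint graph from novel adjacencies and gene models.

    For each gene span (optionally padded by ``gene_pad`` bp on both sides)
    the break-end positions falling inside it, together with the gene's two
    terminal bases, are chained by null edges in genomic order.  A break-end
    inside two overlapping genes joins both genes' chains, so traversal can
    route through any gene containing it.  Break-ends in intergenic space
    become nodes but join no null chain: they are reachable only through
    novel edges.
    """
    bg = BreakpointGraph()
    bg.gene_pad = gene_pad

    seen = set()
    for b in gsr:
        c = canonicalize(b)
        key = (c.in_end, c.out_end, c.score)
        if key in seen:  # exact duplicates collapse; distinct scores stay parallel
            continue
        seen.add(key)
        bg.add_novel(c)

    for g in genes:
        bg.genes[g.gene_id] = g
        bg.gene_index.setdefault(g.chrom, IntervalTree()).addi(
            g.start - gene_pad, g.end + gene_pad + 1, g
        )

    breakend_pos = sorted(bg.g.nodes, key=lambda n: n.sort_key())
    for g in genes:
        lo, hi = g.start - gene_pad, g.end + gene_pad
        chain = {GenomicPosition(g.chrom, g.start), GenomicPosition(g.chrom, g.end)}
        for node in breakend_pos:
            if node.chrom == g.chrom and lo <= node.pos <= hi:
                chain.add(node)
        ordered = sorted(chain, key=lambda n: n.pos)
        for node in ordered:
            bg.g.add_node(node)
        bg.terminal_nodes.add(ordered[0])
        bg.terminal_nodes.add(ordered[-1])
        for a, b in zip(ordered, ordered[1:]):
            bg.add_null(a, b)
    return bg


def neighbors(
    bg: BreakpointGraph, node: GenomicPosition, arriving_strand: str
) -> list:
    """Edges traversable when the walk stands at ``node`` on ``arriving_strand``.

    An edge is traversable if its in-end matches (node, strand) after
    optional reverse-complement reorientation; each hit is returned already
    oriented, paired with the break-end the walk moves to.
    """
    if not bg.g.has_node(node):
        raise KeyError(f"unknown node {node}")
    probe = BreakEnd(node, arriving_strand)
    out = []
    for _, _, data in bg.g.edges(node, data=True):
        b = data["bp"]
        if b.in_end == probe:
            out.append((b, b.out_end))
        rc = reverse_complement(b)
        if rc != b and rc.in_end == probe:
            out.append((rc, rc.out_end))
    out.sort(key=lambda t: (t[1].sort_key(), t[0].score))
    return out


def restore_read_through(
    bg: BreakpointGraph, gene_a: GeneModel, gene_b: GeneModel
) -> BreakpointGraph:
    """Reconnect the reference run between two adjacent genes (in place).

    Off by default because a transcript spanning two neighboring genes
    without any rearrangement (read-through) would otherwise masquerade as
    a validated fusion.  Raises for non-adjacent genes.  Idempotent.
    """
    if gene_a.chrom != gene_b.chrom:
        raise ValueError(
            f"genes {gene_a.gene_id} and {gene_b.gene_id} are on different chromosomes"
        )
    left, right = sorted((gene_a, gene_b), key=lambda g: g.start)
    if left.end >= right.start:
        # overlapping genes already share chain nodes
        raise ValueError(f"genes {left.gene_id} and {right.gene_id} overlap")
    tree = bg.gene_index.get(left.chrom)
    if tree is not None:
        for iv in tree.overlap(left.end + 1, right.start):
            if iv.data.gene_id not in (left.gene_id, right.gene_id):
                raise ValueError(
                    f"genes {left.gene_id} and {right.gene_id} are not adjacent: "
                    f"{iv.data.gene_id} lies between them"
                )
    bg.add_null(
        GenomicPosition(left.chrom, left.end),
        GenomicPosition(right.chrom, right.start),
    )
    return bg
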