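"""Anchoring and allele enumeration, cross-checked against brute force."""

from collections import Counter

import numpy as np
import pytest

from fusegraph.core import (
    BreakEnd,
    Breakpoint,
    BreakpointPath,
    GenomicPosition,
    canonical_path_key,
    canonicalize,
    format_breakpoint_string,
    normalize_path,
    parse_breakpoint_string,
    parse_path,
    reverse_complement,
)
from fusegraph.graph import build_graph, restore_read_through
from fusegraph.io import FusionCandidate, GeneModel
from fusegraph.search import (
    AnchorPair,
    SearchLimits,
    enumerate_alleles,
    find_anchors,
    validate_fusions,
)
from fusegraph import skbr3


def _pos(chrom, pos):
    return GenomicPosition(chrom, pos)


def _end(chrom, pos, strand):
    return BreakEnd(_pos(chrom, pos), strand)


# ---------------------------------------------------------------------------
# independent oracle: recursive DFS over oriented edges
# ---------------------------------------------------------------------------


def brute_force_paths(edges, x0, y0, limits):
    """Exhaustive path enumeration by recursion over raw edge orientations.

    Independent of the graph's neighbor machinery: every edge is tried in
    both orientations at every step.  Returns normalized canonical keys.
    """
    found = set()

    def record(acc):
        found.add(canonical_path_key(normalize_path(BreakpointPath(acc))))

    def step(cur, used, n_novel, acc):
        for e in edges:
            for o in {e, reverse_complement(e)}:
                if o.in_end != cur:
                    continue
                key = format_breakpoint_string(canonicalize(o))
                if used[key] + 1 > limits.max_edge_reuse:
                    continue
                novel = n_novel + (1 if o.score > 0 else 0)
                if novel > limits.max_novel_edges:
                    continue
                if o.out_end == y0:
                    record(acc + [o])
                    continue
                used[key] += 1
                step(o.out_end, used, novel, acc + [o])
                used[key] -= 1

    if x0 == y0:
        record([])
    step(x0, Counter(), 0, [])
    return found


def _random_case(rng):
    """A small random two-gene graph plus a random anchor pair."""
    genes = [
        GeneModel("GA", "1", rng.choice(["+", "-"]), 1_000, 5_000),
        GeneModel("GB", "1", rng.choice(["+", "-"]), 7_000, 11_000),
    ]
    k = int(rng.integers(3, 7))
    positions = sorted(
        int(p)
        for p in rng.choice(
            np.r_[np.arange(1_100, 4_900, 100), np.arange(7_100, 10_900, 100)],
            size=k,
            replace=False,
        )
    )
    novel = []
    for _ in range(int(rng.integers(2, 6))):
        i, j = rng.integers(0, k, size=2)
        a = _end("1", positions[int(i)], rng.choice(["+", "-"]))
        b = _end("1", positions[int(j)], rng.choice(["+", "-"]))
        novel.append(Breakpoint(a, b, int(rng.integers(1, 60))))
    bg = build_graph(novel, genes)
    nodes = sorted(bg.g.nodes, key=lambda n: n.pos)
    x0 = BreakEnd(nodes[int(rng.integers(0, len(nodes)))], rng.choice(["+", "-"]))
    y0 = BreakEnd(nodes[int(rng.integers(0, len(nodes)))], rng.choice(["+", "-"]))
    return bg, AnchorPair(x0, y0)


@pytest.mark.parametrize("seed", range(40))
def test_enumeration_matches_brute_force_on_random_graphs(seed):
    rng = np.random.default_rng(seed)
    limits = SearchLimits(max_novel_edges=4, max_edge_reuse=2, max_paths_per_fusion=500)
    bg, anchor = _random_case(rng)
    got = {canonical_path_key(p) for p in enumerate_alleles(anchor, bg, limits)}
    want = brute_force_paths(list(bg.edge_data()), anchor.x0, anchor.y0, limits)
    assert got == want


def test_raising_limits_never_removes_paths():
    rng = np.random.default_rng(7)
    bg, anchor = _random_case(rng)
    base = SearchLimits(max_novel_edges=3, max_edge_reuse=1, max_paths_per_fusion=500)
    small = {canonical_path_key(p) for p in enumerate_alleles(anchor, bg, base)}
    for kwargs in (
        dict(max_novel_edges=6),
        dict(max_edge_reuse=2),
        dict(max_novel_edges=6, max_edge_reuse=3),
    ):
        big = SearchLimits(max_paths_per_fusion=500, **{**dict(max_novel_edges=3, max_edge_reuse=1), **kwargs})
        larger = {canonical_path_key(p) for p in enumerate_alleles(anchor, bg, big)}
        assert small <= larger


# ---------------------------------------------------------------------------
# anchoring
# ---------------------------------------------------------------------------


class TestAnchors:
    G5 = GeneModel("G5", "1", "-", 10_000, 30_000)  # transcribes high -> low
    G3 = GeneModel("G3", "2", "+", 50_000, 70_000)

    def _graph(self, *edges):
        return build_graph([parse_breakpoint_string(e) for e in edges], [self.G5, self.G3])

    def test_negative_strand_gene_anchors_toward_lower_coordinates(self):
        # x at 25_000; the novel edge end 2 kb further 3' (lower) is x0
        bg = self._graph("1:23000-9|2:52000+")
        f = FusionCandidate("G5", "G3", _pos("1", 25_000), _pos("2", 60_000))
        (pair, *_) = find_anchors(f, bg)
        assert pair.x0 == _end("1", 23_000, "-")
        assert pair.y0 == _end("2", 52_000, "+")

    def test_position_on_breakpoint_node_is_its_own_anchor(self):
        bg = self._graph("1:23000-9|2:52000+")
        f = FusionCandidate("G5", "G3", _pos("1", 23_000), _pos("2", 52_000))
        (pair, *_) = find_anchors(f, bg)
        assert pair.x0.pos == 23_000 and pair.y0.pos == 52_000

    def test_no_edge_beyond_x_gives_empty_anchors(self):
        bg = self._graph("1:27000-9|2:52000+")  # 27000 is upstream of x on '-'
        f = FusionCandidate("G5", "G3", _pos("1", 25_000), _pos("2", 60_000))
        assert find_anchors(f, bg) == []

    def test_unknown_gene_gives_empty_anchors(self):
        bg = self._graph("1:23000-9|2:52000+")
        f = FusionCandidate("NOSUCH", "G3", _pos("1", 25_000), _pos("2", 60_000))
        assert find_anchors(f, bg) == []

    def test_strict_nearest_returns_single_pair(self):
        bg = self._graph("1:23000-9|2:52000+", "1:21000-4|2:55000+")
        f = FusionCandidate("G5", "G3", _pos("1", 25_000), _pos("2", 60_000))
        assert len(find_anchors(f, bg, strict_nearest=True)) == 1
        assert len(find_anchors(f, bg)) == 4  # 2 x-candidates x 2 y-candidates


# ---------------------------------------------------------------------------
# enumeration on constructed fixtures
# ---------------------------------------------------------------------------


class TestEnumeration:
    def test_two_breakpoint_allele_via_pass_through_gene(self, bundle_graph):
        """The PREX1>CPNE1 allele routes through an intron of PHF20."""
        anchor = AnchorPair(_end("20", 46795673, "-"), _end("20", 33679982, "-"))
        paths = enumerate_alleles(anchor, bundle_graph)
        assert len(paths) == 1
        assert [e.score for e in paths[0].novel_edges] == [17, 18]
        assert str(paths[0]) == skbr3.CATALOG["PREX1>CPNE1"][0]

    def test_inverted_duplication_requires_edge_reuse_of_two(self, bundle_graph):
        anchor = AnchorPair(_end("8", 121547851, "+"), _end("8", 119661057, "-"))
        printed = canonical_path_key(parse_path(skbr3.CATALOG["MTBP>SAMD12"][0]))
        found = {
            canonical_path_key(p)
            for p in enumerate_alleles(anchor, bundle_graph, SearchLimits(max_edge_reuse=2))
        }
        assert printed in found
        found_1 = {
            canonical_path_key(p)
            for p in enumerate_alleles(anchor, bundle_graph, SearchLimits(max_edge_reuse=1))
        }
        assert printed not in found_1

    def test_coincident_anchors_give_empty_path(self):
        gene = GeneModel("A", "1", "+", 100, 900)
        e = parse_breakpoint_string("1:300+9|1:700-")
        bg = build_graph([e], [gene])
        anchor = AnchorPair(_end("1", 300, "+"), _end("1", 300, "+"))
        paths = enumerate_alleles(anchor, bg)
        assert any(len(p.edges) == 0 for p in paths)

    def test_orientation_invariance_of_validation(self):
        genes = skbr3.gene_models()
        calls = skbr3.gsr_calls()
        flipped = [reverse_complement(b) for b in calls]
        cands = skbr3.fusion_candidates()
        res_a = validate_fusions(cands, build_graph(calls, genes))
        res_b = validate_fusions(cands, build_graph(flipped, genes))
        key = lambda res: {
            vf.candidate.pair: [canonical_path_key(a) for a in vf.alleles] for vf in res
        }
        assert key(res_a) == key(res_b)

    def test_restored_read_through_enables_null_only_path(self):
        a = GeneModel("A", "1", "+", 100, 900)
        b = GeneModel("B", "1", "+", 2000, 2900)
        bg = build_graph([], [a, b])
        anchor = AnchorPair(_end("1", 100, "+"), _end("1", 2900, "+"))
        assert enumerate_alleles(anchor, bg) == []
        restore_read_through(bg, a, b)
        paths = enumerate_alleles(anchor, bg)
        assert len(paths) == 1 and paths[0].novel_edges == ()


# ---------------------------------------------------------------------------
# validate_fusions
# ---------------------------------------------------------------------------


class TestValidateFusions:
    def test_single_breakpoint_catalog_fusions_validate(self, bundle_graph):
        validated = validate_fusions(skbr3.fusion_candidates(), bundle_graph)
        by_pair = {vf.candidate.pair: vf for vf in validated}
        for pair in (
            "ANKHD1-EIF4EBP3>PCDH1", "CCDC85C>SETD3", "RARA>PKIA",
            "SUMF1>LRRFIP2", "TATDN1>GSDMB", "WDR67>ZNF704",
        ):
            vf = by_pair[pair]
            assert len(vf.alleles) == 1
            assert len(vf.alleles[0].novel_edges) == 1

    def test_fusion_without_edges_absent_from_output(self, bundle_graph):
        validated = validate_fusions(skbr3.fusion_candidates(), bundle_graph)
        pairs = {vf.candidate.pair for vf in validated}
        assert "DHX35>ITCH" not in pairs
        assert "NFS1>PREX1" not in pairs

    def test_two_anchor_pairs_pool_into_one_fusion_with_two_alleles(self):
        """A simple allele at a distal anchor plus a three-breakpoint
        fold-back allele at a proximal anchor report as one fusion."""
        g5 = GeneModel("G5", "1", "+", 1_000, 5_000)
        g3 = GeneModel("G3", "1", "-", 20_000, 28_000)
        edges = [
            # simple allele: single junction at 4000
            Breakpoint(_end("1", 4_000, "+"), _end("1", 25_000, "-"), 18),
            # complex allele: intra-gene jump, inter-gene jump, fold-back
            Breakpoint(_end("1", 2_500, "+"), _end("1", 2_900, "+"), 4),
            Breakpoint(_end("1", 3_000, "+"), _end("1", 27_000, "+"), 10),
            Breakpoint(_end("1", 27_500, "+"), _end("1", 27_200, "-"), 7),
        ]
        bg = build_graph(edges, [g5, g3])
        f = FusionCandidate("G5", "G3", _pos("1", 2_400), _pos("1", 24_500))
        (vf,) = validate_fusions([f], bg)
        assert vf.candidate.pair == "G5>G3"
        novel_counts = sorted(len(a.novel_edges) for a in vf.alleles)
        assert novel_counts[0] == 1 and 3 in novel_counts

    def test_redundant_candidates_merge_within_window(self, bundle_graph):
        base = skbr3.fusion_candidates()
        prex = next(c for c in base if c.pair == "PREX1>CPNE1")
        shifted = FusionCandidate(
            prex.gene5, prex.gene3,
            _pos(prex.x.chrom, prex.x.pos + 5),
            _pos(prex.y.chrom, prex.y.pos - 5),
            "tophat",
        )
        validated = validate_fusions([prex, shifted], bundle_graph, merge_window=10)
        assert len(validated) == 1
        assert set(validated[0].sources) == {"catalog", "tophat"}
        validated = validate_fusions([prex, shifted], bundle_graph, merge_window=1)
        assert len(validated) == 2
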