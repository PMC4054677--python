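"""Call-level rearrangement simulator with planted truth.

The generator builds a toy genome of gene models, plants rearrangement
events into it, and derives the three mutually consistent artifacts a
validation run consumes: the structural-rearrangement (GSR) calls (exactly
the novel edges of each planted derivative allele), the fusion candidates
implied by each allele (5' gene up to the junction, 3' gene after it), and
the expected breakpoint path itself.  Simulation stops at the call level —
the tool's inputs are caller outputs, so no reads are synthesized.

Junctions are placed at exon boundaries of the flattened gene models, with
genomic break-ends offset 50 bp into the flanking intron (RNA junctions sit
on splice sites; DNA breaks rarely do).  All generators are pure functions
of their seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .core import (
    BreakEnd,
    Breakpoint,
    BreakpointPath,
    GenomicPosition,
    canonicalize,
    format_path,
    normalize_path,
    reverse_complement,
)
from .io import FusionCandidate, GeneModel, write_gene_models_bed12

logger = logging.getLogger("fusegraph")

__all__ = [
    "EVENT_KINDS",
    "RearrangementEvent",
    "PlantedTruth",
    "make_genome",
    "plant",
    "add_noise",
    "write_bundle",
]

EVENT_KINDS = (
    "deletion",
    "inversion",
    "tandem_dup",
    "inverted_dup",
    "translocation",
    "chain",
)

#: bp between an RNA junction (exon boundary) and its genomic break-end.
_INTRON_OFFSET = 50

_EXON_LEN = 800
_INTRON_LEN = 1200


@dataclass(frozen=True)
class RearrangementEvent:
    kind: str
    loci: tuple = ()
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "chain" and self.loci and len(self.loci) < 2:
            raise ValueError("chain events require >= 2 component joins")


@dataclass(frozen=True)
class PlantedTruth:
    """One simulated dataset: alleles, implied fusions, and the GSR calls."""

    alleles: tuple  # BreakpointPath per event, normalized reporting form
    expected_fusions: tuple  # FusionCandidate per fusion-producing event
    gsr_calls: tuple  # canonical novel edges of all alleles, deduplicated
    events: tuple  # RearrangementEvent per event, loci filled in

    @property
    def derived_allele(self) -> BreakpointPath:
        return self.alleles[0]


# --------------------------------------------------------------------------
# genome
# --------------------------------------------------------------------------


def make_genome(
    n_chrom: int = 2,
    n_genes: int = 10,
    seed: int = 0,
    overlap: bool = False,
):
    """Deterministic toy genome: gene models plus chromosome lengths.

    Genes are laid out left to right with 20-40 kb intergenic gaps and
    alternate strands within each chromosome, so every chromosome offers
    both orientations.  ``overlap=True`` adds, over every third gene, a
    second gene whose span covers the host's introns and extends past its
    end — the geometry needed for alleles that route through an intronic
    segment of a third gene.
    """
    rng = np.random.default_rng(seed)
    genes: list = []
    chrom_lengths: dict = {}
    per_chrom = [n_genes // n_chrom + (1 if c < n_genes % n_chrom else 0)
                 for c in range(n_chrom)]
    gid = 0
    for c in range(n_chrom):
        chrom = str(c + 1)
        cursor = 100_000
        for k in range(per_chrom[c]):
            n_ex = int(rng.integers(3, 6))
            length = n_ex * _EXON_LEN + (n_ex - 1) * _INTRON_LEN
            start = cursor
            exons = tuple(
                (
                    start + i * (_EXON_LEN + _INTRON_LEN),
                    start + i * (_EXON_LEN + _INTRON_LEN) + _EXON_LEN - 1,
                )
                for i in range(n_ex)
            )
            strand = "+" if k % 2 == 0 else "-"
            name = f"GENE{gid:03d}"
            genes.append(GeneModel(name, chrom, strand, start, start + length - 1, exons))
            if overlap and k % 3 == 2:
                ov_start = start + _EXON_LEN + 100  # inside the first intron
                ov_end = start + length - 1 + 4_000
                genes.append(
                    GeneModel(f"{name}OV", chrom, "+", ov_start, ov_end, None)
                )
                cursor = ov_end
            else:
                cursor = start + length - 1
            cursor += int(rng.integers(20_000, 40_000))
            gid += 1
        chrom_lengths[chrom] = cursor + 100_000
    return genes, chrom_lengths


# --------------------------------------------------------------------------
# junction placement helpers
# --------------------------------------------------------------------------


def _tx_exons(g: GeneModel) -> list:
    """Exons in transcription order."""
    exons = list(g.exons)
    return exons if g.strand == "+" else list(reversed(exons))


def _donor(g: GeneModel, rng) -> tuple:
    """(x, a): RNA junction at an exon 3' boundary, break-end 50 bp into the intron."""
    exons = _tx_exons(g)
    i = int(rng.integers(0, len(exons) - 1))
    if g.strand == "+":
        x = exons[i][1]
        a = x + _INTRON_OFFSET
    else:
        x = exons[i][0]
        a = x - _INTRON_OFFSET
    return GenomicPosition(g.chrom, x), BreakEnd(GenomicPosition(g.chrom, a), g.strand)


def _acceptor(g: GeneModel, rng) -> tuple:
    """(y, b): RNA junction at an exon 5' boundary, break-end 50 bp upstream."""
    exons = _tx_exons(g)
    j = int(rng.integers(1, len(exons)))
    if g.strand == "+":
        y = exons[j][0]
        b = y - _INTRON_OFFSET
    else:
        y = exons[j][1]
        b = y + _INTRON_OFFSET
    return GenomicPosition(g.chrom, y), BreakEnd(GenomicPosition(g.chrom, b), g.strand)


def _score(rng) -> int:
    return int(rng.integers(5, 100))


# --------------------------------------------------------------------------
# planting
# --------------------------------------------------------------------------


class _GenePicker:
    def __init__(self, genes: Sequence[GeneModel], rng):
        self.genes = list(genes)
        self.rng = rng
        self.used: set = set()

    def pick(self, predicate, n: int = 1) -> list:
        """Draw n distinct unused genes jointly satisfying the predicate."""
        pool = [g for g in self.genes if g.gene_id not in self.used]
        order = list(self.rng.permutation(len(pool)))
        from itertools import permutations

        for combo in permutations(order, n):
            cand = [pool[i] for i in combo]
            if predicate(*cand):
                for g in cand:
                    self.used.add(g.gene_id)
                return cand
        raise ValueError("no gene combination satisfies the event constraints")


def _plant_simple_join(kind: str, g5: GeneModel, g3: GeneModel, rng):
    x, a = _donor(g5, rng)
    y, b = _acceptor(g3, rng)
    edge = Breakpoint(a, b, _score(rng))
    path = BreakpointPath([edge])
    fusion = FusionCandidate(g5.gene_id, g3.gene_id, x, y, source="sim")
    return path, fusion, [edge], (a.position, b.position)


def _plant_chain(g5: GeneModel, gm: GeneModel, g3: GeneModel, rng):
    x, a = _donor(g5, rng)
    y, b = _acceptor(g3, rng)
    # two way-points in distinct introns of the pass-through gene, ordered
    # along its strand so the reference walk between them is transcribable
    introns = [
        (gm.exons[i][1] + 1, gm.exons[i + 1][0] - 1) for i in range(len(gm.exons) - 1)
    ]
    i1, i2 = sorted(rng.choice(len(introns), size=2, replace=False))
    p1 = introns[i1][0] + 600
    p2 = introns[i2][0] + 600
    if gm.strand == "-":
        p1, p2 = p2, p1
    w1 = BreakEnd(GenomicPosition(gm.chrom, p1), gm.strand)
    w2 = BreakEnd(GenomicPosition(gm.chrom, p2), gm.strand)
    e1 = Breakpoint(a, w1, _score(rng))
    e2 = Breakpoint(w2, b, _score(rng))
    path = BreakpointPath([e1, Breakpoint(w1, w2, 0), e2])
    fusion = FusionCandidate(g5.gene_id, g3.gene_id, x, y, source="sim")
    return path, fusion, [e1, e2], (a.position, w1.position, w2.position, b.position)


def _plant_inverted_dup(g5: GeneModel, g3: GeneModel, rng):
    """Fold-back amplicon in the 3' gene, entered from the 5' gene.

    The allele traverses two of its breakpoints twice in opposite
    orientations, so recovering it requires an edge-reuse allowance of 2.
    """
    x, a = _donor(g5, rng)
    # RNA junction on the genomically second exon's high edge; the fold-back
    # cluster sits above it, the entry and lower cluster below it
    y_pos = g3.exons[1][1]
    y = GenomicPosition(g3.chrom, y_pos)
    pos = lambda p: GenomicPosition(g3.chrom, p)
    k1, k2, k3 = pos(y_pos - 2300), pos(y_pos - 2100), pos(y_pos - 1900)
    e = pos(y_pos - 1400)
    m1, m2, m3 = pos(y_pos + 400), pos(y_pos + 600), pos(y_pos + 800)
    if m3.pos > g3.end or k1.pos < g3.start:
        raise ValueError("gene too short for an inverted duplication")
    E1 = Breakpoint(a, BreakEnd(e, "+"), _score(rng))
    E2 = Breakpoint(BreakEnd(m1, "+"), BreakEnd(m3, "-"), _score(rng))
    E3 = Breakpoint(BreakEnd(m2, "-"), BreakEnd(k1, "+"), _score(rng))
    E4 = Breakpoint(BreakEnd(k2, "+"), BreakEnd(k3, "-"), _score(rng))
    null = lambda u, v, s: Breakpoint(BreakEnd(u, s), BreakEnd(v, s), 0)
    path = BreakpointPath(
        [
            E1,
            null(e, m1, "+"),
            E2,
            null(m3, m2, "-"),
            E3,
            null(k1, k2, "+"),
            E4,
            null(k3, k1, "-"),
            reverse_complement(E3),
            null(m2, m3, "+"),
            reverse_complement(E2),
        ]
    )
    fusion = FusionCandidate(g5.gene_id, g3.gene_id, x, y, source="sim")
    return path, fusion, [E1, E2, E3, E4], (a.position, e, k1, k2, k3, m1, m2, m3)


def _plant_intragenic_deletion(g: GeneModel, rng):
    """A deletion entirely inside one intron: no fusion is expected."""
    i = int(rng.integers(0, len(g.exons) - 1))
    lo = g.exons[i][1] + 300
    hi = g.exons[i][1] + 900
    if g.strand == "+":
        edge = Breakpoint(
            BreakEnd(GenomicPosition(g.chrom, lo), "+"),
            BreakEnd(GenomicPosition(g.chrom, hi), "+"),
            _score(rng),
        )
    else:
        edge = Breakpoint(
            BreakEnd(GenomicPosition(g.chrom, hi), "-"),
            BreakEnd(GenomicPosition(g.chrom, lo), "-"),
            _score(rng),
        )
    return BreakpointPath([edge]), None, [edge], (
        GenomicPosition(g.chrom, lo),
        GenomicPosition(g.chrom, hi),
    )


def plant(events, genome, seed: int = 0) -> PlantedTruth:
    """Plant events into a genome and derive the consistent truth set.

    ``events`` is a sequence of kind strings or RearrangementEvent objects.
    Each event draws its own disjoint set of genes, so planted fusions are
    independent of one another.
    """
    genes, _ = genome
    rng = np.random.default_rng(seed)
    picker = _GenePicker([g for g in genes if g.exons], rng)
    alleles: list = []
    fusions: list = []
    calls: list = []
    placed: list = []
    for ev in events:
        ev = ev if isinstance(ev, RearrangementEvent) else RearrangementEvent(str(ev))
        kind = ev.kind

        if kind == "deletion" and ev.params.get("intragenic"):
            (g,) = picker.pick(lambda g: len(g.exons) >= 2)
            path, fusion, edges, loci = _plant_intragenic_deletion(g, rng)
        elif kind == "translocation":
            g5, g3 = picker.pick(lambda a, b: a.chrom != b.chrom, 2)
            path, fusion, edges, loci = _plant_simple_join(kind, g5, g3, rng)
        elif kind == "deletion":
            g5, g3 = picker.pick(
                lambda a, b: a.chrom == b.chrom
                and a.strand == b.strand
                and (a.end < b.start if a.strand == "+" else a.start > b.end),
                2,
            )
            path, fusion, edges, loci = _plant_simple_join(kind, g5, g3, rng)
        elif kind == "inversion":
            g5, g3 = picker.pick(
                lambda a, b: a.chrom == b.chrom and a.strand != b.strand, 2
            )
            path, fusion, edges, loci = _plant_simple_join(kind, g5, g3, rng)
        elif kind == "tandem_dup":
            g5, g3 = picker.pick(
                lambda a, b: a.chrom == b.chrom
                and a.strand == b.strand
                and (a.start > b.end if a.strand == "+" else a.end < b.start),
                2,
            )
            path, fusion, edges, loci = _plant_simple_join(kind, g5, g3, rng)
        elif kind == "inverted_dup":
            g5, g3 = picker.pick(
                lambda a, b: b.strand == "-"
                and (a.chrom != b.chrom or a.end < b.start or a.start > b.end),
                2,
            )
            path, fusion, edges, loci = _plant_inverted_dup(g5, g3, rng)
        elif kind == "chain":
            g5, gm, g3 = picker.pick(
                lambda a, m, b: len(m.exons) >= 3 and a.gene_id != b.gene_id, 3
            )
            path, fusion, edges, loci = _plant_chain(g5, gm, g3, rng)
        else:  # pragma: no cover - guarded by RearrangementEvent
            raise ValueError(f"unknown event kind {kind!r}")

        alleles.append(normalize_path(path))
        if fusion is not None:
            fusions.append(fusion)
        calls.extend(edges)
        placed.append(RearrangementEvent(kind, tuple(loci), dict(ev.params)))

    seen: set = set()
    unique_calls = []
    for c in calls:
        cc = canonicalize(c)
        if cc not in seen:
            seen.add(cc)
            unique_calls.append(cc)
    return PlantedTruth(
        alleles=tuple(alleles),
        expected_fusions=tuple(fusions),
        gsr_calls=tuple(unique_calls),
        events=tuple(placed),
    )


# --------------------------------------------------------------------------
# noise
# --------------------------------------------------------------------------


def add_noise(
    truth: PlantedTruth,
    genes: Sequence[GeneModel],
    fp_rate: float = 0.0,
    fn_rate: float = 0.0,
    jitter_bp: int = 0,
    seed: int = 0,
):
    """Degrade the truth call sets: drop, jitter, and inject calls.

    Returns ``(gsr_calls, fusion_candidates)``.  With all rates at zero the
    truth is returned unchanged.  Injected false calls are placement-checked
    (and re-rolled) so they can never complete an unplanted fusion: false
    GSR edges land only in genes uninvolved in any planted allele (or in
    intergenic space), and false fusion candidates name a 5' gene that
    carries no breakpoint at all.  That keeps false-positive accounting in
    tests exact.
    """
    rng = np.random.default_rng(seed)
    if not (fp_rate or fn_rate or jitter_bp):
        return list(truth.gsr_calls), list(truth.expected_fusions)

    involved: set = set()
    for f in truth.expected_fusions:
        involved.update((f.gene5, f.gene3))
    for b in truth.gsr_calls:
        for end in (b.in_end, b.out_end):
            for g in genes:
                if g.contains(end.position):
                    involved.add(g.gene_id)

    gsr: list = []
    for b in truth.gsr_calls:
        if fn_rate and rng.random() < fn_rate:
            continue
        if jitter_bp:
            jit = lambda e: BreakEnd(
                GenomicPosition(
                    e.chrom, max(1, e.pos + int(rng.integers(-jitter_bp, jitter_bp + 1)))
                ),
                e.strand,
            )
            b = Breakpoint(jit(b.in_end), jit(b.out_end), b.score)
        gsr.append(b)

    fusions = [f for f in truth.expected_fusions if not (fn_rate and rng.random() < fn_rate)]

    free_genes = [g for g in genes if g.gene_id not in involved]
    n_fp_gsr = int(round(fp_rate * max(1, len(truth.gsr_calls))))
    for _ in range(n_fp_gsr):
        if len(free_genes) < 2:
            break
        i, j = rng.choice(len(free_genes), size=2, replace=False)
        ga, gb = free_genes[int(i)], free_genes[int(j)]
        a = BreakEnd(
            GenomicPosition(ga.chrom, int(rng.integers(ga.start, ga.end + 1))),
            rng.choice(["+", "-"]),
        )
        b = BreakEnd(
            GenomicPosition(gb.chrom, int(rng.integers(gb.start, gb.end + 1))),
            rng.choice(["+", "-"]),
        )
        gsr.append(Breakpoint(a, b, _score(rng)))

    gsr_nodes = {e.position for c in gsr for e in (c.in_end, c.out_end)}
    n_fp_fus = int(round(fp_rate * max(1, len(truth.expected_fusions))))
    planted_pairs = {(f.gene5, f.gene3) for f in truth.expected_fusions}
    attempts = 0
    added = 0
    while added < n_fp_fus and attempts < 100:
        attempts += 1
        i, j = rng.choice(len(genes), size=2, replace=False)
        g5, g3 = genes[int(i)], genes[int(j)]
        if (g5.gene_id, g3.gene_id) in planted_pairs:
            continue
        if any(n.chrom == g5.chrom and g5.start <= n.pos <= g5.end for n in gsr_nodes):
            continue  # re-roll: this 5' gene carries a breakpoint
        x = GenomicPosition(g5.chrom, (g5.start + g5.end) // 2)
        y = GenomicPosition(g3.chrom, (g3.start + g3.end) // 2)
        fusions.append(FusionCandidate(g5.gene_id, g3.gene_id, x, y, source="noise"))
        added += 1
    return gsr, fusions


# --------------------------------------------------------------------------
# file emission
# --------------------------------------------------------------------------


def write_bundle(
    truth: PlantedTruth,
    genes: Sequence[GeneModel],
    outdir,
    gsr_calls: Optional[Sequence[Breakpoint]] = None,
    fusions: Optional[Sequence[FusionCandidate]] = None,
) -> None:
    """Emit the dataset as BED12 + generic TSVs plus a truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_gene_models_bed12(genes, outdir / "genes.bed")
    calls = truth.gsr_calls if gsr_calls is None else gsr_calls
    cands = truth.expected_fusions if fusions is None else fusions
    with open(outdir / "gsr.tsv", "w") as fh:
        fh.write("#chrom1\tpos1\tstrand1\tchrom2\tpos2\tstrand2\tscore\n")
        for b in calls:
            fh.write(
                f"{b.in_end.chrom}\t{b.in_end.pos}\t{b.in_end.strand}\t"
                f"{b.out_end.chrom}\t{b.out_end.pos}\t{b.out_end.strand}\t{b.score}\n"
            )
    with open(outdir / "fusions.tsv", "w") as fh:
        fh.write("#gene5\tchrom5\tpos5\tgene3\tchrom3\tpos3\tsource\n")
        for f in cands:
            fh.write(
                f"{f.gene5}\t{f.x.chrom}\t{f.x.pos}\t"
                f"{f.gene3}\t{f.y.chrom}\t{f.y.pos}\t{f.source}\n"
            )
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("#fusion\tpath\n")
        fi = 0
        for ev, allele in zip(truth.events, truth.alleles):
            intragenic = ev.kind == "deletion" and ev.params.get("intragenic")
            if intragenic:
                fh.write(f".\t{format_path(allele)}\n")
            else:
                f = truth.expected_fusions[fi]
                fi += 1
                fh.write(f"{f.pair}\t{format_path(allele)}\n")
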