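# Methods

## Breakpoint representation

A rearrangement junction is modeled as an undirected novel adjacency
between two break-ends. Each break-end is a reference coordinate
(chromosome, 1-based position — all coordinates in the package are 1-based
inclusive; BED input is converted at ingest and nowhere else) plus a
strand: `+` means the attached segment runs with increasing coordinates,
`-` with decreasing ones. The serialized form glues
`chrom:pos strand score` for the in-end to `chrom:pos strand` for the
out-end with `|`. Reverse complementing — swapping ends and flipping both
strands — yields the identical junction read from the opposite strand, so
equality of breakpoints (and of paths) is always tested on a canonical
representative: the lexicographically smaller of the two orientations
under (chromosome by natural sort, position, strand with `+` < `-`). The
canonical pick is this package's own convention; only the equivalence
itself is meaningful.

Score 0 is reserved as the null-edge (reference adjacency) sentinel. A
caller-reported junction with zero supporting reads is clamped to score 1
at ingest so it cannot masquerade as reference sequence. A null edge of
zero extent (a position joined to itself) is legal and acts as an
identity, which simplifies path assembly. Classification of novel
intra-chromosomal edges is purely geometric: opposite strands → inverse;
same strand with the out-end strictly ahead in the direction of travel →
jump; at or behind → repeat.

## Graph construction

Nodes are positions; strand semantics live on the edges, so a single node
serves both orientations and a node may carry arbitrarily many edges
(polyploid genomes: each parallel edge is a different allele — exact
duplicates collapse, same junction with different scores stays parallel).
Null edges are inserted per gene: the break-ends inside each (optionally
padded, `--gene-pad`, default 0) gene span, plus the span's terminal
bases, are chained in genomic order. Consequences that matter:

* No null edge joins neighboring genes, so a read-through transcript
  cannot pose as a validated fusion. `restore_read_through` re-adds the
  inter-gene reference edge when such events are of interest.
* A break-end inside two overlapping genes joins both chains; alleles may
  therefore route through any gene containing the end (the PREX1>CPNE1
  worked example routes through an intron of *PHF20* this way).
* Intergenic break-ends are nodes without null edges — reachable only
  through novel adjacencies. Reference traversal is deliberately confined
  to expressed regions; whether near-gene intergenic ends should also be
  chained is genuinely open, and the padding flag covers that reading
  without changing the default.

## Transcriptome-guided search

Anchoring interprets "downstream" transcript-wise. For the 5' gene, x₀
candidates are breakpoint-bearing nodes at or beyond *x* in the gene's
transcription direction (the genomic junction must lie at or past the
last transcribed base); for the 3' gene, y₀ candidates lie between the
gene's transcription start side and *y*, because the genomic join must
precede *y* for transcription to flow into the 3' partner. The wording is
deliberately asymmetric: a symmetric "downstream of both" reading leaves
the 3' side undefined, and the transcript-wise reading is the one that
reproduces the worked-example paths.

Candidates are ordered nearest-first and the top `anchor_depth` (default
3) per side are combined into anchor pairs; caller-position jitter
otherwise silently kills true fusions whose nearest node moved.
`--strict-nearest` restores the strict single-pair behavior. The terminal
reference run y₀→y is not required to be breakpoint-free (also open; the
permissive choice loses no true positives).

Enumeration is breadth-first over (position, strand) states. Each step
appends one traversable edge: an edge whose in-end matches the current
position and strand after optional reverse-complement reorientation. A
path is emitted on arriving at y₀ moving in the 3' gene's transcription
direction and the branch stops there; a branch dies when no edge
continues or a bound is hit. Bounds, with defaults and reasons:

| parameter | default | role |
|---|---|---|
| `max_novel_edges` | 8 | caps allele complexity; chromothripsis-scale graphs otherwise explode |
| `max_edge_reuse` | 2 | per canonical edge per path; 2 is the minimum that recovers inverted-duplication alleles, which cross the same two physical breakpoints twice in opposite orientations, while guaranteeing termination on cycles |
| `max_paths_per_fusion` | 50 | emitted-path cap; excess flags the result truncated |
| `merge_window` | 10 bp | redundant candidates (same pair, positions this close) merge before searching |

Emitted paths are normalized to reporting form: maximal runs of
consecutive null edges merge into one (reported paths write a reference
run as a single null edge even where interior breakpoint nodes subdivide
it in the graph) and terminal null edges are trimmed (a leading or
trailing reference run carries no information about the allele). Paths
are deduplicated under reverse complement and sorted simplest-first
(ascending novel-edge count, then descending total support), so the most
parsimonious mechanism leads the report. Emission orientation is 5'→3'
along the fusion transcript; all equality checks compare canonical forms,
since a path and its reverse complement are the same allele.

Two quantification notes on the worked example. First, counting distinct
breakpoints of the SK-BR-3 inverted-duplication allele (MTBP>SAMD12)
under canonical merging gives 4, because two of its six score>0 edge
traversals are reverse complements of two others; counts of 5 arise only
if orientation-merging is partial, and this package consistently merges.
Second, the two reported WDR67>ZNF704 alleles are printed in mutually
incompatible orientations: no single strand assignment of the two genes
makes both printed strings start in the 5' gene on its transcription
strand. The search therefore recovers the orientation-consistent allele
from the worked-example bundle; the catalog itself (and the codec-level
statistics computed from it) still carries both printed alleles.

With default anchor fallback, complex regions can yield additional
shorter allele hypotheses beside the planted or published one (e.g. a
two-breakpoint variant of the MTBP>SAMD12 amplicon terminating at a
fallback anchor). These are genuine paths the data supports, reported
alongside; `--strict-nearest` suppresses them.

## Input handling

The intra-chromosomal minimum-span filter (default 1000 bp) reflects how
short local calls at typical insert sizes are dominated by alignment
artifacts. The BreakDancer-style adapter maps the majority strand of each
orientation token (`34+12-`) to the break-end strands, flipping the
second end because reads there face back toward the junction — this
mapping sends deletion rows to jump, inversion rows to inverse, and
translocation rows to inter-chromosomal edges. The CREST-style adapter is
best-effort (strands as written, score = larger soft-clip count): the
upstream format is not standardized. Fusion candidates naming unknown
genes or out-of-span positions are kept and flagged at ingest — gene
annotation versions drift — and skipped by the search with a logged
reason.

## Simulator

`fusegraph.simulate` generates study conditions at the call level — the
tool consumes caller outputs, so no reads are synthesized. A toy genome
(deterministic in its seed) lays out genes with 800 bp exons, 1200 bp
introns, 20–40 kb intergenic gaps, alternating strands per chromosome;
fusion junctions are placed exactly at exon boundaries and genomic
break-ends 50 bp into the flanking intron. Six event kinds are planted
(deletion, inversion, tandem duplication, inverted duplication,
translocation, chain through a third gene), each drawing disjoint genes;
multi-event runs use 16-gene genomes (8 per chromosome) so every kind can
draw a compatible disjoint gene set. The derived truth is exact: GSR
calls are precisely the novel edges of the planted allele, and the
planted path is recoverable by construction at zero noise.

Noise injection drops true calls (`fn_rate`), jitters break-end positions
(`jitter_bp`; the 50 bp intron offset keeps jitter up to the merge window
harmless), and injects false calls (`fp_rate`) that are
placement-checked, with re-rolls, so they can never complete an unplanted
fusion — false GSR edges land only in genes uninvolved in any planted
allele, and false fusion candidates name a breakpoint-free 5' gene. This
keeps false-positive accounting in tests exact, at the cost of realism:
real false calls are not adversarially placed but also not guaranteed
harmless. Other features of real data the simulator does not emulate:
caller-specific position biases, shared breakpoints between events,
subclonal mixtures, and reference-alignability artifacts. Passing the
planted-truth suite therefore demonstrates the integration logic is
correct, not that real call sets of any quality will validate cleanly.

## Problem sizes and verification

The test suite cross-checks the enumeration against an independent
brute-force recursion on 200 random ≤12-node graphs, the classifier
against an exhaustive configuration table, involution/idempotence
properties on 10,000 random breakpoints, and planted-truth recovery on 50
seeded six-event simulations; `scripts/acceptance.py` recomputes the
worked-example statistics, the file-based pipeline's validated gene-pair
count, and recovery percentages over 20 seeded simulations (120 planted
fusions). Everything runs in seconds on one CPU.

## Limitations

No sequence-level allele reconstruction (coordinate paths only), no
microhomology or untemplated-insertion modeling at junctions, no
reading-frame assessment of the fused product, no expression modeling,
and no probabilistic re-scoring of paths — scores are carried through
from the callers untouched. Cohort orchestration and copy-number-aware
edge weighting are likewise out of scope.
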