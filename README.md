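# fusegraph

Genomic validation of gene fusions by breakpoint-graph search.

Tumor transcriptomes express chimeric mRNAs whose origins are DNA-level
structural rearrangements (GSRs): deletions, inversions, duplications,
translocations, or complex chains of all of these. RNA-seq fusion callers
(deFuse, Tophat-fusion, BreakFusion, …) and WGS rearrangement callers
(BreakDancer, CREST, …) each produce call sets riddled with independent
false positives. `fusegraph` cross-validates the two: it assembles the WGS
breakpoints into a strand-aware **breakpoint graph** and searches it for a
genomic allele — a **breakpoint path** — that could transcribe each
candidate fusion. A fusion with a supporting allele is genomically
validated, and the path is its mechanistic explanation; because of
splicing, that allele may involve breakpoints far from the RNA junction
and may chain segments of several genes.

The package is for bioinformaticians who already run fusion and SV callers
and want to integrate their outputs, rather than re-align reads.

## Model

A breakpoint joins two directed DNA *break-ends* and is written as a
**breakpoint string**

```
chrom:pos±f | chrom:pos±        e.g.   5:139807117+65|5:141217466-
```

where the in-end ends the entering segment, the out-end starts the exiting
segment, `+`/`-` give the direction each segment runs along the reference,
and `f` is a confidence score (supporting reads). `f = 0` is reserved for
*null* edges — reference adjacencies. A string and its reverse complement
(`x+3|y+` ≡ `y-3|x-`) name the same double-stranded junction. Intra-
chromosomal breakpoints classify as *jump* (deletion-like), *inverse*
(inversion / fold-back), or *repeat* (tandem-duplication-like).

In the graph, nodes are genomic positions and edges are breakpoints: novel
edges come verbatim from the callers (a multigraph — parallel edges are
different alleles), and null edges chain the break-ends lying within each
gene span in genomic order. Null edges never cross gene boundaries, which
excludes read-through transcripts by construction (they can be restored
explicitly).

For a fusion with transcript-side positions *x* (5' gene) and *y*
(3' gene), the search anchors at (*x₀*, *y₀*) — the nearest
breakpoint-bearing nodes downstream of *x* and upstream of *y* in
transcription direction — and expands breadth-first

```
p(x0) = x0 + p(n(x0))
```

following only strand-consistent edges, terminating on reaching *y₀* (or
exhausting a branch). Cycles make the bare recursion non-terminating, so
paths are bounded by a novel-edge cap (8), an edge-reuse cap (2 — exactly
what an inverted-duplication allele needs, since it crosses the same two
breakpoints twice in opposite orientations), and an emitted-path cap.

## Worked example

The package ships a worked example (`fusegraph.skbr3`): the fusion catalog
of the SK-BR-3 breast-cancer cell line, with the 14 underlying genomic
breakpoints and synthetic stand-in gene models. Write it out and validate:

```sh
python -c "from fusegraph import skbr3; skbr3.write_bundle('bundle')"
fusegraph validate --gsr bundle/gsr.tsv --fusions bundle/fusions.tsv \
    --genes bundle/genes.bed --out report.tsv --log-level WARNING
```

prints

```
candidates_in   12
fusions_validated       8
unique_gene_pairs       8
allele_histogram        1:7,6:1
validated       ANKHD1-EIF4EBP3>PCDH1
validated       CCDC85C>SETD3
validated       MTBP>SAMD12
validated       PREX1>CPNE1
validated       RARA>PKIA
validated       SUMF1>LRRFIP2
validated       TATDN1>GSDMB
validated       WDR67>ZNF704
```

Of the 12 candidate gene pairs, 8 are supported by genomic alleles.
`report.tsv` lists each allele as a breakpoint path; for example
PREX1>CPNE1 is explained by

```
20:46795673-17|20:33925625-0|20:33923847-18|20:33679982-
```

two breakpoints (17 and 18 supporting reads) splicing the head of *PREX1*
to the tail of *CPNE1* through an intronic segment of *PHF20*. The
MTBP>SAMD12 row carries a six-breakpoint-traversal path — an inverted
duplication — alongside shorter alternative allele hypotheses found from
fallback anchors (`--strict-nearest` suppresses the latter).

One-off string utilities:

```sh
$ fusegraph path rc "8:124171162+18|8:81916434-"
8:81916434+18|8:124171162-
$ fusegraph path count "20:46795673-17|20:33925625-0|20:33923847-18|20:33679982-"
2
```

Simulated data with planted truth:

```sh
fusegraph simulate --events deletion,inversion,chain,inverted_dup \
    --seed 7 --n-genes 16 --out simdir --check
```

## Input formats

* `--genes`: BED12 (0-based half-open; converted to 1-based inclusive at
  ingest) or GTF (`--gene-format gtf`). Multi-transcript genes flatten to
  a union span.
* `--gsr`: tab-separated, `#` comments. Dialects (`--gsr-format`):
  * `generic`: `chrom1 pos1 strand1 chrom2 pos2 strand2 score`
  * `breakdancer`: `chr1 pos1 or1 chr2 pos2 or2 type size score num_reads`
    (orientation tokens like `34+12-`; majority strand is used, read count
    becomes the score)
  * `crest` (best-effort): `chrom1 pos1 strand1 clip1 chrom2 pos2 strand2
    clip2 [type]`
  Intra-chromosomal calls spanning less than `--min-span` (default
  1000 bp) are dropped at ingest; caller scores of 0 are clamped to 1.
* `--fusions`: `gene5 chrom5 pos5 gene3 chrom3 pos3 source`.

The report is a `#`-headed TSV: gene pair, allele count,
semicolon-joined path strings, per-allele anchors, and caller tags.

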