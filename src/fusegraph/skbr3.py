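"""Worked example: the SK-BR-3 breast-cancer cell line fusion catalog.

SK-BR-3 is the classic demonstration case for genomic validation of gene
fusions: integrating its WGS structural-rearrangement calls with RNA-seq
fusion calls yields eight fusion gene pairs supported by nine derivative
alleles, including a two-breakpoint allele for PREX1>CPNE1 that routes
through an intronic segment of PHF20 and an inverted-duplication allele for
MTBP>SAMD12 that traverses two of its breakpoints twice.

``CATALOG`` transcribes the reported breakpoint paths (build-36
coordinates).  The gene models here are SYNTHETIC stand-ins: real build-36
annotation is not shipped, so each span is a constructed interval chosen to
contain the catalog's break-end coordinates with the gene's correct strand
and chromosome.  They are sufficient for the search geometry but are not
real gene boundaries.

``gene_models`` / ``gsr_calls`` / ``fusion_candidates`` rebuild the full
input bundle from the catalog, and ``write_bundle`` emits it as files for
CLI-driven runs.
"""

from __future__ import annotations

from pathlib import Path

from .core import Breakpoint, GenomicPosition, canonicalize, parse_path
from .io import FusionCandidate, GeneModel, write_gene_models_bed12

__all__ = [
    "CATALOG",
    "catalog_paths",
    "gene_models",
    "gsr_calls",
    "fusion_candidates",
    "write_bundle",
]

#: Fusion gene pair -> list of supporting breakpoint-path strings (empty for
#: the known fusions that genomic data could not support).
CATALOG = {
    "ANKHD1-EIF4EBP3>PCDH1": ["5:139807117+65|5:141217466-"],
    "CCDC85C>SETD3": ["14:99059254-7|14:98966917-"],
    "RARA>PKIA": ["17:35727917+45|8:79637984+"],
    "SUMF1>LRRFIP2": ["3:4338455-34|3:37158400-"],
    "TATDN1>GSDMB": ["8:125618280-93|17:35321200-"],
    "WDR67>ZNF704": [
        "8:81882283-4|8:81882470+0|8:81916434+18|8:124171162-0|"
        "8:124158930-36|8:124161970+",
        "8:124171162+18|8:81916434-",
    ],
    "MTBP>SAMD12": [
        "8:121547851+33|8:119503797+0|8:119661057+2|8:119666167-0|"
        "8:119662603-33|8:118985543+0|8:118990300+28|8:118992237-0|"
        "8:118985543-33|8:119662603+0|8:119666167+2|8:119661057-"
    ],
    "PREX1>CPNE1": ["20:46795673-17|20:33925625-0|20:33923847-18|20:33679982-"],
    "DHX35>ITCH": [],
    "NFS1>PREX1": [],
    "CYTH1>EIF3H": [],
    "CSE1L>ENSG00000236127": [],
}

#: Synthetic gene spans (gene_id, chrom, strand, start, end) chosen to
#: contain the catalog break-ends; strands follow the path orientations.
_GENES = [
    ("ANKHD1-EIF4EBP3", "5", "+", 139740000, 139815000),
    ("PCDH1", "5", "-", 141210000, 141260000),
    ("CCDC85C", "14", "-", 99050000, 99104000),
    ("SETD3", "14", "-", 98920000, 98975000),
    ("RARA", "17", "+", 35700000, 35745000),
    ("GSDMB", "17", "-", 35310000, 35325000),
    ("SUMF1", "3", "-", 4330000, 4350000),
    ("LRRFIP2", "3", "-", 37100000, 37165000),
    ("PKIA", "8", "+", 79600000, 79690000),
    ("ZNF704", "8", "-", 81870000, 81925000),
    ("SAMD12", "8", "-", 118980000, 119670000),
    ("MTBP", "8", "+", 121540000, 121560000),
    ("WDR67", "8", "+", 124140000, 124180000),
    ("TATDN1", "8", "-", 125610000, 125640000),
    ("CPNE1", "20", "-", 33670000, 33695000),
    ("PHF20", "20", "+", 33900000, 33940000),
    ("PREX1", "20", "-", 46700000, 46850000),
    # genes of the catalog's unsupported fusions (no breakpoints land here)
    ("DHX35", "20", "+", 37200000, 37250000),
    ("ITCH", "20", "+", 32900000, 32950000),
    ("NFS1", "20", "+", 34200000, 34250000),
    ("CYTH1", "17", "+", 74100000, 74150000),
    ("EIF3H", "8", "-", 117600000, 117650000),
    ("CSE1L", "20", "+", 47000000, 47050000),
    ("ENSG00000236127", "1", "+", 5000000, 5050000),
]

#: Fusion pair -> transcript-side junction positions (x in the 5' gene,
#: y in the 3' gene), placed upstream of the anchoring break-ends in each
#: gene's transcription direction.
_JUNCTIONS = {
    "ANKHD1-EIF4EBP3>PCDH1": (("5", 139806900), ("5", 141217200)),
    "CCDC85C>SETD3": (("14", 99060000), ("14", 98966500)),
    "RARA>PKIA": (("17", 35727500), ("8", 79638500)),
    "SUMF1>LRRFIP2": (("3", 4339000), ("3", 37158000)),
    "TATDN1>GSDMB": (("8", 125619000), ("17", 35320900)),
    "WDR67>ZNF704": (("8", 124155000), ("8", 81916000)),
    "MTBP>SAMD12": (("8", 121547000), ("8", 119660500)),
    "PREX1>CPNE1": (("20", 46796000), ("20", 33679800)),
    "DHX35>ITCH": (("20", 37220000), ("20", 32920000)),
    "NFS1>PREX1": (("20", 34220000), ("20", 46800000)),
    "CYTH1>EIF3H": (("17", 74120000), ("8", 117620000)),
    "CSE1L>ENSG00000236127": (("20", 47020000), ("1", 5020000)),
}


def catalog_paths() -> dict:
    """Parsed catalog: fusion pair -> list of BreakpointPath."""
    return {pair: [parse_path(s) for s in paths] for pair, paths in CATALOG.items()}


def gene_models() -> list:
    """Synthetic gene models covering the catalog coordinates."""
    return [GeneModel(gid, chrom, strand, s, e) for gid, chrom, strand, s, e in _GENES]


def gsr_calls() -> list:
    """The distinct canonical novel adjacencies underlying the catalog paths."""
    seen = set()
    out = []
    for paths in CATALOG.values():
        for s in paths:
            for edge in parse_path(s).novel_edges:
                c = canonicalize(edge)
                if c not in seen:
                    seen.add(c)
                    out.append(c)
    return out


def fusion_candidates() -> list:
    """One fusion candidate per catalog gene pair (transcript-side positions)."""
    out = []
    for pair, ((cx, px), (cy, py)) in _JUNCTIONS.items():
        g5, g3 = pair.split(">")
        out.append(
            FusionCandidate(g5, g3, GenomicPosition(cx, px), GenomicPosition(cy, py), "catalog")
        )
    return out


def write_bundle(outdir) -> dict:
    """Emit the worked-example bundle as files; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes": outdir / "genes.bed",
        "gsr": outdir / "gsr.tsv",
        "fusions": outdir / "fusions.tsv",
    }
    write_gene_models_bed12(gene_models(), paths["genes"])
    with open(paths["gsr"], "w") as fh:
        fh.write("#chrom1\tpos1\tstrand1\tchrom2\tpos2\tstrand2\tscore\n")
        for b in gsr_calls():
            fh.write(
                f"{b.in_end.chrom}\t{b.in_end.pos}\t{b.in_end.strand}\t"
                f"{b.out_end.chrom}\t{b.out_end.pos}\t{b.out_end.strand}\t{b.score}\n"
            )
    with open(paths["fusions"], "w") as fh:
        fh.write("#gene5\tchrom5\tpos5\tgene3\tchrom3\tpos3\tsource\n")
        for f in fusion_candidates():
            fh.write(
                f"{f.gene5}\t{f.x.chrom}\t{f.x.pos}\t"
                f"{f.gene3}\t{f.y.chrom}\t{f.y.pos}\t{f.source}\n"
            )
    return paths
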