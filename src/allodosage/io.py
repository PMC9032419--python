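"""Plain-text readers and writers.

Genes travel as BED (0-based half-open) plus an orthologue-mapping TSV;
coverage as 4-column bedGraph with a JSON sidecar holding the library
size and bin width; counts as a TSV (gene id first column) with a
sample-metadata TSV sidecar; simulation truth as JSON.  Every writer
has a reader that round-trips losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .types import CountMatrix, CoverageTrack, GeneRecord, Karyotype, Segment


# ---------------------------------------------------------------------------
# genes: BED + orthologue map

def write_genes_bed(path: str | Path, genes: list[GeneRecord]) -> Path:
    """Write genes as 6-column BED; the name field is the gene id."""
    path = Path(path)
    with path.open("w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t+\n")
    return path


def write_ortholog_map(path: str | Path, genes: list[GeneRecord]) -> Path:
    """Write the gene id -> (base id, sub-genome) mapping as TSV."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "base_id": [g.base_id for g in genes],
            "subgenome": [g.subgenome for g in genes],
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def read_genes(bed_path: str | Path, ortholog_path: str | Path) -> list[GeneRecord]:
    """Read genes from BED plus the orthologue-mapping TSV."""
    bed = pd.read_csv(
        bed_path, sep="\t", header=None, usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "gene_id"],
    )
    omap = pd.read_csv(ortholog_path, sep="\t").set_index("gene_id")
    genes = []
    for row in bed.itertuples(index=False):
        meta = omap.loc[row.gene_id]
        genes.append(
            GeneRecord(
                gene_id=row.gene_id,
                base_id=str(meta["base_id"]),
                subgenome=str(meta["subgenome"]),
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
            )
        )
    return genes


# ---------------------------------------------------------------------------
# coverage: bedGraph + JSON sidecar

def write_coverage_bedgraph(
    path: str | Path, tracks: dict[str, CoverageTrack], meta_path: str | Path | None = None
) -> tuple[Path, Path]:
    """Write all tracks to one bedGraph; library size goes to a sidecar."""
    path = Path(path)
    meta_path = Path(meta_path) if meta_path else path.with_suffix(".meta.json")
    lib_sizes = {}
    bin_widths = set()
    with path.open("w") as fh:
        for chrom in sorted(tracks):
            t = tracks[chrom]
            lib_sizes[chrom] = float(t.library_size)
            bin_widths.add(t.bin_width)
            for start, count in zip(t.starts, t.counts):
                fh.write(f"{chrom}\t{start}\t{start + t.bin_width}\t{count:g}\n")
    if len(bin_widths) != 1:
        raise ValueError("tracks must share one bin width")
    meta = {"bin_width": bin_widths.pop(), "library_size": lib_sizes}
    meta_path.write_text(json.dumps(meta, indent=1))
    return path, meta_path


def read_coverage_bedgraph(
    path: str | Path, meta_path: str | Path | None = None
) -> dict[str, CoverageTrack]:
    path = Path(path)
    meta_path = Path(meta_path) if meta_path else path.with_suffix(".meta.json")
    meta = json.loads(Path(meta_path).read_text())
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "count"]
    )
    tracks = {}
    for chrom, sub in df.groupby("chrom", sort=True):
        tracks[str(chrom)] = CoverageTrack(
            chrom=str(chrom),
            starts=sub["start"].to_numpy(),
            counts=sub["count"].to_numpy(),
            library_size=float(meta["library_size"][str(chrom)]),
            bin_width=int(meta["bin_width"]),
        )
    return tracks


# ---------------------------------------------------------------------------
# counts: TSV + sample metadata TSV

def write_count_matrix(
    counts_path: str | Path, samples_path: str | Path, cm: CountMatrix
) -> tuple[Path, Path]:
    counts_path, samples_path = Path(counts_path), Path(samples_path)
    out = cm.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(counts_path, sep="\t")
    meta = cm.samples.copy()
    meta.index.name = "sample"
    meta.to_csv(samples_path, sep="\t")
    return counts_path, samples_path


def read_count_matrix(counts_path: str | Path, samples_path: str | Path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index.name = None
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    return CountMatrix(counts, samples)


# ---------------------------------------------------------------------------
# karyotype reports

def write_karyotype_tsv(path: str | Path, karyotype: Karyotype) -> Path:
    """Segment-level report: chromosome, bin range, mean coverage, CN."""
    rows = []
    for chrom in sorted(karyotype.segments):
        for s in karyotype.segments[chrom]:
            rows.append(
                {
                    "chrom": chrom,
                    "start_bin": s.start_bin,
                    "end_bin": s.end_bin,
                    "mean_norm_cov": s.mean,
                    "cn": s.cn,
                    "modal_cn": karyotype.modal_cn(chrom),
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(Path(path), sep="\t", index=False)
    return Path(path)


def read_karyotype_tsv(path: str | Path, haploid_unit: float = float("nan"),
                       bin_width: int = 500) -> Karyotype:
    df = pd.read_csv(path, sep="\t")
    segments: dict[str, list[Segment]] = {}
    for row in df.itertuples(index=False):
        segments.setdefault(str(row.chrom), []).append(
            Segment(str(row.chrom), int(row.start_bin), int(row.end_bin),
                    float(row.mean_norm_cov), int(row.cn))
        )
    return Karyotype(segments=segments, haploid_unit=haploid_unit, bin_width=bin_width)
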