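"""Simulate an aneuploid hybrid strain and write it as plain-text files.

Generates a hybrid genome (two sub-genomes, random chromosome copy
numbers, two hybrid chromosomes with intragenic breakpoints), binned
WGS coverage and an RNA-seq count matrix, then writes everything to
disk in BED/bedGraph/TSV/JSON form.
"""

from pathlib import Path

import allodosage as ad

cfg = ad.SimConfig(n_chromosomes_per_subgenome=8, genes_per_chromosome=20, seed=7)
strain = ad.simulate.simulate_strain(cfg)

outdir = Path("scratch/example_strain")
paths = ad.simulate.write_fixture(
    outdir, strain.genes, strain.truth, strain.coverage, strain.counts
)

print(f"genes:            {len(strain.genes)} (both sub-genomes)")
print(f"chromosomes:      {len(strain.coverage)} coverage tracks")
print(f"hybrid breakpoints: {len(strain.truth.breakpoints)}")
for bp in strain.truth.breakpoints:
    print(f"  {bp.chrom_sc}/{bp.chrom_se} at {bp.pos} bp inside gene {bp.base_id}")
print(f"count matrix:     {strain.counts.n_genes} genes x {strain.counts.n_samples} samples")
print(f"files written to: {outdir}/")
# The truth JSON records the planted karyotype and per-allele copy
# numbers, so downstream stages can be scored against it.
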