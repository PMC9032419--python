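"""Call an integer karyotype from binned WGS coverage alone.

Normalizes reads/500 bp by library size, segments each chromosome at
copy-number steps, estimates the haploid coverage unit and rounds
segment means to integer copy numbers; hybrid chromosomes show up as
within-chromosome breakpoints mapped to the gene containing them.
"""

import allodosage as ad

cfg = ad.SimConfig(n_chromosomes_per_subgenome=8, genes_per_chromosome=20, seed=7)
strain = ad.simulate.simulate_strain(cfg)

karyo = ad.karyotype.call_karyotype(strain.coverage)
per_chrom, total = ad.karyotype.chromosome_copy_table(karyo)

print(f"haploid coverage unit: {karyo.haploid_unit:.3f} (normalized reads/bin/copy)")
print("chromosome : called CN (true CN)")
for chrom in sorted(per_chrom):
    print(f"  {chrom:6s}   : {per_chrom[chrom]} ({strain.truth.modal_cn(chrom)})")
print(f"total chromosome count: {total} (truth {strain.truth.total_chromosome_cn()})")

bps = ad.karyotype.detect_breakpoints(karyo, strain.genes)
print(f"\nbreakpoints detected: {len(bps)} (copy-number steps inside chromosomes)")
for b in bps:
    print(f"  {b.chrom} at {b.pos} bp, CN {b.left_cn}->{b.right_cn}, gene {b.gene_id}")
# Each planted hybrid chromosome produces one step on the Sc track and
# one on the Se track, both inside the recombination-point gene.
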