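"""End-to-end recovery studies on synthetic hybrids.

Each function simulates data under the generative model, runs the
corresponding analysis stage from scratch and measures how well the
planted truth is recovered.  They back both the acceptance checks and
the reproduction script, and are handy as worked examples of the full
pipeline.

Problem sizes mirror the simulated study design: 16 + 16 chromosomes
of 200 x 500-bp bins with two hybrid chromosome pairs, copy numbers
1-6 at 50 reads per bin per copy, ~500 orthologue pairs, three
replicates per condition, NB dispersion 0.1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import dosage as dos
from . import expression, karyotype
from .consolidate import cn_ratio_correlation, consolidate_counts, cross_strain_de, total_gene_cn
from .simulate import (
    SimConfig,
    default_design,
    simulate_counts,
    simulate_coverage,
    simulate_hybrid_genome,
    simulate_strain,
)
from .types import DosageRegression, SampleInfo


def karyotype_recovery(
    n_genomes: int = 10, seed: int = 0, depth_per_copy: float = 50.0
) -> dict[str, float]:
    """Karyotype and breakpoint recovery over simulated genomes.

    Simulates ``n_genomes`` hybrids (16+16 chromosomes, 2 hybrid
    pairs, CN 1-6), calls karyotypes from coverage alone and compares
    per-chromosome modal copy numbers and breakpoint positions with
    the planted truth.  Positions count as recovered within +/- 2 bins.
    """
    cn_hits = cn_total = 0
    bp_hits = bp_total = 0
    for i in range(n_genomes):
        cfg = SimConfig(depth_per_copy=depth_per_copy, seed=seed * 1009 + i)
        genes, truth = simulate_hybrid_genome(cfg)
        tracks = simulate_coverage(truth, cfg)
        k = karyotype.call_karyotype(tracks)
        for chrom in truth.segments:
            cn_total += 1
            cn_hits += k.modal_cn(chrom) == truth.modal_cn(chrom)
        detected = karyotype.detect_breakpoints(k, genes)
        det_by_chrom: dict[str, list[int]] = {}
        for b in detected:
            det_by_chrom.setdefault(b.chrom, []).append(b.pos)
        bw = cfg.bin_width
        for tb in truth.breakpoints:
            for chrom in (tb.chrom_sc, tb.chrom_se):
                bp_total += 1
                hits = [
                    pos for pos in det_by_chrom.get(chrom, [])
                    if abs(pos // bw - tb.pos // bw) <= 2
                ]
                bp_hits += bool(hits)
    return {
        "cn_accuracy": cn_hits / cn_total,
        "breakpoint_recovery": bp_hits / bp_total if bp_total else float("nan"),
        "n_chromosomes": cn_total,
        "n_breakpoints": bp_total,
    }


def _pipeline_pairs(cfg: SimConfig, condition: str = "day2") -> pd.DataFrame:
    s = simulate_strain(cfg)
    k = karyotype.call_karyotype(s.coverage)
    genes = karyotype.assign_gene_cn(s.genes, k)
    pairs, _ = dos.pair_orthologs(genes)
    return dos.allele_log2fc_table(s.counts, pairs, "sim", condition)


def dosage_recovery(seed: int = 0, condition: str = "day2") -> DosageRegression:
    """Within-strain dosage-expression correlation under pure dosage.

    512 orthologue pairs, copy numbers from coverage, allele log-ratios
    from the NB contrast, regression over >= 5 ratio categories.  Under
    the generative model the true slope is 1 and the intercept 0.
    """
    cfg = SimConfig(
        genes_per_chromosome=32, nb_dispersion=0.1, allele_bias=1.0,
        seed=seed * 2003 + 17,
    )
    tab = _pipeline_pairs(cfg, condition)
    return dos.dosage_correlation(tab)


def cross_strain_recovery(seed: int = 0, condition: str = "day2") -> DosageRegression:
    """Cross-strain total-CN dosage correlation on consolidated counts.

    Two strains with independently drawn (divergent) karyotypes share
    per-gene expression parameters; their consolidated transcriptomes
    are compared and the log2FC regressed on the total copy-number
    log-ratio.  True slope 1.
    """
    shared_expr = seed * 4001 + 7
    out = {}
    for strain, sub_seed in (("A", 1), ("B", 2)):
        cfg = SimConfig(
            genes_per_chromosome=32, nb_dispersion=0.1,
            seed=seed * 4001 + sub_seed * 101, expression_seed=shared_expr,
        )
        s = simulate_strain(cfg, default_design(cfg, strain=strain))
        k = karyotype.call_karyotype(s.coverage)
        genes = karyotype.assign_gene_cn(s.genes, k)
        pairs, unmatched = dos.pair_orthologs(genes)
        out[strain] = (
            consolidate_counts(s.counts, pairs),
            total_gene_cn(pairs, unmatched),
        )
    de, _ = cross_strain_de(out["A"][0], out["B"][0], condition)
    return cn_ratio_correlation(de, out["A"][1], out["B"][1])


def _flat_expression_config(seed: int) -> SimConfig:
    # ~5000 genes, uniform CN, no condition response, two conditions
    return SimConfig(
        genes_per_chromosome=157,
        cn_range=(2, 2),
        n_hybrid_chromosomes=0,
        condition_effect_sd=0.0,
        conditions=("a", "b"),
        nb_dispersion=0.1,
        seed=seed,
    )


def nb_null_calibration(seed: int = 0) -> dict[str, float]:
    """Empirical type-I error of the NB Wald test at nominal 0.05.

    ~5000 genes, 3 vs 3 replicates, dispersion 0.1, no true effects.
    """
    cfg = _flat_expression_config(seed * 3001 + 1)
    genes, truth = simulate_hybrid_genome(cfg)
    design = [SampleInfo("s", c, r) for c in cfg.conditions for r in (1, 2, 3)]
    cm = simulate_counts(genes, truth, design, cfg)
    res = expression.nb_wald(cm, ("b", "a"))
    p = res["p"].dropna()
    return {"type1_error": float((p < 0.05).mean()), "n_genes": int(len(p))}


def nb_planted_recovery(seed: int = 0, planted_frac: float = 0.1) -> dict[str, float]:
    """Median estimated log2FC for genes carrying a planted 2-fold change.

    Half the planted genes go up 2-fold, half down 2-fold (a one-sided
    shift would leak into the size factors, which cannot distinguish a
    global fold change from sequencing depth); the rest stay null.
    Reported medians are over the up- and down-planted genes.
    """
    cfg = _flat_expression_config(seed * 3001 + 2)
    genes, truth = simulate_hybrid_genome(cfg)
    base_ids = sorted({g.base_id for g in genes})
    rng = np.random.default_rng(seed * 3001 + 3)
    n_planted = int(round(planted_frac * len(base_ids)))
    chosen = rng.choice(base_ids, size=n_planted, replace=False).tolist()
    up, down = set(chosen[: n_planted // 2]), set(chosen[n_planted // 2 :])
    eff = pd.DataFrame(1.0, index=base_ids, columns=list(cfg.conditions))
    eff.loc[sorted(up), "b"] = 2.0
    eff.loc[sorted(down), "b"] = 0.5

    design = [SampleInfo("s", c, r) for c in cfg.conditions for r in (1, 2, 3)]
    cm = simulate_counts(genes, truth, design, cfg, condition_effects=eff)
    res = expression.nb_wald(cm, ("b", "a"))
    lfc = res["log2fc"].to_numpy()
    up_mask = np.array([g.base_id in up for g in genes])
    down_mask = np.array([g.base_id in down for g in genes])
    return {
        "median_log2fc": float(np.nanmedian(lfc[up_mask])),
        "median_log2fc_down": float(np.nanmedian(lfc[down_mask])),
        "n_planted_alleles": int(up_mask.sum() + down_mask.sum()),
    }
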