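"""Synthetic aneuploid hybrid genomes, coverage and RNA-seq counts.

The generator emulates the statistical structure of an interspecies
lager-yeast hybrid as seen by a short-read pipeline mapped to the
combined parental reference:

* two divergent sub-genomes (``Sc``/``Se``) with one-to-one orthologue
  pairs laid out on homeologous chromosomes;
* integer chromosome copy numbers drawn per chromosome (aneuploidy);
* hybrid chromosomes carrying a single intragenic recombination
  breakpoint, visible as a copy-number step on both parental tracks;
* binned WGS coverage that is Poisson around copy number x depth;
* RNA-seq counts that are negative-binomial with expectation
  proportional to allele copy number times a condition-dependent
  per-gene expression level.

All randomness flows from a single master seed; each stage draws from
its own derived substream so adding a stage never perturbs another's
draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as adio
from .types import (
    ConfigError,
    CountMatrix,
    CoverageTrack,
    GeneRecord,
    SampleInfo,
)

_STAGES = {"genome": 11, "coverage": 23, "counts": 37, "expression": 53, "conditions": 71}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STAGES[stage]])


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic hybrid.

    ``depth_per_copy`` is the expected WGS reads per 500-bp bin
    contributed by one chromosome copy.  ``base_expression_log_mean`` /
    ``_log_sd`` parameterize the log-normal per-gene expression level
    (natural-log scale).  ``condition_effect_sd`` is the standard
    deviation, on the log2 scale, of per-gene condition effects.
    ``allele_bias`` is the Se/Sc expression ratio per gene copy (1.0
    means pure dosage).  ``nb_dispersion`` is the NB over-dispersion
    alpha in Var = mu + alpha * mu^2; 0 degenerates to Poisson.
    ``expression_seed`` defaults to ``seed``; give two strain configs
    the same value to share per-gene expression parameters (so that
    between-strain expression differences come from karyotype alone).
    """

    n_chromosomes_per_subgenome: int = 16
    genes_per_chromosome: int = 20
    chrom_length: int = 100_000
    bin_width: int = 500
    cn_range: tuple[int, int] = (1, 6)
    n_hybrid_chromosomes: int = 2
    depth_per_copy: float = 50.0
    base_expression_log_mean: float = 4.0
    base_expression_log_sd: float = 1.0
    condition_effect_sd: float = 1.0
    nb_dispersion: float = 0.1
    allele_bias: float = 1.0
    sample_scale_sd: float = 0.1
    conditions: tuple[str, ...] = ("minimal", "day2", "day4")
    seed: int = 0
    expression_seed: int | None = None

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ConfigError("bin_width must be > 0")
        if self.n_chromosomes_per_subgenome < 1:
            raise ConfigError("n_chromosomes_per_subgenome must be >= 1")
        if self.genes_per_chromosome < 1:
            raise ConfigError("genes_per_chromosome must be >= 1")
        lo, hi = self.cn_range
        if not (0 <= lo <= hi <= 8):
            raise ConfigError("cn_range must satisfy 0 <= lo <= hi <= 8")
        if not 0 <= self.n_hybrid_chromosomes <= self.n_chromosomes_per_subgenome:
            raise ConfigError(
                "n_hybrid_chromosomes must be between 0 and n_chromosomes_per_subgenome"
            )
        if self.depth_per_copy < 0:
            raise ConfigError("depth_per_copy must be >= 0")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be >= 0")
        if self.allele_bias <= 0:
            raise ConfigError("allele_bias must be > 0")
        if self.sample_scale_sd < 0:
            raise ConfigError("sample_scale_sd must be >= 0")
        if self.chrom_length < 2 * self.bin_width:
            raise ConfigError("chrom_length must cover at least two bins")

    @property
    def effective_expression_seed(self) -> int:
        return self.seed if self.expression_seed is None else self.expression_seed


@dataclass
class TruthBreakpoint:
    """A planted recombination breakpoint (one per hybrid chromosome pair)."""

    chrom_index: int
    chrom_sc: str
    chrom_se: str
    pos: int
    base_id: str
    orientation: str  # "Sc|Se": the hybrid molecule is Sc left of pos


@dataclass
class SimTruth:
    """Ground truth of one simulated strain.

    ``segments`` maps chromosome id to ``(start_bp, end_bp, cn)`` runs;
    ``gene_cn`` maps allele gene id to its true copy number;
    ``base_expression`` maps base id to the per-copy expression level.
    """

    segments: dict[str, list[tuple[int, int, int]]]
    breakpoints: list[TruthBreakpoint]
    gene_cn: dict[str, int]
    base_expression: dict[str, float]
    chrom_length: int
    bin_width: int

    def modal_cn(self, chrom: str) -> int:
        weights: dict[int, int] = {}
        for start, end, cn in self.segments[chrom]:
            weights[cn] = weights.get(cn, 0) + (end - start)
        return max(sorted(weights), key=lambda cn: weights[cn])

    def total_chromosome_cn(self) -> int:
        return sum(self.modal_cn(c) for c in self.segments)


def _chrom_id(subgenome: str, index: int) -> str:
    return f"{subgenome}{index + 1:02d}"


def _layout_genes(config: SimConfig) -> list[GeneRecord]:
    """Deterministic gene layout: equal slots, gene = central 60% of slot."""
    genes = []
    n, g = config.n_chromosomes_per_subgenome, config.genes_per_chromosome
    slot = config.chrom_length / g
    for ci in range(n):
        for gi in range(g):
            start = int(gi * slot + 0.2 * slot)
            end = int(gi * slot + 0.8 * slot)
            base = f"g{ci + 1:02d}_{gi + 1:03d}"
            for sub in ("Sc", "Se"):
                genes.append(
                    GeneRecord(
                        gene_id=f"{base}_{sub}",
                        base_id=base,
                        subgenome=sub,
                        chrom=_chrom_id(sub, ci),
                        start=start,
                        end=end,
                    )
                )
    return genes


def simulate_hybrid_genome(config: SimConfig) -> tuple[list[GeneRecord], SimTruth]:
    """Draw a karyotype with hybrid chromosomes and per-gene truth.

    Each chromosome pair gets integer copy numbers from ``cn_range``.
    ``n_hybrid_chromosomes`` chromosome indices additionally carry one
    recombination breakpoint, placed inside the body of a gene whose
    midpoint lies in the middle 80% of the chromosome; on those indices
    both parental coverage tracks change copy number at the breakpoint
    (the two sides are redrawn to differ whenever ``cn_range`` allows).
    """
    rng = _rng(config.seed, "genome")
    genes = _layout_genes(config)
    n = config.n_chromosomes_per_subgenome
    lo, hi = config.cn_range
    L = config.chrom_length

    hybrid_idx = sorted(
        int(i) for i in rng.choice(n, size=config.n_hybrid_chromosomes, replace=False)
    )

    # choose breakpoint genes first so segment draws stay aligned
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    breakpoints: list[TruthBreakpoint] = []
    for ci in hybrid_idx:
        sc_genes = by_chrom[_chrom_id("Sc", ci)]
        eligible = [g for g in sc_genes if 0.1 * L <= g.midpoint <= 0.9 * L]
        gene = eligible[int(rng.integers(len(eligible)))]
        pos = int(rng.integers(gene.start + 1, gene.end - 1))
        orientation = "Sc|Se" if rng.random() < 0.5 else "Se|Sc"
        breakpoints.append(
            TruthBreakpoint(
                chrom_index=ci,
                chrom_sc=_chrom_id("Sc", ci),
                chrom_se=_chrom_id("Se", ci),
                pos=pos,
                base_id=gene.base_id,
                orientation=orientation,
            )
        )
    bp_by_index = {b.chrom_index: b for b in breakpoints}

    def draw_cn() -> int:
        return int(rng.integers(lo, hi + 1))

    segments: dict[str, list[tuple[int, int, int]]] = {}
    for ci in range(n):
        for sub in ("Sc", "Se"):
            chrom = _chrom_id(sub, ci)
            if ci in bp_by_index:
                pos = bp_by_index[ci].pos
                left = draw_cn()
                right = draw_cn()
                if lo < hi:
                    while right == left:
                        right = draw_cn()
                segments[chrom] = [(0, pos, left), (pos, L, right)]
            else:
                segments[chrom] = [(0, L, draw_cn())]

    gene_cn: dict[str, int] = {}
    for g in genes:
        for start, end, cn in segments[g.chrom]:
            if start <= g.midpoint < end:
                gene_cn[g.gene_id] = cn
                break

    rng_expr = _rng(config.effective_expression_seed, "expression")
    base_ids = sorted({g.base_id for g in genes})
    levels = rng_expr.lognormal(
        mean=config.base_expression_log_mean,
        sigma=config.base_expression_log_sd,
        size=len(base_ids),
    )
    base_expression = dict(zip(base_ids, levels.astype(float)))

    truth = SimTruth(
        segments=segments,
        breakpoints=breakpoints,
        gene_cn=gene_cn,
        base_expression=base_expression,
        chrom_length=L,
        bin_width=config.bin_width,
    )
    return genes, truth


def simulate_coverage(truth: SimTruth, config: SimConfig) -> dict[str, CoverageTrack]:
    """Binned WGS coverage: Poisson(copy number x depth_per_copy) per bin.

    The library size recorded on every track is the realized total read
    count over all chromosomes, as a mapper would report it.
    """
    rng = _rng(config.seed, "coverage")
    bw = config.bin_width
    n_bins = truth.chrom_length // bw
    starts = np.arange(n_bins, dtype=np.int64) * bw
    mids = starts + bw // 2

    tracks: dict[str, CoverageTrack] = {}
    for chrom in sorted(truth.segments):
        cn = np.zeros(n_bins)
        for seg_start, seg_end, seg_cn in truth.segments[chrom]:
            mask = (mids >= seg_start) & (mids < seg_end)
            cn[mask] = seg_cn
        counts = rng.poisson(cn * config.depth_per_copy).astype(float)
        tracks[chrom] = CoverageTrack(
            chrom=chrom, starts=starts.copy(), counts=counts,
            library_size=0.0, bin_width=bw,
        )
    total = float(sum(t.counts.sum() for t in tracks.values()))
    for t in tracks.values():
        t.library_size = total
    return tracks


def default_design(
    config: SimConfig, strain: str = "sim", n_replicates: int = 3
) -> list[SampleInfo]:
    return [
        SampleInfo(strain=strain, condition=cond, replicate=r + 1)
        for cond in config.conditions
        for r in range(n_replicates)
    ]


def condition_effect_matrix(config: SimConfig, base_ids: list[str]) -> pd.DataFrame:
    """Per-gene multiplicative condition effects, 2^N(0, condition_effect_sd).

    Drawn from the expression substream so that two strains sharing
    ``expression_seed`` respond identically to conditions.
    """
    rng = _rng(config.effective_expression_seed, "conditions")
    base_ids = sorted(base_ids)
    if config.condition_effect_sd == 0:
        eff = np.ones((len(base_ids), len(config.conditions)))
    else:
        eff = 2.0 ** rng.normal(
            0.0, config.condition_effect_sd, size=(len(base_ids), len(config.conditions))
        )
    return pd.DataFrame(eff, index=base_ids, columns=list(config.conditions))


def simulate_counts(
    genes: list[GeneRecord],
    truth: SimTruth,
    design: list[SampleInfo],
    config: SimConfig,
    condition_effects: pd.DataFrame | None = None,
) -> CountMatrix:
    """Draw the RNA-seq count matrix under the dosage model.

    The expected count for gene *g* (allele *a*) in sample *j* is
    ``s_j * b_g * cn_{g,a} * bias_a * f_{g, cond(j)}`` with NB
    dispersion ``nb_dispersion`` (Poisson when 0).  ``bias_a`` is
    ``allele_bias`` for Se alleles and 1 for Sc.  Pass
    ``condition_effects`` (base id x condition, multiplicative) to
    override the random condition response, e.g. to plant exact fold
    changes.
    """
    if not design:
        raise ConfigError("design must contain at least one sample")
    for s in design:
        if s.condition not in config.conditions:
            raise ConfigError(
                f"sample {s.name}: unknown condition {s.condition!r}; "
                f"declared conditions are {config.conditions}"
            )
    base_ids = sorted({g.base_id for g in genes})
    if condition_effects is None:
        condition_effects = condition_effect_matrix(config, base_ids)

    rng = _rng(config.seed, "counts")
    scales = rng.lognormal(mean=0.0, sigma=config.sample_scale_sd, size=len(design))

    gene_ids = [g.gene_id for g in genes]
    b = np.array([truth.base_expression[g.base_id] for g in genes])
    cn = np.array([truth.gene_cn[g.gene_id] for g in genes], dtype=float)
    bias = np.array([config.allele_bias if g.subgenome == "Se" else 1.0 for g in genes])
    f = np.stack(
        [condition_effects.loc[[g.base_id for g in genes], s.condition].to_numpy() for s in design],
        axis=1,
    )
    mu = (b * cn * bias)[:, None] * f * scales[None, :]

    alpha = config.nb_dispersion
    if alpha == 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / alpha
        p = r / (r + mu)
        counts = rng.negative_binomial(r, p)

    names = [s.name for s in design]
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=names)
    samples_df = pd.DataFrame(
        {
            "strain": [s.strain for s in design],
            "condition": [s.condition for s in design],
            "replicate": [s.replicate for s in design],
            "scale": scales,
        },
        index=pd.Index(names, name="sample"),
    )
    return CountMatrix(counts_df, samples_df)


@dataclass
class SimulatedStrain:
    """Bundle of everything simulated for one strain."""

    config: SimConfig
    genes: list[GeneRecord]
    truth: SimTruth
    coverage: dict[str, CoverageTrack]
    counts: CountMatrix


def simulate_strain(
    config: SimConfig,
    design: list[SampleInfo] | None = None,
    condition_effects: pd.DataFrame | None = None,
) -> SimulatedStrain:
    """Run genome, coverage and counts stages end to end."""
    genes, truth = simulate_hybrid_genome(config)
    coverage = simulate_coverage(truth, config)
    if design is None:
        design = default_design(config)
    counts = simulate_counts(genes, truth, design, config, condition_effects)
    return SimulatedStrain(config, genes, truth, coverage, counts)


# ---------------------------------------------------------------------------
# fixtures on disk

def _truth_to_json(truth: SimTruth) -> dict:
    return {
        "segments": {c: [list(s) for s in segs] for c, segs in truth.segments.items()},
        "breakpoints": [
            {
                "chrom_index": b.chrom_index,
                "chrom_sc": b.chrom_sc,
                "chrom_se": b.chrom_se,
                "pos": b.pos,
                "base_id": b.base_id,
                "orientation": b.orientation,
            }
            for b in truth.breakpoints
        ],
        "gene_cn": truth.gene_cn,
        "base_expression": truth.base_expression,
        "chrom_length": truth.chrom_length,
        "bin_width": truth.bin_width,
    }


def _truth_from_json(obj: dict) -> SimTruth:
    return SimTruth(
        segments={
            c: [tuple(int(x) for x in s) for s in segs] for c, segs in obj["segments"].items()
        },
        breakpoints=[TruthBreakpoint(**b) for b in obj["breakpoints"]],
        gene_cn={k: int(v) for k, v in obj["gene_cn"].items()},
        base_expression={k: float(v) for k, v in obj["base_expression"].items()},
        chrom_length=int(obj["chrom_length"]),
        bin_width=int(obj["bin_width"]),
    )


def write_fixture(
    outdir: str | Path,
    genes: list[GeneRecord],
    truth: SimTruth,
    coverage: dict[str, CoverageTrack],
    counts: CountMatrix,
) -> dict[str, Path]:
    """Write a complete strain fixture as plain-text files.

    Emits ``genes.bed``, ``orthologs.tsv``, ``coverage.bedGraph`` (+
    JSON sidecar), ``counts.tsv``, ``samples.tsv`` and ``truth.json``.
    Everything round-trips through :func:`read_fixture`.
    """
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["genes"] = adio.write_genes_bed(outdir / "genes.bed", genes)
    paths["orthologs"] = adio.write_ortholog_map(outdir / "orthologs.tsv", genes)
    paths["coverage"], paths["coverage_meta"] = adio.write_coverage_bedgraph(
        outdir / "coverage.bedGraph", coverage
    )
    paths["counts"], paths["samples"] = adio.write_count_matrix(
        outdir / "counts.tsv", outdir / "samples.tsv", counts
    )
    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(_truth_to_json(truth), indent=1))
    paths["truth"] = truth_path
    return paths


def read_fixture(outdir: str | Path) -> SimulatedStrain:
    """Read a fixture written by :func:`write_fixture` (config not restored)."""
    import json

    outdir = Path(outdir)
    genes = adio.read_genes(outdir / "genes.bed", outdir / "orthologs.tsv")
    coverage = adio.read_coverage_bedgraph(outdir / "coverage.bedGraph")
    counts = adio.read_count_matrix(outdir / "counts.tsv", outdir / "samples.tsv")
    truth = _truth_from_json(json.loads((outdir / "truth.json").read_text()))
    return SimulatedStrain(None, genes, truth, coverage, counts)
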