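"""Shared domain containers.

The analysis revolves around a small number of objects: annotated genes
carrying a sub-genome label (``Sc`` for the *S. cerevisiae*-derived
sub-genome, ``Se`` for *S. eubayanus*), binned whole-genome-sequencing
coverage tracks, piecewise-constant copy-number segmentations
(karyotypes), and genes x samples count matrices with sample metadata.

Tabular results (differential expression, orthologue pairs, enrichment)
are plain :class:`pandas.DataFrame` objects with documented columns
rather than bespoke classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SUBGENOMES = ("Sc", "Se")


class ConfigError(ValueError):
    """Raised when a simulation or analysis configuration is invalid."""


class AllodosageError(RuntimeError):
    """Raised for analysis-level failures (degenerate inputs, no signal)."""


@dataclass
class GeneRecord:
    """A gene (one allele) with its sub-genome label and coordinates.

    ``base_id`` names the orthologue group: the Sc and Se alleles of one
    ancestral gene share a base id.  Coordinates are 0-based half-open.
    ``cn`` is filled in by :func:`allodosage.karyotype.assign_gene_cn`.
    """

    gene_id: str
    base_id: str
    subgenome: str
    chrom: str
    start: int
    end: int
    cn: int | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")
        if self.subgenome not in SUBGENOMES:
            raise ValueError(f"gene {self.gene_id}: unknown sub-genome {self.subgenome!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class CoverageTrack:
    """Binned read-depth over one chromosome.

    ``starts`` are bin start positions (bp, 0-based, fixed width),
    ``counts`` raw reads per bin.  ``library_size`` is the total number
    of mapped reads in the library the track came from; it may exceed
    the sum of counts (a track covers one chromosome of many).
    """

    chrom: str
    starts: np.ndarray
    counts: np.ndarray
    library_size: float
    bin_width: int = 500

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.starts.shape != self.counts.shape:
            raise ValueError("starts and counts must have the same length")
        if np.any(np.diff(self.starts) <= 0):
            raise ValueError(f"{self.chrom}: bins must be sorted and non-overlapping")
        if np.any(self.counts < 0):
            raise ValueError(f"{self.chrom}: negative bin counts")

    @property
    def n_bins(self) -> int:
        return int(self.starts.size)


@dataclass
class Segment:
    """A run of bins with (approximately) constant coverage.

    Bin indices are half-open: the segment covers bins
    ``start_bin .. end_bin - 1``.  ``mean`` is the mean normalized
    coverage; ``cn`` the integer copy number once called.
    """

    chrom: str
    start_bin: int
    end_bin: int
    mean: float
    cn: int | None = None

    def __post_init__(self) -> None:
        if self.end_bin <= self.start_bin:
            raise ValueError("segment end_bin must be > start_bin")

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin


@dataclass
class Breakpoint:
    """A copy-number change-point inside a chromosome."""

    chrom: str
    pos: int
    left_cn: int | None = None
    right_cn: int | None = None
    gene_id: str | None = None
    left_subgenome: str | None = None
    right_subgenome: str | None = None


@dataclass
class Karyotype:
    """Per-chromosome copy-number segmentation of one strain.

    ``segments`` maps chromosome id to its contiguous list of called
    :class:`Segment` objects; ``haploid_unit`` is the normalized
    coverage contributed by a single chromosome copy.
    """

    segments: dict[str, list[Segment]]
    haploid_unit: float
    bin_width: int = 500

    def modal_cn(self, chrom: str) -> int:
        """Length-weighted modal copy number of one chromosome.

        Ties are broken toward the lower copy number.
        """
        segs = self.segments[chrom]
        weights: dict[int, int] = {}
        for s in segs:
            if s.cn is None:
                raise AllodosageError(f"{chrom}: segments not yet called")
            weights[s.cn] = weights.get(s.cn, 0) + s.n_bins
        best = max(sorted(weights), key=lambda cn: weights[cn])
        return best

    def chromosomes(self) -> list[str]:
        return list(self.segments)


@dataclass(frozen=True)
class SampleInfo:
    """Metadata for one RNA-seq library."""

    strain: str
    condition: str
    replicate: int

    @property
    def name(self) -> str:
        return f"{self.strain}_{self.condition}_r{self.replicate}"


@dataclass
class CountMatrix:
    """Raw RNA-seq counts (genes x samples) plus sample metadata.

    ``counts``: DataFrame indexed by gene id, one column per sample.
    ``samples``: DataFrame indexed by sample name with at least
    ``strain``, ``condition`` and ``replicate`` columns.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        missing = [c for c in ("strain", "condition", "replicate") if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample metadata missing columns: {missing}")
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("count columns and sample metadata rows do not match")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    def subset_samples(self, mask: pd.Series) -> "CountMatrix":
        keep = self.samples.index[np.asarray(mask, dtype=bool)]
        return CountMatrix(self.counts[keep].copy(), self.samples.loc[keep].copy())

    def select(self, strain: str | None = None, condition: str | None = None) -> "CountMatrix":
        mask = pd.Series(True, index=self.samples.index)
        if strain is not None:
            mask &= self.samples["strain"] == strain
        if condition is not None:
            mask &= self.samples["condition"] == condition
        return self.subset_samples(mask)

    @property
    def n_genes(self) -> int:
        return int(self.counts.shape[0])

    @property
    def n_samples(self) -> int:
        return int(self.counts.shape[1])


@dataclass
class DosageRegression:
    """Result of regressing expression log-ratios on copy-number log-ratios.

    The primary fit is over ratio-category means weighted by category
    size (mirroring how per-category means are displayed); an unbinned
    per-gene fit is reported alongside.
    """

    slope: float
    intercept: float
    r2: float
    p: float
    n_pairs: int
    n_categories: int
    category_table: pd.DataFrame = field(repr=False, default=None)
    unbinned_slope: float = float("nan")
    unbinned_intercept: float = float("nan")
    unbinned_r2: float = float("nan")
    unbinned_p: float = float("nan")


@dataclass
class RepresentationTest:
    """Chi-squared goodness-of-fit for Sc/Se membership of a gene pool."""

    label: str
    n_sc: int
    n_se: int
    p_sc: float
    p_se: float
    chi2: float
    p: float
    stars: str
    warning: str | None = None
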