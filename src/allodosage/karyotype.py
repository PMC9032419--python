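"""Copy-number karyotyping from binned WGS coverage.

The pipeline mirrors how aneuploid hybrid yeast karyotypes are read off
a combined parental reference: per-bin read counts (reads per 500 bp)
are normalized by library size, chromosomes are segmented at mean
shifts (hybrid chromosomes show up as an internal copy-number step), a
genome-wide haploid coverage unit is estimated, segment means are
rounded to integer copy numbers, and genes inherit the copy number of
the segment containing their midpoint.
"""

from __future__ import annotations

import warnings

import numpy as np

from .types import (
    AllodosageError,
    Breakpoint,
    CoverageTrack,
    GeneRecord,
    Karyotype,
    Segment,
)


def normalize_coverage(track: CoverageTrack) -> np.ndarray:
    """Reads per bin per million mapped reads.

    ``value_i = raw_i / library_size * 1e6``.  Linear and positively
    homogeneous in the raw counts; bin order is preserved.
    """
    if track.library_size <= 0:
        raise AllodosageError(
            f"{track.chrom}: library_size must be > 0 to normalize coverage"
        )
    return track.counts / track.library_size * 1e6


def _sse_split_gain(values: np.ndarray) -> tuple[int, float]:
    """Best single change-point by SSE reduction, via cumulative sums.

    Returns (split index k, gain); splitting at k puts bins [0, k) left
    and [k, n) right.  Gain is total SSE minus the two children's SSE.
    """
    n = values.size
    cs = np.cumsum(values)
    css = np.cumsum(values**2)
    total_sse = css[-1] - cs[-1] ** 2 / n
    ks = np.arange(1, n)
    left_n = ks
    right_n = n - ks
    left_sum = cs[ks - 1]
    right_sum = cs[-1] - left_sum
    left_sse = css[ks - 1] - left_sum**2 / left_n
    right_sse = (css[-1] - css[ks - 1]) - right_sum**2 / right_n
    gains = total_sse - left_sse - right_sse
    best = int(np.argmax(gains))
    return int(ks[best]), float(gains[best])


def _noise_variance(values: np.ndarray) -> float:
    """Robust noise variance from first differences (MAD based).

    Differencing removes the piecewise-constant signal except at the
    few change-points, which the median absorbs.
    """
    d = np.diff(values)
    if d.size == 0:
        return 0.0
    mad = np.median(np.abs(d - np.median(d)))
    sigma = 1.4826 * mad / np.sqrt(2.0)
    return float(sigma**2)


def segment_bins(
    values: np.ndarray,
    chrom: str = "chr",
    min_seg_bins: int = 20,
    penalty: float = 5.0,
) -> list[Segment]:
    """Recursive binary segmentation on mean shifts.

    A candidate split is kept iff it reduces the within-segment SSE by
    more than ``penalty * log(n_bins) * sigma^2`` (``sigma^2`` a robust
    noise-variance estimate for the chromosome, ``n_bins`` the length
    of the segment being split) and both children have at least
    ``min_seg_bins`` bins.  Always returns >= 1 contiguous segment.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < min_seg_bins:
        warnings.warn(
            f"{chrom}: only {n} bins (< min_seg_bins={min_seg_bins}); "
            "returning a single segment"
        )
        return [Segment(chrom, 0, n, float(values.mean()))]

    sigma2 = _noise_variance(values)
    boundaries = [0, n]

    def recurse(start: int, end: int) -> None:
        length = end - start
        if length < 2 * min_seg_bins:
            return
        sub = values[start:end]
        k, gain = _sse_split_gain(sub)
        if k < min_seg_bins or length - k < min_seg_bins:
            # best split violates the minimum; search admissible range
            cs = np.cumsum(sub)
            css = np.cumsum(sub**2)
            total_sse = css[-1] - cs[-1] ** 2 / length
            ks = np.arange(min_seg_bins, length - min_seg_bins + 1)
            if ks.size == 0:
                return
            left_sum = cs[ks - 1]
            right_sum = cs[-1] - left_sum
            left_sse = css[ks - 1] - left_sum**2 / ks
            right_sse = (css[-1] - css[ks - 1]) - right_sum**2 / (length - ks)
            gains = total_sse - left_sse - right_sse
            i = int(np.argmax(gains))
            k, gain = int(ks[i]), float(gains[i])
        if gain > penalty * np.log(length) * sigma2 and sigma2 >= 0:
            boundaries.append(start + k)
            recurse(start, start + k)
            recurse(start + k, end)

    if sigma2 > 0:
        recurse(0, n)
    boundaries = sorted(set(boundaries))
    return [
        Segment(chrom, b0, b1, float(values[b0:b1].mean()))
        for b0, b1 in zip(boundaries[:-1], boundaries[1:])
    ]


def _round_half_away(x: np.ndarray | float) -> np.ndarray | float:
    """Round half away from zero (np.round rounds half to even)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def estimate_haploid_unit(segments: list[Segment], max_cn: int = 8) -> float:
    """Estimate the normalized coverage contributed by one chromosome copy.

    The candidate grid spans the admissible range: from
    ``max_mean / (max_cn + 0.5)`` (below which some copy number would
    exceed ``max_cn``) up to the largest segment mean (above which the
    deepest segment would round to CN 0), densified with the exact
    ``mean_s / k`` ratios.  The unit minimizes the length-weighted
    squared distance of ``mean_s / u`` to the nearest integer; among
    candidates within 1% of the optimal cost the largest unit wins,
    which resolves the u -> u/2 degeneracy toward the parsimonious
    (smaller copy number) solution.
    """
    means = np.array([s.mean for s in segments], dtype=float)
    lens = np.array([s.n_bins for s in segments], dtype=float)
    pos = means > 0
    if not pos.any():
        raise AllodosageError("no coverage signal: all segment means are zero")
    means_p, lens_p = means[pos], lens[pos]

    lo = means_p.max() / (max_cn + 0.5)
    hi = means_p.max()
    seeds = np.concatenate([means_p / k for k in range(1, max_cn + 1)])
    grid = np.linspace(lo, hi, 4001)
    candidates = np.unique(np.concatenate([seeds, grid]))
    candidates = candidates[(candidates >= lo) & (candidates <= hi)]
    if candidates.size == 0:
        raise AllodosageError("no admissible haploid unit candidates")

    ratios = means_p[:, None] / candidates[None, :]
    frac = ratios - _round_half_away(ratios)
    costs = (lens_p[:, None] * frac**2).sum(axis=0)
    best = costs.min()
    tol = best * 1.01 + 1e-12 * lens_p.sum()
    admissible = candidates[costs <= tol]
    return float(admissible.max())


def call_integer_cn(
    segments: list[Segment], unit: float, max_cn: int = 8
) -> list[Segment]:
    """Round ``mean / unit`` half-away-from-zero to integer CN, clip to [0, max_cn]."""
    if unit <= 0:
        raise AllodosageError("haploid unit must be > 0")
    for s in segments:
        cn = int(_round_half_away(s.mean / unit))
        if cn > max_cn:
            warnings.warn(
                f"{s.chrom}: called CN {cn} exceeds max_cn={max_cn}; clipping"
            )
            cn = max_cn
        s.cn = max(0, cn)
    return segments


def call_karyotype(
    tracks: dict[str, CoverageTrack],
    min_seg_bins: int = 20,
    penalty: float = 5.0,
    max_cn: int = 8,
) -> Karyotype:
    """Normalize, segment, estimate the haploid unit and call integer CNs."""
    if not tracks:
        raise AllodosageError("no coverage tracks given")
    bin_widths = {t.bin_width for t in tracks.values()}
    if len(bin_widths) != 1:
        raise AllodosageError("tracks must share one bin width")
    segments: dict[str, list[Segment]] = {}
    all_segs: list[Segment] = []
    for chrom in sorted(tracks):
        values = normalize_coverage(tracks[chrom])
        segs = segment_bins(values, chrom=chrom, min_seg_bins=min_seg_bins, penalty=penalty)
        segments[chrom] = segs
        all_segs.extend(segs)
    unit = estimate_haploid_unit(all_segs, max_cn=max_cn)
    call_integer_cn(all_segs, unit, max_cn=max_cn)
    return Karyotype(segments=segments, haploid_unit=unit, bin_width=bin_widths.pop())


def chromosome_copy_table(karyotype: Karyotype) -> tuple[dict[str, int], int]:
    """Length-weighted modal CN per chromosome and the genome total.

    A hybrid chromosome contributes a single count per copy via its
    modal segment, so totals are well defined in the presence of
    internal breakpoints.
    """
    per_chrom = {c: karyotype.modal_cn(c) for c in karyotype.chromosomes()}
    return per_chrom, int(sum(per_chrom.values()))


def detect_breakpoints(
    karyotype: Karyotype, genes: list[GeneRecord] | None = None
) -> list[Breakpoint]:
    """Copy-number change-points with their containing (or nearest) gene.

    Every internal segment boundary where the called CN changes becomes
    a breakpoint at ``boundary_bin * bin_width``.  If a gene's
    [start, end) spans the position it is reported; otherwise the
    nearest gene by midpoint distance (ties to the lower coordinate).
    """
    bw = karyotype.bin_width
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes or []:
        by_chrom.setdefault(g.chrom, []).append(g)
    for lst in by_chrom.values():
        lst.sort(key=lambda g: g.start)

    out: list[Breakpoint] = []
    for chrom in karyotype.chromosomes():
        segs = karyotype.segments[chrom]
        for left, right in zip(segs[:-1], segs[1:]):
            if left.cn == right.cn:
                continue
            pos = right.start_bin * bw
            gene_id = None
            if chrom in by_chrom:
                containing = [
                    g for g in by_chrom[chrom] if g.start <= pos < g.end
                ]
                if containing:
                    gene_id = min(containing, key=lambda g: g.start).gene_id
                else:
                    gene_id = min(
                        by_chrom[chrom],
                        key=lambda g: (abs(g.midpoint - pos), g.start),
                    ).gene_id
            out.append(
                Breakpoint(
                    chrom=chrom, pos=pos, left_cn=left.cn, right_cn=right.cn,
                    gene_id=gene_id,
                )
            )
    return out


def assign_gene_cn(
    genes: list[GeneRecord], karyotype: Karyotype
) -> list[GeneRecord]:
    """Fill each gene's ``cn`` from the segment containing its midpoint.

    The segment CN on a parental reference track already totals every
    chromosome copy carrying the allele (parental copies plus the
    matching arm of hybrid copies), so no further summation is needed.
    Genes on chromosomes absent from the karyotype get CN 0 with a
    warning.
    """
    missing: set[str] = set()
    bw = karyotype.bin_width
    for g in genes:
        if g.chrom not in karyotype.segments:
            g.cn = 0
            missing.add(g.chrom)
            continue
        mid_bin = g.midpoint // bw
        segs = karyotype.segments[g.chrom]
        g.cn = None
        for s in segs:
            if s.start_bin <= mid_bin < s.end_bin:
                g.cn = s.cn
                break
        if g.cn is None:  # midpoint beyond the last bin: use the last segment
            g.cn = segs[-1].cn
    if missing:
        warnings.warn(
            f"chromosomes absent from karyotype, genes set to CN 0: {sorted(missing)}"
        )
    return genes


def assign_subgenome_hybrid(
    gene: GeneRecord, breakpoints: list[Breakpoint]
) -> str:
    """Sub-genome label for a gene on a hybrid (recombinant) chromosome.

    The label is the sub-genome of the breakpoint side containing the
    gene midpoint; the breakpoint-spanning gene itself takes the side
    holding the larger fraction of its length.  Breakpoints must carry
    ``left_subgenome``/``right_subgenome`` annotations.
    """
    bps = sorted(
        (b for b in breakpoints if b.chrom == gene.chrom), key=lambda b: b.pos
    )
    if not bps:
        return gene.subgenome
    for b in bps:
        if b.left_subgenome is None or b.right_subgenome is None:
            raise AllodosageError(
                f"breakpoint at {b.chrom}:{b.pos} lacks sub-genome annotations"
            )
        if gene.end <= b.pos:
            return b.left_subgenome
        if gene.start < b.pos < gene.end:
            left_frac = (b.pos - gene.start) / (gene.end - gene.start)
            return b.left_subgenome if left_frac > 0.5 else b.right_subgenome
    return bps[-1].right_subgenome
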