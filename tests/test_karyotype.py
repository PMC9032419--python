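"""Karyotyping: normalization, segmentation, CN calling, breakpoints."""

import numpy as np
import pytest

import allodosage as ad
from allodosage.karyotype import (
    _sse_split_gain,
    assign_gene_cn,
    assign_subgenome_hybrid,
    call_integer_cn,
    call_karyotype,
    chromosome_copy_table,
    detect_breakpoints,
    estimate_haploid_unit,
    normalize_coverage,
    segment_bins,
)
from allodosage.types import Breakpoint, CoverageTrack, GeneRecord, Karyotype, Segment


def _track(counts, lib=1e6, chrom="Sc01", bw=500):
    counts = np.asarray(counts, dtype=float)
    starts = np.arange(counts.size) * bw
    return CoverageTrack(chrom=chrom, starts=starts, counts=counts,
                         library_size=lib, bin_width=bw)


class TestNormalize:
    def test_per_million_scaling(self):
        vals = normalize_coverage(_track([100, 200], lib=1e6))
        np.testing.assert_allclose(vals, [100.0, 200.0])

    def test_doubling_library_halves_values(self):
        a = normalize_coverage(_track([50, 80], lib=1e6))
        b = normalize_coverage(_track([50, 80], lib=2e6))
        np.testing.assert_allclose(a, 2 * b)

    def test_zero_bins_stay_zero(self):
        np.testing.assert_array_equal(normalize_coverage(_track([0, 0, 0])), 0.0)

    def test_linearity_and_homogeneity(self, rng):
        raw = rng.poisson(100, size=50).astype(float)
        extra = rng.poisson(40, size=50).astype(float)
        lib = 5e6
        f = lambda c: normalize_coverage(_track(c, lib=lib))
        np.testing.assert_allclose(f(raw + extra), f(raw) + f(extra))
        np.testing.assert_allclose(f(3 * raw), 3 * f(raw))

    def test_nonpositive_library_is_error(self):
        with pytest.raises(ad.AllodosageError):
            normalize_coverage(_track([1, 2], lib=0))


class TestSegmentation:
    def test_flat_profile_single_segment(self, rng):
        values = 300 + rng.normal(0, 10, size=400)
        segs = segment_bins(values)
        assert len(segs) == 1
        assert segs[0].n_bins == 400

    def test_single_step_recovered(self):
        rng = np.random.default_rng(7)
        values = np.concatenate([rng.poisson(300, 200), rng.poisson(100, 200)]).astype(float)
        segs = segment_bins(values)
        assert len(segs) == 2
        assert abs(segs[0].end_bin - 200) <= 2

    def test_two_steps_recovered(self):
        rng = np.random.default_rng(8)
        values = np.concatenate(
            [rng.poisson(100, 150), rng.poisson(300, 150), rng.poisson(150, 150)]
        ).astype(float)
        segs = segment_bins(values)
        assert len(segs) == 3
        assert abs(segs[0].end_bin - 150) <= 2
        assert abs(segs[1].end_bin - 300) <= 2

    def test_too_few_bins_warns_and_returns_one_segment(self):
        with pytest.warns(UserWarning, match="min_seg_bins"):
            segs = segment_bins(np.array([1.0, 2.0, 3.0]), min_seg_bins=20)
        assert len(segs) == 1

    @pytest.mark.parametrize("seed", range(8))
    def test_best_split_matches_exhaustive_enumeration(self, seed):
        """On short profiles the split equals the brute-force SSE argmax."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 31))
        values = rng.normal(0, 1, n) + np.where(np.arange(n) < n // 2, 0, rng.normal(0, 3))

        def sse(v):
            return float(((v - v.mean()) ** 2).sum())

        gains = [sse(values) - sse(values[:k]) - sse(values[k:]) for k in range(1, n)]
        k_oracle = int(np.argmax(gains)) + 1
        k_impl, gain_impl = _sse_split_gain(values)
        assert k_impl == k_oracle
        assert gain_impl == pytest.approx(max(gains))

    def test_segments_partition_the_bins(self, rng):
        values = rng.poisson(200, 300).astype(float)
        segs = segment_bins(values)
        assert segs[0].start_bin == 0 and segs[-1].end_bin == 300
        for a, b in zip(segs[:-1], segs[1:]):
            assert a.end_bin == b.start_bin


class TestHaploidUnit:
    def test_exact_multiples(self):
        segs = [Segment("c", 0, 100, m) for m in (100.0, 200.0, 300.0)]
        assert estimate_haploid_unit(segs) == pytest.approx(100.0)

    def test_noisy_multiples_match_dense_grid_oracle(self):
        segs = [Segment("c", 0, 100, m) for m in (95.0, 210.0, 298.0)]
        u = estimate_haploid_unit(segs)

        # independent dense-grid search over the same objective
        def cost(u_):
            cns = np.array([95.0, 210.0, 298.0]) / u_
            if np.any(np.floor(cns + 0.5) > 8):
                return np.inf
            return float((100 * (cns - np.floor(cns + 0.5)) ** 2).sum())

        grid = np.linspace(298.0 / 8.5, 298.0, 200001)
        best = min(grid, key=cost)
        assert cost(u) <= cost(best) * 1.01 + 1e-9
        assert 95 <= u <= 106
        cns = [round(m / u) for m in (95, 210, 298)]
        assert cns == [1, 2, 3]

    def test_single_segment_resolves_to_largest_unit(self):
        segs = [Segment("c", 0, 100, 240.0)]
        assert estimate_haploid_unit(segs) == pytest.approx(240.0)

    def test_all_zero_is_an_error(self):
        with pytest.raises(ad.AllodosageError, match="no coverage signal"):
            estimate_haploid_unit([Segment("c", 0, 100, 0.0)])


class TestIntegerCalls:
    def test_rounding_is_half_away_from_zero(self):
        u = 10.0
        segs = [Segment("c", 0, 10, 24.9), Segment("c", 10, 20, 25.1)]
        call_integer_cn(segs, u)
        assert [s.cn for s in segs] == [2, 3]

    def test_zero_mean_calls_zero(self):
        segs = [Segment("c", 0, 10, 0.0)]
        call_integer_cn(segs, 10.0)
        assert segs[0].cn == 0

    def test_clipping_warns(self):
        segs = [Segment("c", 0, 10, 200.0)]
        with pytest.warns(UserWarning, match="clip"):
            call_integer_cn(segs, 10.0, max_cn=8)
        assert segs[0].cn == 8


class TestCopyTable:
    def test_truth_totals_recovered(self, small_strain, called_strain):
        k, _ = called_strain
        per_chrom, total = chromosome_copy_table(k)
        truth = small_strain.truth
        assert total == truth.total_chromosome_cn()
        assert per_chrom == {c: truth.modal_cn(c) for c in truth.segments}

    def test_total_invariant_under_bin_permutation(self):
        """For CN-uniform chromosomes the total ignores bin order."""
        cfg = ad.SimConfig(n_chromosomes_per_subgenome=3, n_hybrid_chromosomes=0,
                           depth_per_copy=80.0, seed=55)
        s = ad.simulate.simulate_strain(cfg)
        k1 = call_karyotype(s.coverage)
        rng = np.random.default_rng(0)
        shuffled = {}
        for chrom, t in s.coverage.items():
            perm = rng.permutation(t.n_bins)
            shuffled[chrom] = CoverageTrack(
                chrom=chrom, starts=t.starts, counts=t.counts[perm],
                library_size=t.library_size, bin_width=t.bin_width,
            )
        k2 = call_karyotype(shuffled)
        assert chromosome_copy_table(k1)[1] == chromosome_copy_table(k2)[1]


class TestBreakpoints:
    def test_planted_breakpoint_maps_to_its_gene(self):
        cfg = ad.SimConfig(
            n_chromosomes_per_subgenome=4, genes_per_chromosome=5,
            chrom_length=200_000, n_hybrid_chromosomes=2,
            depth_per_copy=100.0, seed=17,
        )
        s = ad.simulate.simulate_strain(cfg)
        k = call_karyotype(s.coverage)
        bps = detect_breakpoints(k, s.genes)
        truth_by_chrom = {
            b.chrom_sc: b for b in s.truth.breakpoints
        } | {b.chrom_se: b for b in s.truth.breakpoints}
        assert len(bps) == 2 * len(s.truth.breakpoints)
        for bp in bps:
            t = truth_by_chrom[bp.chrom]
            assert abs(bp.pos - t.pos) <= 2 * cfg.bin_width + cfg.bin_width
            assert bp.gene_id.rsplit("_", 1)[0] == t.base_id

    def test_uniform_chromosome_has_no_breakpoints(self):
        segs = {"Sc01": [Segment("Sc01", 0, 100, 50.0, cn=2)]}
        k = Karyotype(segments=segs, haploid_unit=25.0)
        assert detect_breakpoints(k) == []

    def test_equidistant_tie_prefers_lower_coordinate(self):
        segs = {
            "Sc01": [Segment("Sc01", 0, 2, 50.0, cn=1), Segment("Sc01", 2, 4, 100.0, cn=2)]
        }
        k = Karyotype(segments=segs, haploid_unit=50.0, bin_width=100)
        genes = [
            GeneRecord("a_Sc", "a", "Sc", "Sc01", 0, 100),    # midpoint 50
            GeneRecord("b_Sc", "b", "Sc", "Sc01", 300, 400),  # midpoint 350
        ]
        bps = detect_breakpoints(k, genes)  # boundary at 200, equidistant
        assert len(bps) == 1
        assert bps[0].gene_id == "a_Sc"


class TestGeneAssignment:
    def test_gene_cn_matches_truth(self, small_strain, called_strain):
        _, genes = called_strain
        truth = small_strain.truth
        correct = np.mean([g.cn == truth.gene_cn[g.gene_id] for g in genes])
        assert correct >= 0.99

    def test_absent_chromosome_gives_zero_cn_with_warning(self):
        k = Karyotype(
            segments={"Sc01": [Segment("Sc01", 0, 100, 50.0, cn=2)]},
            haploid_unit=25.0,
        )
        genes = [GeneRecord("x_Sc", "x", "Sc", "Sc09", 0, 1000)]
        with pytest.warns(UserWarning, match="Sc09"):
            assign_gene_cn(genes, k)
        assert genes[0].cn == 0

    def test_whole_chromosome_loss_zeroes_every_gene(self):
        """A strain missing an Sc chromosome has CN 0 for all its genes."""
        segs = {
            "Sc01": [Segment("Sc01", 0, 200, 0.0, cn=0)],
            "Se01": [Segment("Se01", 0, 200, 60.0, cn=2)],
        }
        k = Karyotype(segments=segs, haploid_unit=30.0)
        genes = [
            GeneRecord(f"g{i}_Sc", f"g{i}", "Sc", "Sc01", i * 1000, i * 1000 + 500)
            for i in range(5)
        ]
        assign_gene_cn(genes, k)
        assert all(g.cn == 0 for g in genes)


class TestChromosomeXScenario:
    """2 Sc + 1 Se + 1 hybrid chromosome recombining inside a gene.

    On the parental reference this reads as Sc coverage stepping 3 -> 2
    at the breakpoint and Se coverage 1 -> 2, so allele ratios are 3:1
    left of the breakpoint gene and 1:1 to its right.
    """

    def _scenario(self):
        rng = np.random.default_rng(99)
        depth = 120.0
        n = 200
        bp_bin = 100
        sc = np.concatenate([rng.poisson(3 * depth, bp_bin), rng.poisson(2 * depth, n - bp_bin)])
        se = np.concatenate([rng.poisson(1 * depth, bp_bin), rng.poisson(2 * depth, n - bp_bin)])
        # two uniform context chromosomes pin the haploid unit
        c1 = rng.poisson(1 * depth, n)
        c2 = rng.poisson(4 * depth, n)
        lib = float(sc.sum() + se.sum() + c1.sum() + c2.sum())
        tracks = {
            "Sc10": _track(sc, lib=lib, chrom="Sc10"),
            "Se10": _track(se, lib=lib, chrom="Se10"),
            "Sc02": _track(c1, lib=lib, chrom="Sc02"),
            "Se02": _track(c2, lib=lib, chrom="Se02"),
        }
        genes = []
        for gi in range(10):
            start, end = gi * 10_000 + 2000, gi * 10_000 + 8000
            base = f"y{gi + 1:02d}"
            genes.append(GeneRecord(f"{base}_Sc", base, "Sc", "Sc10", start, end))
            genes.append(GeneRecord(f"{base}_Se", base, "Se", "Se10", start, end))
        return tracks, genes

    def test_ratios_flip_from_3_to_1_to_1_to_1(self):
        tracks, genes = self._scenario()
        k = call_karyotype(tracks)
        assign_gene_cn(genes, k)
        pairs, _ = ad.dosage.pair_orthologs(genes)
        left = pairs[pairs["base_id"] < "y06"]
        right = pairs[pairs["base_id"] >= "y06"]
        assert set(left["category"]) == {"3:1"}
        assert set(right["category"]) == {"1:1"}
        assert set(right["cn_sc"]) == {2} and set(right["cn_se"]) == {2}


class TestSubgenomeAssignment:
    BPS = [Breakpoint("hyb03", 50_000, left_subgenome="Sc", right_subgenome="Se")]

    def test_gene_left_of_breakpoint_is_sc(self):
        g = GeneRecord("a_Se", "a", "Se", "hyb03", 10_000, 12_000)
        assert assign_subgenome_hybrid(g, self.BPS) == "Sc"

    def test_gene_right_of_breakpoint_is_se(self):
        g = GeneRecord("b_Sc", "b", "Sc", "hyb03", 80_000, 82_000)
        assert assign_subgenome_hybrid(g, self.BPS) == "Se"

    def test_spanning_gene_takes_majority_side(self):
        # 30% of the gene left of the breakpoint, 70% right -> Se
        g = GeneRecord("c_Sc", "c", "Sc", "hyb03", 47_000, 57_000)
        assert assign_subgenome_hybrid(g, self.BPS) == "Se"

    def test_chromosome_without_breakpoints_keeps_label(self):
        g = GeneRecord("d_Sc", "d", "Sc", "Sc01", 0, 1000)
        assert assign_subgenome_hybrid(g, self.BPS) == "Sc"


def test_end_to_end_recovery_across_seeds():
    """Called chromosome CNs equal truth for >=95% of chromosomes."""
    hits = total = 0
    for seed in range(3):
        cfg = ad.SimConfig(n_chromosomes_per_subgenome=6, depth_per_copy=50.0, seed=seed)
        s = ad.simulate.simulate_strain(cfg)
        k = call_karyotype(s.coverage)
        for chrom in s.truth.segments:
            total += 1
            hits += k.modal_cn(chrom) == s.truth.modal_cn(chrom)
    assert hits / total >= 0.95
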