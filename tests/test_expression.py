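"""Negative-binomial DE machinery: filters, normalization, test, BH."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import allodosage as ad
from allodosage.expression import (
    ALPHA_MIN,
    bh_adjust,
    classify_deg,
    cpm,
    estimate_dispersion,
    filter_detected,
    log_cpm,
    nb_wald,
    size_factors,
)


def _cm(counts, conditions, genes=None):
    counts = np.atleast_2d(np.asarray(counts))
    genes = genes or [f"g{i}" for i in range(counts.shape[0])]
    cols = [f"s{j}" for j in range(counts.shape[1])]
    samples = pd.DataFrame(
        {
            "strain": "x",
            "condition": conditions,
            "replicate": list(range(len(cols))),
        },
        index=pd.Index(cols, name="sample"),
    )
    return ad.CountMatrix(pd.DataFrame(counts, index=genes, columns=cols), samples)


class TestCpm:
    def test_definition(self):
        counts = pd.DataFrame({"s1": [5, 10_000_000 - 5]})
        assert cpm(counts).iloc[0, 0] == pytest.approx(0.5)

    def test_scale_invariance(self):
        counts = pd.DataFrame({"s1": [10, 90], "s2": [20, 180]})
        c = cpm(counts)
        pd.testing.assert_series_equal(c["s1"], c["s2"], check_names=False)

    def test_zero_library_names_sample(self):
        counts = pd.DataFrame({"good": [5], "empty": [0]})
        with pytest.raises(ad.AllodosageError, match="empty"):
            cpm(counts)

    def test_log_variant_zero_prior_zero_count_is_finite(self):
        counts = pd.DataFrame({"s1": [0, 100]})
        vals = log_cpm(counts, prior_count=0)
        assert np.isfinite(vals.iloc[0, 0])


class TestFilterDetected:
    def test_boundary_is_inclusive(self):
        # one sample with CPM exactly 0.5 keeps the gene
        cm = _cm([[5, 0], [10_000_000 - 5, 100]], ["a", "b"])
        kept = filter_detected(cm, min_cpm=0.5, min_libraries=1)
        assert "g0" in kept.counts.index

    def test_all_zero_gene_removed(self):
        cm = _cm([[0, 0], [10, 10]], ["a", "b"])
        kept = filter_detected(cm)
        assert list(kept.counts.index) == ["g1"]

    def test_zero_threshold_is_identity(self):
        cm = _cm([[0, 1], [5, 5]], ["a", "b"])
        kept = filter_detected(cm, min_cpm=0.0)
        assert list(kept.counts.index) == ["g0", "g1"]


class TestSizeFactors:
    def test_proportional_columns(self):
        counts = pd.DataFrame({"a": [10, 100, 4], "b": [20, 200, 8]})
        f = size_factors(counts)
        assert f["b"] / f["a"] == pytest.approx(2.0)

    def test_identical_columns_equal_factors(self):
        counts = pd.DataFrame({"a": [3, 7, 11], "b": [3, 7, 11]})
        f = size_factors(counts)
        assert f["a"] == pytest.approx(f["b"]) == pytest.approx(1.0)

    def test_hand_computed_median_of_ratios(self):
        # geometric means: sqrt(200), sqrt(20000), sqrt(32); every ratio
        # in column a is 1/sqrt(2), in column b sqrt(2)
        counts = pd.DataFrame({"a": [10, 100, 4], "b": [20, 200, 8]})
        f = size_factors(counts)
        assert f["a"] == pytest.approx(1 / np.sqrt(2))
        assert f["b"] == pytest.approx(np.sqrt(2))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(c=st.floats(0.25, 4.0), seed=st.integers(0, 100))
    def test_scale_equivariance_of_factor_ratios(self, c, seed):
        # scaling one column by c scales its factor relative to any
        # other column by c (absolute factors shift by the shared
        # geometric-mean reference, which the GLM offset absorbs)
        rng = np.random.default_rng(seed)
        counts = pd.DataFrame(rng.poisson(50, size=(30, 4)) + 1,
                              columns=list("abcd"))
        base = size_factors(counts)
        scaled = counts.copy()
        scaled["c"] = scaled["c"] * c
        f = size_factors(scaled)
        assert (f["c"] / f["a"]) / (base["c"] / base["a"]) == pytest.approx(c, rel=1e-9)

    def test_no_common_gene_is_error(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ad.AllodosageError):
            size_factors(counts)


class TestDispersion:
    def test_poisson_data_has_tiny_dispersion(self, rng):
        mu = rng.lognormal(4, 1, 1000)
        y = rng.poisson(mu[:, None], size=(1000, 6))
        cm = _cm(y, ["a"] * 3 + ["b"] * 3)
        alpha = estimate_dispersion(cm)
        assert alpha.median() <= 0.01

    def test_recovers_planted_dispersion(self, rng):
        a = 0.2
        mu = rng.lognormal(4.5, 1, 2000)
        r = 1 / a
        y = rng.negative_binomial(r, r / (r + mu[:, None]), size=(2000, 12))
        cm = _cm(y, ["a"] * 6 + ["b"] * 6)
        alpha = estimate_dispersion(cm)
        assert 0.1 <= alpha.median() <= 0.4

    def test_constant_gene_floors_at_alpha_min(self):
        cm = _cm([[10, 10, 10, 10]], ["a", "a", "b", "b"])
        raw = estimate_dispersion(cm, shrink_weight=0.0)
        assert raw.iloc[0] == ALPHA_MIN

    def test_unreplicated_design_is_error(self):
        cm = _cm([[5, 6]], ["a", "b"])
        with pytest.raises(ad.AllodosageError):
            estimate_dispersion(cm)


class TestNbWald:
    def test_identical_groups_give_zero_log2fc(self):
        col = np.array([13, 55, 120, 7, 300])
        cm = _cm(np.column_stack([col] * 6), ["a"] * 3 + ["b"] * 3)
        res = nb_wald(cm, ("b", "a"))
        np.testing.assert_allclose(res["log2fc"], 0.0, atol=1e-9)

    def test_exact_double_counts_give_log2fc_one(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(100, size=(50, 3))
        y = np.concatenate([base, 2 * base], axis=1)
        cm = _cm(y, ["a"] * 3 + ["b"] * 3)
        sf = pd.Series(1.0, index=cm.counts.columns)
        res = nb_wald(cm, ("b", "a"), size_factors_=sf)
        np.testing.assert_allclose(res["log2fc"], 1.0, atol=1e-6)

    def test_type_one_error_is_calibrated(self):
        rng = np.random.default_rng(5)
        alpha = 0.1
        r = 1 / alpha
        mu = rng.lognormal(4, 1, 2000) * 2
        y = rng.negative_binomial(r, r / (r + mu[:, None]), size=(2000, 6))
        cm = _cm(y, ["a"] * 3 + ["b"] * 3)
        res = nb_wald(cm, ("b", "a"))
        p = res["p"].dropna()
        assert 0.03 <= (p < 0.05).mean() <= 0.07

    def test_recovers_planted_twofold_change(self):
        rng = np.random.default_rng(6)
        alpha = 0.1
        r = 1 / alpha
        mu = rng.lognormal(4, 1, 2000) * 2
        mu2 = mu.copy()
        planted = np.zeros(2000, dtype=bool)
        planted[:200] = True
        mu2[planted] *= 2
        ya = rng.negative_binomial(r, r / (r + mu[:, None]), size=(2000, 3))
        yb = rng.negative_binomial(r, r / (r + mu2[:, None]), size=(2000, 3))
        cm = _cm(np.concatenate([ya, yb], axis=1), ["a"] * 3 + ["b"] * 3)
        res = nb_wald(cm, ("b", "a"))
        med = res["log2fc"][planted].median()
        assert med == pytest.approx(1.0, abs=0.15)

    def test_empty_group_is_error(self):
        cm = _cm([[1, 2, 3]], ["a", "a", "a"])
        with pytest.raises(ad.AllodosageError):
            nb_wald(cm, ("b", "a"))

    def test_agrees_with_statsmodels_glm(self):
        """Independent oracle: statsmodels NB GLM with the same fixed alpha."""
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        alpha = 0.15
        r = 1 / alpha
        mu = np.array([40.0] * 3 + [90.0] * 3)
        y = rng.negative_binomial(r, r / (r + mu[None, :]), size=(25, 6))
        sf = np.array([0.9, 1.0, 1.1, 0.95, 1.05, 1.0])
        cm = _cm(y, ["a"] * 3 + ["b"] * 3)
        res = nb_wald(
            cm, ("b", "a"),
            size_factors_=pd.Series(sf, index=cm.counts.columns),
            dispersions=pd.Series(alpha, index=cm.counts.index),
        )
        X = sm.add_constant(np.array([0.0] * 3 + [1.0] * 3))
        for i in range(25):
            fit = sm.GLM(
                y[i], X, family=sm.families.NegativeBinomial(alpha=alpha),
                offset=np.log(sf),
            ).fit()
            assert res["log2fc"].iloc[i] == pytest.approx(fit.params[1] / np.log(2), abs=1e-5)
            assert res["se"].iloc[i] == pytest.approx(fit.bse[1] / np.log(2), rel=1e-3)


def _bh_bruteforce(p):
    """O(n^2) literal step-up definition."""
    p = np.asarray(p, dtype=float)
    m = p.size
    adj = np.empty(m)
    order = np.argsort(p, kind="mergesort")
    sorted_p = p[order]
    for i in range(m):
        adj[i] = min(min(sorted_p[j] * m / (j + 1) for j in range(i, m)), 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


class TestBhAdjust:
    def test_textbook_example(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.3]))[0] == pytest.approx(0.3)

    def test_all_ones_stay_ones(self):
        np.testing.assert_allclose(bh_adjust(np.ones(5)), 1.0)

    def test_nan_propagates_and_reduces_m(self):
        out = bh_adjust(np.array([0.01, np.nan, 0.04]))
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], _bh_bruteforce([0.01, 0.04]))

    def test_out_of_range_is_error(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.5]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=200))
    def test_matches_bruteforce_stepup(self, ps):
        np.testing.assert_allclose(bh_adjust(np.array(ps)), _bh_bruteforce(ps), atol=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        ps = rng.uniform(size=500)
        np.testing.assert_allclose(
            bh_adjust(ps), multipletests(ps, method="fdr_bh")[1], atol=1e-12
        )

    def test_padj_never_below_p(self, rng):
        ps = rng.uniform(size=300)
        assert (bh_adjust(ps) >= ps).all()


class TestClassifyDeg:
    @pytest.mark.parametrize(
        "lfc, padj, expected",
        [
            (1.0, 0.049, "up"),       # inclusive LFC boundary
            (-1.0, 0.049, "down"),
            (-0.99, 0.001, "ns"),     # below LFC threshold
            (3.0, 0.05, "ns"),        # strict FDR boundary
            (2.0, np.nan, "ns"),      # missing padj
            (0.0, 0.001, "ns"),
        ],
    )
    def test_boundary_table(self, lfc, padj, expected):
        df = pd.DataFrame({"log2fc": [lfc], "padj": [padj]})
        assert classify_deg(df).iloc[0] == expected

    def test_partitions_into_three_statuses(self, rng):
        df = pd.DataFrame(
            {"log2fc": rng.normal(0, 2, 500), "padj": rng.uniform(size=500)}
        )
        status = classify_deg(df)
        assert set(status.unique()) <= {"up", "down", "ns"}
        assert len(status) == 500
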