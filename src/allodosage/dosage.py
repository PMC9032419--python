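"""Orthologue (homeolog) dosage-expression analysis.

Within a hybrid strain, every ancestral gene may be present as an Sc
and an Se allele with different copy numbers.  This module pairs the
alleles, computes the within-strain allele expression log-ratio (Sc
over Se) with the NB machinery, bins pairs by their canonical copy
number ratio (``3:1``, ``1:2``...), and quantifies how strongly the
expression ratio tracks the dosage ratio.
"""

from __future__ import annotations

from math import gcd

import numpy as np
import pandas as pd
from scipy import stats

from . import expression
from .types import AllodosageError, CountMatrix, DosageRegression, GeneRecord


def pair_orthologs(
    genes: list[GeneRecord],
) -> tuple[pd.DataFrame, list[GeneRecord]]:
    """Pair Sc/Se alleles sharing a base id.

    Returns a pairs DataFrame (``base_id, sc_id, se_id`` and, when the
    genes carry copy numbers, ``cn_sc, cn_se, category``) plus the list
    of unmatched genes.  More than one allele per sub-genome for a base
    id is an error.
    """
    by_base: dict[str, dict[str, list[GeneRecord]]] = {}
    for g in genes:
        by_base.setdefault(g.base_id, {}).setdefault(g.subgenome, []).append(g)

    dups = [
        f"{base}/{sub}"
        for base, subs in by_base.items()
        for sub, lst in subs.items()
        if len(lst) > 1
    ]
    if dups:
        raise AllodosageError(f"duplicate alleles per sub-genome: {sorted(dups)[:10]}")

    rows, unmatched = [], []
    for base in sorted(by_base):
        subs = by_base[base]
        if "Sc" in subs and "Se" in subs:
            sc, se = subs["Sc"][0], subs["Se"][0]
            row = {"base_id": base, "sc_id": sc.gene_id, "se_id": se.gene_id}
            if sc.cn is not None and se.cn is not None:
                row["cn_sc"] = sc.cn
                row["cn_se"] = se.cn
                row["category"] = ratio_category(sc.cn, se.cn)
            rows.append(row)
        else:
            unmatched.extend(lst[0] for lst in subs.values())
    return pd.DataFrame(rows), unmatched


def ratio_category(cn_sc: int, cn_se: int) -> str:
    """Canonical ``sc:se`` copy-number ratio string, reduced by gcd."""
    if cn_sc < 0 or cn_se < 0:
        raise ValueError("copy numbers must be >= 0")
    if cn_sc == 0 and cn_se == 0:
        return "0:0"
    d = gcd(cn_sc, cn_se)
    return f"{cn_sc // d}:{cn_se // d}"


def allele_log2fc_table(
    cm: CountMatrix,
    pairs: pd.DataFrame,
    strain: str,
    condition: str,
) -> pd.DataFrame:
    """Sc-over-Se expression log-ratio per orthologue pair.

    The two alleles are treated as the two groups of an NB Wald
    contrast over the same replicate libraries: the pair's Sc and Se
    counts across replicates become two pseudo-samples per library,
    sharing that library's size factor.  Positive log2fc means the Sc
    allele is higher.  Pairs with zero counts for both alleles in all
    replicates get missing results.  BH adjustment is across pairs.
    """
    sub = cm.select(strain=strain, condition=condition)
    if sub.n_samples < 2:
        raise AllodosageError(
            f"need >= 2 replicates for {strain}/{condition}, found {sub.n_samples}"
        )
    sf = expression.size_factors(sub.counts)

    missing = [
        gid
        for gid in pd.concat([pairs["sc_id"], pairs["se_id"]])
        if gid not in sub.counts.index
    ]
    if missing:
        raise AllodosageError(f"pair members absent from counts: {missing[:10]}")

    sc_counts = sub.counts.loc[pairs["sc_id"]].to_numpy(dtype=float)
    se_counts = sub.counts.loc[pairs["se_id"]].to_numpy(dtype=float)
    y = np.concatenate([sc_counts, se_counts], axis=1)
    reps = sub.n_samples

    allele_cols = [f"sc_r{i}" for i in range(reps)] + [f"se_r{i}" for i in range(reps)]
    counts_df = pd.DataFrame(y, index=pairs["base_id"].to_numpy(), columns=allele_cols)
    samples_df = pd.DataFrame(
        {
            "strain": strain,
            "condition": ["Sc"] * reps + ["Se"] * reps,
            "replicate": list(range(reps)) * 2,
        },
        index=pd.Index(allele_cols, name="sample"),
    )
    pseudo = CountMatrix(counts_df, samples_df)
    sf2 = pd.Series(
        np.concatenate([sf.to_numpy(), sf.to_numpy()]), index=allele_cols
    )
    res = expression.nb_wald(
        pseudo, contrast=("Sc", "Se"), by="condition", size_factors_=sf2
    )
    both_zero = (y.sum(axis=1) == 0)
    res.loc[both_zero, ["log2fc", "se", "stat", "p"]] = np.nan
    res["padj"] = expression.bh_adjust(res["p"])

    out = pairs.copy()
    out["log2fc"] = res["log2fc"].to_numpy()
    out["se"] = res["se"].to_numpy()
    out["p"] = res["p"].to_numpy()
    out["padj"] = res["padj"].to_numpy()
    return out


def allele_log2fc(
    cm: CountMatrix, pair: pd.Series | dict, strain: str, condition: str
) -> tuple[float, float]:
    """(log2FC, padj) for a single orthologue pair; see :func:`allele_log2fc_table`."""
    pairs = pd.DataFrame([dict(pair)])
    res = allele_log2fc_table(cm, pairs, strain, condition)
    return float(res["log2fc"].iloc[0]), float(res["padj"].iloc[0])


def _ratio_regression(
    x: np.ndarray, y: np.ndarray, category: np.ndarray, min_categories: int = 3
) -> DosageRegression:
    """Weighted per-category OLS of y on x plus the unbinned fit.

    Categories are weighted by their pair count; the slope p value
    comes from a t test with (categories - 2) degrees of freedom.
    """
    ok = np.isfinite(x) & np.isfinite(y)
    x, y, category = x[ok], y[ok], category[ok]
    df = pd.DataFrame({"x": x, "y": y, "category": category})
    summary = (
        df.groupby("category")
        .agg(x=("x", "first"), mean=("y", "mean"), n=("y", "size"), sem=("y", "sem"))
        .reset_index()
    )
    n_cat = len(summary)
    if n_cat < min_categories or summary["x"].nunique() < 2:
        raise AllodosageError(
            f"dosage regression needs >= {min_categories} distinct finite "
            f"copy-number ratio categories, found {n_cat}"
        )

    w = summary["n"].to_numpy(dtype=float)
    xs = summary["x"].to_numpy()
    ys = summary["mean"].to_numpy()
    W = np.diag(w)
    X = np.column_stack([np.ones(n_cat), xs])
    XtWX = X.T @ W @ X
    beta = np.linalg.solve(XtWX, X.T @ (w * ys))
    resid = ys - X @ beta
    wmean = np.average(ys, weights=w)
    ss_res = float(np.sum(w * resid**2))
    ss_tot = float(np.sum(w * (ys - wmean) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    dof = n_cat - 2
    if dof > 0 and ss_res >= 0:
        sigma2 = ss_res / dof
        se_slope = float(np.sqrt(sigma2 * np.linalg.inv(XtWX)[1, 1]))
        tstat = beta[1] / se_slope if se_slope > 0 else np.inf
        p = float(2.0 * stats.t.sf(abs(tstat), dof))
    else:
        p = float("nan")

    lr = stats.linregress(x, y)
    return DosageRegression(
        slope=float(beta[1]),
        intercept=float(beta[0]),
        r2=float(r2),
        p=p,
        n_pairs=int(len(x)),
        n_categories=n_cat,
        category_table=summary,
        unbinned_slope=float(lr.slope),
        unbinned_intercept=float(lr.intercept),
        unbinned_r2=float(lr.rvalue**2),
        unbinned_p=float(lr.pvalue),
    )


def dosage_correlation(pairs: pd.DataFrame, min_categories: int = 3) -> DosageRegression:
    """Regress allele expression log-ratio on log2 copy-number ratio.

    Pairs where either allele has CN 0 are excluded (the log ratio is
    undefined); the per-category fit is weighted by category size.
    """
    usable = pairs[(pairs["cn_sc"] > 0) & (pairs["cn_se"] > 0)].copy()
    x = np.log2(usable["cn_sc"].to_numpy(float) / usable["cn_se"].to_numpy(float))
    y = usable["log2fc"].to_numpy(dtype=float)
    return _ratio_regression(x, y, usable["category"].to_numpy(), min_categories)


def category_summary(pairs: pd.DataFrame, lfc_min: float = 1.0) -> pd.DataFrame:
    """Per ratio category: n, mean, SEM and the two tail counts.

    ``n_up``/``n_down`` count pairs with log2FC >= lfc_min (Sc side)
    and <= -lfc_min (Se side), mirroring how pair counts are displayed
    above dosage-ratio plots.  Empty categories are omitted.
    """
    usable = pairs[np.isfinite(pairs["log2fc"])]
    rows = []
    for cat, sub in usable.groupby("category"):
        vals = sub["log2fc"].to_numpy()
        rows.append(
            {
                "category": cat,
                "n": len(vals),
                "mean": float(vals.mean()),
                "sem": float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan"),
                "n_up": int((vals >= lfc_min).sum()),
                "n_down": int((vals <= -lfc_min).sum()),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["sort_key"] = [
            np.log2(int(c.split(":")[0]) / int(c.split(":")[1]))
            if "0" not in c.split(":")
            else np.inf * (1 if c.split(":")[1] == "0" else -1)
            for c in out["category"]
        ]
        out = out.sort_values("sort_key").drop(columns="sort_key").reset_index(drop=True)
    return out
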