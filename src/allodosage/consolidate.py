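"""Orthologue-consolidated transcriptome and cross-strain comparison.

Summing the Sc and Se allele counts of each orthologue pair yields one
row per ancestral gene; unmatched genes pass through.  Two strains'
consolidated matrices can then be compared with the NB machinery, and
the cross-strain expression log-ratio correlated with the ratio of
total (Sc+Se) gene copy number between the strains.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import expression
from .dosage import _ratio_regression, ratio_category
from .types import AllodosageError, CountMatrix, DosageRegression, GeneRecord


def consolidate_counts(cm: CountMatrix, pairs: pd.DataFrame) -> CountMatrix:
    """Sum paired allele rows under the base id; keep unmatched rows.

    Consolidated counts equal the sum of member allele counts per
    sample; genes with zero reads in every sample are dropped.  A pair
    referencing a gene absent from the matrix is an error.
    """
    if len(pairs):
        wanted = pd.concat([pairs["sc_id"], pairs["se_id"]])
        missing = [g for g in wanted if g not in cm.counts.index]
        if missing:
            raise AllodosageError(f"pair members absent from counts: {missing[:10]}")
        summed = (
            cm.counts.loc[pairs["sc_id"]].to_numpy()
            + cm.counts.loc[pairs["se_id"]].to_numpy()
        )
        consolidated = pd.DataFrame(
            summed, index=pairs["base_id"].to_numpy(), columns=cm.counts.columns
        )
        paired_ids = set(pairs["sc_id"]) | set(pairs["se_id"])
    else:
        consolidated = None
        paired_ids = set()

    passthrough = cm.counts.loc[[g for g in cm.counts.index if g not in paired_ids]]
    out = passthrough if consolidated is None else pd.concat([consolidated, passthrough])
    if out.index.has_duplicates:
        raise AllodosageError("duplicate base ids after consolidation")
    out = out[out.sum(axis=1) > 0]
    return CountMatrix(out, cm.samples.copy())


def total_gene_cn(
    pairs: pd.DataFrame, unmatched: list[GeneRecord] | None = None
) -> pd.Series:
    """Total copy number per base id: cn_sc + cn_se (single allele if unmatched)."""
    vals = {}
    for row in pairs.itertuples(index=False):
        vals[row.base_id] = int(row.cn_sc) + int(row.cn_se)
    for g in unmatched or []:
        if g.cn is None:
            raise AllodosageError(f"unmatched gene {g.gene_id} has no copy number")
        vals[g.base_id] = int(g.cn)
    return pd.Series(vals, name="cn_total").sort_index()


def cross_strain_de(
    cons_a: CountMatrix,
    cons_b: CountMatrix,
    condition: str,
    strain_a: str | None = None,
    strain_b: str | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """NB Wald test of strain A vs strain B on consolidated counts.

    Both strains' replicates for ``condition`` are joined into one
    matrix over the shared base ids; size factors are computed jointly
    across all samples and dispersions with strain as the grouping.
    Positive log2fc means higher in strain A.  Base ids present in only
    one strain are excluded and returned as the second element.
    """
    sub_a = cons_a.select(condition=condition)
    sub_b = cons_b.select(condition=condition)
    if sub_a.n_samples < 2 or sub_b.n_samples < 2:
        raise AllodosageError("both strains need >= 2 replicates in the condition")
    a_label = strain_a or str(sub_a.samples["strain"].iloc[0])
    b_label = strain_b or str(sub_b.samples["strain"].iloc[0])
    if a_label == b_label:
        raise AllodosageError("strain labels must differ for a cross-strain contrast")

    shared = sub_a.counts.index.intersection(sub_b.counts.index)
    if len(shared) == 0:
        raise AllodosageError("no shared base ids between the strains")
    only = sorted(
        set(sub_a.counts.index).symmetric_difference(set(sub_b.counts.index))
    )

    counts = pd.concat([sub_a.counts.loc[shared], sub_b.counts.loc[shared]], axis=1)
    samples = pd.concat([sub_a.samples, sub_b.samples])
    samples["strain"] = [a_label] * sub_a.n_samples + [b_label] * sub_b.n_samples
    combined = CountMatrix(counts, samples)

    res = expression.nb_wald(combined, contrast=(a_label, b_label), by="strain")
    res["padj"] = expression.bh_adjust(res["p"])
    res["status"] = expression.classify_deg(res)
    return res, only


def cn_ratio_correlation(
    de: pd.DataFrame,
    cn_a: pd.Series,
    cn_b: pd.Series,
    min_categories: int = 3,
) -> DosageRegression:
    """Regress cross-strain log2FC on log2 total copy-number ratio.

    Genes with zero total CN in either strain are excluded (counted via
    ``n_pairs`` shrinkage); the fit is per canonical ratio category,
    weighted by category size, with an unbinned fit alongside.
    """
    shared = de.index.intersection(cn_a.index).intersection(cn_b.index)
    a = cn_a.loc[shared].to_numpy(dtype=float)
    b = cn_b.loc[shared].to_numpy(dtype=float)
    y = de.loc[shared, "log2fc"].to_numpy(dtype=float)
    ok = (a > 0) & (b > 0)
    if ok.sum() == 0:
        raise AllodosageError("no genes with positive total CN in both strains")
    cats = np.array(
        [ratio_category(int(ai), int(bi)) for ai, bi in zip(a[ok], b[ok])]
    )
    x = np.log2(a[ok] / b[ok])
    return _ratio_regression(x, y[ok], cats, min_categories=min_categories)
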