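"""Sub-genome representation tests and DEG-list set operations.

In a hybrid, up- or down-regulated gene pools can be asked whether
their Sc/Se membership deviates from the strain's genome-wide
expectation (the fraction of detected transcripts per sub-genome); a
chi-squared goodness-of-fit with one degree of freedom answers it.
Venn-style intersections of DEG lists across condition comparisons are
computed here too.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import pandas as pd
from scipy import stats

from .types import AllodosageError, GeneRecord, RepresentationTest


def expected_subgenome_ratio(
    genes: list[GeneRecord] | pd.Series,
) -> tuple[float, float]:
    """(p_sc, p_se) among detected genes.

    Accepts GeneRecords or a Series of "Sc"/"Se" labels.  With one
    sub-genome entirely absent the ratio is degenerate; a warning is
    raised and the caller should skip the test.
    """
    if isinstance(genes, pd.Series):
        labels = genes
    else:
        labels = pd.Series([g.subgenome for g in genes])
    n_sc = int((labels == "Sc").sum())
    n_se = int((labels == "Se").sum())
    total = n_sc + n_se
    if total == 0:
        raise AllodosageError("no genes with sub-genome labels")
    if n_sc == 0 or n_se == 0:
        warnings.warn("one sub-genome absent: expected ratio is degenerate")
    return n_sc / total, n_se / total


def _stars(p: float) -> str:
    if p <= 0.001:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def subgenome_chi2(
    n_sc: int, n_se: int, expected: tuple[float, float], label: str = ""
) -> RepresentationTest:
    """Chi-squared goodness of fit of an (n_sc, n_se) pool vs expectation.

    ``chi2 = sum (O - E)^2 / E`` with ``E = N * p`` and df = 1; no
    continuity correction.  Stars: ``**`` for p <= 0.001, ``*`` for
    p <= 0.05 (inclusive thresholds).  Expected cells below 1 attach a
    small-sample warning to the result.
    """
    p_sc, p_se = expected
    if not (0 < p_sc < 1 and 0 < p_se < 1) or abs(p_sc + p_se - 1) > 1e-9:
        raise AllodosageError("expected proportions must be in (0,1) and sum to 1")
    n = n_sc + n_se
    if n < 1:
        raise AllodosageError("empty pool")
    e_sc, e_se = n * p_sc, n * p_se
    warning = None
    if min(e_sc, e_se) < 1:
        warning = "expected cell < 1: chi-squared approximation unreliable"
        warnings.warn(warning)
    chi2 = (n_sc - e_sc) ** 2 / e_sc + (n_se - e_se) ** 2 / e_se
    p = float(stats.chi2.sf(chi2, df=1))
    return RepresentationTest(
        label=label, n_sc=n_sc, n_se=n_se, p_sc=p_sc, p_se=p_se,
        chi2=float(chi2), p=p, stars=_stars(p), warning=warning,
    )


def representation_table(
    pools: dict[str, tuple[int, int]], expected: tuple[float, float]
) -> pd.DataFrame:
    """Run :func:`subgenome_chi2` over labelled pools; one row each."""
    rows = []
    for label, (n_sc, n_se) in pools.items():
        t = subgenome_chi2(n_sc, n_se, expected, label=label)
        rows.append(
            {
                "pool": label, "n_sc": t.n_sc, "n_se": t.n_se,
                "chi2": t.chi2, "p": t.p, "stars": t.stars,
            }
        )
    return pd.DataFrame(rows)


def deg_set_ops(
    lists: dict[str, set[str] | list[str]],
) -> tuple[pd.DataFrame, dict[frozenset, set[str]]]:
    """Exclusive Venn regions of up to a handful of DEG lists.

    Returns a counts DataFrame (one row per non-empty combination of
    lists, exclusive membership) and the region -> member mapping.
    Region counts sum to the size of the union.
    """
    sets = {k: set(v) for k, v in lists.items()}
    names = list(sets)
    regions: dict[frozenset, set[str]] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[c] for c in combo))
            outside = set.union(set(), *(sets[c] for c in names if c not in combo))
            regions[frozenset(combo)] = inside - outside
    rows = [
        {
            "lists": "&".join(sorted(combo)),
            "n_lists": len(combo),
            "count": len(members),
        }
        for combo, members in regions.items()
    ]
    df = pd.DataFrame(rows).sort_values(["n_lists", "lists"]).reset_index(drop=True)
    return df, regions
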