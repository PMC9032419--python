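"""Gene-set over-representation with sub-genome composition scores.

Upper-tail hypergeometric enrichment of a regulated gene list against
GMT gene sets, with the filter conventions used for pathway readouts
of hybrid DEG pools: at least four overlapping genes, at least 25% of
the pathway regulated, p < 0.05, BH adjustment over all tested terms.
For each surviving term the Sc/Se composition of the overlap is scored
as the deviation of the observed Sc fraction from the genome-wide
expectation (positive = Sc-enriched, negative = Se-enriched; an
all-Se overlap scores exactly -p_sc and is flagged exclusive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy import stats

from .expression import bh_adjust
from .types import AllodosageError


@dataclass
class GeneSet:
    term: str
    name: str
    members: set[str]


def load_gene_sets(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file (term, description, members; tab-separated)."""
    path = Path(path)
    sets: list[GeneSet] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise AllodosageError(
                    f"{path.name}:{lineno}: GMT line needs term, description "
                    f"and >= 1 member"
                )
            term, name, *members = fields
            members = [m for m in members if m]
            if not members:
                raise AllodosageError(f"{path.name}:{lineno}: empty gene set {term!r}")
            uniq = set(members)
            if len(uniq) < len(members):
                warnings.warn(f"{path.name}:{lineno}: duplicate members in {term!r}")
            sets.append(GeneSet(term=term, name=name, members=uniq))
    if not sets:
        raise AllodosageError(f"{path}: no gene sets found")
    return sets


def hypergeom_enrich(
    gene_list: set[str] | list[str],
    universe: set[str] | list[str],
    sets: list[GeneSet],
    min_genes: int = 4,
    min_frac: float = 0.25,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment with pathway filters.

    For each term (intersected with the universe): ``k`` overlap genes
    of ``n`` list genes, term size ``K``, universe size ``N``,
    ``p = P[X >= k]`` for X ~ Hypergeom(N, K, n).  BH runs over all
    tested terms; kept terms need ``k >= min_genes``, ``k/K >=
    min_frac`` and ``p < alpha``.  Returns the kept terms with overlap
    membership.
    """
    gene_list = set(gene_list)
    universe = set(universe)
    if not gene_list or not universe:
        raise AllodosageError("gene list and universe must be non-empty")
    if not gene_list <= universe:
        raise AllodosageError(
            f"{len(gene_list - universe)} list genes are outside the universe"
        )
    n = len(gene_list)
    N = len(universe)

    rows = []
    for gs in sets:
        members = gs.members & universe
        K = len(members)
        if K == 0:
            continue
        overlap = members & gene_list
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term": gs.term,
                "name": gs.name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": p,
                "fraction": k / K,
                "overlap": sorted(overlap),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["term", "name", "k", "K", "n", "N", "p", "padj", "fraction", "overlap"]
        )
    df = pd.DataFrame(rows)
    df["padj"] = bh_adjust(df["p"])
    kept = df[(df["k"] >= min_genes) & (df["fraction"] >= min_frac) & (df["p"] < alpha)]
    return kept.reset_index(drop=True)


def subgenome_composition(
    results: pd.DataFrame,
    labels: dict[str, str] | pd.Series,
    p_sc: float,
) -> pd.DataFrame:
    """Sc/Se composition score per enriched term.

    ``score = observed Sc fraction of the overlap - p_sc``, bounded in
    ``[-p_sc, 1 - p_sc]``.  Terms whose overlap is entirely Se score
    exactly ``-p_sc`` and are flagged ``exclusive_se`` (the strongest
    Se-skew the score can express); all-Sc overlaps are flagged
    ``exclusive_sc`` symmetrically.
    """
    if not 0 < p_sc < 1:
        raise AllodosageError("p_sc must be in (0, 1)")
    if isinstance(labels, pd.Series):
        labels = labels.to_dict()
    out = results.copy()
    scores, flags = [], []
    for overlap in out["overlap"]:
        subs = [labels[g] for g in overlap]
        n_sc = sum(1 for s in subs if s == "Sc")
        frac_sc = n_sc / len(subs) if subs else float("nan")
        scores.append(frac_sc - p_sc)
        if subs and n_sc == 0:
            flags.append("exclusive_se")
        elif subs and n_sc == len(subs):
            flags.append("exclusive_sc")
        else:
            flags.append("")
    out["sc_composition_score"] = scores
    out["composition_flag"] = flags
    return out
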