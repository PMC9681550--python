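"""Gene-set analysis of tsRNA-correlated mRNAs.

Two complementary tests over user-supplied GMT gene sets:

* over-representation (ORA): hypergeometric upper-tail probability of the
  overlap between a hit list and a gene set within a stated universe;
* gene-set enrichment (GSEA): the weighted Kolmogorov-Smirnov running-sum
  enrichment score over a ranked gene list, with a gene-label permutation
  null for NES and p-values.

The running sum adds |metric|^p / sum_hits |metric|^p at each set member and
subtracts 1/(N - N_hits) at each miss; the enrichment score (ES) is the
signed maximum deviation from zero.  ``weight_exponent=0`` recovers the
classical unweighted KS form; the default 1 is the canonical weighted
statistic.  The null permutes set membership over ranked genes (not
phenotypes), which needs no expression matrix and suits desk-scale reruns;
p-values carry +1 smoothing, so the smallest attainable p is 1/(n_perm+1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSet",
    "read_gmt",
    "as_ranked_list",
    "ora_test",
    "ora_table",
    "gsea_enrichment_score",
    "gsea_significance",
    "gsea_table",
]


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset
    description: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")


def read_gmt(path) -> list[GeneSet]:
    """Parse a GMT file: one set per line, name <tab> description <tab> genes..."""
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets.append(GeneSet(parts[0], frozenset(g for g in parts[2:] if g), parts[1]))
    return sets


def as_ranked_list(metric: pd.Series) -> pd.Series:
    """Validate and sort a gene -> metric Series into a descending ranked list."""
    if metric.index.has_duplicates:
        raise ValueError("ranked list has duplicate gene ids")
    if not np.isfinite(metric.to_numpy(dtype=float)).all():
        raise ValueError("ranking metric must be finite")
    # stable sort keeps input order among ties (documented tie-break)
    return metric.sort_values(ascending=False, kind="stable")


def ora_test(hits, gene_set: GeneSet, universe) -> tuple[float, int]:
    """Hypergeometric upper-tail over-representation p-value and overlap."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    hits = set(hits) & universe
    members = gene_set.members & universe
    if not members:
        raise ValueError(f"gene set {gene_set.name!r} has no genes in the universe")
    overlap = len(hits & members)
    # P[X >= overlap], X ~ Hypergeom(M=|U|, K=|set|, n=|hits|)
    p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(members), len(hits)))
    return min(p, 1.0), overlap


def ora_table(hits, gene_sets: list[GeneSet], universe) -> pd.DataFrame:
    rows = []
    for gs in gene_sets:
        try:
            p, k = ora_test(hits, gs, universe)
        except ValueError:
            continue
        rows.append({"set": gs.name, "overlap": k, "p_value": p})
    out = pd.DataFrame(rows).set_index("set")
    if not out.empty:
        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def gsea_enrichment_score(
    ranked: pd.Series, gene_set: GeneSet, weight_exponent: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted KS enrichment score and the full running-sum profile.

    ``ranked`` maps gene ids (ordered, descending metric) to metric values.
    ES is the running-sum value of largest magnitude; at weight 0 the sum
    returns to 0 at the end of the list.
    """
    genes = np.asarray(ranked.index)
    metric = ranked.to_numpy(dtype=float)
    is_hit = np.isin(genes, list(gene_set.members))
    n_hits = int(is_hit.sum())
    n = len(genes)
    if n_hits == 0:
        raise ValueError(f"no member of {gene_set.name!r} appears in the ranked list")
    if n_hits == n:
        raise ValueError("gene set covers the whole ranked list")
    weights = np.abs(metric) ** weight_exponent
    hit_total = weights[is_hit].sum()
    if hit_total == 0:
        # all-hit metrics are zero: fall back to equal weights
        steps_hit = np.where(is_hit, 1.0 / n_hits, 0.0)
    else:
        steps_hit = np.where(is_hit, weights / hit_total, 0.0)
    steps = steps_hit - np.where(is_hit, 0.0, 1.0 / (n - n_hits))
    running = np.cumsum(steps)
    es = float(running[np.argmax(np.abs(running))])
    return es, running


def gsea_significance(
    ranked: pd.Series,
    gene_set: GeneSet,
    n_perm: int = 1000,
    seed: int | None = None,
    weight_exponent: float = 1.0,
) -> dict:
    """Permutation NES and p for one set via random same-size member labels."""
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)
    es, _ = gsea_enrichment_score(ranked, gene_set, weight_exponent)
    size = len(set(ranked.index) & gene_set.members)
    genes = list(ranked.index)
    null = np.empty(n_perm)
    for i in range(n_perm):
        draw = rng.choice(len(genes), size=size, replace=False)
        fake = GeneSet(f"_perm{i}", frozenset(genes[j] for j in draw))
        null[i], _ = gsea_enrichment_score(ranked, fake, weight_exponent)
    same_sign = null[null >= 0] if es >= 0 else null[null < 0]
    denom = np.abs(same_sign).mean() if len(same_sign) else np.abs(null).mean()
    nes = es / denom if denom > 0 else np.nan
    if es >= 0:
        p = (1 + int((null >= es).sum())) / (n_perm + 1)
    else:
        p = (1 + int((null <= es).sum())) / (n_perm + 1)
    return {"es": es, "nes": float(nes), "p_value": float(p), "null": null}


def gsea_table(
    ranked: pd.Series,
    gene_sets: list[GeneSet],
    n_perm: int = 1000,
    seed: int | None = None,
    weight_exponent: float = 1.0,
) -> pd.DataFrame:
    """ES/NES/p/q for every set with at least one ranked member."""
    rng = np.random.default_rng(seed)
    rows = []
    for gs in gene_sets:
        try:
            res = gsea_significance(
                ranked, gs, n_perm=n_perm,
                seed=int(rng.integers(2**31)), weight_exponent=weight_exponent,
            )
        except ValueError:
            continue
        rows.append({"set": gs.name, "es": res["es"], "nes": res["nes"],
                     "p_value": res["p_value"],
                     "overlap": len(set(ranked.index) & gs.members)})
    out = pd.DataFrame(rows).set_index("set") if rows else pd.DataFrame()
    if not out.empty:
        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out
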