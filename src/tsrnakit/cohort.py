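"""Cohort-level statistics for tsRNA expression studies.

Implements the analyses run on a tumor/non-tumor cohort with survival and
molecular-pathology annotation:

* two-group differential expression on log2(RPM + 1) (Welch t by default),
* median split of a fragment's expression into low/high groups,
* Kaplan-Meier product-limit curves and the log-rank test (own
  implementation of the observed-vs-expected form with hypergeometric
  variance at each distinct death time),
* Pearson chi-square association of expression group with a categorical
  pathology feature (no continuity correction),
* fragment-to-mRNA correlation (Pearson or Spearman) with t-approximation
  p-values,
* deterministic average-linkage hierarchical clustering under the
  1 - Pearson distance, for heatmap export.

Multiple testing within each call uses Benjamini-Hochberg.

Sample annotation is carried as a pandas DataFrame indexed by sample_id with
columns ``group`` (tumor | nontumor), optional ``survival_time`` (days) and
``event`` (0/1), plus arbitrary categorical feature columns (IDH status,
1p19q codeletion, subtype, grade, MGMT, sex, ...).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "load_cohort_annotation",
    "differential_expression",
    "median_split",
    "km_estimate",
    "logrank_test",
    "km_logrank",
    "chisq_association",
    "correlate_with_mrna",
    "hierarchical_cluster",
]


def load_cohort_annotation(path) -> pd.DataFrame:
    """Read the per-sample annotation TSV keyed by sample_id."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}).set_index("sample_id")
    if "survival_time" in df.columns:
        bad = df["survival_time"].dropna() < 0
        if bad.any():
            raise ValueError(f"negative survival_time for {list(bad.index[bad])}")
        if "event" in df.columns:
            orphans = df["event"].notna() & df["survival_time"].isna()
            if orphans.any():
                raise ValueError("event recorded without survival_time")
    return df


def differential_expression(
    matrix,
    annotation: pd.DataFrame,
    *,
    group_col: str = "group",
    groups: tuple[str, str] = ("tumor", "nontumor"),
    pseudocount: float = 1.0,
    welch: bool = True,
) -> pd.DataFrame:
    """Per-fragment two-group test on log2(RPM + pseudocount).

    ``effect`` is mean(groups[0]) - mean(groups[1]) in log2 units, so a
    negative value means down-regulation in the first (tumor) group.  Welch's
    unequal-variance t is the default; ``welch=False`` gives the pooled test.
    Degenerate rows (zero variance in a group of n=2) get a variance floor of
    1e-12 and are flagged in the ``degenerate`` column.
    """
    data = matrix.data if hasattr(matrix, "data") else matrix
    a_ids = annotation.index[annotation[group_col] == groups[0]]
    b_ids = annotation.index[annotation[group_col] == groups[1]]
    a_ids = [s for s in a_ids if s in data.columns]
    b_ids = [s for s in b_ids if s in data.columns]
    if len(a_ids) < 2 or len(b_ids) < 2:
        raise ValueError("both groups need at least 2 samples")
    a = np.log2(data[a_ids].to_numpy(dtype=float) + pseudocount)
    b = np.log2(data[b_ids].to_numpy(dtype=float) + pseudocount)

    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    na, nb = a.shape[1], b.shape[1]
    degenerate = ((va == 0) & (na == 2)) | ((vb == 0) & (nb == 2))
    va = np.maximum(va, 1e-12)
    vb = np.maximum(vb, 1e-12)
    if welch:
        se2 = va / na + vb / nb
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        t = (ma - mb) / np.sqrt(sp2 * (1 / na + 1 / nb))
        df = np.full_like(t, na + nb - 2, dtype=float)
    p = 2 * stats.t.sf(np.abs(t), df)
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "statistic": t,
            "p_value": p,
            "effect": ma - mb,
            "q_value": q,
            "degenerate": degenerate,
        },
        index=data.index.rename("item_id"),
    )


def median_split(values: pd.Series) -> pd.Series:
    """Label each sample low/high at the median; ties go to the low group."""
    values = pd.Series(values)
    if len(values) < 2:
        raise ValueError("median split needs at least 2 samples")
    med = values.median()
    labels = pd.Series(
        np.where(values > med, "high", "low"), index=values.index, name="expr_group"
    )
    if (labels == "low").all():
        warnings.warn("all values at or below the median: every sample labeled low")
    return labels


def km_estimate(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit curve: (time, at_risk, events, survival)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    rows = []
    surv = 1.0
    n = len(t)
    for ti in np.unique(t):
        at = t == ti
        n_risk = int((t >= ti).sum())
        d = int(e[at].sum())
        if d > 0:
            surv *= 1.0 - d / n_risk
        rows.append({"time": ti, "at_risk": n_risk, "events": d, "survival": surv})
    return pd.DataFrame(rows)


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank test, (O-E)^2/V form with hypergeometric variance.

    Tied deaths at one time are counted together.  Returns (chi2, p) with 1
    degree of freedom; with no events at all the result is (nan, nan) with a
    warning.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    labels = np.unique(g)
    if len(labels) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {list(labels)}")
    if e.sum() == 0:
        warnings.warn("no events: log-rank statistic undefined (NA)")
        return float("nan"), float("nan")
    death_times = np.unique(t[e == 1])
    in_a = g == labels[0]
    o_minus_e = 0.0
    var = 0.0
    for ti in death_times:
        at_risk = t >= ti
        n = at_risk.sum()
        n_a = (at_risk & in_a).sum()
        d = ((t == ti) & (e == 1)).sum()
        d_a = ((t == ti) & (e == 1) & in_a).sum()
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var == 0:
        warnings.warn("zero log-rank variance: statistic undefined (NA)")
        return float("nan"), float("nan")
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def km_logrank(times, events, groups) -> dict:
    """KM curves per group plus the log-rank comparison."""
    g = np.asarray(groups)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    curves = {
        str(lab): km_estimate(t[g == lab], e[g == lab]) for lab in np.unique(g)
    }
    stat, p = logrank_test(t, e, g)
    return {"curves": curves, "statistic": stat, "p_value": p}


def chisq_association(expr_group, feature) -> dict:
    """Pearson chi-square (no continuity correction) of group vs feature.

    Returns statistic, df, p, the observed table, and a low-expected-count
    flag (any expected cell below 5).
    """
    table = pd.crosstab(pd.Series(expr_group, name="expr_group"),
                        pd.Series(feature, name="feature"))
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError(f"contingency table must be at least 2x2:\n{table}")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError(f"zero margin in contingency table:\n{table}")
    chi2, p, df, expected = stats.chi2_contingency(table.to_numpy(), correction=False)
    low = bool((expected < 5).any())
    if low:
        warnings.warn("expected count below 5 in the contingency table")
    return {
        "statistic": float(chi2),
        "df": int(df),
        "p_value": float(p),
        "table": table,
        "low_expected": low,
    }


def correlate_with_mrna(
    fragment_values: pd.Series,
    mrna: pd.DataFrame,
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlate one fragment's expression with every mRNA row.

    ``mrna`` is genes x samples; only samples shared with ``fragment_values``
    are used (missing values dropped pairwise per gene, needing >= 3 pairs).
    p-values use the t approximation t = r*sqrt((n-2)/(1-r^2)); constant
    vectors give NaN and are flagged.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be pearson or spearman")
    shared = [s for s in mrna.columns if s in fragment_values.index]
    x = fragment_values.loc[shared].astype(float)
    rows = []
    for gene, y in mrna[shared].iterrows():
        pair = pd.concat([x, y.astype(float)], axis=1).dropna()
        n = len(pair)
        if n < 3:
            rows.append((gene, np.nan, np.nan, np.nan, "too_few_pairs"))
            continue
        xv, yv = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
        if np.std(xv) == 0 or np.std(yv) == 0:
            rows.append((gene, np.nan, np.nan, np.nan, "constant"))
            continue
        if method == "spearman":
            xv = stats.rankdata(xv)
            yv = stats.rankdata(yv)
        r = float(np.corrcoef(xv, yv)[0, 1])
        if abs(r) >= 1.0:
            p = 0.0
        else:
            tval = r * np.sqrt((n - 2) / (1 - r**2))
            p = float(2 * stats.t.sf(abs(tval), n - 2))
        rows.append((gene, r, tval if abs(r) < 1 else np.inf * np.sign(r), p, ""))
    out = pd.DataFrame(
        rows, columns=["item_id", "effect", "statistic", "p_value", "flag"]
    ).set_index("item_id")
    ok = out["p_value"].notna()
    q = pd.Series(np.nan, index=out.index)
    if ok.any():
        q[ok] = multipletests(out.loc[ok, "p_value"], method="fdr_bh")[1]
    out["q_value"] = q
    return out


def _correlation_distance(data: np.ndarray) -> np.ndarray:
    """1 - Pearson between rows; zero-variance rows sit at distance 1."""
    n = data.shape[0]
    sd = data.std(axis=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance rows: distance to them set to 1")
    d = np.ones((n, n))
    ok = ~flat
    if ok.sum() >= 2:
        c = np.corrcoef(data[ok])
        d[np.ix_(ok, ok)] = 1 - c
    np.fill_diagonal(d, 0.0)
    return d


def hierarchical_cluster(matrix: pd.DataFrame) -> dict:
    """Average-linkage agglomeration under the 1 - Pearson row distance.

    Deterministic: at each step the minimum-distance pair merges, ties broken
    by the lower (then lower second) cluster index.  Returns the merge list
    [(i, j, height, size), ...] in scipy's newly-formed-cluster indexing and
    the left-to-right leaf order for heatmap rendering.
    """
    data = matrix.to_numpy(dtype=float)
    n = data.shape[0]
    if n < 2:
        raise ValueError("clustering needs at least 2 rows")
    d = _correlation_distance(data)
    # active clusters: id -> (member leaf set, current row in dist structure)
    dist: dict[tuple[int, int], float] = {
        (i, j): d[i, j] for i in range(n) for j in range(i + 1, n)
    }
    sizes = {i: 1 for i in range(n)}
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    active = set(range(n))
    merges = []
    next_id = n
    while len(active) > 1:
        best = min(
            ((dist[(min(i, j), max(i, j))], i, j)
             for i in active for j in active if i < j),
        )
        h, i, j = best
        merges.append((i, j, h, sizes[i] + sizes[j]))
        # UPGMA update: size-weighted average distance to the new cluster
        for k in active - {i, j}:
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            dist[(min(next_id, k), max(next_id, k))] = (
                sizes[i] * dik + sizes[j] * djk
            ) / (sizes[i] + sizes[j])
        sizes[next_id] = sizes[i] + sizes[j]
        members[next_id] = members[i] + members[j]
        active -= {i, j}
        active.add(next_id)
        next_id += 1
    (root,) = active
    leaf_order = members[root]
    return {
        "merges": merges,
        "leaf_order": [str(matrix.index[i]) for i in leaf_order],
        "leaf_indices": leaf_order,
    }
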