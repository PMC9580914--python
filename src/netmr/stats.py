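"""Downstream statistics: pathway enrichment and survival analysis.

Hypergeometric over-representation of a query gene list in GMT collections
(BH-adjusted across the collection), Kaplan-Meier curves and the log-rank
test (via lifelines), a Mantel-Haenszel O/E hazard-ratio summary, and the
median-split grouping of samples by mean expression of a gene set.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .sigtools import GeneSignature

__all__ = [
    "hypergeom_enrich",
    "km_curve",
    "logrank_test",
    "split_by_expression",
]


def hypergeom_enrich(
    query: Iterable[str],
    collection: Sequence[GeneSignature] | Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``query`` in each gene set.

    Every set (and the query) is intersected with the universe first.
    Returns a frame with columns ``set, k, K, n, N, p, fdr`` where p is
    P(X >= k) for X ~ Hypergeometric(N, K, n) and fdr is BH across the
    collection.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    query = set(query) & universe
    if isinstance(collection, Mapping):
        items = list(collection.items())
    else:
        items = [(s.name, s.genes) for s in collection]
    rows = []
    for name, genes in items:
        genes = set(genes) & universe
        k = len(query & genes)
        K, n, N = len(genes), len(query), len(universe)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        rows.append((name, k, K, n, N, p))
    out = pd.DataFrame(rows, columns=["set", "k", "K", "n", "N", "p"])
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1] if len(out) else []
    return out


def _surv_subset(surv: pd.DataFrame, group: Iterable[str]) -> pd.DataFrame:
    group = set(group)
    sub = surv[surv["sample"].isin(group)]
    missing = group - set(sub["sample"])
    if missing:
        raise KeyError(f"samples absent from survival table: {sorted(missing)[:5]}")
    return sub


def km_curve(surv: pd.DataFrame, group: Iterable[str]) -> pd.DataFrame:
    """Kaplan-Meier product-limit curve for one sample group.

    Returns a step function as a frame with columns ``time`` and
    ``survival``; S(0) = 1 and the curve is non-increasing.  Censored times
    only reduce the risk set.
    """
    sub = _surv_subset(surv, group)
    if len(sub) == 0:
        raise ValueError("empty group")
    kmf = KaplanMeierFitter()
    kmf.fit(sub["time"], event_observed=sub["event"])
    sf = kmf.survival_function_
    return pd.DataFrame(
        {"time": sf.index.to_numpy(float), "survival": sf.iloc[:, 0].to_numpy(float)}
    )


def _oe_hazard_ratio(
    time_a: np.ndarray, event_a: np.ndarray, time_b: np.ndarray, event_b: np.ndarray
) -> float:
    """Mantel-Haenszel (O_a/E_a)/(O_b/E_b) over the pooled event times."""
    o_a = float(event_a.sum())
    o_b = float(event_b.sum())
    event_times = np.unique(np.concatenate([time_a[event_a == 1], time_b[event_b == 1]]))
    e_a = 0.0
    e_b = 0.0
    for t in event_times:
        na = float((time_a >= t).sum())
        nb = float((time_b >= t).sum())
        d = float((event_a[time_a == t] == 1).sum() + (event_b[time_b == t] == 1).sum())
        if na + nb > 0:
            e_a += d * na / (na + nb)
            e_b += d * nb / (na + nb)
    if e_a == 0 or e_b == 0 or o_b == 0:
        return float("nan")
    return (o_a / e_a) / (o_b / e_b)


def logrank_test(
    surv: pd.DataFrame, group_a: Iterable[str], group_b: Iterable[str]
) -> tuple[float, float, float]:
    """Log-rank test between two sample groups.

    Returns ``(chi2, p, hr)`` where hr is the Mantel-Haenszel observed/
    expected hazard-ratio summary of group A relative to group B.  Requires
    disjoint groups and at least one event overall.
    """
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    a = _surv_subset(surv, group_a)
    b = _surv_subset(surv, group_b)
    if a["event"].sum() + b["event"].sum() == 0:
        raise ValueError("no events in either group; log-rank p undefined")
    res = _ll_logrank(
        a["time"], b["time"], event_observed_A=a["event"], event_observed_B=b["event"]
    )
    hr = _oe_hazard_ratio(
        a["time"].to_numpy(float),
        a["event"].to_numpy(int),
        b["time"].to_numpy(float),
        b["event"].to_numpy(int),
    )
    return float(res.test_statistic), float(res.p_value), hr


def split_by_expression(
    matrix: pd.DataFrame, genes: Iterable[str]
) -> tuple[list[str], list[str]]:
    """Median split of samples by mean expression of a gene set.

    Each sample is scored by the mean expression of ``genes``; samples above
    the median score form the high group, ties go to low.  A degenerate split
    (all scores equal) raises.
    """
    genes = sorted(set(genes))
    missing = [g for g in genes if g not in matrix.index]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing[:10]}")
    score = matrix.loc[genes].mean(axis=0)
    med = float(score.median())
    high = score.index[score > med].tolist()
    low = score.index[score <= med].tolist()
    if not high:
        raise ValueError("degenerate split: all scores at or below the median")
    return high, low
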