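"""Per-cohort master-regulator calling.

Pipeline: score every sample's signature enrichment with a within-sample
rank-sum z, take the k most and least enriched samples, form a gene-level
differential signature (per-gene rank-sum z, extremes high vs low), and test
every regulon for enrichment in that signature with a mode-signed,
MI-weighted normalized enrichment score (NES).  A regulator is "activated"
when NES > 0 with p < alpha, "repressed" when NES < 0 with p < alpha.

The NES statistic is a two-tail, mode-signed, interaction-weighted enrichment
of the gene-level z-scores: NES = sum_t v_t z_t / sqrt(v' P v), where
v_t = w_t m_t combines an MI-proportional weight w_t (0 for
mode-undetermined edges) with the mode m_t in {-1, +1}.  The gene-level
scores are two-sample rank-sum z-values, already standard normal under the
per-gene null, so no further cross-gene transform is applied.  P is the
Spearman correlation matrix of the regulon's targets across the cohort:
targets of one regulator are co-expressed, so their gene-level scores
fluctuate together under reassignment of the extreme groups, and treating
them as independent (P = I) would overdisperse the score several-fold.  The
correlation-adjusted denominator restores the calibration a sample-
permutation null would provide; for independent targets it reduces to
sqrt(sum_t w_t^2).  Under the null, NES is standard normal and
p = 2 Phi(-|NES|).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .netinf import RegulatoryNetwork, validate_expression
from .sigtools import GeneSignature

logger = logging.getLogger(__name__)

__all__ = [
    "StratConfig",
    "sample_enrichment_score",
    "signature_scores",
    "select_extremes",
    "differential_signature",
    "regulon_enrichment",
    "call_master_regulators",
]

MR_COLUMNS = ["regulator", "cohort", "nes", "p", "direction", "regulon_size"]


@dataclass
class StratConfig:
    """Stratification and calling parameters.

    k_extreme
        Number of samples in each extreme group (default 50, i.e. the 50
        highest- and 50 lowest-enrichment samples).
    mr_alpha
        Two-sided p cutoff on the NES for calling a regulator (default 0.01).
    min_cohort_n
        Smallest cohort the call is allowed on (default 100).
    min_regulon
        Regulons with fewer scored targets are skipped (default 10).
    """

    k_extreme: int = 50
    mr_alpha: float = 0.01
    min_cohort_n: int = 100
    min_regulon: int = 10

    def __post_init__(self) -> None:
        if self.k_extreme < 1:
            raise ValueError("k_extreme must be positive")
        if not (0.0 < self.mr_alpha < 1.0):
            raise ValueError("mr_alpha must lie in (0, 1)")


# ---------------------------------------------------------------------------
# Rank-sum machinery
# ---------------------------------------------------------------------------

def _tie_term(ranks_2d: np.ndarray) -> np.ndarray:
    """sum(t^3 - t) over tie groups for each row of a rank matrix."""
    out = np.zeros(ranks_2d.shape[0])
    for i, row in enumerate(ranks_2d):
        _, counts = np.unique(row, return_counts=True)
        t = counts[counts > 1].astype(float)
        out[i] = (t**3 - t).sum()
    return out


def _ranksum_z(rank_sum: np.ndarray, n1: int, n2: int, ties: np.ndarray) -> np.ndarray:
    """Mann-Whitney normal-approximation z from group-1 rank sums.

    Positive when group 1 holds higher ranks; tie-corrected sigma.
    """
    n = n1 + n2
    u = rank_sum - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - ties / (n * (n - 1)))
    sigma = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sigma > 0, (u - mu) / sigma, 0.0)
    return z


def signature_scores(matrix: pd.DataFrame, signature: GeneSignature) -> pd.Series:
    """Per-sample signature enrichment scores (vectorized over samples).

    Within each sample, all genes are midranked and the up-genes are compared
    to every remaining gene by the Mann-Whitney rank-sum z; with a down part,
    the score is z_up - z_down.
    """
    validate_expression(matrix)
    universe = matrix.index
    up = [g for g in signature.up if g in universe]
    down = [g for g in signature.down if g in universe]
    if not (up or down):
        raise ValueError("no signature gene present in the matrix")
    if len(signature.genes & set(universe)) >= len(universe):
        raise ValueError("signature covers the whole gene universe")

    ranks = sps.rankdata(matrix.to_numpy(float), axis=0)  # within-sample ranks
    ties = _tie_term(ranks.T)
    n_genes = matrix.shape[0]

    def part_z(part: list[str]) -> np.ndarray:
        rows = universe.get_indexer(part)
        rank_sum = ranks[rows].sum(axis=0)
        return _ranksum_z(rank_sum, len(part), n_genes - len(part), ties)

    score = part_z(up) if up else 0.0
    if down:
        score = score - part_z(down)
    return pd.Series(score, index=matrix.columns, name="enrichment")


def sample_enrichment_score(
    sample_values: pd.Series, signature: GeneSignature
) -> float:
    """Signature enrichment score of a single sample (see
    :func:`signature_scores`)."""
    frame = sample_values.to_frame("s")
    frame["pad"] = sample_values  # validate_expression needs >= 2 columns
    return float(signature_scores(frame, signature).iloc[0])


def select_extremes(scores: pd.Series, k: int) -> tuple[list[str], list[str]]:
    """The k highest- and k lowest-scoring samples.

    Samples are put in one ascending order by (score, sample id); the low
    group is the first k, the high group the last k, making boundary ties
    deterministic.
    """
    n = len(scores)
    if 2 * k > n:
        raise ValueError(
            f"2*k = {2 * k} exceeds the {n} available samples; lower k_extreme"
        )
    order = scores.reset_index()
    order.columns = ["sample", "score"]
    order = order.sort_values(["score", "sample"], kind="mergesort")
    ids = order["sample"].tolist()
    return ids[-k:], ids[:k]


def differential_signature(
    matrix: pd.DataFrame, high: list[str], low: list[str]
) -> pd.Series:
    """Per-gene two-sample rank-sum z (high vs low), positive when the gene
    is higher in the high group."""
    high = sorted(set(high))
    low = sorted(set(low))
    if set(high) & set(low):
        raise ValueError("high and low groups overlap")
    if len(high) < 3 or len(low) < 3:
        raise ValueError("each group needs >= 3 samples")
    sub = matrix[high + low].to_numpy(float)
    ranks = sps.rankdata(sub, axis=1)  # within gene, across pooled samples
    ties = _tie_term(ranks)
    rank_sum = ranks[:, : len(high)].sum(axis=1)
    z = _ranksum_z(rank_sum, len(high), len(low), ties)
    return pd.Series(z, index=matrix.index, name="diff_z")


# ---------------------------------------------------------------------------
# Regulon enrichment
# ---------------------------------------------------------------------------

def _target_correlation(expression: pd.DataFrame, targets: list[str]) -> np.ndarray:
    """Spearman correlation matrix of target rows across the cohort."""
    ranks = sps.rankdata(expression.loc[targets].to_numpy(float), axis=1)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((ranks**2).sum(axis=1))
    norms[norms == 0] = 1.0
    ranks /= norms[:, None]
    return ranks @ ranks.T


def _nes(
    diff: pd.Series,
    regulon: pd.DataFrame,
    min_regulon: int,
    expression: pd.DataFrame | None = None,
) -> tuple[float, float, int] | None:
    present = regulon[regulon["target"].isin(diff.index)]
    if len(present) < min_regulon:
        return None
    w = present["weight"].to_numpy(float)
    wmax = w.max()
    if wmax > 0:
        w = w / wmax
    v = w * present["mode"].to_numpy(float)
    if expression is not None:
        corr = _target_correlation(expression, present["target"].tolist())
        var = float(v @ corr @ v)
        # the correlation matrix is PSD; guard only against degenerate zeros
        var = max(var, 1e-4 * float((v**2).sum()))
    else:
        var = float((v**2).sum())
    if var <= 0:
        return None
    zt = diff.loc[present["target"]].to_numpy(float)
    nes = float((v * zt).sum() / math.sqrt(var))
    p = float(2.0 * sps.norm.sf(abs(nes)))
    return nes, p, len(present)


def regulon_enrichment(
    diff: pd.Series,
    regulon: pd.DataFrame,
    min_regulon: int = 10,
    expression: pd.DataFrame | None = None,
):
    """NES and two-sided p of one regulon against a gene-level signature.

    ``regulon`` is an edge table with columns ``target``, ``mode`` and
    ``weight`` (MI; weight-0 edges are excluded from weighting but count
    toward regulon size).  When ``expression`` is given, the variance of the
    score accounts for the inter-target Spearman correlation estimated from
    it; otherwise targets are assumed independent.  Returns ``(nes, p)`` or
    ``None`` when fewer than ``min_regulon`` targets are scored.
    """
    res = _nes(diff, regulon, min_regulon, expression)
    if res is None:
        return None
    return res[0], res[1]


def call_master_regulators(
    matrix: pd.DataFrame,
    network: RegulatoryNetwork,
    signature: GeneSignature,
    config: StratConfig = StratConfig(),
    cohort_id: str = "cohort",
) -> pd.DataFrame:
    """Call activated and repressed master regulators in one cohort.

    Returns a frame with columns ``regulator, cohort, nes, p, direction,
    regulon_size``; ``direction`` is ``activated``/``repressed``/``none``
    according to the sign of the NES at ``mr_alpha``.
    """
    if matrix.shape[1] < config.min_cohort_n:
        raise ValueError(
            f"cohort has {matrix.shape[1]} samples; minimum is {config.min_cohort_n}"
        )
    if len(network) == 0:
        raise ValueError("empty regulatory network")

    scores = signature_scores(matrix, signature)
    high, low = select_extremes(scores, config.k_extreme)
    diff = differential_signature(matrix, high, low)

    rows = []
    for reg, regulon in network.regulons().items():
        res = _nes(diff, regulon, config.min_regulon, expression=matrix)
        if res is None:
            logger.info("regulator %s skipped: fewer than %d scored targets",
                        reg, config.min_regulon)
            continue
        nes, p, size = res
        if p < config.mr_alpha:
            direction = "activated" if nes > 0 else "repressed"
        else:
            direction = "none"
        rows.append((reg, cohort_id, nes, p, direction, size))
    return pd.DataFrame(rows, columns=MR_COLUMNS)
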