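"""Inference of signed transcriptional regulatory networks from expression data.

The approach follows the classic mutual-information (MI) reverse-engineering
recipe: estimate MI between every candidate regulator and every gene with an
adaptive-partitioning estimator on rank-transformed data, keep pairs whose MI
exceeds a permutation-calibrated significance threshold, prune likely indirect
edges with the data-processing inequality (DPI), repeat over bootstrap
resamples of the samples, and retain edges with significant bootstrap support
under a Poisson consensus model.  A mode of regulation (+1 activating, -1
repressing) is assigned to each surviving edge from the sign of the
regulator-target Spearman correlation.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numba as nb
import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "NetInfConfig",
    "RegulatoryNetwork",
    "estimate_mi",
    "calibrate_threshold",
    "apply_dpi",
    "assign_modes",
    "infer_network",
    "read_expression",
    "write_expression",
    "read_network",
    "write_network",
]

# chi-square(3 df) critical value at p=0.05; a 2x2 refinement of a cell is
# accepted only while this uniformity test rejects
_CHI2_SPLIT = 7.815

EDGE_COLUMNS = ["regulator", "target", "mi", "mode", "support", "weight"]


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def validate_expression(matrix: pd.DataFrame) -> pd.DataFrame:
    """Validate a genes x samples expression matrix.

    Requires unique (case-sensitive) gene ids, unique sample ids, at least two
    samples and no missing values.
    """
    if matrix.index.has_duplicates:
        dup = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dup[:5]}")
    if matrix.columns.has_duplicates:
        raise ValueError("duplicate sample ids")
    if matrix.shape[1] < 2:
        raise ValueError("expression matrix needs >= 2 samples")
    if matrix.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    return matrix


def read_expression(path) -> pd.DataFrame:
    """Read a TSV expression matrix (first column gene symbols, header row
    of sample ids)."""
    mat = pd.read_csv(path, sep="\t", index_col=0)
    mat.index = mat.index.astype(str)
    mat.columns = mat.columns.astype(str)
    return validate_expression(mat)


def write_expression(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene", float_format="%.6g")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class NetInfConfig:
    """Parameters of the network-inference stage.

    mi_pvalue
        Significance level on the permutation null used to calibrate the MI
        edge threshold (default 1e-8).
    n_bootstraps
        Number of sample resamples over which consensus is formed
        (default 100).
    dpi_tolerance
        DPI tolerance in [0, 1]; 0 removes the weakest edge of every
        triangle, 1 disables pruning.
    n_null_pairs
        Number of permuted gene pairs used to sample the MI null.
    regulator_list
        Gene ids treated as candidate regulators (transcription factors and
        signaling genes).  Supplied by the caller; for synthetic cohorts the
        planted regulator set is the natural choice.
    consensus_alpha
        Family-wise (Bonferroni) significance of the Poisson bootstrap
        consensus test.  ``None`` disables consensus filtering, keeping any
        edge seen in at least one bootstrap.
    seed
        Seed for permutation and bootstrap sampling.
    """

    regulator_list: Sequence[str] = field(default_factory=list)
    mi_pvalue: float = 1e-8
    n_bootstraps: int = 100
    dpi_tolerance: float = 0.0
    n_null_pairs: int = 100_000
    consensus_alpha: float | None = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.mi_pvalue < 1.0):
            raise ValueError("mi_pvalue must lie in (0, 1)")
        if self.n_bootstraps < 1:
            raise ValueError("n_bootstraps must be >= 1")
        if not (0.0 <= self.dpi_tolerance <= 1.0):
            raise ValueError("dpi_tolerance must lie in [0, 1]")


@dataclass
class RegulatoryNetwork:
    """A set of signed, weighted regulator->target edges.

    ``edges`` is a data frame with columns ``regulator, target, mi, mode,
    support, weight``; ``weight`` equals ``mi`` except for edges whose mode
    could not be determined (constant rows, zero correlation), which carry
    weight 0 and are excluded from enrichment weighting downstream.
    """

    edges: pd.DataFrame
    regulators: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in ("regulator", "target", "mi") if c not in self.edges.columns]
        if missing:
            raise ValueError(f"edge table lacks columns {missing}")
        e = self.edges
        if (e["mi"] < 0).any():
            raise ValueError("negative MI weight")
        if (e["regulator"] == e["target"]).any():
            raise ValueError("self-edge present")
        if e.duplicated(["regulator", "target"]).any():
            raise ValueError("duplicate (regulator, target) pair")
        for col, default in (("mode", 1), ("support", 0), ("weight", np.nan)):
            if col not in e.columns:
                e[col] = default
        e["weight"] = e["weight"].fillna(e["mi"])
        if not self.regulators:
            self.regulators = sorted(e["regulator"].unique().tolist())

    def __len__(self) -> int:
        return len(self.edges)

    def regulons(self) -> dict[str, pd.DataFrame]:
        """Per-regulator target tables."""
        return {r: g.reset_index(drop=True) for r, g in self.edges.groupby("regulator")}


def write_network(network: RegulatoryNetwork, path, extended: bool = True) -> None:
    """Write a network TSV (columns Regulator, Target, MI; the extended
    dialect adds Mode, Support and Weight)."""
    e = network.edges
    out = pd.DataFrame(
        {"Regulator": e["regulator"], "Target": e["target"], "MI": e["mi"]}
    )
    if extended:
        out["Mode"] = e["mode"].astype(int)
        out["Support"] = e["support"].astype(int)
        out["Weight"] = e["weight"]
    out.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_network(path) -> RegulatoryNetwork:
    tab = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in tab.columns}
    for need in ("regulator", "target", "mi"):
        if need not in cols:
            raise ValueError(f"network file lacks column {need!r}")
    edges = pd.DataFrame(
        {
            "regulator": tab[cols["regulator"]].astype(str),
            "target": tab[cols["target"]].astype(str),
            "mi": tab[cols["mi"]].astype(float),
        }
    )
    if "mode" in cols:
        edges["mode"] = tab[cols["mode"]].astype(int)
    if "support" in cols:
        edges["support"] = tab[cols["support"]].astype(int)
    if "weight" in cols:
        edges["weight"] = tab[cols["weight"]].astype(float)
    return RegulatoryNetwork(edges)


# ---------------------------------------------------------------------------
# Mutual information (adaptive partitioning)
# ---------------------------------------------------------------------------

@nb.njit(cache=True)
def _apmi(rx, ry):  # pragma: no cover - exercised through estimate_mi
    """Adaptive-partitioning MI (nats) of two rank vectors scaled to (0,1).

    Recursively quarters the unit square while the 2x2 chi-square uniformity
    test rejects (chi2 > 7.815) and every quadrant holds >= 2 points; the MI
    is summed over the leaf cells, with marginal cell probabilities given by
    the cell side lengths (exact for rank-uniform margins).
    """
    n = rx.shape[0]
    idx = np.empty(n, np.int64)
    for i in range(n):
        idx[i] = i
    buf = np.empty(n, np.int64)
    cap = 4 * n + 64
    lo_s = np.empty(cap, np.int64)
    hi_s = np.empty(cap, np.int64)
    x0_s = np.empty(cap, np.float64)
    x1_s = np.empty(cap, np.float64)
    y0_s = np.empty(cap, np.float64)
    y1_s = np.empty(cap, np.float64)
    lo_s[0] = 0
    hi_s[0] = n
    x0_s[0] = 0.0
    x1_s[0] = 1.0
    y0_s[0] = 0.0
    y1_s[0] = 1.0
    sp = 1
    mi = 0.0
    while sp > 0:
        sp -= 1
        lo = lo_s[sp]
        hi = hi_s[sp]
        x0 = x0_s[sp]
        x1 = x1_s[sp]
        y0 = y0_s[sp]
        y1 = y1_s[sp]
        m = hi - lo
        xm = 0.5 * (x0 + x1)
        ym = 0.5 * (y0 + y1)
        n1 = 0
        n2 = 0
        n3 = 0
        n4 = 0
        for t in range(lo, hi):
            p = idx[t]
            if rx[p] < xm:
                if ry[p] < ym:
                    n1 += 1
                else:
                    n2 += 1
            else:
                if ry[p] < ym:
                    n3 += 1
                else:
                    n4 += 1
        split = False
        if n1 >= 2 and n2 >= 2 and n3 >= 2 and n4 >= 2:
            e = m / 4.0
            chi2 = ((n1 - e) ** 2 + (n2 - e) ** 2 + (n3 - e) ** 2 + (n4 - e) ** 2) / e
            if chi2 > _CHI2_SPLIT:
                split = True
        if split:
            # stable partition of idx[lo:hi] into the four quadrants
            c1 = 0
            c2 = n1
            c3 = n1 + n2
            c4 = n1 + n2 + n3
            for t in range(lo, hi):
                p = idx[t]
                if rx[p] < xm:
                    if ry[p] < ym:
                        buf[c1] = p
                        c1 += 1
                    else:
                        buf[c2] = p
                        c2 += 1
                else:
                    if ry[p] < ym:
                        buf[c3] = p
                        c3 += 1
                    else:
                        buf[c4] = p
                        c4 += 1
            for t in range(m):
                idx[lo + t] = buf[t]
            # push children: (x-range, y-range, idx-range)
            b0 = lo
            b1 = lo + n1
            b2 = lo + n1 + n2
            b3 = lo + n1 + n2 + n3
            lo_s[sp] = b0
            hi_s[sp] = b1
            x0_s[sp] = x0
            x1_s[sp] = xm
            y0_s[sp] = y0
            y1_s[sp] = ym
            sp += 1
            lo_s[sp] = b1
            hi_s[sp] = b2
            x0_s[sp] = x0
            x1_s[sp] = xm
            y0_s[sp] = ym
            y1_s[sp] = y1
            sp += 1
            lo_s[sp] = b2
            hi_s[sp] = b3
            x0_s[sp] = xm
            x1_s[sp] = x1
            y0_s[sp] = y0
            y1_s[sp] = ym
            sp += 1
            lo_s[sp] = b3
            hi_s[sp] = hi
            x0_s[sp] = xm
            x1_s[sp] = x1
            y0_s[sp] = ym
            y1_s[sp] = y1
            sp += 1
        elif m > 0:
            pij = m / n
            mi += pij * math.log(pij / ((x1 - x0) * (y1 - y0)))
    if mi < 0.0:
        mi = 0.0
    return mi


@nb.njit(cache=True)
def _apmi_cross(RX, RY, out):  # pragma: no cover
    """MI of every row of RX against every row of RY (rank-scaled inputs)."""
    for i in range(RX.shape[0]):
        for j in range(RY.shape[0]):
            out[i, j] = _apmi(RX[i], RY[j])


@nb.njit(cache=True)
def _apmi_pairs(X, Y, out):  # pragma: no cover
    for k in range(X.shape[0]):
        out[k] = _apmi(X[k], Y[k])


def _rank_scale(values: np.ndarray) -> np.ndarray:
    """Midrank-transform each row and scale ranks to (0, 1)."""
    v = np.asarray(values, dtype=np.float64)
    ranks = sps.rankdata(v, axis=-1, method="average")
    return np.ascontiguousarray((ranks - 0.5) / v.shape[-1])


def estimate_mi(x: Sequence[float], y: Sequence[float]) -> float:
    """Mutual information (nats) between two continuous vectors.

    Adaptive-partitioning estimator on midrank-transformed data; symmetric in
    its arguments and nonnegative.  Requires equal lengths with n >= 8.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 8:
        raise ValueError("MI estimation requires n >= 8")
    return float(_apmi(_rank_scale(x), _rank_scale(y)))


# ---------------------------------------------------------------------------
# Permutation-calibrated threshold
# ---------------------------------------------------------------------------

def _null_mi_sample(
    rank_matrix: np.ndarray, n_pairs: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample the MI null by pairing random genes with one profile permuted."""
    g, n = rank_matrix.shape
    out = np.empty(n_pairs)
    chunk = 4096
    done = 0
    while done < n_pairs:
        m = min(chunk, n_pairs - done)
        ii = rng.integers(0, g, m)
        jj = rng.integers(0, g, m)
        X = rank_matrix[ii]
        Y = np.empty_like(X)
        for k in range(m):
            Y[k] = rank_matrix[jj[k]][rng.permutation(n)]
        _apmi_pairs(np.ascontiguousarray(X), np.ascontiguousarray(Y), out[done : done + m])
        done += m
    return out


def _threshold_from_null(null_mi: np.ndarray, mi_pvalue: float) -> float:
    """Exponential-tail extrapolation of the MI null.

    Fits P(MI > m) ~ a*exp(-b*m) by least squares on the log empirical
    survival of the top 5% of null MIs and solves for the MI at the requested
    tail probability.  Raises on a degenerate (non-decaying) fit.
    """
    null_sorted = np.sort(null_mi)[::-1]
    n = null_sorted.size
    k = max(int(0.05 * n), 20)
    k = min(k, n)
    m_tail = null_sorted[:k]
    if np.ptp(m_tail) < 1e-12:
        raise ValueError("degenerate null-tail fit (constant tail)")
    surv = (np.arange(k) + 1.0) / n
    slope, intercept = np.polyfit(m_tail, np.log(surv), 1)
    b = -slope
    if b <= 0 or not np.isfinite(b):
        raise ValueError("degenerate null-tail fit (non-positive decay rate)")
    return float((intercept - math.log(mi_pvalue)) / b)


def calibrate_threshold(
    matrix: pd.DataFrame,
    config: NetInfConfig,
    rng: np.random.Generator | None = None,
) -> float:
    """MI significance threshold at ``config.mi_pvalue`` on a permutation null.

    Computes MI for ``n_null_pairs`` random gene pairs with one member's
    samples permuted, then extrapolates the null tail with an exponential fit
    (the requested tail probabilities, e.g. 1e-8, lie far beyond the reach of
    any feasible number of permutations).
    """
    validate_expression(matrix)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ranks = _rank_scale(matrix.to_numpy())
    null_mi = _null_mi_sample(ranks, config.n_null_pairs, rng)
    return _threshold_from_null(null_mi, config.mi_pvalue)


# ---------------------------------------------------------------------------
# DPI pruning
# ---------------------------------------------------------------------------

def _dpi_mask(reg: np.ndarray, tgt: np.ndarray, mi: np.ndarray, tolerance: float) -> np.ndarray:
    """Boolean keep-mask after simultaneous DPI marking.

    The network is viewed as an undirected weighted graph; within every
    triangle the edge A-C is marked for removal when
    mi(A,C) < min(mi(A,B), mi(B,C)) * (1 - tolerance), all marks being
    evaluated against the input network before any removal.
    """
    adj: dict[str, dict[str, float]] = {}
    for a, b, w in zip(reg, tgt, mi):
        adj.setdefault(a, {})[b] = w
        adj.setdefault(b, {})[a] = w
    keep = np.ones(len(mi), dtype=bool)
    scale = 1.0 - tolerance
    for k, (a, b, w) in enumerate(zip(reg, tgt, mi)):
        na, nb_ = adj[a], adj[b]
        # iterate over the smaller neighbourhood
        if len(na) > len(nb_):
            na, nb_ = nb_, na
        for c, w_ac in na.items():
            if c == a or c == b:
                continue
            w_bc = nb_.get(c)
            if w_bc is None:
                continue
            if w < min(w_ac, w_bc) * scale:
                keep[k] = False
                break
    return keep


def apply_dpi(network: RegulatoryNetwork, tolerance: float = 0.0) -> RegulatoryNetwork:
    """Prune likely indirect edges with the data-processing inequality."""
    if not (0.0 <= tolerance <= 1.0):
        raise ValueError("tolerance must lie in [0, 1]")
    e = network.edges
    if len(e) == 0:
        return network
    keep = _dpi_mask(
        e["regulator"].to_numpy(), e["target"].to_numpy(), e["mi"].to_numpy(float), tolerance
    )
    return RegulatoryNetwork(e.loc[keep].reset_index(drop=True), list(network.regulators))


# ---------------------------------------------------------------------------
# Mode assignment
# ---------------------------------------------------------------------------

def assign_modes(matrix: pd.DataFrame, network: RegulatoryNetwork) -> RegulatoryNetwork:
    """Sign each edge by the Spearman correlation of regulator and target.

    Edges with zero correlation or a constant profile keep mode +1 but get
    weight 0, excluding them from enrichment weighting downstream.
    """
    e = network.edges.copy()
    genes_needed = pd.unique(pd.concat([e["regulator"], e["target"]]))
    missing = [g for g in genes_needed if g not in matrix.index]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing[:10]}")
    sub = matrix.loc[genes_needed]
    ranks = sps.rankdata(sub.to_numpy(float), axis=1)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((ranks**2).sum(axis=1))
    pos = {g: i for i, g in enumerate(genes_needed)}
    ri = np.array([pos[g] for g in e["regulator"]])
    ti = np.array([pos[g] for g in e["target"]])
    num = (ranks[ri] * ranks[ti]).sum(axis=1)
    den = norms[ri] * norms[ti]
    rho = np.divide(num, den, out=np.zeros(len(e)), where=den > 0)
    mode = np.where(rho < 0, -1, 1)
    weight = np.where(rho == 0, 0.0, e["mi"].to_numpy(float))
    e["mode"] = mode
    e["weight"] = weight
    return RegulatoryNetwork(e, list(network.regulators))


# ---------------------------------------------------------------------------
# Bootstrap-consensus network inference
# ---------------------------------------------------------------------------

def infer_network(matrix: pd.DataFrame, config: NetInfConfig) -> RegulatoryNetwork:
    """Infer a signed regulatory network from one expression matrix.

    For each bootstrap resample of the samples: estimate regulator-gene MI,
    keep pairs above the permutation-calibrated threshold, prune with DPI.
    Edges are then retained when their bootstrap support is significant under
    a Poisson null whose mean is the average support over all edges ever seen
    (Bonferroni-corrected at ``consensus_alpha``); the final MI is the mean
    over supporting bootstraps and modes come from :func:`assign_modes`.
    """
    validate_expression(matrix)
    regulators = [r for r in config.regulator_list if r in matrix.index]
    if not regulators:
        raise ValueError("regulator_list is empty or disjoint from the matrix")
    if matrix.shape[1] < 8:
        raise ValueError("need >= 8 samples for MI estimation")

    rng = np.random.default_rng(config.seed)
    threshold = calibrate_threshold(matrix, config, rng)
    logger.info("MI threshold at p=%.3g: %.4f", config.mi_pvalue, threshold)

    genes = matrix.index.to_numpy()
    values = matrix.to_numpy(float)
    reg_rows = np.array([matrix.index.get_loc(r) for r in regulators])
    n_samples = values.shape[1]

    support: dict[tuple[int, int], int] = {}
    mi_sum: dict[tuple[int, int], float] = {}
    mi_buf = np.empty((len(reg_rows), values.shape[0]))
    for _ in range(config.n_bootstraps):
        if config.n_bootstraps == 1:
            # degenerate consensus: single pass on the original samples
            cols = np.arange(n_samples)
        else:
            cols = rng.integers(0, n_samples, n_samples)
        ranks = _rank_scale(values[:, cols])
        _apmi_cross(np.ascontiguousarray(ranks[reg_rows]), ranks, mi_buf)
        ri, gi = np.nonzero(mi_buf > threshold)
        keep = reg_rows[ri] != gi  # drop self-edges
        ri, gi = ri[keep], gi[keep]
        if ri.size == 0:
            continue
        mi_vals = mi_buf[ri, gi]
        dpi_keep = _dpi_mask(
            genes[reg_rows[ri]], genes[gi], mi_vals, config.dpi_tolerance
        )
        for r, g, w in zip(ri[dpi_keep], gi[dpi_keep], mi_vals[dpi_keep]):
            key = (int(r), int(g))
            support[key] = support.get(key, 0) + 1
            mi_sum[key] = mi_sum.get(key, 0.0) + w

    if not support:
        warnings.warn("no edge survived thresholding; returning empty network")
        empty = pd.DataFrame(columns=EDGE_COLUMNS)
        return RegulatoryNetwork(empty, regulators)

    keys = list(support.keys())
    counts = np.array([support[k] for k in keys])
    n_distinct = len(keys)
    if config.consensus_alpha is not None:
        mu = counts.sum() / n_distinct
        pvals = sps.poisson.sf(counts - 1, mu)
        # edges supported by every bootstrap are always retained; the Poisson
        # test (whose null mean approaches n_bootstraps when the network is
        # stable) only discriminates among partially supported edges
        keep = (pvals < config.consensus_alpha / n_distinct) | (
            counts == config.n_bootstraps
        )
    else:
        keep = np.ones(n_distinct, dtype=bool)

    edges = pd.DataFrame(
        {
            "regulator": [genes[reg_rows[keys[i][0]]] for i in np.nonzero(keep)[0]],
            "target": [genes[keys[i][1]] for i in np.nonzero(keep)[0]],
            "mi": [mi_sum[keys[i]] / support[keys[i]] for i in np.nonzero(keep)[0]],
            "support": counts[keep],
        }
    )
    if len(edges) == 0:
        warnings.warn("no edge passed the consensus test; returning empty network")
        return RegulatoryNetwork(pd.DataFrame(columns=EDGE_COLUMNS), regulators)
    edges = edges.sort_values(["regulator", "target"]).reset_index(drop=True)
    network = RegulatoryNetwork(edges, regulators)
    return assign_modes(matrix, network)
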