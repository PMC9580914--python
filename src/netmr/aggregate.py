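"""Cross-cohort aggregation of master-regulator calls.

A regulator's *recurrence* is the number of independent cohorts in which it
was called with a given direction.  Recurrence counts under two signatures
are summarized as a 2D histogram; regulators recurrent in at least
``min_count`` cohorts form per-signature sets whose intersections identify
shared master regulators; and the subsampled-Jaccard procedure measures
workflow robustness by re-running the whole call on random 80% subsignatures
and comparing the recurrent sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .mrcall import StratConfig, call_master_regulators
from .netinf import RegulatoryNetwork
from .sigtools import GeneSignature, jaccard

__all__ = [
    "count_recurrence",
    "recurrence_histogram2d",
    "shared_mrs",
    "robustness_jaccard",
    "RobustnessResult",
]

DIRECTIONS = ("activated", "repressed")


def _as_frame(results: Sequence[pd.DataFrame] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        return results
    if len(results) == 0:
        raise ValueError("no MR results supplied")
    frames = list(results)
    ids = [f["cohort"].iloc[0] if len(f) else None for f in frames]
    ids = [i for i in ids if i is not None]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate cohort_id across MR results")
    return pd.concat(frames, ignore_index=True)


def count_recurrence(
    results: Sequence[pd.DataFrame] | pd.DataFrame,
    direction: str,
    regulators: Sequence[str] | None = None,
) -> pd.Series:
    """Number of cohorts in which each regulator was called with
    ``direction``.

    ``results`` is a list of per-cohort MR tables (distinct ``cohort`` ids)
    or one concatenated table.  Regulators never called get count 0 when a
    universe is supplied.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    frame = _as_frame(results)
    if isinstance(results, pd.DataFrame):
        if frame.groupby(["regulator", "cohort"]).size().gt(1).any():
            raise ValueError("duplicate (regulator, cohort) entries")
    hits = frame[frame["direction"] == direction]
    counts = hits.groupby("regulator").size()
    if regulators is None:
        regulators = sorted(frame["regulator"].unique())
    return counts.reindex(regulators, fill_value=0).astype(int).rename(direction)


def recurrence_histogram2d(
    counts_sig1: pd.Series, counts_sig2: pd.Series, n_cohorts: int
) -> pd.DataFrame:
    """2D histogram of recurrence counts under two signatures.

    Cell (i, j) holds the number of regulators identified in exactly i
    cohorts by signature 1 and j cohorts by signature 2; the matrix total
    equals the size of the regulator universe.
    """
    if set(counts_sig1.index) != set(counts_sig2.index):
        raise ValueError("the two count series must share a regulator universe")
    c2 = counts_sig2.reindex(counts_sig1.index)
    hist = np.zeros((n_cohorts + 1, n_cohorts + 1), dtype=int)
    for i, j in zip(counts_sig1.to_numpy(int), c2.to_numpy(int)):
        hist[i, j] += 1
    idx = pd.RangeIndex(n_cohorts + 1)
    return pd.DataFrame(hist, index=idx, columns=idx)


def shared_mrs(
    results_per_signature: Mapping[str, Sequence[pd.DataFrame] | pd.DataFrame],
    min_count: int,
    regulators: Sequence[str] | None = None,
) -> dict[str, dict]:
    """Recurrent master-regulator sets per signature and their intersections.

    For each direction: per-signature sets of regulators recurrent in at
    least ``min_count`` cohorts, all pairwise intersections, and the overall
    intersection.
    """
    if len(results_per_signature) < 2:
        raise ValueError("need results for >= 2 signatures")
    out: dict[str, dict] = {}
    for direction in DIRECTIONS:
        sets = {
            name: set(
                (c := count_recurrence(res, direction, regulators))[c >= min_count].index
            )
            for name, res in results_per_signature.items()
        }
        names = list(sets)
        pairwise = {
            (a, b): sets[a] & sets[b]
            for i, a in enumerate(names)
            for b in names[i + 1 :]
        }
        overall = set.intersection(*sets.values())
        out[direction] = {"sets": sets, "pairwise": pairwise, "intersection": overall}
    return out


@dataclass
class RobustnessResult:
    """Per-repetition Jaccard indices of the subsampling robustness run."""

    activated: list[float]
    repressed: list[float]

    @property
    def median_activated(self) -> float:
        return float(np.median(self.activated))

    @property
    def median_repressed(self) -> float:
        return float(np.median(self.repressed))


def _default_caller(strat: StratConfig) -> Callable:
    def call(signature: GeneSignature, matrix: pd.DataFrame,
             network: RegulatoryNetwork, cohort_id: str) -> pd.DataFrame:
        return call_master_regulators(matrix, network, signature, strat, cohort_id)

    return call


def robustness_jaccard(
    sig_a: GeneSignature,
    sig_b: GeneSignature,
    cohorts: Sequence[pd.DataFrame],
    networks: Sequence[RegulatoryNetwork],
    frac: float = 0.8,
    reps: int = 100,
    seed: int = 0,
    min_count: int = 4,
    strat: StratConfig = StratConfig(),
    caller: Callable | None = None,
) -> RobustnessResult:
    """Subsampled-Jaccard robustness of the master-regulator workflow.

    Per repetition, each signature is subsampled to ceil(frac * |S|) genes
    without replacement, the full MR call runs on every cohort for both
    subsignatures, regulators recurrent in >= ``min_count`` cohorts are
    collected per direction, and the Jaccard index between the two
    signatures' recurrent sets is recorded.  Returns the per-repetition
    indices; report the medians.

    ``caller(signature, matrix, network, cohort_id) -> MR table`` may be
    injected (e.g. for calibration studies with a mock caller).
    """
    if not (0.0 < frac <= 1.0):
        raise ValueError("frac must lie in (0, 1]")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if len(cohorts) != len(networks):
        raise ValueError("need one network per cohort")
    for sig in (sig_a, sig_b):
        if int(np.ceil(frac * len(sig))) < 10:
            raise ValueError(
                f"subsample of signature {sig.name!r} would fall below 10 genes"
            )
    if caller is None:
        caller = _default_caller(strat)
    rng = np.random.default_rng(seed)

    jac_act: list[float] = []
    jac_rep: list[float] = []
    for _ in range(reps):
        recurrent: dict[str, dict[str, set]] = {}
        for label, sig in (("a", sig_a), ("b", sig_b)):
            sub = sig.subsample(frac, rng)
            results = [
                caller(sub, mat, net, f"c{k}")
                for k, (mat, net) in enumerate(zip(cohorts, networks))
            ]
            recurrent[label] = {
                d: set((c := count_recurrence(results, d))[c >= min_count].index)
                for d in DIRECTIONS
            }
        jac_act.append(jaccard(recurrent["a"]["activated"], recurrent["b"]["activated"]))
        jac_rep.append(jaccard(recurrent["a"]["repressed"], recurrent["b"]["repressed"]))
    return RobustnessResult(jac_act, jac_rep)
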