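"""Gene signatures: GMT I/O, differential expression, overlap construction.

A signature is a named gene set, optionally split into up- and down-regulated
parts.  Signatures can be built from two differential-expression runs as the
genes significantly up-regulated in both (the overlap rule used to derive
treatment-resistance signatures from independent datasets), loaded from GMT
collections, or compared with the Jaccard index.

Differential expression here is a per-gene Welch t-test with
Benjamini-Hochberg FDR on continuous log-scale matrices — a deliberately
simple model kept behind the same interface a count- or array-specific DE
stack would occupy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSignature",
    "read_gmt",
    "write_gmt",
    "differential_expression",
    "build_overlap_signature",
    "tcell_abundance",
    "jaccard",
    "signature_overlap_report",
]

TCELL_GENES = ("CD8A", "CD8B", "GZMA", "GZMB")


@dataclass
class GeneSignature:
    """A named gene set with optional down-regulated part."""

    name: str
    up: set = field(default_factory=set)
    down: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.up = set(self.up)
        self.down = set(self.down)
        if self.up & self.down:
            raise ValueError("up and down parts must be disjoint")
        if not (self.up or self.down):
            raise ValueError("signature must contain at least one gene")

    @property
    def genes(self) -> set:
        return self.up | self.down

    def __len__(self) -> int:
        return len(self.up) + len(self.down)

    def flipped(self) -> "GeneSignature":
        """The signature with up and down parts swapped."""
        if not self.down:
            raise ValueError("cannot flip a signature with no down part")
        return GeneSignature(self.name + "_flipped", set(self.down), set(self.up))

    def subsample(self, frac: float, rng: np.random.Generator) -> "GeneSignature":
        """Subsample ceil(frac * |part|) genes from each part without
        replacement."""
        if not (0.0 < frac <= 1.0):
            raise ValueError("frac must lie in (0, 1]")

        def pick(part: set) -> set:
            if not part:
                return set()
            k = int(np.ceil(frac * len(part)))
            return set(rng.choice(sorted(part), size=k, replace=False))

        return GeneSignature(self.name, pick(self.up), pick(self.down))


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------

def read_gmt(path) -> list[GeneSignature]:
    """Read a GMT file (tab-separated: name, description, genes...).

    Lines named ``X_up``/``X_down`` (case-insensitive suffix) are merged into
    one two-sided signature ``X``.
    """
    raw: dict[str, list[str]] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            name = parts[0]
            raw[name] = [g for g in parts[2:] if g]
            order.append(name)

    sigs: dict[str, GeneSignature] = {}
    consumed = set()
    for name in order:
        if name in consumed:
            continue
        low = name.lower()
        if low.endswith("_up"):
            base = name[:-3]
            down_key = next(
                (k for k in raw if k.lower() == base.lower() + "_down"), None
            )
            if down_key is not None:
                sigs[base] = GeneSignature(base, set(raw[name]), set(raw[down_key]))
                consumed.update({name, down_key})
                continue
        sigs[name] = GeneSignature(name, set(raw[name]))
        consumed.add(name)
    return list(sigs.values())


def write_gmt(signatures: Iterable[GeneSignature], path) -> None:
    """Write signatures as GMT; two-sided signatures become ``name_up`` and
    ``name_down`` lines."""
    with open(path, "w") as fh:
        for sig in signatures:
            if sig.down:
                fh.write("\t".join([sig.name + "_up", "na", *sorted(sig.up)]) + "\n")
                fh.write("\t".join([sig.name + "_down", "na", *sorted(sig.down)]) + "\n")
            else:
                fh.write("\t".join([sig.name, "na", *sorted(sig.up)]) + "\n")


# ---------------------------------------------------------------------------
# Differential expression (Welch t + BH)
# ---------------------------------------------------------------------------

def differential_expression(
    matrix: pd.DataFrame, group_a: Sequence[str], group_b: Sequence[str]
) -> pd.DataFrame:
    """Per-gene Welch t-test of group A vs group B with BH adjustment.

    Returns a frame indexed by gene with columns ``effect`` (mean A - mean B
    on the log scale), ``stat``, ``p`` and ``fdr``.  Genes with zero variance
    in both groups get statistic 0 and p = 1.
    """
    a = sorted(set(group_a))
    b = sorted(set(group_b))
    if set(a) & set(b):
        raise ValueError("groups overlap")
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs >= 3 samples")
    missing = [s for s in a + b if s not in matrix.columns]
    if missing:
        raise KeyError(f"samples absent from matrix: {missing[:5]}")

    xa = matrix[a].to_numpy(float)
    xb = matrix[b].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat, p = sps.ttest_ind(xa, xb, axis=1, equal_var=False)
    effect = xa.mean(axis=1) - xb.mean(axis=1)
    degenerate = ~np.isfinite(stat)
    stat = np.where(degenerate, 0.0, stat)
    p = np.where(degenerate, 1.0, p)
    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"effect": effect, "stat": stat, "p": p, "fdr": fdr}, index=matrix.index
    )


def build_overlap_signature(
    de_a: pd.DataFrame, de_b: pd.DataFrame, fdr_cut: float = 0.05, name: str = "overlap"
) -> GeneSignature:
    """Genes significantly up-regulated (FDR < cut, positive effect) in BOTH
    differential-expression results."""
    if not (0.0 < fdr_cut < 1.0):
        raise ValueError("fdr_cut must lie in (0, 1)")

    def up(de: pd.DataFrame) -> set:
        return set(de.index[(de["fdr"] < fdr_cut) & (de["effect"] > 0)])

    return GeneSignature(name, up(de_a) & up(de_b))


# ---------------------------------------------------------------------------
# Simple scores and set comparisons
# ---------------------------------------------------------------------------

def tcell_abundance(matrix: pd.DataFrame) -> pd.Series:
    """Per-sample T-cell abundance: mean expression of CD8A, CD8B, GZMA and
    GZMB."""
    missing = [g for g in TCELL_GENES if g not in matrix.index]
    if missing:
        raise KeyError(f"T-cell marker genes missing: {missing}")
    return matrix.loc[list(TCELL_GENES)].mean(axis=0).rename("tcell_abundance")


def jaccard(a: Iterable, b: Iterable) -> float:
    """Jaccard index |a n b| / |a u b|; 0 when both sets are empty."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def signature_overlap_report(signatures: Sequence[GeneSignature]) -> pd.DataFrame:
    """Pairwise Jaccard matrix over a signature collection (total gene
    content, up and down pooled)."""
    names = [s.name for s in signatures]
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, si in enumerate(signatures):
        for j in range(i + 1, len(signatures)):
            v = jaccard(si.genes, signatures[j].genes)
            out.iat[i, j] = out.iat[j, i] = v
    return out
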