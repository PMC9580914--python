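"""Multi-cohort synthetic expression data with a planted regulatory network.

The generator emulates the statistical structure the downstream workflow
assumes: several independent patient cohorts share one latent transcriptional
network; a subset of "driver" regulators covaries with a phenotype factor;
a gene signature is drawn from the drivers' activated targets; and survival
times follow an exponential model whose log-hazard increases with driver
activity, with administrative censoring at a fixed horizon.

Latent model per cohort (samples indexed s, genes g):

* regulator activities ``a_r(s)`` are standard normal; drivers mix a shared
  phenotype factor F(s): ``a_d = sqrt(rho) F + sqrt(1-rho) eps``;
* a regulator's own mRNA row equals its activity plus noise, so
  expression-based mode assignment is meaningful;
* target expression ``x_g = mu_g + sum_r effect_size * mode_rg * a_r + noise``;
* survival: T ~ Exp(rate = baseline_hazard * exp(hazard_log_hr * mean driver
  activity)), censored administratively at the horizon where a baseline-rate
  subject survives with probability ~0.4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .sigtools import GeneSignature, write_gmt
from .netinf import RegulatoryNetwork, write_expression

__all__ = [
    "SimConfig",
    "PlantedTruth",
    "generate_truth",
    "simulate_cohort",
    "simulate_cohorts",
    "make_random_signature",
    "write_truth",
    "write_survival",
    "read_survival",
]


@dataclass
class SimConfig:
    """Shape and signal strength of the synthetic study.

    Defaults describe a seven-cohort study of 150 samples x 2000 genes with
    60 candidate regulators (mean regulon size 20), six of which drive the
    phenotype with coupling ``effect_size`` standard deviations per unit
    activity and residual noise ``noise_sd``.
    """

    n_genes: int = 2000
    n_samples: int = 150
    n_cohorts: int = 7
    n_regulators: int = 60
    regulon_size: int = 20
    n_drivers: int = 6
    effect_size: float = 2.0
    noise_sd: float = 1.0
    frac_repressed: float = 0.25
    reg_noise_sd: float = 0.3  # measurement noise on the regulator's own mRNA
    rho: float = 0.5  # driver-activity share of the common phenotype factor
    baseline_hazard: float = 0.1
    hazard_log_hr: float = 1.0
    signature_size: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_samples", "n_cohorts", "n_regulators", "regulon_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_drivers > self.n_regulators:
            raise ValueError("n_drivers cannot exceed n_regulators")
        if not (0.0 <= self.frac_repressed <= 1.0):
            raise ValueError("frac_repressed must lie in [0, 1]")
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError("rho must lie in [0, 1]")


@dataclass
class PlantedTruth:
    """Ground truth shared by every cohort of one synthetic study."""

    network: RegulatoryNetwork
    drivers: set[str]
    signature: GeneSignature
    baselines: pd.Series = field(repr=False, default=None)

    def __post_init__(self) -> None:
        regs = set(self.network.regulators)
        if not self.drivers <= regs:
            raise ValueError("drivers must be a subset of the network regulators")
        targeted = set(self.network.edges["target"])
        if not set(self.signature.up) <= targeted:
            raise ValueError("every signature gene must be a target of some regulator")


def _gene_names(config: SimConfig) -> tuple[list[str], list[str]]:
    regs = [f"REG{i:03d}" for i in range(config.n_regulators)]
    tgts = [f"GEN{i:05d}" for i in range(config.n_genes - config.n_regulators)]
    return regs, tgts


def generate_truth(config: SimConfig) -> PlantedTruth:
    """Draw the planted network, driver set and signature for one study.

    Regulon sizes are Poisson around ``regulon_size`` (floor 2); each target's
    mode is -1 with probability ``frac_repressed`` else +1.  Regulons
    partition the target pool while it lasts, so they are disjoint unless the
    configuration requests more regulon mass than the pool holds.  The
    signature samples ``signature_size`` genes from the union of
    positive-mode driver targets.
    """
    rng = np.random.default_rng(config.seed)
    regs, pool = _gene_names(config)
    if len(pool) < max(2 * config.regulon_size, 10):
        raise ValueError(
            "n_genes too small to host the regulators and their targets"
        )
    # regulons partition the target pool while it lasts (a fresh shuffled
    # pool is started when exhausted, so very dense configurations overlap)
    rows = []
    shuffled = list(rng.permutation(pool))
    for r in regs:
        size = max(2, rng.poisson(config.regulon_size))
        size = min(size, len(pool))
        if size > len(shuffled):
            shuffled = list(rng.permutation(pool))
        targets = [shuffled.pop() for _ in range(size)]
        modes = np.where(rng.random(size) < config.frac_repressed, -1, 1)
        for t, m in zip(targets, modes):
            rows.append((r, t, 1.0, int(m)))
    edges = pd.DataFrame(rows, columns=["regulator", "target", "mi", "mode"])
    network = RegulatoryNetwork(edges, regs)

    drivers = set(rng.choice(regs, size=config.n_drivers, replace=False)) if config.n_drivers else set()
    up_pool = sorted(
        set(
            edges.loc[
                edges["regulator"].isin(drivers) & (edges["mode"] > 0), "target"
            ]
        )
    )
    if len(up_pool) < 10:
        raise ValueError(
            "fewer than 10 activated driver targets available for the signature; "
            "increase n_drivers or regulon_size"
        )
    size = min(config.signature_size, len(up_pool))
    sig_genes = rng.choice(up_pool, size=size, replace=False)
    signature = GeneSignature("planted", set(sig_genes))

    baselines = pd.Series(
        rng.normal(0.0, 1.0, config.n_genes), index=regs + pool, name="baseline"
    )
    return PlantedTruth(network, drivers, signature, baselines)


def simulate_cohort(
    truth: PlantedTruth, config: SimConfig, cohort_seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one cohort: an expression matrix and its survival table.

    Returns ``(matrix, survival)`` where ``matrix`` is genes x samples and
    ``survival`` has columns ``sample, time, event``.
    """
    rng = np.random.default_rng(cohort_seed)
    regs = list(truth.network.regulators)
    genes = list(truth.baselines.index)
    n_r, n_s = len(regs), config.n_samples

    activity = rng.normal(size=(n_r, n_s))
    reg_pos = {r: i for i, r in enumerate(regs)}
    if truth.drivers:
        factor = rng.normal(size=n_s)
        for d in truth.drivers:
            i = reg_pos[d]
            activity[i] = np.sqrt(config.rho) * factor + np.sqrt(1.0 - config.rho) * activity[i]

    values = np.zeros((len(genes), n_s))
    gene_pos = {g: i for i, g in enumerate(genes)}
    # regulator mRNA mirrors its latent activity
    for r in regs:
        values[gene_pos[r]] = activity[reg_pos[r]]
    e = truth.network.edges
    for r, grp in e.groupby("regulator"):
        a = activity[reg_pos[r]]
        for t, m in zip(grp["target"], grp["mode"]):
            values[gene_pos[t]] += config.effect_size * m * a
    values += truth.baselines.to_numpy()[:, None]
    noise_scale = np.full(len(genes), config.noise_sd)
    for r in regs:  # regulator mRNA is a low-noise readout of its activity
        noise_scale[gene_pos[r]] = config.reg_noise_sd
    values += noise_scale[:, None] * rng.normal(size=values.shape)

    samples = [f"S{cohort_seed:04d}_{j:04d}" for j in range(n_s)]
    matrix = pd.DataFrame(values, index=genes, columns=samples)

    if truth.drivers:
        score = activity[[reg_pos[d] for d in sorted(truth.drivers)]].mean(axis=0)
    else:
        score = np.zeros(n_s)
    rate = config.baseline_hazard * np.exp(config.hazard_log_hr * score)
    t_event = rng.exponential(1.0 / rate)
    horizon = -np.log(0.4) / config.baseline_hazard  # ~40% censored at baseline
    event = (t_event <= horizon).astype(int)
    time = np.minimum(t_event, horizon)
    survival = pd.DataFrame({"sample": samples, "time": time, "event": event})
    return matrix, survival


def simulate_cohorts(
    truth: PlantedTruth, config: SimConfig
) -> list[tuple[pd.DataFrame, pd.DataFrame]]:
    """All cohorts of the study, with per-cohort seeds derived from the
    study seed (cohort k uses ``seed + k + 1``)."""
    return [
        simulate_cohort(truth, config, config.seed + k + 1)
        for k in range(config.n_cohorts)
    ]


def make_random_signature(
    gene_universe: list[str], size: int, seed: int, name: str = "random"
) -> GeneSignature:
    """Uniform random signature of ``size`` genes sampled without replacement."""
    if size <= 0:
        raise ValueError("signature size must be positive")
    if size > len(gene_universe):
        raise ValueError("signature size exceeds the gene universe")
    rng = np.random.default_rng(seed)
    genes = rng.choice(np.asarray(gene_universe, dtype=object), size=size, replace=False)
    return GeneSignature(name, set(genes))


# ---------------------------------------------------------------------------
# On-disk formats
# ---------------------------------------------------------------------------

def write_survival(survival: pd.DataFrame, path) -> None:
    survival.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_survival(path) -> pd.DataFrame:
    surv = pd.read_csv(path, sep="\t")
    need = {"sample", "time", "event"}
    if not need <= set(surv.columns):
        raise ValueError(f"survival table lacks columns {sorted(need - set(surv.columns))}")
    if (surv["time"] < 0).any():
        raise ValueError("negative survival time")
    if not surv["event"].isin([0, 1]).all():
        raise ValueError("event must be 0 or 1")
    return surv


def write_truth(truth: PlantedTruth, outdir) -> None:
    """Write the planted truth: signature GMT and signed-network TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_gmt([truth.signature], outdir / "truth_signature.gmt")
    e = truth.network.edges
    signed = pd.DataFrame(
        {
            "regulator": e["regulator"],
            "target": e["target"],
            "weight": e["mi"] * e["mode"],
        }
    )
    signed.to_csv(outdir / "truth_network.tsv", sep="\t", index=False)
    with open(outdir / "truth_drivers.txt", "w") as fh:
        for d in sorted(truth.drivers):
            fh.write(d + "\n")
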