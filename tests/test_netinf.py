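import itertools

import numpy as np
import pandas as pd
import pytest

from netmr.netinf import (
    NetInfConfig,
    RegulatoryNetwork,
    _rank_scale,
    _threshold_from_null,
    apply_dpi,
    assign_modes,
    calibrate_threshold,
    estimate_mi,
    infer_network,
    read_network,
    write_network,
)
from netmr.simdata import SimConfig, generate_truth, simulate_cohort


def _matrix(values, genes=None, samples=None):
    values = np.asarray(values, float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


class TestEstimateMI:
    def test_symmetry_exact(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.normal(size=100)
            y = 0.5 * x + rng.normal(size=100)
            assert abs(estimate_mi(x, y) - estimate_mi(y, x)) < 1e-12

    def test_nonnegative(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            assert estimate_mi(rng.normal(size=64), rng.normal(size=64)) >= 0.0

    def test_perfect_dependence_dominates_permutations(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=1000)
        mi_self = estimate_mi(x, x)
        for _ in range(100):
            assert mi_self >= estimate_mi(x, rng.permutation(x))

    def test_independent_pairs_below_permutation_quantile(self):
        # under independence the MI should rarely exceed the p=0.05
        # permutation quantile of its own null
        rng = np.random.default_rng(3)
        x = rng.normal(size=1000)
        null = np.sort([estimate_mi(x, rng.permutation(x)) for _ in range(99)])
        q95 = null[94]
        hits = sum(
            estimate_mi(rng.normal(size=1000), rng.normal(size=1000)) <= q95
            for _ in range(100)
        )
        assert hits >= 90

    def test_input_validation(self):
        with pytest.raises(ValueError):
            estimate_mi(np.arange(7.0), np.arange(7.0))
        with pytest.raises(ValueError):
            estimate_mi(np.arange(10.0), np.arange(9.0))


class TestCalibrateThreshold:
    def test_synthetic_exponential_null_closed_form(self):
        # null MIs ~ Exp(rate=50): the p-quantile is ln(1/p)/50
        rng = np.random.default_rng(0)
        null = rng.exponential(1 / 50, 200_000)
        m_star = _threshold_from_null(null, 1e-4)
        assert m_star == pytest.approx(np.log(1e4) / 50, rel=0.10)

    def test_monotone_in_p_and_seeded(self):
        rng = np.random.default_rng(1)
        mat = _matrix(rng.normal(size=(40, 60)))
        cfg_lo = NetInfConfig(regulator_list=["g0"], mi_pvalue=1e-8,
                              n_null_pairs=3000, seed=9)
        cfg_hi = NetInfConfig(regulator_list=["g0"], mi_pvalue=1e-2,
                              n_null_pairs=3000, seed=9)
        t_lo = calibrate_threshold(mat, cfg_lo)
        t_hi = calibrate_threshold(mat, cfg_hi)
        assert t_lo > t_hi
        assert calibrate_threshold(mat, cfg_lo) == t_lo  # same seed, same value

    def test_degenerate_fit_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            _threshold_from_null(np.ones(1000), 1e-4)


def brute_force_dpi(edges, tolerance):
    """Triple-loop DPI oracle: evaluate every node triangle on the input
    network and drop marked edges simultaneously."""
    w = {}
    for r, t, mi in edges:
        w[frozenset((r, t))] = mi
    nodes = sorted({n for r, t, _ in edges for n in (r, t)})
    marked = set()
    for a, b, c in itertools.combinations(nodes, 3):
        ab, bc, ac = frozenset((a, b)), frozenset((b, c)), frozenset((a, c))
        if ab in w and bc in w and ac in w:
            for weakest, others in ((ab, (bc, ac)), (bc, (ab, ac)), (ac, (ab, bc))):
                if w[weakest] < min(w[others[0]], w[others[1]]) * (1 - tolerance):
                    marked.add(weakest)
    return {frozenset((r, t)) for r, t, _ in edges} - marked


def _random_network(rng, n_nodes=20, p_edge=0.3):
    nodes = [f"n{i}" for i in range(n_nodes)]
    rows = []
    for i, j in itertools.combinations(range(n_nodes), 2):
        if rng.random() < p_edge:
            rows.append((nodes[i], nodes[j], float(rng.random()) + 1e-6))
    return rows


class TestDPI:
    def test_chain_triangle_weakest_removed(self):
        edges = pd.DataFrame(
            [("X", "Y", 0.9), ("Y", "Z", 0.8), ("X", "Z", 0.3)],
            columns=["regulator", "target", "mi"],
        )
        out = apply_dpi(RegulatoryNetwork(edges), 0.0)
        kept = set(zip(out.edges["regulator"], out.edges["target"]))
        assert kept == {("X", "Y"), ("Y", "Z")}

    def test_tolerance_one_removes_nothing(self):
        rng = np.random.default_rng(0)
        rows = _random_network(rng)
        edges = pd.DataFrame(rows, columns=["regulator", "target", "mi"])
        assert len(apply_dpi(RegulatoryNetwork(edges), 1.0)) == len(rows)

    def test_invalid_tolerance(self):
        edges = pd.DataFrame([("a", "b", 0.1)], columns=["regulator", "target", "mi"])
        with pytest.raises(ValueError):
            apply_dpi(RegulatoryNetwork(edges), 1.5)

    @pytest.mark.parametrize("tolerance", [0.0, 0.15])
    def test_matches_brute_force_oracle(self, tolerance):
        rng = np.random.default_rng(42)
        for _ in range(100):
            rows = _random_network(rng)
            if not rows:
                continue
            edges = pd.DataFrame(rows, columns=["regulator", "target", "mi"])
            out = apply_dpi(RegulatoryNetwork(edges), tolerance)
            kept = {
                frozenset((r, t))
                for r, t in zip(out.edges["regulator"], out.edges["target"])
            }
            assert kept == brute_force_dpi(rows, tolerance)

    def test_never_removes_global_maximum_edge(self):
        # an edge can be the strongest of one triangle yet the weakest of
        # another; only the graph-wide maximum can never be marked
        rng = np.random.default_rng(7)
        for _ in range(100):
            rows = _random_network(rng, n_nodes=12, p_edge=0.5)
            edges = pd.DataFrame(rows, columns=["regulator", "target", "mi"])
            out = apply_dpi(RegulatoryNetwork(edges), 0.0)
            kept = {
                frozenset((r, t))
                for r, t in zip(out.edges["regulator"], out.edges["target"])
            }
            best = max(rows, key=lambda e: e[2])
            assert frozenset((best[0], best[1])) in kept


class TestAssignModes:
    def test_identical_and_negated_targets(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        mat = _matrix(np.vstack([x, x, -x]), genes=["r", "tpos", "tneg"])
        edges = pd.DataFrame(
            [("r", "tpos", 0.5), ("r", "tneg", 0.5)],
            columns=["regulator", "target", "mi"],
        )
        out = assign_modes(mat, RegulatoryNetwork(edges)).edges.set_index("target")
        assert out.loc["tpos", "mode"] == 1
        assert out.loc["tneg", "mode"] == -1
        assert out.loc["tpos", "weight"] == 0.5

    def test_constant_target_gets_zero_weight_but_stays(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        mat = _matrix(np.vstack([x, np.ones(30)]), genes=["r", "flat"])
        edges = pd.DataFrame([("r", "flat", 0.4)], columns=["regulator", "target", "mi"])
        out = assign_modes(mat, RegulatoryNetwork(edges)).edges
        assert len(out) == 1
        assert out.loc[0, "mode"] == 1
        assert out.loc[0, "weight"] == 0.0

    def test_missing_gene_named(self):
        mat = _matrix(np.random.default_rng(2).normal(size=(1, 10)), genes=["r"])
        edges = pd.DataFrame([("r", "ghost", 0.4)], columns=["regulator", "target", "mi"])
        with pytest.raises(KeyError, match="ghost"):
            assign_modes(mat, RegulatoryNetwork(edges))


@pytest.fixture(scope="module")
def small_cohort():
    cfg = SimConfig(n_genes=400, n_samples=150, n_cohorts=1, n_regulators=15,
                    regulon_size=12, n_drivers=3, seed=5)
    truth = generate_truth(cfg)
    mat, _ = simulate_cohort(truth, cfg, 77)
    return cfg, truth, mat


class TestInferNetwork:
    def test_single_bootstrap_equals_manual_single_pass(self, small_cohort):
        _, truth, mat = small_cohort
        cfg = NetInfConfig(regulator_list=list(truth.network.regulators),
                           n_bootstraps=1, consensus_alpha=None,
                           n_null_pairs=20000, seed=3)
        net = infer_network(mat, cfg)

        thr = calibrate_threshold(mat, cfg, np.random.default_rng(3))
        manual = []
        for r in truth.network.regulators:
            for g in mat.index:
                if g == r:
                    continue
                mi = estimate_mi(mat.loc[r], mat.loc[g])
                if mi > thr:
                    manual.append((r, g, mi))
        manual_net = apply_dpi(
            RegulatoryNetwork(pd.DataFrame(manual, columns=["regulator", "target", "mi"])),
            cfg.dpi_tolerance,
        )
        got = set(zip(net.edges["regulator"], net.edges["target"]))
        want = set(zip(manual_net.edges["regulator"], manual_net.edges["target"]))
        assert got == want

    def test_planted_network_recovery(self, small_cohort):
        _, truth, mat = small_cohort
        cfg = NetInfConfig(regulator_list=list(truth.network.regulators),
                           n_bootstraps=50, n_null_pairs=30000, seed=11)
        net = infer_network(mat, cfg)
        planted = set(zip(truth.network.edges["regulator"], truth.network.edges["target"]))
        got = set(zip(net.edges["regulator"], net.edges["target"]))
        assert len(planted & got) / len(planted) >= 0.70
        assert len(got - planted) / max(len(got), 1) <= 0.10

    def test_full_support_edges_always_retained(self, small_cohort):
        _, truth, mat = small_cohort
        cfg = NetInfConfig(regulator_list=list(truth.network.regulators),
                           n_bootstraps=20, n_null_pairs=20000, seed=2)
        net = infer_network(mat, cfg)
        assert (net.edges["support"] == 20).any()

    def test_consensus_monotone_in_alpha(self, small_cohort):
        _, truth, mat = small_cohort
        base = dict(regulator_list=list(truth.network.regulators),
                    n_bootstraps=20, n_null_pairs=20000, seed=4)
        strict = infer_network(mat, NetInfConfig(consensus_alpha=1e-4, **base))
        loose = infer_network(mat, NetInfConfig(consensus_alpha=0.5, **base))
        e_strict = set(zip(strict.edges["regulator"], strict.edges["target"]))
        e_loose = set(zip(loose.edges["regulator"], loose.edges["target"]))
        assert e_strict <= e_loose

    def test_mode_recovery_on_planted_edges(self, small_cohort):
        _, truth, mat = small_cohort
        cfg = NetInfConfig(regulator_list=list(truth.network.regulators),
                           n_bootstraps=20, n_null_pairs=20000, seed=6)
        net = infer_network(mat, cfg)
        merged = net.edges.merge(truth.network.edges, on=["regulator", "target"],
                                 suffixes=("", "_true"))
        assert (merged["mode"] == merged["mode_true"]).mean() >= 0.95


class TestNetworkIO:
    def test_round_trip(self, tmp_path):
        edges = pd.DataFrame(
            [("r1", "t1", 0.5, 1, 10, 0.5), ("r1", "t2", 0.25, -1, 8, 0.0)],
            columns=["regulator", "target", "mi", "mode", "support", "weight"],
        )
        net = RegulatoryNetwork(edges)
        path = tmp_path / "net.tsv"
        write_network(net, path)
        back = read_network(path)
        pd.testing.assert_frame_equal(
            back.edges[["regulator", "target", "mi", "mode", "support", "weight"]],
            net.edges[["regulator", "target", "mi", "mode", "support", "weight"]],
        )

    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="self-edge"):
            RegulatoryNetwork(pd.DataFrame([("a", "a", 0.1)],
                                           columns=["regulator", "target", "mi"]))
        with pytest.raises(ValueError, match="duplicate"):
            RegulatoryNetwork(pd.DataFrame([("a", "b", 0.1), ("a", "b", 0.2)],
                                           columns=["regulator", "target", "mi"]))
        with pytest.raises(ValueError, match="negative"):
            RegulatoryNetwork(pd.DataFrame([("a", "b", -0.1)],
                                           columns=["regulator", "target", "mi"]))
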