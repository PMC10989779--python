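import numpy as np
import pandas as pd
import pytest
from scipy import stats

from qmpflow import conetwork
from qmpflow.tables import FeatureTable


def _table(matrix, meta=None, mode="QMP", columns=None):
    idx = [f"s{i}" for i in range(len(matrix))]
    cols = columns or [f"g{j}" for j in range(np.shape(matrix)[1])]
    return FeatureTable(
        pd.DataFrame(matrix, index=idx, columns=cols),
        pd.DataFrame(meta or {}, index=idx),
        mode=mode,
    )


class TestPrevalenceFilter:
    def test_boundary_inclusive(self):
        m = np.zeros((10, 2))
        m[:3, 0] = 1.0  # exactly 30%
        m[:2, 1] = 1.0  # 20%
        kept = conetwork.prevalence_filter(_table(m)).taxa
        assert list(kept) == ["g0"]

    def test_ubiquitous_taxa_kept(self):
        m = np.ones((10, 3))
        assert len(conetwork.prevalence_filter(_table(m)).taxa) == 3


class TestPartialSpearman:
    def test_monotone_function_is_one(self):
        x = np.linspace(0, 5, 30)
        rho, p = conetwork.partial_spearman(x, np.exp(x))
        assert rho == pytest.approx(1.0)

    def test_matches_recursive_formula(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=200)
        x = z + rng.normal(0, 0.5, 200)
        y = z + rng.normal(0, 0.5, 200)
        r_xy = stats.spearmanr(x, y).statistic
        r_xz = stats.spearmanr(x, z).statistic
        r_yz = stats.spearmanr(y, z).statistic
        oracle = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
        mine, _ = conetwork.partial_spearman(x, y, z)
        assert mine == pytest.approx(oracle, abs=1e-10)

    def test_empty_conditioning_equals_plain_spearman(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=50), rng.normal(size=50)
        mine, _ = conetwork.partial_spearman(x, y)
        ref = stats.spearmanr(x, y).statistic
        assert mine == pytest.approx(ref, abs=1e-12)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        z = rng.normal(size=80)
        df = pd.DataFrame(
            {"x": z + rng.normal(0, 1, 80), "y": z + rng.normal(0, 1, 80), "z": z}
        )
        ref = pingouin.partial_corr(df, x="x", y="y", covar="z", method="spearman")
        mine, p = conetwork.partial_spearman(df.x, df.y, df.z)
        assert mine == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        pcol = "p_val" if "p_val" in ref.columns else "p-val"
        assert p == pytest.approx(float(ref[pcol].iloc[0]), abs=1e-9)

    def test_constant_variable_is_ns(self):
        with pytest.warns(UserWarning):
            rho, p = conetwork.partial_spearman(np.ones(10), np.arange(10))
        assert np.isnan(rho) and p == 1.0


def _brute_force_bh(pvals):
    """Independent Benjamini–Hochberg oracle."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


def test_bh_matches_brute_force_oracle():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(3)
    for size in (1, 10, 317, 1000):
        p = rng.random(size)
        np.testing.assert_allclose(
            multipletests(p, method="fdr_bh")[1], _brute_force_bh(p), atol=1e-12
        )


class TestBuildNetwork:
    def test_planted_block_recovered(self):
        rng = np.random.default_rng(4)
        n, p_block, p_noise = 80, 6, 20
        latent = rng.normal(size=n)
        block = latent[:, None] + rng.normal(0, 0.7, (n, p_block))  # rho ~ 0.7
        noise = rng.normal(size=(n, p_noise))
        # exp keeps abundances positive without breaking monotone ranks
        t = _table(np.exp(0.5 * np.hstack([block, noise])))
        net = conetwork.build_network(t, covariates=None)
        block_names = {f"g{j}" for j in range(p_block)}
        found = sum(
            1
            for _, e in net.edges.iterrows()
            if e.genus_a in block_names and e.genus_b in block_names
        )
        possible = p_block * (p_block - 1) // 2
        assert found / possible >= 0.8

    def test_identical_tables_same_network_across_modes(self):
        rng = np.random.default_rng(5)
        m = np.abs(rng.normal(size=(30, 8))) + 0.1
        t_qmp = _table(m, mode="QMP")
        t_rmp = _table(m, mode="RMP")
        n1 = conetwork.build_network(t_qmp, covariates=None)
        n2 = conetwork.build_network(t_rmp, covariates=None)
        pd.testing.assert_frame_equal(n1.edges, n2.edges)

    def test_too_few_samples_rejected(self):
        t = _table(np.ones((4, 3)))
        with pytest.raises(ValueError):
            conetwork.build_network(t)

    def test_false_discovery_controlled_under_independence(self):
        rng = np.random.default_rng(6)
        fdps = []
        for rep in range(10):
            t = _table(np.abs(rng.normal(size=(60, 20))) + 0.01)
            net = conetwork.build_network(t, covariates=None)
            fdps.append(len(net.edges) / max(len(net.all_pairs), 1))
        assert np.mean(fdps) <= 0.10


class TestTopology:
    def _net(self, edges, vertices):
        df = pd.DataFrame(
            [{"genus_a": a, "genus_b": b, "rho": r, "p": 0.001, "p_adj": 0.01,
              "sign": int(np.sign(r))} for a, b, r in edges]
        )
        return conetwork.CoNetwork(edges=df, vertices=vertices)

    def test_triangle(self):
        net = self._net([("a", "b", 0.9), ("b", "c", 0.9), ("a", "c", 0.9)],
                        ["a", "b", "c"])
        topo = conetwork.topology(net)
        assert topo.clustering == pytest.approx(1.0)
        assert topo.avg_separation == pytest.approx(1.0)
        assert topo.avg_betweenness == pytest.approx(0.0)

    def test_three_path(self):
        net = self._net([("a", "b", 0.9), ("b", "c", 0.9)], ["a", "b", "c"])
        topo = conetwork.topology(net)
        assert topo.clustering == pytest.approx(0.0)
        assert topo.avg_separation == pytest.approx(4 / 3)
        assert topo.avg_betweenness == pytest.approx(1 / 3)  # only the middle vertex

    def test_disconnected_pairs_excluded_from_separation(self):
        net = self._net([("a", "b", 0.9), ("c", "d", 0.9)], list("abcd"))
        topo = conetwork.topology(net)
        assert topo.avg_separation == pytest.approx(1.0)

    def test_empty_graph_flagged(self):
        net = self._net([], list("ab"))
        topo = conetwork.topology(net)
        assert topo.empty and topo.n_edges == 0


class TestKeystoneAndEdges:
    def _star(self):
        edges = [("hub", f"leaf{i}", 0.9) for i in range(5)]
        df = pd.DataFrame(
            [{"genus_a": a, "genus_b": b, "rho": r, "p": 0.001, "p_adj": 0.01,
              "sign": 1} for a, b, r in edges]
        )
        return conetwork.CoNetwork(edges=df, vertices=["hub"] + [f"leaf{i}" for i in range(5)])

    def test_star_hub_first(self):
        ranked = conetwork.keystone(self._star(), top_n=3)
        assert ranked.genus.iloc[0] == "hub"

    def test_equal_degree_tie_broken_lexically(self):
        df = pd.DataFrame(
            [
                {"genus_a": "b", "genus_b": "c", "rho": 0.5, "p": 0.01, "p_adj": 0.01, "sign": 1},
                {"genus_a": "a", "genus_b": "d", "rho": 0.5, "p": 0.01, "p_adj": 0.01, "sign": 1},
            ]
        )
        net = conetwork.CoNetwork(edges=df, vertices=list("abcd"))
        ranked = conetwork.keystone(net, top_n=4)
        assert list(ranked.genus) == ["a", "b", "c", "d"]

    def test_edge_sharing_labels(self):
        n1 = self._star()
        n1.segment = "cecum"
        df2 = pd.DataFrame(
            [{"genus_a": "hub", "genus_b": "leaf0", "rho": -0.8, "p": 0.001,
              "p_adj": 0.01, "sign": -1}]
        )
        n2 = conetwork.CoNetwork(edges=df2, vertices=["hub", "leaf0"], segment="ileum")
        edge_df, seg_df = conetwork.edge_sharing([n1, n2])
        shared = edge_df.query("genus_a == 'hub' and genus_b == 'leaf0'")
        assert shared.label.iloc[0] == "generalist"  # sign ignored
        assert seg_df.set_index("segment").loc["ileum", "pct_specialist"] == 0.0

    def test_single_network_rejected(self):
        with pytest.raises(ValueError):
            conetwork.edge_sharing([self._star()])

    def test_sign_ratio(self):
        net = self._star()  # hub: 5 positive, 0 negative
        sr = conetwork.sign_ratio(net).set_index("genus")
        assert sr.loc["hub", "log10_neg_pos"] == pytest.approx(np.log10(0.5 / 5.5))
        df = pd.DataFrame(
            [
                {"genus_a": "x", "genus_b": "y", "rho": 0.5, "p": 0.01, "p_adj": 0.01, "sign": 1},
                {"genus_a": "x", "genus_b": "z", "rho": -0.5, "p": 0.01, "p_adj": 0.01, "sign": -1},
            ]
        )
        net2 = conetwork.CoNetwork(edges=df, vertices=list("xyz"))
        sr2 = conetwork.sign_ratio(net2).set_index("genus")
        assert sr2.loc["x", "log10_neg_pos"] == pytest.approx(0.0)


class TestConsistency:
    def test_identical_networks_fully_consistent(self):
        rng = np.random.default_rng(7)
        m = np.abs(rng.normal(size=(40, 10))) + 0.1
        net = conetwork.build_network(_table(m), covariates=None)
        res = conetwork.qmp_rmp_consistency(net, net)
        assert res.consistency_pct == pytest.approx(100.0)

    def test_empty_networks_consistent(self):
        rng = np.random.default_rng(8)
        m = np.abs(rng.normal(size=(20, 6))) + 0.5
        net = conetwork.build_network(_table(m), covariates=None, alpha=1e-12)
        res = conetwork.qmp_rmp_consistency(net, net)
        assert res.consistency_pct == 100.0
        assert res.counts.loc["NS", "NS"] == len(net.all_pairs)

    def test_compositional_artifact_creates_offdiagonal_mass(self):
        """A taxon constant in absolute terms turns spuriously negative in
        relative terms when another taxon blooms 100-fold."""
        rng = np.random.default_rng(9)
        n = 60
        load = 10 ** rng.uniform(4, 6, n)  # 100-fold load swing
        bloomer = load * 0.5 * np.exp(rng.normal(0, 0.05, n))
        constant = np.full(n, 1e3) * np.exp(rng.normal(0, 0.05, n))
        fillers = np.abs(rng.normal(1e3, 50, (n, 4)))
        aa = np.column_stack([bloomer, constant, fillers])
        t_qmp = _table(aa, mode="QMP")
        rel = aa / aa.sum(axis=1, keepdims=True)
        t_rmp = _table(rel, mode="RMP")
        net_q = conetwork.build_network(t_qmp, covariates=None)
        net_r = conetwork.build_network(t_rmp, covariates=None)
        res = conetwork.qmp_rmp_consistency(net_q, net_r)
        off_diag = res.counts.to_numpy().sum() - np.trace(res.counts.to_numpy())
        assert off_diag > 0
        assert res.consistency_pct < 100.0
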