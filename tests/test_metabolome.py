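import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr
from sklearn.metrics import adjusted_rand_score

from qmpflow import metabolome
from qmpflow.synthio import TRAJECTORY_TEMPLATES


def _raw(n=40, p=30, seed=0):
    rng = np.random.default_rng(seed)
    data = pd.DataFrame(
        10 ** rng.uniform(3, 6, size=(n, p)),
        index=[f"s{i}" for i in range(n)],
        columns=[f"M{j}" for j in range(p)],
    )
    dph = pd.Series(np.tile([1, 4, 7, 14, 21, 28, 35, 42], n // 8), index=data.index)
    tax = pd.DataFrame(
        {"superclass": ["Lipids"] * p, "class": ["c"] * p, "subclass": ["s"] * p},
        index=data.columns,
    )
    return data, dph, tax


class TestFilter:
    def test_prevalence_strictly_above_30pct(self):
        data, dph, tax = _raw(n=40)
        data.iloc[12:, 0] = 0.0  # exactly 30% prevalence -> dropped
        data.iloc[13:, 1] = 0.0  # 32.5% -> kept
        table, log = metabolome.filter_features(data, dph, tax)
        assert "M0" not in table.data.columns
        assert "M1" in table.data.columns
        assert log["n_low_prevalence"] == 1

    def test_unannotated_dropped(self):
        data, dph, tax = _raw()
        tax.loc["M2", "superclass"] = "unknown"
        table, log = metabolome.filter_features(data, dph, tax)
        assert "M2" not in table.data.columns
        assert log["n_unannotated"] == 1


class TestOplsDa:
    def _planted(self, shift=2.0, n=40, p=200, seed=3):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(n, p))
        x[n // 2 :, :10] += shift
        data = pd.DataFrame(
            10 ** (0.1 * x + 4), index=[f"s{i}" for i in range(n)],
            columns=[f"M{j}" for j in range(p)],
        )
        groups = pd.Series(["early"] * (n // 2) + ["late"] * (n // 2), index=data.index)
        return data, groups

    def test_mean_squared_vip_is_one(self):
        data, groups = self._planted()
        res = metabolome.opls_da(data, groups)
        assert res.vip.pow(2).mean() == pytest.approx(1.0, abs=1e-8)

    def test_planted_discriminators_top_ranked_and_above_cutoff(self):
        data, groups = self._planted()
        res = metabolome.opls_da(data, groups)
        top10 = set(res.vip.sort_values(ascending=False).index[:10])
        planted = {f"M{j}" for j in range(10)}
        assert top10 == planted
        assert (res.vip[list(planted)] > 1.5).all()

    def test_shuffled_labels_collapse_signal(self):
        data, groups = self._planted()
        rng = np.random.default_rng(0)
        shuffled = pd.Series(rng.permutation(groups.to_numpy()), index=groups.index)
        res = metabolome.opls_da(data, shuffled)
        planted = [f"M{j}" for j in range(10)]
        assert res.vip[planted].mean() < 1.5
        # P1 no longer separates the true groups
        true_late = groups == "late"
        sep = abs(res.p1[true_late].mean() - res.p1[~true_late].mean()) / res.p1.std()
        assert sep < 1.0

    def test_p1_invariant_to_orthogonal_count_without_orthogonal_structure(self):
        # X = group direction + iid noise: no systematic Y-orthogonal
        # variation, so extra orthogonal components barely move P1
        rng = np.random.default_rng(7)
        n, p = 40, 100
        t = np.repeat([-1.0, 1.0], n // 2)
        loadings = rng.normal(size=p)
        x = np.outer(t, loadings) + rng.normal(0, 0.3, (n, p))
        data = pd.DataFrame(
            10 ** (0.1 * x + 4), index=[f"s{i}" for i in range(n)],
            columns=[f"M{j}" for j in range(p)],
        )
        groups = pd.Series(["a"] * (n // 2) + ["b"] * (n // 2), index=data.index)
        p1_a = metabolome.opls_da(data, groups, n_orth=1).p1
        p1_b = metabolome.opls_da(data, groups, n_orth=2).p1
        corr = abs(np.corrcoef(p1_a, p1_b)[0, 1])
        assert corr >= 0.999

    def test_single_sample_group_rejected(self):
        data, groups = self._planted()
        groups.iloc[0] = "loner"
        with pytest.raises(ValueError):
            metabolome.opls_da(data, groups)

    def test_constant_metabolite_dropped_with_warning(self):
        data, groups = self._planted()
        data["M0"] = 100.0
        with pytest.warns(UserWarning, match="constant"):
            res = metabolome.opls_da(data, groups)
        assert "M0" not in res.vip.index


class TestGlmTimeAssociation:
    def test_constant_metabolite_not_associated(self):
        data, dph, tax = _raw()
        data["M0"] = 500.0
        res = metabolome.glm_time_association(data, dph)
        assert not res.loc["M0", "associated"]
        assert res.loc["M0", "p"] == 1.0

    def test_planted_step_change_detected(self):
        rng = np.random.default_rng(1)
        n = 80
        dph = pd.Series(np.tile([1, 4, 7, 14, 21, 28, 35, 42], 10))
        x = rng.normal(0, 1, (n, 5))
        x[(dph >= 14).to_numpy(), 0] += 3.0  # 3 SD shift
        data = pd.DataFrame(10 ** (0.2 * x + 4), columns=[f"M{j}" for j in range(5)])
        res = metabolome.glm_time_association(data, dph)
        assert res.loc["M0", "associated"]

    def test_single_timepoint_rejected(self):
        data, dph, _ = _raw()
        with pytest.raises(ValueError):
            metabolome.glm_time_association(data, pd.Series(7, index=data.index))


class TestClusterTrajectories:
    def _template_table(self, per=20, noise=0.03, seed=2):
        rng = np.random.default_rng(seed)
        days = [1, 4, 7, 14, 21, 28, 35, 42]
        names, rows = [], []
        truth = {}
        for tname, shape in TRAJECTORY_TEMPLATES.items():
            for i in range(per):
                m = f"{tname}-{i}"
                truth[m] = tname
                names.append(m)
        samples = []
        for b in range(10):
            for di, d in enumerate(days):
                row = []
                for m in names:
                    shape = TRAJECTORY_TEMPLATES[truth[m]]
                    row.append(10 ** (4 + 0.5 * shape[di] + rng.normal(0, noise)))
                rows.append(row)
                samples.append(f"b{b}_d{d}")
        data = pd.DataFrame(rows, index=samples, columns=names)
        dph = pd.Series([int(s.split("_d")[1]) for s in samples], index=samples)
        tax = pd.DataFrame(
            {"superclass": "x", "class": "y", "subclass": "z"}, index=names
        )
        return metabolome.MetaboliteTable(data, dph, tax), pd.Series(truth)

    def test_planted_templates_recovered(self):
        table, truth = self._template_table()
        clusters = metabolome.cluster_trajectories(table, k=6)
        ari = adjusted_rand_score(truth.reindex(clusters.labels.index), clusters.labels)
        assert ari >= 0.9

    def test_monotone_up_lands_in_most_time_correlated_cluster(self):
        table, truth = self._template_table()
        clusters = metabolome.cluster_trajectories(table, k=6)
        days = clusters.mean_trajectories.columns.to_numpy(dtype=float)
        rho = {
            c: spearmanr(days, clusters.mean_trajectories.loc[c]).statistic
            for c in clusters.mean_trajectories.index
        }
        best_cluster = max(rho, key=rho.get)
        ups = truth[truth == "monotone-up"].index
        assert (clusters.labels.reindex(ups) == best_cluster).all()

    def test_k_exceeding_metabolites_rejected(self):
        table, _ = self._template_table(per=1)
        with pytest.raises(ValueError):
            metabolome.cluster_trajectories(table, k=10)

    def test_identical_profiles_flagged_degenerate(self):
        data = pd.DataFrame(
            np.tile(10 ** np.linspace(4, 5, 8), (10, 1)).T.repeat(3, axis=1),
            index=[f"s{i}" for i in range(8)],
        )
        dph = pd.Series([1, 4, 7, 14, 21, 28, 35, 42], index=data.index)
        tax = pd.DataFrame({"superclass": "x"}, index=data.columns)
        table = metabolome.MetaboliteTable(data, dph, tax)
        with pytest.warns(UserWarning, match="degenerate"):
            clusters = metabolome.cluster_trajectories(table, k=6)
        assert clusters.degenerate

    def test_deterministic_given_input_order(self):
        table, _ = self._template_table()
        a = metabolome.cluster_trajectories(table, k=6).labels
        b = metabolome.cluster_trajectories(table, k=6).labels
        pd.testing.assert_series_equal(a, b)


class TestClusterComposition:
    def test_single_cluster_single_superclass(self):
        table, truth = TestClusterTrajectories()._template_table(per=2)
        clusters = metabolome.cluster_trajectories(table, k=6)
        comp = metabolome.cluster_composition(clusters, table.taxonomy)
        np.testing.assert_allclose(comp.sum(axis=1), 1.0)
        assert set(comp.columns) == {"x"}
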