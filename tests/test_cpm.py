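"""CPM: edge selection, strength, cross-validation, permutation, hubs."""

import warnings

import numpy as np
import pytest

import connkit as ck
from connkit.cpm import (
    CPM,
    CpmConfig,
    degree_table,
    groupwise_evaluation,
    high_degree_followup,
    network_strength,
    partial_correlation,
    select_edges,
)


class TestSelectEdges:
    def test_behavior_copy_edge_selected_with_r_one(self, rng):
        X = rng.normal(size=(30, 40))
        y = X[:, 7].copy()
        pos, neg, r = select_edges(X, y)
        assert 7 in pos
        assert r[7] == pytest.approx(1.0)
        pos2, neg2, r2 = select_edges(X, -y)
        assert 7 in neg2 and r2[7] == pytest.approx(-1.0)

    def test_null_selection_count_near_alpha_e(self, rng):
        E, n, alpha = 6670, 60, 0.005
        X = rng.normal(size=(n, E))
        y = rng.normal(size=n)
        pos, neg, _ = select_edges(X, y, alpha)
        total = len(pos) + len(neg)
        # binomial(E, alpha): mean ~33, sd ~5.8
        assert 10 <= total <= 60

    def test_constant_edge_excluded_with_warning(self, rng):
        X = rng.normal(size=(20, 5))
        X[:, 2] = 1.0
        y = X[:, 0] + rng.normal(0, 0.01, 20)
        with pytest.warns(UserWarning, match="constant"):
            pos, neg, r = select_edges(X, y)
        assert 2 not in pos and 2 not in neg and np.isnan(r[2])

    def test_constant_behavior_rejected(self, rng):
        with pytest.raises(ValueError, match="zero variance"):
            select_edges(rng.normal(size=(10, 4)), np.ones(10))


class TestNetworkStrength:
    def test_empty_set_is_zero(self, rng):
        assert network_strength(rng.normal(size=8), np.array([], int)) == 0.0

    def test_singleton_and_additivity(self, rng):
        v = rng.normal(size=20)
        a = np.array([1, 4, 7])
        b = np.array([2, 9])
        assert network_strength(v, np.array([3])) == pytest.approx(v[3])
        assert network_strength(v, np.concatenate([a, b])) == pytest.approx(
            network_strength(v, a) + network_strength(v, b)
        )

    def test_matrix_input_gives_per_subject_strengths(self, rng):
        X = rng.normal(size=(5, 10))
        s = network_strength(X, np.array([0, 3]))
        assert s.shape == (5,)
        assert np.allclose(s, X[:, [0, 3]].sum(axis=1))


def _noiseless_cohort(seed=0):
    spec = ck.CohortSpec(
        n_regions=35,
        behavior_edges=ck.planted_component(35, 20, offset=10),
        noise_sd_behavior=0.0,
        seed=seed,
    )
    c = ck.generate_matrix_cohort(spec)
    ck.generate_behavior(spec, c)
    return spec, c


class TestCrossValidation:
    def test_noiseless_planted_network_recovered(self):
        spec, c = _noiseless_cohort()
        model = CPM(c.edge_matrix(), c.manifest["wis"].to_numpy(float),
                    CpmConfig(seed=0), n_regions=35)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit()
        assert set(spec.behavior_edges) <= set(res.consensus_positive)
        assert res.performance("positive") >= 0.95
        assert res.performance("combined") >= 0.95

    def test_no_leakage_from_held_out_subject(self):
        spec, c = _noiseless_cohort(seed=1)
        X = c.edge_matrix().copy()
        y = c.manifest["wis"].to_numpy(float)
        model = CPM(X, y, CpmConfig(seed=0), n_regions=35)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            base = model.fit()
        # corrupting one subject's edges must not change that fold's selection
        X2 = X.copy()
        X2[3] = 1e6 * np.arange(X.shape[1])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pert = CPM(X2, y, CpmConfig(seed=0), n_regions=35).fit()
        assert np.array_equal(base.fold_positive[3], pert.fold_positive[3])
        assert np.array_equal(base.fold_negative[3], pert.fold_negative[3])

    def test_consensus_subset_of_every_fold(self):
        _, c = _noiseless_cohort(seed=2)
        model = CPM(c.edge_matrix(), c.manifest["wis"].to_numpy(float),
                    CpmConfig(seed=0), n_regions=35)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit()
        for fold in res.fold_positive:
            assert set(res.consensus_positive) <= set(fold)

    def test_consensus_invariant_to_subject_order_loocv(self):
        _, c = _noiseless_cohort(seed=3)
        X = c.edge_matrix()
        y = c.manifest["wis"].to_numpy(float)
        perm = np.random.default_rng(0).permutation(len(y))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1 = CPM(X, y, CpmConfig(seed=0), n_regions=35).fit()
            r2 = CPM(X[perm], y[perm], CpmConfig(seed=0), n_regions=35).fit()
        assert np.array_equal(np.sort(r1.consensus_positive),
                              np.sort(r2.consensus_positive))

    def test_kfold_reproducible_under_seed(self):
        _, c = _noiseless_cohort(seed=4)
        X = c.edge_matrix()
        y = c.manifest["wis"].to_numpy(float)
        cfg = CpmConfig(cv="kfold", n_folds=5, seed=9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p1 = CPM(X, y, cfg, groups=c.groups).fit().predictions
            p2 = CPM(X, y, cfg, groups=c.groups).fit().predictions
        assert p1.equals(p2)

    def test_zero_selection_fold_predicts_training_mean(self, rng):
        X = rng.normal(size=(12, 30))
        y = rng.normal(size=12)
        with pytest.warns(UserWarning, match="no edges"):
            res = CPM(X, y, CpmConfig(select_alpha=1e-9, seed=0)).fit()
        train_means = [np.delete(y, i).mean() for i in range(12)]
        assert np.allclose(res.predictions["combined"].to_numpy(), train_means)

    def test_negative_r_reported_as_zero_when_configured(self, rng):
        X = rng.normal(size=(14, 25))
        y = rng.normal(size=14)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = CPM(X, y, CpmConfig(select_alpha=0.3, seed=0)).fit()
        for m in ("positive", "negative", "combined"):
            assert res.performance(m) >= 0.0


class TestPermutationTest:
    def test_strong_signal_attains_lower_bound(self):
        _, c = _noiseless_cohort(seed=5)
        model = CPM(c.edge_matrix(), c.manifest["wis"].to_numpy(float),
                    CpmConfig(seed=0), n_regions=35)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit()
            p = model.permutation_test(res, n_permutations=50, seed=1)
        assert p["positive"] == pytest.approx(1 / 51)
        assert res.permutation_p == p

    def test_null_data_large_p(self, rng):
        X = rng.normal(size=(20, 40))
        y = rng.normal(size=20)
        model = CPM(X, y, CpmConfig(select_alpha=0.1, seed=0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = model.permutation_test(n_permutations=100, seed=2)
        assert p["combined"] > 0.05


class TestDegreeAndFollowup:
    def test_degree_example_and_handshake(self, rng):
        # edges (0,1) and (0,2) are the first two row-major edges at N=4
        tbl = degree_table(np.array([0, 1]), 4)
        deg = tbl.set_index("region_id")["degree"]
        assert deg[0] == 2 and deg[1] == 1 and deg[2] == 1 and deg[3] == 0
        for _ in range(100):
            edges = rng.choice(ck.n_edges(12), size=rng.integers(0, 30),
                               replace=False)
            t = degree_table(edges, 12)
            assert t["degree"].sum() == 2 * len(edges)

    def test_star_hub_degree(self):
        iu, ju = ck.edge_index(10)
        star = np.flatnonzero((iu == 0) | (ju == 0))[:6]
        tbl = degree_table(star, 10)
        assert tbl.iloc[0]["region_id"] == 0
        assert tbl.iloc[0]["degree"] == 6

    def test_hub_subnetwork_reproduces_full_network_when_star(self, rng):
        # consensus = star on node 0 -> the hub's incident set IS the network
        spec = ck.CohortSpec(n_regions=15, seed=8)
        iu, ju = ck.edge_index(15)
        star = tuple(int(e) for e in np.flatnonzero(iu == 0)[:10])
        spec2 = ck.CohortSpec(n_regions=15, behavior_edges=star,
                              noise_sd_behavior=0.0, seed=8)
        c = ck.generate_matrix_cohort(spec2)
        ck.generate_behavior(spec2, c)
        X = c.edge_matrix()
        y = c.manifest["wis"].to_numpy(float)
        model = CPM(X, y, CpmConfig(seed=0), n_regions=15)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit()
            tbl = high_degree_followup(X, y, res, k=1)
        s_full = network_strength(X, res.consensus_positive)
        r_full, _ = partial_correlation(s_full, y)
        hub_edges = res.consensus_positive[
            (iu[res.consensus_positive] == 0) | (ju[res.consensus_positive] == 0)
        ]
        if len(hub_edges) == len(res.consensus_positive):
            assert tbl.iloc[0]["r"] == pytest.approx(r_full, abs=1e-12)
        else:  # a few off-hub false positives entered the consensus
            assert tbl.iloc[0]["r"] >= 0.9 * r_full

    def test_followup_fdr_column_monotone_with_p(self):
        _, c = _noiseless_cohort(seed=6)
        X = c.edge_matrix()
        y = c.manifest["wis"].to_numpy(float)
        model = CPM(X, y, CpmConfig(seed=0), n_regions=35)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit()
            tbl = high_degree_followup(X, y, res, k=4)
        assert (tbl["p_fdr"] >= tbl["p"] - 1e-15).all()
        assert (tbl["p_fdr"] <= 1.0).all()


class TestGroupwise:
    def test_patient_only_dependence_detected(self, rng):
        n_p, n_c = 25, 35
        s = rng.normal(size=n_p + n_c)
        y = np.empty(n_p + n_c)
        y[:n_p] = 2.0 * s[:n_p] + rng.normal(0, 0.5, n_p)
        y[n_p:] = rng.normal(0, 1.0, n_c)
        groups = np.array(["patient"] * n_p + ["control"] * n_c)
        tbl = groupwise_evaluation(s, y, groups).set_index("group")
        assert tbl.loc["patient", "p"] < 0.01
        assert tbl.loc["control", "p"] > 0.05

    def test_symmetric_dependence_similar_r(self, rng):
        s = rng.normal(size=60)
        y = s + rng.normal(0, 0.3, 60)
        groups = np.array(["patient"] * 30 + ["control"] * 30)
        tbl = groupwise_evaluation(s, y, groups)
        assert abs(tbl["r"].iloc[0] - tbl["r"].iloc[1]) < 0.25

    def test_tiny_group_excluded_with_warning(self, rng):
        s = rng.normal(size=10)
        y = rng.normal(size=10)
        groups = np.array(["patient"] * 3 + ["control"] * 7)
        with pytest.warns(UserWarning, match="fewer than 4"):
            tbl = groupwise_evaluation(s, y, groups)
        assert tbl["group"].tolist() == ["control"]
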