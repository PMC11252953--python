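"""Joint group-lasso GGM: standardization, fitting, BIC, stability."""

import numpy as np
import pandas as pd
import pytest

from synovnet import ggm
from conftest import edges_of


@pytest.fixture(scope="module")
def two_group_gauss():
    rng = np.random.default_rng(3)
    return {
        "healthy": rng.standard_normal((60, 6)),
        "mild": rng.standard_normal((55, 6)),
    }


class TestStandardize:
    def test_moments(self, two_group_gauss):
        std = ggm.standardize(two_group_gauss)
        for X in std.values():
            assert np.abs(X.mean(axis=0)).max() < 1e-12
            assert np.abs(X.std(axis=0, ddof=1) - 1).max() < 1e-12

    def test_location_invariance(self, two_group_gauss):
        std = ggm.standardize(two_group_gauss)
        shifted = {g: X + 13.5 for g, X in two_group_gauss.items()}
        std2 = ggm.standardize(shifted)
        for g in std:
            np.testing.assert_allclose(std[g], std2[g], atol=1e-9)

    def test_idempotence(self, two_group_gauss):
        once = ggm.standardize(two_group_gauss)
        twice = ggm.standardize(once)
        for g in once:
            np.testing.assert_allclose(once[g], twice[g], atol=1e-12)

    def test_zero_variance_column_reported(self):
        X = np.ones((10, 3))
        X[:, 0] = np.arange(10)
        df = pd.DataFrame(X, columns=["ok", "flat1", "flat2"])
        with pytest.raises(ValueError, match="flat1"):
            ggm.standardize({"g": df})


class TestFitJewel:
    def test_full_shrinkage_gives_empty_graphs(self, two_group_gauss):
        std = ggm.standardize(two_group_gauss)
        lmax = ggm.lambda1_max(std)
        fit = ggm.fit_jewel(
            std, ggm.JewelConfig(lambda1=lmax * 1.01, lambda2=10.0)
        )
        for g in fit.groups:
            assert fit.edge_set(g) == set()
        assert np.count_nonzero(fit.omega) == 0

    def test_symmetry_and_zero_diagonal(self, two_group_gauss):
        std = ggm.standardize(two_group_gauss)
        fit = ggm.fit_jewel(std, ggm.JewelConfig(lambda1=0.1, lambda2=0.1))
        for g in fit.groups:
            adj = fit.adjacency(g)
            np.testing.assert_array_equal(adj, adj.T)
            assert not adj.diagonal().any()
            assert not fit.theta(g).diagonal().any()

    def test_objective_monotone_nonincreasing(self, two_group_gauss):
        std = ggm.standardize(two_group_gauss)
        fit = ggm.fit_jewel(
            std, ggm.JewelConfig(lambda1=0.05, lambda2=0.05),
            track_objective=True,
        )
        path = fit.objective_path
        assert len(path) >= 1
        assert (np.diff(path) <= 1e-10).all()

    def test_edge_count_nonincreasing_in_lambda1(self, two_group_gauss):
        std = ggm.standardize(two_group_gauss)
        counts = []
        for l1 in (0.02, 0.08, 0.2, 0.5):
            fit = ggm.fit_jewel(std, ggm.JewelConfig(lambda1=l1, lambda2=0.3))
            counts.append(sum(len(fit.edge_set(g)) for g in fit.groups))
        assert counts == sorted(counts, reverse=True)

    def test_kkt_conditions_at_convergence(self, two_group_gauss):
        std = ggm.standardize(two_group_gauss)
        cfg = ggm.JewelConfig(lambda1=0.1, lambda2=0.08, tol=1e-7,
                              max_iter=5000)
        fit = ggm.fit_jewel(std, cfg, track_objective=False)
        viol = ggm.kkt_check(std, fit, cfg)
        assert viol["zero"] <= 1e-5
        assert viol["active"] <= 1e-5

    def test_chain_support_recovery_two_groups(self, chain_precision):
        cov = np.linalg.inv(chain_precision)
        L = np.linalg.cholesky(cov)
        rng = np.random.default_rng(0)
        Xs = {g: rng.standard_normal((500, 3)) @ L.T for g in ("h", "m")}
        fit = ggm.fit_jewel(
            ggm.standardize(Xs), ggm.JewelConfig(lambda1=0.1, lambda2=0.1)
        )
        for g in ("h", "m"):
            assert fit.edge_set(g) == {(0, 1), (1, 2)}

    def test_unstandardized_input_rejected(self, two_group_gauss):
        bad = {g: X + 5.0 for g, X in two_group_gauss.items()}
        with pytest.raises(ValueError, match="standardized"):
            ggm.fit_jewel(bad, ggm.JewelConfig())

    def test_mismatched_variable_sets_rejected(self, two_group_gauss):
        std = ggm.standardize(two_group_gauss)
        std["mild"] = std["mild"][:, :4]
        with pytest.raises(ValueError, match="variable"):
            ggm.fit_jewel(std, ggm.JewelConfig())


class TestBIC:
    def test_single_point_grids(self, two_group_gauss):
        std = ggm.standardize(two_group_gauss)
        (l1, l2), path = ggm.bic_select(std, [0.12], [0.05])
        assert (l1, l2) == (0.12, 0.05)
        assert len(path) == 2  # one evaluation per stage

    def test_bic_matches_independent_recomputation(self, two_group_gauss):
        std = ggm.standardize(two_group_gauss)
        cfg = ggm.JewelConfig(lambda1=0.15, lambda2=0.1)
        fit = ggm.fit_jewel(std, cfg)
        expected = 0.0
        for g in fit.groups:
            R = fit.residuals[g]
            n_k = fit.n_k[g]
            rss = (R**2).sum(axis=0)
            df_k = len(fit.edge_set(g))
            expected += float(n_k * np.log(rss / n_k).sum()) + np.log(n_k) * df_k
        assert ggm.bic(fit) == pytest.approx(expected, rel=1e-12)

    def test_two_stage_structure(self, two_group_gauss):
        std = ggm.standardize(two_group_gauss)
        (l1, l2), path = ggm.bic_select(
            std, [0.05, 0.15, 0.3], [0.01, 0.1], lambda2_fixed=0.2
        )
        stage1 = path[path["stage"] == 1]
        assert (stage1["lambda2"] == 0.2).all()
        assert l1 in {0.05, 0.15, 0.3}
        stage2 = path[path["stage"] == 2]
        assert (stage2["lambda1"] == l1).all()
        assert l2 in {0.01, 0.1}


class TestStabilitySelection:
    def test_degenerate_resampling_equals_single_fit(self, two_group_gauss):
        std = ggm.standardize(two_group_gauss)
        cfg = ggm.JewelConfig(lambda1=0.15, lambda2=0.15, B=1,
                              subset_fraction=1.0, pi_thr=0.8, seed=0)
        fit = ggm.fit_jewel(std, cfg)
        est = ggm.stability_selection(std, cfg)
        for g in fit.groups:
            assert edges_of(est.adjacency[g]) == fit.edge_set(g)

    def test_reduces_false_positives_on_truth(self, recovery_data):
        truth, Xs = recovery_data
        std = ggm.standardize(Xs)
        cfg = ggm.JewelConfig(lambda1=0.3, lambda2=0.3, B=60,
                              subset_fraction=0.8, pi_thr=0.8, seed=1)
        single = ggm.fit_jewel(std, cfg)
        est = ggm.stability_selection(std, cfg)
        for g in ("healthy", "mild"):
            true = truth.edge_set(g)
            single_edges = single.edge_set(g)
            stab_edges = edges_of(est.adjacency[g])
            assert len(stab_edges) <= len(single_edges)
            assert len(stab_edges - true) <= len(single_edges - true)

    def test_frequencies_within_unit_interval(self, two_group_gauss):
        std = ggm.standardize(two_group_gauss)
        cfg = ggm.JewelConfig(lambda1=0.1, lambda2=0.1, B=20,
                              subset_fraction=0.7, seed=2)
        est = ggm.stability_selection(std, cfg)
        for g in est.groups:
            f = est.frequency[g]
            assert (f >= 0).all() and (f <= 1).all()
        assert est.n_undefined_edges >= 0


class TestSelectFeatures:
    def _table(self):
        return pd.DataFrame(
            {
                "seq_id": ["a", "b", "c", "d"],
                "contrast": ["mild-healthy"] * 4,
                "log2fc": [2.0, -2.0, 1.0, 0.5],
                "se": [0.3, 0.2, 0.1, 0.1],
                "uniprot": ["P1", "P2", "P2", "P3"],
            }
        )

    def test_take_all_when_n_exceeds_available(self):
        with pytest.warns(UserWarning):
            chosen, n_prot = ggm.select_features(self._table(), n_aptamers=10)
        assert set(chosen) == {"a", "b", "c", "d"}
        assert n_prot == 3

    def test_tie_break_order(self):
        # a and b tie on |fc| = 2.0; b wins on smaller SE
        chosen, _ = ggm.select_features(self._table(), n_aptamers=1)
        assert chosen == ["b"]
        chosen3, _ = ggm.select_features(self._table(), n_aptamers=3)
        assert chosen3 == ["b", "a", "c"]

    def test_seq_id_breaks_exact_ties(self):
        t = self._table()
        t["se"] = 0.2
        chosen, _ = ggm.select_features(t, n_aptamers=2)
        assert chosen == ["a", "b"]


class TestCollapse:
    def test_duplicate_protein_nodes_merge_by_edge_union(self):
        import networkx as nx

        G = nx.Graph([("apt1", "apt2"), ("apt2", "apt3"), ("apt1", "apt3")])
        labels = {"apt1": "ProtA", "apt2": "ProtA", "apt3": "ProtB"}
        H = ggm.collapse_by_label(G, labels)
        assert set(H.nodes) == {"ProtA", "ProtB"}
        assert set(map(frozenset, H.edges)) == {frozenset(("ProtA", "ProtB"))}
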