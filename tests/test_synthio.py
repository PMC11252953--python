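"""Synthetic data generator: edge truth, positive definiteness, sampling."""

import numpy as np
import pandas as pd
import pytest

from synovnet import synthio


def _base_cfg(**kw):
    defaults = dict(
        p=20,
        n_per_group={"healthy": 10, "mild": 10},
        n_shared_edges=15,
        n_unique_edges_per_group=3,
        n_differential=5,
        frac_unmapped=0.0,
        frac_nonhuman=0.0,
        n_buffer=3,
        n_replicate_pairs=2,
        seed=0,
    )
    defaults.update(kw)
    return synthio.SyntheticConfig(**defaults)


class TestPrecisionMatrices:
    def test_no_unique_edges_gives_identical_matrices(self):
        truth = synthio.make_precision_matrices(
            _base_cfg(n_unique_edges_per_group=0)
        )
        mats = list(truth.precision_matrices.values())
        np.testing.assert_array_equal(mats[0], mats[1])

    @pytest.mark.parametrize("seed", range(5))
    def test_positive_definite_by_eigendecomposition(self, seed):
        truth = synthio.make_precision_matrices(_base_cfg(seed=seed))
        for om in truth.precision_matrices.values():
            assert np.linalg.eigvalsh(om)[0] > 0
            np.testing.assert_array_equal(om, om.T)
            assert (np.diag(om) > 0).all()

    def test_partial_correlation_identity_single_edge(self):
        # p=3, one shared edge: ρij = −ωij/√(ωii ωjj) must reproduce the
        # drawn magnitude exactly when no diagonal loading is needed
        cfg = _base_cfg(
            p=3, n_shared_edges=1, n_unique_edges_per_group=0,
            partial_corr_range=(0.5, 0.5), n_differential=0,
        )
        truth = synthio.make_precision_matrices(cfg)
        (i, j) = next(iter(truth.shared_edges))
        om = truth.precision_matrices["healthy"]
        rho = -om[i, j] / np.sqrt(om[i, i] * om[j, j])
        assert abs(abs(rho) - 0.5) < 1e-9

    @pytest.mark.parametrize("seed", range(4))
    def test_edge_sets_round_trip_from_matrices(self, seed):
        truth = synthio.make_precision_matrices(_base_cfg(seed=seed))
        for g, om in truth.precision_matrices.items():
            assert synthio._edges_from_precision(om) == truth.edge_set(g)
        for g in truth.unique_edges:
            assert not (truth.shared_edges & truth.unique_edges[g])

    def test_infeasible_edge_count_rejected(self):
        with pytest.raises(ValueError, match="edges"):
            _base_cfg(p=4, n_shared_edges=10).validate()


class TestSampleDataset:
    def test_noiseless_degenerate_case_equals_group_means(self):
        cfg = _base_cfg(
            sigma_subject=0.0, network_scale=0.0, n_differential=0,
            n_covariate_affected=0, n_replicate_pairs=0,
        )
        truth = synthio.make_precision_matrices(cfg)
        matrix, samples, _ = synthio.sample_dataset(truth, cfg)
        study = samples[samples["sample_type"] == "study"]
        log2 = np.log2(matrix.data.loc[list(study["sample_id"])])
        np.testing.assert_allclose(
            log2.to_numpy(), np.tile(truth.baseline_log2, (len(study), 1)),
            atol=1e-9,
        )

    def test_large_n_partial_correlations_recovered(self, chain_precision):
        om5 = np.eye(5)
        for i in range(4):
            om5[i, i + 1] = om5[i + 1, i] = -0.4
        truth = synthio.make_precision_matrices(
            _base_cfg(p=5, n_shared_edges=0, n_unique_edges_per_group=0,
                      n_differential=0, n_covariate_affected=0,
                      sigma_subject=0.0,
                      n_per_group={"healthy": 2000, "mild": 3})
        )
        truth.precision_matrices["healthy"] = om5
        cfg = _base_cfg(p=5, n_shared_edges=0, n_unique_edges_per_group=0,
                        n_differential=0, n_covariate_affected=0,
                        sigma_subject=0.0,
                        n_per_group={"healthy": 2000, "mild": 3})
        matrix, samples, _ = synthio.sample_dataset(truth, cfg)
        ids = samples.loc[samples["group"] == "healthy", "sample_id"]
        X = np.log2(matrix.data.loc[list(ids)].to_numpy())
        emp_prec = np.linalg.inv(np.cov(X, rowvar=False))
        d = np.sqrt(np.diag(emp_prec))
        emp_pc = -emp_prec / np.outer(d, d)
        true_pc = -om5 / np.outer(np.sqrt(np.diag(om5)), np.sqrt(np.diag(om5)))
        off = ~np.eye(5, dtype=bool)
        assert np.abs(emp_pc[off] - true_pc[off]).max() < 0.05

    def test_partial_correlation_error_shrinks_with_n(self):
        maes = []
        for n in (100, 1000, 10000):
            per_seed = []
            for seed in (3, 4, 5, 6):
                cfg = _base_cfg(p=5, n_shared_edges=4,
                                n_unique_edges_per_group=0,
                                n_differential=0, n_covariate_affected=0,
                                sigma_subject=0.0,
                                n_per_group={"healthy": n, "mild": 3}, seed=seed)
                truth = synthio.make_precision_matrices(cfg)
                matrix, samples, _ = synthio.sample_dataset(truth, cfg)
                ids = samples.loc[samples["group"] == "healthy", "sample_id"]
                X = np.log2(matrix.data.loc[list(ids)].to_numpy())
                emp = np.linalg.inv(np.cov(X, rowvar=False))
                d = np.sqrt(np.diag(emp))
                emp_pc = -emp / np.outer(d, d)
                om = truth.precision_matrices["healthy"]
                dd = np.sqrt(np.diag(om))
                true_pc = -om / np.outer(dd, dd)
                off = ~np.eye(5, dtype=bool)
                per_seed.append(np.abs(emp_pc[off] - true_pc[off]).mean())
            maes.append(np.mean(per_seed))
        assert maes[0] > maes[1] > maes[2]

    def test_reproducibility_bit_identical(self):
        cfg = _base_cfg(seed=42)
        t1 = synthio.make_precision_matrices(cfg)
        t2 = synthio.make_precision_matrices(cfg)
        m1, s1, a1 = synthio.sample_dataset(t1, cfg)
        m2, s2, a2 = synthio.sample_dataset(t2, cfg)
        pd.testing.assert_frame_equal(m1.data, m2.data)
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(a1, a2)

    def test_unmapped_fraction_exact_count(self):
        cfg = _base_cfg(p=100, frac_unmapped=0.1, n_shared_edges=0,
                        n_unique_edges_per_group=0)
        truth = synthio.make_precision_matrices(cfg)
        assert int((truth.annotations["uniprot_ids"] == "").sum()) == 10

    def test_buffer_and_replicate_rows_present(self):
        cfg = _base_cfg(n_buffer=4, n_replicate_pairs=3)
        truth = synthio.make_precision_matrices(cfg)
        _, samples, _ = synthio.sample_dataset(truth, cfg)
        assert (samples["sample_type"] == "buffer").sum() == 4
        pairs = synthio.replicate_pairs(samples)
        assert len(pairs) == 3
        lut = samples.set_index("sample_id")
        for orig, rep in pairs:
            assert lut.loc[rep, "subject_id"] == lut.loc[orig, "subject_id"]
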