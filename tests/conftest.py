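import numpy as np
import pandas as pd
import pytest

from synovnet import preprocess, synthio


@pytest.fixture(scope="session")
def chain_precision():
    """3-variable chain 1–2–3 with partial correlation 0.5 on each edge."""
    om = np.eye(3)
    om[0, 1] = om[1, 0] = -0.5
    om[1, 2] = om[2, 1] = -0.5
    return om


@pytest.fixture(scope="session")
def recovery_data():
    """Fixed two-group dataset with known graph truth for recovery tests."""
    cfg = synthio.SyntheticConfig(
        p=30,
        n_per_group={"healthy": 150, "mild": 150},
        n_shared_edges=40,
        n_unique_edges_per_group=5,
        partial_corr_range=(0.3, 0.5),
        n_differential=0,
        sigma_subject=0.0,
        n_covariate_affected=0,
        frac_unmapped=0.0,
        frac_nonhuman=0.0,
        n_buffer=0,
        n_replicate_pairs=0,
        seed=7,
    )
    truth = synthio.make_precision_matrices(cfg)
    matrix, samples, _ = synthio.sample_dataset(truth, cfg)
    log2m = preprocess.log2_transform(matrix)
    Xs = {
        g: log2m.data.loc[list(samples.loc[samples["group"] == g, "sample_id"])]
        for g in ("healthy", "mild")
    }
    return truth, Xs


@pytest.fixture()
def two_group_samples():
    """Balanced two-group sample table without covariate variation."""
    n = 12
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "subject_id": [f"u{i}" for i in range(n)],
            "group": ["healthy"] * (n // 2) + ["mild"] * (n // 2),
            "sex": ["M"] * n,
            "age": [70.0] * n,
            "sample_type": ["study"] * n,
        }
    )


def edges_of(adj: np.ndarray) -> set[tuple[int, int]]:
    p = adj.shape[0]
    return {(i, j) for i in range(p) for j in range(i + 1, p) if adj[i, j]}
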