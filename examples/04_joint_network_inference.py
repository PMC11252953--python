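"""Joint two-group Gaussian graphical model with stability selection.

Node-wise regressions with a two-level group-lasso penalty estimate a
common edge backbone (λ1) plus group-specific deviations (λ2); stability
selection over random variable subsets keeps edges present in ≥80% of the
refits where both endpoints were sampled.
"""

import numpy as np

from synovnet import ggm, preprocess, synthio

cfg = synthio.SyntheticConfig(
    p=40, n_per_group={"healthy": 150, "mild": 150},
    n_shared_edges=40, n_unique_edges_per_group=8,
    partial_corr_range=(0.3, 0.5), n_differential=0, sigma_subject=0.0,
    n_covariate_affected=0, frac_unmapped=0.0, frac_nonhuman=0.0,
    n_buffer=0, n_replicate_pairs=0, seed=4,
)
truth = synthio.make_precision_matrices(cfg)
matrix, samples, _ = synthio.sample_dataset(truth, cfg)
log2m = preprocess.log2_transform(matrix)
Xs = {g: log2m.data.loc[list(samples.loc[samples["group"] == g, "sample_id"])]
      for g in ("healthy", "mild")}
std = ggm.standardize(Xs)

jcfg = ggm.JewelConfig(lambda1=0.3, lambda2=0.3, B=200, pi_thr=0.8, seed=0)
single = ggm.fit_jewel(std, jcfg)
est = ggm.stability_selection(std, jcfg, var_names=log2m.seq_ids)


def score(edges, true):
    tp = len(edges & true)
    return tp, len(edges - true), 2 * tp / max(2 * tp + len(edges ^ true), 1)


for g in ("healthy", "mild"):
    true = truth.edge_set(g)
    adj = est.adjacency[g]
    p = adj.shape[0]
    stab = {(i, j) for i in range(p) for j in range(i + 1, p) if adj[i, j]}
    tp1, fp1, f11 = score(single.edge_set(g), true)
    tp2, fp2, f12 = score(stab, true)
    print(f"{g}: single fit TP={tp1} FP={fp1} F1={f11:.2f} | "
          f"stability TP={tp2} FP={fp2} F1={f12:.2f} (true edges: {len(true)})")
# Stability selection trades a little recall for precision: false-positive
# edges (FP) drop while most true conditional dependencies survive.
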