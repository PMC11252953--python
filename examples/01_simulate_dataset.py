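"""Generate a synthetic synovial-fluid proteomics dataset with known truth.

The generator draws per-group multivariate-normal log2 abundances whose
precision matrices share a common edge backbone, then layers on disease,
sex and age effects, donor intercepts, buffer wells and replicate pairs.
"""

from synovnet import synthio

cfg = synthio.SyntheticConfig(
    p=80,
    n_shared_edges=40,
    n_unique_edges_per_group=6,
    n_differential=15,
    seed=1,
)
truth = synthio.make_precision_matrices(cfg)
matrix, samples, annotations = synthio.sample_dataset(truth, cfg)

print(f"intensity matrix: {matrix.data.shape[0]} samples x "
      f"{matrix.data.shape[1]} aptamers ({matrix.scale} scale)")
study = samples[samples["sample_type"] == "study"]
print(f"study groups: {study['group'].value_counts().to_dict()} "
      f"(+{(samples['sample_type'] == 'replicate').sum()} replicates, "
      f"{(samples['sample_type'] == 'buffer').sum()} buffer wells)")
print(f"true shared edges: {len(truth.shared_edges)}; "
      f"unique per group: { {g: len(e) for g, e in truth.unique_edges.items()} }")
print(f"aptamers with true group shifts: {len(truth.differential_aptamers)}")
# The edge sets and shift magnitudes above are the ground truth that the
# preprocessing, differential and network stages are later scored against.
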