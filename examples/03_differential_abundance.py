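"""Batched mixed-model differential abundance with group contrasts.

Aptamers are modeled 25 at a time in one linear mixed model per batch
(fixed: aptamer, group, sex, age + aptamer interactions; random intercept
per donor). Contrasts are mild−healthy and lateOA−healthy with 95% CIs.
"""

from synovnet import diffabund, preprocess, synthio

cfg = synthio.SyntheticConfig(p=50, n_differential=12, effect_range=(0.8, 2.5),
                              frac_unmapped=0.0, frac_nonhuman=0.0, seed=3)
truth = synthio.make_precision_matrices(cfg)
matrix, samples, annotations = synthio.sample_dataset(truth, cfg)
study = samples[samples["sample_type"] == "study"]
log2m = preprocess.log2_transform(matrix.subset_samples(list(study["sample_id"])))

table = diffabund.run_differential(log2m, study, annotations,
                                   batch_size=25, seed=0)
table = diffabund.flag_differential(table)

late = table[table["contrast"] == "lateOA-healthy"].copy()
top = late.loc[late["log2fc"].abs().sort_values(ascending=False).index].head(5)
print(top[["seq_id", "gene", "log2fc", "ci_low", "ci_high", "direction"]]
      .to_string(index=False))
counts = diffabund.protein_direction_counts(table, "lateOA-healthy")
print(f"proteins up/down in late-stage OA vs healthy: {counts}")
# 'up' means the 95% CI of the log2 fold change lies entirely above zero;
# a log2fc of 2 is a four-fold abundance increase.
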