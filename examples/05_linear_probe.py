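"""Linear evaluation: reuse frozen representations for a new task.

Extract features with a (here: randomly initialized) encoder, z-score
them with training-set statistics, fit a ridge logistic probe with
4-fold CV over the 10-value l2 penalty grid, and report holdout f1 with
a bootstrap standard deviation.
"""

import numpy as np

from pclr.architecture import EncoderConfig, build_encoder
from pclr.linear_eval import (FeatureTable, evaluate_probe, extract_features,
                              fit_probe)
from pclr.preprocess import preprocess_cohort
from pclr.synthetic import generate_cohort

cohort = generate_cohort(160, 1, seed=12)
groups = preprocess_cohort(cohort, resample_to=1024)
records = [g.records[0] for g in groups]
y = np.array([g.records[0].labels["hypertrophy_like"] for g in cohort])

encoder = build_encoder(EncoderConfig(
    input_length=1024, conv_filter_size=8, channels_per_stage=(8, 16, 32),
    representation_dim=32, downsample_per_block=4), seed=0)
table = extract_features(encoder, records)
print(f"feature table: {table.features.shape[0]} records x "
      f"{table.n_features} representation features")

train_idx, hold_idx = np.arange(100), np.arange(100, 160)


def subset(idx):
    return FeatureTable([table.record_ids[i] for i in idx],
                        table.features[idx])


train = subset(train_idx).normalized()              # stats from train rows
hold = subset(hold_idx).normalized(train.stats)     # train stats reused

probe = fit_probe(train, y[train_idx], "classification", seed=0)
print(f"selected l2 penalty: {probe.selected_penalty:g} "
      f"(4-fold CV over 10 values in [1e-6, 1e5])")

result = evaluate_probe(probe, hold, y[hold_idx], n_bootstraps=500, seed=0)
print(result.summary())
print("the +- value is one SD over bootstrap resamples of the holdout; "
      "hypertrophy-like is an amplitude criterion, so even a random "
      "encoder's features carry some signal")
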