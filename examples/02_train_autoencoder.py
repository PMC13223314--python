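"""Train the convolutional sparse autoencoder and check reconstruction.

Fits the CSAE without labels on the source-domain training trials of one
leave-one-subject-out fold, then reports the held-out-trial reconstruction
R^2 and the sparsity level of the bottleneck.  Takes about a minute.
"""

from dataclasses import replace

import numpy as np

from semglearn import (
    TrainConfig,
    apply_scaler,
    build_csae,
    fit_scaler,
    generate_cohort,
    make_loso_folds,
    r2_reconstruction,
    reference_cohorts,
    segment_cohort,
    small_csae_config,
    train_csae,
)

cohort = generate_cohort(replace(reference_cohorts(reduced=True)["easy6"], seed=0))
batch = segment_cohort(cohort, 250.0, 125.0)
plan = make_loso_folds(cohort)[0]

src = batch.select(subjects=plan.source_subjects)
train = src.select(trials=plan.source_train_trials)
scaler = fit_scaler(train)  # fitted on training trials only
train_s = apply_scaler(train, scaler)
val_s = apply_scaler(src.select(trials=plan.source_val_trials), scaler)
test_s = apply_scaler(src.select(trials=plan.source_test_trials), scaler)

model = build_csae(small_csae_config(seed=0), train_s.segments.shape[1:])
train_csae(model, train_s, val_s,
           TrainConfig(max_epochs=30, early_stop_patience=8, learning_rate=2e-3))

r2 = r2_reconstruction(model, test_s)
z = model.encode(test_s)
print(f"stopped after {model.history['stopped_epoch']} epochs")
print(f"held-out reconstruction R^2 = {r2:.3f}")
print(f"bottleneck Z shape = {z.shape} (T' x D per window)")
print(f"mean |Z| = {np.abs(z).mean():.3f}")
# R^2 above 0.9 means the compressed temporal code retains nearly all the
# signal; Z is the feature map the classifier consumes.
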