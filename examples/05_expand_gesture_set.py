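"""Incremental expansion from 6 to 10 gestures with weight transfer.

Trains a 6-class model on the base gestures of the "easy10" preset, widens
its softmax layer to 10 units (copying the original class weights), runs
the two-phase protocol, and prints the phase scores plus the forgetting
table for the original gestures.  Takes a few minutes.
"""

from dataclasses import replace

from semglearn import (
    generate_cohort,
    reference_cohorts,
    run_loso,
    small_classifier_config,
    small_csae_config,
    TrainConfig,
)
from semglearn.experiments import TC_PHASE2

cohort = generate_cohort(replace(reference_cohorts(reduced=True)["easy10"],
                                 seed=2))
out = run_loso(
    cohort, protocol="expand",
    csae_config=small_csae_config(),
    clf_config=small_classifier_config(6),
    tc_csae=TrainConfig(max_epochs=30, early_stop_patience=8, learning_rate=2e-3),
    tc_clf=TrainConfig(max_epochs=200, early_stop_patience=30, learning_rate=2e-3),
    tc_phase2=TC_PHASE2,
    seed=2, folds=[0])

print(f"6-class baseline micro-F1:      {out['base6'].mean_micro_f1:.3f}")
print(f"Phase I (output layer only):    {out['phase1'].mean_micro_f1:.3f}")
print(f"Phase II (full head, low rate): {out['phase2'].mean_micro_f1:.3f}")
print("\nForgetting on the original classes (F1 before vs after expansion):")
print(out["forgetting"][0][["f1_before", "f1_after", "delta"]].round(3))
# negative deltas mark classes absorbed by their combined counterparts —
# the hierarchical ambiguity between a finger flexion and thumb+finger.
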