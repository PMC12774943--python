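"""Run the dual-network b-value selector on a synthetic cohort and print the
reduced 4-b-value protocol it emits."""

import numpy as np

import verdictmri as v

scheme = v.kidney_full_protocol()
cohort = v.make_cohort(
    v.PhantomSpec(shape=(16, 16, 3), snr=50.0, seed=0),
    n_subjects=6,
    seed=0,
    scheme=scheme,
)

cfg = v.SelectionConfig(seed=0)
scores = v.train_dual_network(cohort, cfg)
per_b = scores.cohort.reshape(scheme.n_combos, 3).mean(axis=1)

print(f"{'b (s/mm^2)':>10} {'mean importance score':>22}")
for b, s in zip(scheme.b_values, per_b):
    print(f"{b:10.0f} {s:22.3f}")

selected = v.select_protocol(scores, cfg, scheme)
reduced = v.reduce_scheme(scheme, selected)
print(
    f"\nretained b-values: {sorted(selected.b_values)} "
    f"({len(selected.measurement_indices)} measurements in 3 directions)"
)
print(f"reduced scheme: {reduced.n_combos} combos, {reduced.n_volumes} volumes")
print(
    "\nScores are sigmoid outputs in [0,1], averaged over each b-value's "
    "direction triplet\nand over subjects; the four highest-scoring b-values "
    "form an acquirable short protocol."
)
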