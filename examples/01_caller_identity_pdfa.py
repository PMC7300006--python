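"""Is caller identity encoded in conflict-call acoustics?

Generates a study-scale call-unit table (9 callers, 6 bouts each, with a
planted caller effect about twice the within-caller noise), applies the
inclusion rule, and runs the permuted discriminant function analysis:
an LDA classifies every unit to a caller, and the observed accuracy is
compared with a null built by shuffling caller labels at the bout level.
"""

import troopkit as tk

spec = tk.CallSimSpec(seed=11)
table = tk.gen_call_features(spec)
eligible, table = tk.check_inclusion(table)
print(f"{len(table)} call units from {table['bout_id'].nunique()} bouts, "
      f"{len(eligible)} eligible callers")

res = tk.pdfa_test(table, n_perm=999, seed=1)
print(f"observed accuracy : {res.observed_accuracy:.1%}")
print(f"chance (null mean): {res.null_mean:.1%} "
      f"[95% CI {res.null_ci[0]:.1%}-{res.null_ci[1]:.1%}]")
print(f"p-value           : {res.p_value:.4g}")

# Observed accuracy far above the null interval means the calls carry a
# caller-identity signature that bout-level label shuffling cannot mimic.
cv = tk.pdfa_crossvalidated(table, n_perm=199, seed=1)
print(f"leave-one-out accuracy: {cv.observed_accuracy:.1%} "
      "(guards against overfitting of the resubstitution estimate)")
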