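"""Rotation-invariant feature reduction in action.

Extracts the 254-feature axis-dependent vectors from a recording and a
randomly rotated copy, collapses both to the 90-feature rotation-invariant
layout, and reports how much each class of reduced feature moved.
"""

import numpy as np

import wearact as wa
from wearact.classify import recording_features
from wearact.features import AXIS_MANIFEST, ROTINV_MANIFEST, FeaturePrimitive

rec, _ = wa.simulate_recording(wa.SynthSubjectParams(seed=5), subject_id="demo")
windows = wa.segment_windows(rec)
rotated = wa.apply_rotation(rec, wa.random_rotation(np.random.default_rng(2)))

X = recording_features(rec, windows.start_indices, windows.window_len)
Xr = recording_features(rotated, windows.start_indices, windows.window_len)
print(f"axis-dependent features: {X.shape[1]} per window, {X.shape[0]} windows")

R = wa.rotation_invariant_reduce(X)
Rr = wa.rotation_invariant_reduce(Xr)
print(f"reduced to {R.shape[1]} rotation-invariant features")

rel = np.abs(Rr - R) / (np.abs(R) + 1e-12)
time_signals = {"body_acc", "gravity_acc", "body_jerk"}
exact, stable = [], []
for j, entry in enumerate(ROTINV_MANIFEST.entries):
    src = AXIS_MANIFEST.entries[entry.source_indices[0]]
    is_exact = (
        entry.kind == "sqrt_sum"
        or (entry.kind == "norm" and src.signal in time_signals
            and src.primitive in (FeaturePrimitive.MEAN, FeaturePrimitive.STD))
        or (entry.kind == "pass" and src.signal.startswith("mag_"))
    )
    (exact if is_exact else stable).append(j)

print(f"exactly invariant subset ({len(exact)} features): "
      f"max relative change {rel[:, exact].max():.2e}")
print(f"approximately stable remainder ({len(stable)} features): "
      f"median relative change {np.median(rel[:, stable]):.3f}")

# The invariant core (means, trace-of-covariance SDs, energies, band
# energies, magnitude-signal features) moves only at machine precision;
# the remaining order-statistic and spectral-shape reductions drift but
# stay informative — they are what the surrogate classifier runs on.
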