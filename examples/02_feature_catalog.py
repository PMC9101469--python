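"""Walk through the 333-feature catalog and extract one window's features.

Shows the catalog arithmetic (166 per foot + 1 bilateral weight-shift
count; 25 time-domain, 112 FFT, 196 wavelet features) and evaluates the
catalog on a single sliding window of a simulated trial.
"""

from fogcast import (
    GaitSimConfig,
    ParticipantProfile,
    WindowSpec,
    build_catalog,
    build_signal_bundle,
    extract_feature_vector,
    make_windows,
    simulate_trial,
)

catalog = build_catalog()
print(f"bilateral catalog: {len(catalog)} features")
print("by domain:", catalog.counts_by_domain())
print("feature types:", catalog.n_feature_types())
print("first five:", catalog.names[:5])
print("last (bilateral):", catalog.names[-1])

trial = simulate_trial(
    GaitSimConfig(trial_duration=30.0, seed=3),
    ParticipantProfile("P01", "left", True),
    "P01_T00",
)
bundle = build_signal_bundle(trial)
windows = make_windows(trial, WindowSpec())
target = next(w for w in windows if w.is_target)
fv = extract_feature_vector(bundle, target, catalog)
print(f"\nwindow [{target.start:.1f}, {target.end:.1f}) s is '{target.window_class}'")
for name in ("left_vel_ap_fft_freeze_index", "left_cop_ap_reversal_count",
             "bilateral_weight_shift_count"):
    print(f"  {name:35s} = {fv.values[catalog.names.index(name)]:.3f}")
print("-> one row of the window × 333 feature matrix fed to Relief-F.")
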