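"""Simulate one walking trial with freezing-of-gait episodes and inspect it.

Generates a 30 s trial for a freezer, then contrasts the freeze index
(3–8 Hz over 0.5–3 Hz spectral power of AP COP velocity) during a freeze
against steady walking — the spectral signature the whole pipeline exploits.
"""

import numpy as np

from fogcast import GaitSimConfig, ParticipantProfile, build_signal_bundle, simulate_trial
from fogcast.features import fft_feature_block

config = GaitSimConfig(trial_duration=30.0, seed=7)
profile = ParticipantProfile("P01", mas_side="left", is_freezer=True)
trial = simulate_trial(config, profile, "P01_T00")

print(f"trial {trial.trial_id}: {trial.duration:.0f} s at {trial.sampling_rate:.0f} Hz")
print("segments:", [(s.kind, round(s.start, 1), round(s.end, 1)) for s in trial.segments])
print("episodes:", [(round(e.onset, 2), round(e.end, 2)) for e in trial.episodes])

bundle = build_signal_bundle(trial)
fs = trial.sampling_rate
episode = trial.episodes[0]
i0 = int(episode.onset * fs)
fog_window = bundle.left["vel_ap"][i0 : i0 + 100]
walk_start = int((trial.segments[1].start + 0.5) * fs)
walk_window = bundle.left["vel_ap"][walk_start : walk_start + 100]

fi_fog = fft_feature_block(fog_window, fs)[7]
fi_walk = fft_feature_block(walk_window, fs)[7]
print(f"freeze index during FOG:     {fi_fog:10.2f}")
print(f"freeze index while walking:  {fi_walk:10.4f}")
print("-> trembling shifts COP power into the 3-8 Hz freeze band, so the")
print("   ratio is an order of magnitude larger during an episode.")
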