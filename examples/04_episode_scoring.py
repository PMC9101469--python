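"""Episode-level evaluation on a hand-made classification timeline.

Three consecutive target-class windows raise a model trigger decision
(MTD); MTDs within 2.5 s of the last cue are suppressed; each freeze
episode owns a target zone opening up to 6 s before onset. This example
scores a small timeline by hand so every disposition is visible.
"""

import numpy as np

from fogcast import EvalConfig, build_target_zones, detect_mtds, score_episodes
from fogcast.synthetic import EpisodeAnnotation, SegmentAnnotation

# one 30 s trial: windows end every 0.2 s from t = 1 s
ends = 1.0 + 0.2 * np.arange(146)
classes = np.zeros(146, dtype=bool)
classes[12:15] = True   # a spurious early run  -> MTD at 3.8 s (false positive)
classes[85:110] = True  # run-up to the episode -> first MTD at 19.0 s

episodes = [EpisodeAnnotation(onset=19.5, end=23.0)]
segments = [SegmentAnnotation("stand", 0.0, 2.5), SegmentAnnotation("walk", 2.5, 30.0)]

config = EvalConfig()
mtds = detect_mtds(ends, classes, config, trial_id="T0")
zones = build_target_zones(episodes, segments, config, trial_id="T0")
card = score_episodes(mtds, zones, {"T0": segments}, n_trials=1, config=config)

print(f"zone for episode at {episodes[0].onset} s:",
      (round(zones[0].zone_start, 2), round(zones[0].zone_end, 2)),
      "| truncated by:", zones[0].truncation_reason)
for m in mtds:
    print(f"  MTD at {m.instant:5.1f} s  -> {m.disposition}")
print(f"episodes identified: {card.episodes_identified:.0f} %")
print(f"identification delay: {card.mean_identification_delay:+.1f} s "
      "(negative = predicted before onset)")
print(f"false positives/trial: {card.false_positives_per_trial:.1f}")
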