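"""Two-layer model evaluation: window-level sensitivity/specificity and
episode-level model-trigger-decision (MTD) scoring.

An MTD fires at the end of every window that completes a run of ≥ 3
consecutive target-class classifications — the instant a cueing system would
cue. A 2.5 s no-cue (refractory) interval then suppresses any MTD that
follows the last unsuppressed MTD too closely.

Each freeze episode owns an *MTD target zone*: it opens 6 s before onset —
raised to 1 s after the end of any turn or stand segment intruding on that
span, or to the end of a prior episode (no delay) — and extends through the
episode's end, so late detections still count as identifications with a
positive identification delay (ID). Unsuppressed MTDs inside a zone are true
positives; those outside are false positives unless they fall within a stand
segment or the first second of walking after standing (gait initiation),
which are ignored. Episode metrics per participant: percentage of episodes
identified (EI), mean ID over identified episodes (negative = predicted
before onset), and false positives per trial (FPR).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "EvalConfig",
    "MTDEvent",
    "TargetZone",
    "EpisodeScorecard",
    "window_metrics",
    "detect_mtds",
    "build_target_zones",
    "score_episodes",
    "rank_sum_select",
    "METRIC_ORIENTATION",
]


@dataclass(frozen=True)
class EvalConfig:
    consecutive_windows_for_mtd: int = 3
    prediction_zone: float = 6.0
    event_delay: float = 1.0  # delay after turn/stand ends before a zone opens
    no_cue_interval: float = 2.5
    gait_initiation: float = 1.0  # first second of walking after standing

    def __post_init__(self) -> None:
        for name in ("consecutive_windows_for_mtd", "prediction_zone",
                     "event_delay", "no_cue_interval", "gait_initiation"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class MTDEvent:
    instant: float  # end time of the third consecutive target window
    trial_id: str = ""
    suppressed: bool = False
    disposition: str | None = None  # set once by score_episodes


@dataclass(frozen=True)
class TargetZone:
    onset: float  # episode onset
    zone_start: float
    zone_end: float  # = episode end
    truncation_reason: str = "none"  # none | prior-FOG | turn | stand
    trial_id: str = ""

    def contains(self, instant: float) -> bool:
        return self.zone_start <= instant <= self.zone_end


@dataclass
class EpisodeScorecard:
    participant_id: str = ""
    sensitivity: float = np.nan  # %, window level
    specificity: float = np.nan  # %, window level
    episodes_identified: float = np.nan  # EI, %
    mean_identification_delay: float = np.nan  # ID, s (negative = early)
    false_positives_per_trial: float = np.nan  # FPR
    n_episodes: int = 0
    n_trials: int = 0

    def as_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
            "episodes_identified_pct": self.episodes_identified,
            "identification_delay_s": self.mean_identification_delay,
            "false_positives_per_trial": self.false_positives_per_trial,
            "n_episodes": self.n_episodes,
            "n_trials": self.n_trials,
        }


def window_metrics(predicted, truth):
    """Window-level (sensitivity %, specificity %) of target-class calls.

    ``predicted`` and ``truth`` are boolean arrays (True = target). A truth
    vector missing a class yields NaN for the metric that is undefined.
    """
    pred = np.asarray(predicted, dtype=bool)
    true = np.asarray(truth, dtype=bool)
    if pred.shape != true.shape:
        raise ValueError("predicted and truth must align")
    tp = int(np.sum(pred & true))
    fn = int(np.sum(~pred & true))
    tn = int(np.sum(~pred & ~true))
    fp = int(np.sum(pred & ~true))
    sens = 100.0 * tp / (tp + fn) if (tp + fn) else np.nan
    spec = 100.0 * tn / (tn + fp) if (tn + fp) else np.nan
    return sens, spec


def detect_mtds(
    window_end_times,
    window_classes,
    config: EvalConfig = EvalConfig(),
    trial_id: str = "",
) -> list:
    """Fire an MTD at the end of every window completing a run of ≥ 3
    consecutive target classifications, then apply the no-cue filter.

    Overlapping runs emit one MTD per completing window; suppression marks
    any MTD closer than ``no_cue_interval`` to the last *unsuppressed* MTD.
    """
    ends = np.asarray(window_end_times, dtype=float)
    classes = np.asarray(window_classes, dtype=bool)
    if ends.shape != classes.shape:
        raise ValueError("window times and classes must align")
    if np.any(np.diff(ends) < 0):
        raise ValueError("windows must be time-ordered")
    events = []
    run = 0
    for end, is_target in zip(ends, classes):
        run = run + 1 if is_target else 0
        if run >= config.consecutive_windows_for_mtd:
            events.append(MTDEvent(instant=float(end), trial_id=trial_id))
    last_unsuppressed = -np.inf
    for ev in events:
        if ev.instant - last_unsuppressed < config.no_cue_interval:
            ev.suppressed = True
            ev.disposition = "suppressed"
        else:
            last_unsuppressed = ev.instant
    return events


def build_target_zones(
    episodes, segments, config: EvalConfig = EvalConfig(), trial_id: str = ""
) -> list:
    """Per-episode MTD target zones, truncated by intruding events.

    The zone opens at ``onset − prediction_zone``; a turn or stand segment
    ending inside that span pushes the opening to ``segment end +
    event_delay``, a prior episode to its end (no delay). A zone whose
    opening would pass the onset collapses to a detection-only zone
    ``[onset, episode end]``.
    """
    eps = [(e.onset, e.end) if not isinstance(e, tuple) else e for e in episodes]
    if any(b[0] < a[1] for a, b in zip(eps, eps[1:])):
        raise ValueError("episodes must be ordered and non-overlapping")
    segs = [
        (s.kind, s.start, s.end) if not isinstance(s, tuple) else s for s in segments
    ]
    zones = []
    for i, (onset, ep_end) in enumerate(eps):
        start = onset - config.prediction_zone
        reason = "none"
        for prev_onset, prev_end in eps[:i]:
            if start < prev_end <= onset and prev_end > start:
                start, reason = prev_end, "prior-FOG"
        for kind, _s_start, s_end in segs:
            if kind in ("turn", "stand") and onset - config.prediction_zone < s_end < onset:
                candidate = s_end + config.event_delay
                if candidate > start:
                    start, reason = candidate, kind
        if start > onset:
            start = onset  # collapsed: detection-only zone
        zones.append(
            TargetZone(onset=onset, zone_start=float(start), zone_end=float(ep_end),
                       truncation_reason=reason, trial_id=trial_id)
        )
    return zones


def _in_stand(instant: float, segs) -> bool:
    return any(k == "stand" and s <= instant < e for k, s, e in segs)


def _in_gait_initiation(instant: float, segs, config: EvalConfig) -> bool:
    for k, _s, e in segs:
        if k == "stand" and e <= instant < e + config.gait_initiation:
            return True
    return False


def score_episodes(
    mtds: list,
    zones: list,
    segments_by_trial: dict,
    n_trials: int,
    config: EvalConfig = EvalConfig(),
    participant_id: str = "",
) -> EpisodeScorecard:
    """Assign a disposition to every MTD and aggregate episode metrics.

    Suppressed MTDs never enter scoring. Each unsuppressed MTD is a true
    positive (inside a zone of its trial), ignored (inside a stand segment or
    the gait-initiation second after one), or a false positive. An episode is
    identified iff at least one MTD lies in its zone; its ID is the earliest
    such instant minus onset.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    segs_norm = {
        tid: [(s.kind, s.start, s.end) if not isinstance(s, tuple) else s
              for s in segs]
        for tid, segs in segments_by_trial.items()
    }
    zones_by_trial: dict = {}
    for z in zones:
        zones_by_trial.setdefault(z.trial_id, []).append(z)
    identified: dict = {}
    n_fp = 0
    for ev in mtds:
        if ev.suppressed:
            ev.disposition = "suppressed"
            continue
        hit_zones = [
            z for z in zones_by_trial.get(ev.trial_id, []) if z.contains(ev.instant)
        ]
        if hit_zones:
            ev.disposition = "true-positive"
            for z in hit_zones:
                key = (ev.trial_id, z.onset)
                identified[key] = min(identified.get(key, np.inf), ev.instant)
        else:
            segs = segs_norm.get(ev.trial_id, [])
            if _in_stand(ev.instant, segs):
                ev.disposition = "ignored-standing"
            elif _in_gait_initiation(ev.instant, segs, config):
                ev.disposition = "ignored-gait-initiation"
            else:
                ev.disposition = "false-positive"
                n_fp += 1
    n_episodes = len(zones)
    if n_episodes:
        ei = 100.0 * len(identified) / n_episodes
        delays = [inst - onset for (_tid, onset), inst in identified.items()]
        mean_id = float(np.mean(delays)) if delays else np.nan
    else:
        ei, mean_id = np.nan, np.nan
    return EpisodeScorecard(
        participant_id=participant_id,
        episodes_identified=ei,
        mean_identification_delay=mean_id,
        false_positives_per_trial=n_fp / n_trials,
        n_episodes=n_episodes,
        n_trials=n_trials,
    )


# Orientation of each scorecard metric when ranking models (True = higher is
# better). ID ranks by signed value: earlier identification is better.
METRIC_ORIENTATION = {
    "sensitivity_pct": True,
    "specificity_pct": True,
    "episodes_identified_pct": True,
    "identification_delay_s": False,
    "false_positives_per_trial": False,
}


def rank_sum_select(metric_table: pd.DataFrame, orientation: dict | None = None):
    """Pick the model with the smallest rank sum across evaluation metrics.

    ``metric_table`` has one row per model (index = number of features) and
    one column per metric. Per metric, models are ranked 1 = best with
    average ranks on ties; the smallest rank sum wins, ties going to the
    model with fewer features. Returns ``(best_index, rank_sums)``.
    """
    orientation = METRIC_ORIENTATION if orientation is None else orientation
    missing = [c for c in orientation if c not in metric_table.columns]
    if missing:
        raise ValueError(f"metric table is missing columns: {missing}")
    if metric_table[list(orientation)].isna().any().any():
        raise ValueError("metric table contains missing values")
    ranks = pd.DataFrame(index=metric_table.index)
    for metric, higher_better in orientation.items():
        vals = metric_table[metric].to_numpy(dtype=float)
        ranks[metric] = rankdata(-vals if higher_better else vals, method="average")
    rank_sums = ranks.sum(axis=1)
    best_sum = rank_sums.min()
    tied = rank_sums[rank_sums == best_sum]
    best = tied.index.min()  # fewer features wins ties
    return best, rank_sums
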