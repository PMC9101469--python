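"""Episode-level evaluation: MTD detection, target zones, scoring, and the
rank-sum model selector, checked against a brute-force timeline simulator."""

import numpy as np
import pandas as pd
import pytest

from fogcast.evaluation import (
    EvalConfig,
    MTDEvent,
    build_target_zones,
    detect_mtds,
    rank_sum_select,
    score_episodes,
    window_metrics,
)
from fogcast.synthetic import EpisodeAnnotation, SegmentAnnotation


class TestWindowMetrics:
    def test_two_by_two_counts(self):
        sens, spec = window_metrics([True, False, False, True], [True, True, False, False])
        assert (sens, spec) == (50.0, 50.0)

    def test_perfect_prediction(self):
        truth = np.array([True, False, True, False])
        assert window_metrics(truth, truth) == (100.0, 100.0)

    def test_all_nontarget_prediction(self):
        sens, spec = window_metrics(np.zeros(4, bool), np.array([1, 1, 0, 0], bool))
        assert (sens, spec) == (0.0, 100.0)

    def test_one_sided_truth_is_undefined(self):
        sens, spec = window_metrics(np.zeros(3, bool), np.zeros(3, bool))
        assert np.isnan(sens) and spec == 100.0


class TestDetectMtds:
    def test_minimal_run_fires_once(self):
        events = detect_mtds([5.0, 5.2, 5.4], [True, True, True])
        assert len(events) == 1 and events[0].instant == 5.4

    def test_broken_run_restarts(self):
        classes = [True, True, False, True, True, True]
        ends = [1.0, 1.2, 1.4, 1.6, 1.8, 2.0]
        events = detect_mtds(ends, classes)
        assert [e.instant for e in events] == [2.0]

    def test_no_cue_filter(self):
        ends = [5.0, 5.2, 5.4, 5.6, 5.8]
        events = detect_mtds(ends, [True] * 5)
        assert [e.instant for e in events] == [5.4, 5.6, 5.8]
        assert [e.suppressed for e in events] == [False, True, True]

    def test_unsuppressed_events_respect_refractory_interval(self, rng):
        ends = 1.0 + 0.2 * np.arange(200)
        classes = rng.random(200) < 0.5
        events = detect_mtds(ends, classes)
        kept = [e.instant for e in events if not e.suppressed]
        assert all(b - a >= 2.5 for a, b in zip(kept, kept[1:]))


class TestBuildTargetZones:
    def test_isolated_episode_gets_full_zone(self):
        zones = build_target_zones([EpisodeAnnotation(20.0, 24.0)], [])
        assert (zones[0].zone_start, zones[0].zone_end) == (14.0, 24.0)
        assert zones[0].truncation_reason == "none"

    def test_turn_end_delays_zone_start(self):
        segments = [SegmentAnnotation("turn", 15.0, 17.5)]
        zones = build_target_zones([EpisodeAnnotation(20.0, 24.0)], segments)
        assert zones[0].zone_start == 18.5
        assert zones[0].truncation_reason == "turn"

    def test_prior_episode_truncates_without_delay(self):
        episodes = [EpisodeAnnotation(17.0, 19.5), EpisodeAnnotation(20.0, 24.0)]
        zones = build_target_zones(episodes, [])
        assert zones[1].zone_start == 19.5
        assert zones[1].truncation_reason == "prior-FOG"

    def test_collapsed_zone_becomes_detection_only(self):
        segments = [SegmentAnnotation("stand", 10.0, 19.8)]
        zones = build_target_zones([EpisodeAnnotation(20.0, 24.0)], segments)
        assert zones[0].zone_start == 20.0

    def test_zone_containment_invariant(self, rng):
        for _ in range(50):
            onset = float(rng.uniform(10, 40))
            episodes = [EpisodeAnnotation(onset, onset + float(rng.uniform(1, 5)))]
            segments = [
                SegmentAnnotation("turn", onset - 8, onset - 8 + float(rng.uniform(0.5, 7)))
            ]
            z = build_target_zones(episodes, segments)[0]
            assert onset - 6 <= z.zone_start <= onset < z.zone_end == episodes[0].end


class TestScoreEpisodes:
    config = EvalConfig()

    def _zone(self, onset=20.0, end=24.0, start=14.0, trial="T"):
        from fogcast.evaluation import TargetZone

        return TargetZone(onset=onset, zone_start=start, zone_end=end, trial_id=trial)

    def test_early_identification_negative_delay(self):
        mtds = [MTDEvent(19.2, "T")]
        card = score_episodes(mtds, [self._zone()], {"T": []}, n_trials=1)
        assert card.episodes_identified == 100.0
        assert card.mean_identification_delay == pytest.approx(-0.8)
        assert mtds[0].disposition == "true-positive"

    def test_out_of_zone_is_false_positive(self):
        mtds = [MTDEvent(13.0, "T")]
        card = score_episodes(mtds, [self._zone()], {"T": []}, n_trials=1)
        assert card.false_positives_per_trial == 1.0
        assert mtds[0].disposition == "false-positive"

    def test_standing_mtd_ignored(self):
        mtds = [MTDEvent(5.0, "T")]
        segments = {"T": [SegmentAnnotation("stand", 4.0, 6.0)]}
        card = score_episodes(mtds, [self._zone()], segments, n_trials=1)
        assert card.false_positives_per_trial == 0.0
        assert mtds[0].disposition == "ignored-standing"

    def test_gait_initiation_mtd_ignored(self):
        mtds = [MTDEvent(6.5, "T")]
        segments = {"T": [SegmentAnnotation("stand", 4.0, 6.0),
                          SegmentAnnotation("walk", 6.0, 30.0)]}
        card = score_episodes(mtds, [self._zone()], segments, n_trials=1)
        assert mtds[0].disposition == "ignored-gait-initiation"
        assert card.false_positives_per_trial == 0.0

    def test_no_episodes_keeps_fpr_defined(self):
        mtds = [MTDEvent(3.0, "T")]
        card = score_episodes(mtds, [], {"T": []}, n_trials=2)
        assert np.isnan(card.episodes_identified)
        assert card.false_positives_per_trial == 0.5

    def test_suppressed_events_never_scored(self):
        mtds = [MTDEvent(19.2, "T"), MTDEvent(19.4, "T", suppressed=True)]
        score_episodes(mtds, [self._zone()], {"T": []}, n_trials=1)
        assert mtds[1].disposition == "suppressed"


class TestRankSumSelect:
    metrics = ["sensitivity_pct", "specificity_pct", "episodes_identified_pct",
               "identification_delay_s", "false_positives_per_trial"]

    def _table_with_worked_ranks(self):
        """Six models whose per-metric ranks give (3, 5, 3, 1, 5) for the
        5-feature model: third for sensitivity, fifth for specificity, third
        for episodes identified, first for ID, fifth for false positives."""
        table = pd.DataFrame(
            {
                "sensitivity_pct":          [74.0, 76.0, 70.0, 75.0, 69.0, 68.0],
                "specificity_pct":          [82.0, 84.0, 85.0, 86.0, 81.0, 87.0],
                "episodes_identified_pct":  [92.0, 94.0, 90.0, 93.0, 89.0, 88.0],
                "identification_delay_s":   [-0.8, -0.6, -0.5, -0.4, -0.3, -0.2],
                "false_positives_per_trial": [2.0, 2.2, 1.5, 1.8, 1.2, 1.0],
            },
            index=[5, 10, 15, 20, 25, 30],
        )
        return table

    def test_worked_example_sums_to_17(self):
        _best, sums = rank_sum_select(self._table_with_worked_ranks())
        assert sums.loc[5] == 17.0

    def test_dominant_model_selected(self):
        table = self._table_with_worked_ranks()
        table.loc[10] = [99.0, 99.0, 100.0, -5.0, 0.1]
        best, sums = rank_sum_select(table)
        assert best == 10 and sums.loc[10] == 5.0

    def test_ties_get_average_ranks(self):
        table = self._table_with_worked_ranks()
        table.loc[10, "sensitivity_pct"] = table.loc[5, "sensitivity_pct"]
        _best, sums = rank_sum_select(table)
        # the tied models share rank (2+3)/2 = 2.5 for sensitivity
        assert sums.loc[5] == 16.5

    def test_missing_metric_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_select(self._table_with_worked_ranks().drop(columns=["sensitivity_pct"]))


# --------------------------------------------------------------------------
# Oracle equivalence: brute-force event-by-event timeline simulator


def brute_force_timeline(ends, classes, episodes, segments, cfg):
    """Independent event-by-event simulation of the whole MTD pipeline."""
    raw = []
    run = 0
    for end, c in zip(ends, classes):
        run = run + 1 if c else 0
        if run >= cfg.consecutive_windows_for_mtd:
            raw.append(end)
    unsuppressed, last = [], -np.inf
    for m in raw:
        if m - last >= cfg.no_cue_interval:
            unsuppressed.append(m)
            last = m
    zones = []
    for i, (onset, ep_end) in enumerate(episodes):
        zs = onset - cfg.prediction_zone
        for p_onset, p_end in episodes[:i]:
            if zs < p_end <= onset:
                zs = max(zs, p_end)
        for kind, _s, s_end in segments:
            if kind in ("turn", "stand") and onset - cfg.prediction_zone < s_end < onset:
                zs = max(zs, s_end + cfg.event_delay)
        zones.append((min(zs, onset), ep_end, onset))
    identified = {}
    n_fp = 0
    for m in unsuppressed:
        hits = [z for z in zones if z[0] <= m <= z[1]]
        if hits:
            for z in hits:
                identified[z[2]] = min(identified.get(z[2], np.inf), m)
        else:
            in_stand = any(k == "stand" and s <= m < e for k, s, e in segments)
            in_init = any(
                k == "stand" and e <= m < e + cfg.gait_initiation
                for k, s, e in segments
            )
            if not in_stand and not in_init:
                n_fp += 1
    ei = 100.0 * len(identified) / len(episodes) if episodes else np.nan
    delays = [inst - onset for onset, inst in identified.items()]
    mean_id = float(np.mean(delays)) if delays else np.nan
    return ei, mean_id, n_fp, len(raw), len(unsuppressed)


def _random_timeline(rng):
    n_windows = int(rng.integers(20, 250))
    ends = 1.0 + 0.2 * np.arange(n_windows)
    classes = rng.random(n_windows) < rng.uniform(0.1, 0.6)
    duration = ends[-1]
    episodes = []
    t = float(rng.uniform(4, 10))
    while t + 3 < duration and len(episodes) < 4:
        end = t + float(rng.uniform(1, 5))
        episodes.append((t, min(end, duration)))
        t = end + float(rng.uniform(2.5, 12))
    segments = []
    if rng.random() < 0.8:
        segments.append(("stand", 0.0, float(rng.uniform(1, 3))))
    if rng.random() < 0.8:
        s = float(rng.uniform(5, max(6.0, duration - 4)))
        segments.append(("turn", s, s + 2.5))
    return ends, classes, episodes, segments


def test_scorer_matches_brute_force_simulator_on_200_timelines():
    cfg = EvalConfig()
    rng = np.random.default_rng(987)
    for _ in range(200):
        ends, classes, episodes, segments = _random_timeline(rng)
        mtds = detect_mtds(ends, classes, cfg, trial_id="T")
        zones = build_target_zones(episodes, segments, cfg, trial_id="T")
        card = score_episodes(mtds, zones, {"T": segments}, n_trials=1, config=cfg)
        ei, mean_id, n_fp, n_raw, n_unsup = brute_force_timeline(
            ends, classes, episodes, segments, cfg
        )
        assert len(mtds) == n_raw
        assert sum(not m.suppressed for m in mtds) == n_unsup
        np.testing.assert_equal(card.episodes_identified, ei)
        np.testing.assert_equal(card.mean_identification_delay, mean_id)
        assert card.false_positives_per_trial == n_fp
        # disposition partition: every raw MTD ends with exactly one label
        labels = [m.disposition for m in mtds]
        assert all(
            d in ("suppressed", "true-positive", "false-positive",
                  "ignored-standing", "ignored-gait-initiation")
            for d in labels
        )
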