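"""Synthetic plantar-pressure gait cohorts with freezing-of-gait episodes.

Real freezing-of-gait (FOG) recordings are clinical data that cannot be
redistributed, so this module generates trials carrying the statistical
structure the downstream analysis relies on:

* alternating-stance walking at a ~1 Hz stride rate, with a half-sine stance
  ground-reaction-force (GRF) profile carrying a 10 % double-bump
  modulation, heel→toe centre-of-pressure (COP) progression each stance, and
  residual swing-phase pressure (exercising the 5 % zeroing rule);
* FOG episodes during which both feet stay loaded, GRF is near-constant, AP
  progression stops, and the COP oscillates ("trembling") at a dominant
  frequency drawn uniformly from the freeze band (3–8 Hz by default);
* a pre-FOG transition during which the stride shortens and a freeze-band
  oscillation ramps in linearly, so pre-FOG windows are statistically
  separable from steady walking;
* most-affected-side (MAS) asymmetry as inflated noise on the MAS foot, and
  per-participant freeze propensity including non-freezers.

Annotation labels are first produced at a video-like frame rate (30 Hz) and
then transferred to the 100 Hz sample clock, emulating offline video labeling.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocessing import (
    FOG,
    NON_FOG,
    WindowSpec,
    apply_prefog_labels,
    hold_last_valid,
    transfer_labels,
)

__all__ = [
    "GaitSimConfig",
    "SegmentAnnotation",
    "EpisodeAnnotation",
    "ParticipantProfile",
    "TrialRecording",
    "simulate_trial",
    "simulate_cohort",
    "default_cohort_profiles",
    "write_trial_csv",
    "read_trial_csv",
    "write_annotations_json",
    "read_annotations_json",
]

BODY_WEIGHT = 700.0  # nominal two-foot standing load, force units
FOOT_HALF_LENGTH_MM = 120.0  # heel→toe COP excursion is ±this about mid-foot
WALK_ML_SWAY_MM = 3.0
TURN_ML_SWAY_FACTOR = 2.5
FOG_AP_TREMOR_MM = 5.0
FOG_ML_TREMOR_MM = 9.0
FOG_GRF_TREMOR_FRACTION = 0.04
PREFOG_CADENCE_GAIN = 0.35  # stride-rate increase at FOG onset
# An episode onset keeps this much clearance after its segment starts, so the
# 2 s pre-FOG run-up lies inside the segment and the MTD target zone stays
# open ahead of onset (turn/stand truncation lands >= 2.5 s before onset).
EPISODE_RUNUP_S = 3.5
# Each episode needs roughly this much clean context (run-up + episode +
# inter-episode clearance); the per-trial episode count is capped accordingly.
EPISODE_FOOTPRINT_S = 12.0


@dataclass(frozen=True)
class GaitSimConfig:
    """Generator settings; defaults are the study conditions emulated here."""

    sampling_rate: float = 100.0
    label_rate: float = 30.0
    trial_duration: float = 60.0
    stride_period: float = 1.1
    stance_fraction: float = 0.62
    fog_rate: float = 2.0
    fog_duration_range: tuple = (2.0, 6.0)
    prefog_transition: float = 2.0
    tremor_band: tuple = (3.0, 8.0)
    mas_side: str = "left"
    asymmetry_factor: float = 1.5
    noise_sd_grf: float = 8.0
    noise_sd_cop: float = 0.8
    residual_swing_fraction: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0 or self.label_rate <= 0:
            raise ValueError("rates must be positive")
        if not self.tremor_band[0] < self.tremor_band[1]:
            raise ValueError("tremor_band must satisfy low < high")
        if not self.fog_duration_range[0] <= self.fog_duration_range[1]:
            raise ValueError("fog_duration_range must satisfy min <= max")
        if not 0 < self.stance_fraction < 1:
            raise ValueError("stance_fraction must lie in (0, 1)")
        if self.fog_rate < 0:
            raise ValueError("fog_rate must be >= 0")
        if not 0 <= self.residual_swing_fraction < 0.1:
            raise ValueError("residual_swing_fraction must lie in [0, 0.1)")
        if self.mas_side not in ("left", "right"):
            raise ValueError("mas_side must be 'left' or 'right'")
        if self.asymmetry_factor < 1:
            raise ValueError("asymmetry_factor must be >= 1")


@dataclass(frozen=True)
class SegmentAnnotation:
    kind: str  # walk | turn | stand
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.kind not in ("walk", "turn", "stand"):
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if not self.start < self.end:
            raise ValueError("segment start must precede end")


@dataclass(frozen=True)
class EpisodeAnnotation:
    onset: float
    end: float

    def __post_init__(self) -> None:
        if not self.onset < self.end:
            raise ValueError("episode onset must precede end")


@dataclass(frozen=True)
class ParticipantProfile:
    participant_id: str
    mas_side: str
    is_freezer: bool
    n_trials: int = 2
    freeze_propensity: float = 1.0  # multiplies fog_rate for this participant


@dataclass
class TrialRecording:
    """Synchronized per-foot GRF/COP series, labels and annotations."""

    participant_id: str
    trial_id: str
    sampling_rate: float
    mas_side: str
    time: np.ndarray
    left_grf: np.ndarray
    left_cop_ap: np.ndarray
    left_cop_ml: np.ndarray
    right_grf: np.ndarray
    right_cop_ap: np.ndarray
    right_cop_ml: np.ndarray
    sample_labels: np.ndarray
    segments: list = field(default_factory=list)
    episodes: list = field(default_factory=list)

    @property
    def duration(self) -> float:
        return self.time.size / self.sampling_rate

    def validate(self) -> None:
        n = self.time.size
        vectors = (
            self.left_grf, self.left_cop_ap, self.left_cop_ml,
            self.right_grf, self.right_cop_ap, self.right_cop_ml,
            self.sample_labels,
        )
        if any(v.shape != (n,) for v in vectors):
            raise ValueError("all signal vectors must share the time length")
        if np.any(self.left_grf < 0) or np.any(self.right_grf < 0):
            raise ValueError("GRF must be non-negative")
        fog_times = self.time[self.sample_labels == FOG]
        half_frame = 0.5 / 30.0 + 1e-9
        for t in fog_times:
            if not any(ep.onset - half_frame <= t <= ep.end + half_frame
                       for ep in self.episodes):
                raise ValueError("FOG-labeled sample outside every episode")


def _seed_for(master_seed: int, *tokens) -> np.random.SeedSequence:
    """Order-independent per-entity seed: hash tokens, not positions."""
    entropy = [int(master_seed) & 0x7FFFFFFF]
    entropy += [zlib.crc32(str(t).encode()) for t in tokens]
    return np.random.SeedSequence(entropy)


def _plan_segments(duration: float, rng: np.random.Generator) -> list:
    """Stand / walk / turn layout; ≥ 1 stand and 1 turn when duration ≥ 30 s."""
    if duration < 30.0:
        return [SegmentAnnotation("walk", 0.0, duration)]
    segments = [SegmentAnnotation("stand", 0.0, 2.5)]
    t = 2.5
    kind = "walk"
    while duration - t > 4.0:
        if kind == "walk":
            length = min(float(rng.uniform(7.0, 10.0)), duration - t)
        else:
            length = min(2.5, duration - t)
        segments.append(SegmentAnnotation(kind, t, t + length))
        t += length
        kind = "turn" if kind == "walk" else "walk"
    if t < duration:
        last = segments[-1]
        segments[-1] = SegmentAnnotation(last.kind, last.start, duration)
    return segments


def _place_episodes(
    config: GaitSimConfig,
    segments: list,
    n_episodes: int,
    rng: np.random.Generator,
) -> list:
    """Uniform placement within walk/turn segments; never in the first 2 s."""
    if n_episodes == 0:
        return []
    dmin, dmax = config.fog_duration_range
    if config.trial_duration < 2.0 + dmin + 1.0:
        raise ValueError(
            f"trial of {config.trial_duration} s is too short for a FOG episode "
            f"of at least {dmin} s with a 2 s run-up"
        )
    eligible = [s for s in segments if s.kind in ("walk", "turn")]
    placed: list[EpisodeAnnotation] = []
    attempts = 0
    while len(placed) < n_episodes and attempts < 400:
        attempts += 1
        weights = np.array([s.end - s.start for s in eligible], dtype=float)
        seg = eligible[rng.choice(len(eligible), p=weights / weights.sum())]
        duration = float(rng.uniform(dmin, dmax))
        lo = max(seg.start + EPISODE_RUNUP_S, 2.0)
        hi = min(seg.end, config.trial_duration - 1.0) - duration
        if hi <= lo:
            continue
        onset = float(rng.uniform(lo, hi))
        candidate = EpisodeAnnotation(onset, onset + duration)
        # 3 s clearance keeps pre-FOG spans and MTD target zones disjoint.
        if all(candidate.onset - ep.end >= 3.0 or ep.onset - candidate.end >= 3.0
               for ep in placed):
            placed.append(candidate)
    return sorted(placed, key=lambda ep: ep.onset)


def simulate_trial(
    config: GaitSimConfig,
    profile: ParticipantProfile,
    trial_id: str,
    n_episodes: int | None = None,
) -> TrialRecording:
    """Generate one walking trial for one participant.

    The per-trial random stream is derived from ``config.seed`` and the
    participant/trial identifiers only, so identical identifiers reproduce a
    bitwise-identical trial regardless of simulation order. Non-freezers get
    zero episodes; for freezers the episode count defaults to
    ``max(1, Poisson(fog_rate × freeze_propensity))``.
    """
    fs = config.sampling_rate
    n = int(round(config.trial_duration * fs))
    rng = np.random.default_rng(_seed_for(config.seed, profile.participant_id, trial_id))
    t = np.arange(n) / fs

    segments = _plan_segments(config.trial_duration, rng)
    if n_episodes is None:
        if profile.is_freezer and config.fog_rate > 0:
            lam = config.fog_rate * profile.freeze_propensity
            cap = max(1, int(config.trial_duration // EPISODE_FOOTPRINT_S))
            n_episodes = min(cap, max(1, int(rng.poisson(lam))))
        else:
            n_episodes = 0
    episodes = _place_episodes(config, segments, n_episodes, rng)

    # --- per-sample regime masks -----------------------------------------
    standing = np.zeros(n, dtype=bool)
    turning = np.zeros(n, dtype=bool)
    for seg in segments:
        m = (t >= seg.start) & (t < seg.end)
        if seg.kind == "stand":
            standing[m] = True
        elif seg.kind == "turn":
            turning[m] = True
    frozen = np.zeros(n, dtype=bool)
    ramp = np.zeros(n)  # pre-FOG transition ramp in [0, 1]
    tremor_freq = np.zeros(n)
    tremor_phase_ap = np.zeros(n)
    tremor_phase_ml = np.zeros(n)
    for ep in episodes:
        f = float(rng.uniform(*config.tremor_band))
        ph_ap = float(rng.uniform(0, 2 * np.pi))
        ph_ml = float(rng.uniform(0, 2 * np.pi))
        m_fog = (t >= ep.onset) & (t < ep.end)
        frozen[m_fog] = True
        m_pre = (t >= ep.onset - config.prefog_transition) & (t < ep.onset)
        ramp[m_pre] = np.maximum(
            ramp[m_pre],
            (t[m_pre] - (ep.onset - config.prefog_transition)) / config.prefog_transition,
        )
        m_any = m_fog | m_pre
        tremor_freq[m_any] = f
        tremor_phase_ap[m_any] = ph_ap
        tremor_phase_ml[m_any] = ph_ml
    ramp[frozen] = 1.0
    walking = ~standing & ~frozen  # turns are walking with elevated ML sway

    # --- gait phase: stride rate rises through the pre-FOG transition -----
    stride_rate = np.where(
        walking, (1.0 + PREFOG_CADENCE_GAIN * ramp) / config.stride_period, 0.0
    )
    phase = np.cumsum(stride_rate) / fs

    tremor = np.sin(2 * np.pi * tremor_freq * t + tremor_phase_ap)
    tremor_ml = np.sin(2 * np.pi * tremor_freq * t + tremor_phase_ml)

    recording_signals = {}
    for side, phase_offset in (("left", 0.0), ("right", 0.5)):
        foot_phase = np.mod(phase + phase_offset, 1.0)
        stance = walking & (foot_phase < config.stance_fraction)
        u = np.clip(foot_phase / config.stance_fraction, 0.0, 1.0)

        grf = np.full(n, config.residual_swing_fraction * BODY_WEIGHT)
        shape = np.sin(np.pi * u) * (1.0 + 0.1 * np.cos(2 * np.pi * u))
        grf[stance] = BODY_WEIGHT * shape[stance]
        grf[standing] = 0.5 * BODY_WEIGHT
        grf[frozen] = 0.5 * BODY_WEIGHT * (
            1.0 + FOG_GRF_TREMOR_FRACTION * tremor[frozen]
        )

        cop_ap = np.where(
            stance, -FOOT_HALF_LENGTH_MM + 2 * FOOT_HALF_LENGTH_MM * u, np.nan
        )
        cop_ap[standing] = 0.0
        cop_ap = hold_last_valid(cop_ap, ~np.isnan(cop_ap))
        cop_ap = cop_ap + FOG_AP_TREMOR_MM * ramp * tremor

        sway_amp = np.where(turning, WALK_ML_SWAY_MM * TURN_ML_SWAY_FACTOR,
                            WALK_ML_SWAY_MM)
        cop_ml = np.where(walking, sway_amp * np.sin(2 * np.pi * phase), 0.0)
        cop_ml = cop_ml + FOG_ML_TREMOR_MM * ramp * tremor_ml

        noise_scale = config.asymmetry_factor if side == profile.mas_side else 1.0
        grf = grf + rng.normal(0.0, config.noise_sd_grf * noise_scale, n)
        cop_ap = cop_ap + rng.normal(0.0, config.noise_sd_cop * noise_scale, n)
        cop_ml = cop_ml + rng.normal(0.0, config.noise_sd_cop * noise_scale, n)
        recording_signals[side] = (np.clip(grf, 0.0, None), cop_ap, cop_ml)

    # --- labels: frame-rate annotation, then transfer to the sample clock --
    frame_times = np.arange(0.0, config.trial_duration, 1.0 / config.label_rate)
    frame_labels = np.full(frame_times.size, NON_FOG, dtype=np.int64)
    for ep in episodes:
        frame_labels[(frame_times >= ep.onset) & (frame_times < ep.end)] = FOG
    sample_labels = transfer_labels(frame_labels, frame_times, t)
    sample_labels = apply_prefog_labels(sample_labels, t, episodes, WindowSpec())

    rec = TrialRecording(
        participant_id=profile.participant_id,
        trial_id=trial_id,
        sampling_rate=fs,
        mas_side=profile.mas_side,
        time=t,
        left_grf=recording_signals["left"][0],
        left_cop_ap=recording_signals["left"][1],
        left_cop_ml=recording_signals["left"][2],
        right_grf=recording_signals["right"][0],
        right_cop_ap=recording_signals["right"][1],
        right_cop_ml=recording_signals["right"][2],
        sample_labels=sample_labels,
        segments=segments,
        episodes=episodes,
    )
    rec.validate()
    return rec


def simulate_cohort(config: GaitSimConfig, profiles: list) -> list:
    """Generate all trials for a cohort of participants.

    Freeze propensity is drawn per freezer from a Gamma(2, 1/2) multiplier
    (mean 1), giving the heavy between-participant dispersion of episode
    counts typical of freezer cohorts. Per-participant streams are seeded
    from the master seed and the participant id, so permuting the profile
    list does not change anyone's trials.
    """
    freezers = [p for p in profiles if p.is_freezer]
    if len(freezers) < 2:
        raise ValueError(
            "need at least 2 freezers: leave-one-freezer-out CV is undefined otherwise"
        )
    recordings = []
    for profile in profiles:
        prop_rng = np.random.default_rng(
            _seed_for(config.seed, profile.participant_id, "propensity")
        )
        propensity = float(prop_rng.gamma(2.0, 0.5)) if profile.is_freezer else 0.0
        prof = ParticipantProfile(
            participant_id=profile.participant_id,
            mas_side=profile.mas_side,
            is_freezer=profile.is_freezer,
            n_trials=profile.n_trials,
            freeze_propensity=propensity if profile.is_freezer else 1.0,
        )
        for k in range(profile.n_trials):
            trial_id = f"{profile.participant_id}_T{k:02d}"
            recordings.append(simulate_trial(config, prof, trial_id))
    return recordings


def default_cohort_profiles(
    n_freezers: int = 7, n_nonfreezers: int = 4, n_trials: int = 2
) -> list:
    """A cohort mirroring the reference study design: 11 participants,
    7 freezers, MAS alternating between sides."""
    profiles = []
    for i in range(n_freezers + n_nonfreezers):
        profiles.append(
            ParticipantProfile(
                participant_id=f"P{i + 1:02d}",
                mas_side="left" if i % 2 == 0 else "right",
                is_freezer=i < n_freezers,
                n_trials=n_trials,
            )
        )
    return profiles


# --------------------------------------------------------------------------
# Plain-text trial interchange: CSV signals + JSON annotations.

_CSV_COLUMNS = [
    "time_s", "left_grf", "left_cop_ap_mm", "left_cop_ml_mm",
    "right_grf", "right_cop_ap_mm", "right_cop_ml_mm", "label",
]


def write_trial_csv(recording: TrialRecording, path) -> None:
    df = pd.DataFrame(
        {
            "time_s": recording.time,
            "left_grf": recording.left_grf,
            "left_cop_ap_mm": recording.left_cop_ap,
            "left_cop_ml_mm": recording.left_cop_ml,
            "right_grf": recording.right_grf,
            "right_cop_ap_mm": recording.right_cop_ap,
            "right_cop_ml_mm": recording.right_cop_ml,
            "label": recording.sample_labels,
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def write_annotations_json(recording: TrialRecording, path) -> None:
    payload = {
        "participant_id": recording.participant_id,
        "trial_id": recording.trial_id,
        "mas_side": recording.mas_side,
        "sampling_rate": recording.sampling_rate,
        "segments": [asdict(s) for s in recording.segments],
        "episodes": [asdict(e) for e in recording.episodes],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_annotations_json(path) -> dict:
    payload = json.loads(Path(path).read_text())
    payload["segments"] = [SegmentAnnotation(**s) for s in payload["segments"]]
    payload["episodes"] = [EpisodeAnnotation(**e) for e in payload["episodes"]]
    return payload


def read_trial_csv(csv_path, annotations_path) -> TrialRecording:
    df = pd.read_csv(csv_path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial CSV missing columns: {sorted(missing)}")
    ann = read_annotations_json(annotations_path)
    return TrialRecording(
        participant_id=ann["participant_id"],
        trial_id=ann["trial_id"],
        sampling_rate=float(ann.get("sampling_rate", 100.0)),
        mas_side=ann["mas_side"],
        time=df["time_s"].to_numpy(),
        left_grf=df["left_grf"].to_numpy(),
        left_cop_ap=df["left_cop_ap_mm"].to_numpy(),
        left_cop_ml=df["left_cop_ml_mm"].to_numpy(),
        right_grf=df["right_grf"].to_numpy(),
        right_cop_ap=df["right_cop_ap_mm"].to_numpy(),
        right_cop_ml=df["right_cop_ml_mm"].to_numpy(),
        sample_labels=df["label"].to_numpy(dtype=np.int64),
        segments=ann["segments"],
        episodes=ann["episodes"],
    )
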