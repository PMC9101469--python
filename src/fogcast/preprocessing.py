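"""Raw-recording preprocessing: COP derivation, swing-phase zeroing, label
transfer, pre-FOG labeling, and sliding-window construction.

The conventions here are deliberately explicit because downstream features are
sensitive to them:

* windows are half-open sample intervals ``[start, start + length)``;
* the swing-phase ground-reaction-force (GRF) threshold is a strict ``< 5 %``
  of the two-foot total;
* derivatives use central differences in the interior and one-sided
  differences at the ends (:func:`numpy.gradient`);
* the centre of pressure (COP) of an unloaded foot is held at its last valid
  value rather than zero-filled, so swing onset does not create spurious
  direction reversals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NON_FOG",
    "PRE_FOG",
    "FOG",
    "WindowSpec",
    "Window",
    "SignalBundle",
    "cop_from_pressure_grid",
    "low_grf_mask",
    "zero_low_grf",
    "hold_last_valid",
    "differentiate",
    "transfer_labels",
    "apply_prefog_labels",
    "make_windows",
    "build_signal_bundle",
]

# Sample-label codes (shared with the synthetic generator and the CSV format).
NON_FOG = 0
PRE_FOG = 1
FOG = 2


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window and labeling geometry.

    Parameters
    ----------
    window_length : float
        Window duration in seconds (default 1.0).
    window_shift : float
        Shift between consecutive window starts in seconds (default 0.2).
    prefog_duration : float
        Length of the pre-FOG interval labeled immediately before each
        freeze onset, in seconds (default 2.0).
    """

    window_length: float = 1.0
    window_shift: float = 0.2
    prefog_duration: float = 2.0

    def __post_init__(self) -> None:
        if not (0 < self.window_shift <= self.window_length):
            raise ValueError("require 0 < window_shift <= window_length")
        if self.prefog_duration <= 0:
            raise ValueError("prefog_duration must be positive")


@dataclass(frozen=True)
class Window:
    """One sliding window of a trial.

    ``window_class`` is "target" iff the window contains only pre-FOG and/or
    FOG samples (pure pre-FOG, pre-FOG + FOG, or pure FOG); every other
    composition — including non-FOG mixed with pre-FOG or FOG — is
    "non-target".
    """

    start: float
    end: float
    start_index: int
    end_index: int
    label_composition: frozenset
    window_class: str
    trial_id: str = ""
    index: int = 0

    @property
    def is_target(self) -> bool:
        return self.window_class == "target"


def classify_composition(composition) -> str:
    comp = frozenset(composition)
    if comp and comp <= {PRE_FOG, FOG}:
        return "target"
    return "non-target"


def cop_from_pressure_grid(pressures, coords_ap, coords_ml):
    """Pressure-weighted centroid of insole cells.

    Parameters
    ----------
    pressures : array_like
        Cell pressures, shape ``(..., n_cells)`` — a trailing cell axis with
        optional leading time axes. Must be non-negative.
    coords_ap, coords_ml : array_like
        Anterior–posterior and medial–lateral cell coordinates in mm, shape
        ``(n_cells,)`` (or broadcastable to ``pressures``).

    Returns
    -------
    (cop_ap, cop_ml)
        Centroid coordinates in mm; NaN where the total pressure is zero.
    """
    p = np.asarray(pressures, dtype=float)
    if np.any(p < 0):
        raise ValueError("negative pressure is not physical")
    ap = np.asarray(coords_ap, dtype=float)
    ml = np.asarray(coords_ml, dtype=float)
    total = p.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cop_ap = (p * ap).sum(axis=-1) / total
        cop_ml = (p * ml).sum(axis=-1) / total
    cop_ap = np.where(total > 0, cop_ap, np.nan)
    cop_ml = np.where(total > 0, cop_ml, np.nan)
    if cop_ap.ndim == 0:
        return float(cop_ap), float(cop_ml)
    return cop_ap, cop_ml


def low_grf_mask(left_grf, right_grf, threshold_fraction: float = 0.05):
    """Boolean masks flagging samples where a foot carries < 5 % of the total.

    Returns ``(left_low, right_low)``; a zero two-foot total flags neither
    foot (both already zero or genuinely unloaded).
    """
    left = np.asarray(left_grf, dtype=float)
    right = np.asarray(right_grf, dtype=float)
    total = left + right
    with np.errstate(invalid="ignore", divide="ignore"):
        left_low = left < threshold_fraction * total
        right_low = right < threshold_fraction * total
    return left_low, right_low


def zero_low_grf(left_grf, right_grf, threshold_fraction: float = 0.05):
    """Zero any foot's GRF that is strictly below 5 % of the two-foot total.

    Removes residual swing-phase pressure before COP-based analysis. The
    inequality is strict: a foot carrying exactly 5 % is left unchanged.
    Idempotent: zeroing a foot cannot drop the other foot below threshold
    (the other foot then holds > 95 % of the new total).
    """
    left = np.asarray(left_grf, dtype=float)
    right = np.asarray(right_grf, dtype=float)
    if np.any(left < 0) or np.any(right < 0):
        raise ValueError("GRF must be non-negative")
    left_low, right_low = low_grf_mask(left, right, threshold_fraction)
    return np.where(left_low, 0.0, left), np.where(right_low, 0.0, right)


def hold_last_valid(signal, valid_mask):
    """Carry the last valid sample forward through invalid runs.

    Leading invalid samples take the first valid value; an all-invalid signal
    is returned unchanged.
    """
    x = np.asarray(signal, dtype=float).copy()
    valid = np.asarray(valid_mask, dtype=bool)
    if not valid.any():
        return x
    idx = np.where(valid, np.arange(len(x)), -1)
    idx = np.maximum.accumulate(idx)
    first_valid = int(np.argmax(valid))
    idx[idx < 0] = first_valid
    return x[idx]


def differentiate(signal, sampling_rate: float):
    """First and second derivatives of a position signal.

    Central differences at interior samples, one-sided at the ends; the
    acceleration is the derivative of the velocity.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples to differentiate")
    dt = 1.0 / sampling_rate
    velocity = np.gradient(x, dt)
    acceleration = np.gradient(velocity, dt)
    return velocity, acceleration


def transfer_labels(frame_labels, frame_times, sample_times):
    """Transfer frame-rate annotation labels to sample timestamps.

    Emulates transferring 30 Hz video labels onto a 100 Hz pressure stream:
    each sample takes the label of the nearest frame timestamp; a sample
    exactly halfway between two frames takes the earlier frame's label.
    """
    labels = np.asarray(frame_labels)
    ft = np.asarray(frame_times, dtype=float)
    st = np.asarray(sample_times, dtype=float)
    if labels.size == 0:
        raise ValueError("empty frame stream")
    if labels.shape != ft.shape:
        raise ValueError("frame_labels and frame_times must align")
    if np.any(np.diff(ft) <= 0):
        raise ValueError("frame timestamps must be strictly ascending")
    right = np.searchsorted(ft, st, side="left")
    right = np.clip(right, 0, ft.size - 1)
    left = np.clip(right - 1, 0, ft.size - 1)
    # ties (equal distance) go to the earlier frame: strict '<' keeps `right`
    # only when it is strictly closer.
    pick_right = np.abs(ft[right] - st) < np.abs(st - ft[left])
    nearest = np.where(pick_right, right, left)
    return labels[nearest]


def apply_prefog_labels(sample_labels, sample_times, episodes, spec: WindowSpec):
    """Label the run-up to each freeze as pre-FOG.

    Non-FOG samples within ``prefog_duration`` seconds before each episode
    onset become pre-FOG (clipped at the trial start). FOG labels are never
    overwritten, which also realises the merge rule: when two episodes are
    less than ``prefog_duration`` apart the whole inter-episode gap falls
    inside the second episode's pre-FOG span and is relabeled.
    """
    labels = np.asarray(sample_labels).copy()
    times = np.asarray(sample_times, dtype=float)
    onsets = [ep[0] if isinstance(ep, tuple) else ep.onset for ep in episodes]
    if any(b > a for a, b in zip(onsets[1:], onsets[:-1])):
        raise ValueError("episodes must be time-ordered")
    for onset in onsets:
        mask = (times >= onset - spec.prefog_duration) & (times < onset)
        labels[mask & (labels != FOG)] = PRE_FOG
    return labels


def window_starts(n_samples: int, spec: WindowSpec, sampling_rate: float):
    """Start indices of all full windows: 0, shift, 2·shift, …"""
    length_n = int(round(spec.window_length * sampling_rate))
    shift_n = int(round(spec.window_shift * sampling_rate))
    if shift_n < 1:
        raise ValueError("window shift below one sample period")
    return np.arange(0, n_samples - length_n + 1, shift_n, dtype=int), length_n


def make_windows(recording, spec: WindowSpec) -> list:
    """Slide a window over a trial and classify each by label composition.

    A ``duration``-second trial yields ``floor((n - length)/shift) + 1``
    windows. A trial shorter than one window yields an empty list with a
    warning.
    """
    labels = np.asarray(recording.sample_labels)
    n = labels.size
    fs = recording.sampling_rate
    length_n = int(round(spec.window_length * fs))
    if n < length_n:
        warnings.warn(
            f"trial {recording.trial_id!r} shorter than one window; no windows",
            stacklevel=2,
        )
        return []
    starts, length_n = window_starts(n, spec, fs)
    out = []
    for w_idx, i0 in enumerate(starts):
        comp = frozenset(np.unique(labels[i0 : i0 + length_n]).tolist())
        out.append(
            Window(
                start=i0 / fs,
                end=(i0 + length_n) / fs,
                start_index=int(i0),
                end_index=int(i0 + length_n),
                label_composition=comp,
                window_class=classify_composition(comp),
                trial_id=recording.trial_id,
                index=w_idx,
            )
        )
    return out


# Fixed per-foot signal ordering used throughout feature extraction.
SIGNAL_NAMES = ("grf", "cop_ap", "cop_ml", "vel_ap", "vel_ml", "acc_ap", "acc_ml")


@dataclass
class SignalBundle:
    """The 7 model-ready signals per foot for one trial.

    Per foot: GRF (force units), COP position AP/ML (mm), COP velocity AP/ML
    (mm/s), COP acceleration AP/ML (mm/s²). All vectors share one length.
    """

    sampling_rate: float
    left: dict = field(default_factory=dict)
    right: dict = field(default_factory=dict)

    def foot(self, side: str) -> dict:
        if side not in ("left", "right"):
            raise ValueError(f"unknown side {side!r}")
        return self.left if side == "left" else self.right

    @property
    def n_samples(self) -> int:
        return len(self.left["grf"])


def build_signal_bundle(recording, threshold_fraction: float = 0.05) -> SignalBundle:
    """Raw recording → model-ready :class:`SignalBundle`.

    Applies the 5 % swing-phase GRF zeroing, holds COP of an unloaded foot at
    its last valid value, and differentiates COP position twice.
    """
    fs = recording.sampling_rate
    left_grf, right_grf = zero_low_grf(
        recording.left_grf, recording.right_grf, threshold_fraction
    )
    left_low, right_low = low_grf_mask(
        recording.left_grf, recording.right_grf, threshold_fraction
    )
    bundle = SignalBundle(sampling_rate=fs)
    for side, grf, low, cop_ap, cop_ml in (
        ("left", left_grf, left_low, recording.left_cop_ap, recording.left_cop_ml),
        ("right", right_grf, right_low, recording.right_cop_ap, recording.right_cop_ml),
    ):
        ap = hold_last_valid(cop_ap, ~low)
        ml = hold_last_valid(cop_ml, ~low)
        vel_ap, acc_ap = differentiate(ap, fs)
        vel_ml, acc_ml = differentiate(ml, fs)
        bundle.foot(side).update(
            grf=grf, cop_ap=ap, cop_ml=ml,
            vel_ap=vel_ap, vel_ml=vel_ml, acc_ap=acc_ap, acc_ml=acc_ml,
        )
    return bundle
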