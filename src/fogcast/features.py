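"""The plantar-pressure feature catalog: 13 time-domain and 22
frequency-domain feature types over 7 signals per foot.

Per foot the catalog holds 166 features:

* 3 COP-path reversal features on AP position (count, mean duration, mean
  length of runs against the window's net AP direction);
* 3 COP deviation features on ML position (runs of first differences whose
  magnitude exceeds 0.5 mm);
* 6 coefficients of variation: COP position, velocity, acceleration × AP, ML;
* 8 FFT features × 7 signals = 56: total spectral power, dominant frequency,
  max/min/mean one-sided amplitude, power in the locomotion band (0.5–3 Hz)
  and the freeze band (3–8 Hz), and the freeze index (freeze / locomotion
  band power);
* 14 Haar wavelet features × 7 signals = 98: variance, max, min, mean and
  max/min/mean energy of the approximation and detail coefficient vectors.

One bilateral feature — the number of weight shifts, i.e. changes of which
foot carries the majority (> 50 %) of the total GRF — completes the
333-feature bilateral catalog (166 left + 166 right + 1).

Spectral conventions: windows are mean-detrended; the one-sided amplitude
spectrum covers bins 1 … N/2 (DC excluded) with amplitude 2|X_k|/N at
interior bins and √2·|X_{N/2}|/N at Nyquist, so Parseval's identity holds
exactly as Σ x² = (N/2)·Σ a². The 3 Hz edge belongs to the freeze band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pywt

from .preprocessing import SIGNAL_NAMES, SignalBundle, Window

logger = logging.getLogger(__name__)

__all__ = [
    "BandSpec",
    "FeatureDescriptor",
    "FeatureCatalog",
    "FeatureVector",
    "build_catalog",
    "reversal_features",
    "deviation_features",
    "cv_feature",
    "weight_shift_count",
    "fft_feature_block",
    "dwt_feature_block",
    "extract_feature_vector",
    "extract_feature_matrix",
    "FFT_FEATURE_NAMES",
    "DWT_FEATURE_NAMES",
    "quality_report",
]

FREEZE_INDEX_CAP = 1e6
DEVIATION_THRESHOLD_MM = 0.5


@dataclass(frozen=True)
class BandSpec:
    """Locomotion and freeze frequency bands in Hz.

    The shared 3 Hz edge is assigned to the freeze band: locomotion power
    sums bins in [0.5, 3) Hz, freeze power bins in [3, 8] Hz.
    """

    locomotion_band: tuple = (0.5, 3.0)
    freeze_band: tuple = (3.0, 8.0)

    def __post_init__(self) -> None:
        lo, fr = self.locomotion_band, self.freeze_band
        if not (lo[0] < lo[1] <= fr[0] < fr[1]):
            raise ValueError("bands must be ordered and non-overlapping")


@dataclass(frozen=True)
class FeatureDescriptor:
    name: str
    side: str  # left | right | bilateral
    signal: str  # one of SIGNAL_NAMES, or "grf_pair" for the bilateral feature
    ftype: str
    component: str = ""  # sub-feature within a block


FFT_FEATURE_NAMES = (
    "total_power", "dominant_freq", "max_amp", "min_amp", "mean_amp",
    "locomotion_power", "freeze_power", "freeze_index",
)
DWT_FEATURE_NAMES = tuple(
    f"{vec}_{stat}"
    for vec in ("approx", "detail")
    for stat in ("var", "max", "min", "mean", "max_energy", "min_energy", "mean_energy")
)
_CV_SIGNALS = ("cop_ap", "cop_ml", "vel_ap", "vel_ml", "acc_ap", "acc_ml")


class FeatureCatalog:
    """Ordered registry of feature descriptors.

    The bilateral catalog lists 166 left-foot features, 166 right-foot
    features, then the single bilateral weight-shift feature (333 total).
    """

    def __init__(self, descriptors: list):
        self.descriptors = list(descriptors)
        self.names = [d.name for d in self.descriptors]
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")

    def __len__(self) -> int:
        return len(self.descriptors)

    def __iter__(self):
        return iter(self.descriptors)

    def __getitem__(self, i):
        return self.descriptors[i]

    def side_indices(self, side: str) -> np.ndarray:
        return np.array(
            [i for i, d in enumerate(self.descriptors) if d.side == side], dtype=int
        )

    def counts_by_domain(self) -> dict:
        counts = {"time": 0, "fft": 0, "dwt": 0}
        for d in self.descriptors:
            if d.ftype in ("reversal", "deviation", "cv", "weight_shifts"):
                counts["time"] += 1
            elif d.ftype == "fft":
                counts["fft"] += 1
            elif d.ftype == "dwt":
                counts["dwt"] += 1
        return counts

    def n_feature_types(self) -> dict:
        """Feature-type tally: 13 time-domain + 22 frequency-domain types."""
        time_types = 3 + 3 + 6 + 1  # reversals, deviations, CVs, weight shifts
        freq_types = len(FFT_FEATURE_NAMES) + len(DWT_FEATURE_NAMES)
        return {"time": time_types, "frequency": freq_types}

    def to_json(self) -> list:
        return [
            {"name": d.name, "side": d.side, "signal": d.signal,
             "ftype": d.ftype, "component": d.component}
            for d in self.descriptors
        ]


def _unilateral_descriptors(side: str) -> list:
    prefix = f"{side}_"
    out = []
    for comp in ("count", "mean_duration", "mean_length"):
        out.append(FeatureDescriptor(f"{prefix}cop_ap_reversal_{comp}",
                                     side, "cop_ap", "reversal", comp))
    for comp in ("count", "mean_duration", "mean_length"):
        out.append(FeatureDescriptor(f"{prefix}cop_ml_deviation_{comp}",
                                     side, "cop_ml", "deviation", comp))
    for sig in _CV_SIGNALS:
        out.append(FeatureDescriptor(f"{prefix}{sig}_cv", side, sig, "cv"))
    for sig in SIGNAL_NAMES:
        for comp in FFT_FEATURE_NAMES:
            out.append(FeatureDescriptor(f"{prefix}{sig}_fft_{comp}",
                                         side, sig, "fft", comp))
    for sig in SIGNAL_NAMES:
        for comp in DWT_FEATURE_NAMES:
            out.append(FeatureDescriptor(f"{prefix}{sig}_dwt_{comp}",
                                         side, sig, "dwt", comp))
    return out


def build_catalog(bilateral: bool = True) -> FeatureCatalog:
    """Build the bilateral 333-feature catalog (or a 166-feature single-side
    catalog with side-neutral ordering when ``bilateral=False``)."""
    if not bilateral:
        return FeatureCatalog(
            [FeatureDescriptor(d.name.split("_", 1)[1], "unilateral", d.signal,
                               d.ftype, d.component)
             for d in _unilateral_descriptors("left")]
        )
    descriptors = _unilateral_descriptors("left") + _unilateral_descriptors("right")
    descriptors.append(
        FeatureDescriptor("bilateral_weight_shift_count", "bilateral",
                          "grf_pair", "weight_shifts")
    )
    return FeatureCatalog(descriptors)


@dataclass
class FeatureVector:
    values: np.ndarray
    trial_id: str
    window_index: int
    window_class: str


class QualityReport:
    """Run-level tally of guarded (non-finite or degenerate) feature values."""

    def __init__(self) -> None:
        self.flagged = 0

    def flag(self, what: str) -> None:
        self.flagged += 1
        logger.debug("feature guard applied: %s", what)

    def reset(self) -> None:
        self.flagged = 0


quality_report = QualityReport()


# --------------------------------------------------------------------------
# Time-domain features


def _run_stats(run_mask: np.ndarray, magnitudes: np.ndarray, sampling_rate: float):
    """Count maximal True-runs; mean run duration (s) and summed |Δ| length."""
    if not run_mask.any():
        return 0.0, 0.0, 0.0
    padded = np.concatenate(([False], run_mask, [False]))
    starts = np.flatnonzero(padded[1:] & ~padded[:-1])
    ends = np.flatnonzero(~padded[1:] & padded[:-1])
    durations = (ends - starts) / sampling_rate
    lengths = np.array([magnitudes[s:e].sum() for s, e in zip(starts, ends)])
    return float(starts.size), float(durations.mean()), float(lengths.mean())


def reversal_features(cop_ap, sampling_rate: float):
    """COP path direction reversals: maximal runs of first differences moving
    against the window's net AP direction. Returns (count, mean duration in
    seconds, mean length in mm)."""
    x = np.asarray(cop_ap, dtype=float)
    if x.size < 2:
        return 0.0, 0.0, 0.0
    d = np.diff(x)
    sign = 1.0 if (x[-1] - x[0]) >= 0 else -1.0
    against = sign * d < 0
    return _run_stats(against, np.abs(d), sampling_rate)


def deviation_features(cop_ml, sampling_rate: float, threshold: float = DEVIATION_THRESHOLD_MM):
    """ML COP deviations: maximal runs where |Δ COP_ML| exceeds ±0.5 mm per
    sample. Returns (count, mean duration in seconds, mean length in mm)."""
    x = np.asarray(cop_ml, dtype=float)
    if x.size < 2:
        return 0.0, 0.0, 0.0
    d = np.diff(x)
    return _run_stats(np.abs(d) > threshold, np.abs(d), sampling_rate)


def cv_feature(signal) -> float:
    """Coefficient of variation: sample standard deviation over |mean|.

    A mean indistinguishable from zero (|mean| < 1e-9 × std) makes the ratio
    meaningless; the guarded value 0 is returned and flagged."""
    x = np.asarray(signal, dtype=float)
    if x.size < 2:
        raise ValueError("coefficient of variation needs at least 2 samples")
    if x.max() == x.min():
        return 0.0  # constant signal: zero variance exactly
    std = float(np.std(x, ddof=1))
    mean = float(np.mean(x))
    if abs(mean) < 1e-9 * std:
        quality_report.flag("cv zero-mean sentinel")
        return 0.0
    return std / abs(mean)


def weight_shift_count(left_grf, right_grf) -> float:
    """Number of times the foot carrying > 50 % of the total GRF changed.

    Exact 50/50 splits (and zero totals) retain the previous majority state;
    the initial state establishes without counting a shift."""
    left = np.asarray(left_grf, dtype=float)
    right = np.asarray(right_grf, dtype=float)
    if left.shape != right.shape:
        raise ValueError("left and right GRF must align")
    state = 0  # 0 undecided, +1 left, -1 right
    shifts = 0
    for l, r in zip(left, right):
        if l > r:
            new = 1
        elif r > l:
            new = -1
        else:
            new = state
        if state != 0 and new != state:
            shifts += 1
        state = new
    return float(shifts)


# --------------------------------------------------------------------------
# Frequency-domain features


def _amplitude_spectrum(x: np.ndarray, sampling_rate: float):
    """One-sided amplitude spectrum of the mean-detrended window, DC excluded.

    Returns (freqs, amplitudes) over bins 1 … N//2, scaled so that
    Σ x_detrended² = (N/2)·Σ amplitude² exactly.
    """
    n = x.size
    spectrum = np.fft.rfft(x - x.mean())
    k = np.arange(1, n // 2 + 1)
    amp = 2.0 * np.abs(spectrum[k]) / n
    if n % 2 == 0:
        amp[-1] = np.sqrt(2.0) * np.abs(spectrum[n // 2]) / n
    return k * sampling_rate / n, amp


def _fft_features_from_amp(freqs, amp, bands: BandSpec):
    power = amp**2
    total_power = float(power.sum())
    dominant = float(freqs[int(np.argmax(amp))])
    lo = bands.locomotion_band
    fr = bands.freeze_band
    loc = float(power[(freqs >= lo[0]) & (freqs < lo[1])].sum())
    frz = float(power[(freqs >= fr[0]) & (freqs <= fr[1])].sum())
    if frz == 0.0:
        fi = 0.0
    elif loc == 0.0:
        fi = FREEZE_INDEX_CAP
    else:
        fi = min(frz / loc, FREEZE_INDEX_CAP)
    return (
        total_power, dominant, float(amp.max()), float(amp.min()),
        float(amp.mean()), loc, frz, fi,
    )


def fft_feature_block(signal, sampling_rate: float, bands: BandSpec = BandSpec()):
    """The 8 FFT features of one windowed signal (see module docstring).

    Returns a tuple ordered as :data:`FFT_FEATURE_NAMES`.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 10:
        raise ValueError("window too short for spectral features (need >= 10 samples)")
    freqs, amp = _amplitude_spectrum(x, sampling_rate)
    return _fft_features_from_amp(freqs, amp, bands)


def _dwt_features_from_coeffs(c: np.ndarray):
    var = float(np.var(c, ddof=1)) if c.size > 1 else 0.0
    energy = c**2
    return (
        var, float(c.max()), float(c.min()), float(c.mean()),
        float(energy.max()), float(energy.min()), float(energy.mean()),
    )


def dwt_feature_block(signal):
    """The 14 single-level Haar wavelet features of one windowed signal.

    An odd-length window is padded by repeating its last sample. Returns a
    tuple ordered as :data:`DWT_FEATURE_NAMES` (approximation vector first).
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 2:
        raise ValueError("wavelet features need at least 2 samples")
    if x.size % 2:
        x = np.concatenate([x, x[-1:]])
    approx, detail = pywt.dwt(x, "haar")
    return _dwt_features_from_coeffs(approx) + _dwt_features_from_coeffs(detail)


# --------------------------------------------------------------------------
# Per-window assembly


def _guard(values: np.ndarray) -> np.ndarray:
    bad = ~np.isfinite(values)
    if bad.any():
        for _ in range(int(bad.sum())):
            quality_report.flag("non-finite feature zeroed")
        values = np.where(bad, 0.0, values)
    return values


def extract_feature_vector(
    bundle: SignalBundle,
    window: Window,
    catalog: FeatureCatalog | None = None,
    bands: BandSpec = BandSpec(),
) -> FeatureVector:
    """Evaluate the catalog on one window of a signal bundle.

    The reference (per-window) path; :func:`extract_feature_matrix` is the
    vectorized equivalent for whole trials and is tested to agree with it.
    """
    if catalog is None:
        catalog = build_catalog()
    fs = bundle.sampling_rate
    i0, i1 = window.start_index, window.end_index
    if i1 > bundle.n_samples:
        raise ValueError("bundle does not cover the window")
    sliced = {
        side: {name: bundle.foot(side)[name][i0:i1] for name in SIGNAL_NAMES}
        for side in ("left", "right")
    }
    for side in ("left", "right"):
        for name in SIGNAL_NAMES:
            if len(sliced[side][name]) == 0:
                raise ValueError(f"missing signal {side}/{name}")

    cache: dict = {}

    def block(side, sig, ftype):
        key = (side, sig, ftype)
        if key not in cache:
            x = sliced[side][sig]
            if ftype == "fft":
                cache[key] = fft_feature_block(x, fs, bands)
            elif ftype == "dwt":
                cache[key] = dwt_feature_block(x)
            elif ftype == "reversal":
                cache[key] = reversal_features(x, fs)
            elif ftype == "deviation":
                cache[key] = deviation_features(x, fs)
        return cache[key]

    comp_index = {
        "reversal": {"count": 0, "mean_duration": 1, "mean_length": 2},
        "deviation": {"count": 0, "mean_duration": 1, "mean_length": 2},
        "fft": {c: i for i, c in enumerate(FFT_FEATURE_NAMES)},
        "dwt": {c: i for i, c in enumerate(DWT_FEATURE_NAMES)},
    }
    values = np.empty(len(catalog))
    for j, d in enumerate(catalog):
        if d.ftype == "weight_shifts":
            values[j] = weight_shift_count(sliced["left"]["grf"], sliced["right"]["grf"])
        elif d.ftype == "cv":
            values[j] = cv_feature(sliced[d.side][d.signal])
        else:
            values[j] = block(d.side, d.signal, d.ftype)[comp_index[d.ftype][d.component]]
    return FeatureVector(
        values=_guard(values),
        trial_id=window.trial_id,
        window_index=window.index,
        window_class=window.window_class,
    )


def _batch_fft_features(wins: np.ndarray, sampling_rate: float, bands: BandSpec):
    """Vectorized FFT block over a (n_windows, n_samples) stack."""
    n = wins.shape[1]
    x = wins - wins.mean(axis=1, keepdims=True)
    spectrum = np.fft.rfft(x, axis=1)
    k = np.arange(1, n // 2 + 1)
    amp = 2.0 * np.abs(spectrum[:, k]) / n
    if n % 2 == 0:
        amp[:, -1] = np.sqrt(2.0) * np.abs(spectrum[:, n // 2]) / n
    freqs = k * sampling_rate / n
    power = amp**2
    total = power.sum(axis=1)
    dominant = freqs[np.argmax(amp, axis=1)]
    lo, fr = bands.locomotion_band, bands.freeze_band
    loc = power[:, (freqs >= lo[0]) & (freqs < lo[1])].sum(axis=1)
    frz = power[:, (freqs >= fr[0]) & (freqs <= fr[1])].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fi = np.where(frz == 0.0, 0.0,
                      np.where(loc == 0.0, FREEZE_INDEX_CAP,
                               np.minimum(frz / np.where(loc == 0, 1.0, loc),
                                          FREEZE_INDEX_CAP)))
    return np.column_stack(
        [total, dominant, amp.max(axis=1), amp.min(axis=1), amp.mean(axis=1),
         loc, frz, fi]
    )


def _batch_dwt_features(wins: np.ndarray):
    n = wins.shape[1]
    if n % 2:
        wins = np.concatenate([wins, wins[:, -1:]], axis=1)
        n += 1
    pairs = wins.reshape(wins.shape[0], n // 2, 2)
    inv_sqrt2 = 1.0 / np.sqrt(2.0)
    approx = (pairs[:, :, 0] + pairs[:, :, 1]) * inv_sqrt2
    detail = (pairs[:, :, 0] - pairs[:, :, 1]) * inv_sqrt2
    cols = []
    for c in (approx, detail):
        ddof = 1 if c.shape[1] > 1 else 0
        energy = c**2
        cols += [
            np.var(c, axis=1, ddof=ddof), c.max(axis=1), c.min(axis=1),
            c.mean(axis=1), energy.max(axis=1), energy.min(axis=1),
            energy.mean(axis=1),
        ]
    return np.column_stack(cols)


def _batch_cv(wins: np.ndarray):
    std = wins.std(axis=1, ddof=1)
    mean = wins.mean(axis=1)
    constant = wins.max(axis=1) == wins.min(axis=1)
    guarded = (np.abs(mean) < 1e-9 * std) | (std == 0.0) | constant
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = std / np.abs(mean)
    return np.where(guarded, 0.0, cv)


def extract_feature_matrix(
    bundle: SignalBundle,
    windows: list,
    catalog: FeatureCatalog | None = None,
    bands: BandSpec = BandSpec(),
):
    """Evaluate the catalog on all windows of one trial at once.

    Returns ``(matrix, catalog)`` with one row per window, columns ordered by
    the catalog. Spectral and wavelet blocks are computed on a strided window
    stack per signal; the run-based features fall back to a per-window loop.
    """
    if catalog is None:
        catalog = build_catalog()
    fs = bundle.sampling_rate
    if not windows:
        return np.empty((0, len(catalog))), catalog
    length = windows[0].end_index - windows[0].start_index
    starts = np.array([w.start_index for w in windows])
    n_win = len(windows)

    def stack(side, sig):
        x = bundle.foot(side)[sig]
        view = np.lib.stride_tricks.sliding_window_view(x, length)
        return view[starts]

    columns = {}
    for side in ("left", "right"):
        for sig in SIGNAL_NAMES:
            wins = stack(side, sig)
            columns[(side, sig, "fft")] = _batch_fft_features(wins, fs, bands)
            columns[(side, sig, "dwt")] = _batch_dwt_features(wins)
        for sig in _CV_SIGNALS:
            columns[(side, sig, "cv")] = _batch_cv(stack(side, sig))
        rev = np.array([reversal_features(row, fs) for row in stack(side, "cop_ap")])
        dev = np.array([deviation_features(row, fs) for row in stack(side, "cop_ml")])
        columns[(side, "cop_ap", "reversal")] = rev
        columns[(side, "cop_ml", "deviation")] = dev
    lg, rg = stack("left", "grf"), stack("right", "grf")
    shifts = np.array([weight_shift_count(a, b) for a, b in zip(lg, rg)])

    comp_index = {
        "reversal": {"count": 0, "mean_duration": 1, "mean_length": 2},
        "deviation": {"count": 0, "mean_duration": 1, "mean_length": 2},
        "fft": {c: i for i, c in enumerate(FFT_FEATURE_NAMES)},
        "dwt": {c: i for i, c in enumerate(DWT_FEATURE_NAMES)},
    }
    matrix = np.empty((n_win, len(catalog)))
    for j, d in enumerate(catalog):
        if d.ftype == "weight_shifts":
            matrix[:, j] = shifts
        elif d.ftype == "cv":
            matrix[:, j] = columns[(d.side, d.signal, "cv")]
        else:
            matrix[:, j] = columns[(d.side, d.signal, d.ftype)][
                :, comp_index[d.ftype][d.component]
            ]
    bad = ~np.isfinite(matrix)
    if bad.any():
        for _ in range(int(bad.sum())):
            quality_report.flag("non-finite feature zeroed")
        matrix = np.where(bad, 0.0, matrix)
    return matrix, catalog
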