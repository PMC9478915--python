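"""Pairwise signal distance between detections.

The tracker decides which detections belong to the same fish from a distance

    eps = w_f * eps_f + w_S * eps_S,          w_f = 1/3, w_S = 2/3,

combining a frequency error eps_f and a field error eps_S, both in [0, 1].
The field error carries twice the weight because tracking conflicts mostly
arise between fish with similar EOD frequencies.

* eps_f is a logistic transform of the absolute EOD frequency difference
  with midpoint f0 = 0.35 Hz and inverse slope 0.08 Hz, saturating near 1
  already at ~0.8 Hz.
* eps_S maps the Euclidean distance between min-max-normalized spatial power
  profiles through the empirical cumulative distribution of such distances,
  calibrated once per recording on all detection pairs (within +-10 s, any
  frequency difference) of a 30 s reference window.  The CDF mapping makes
  the field error independent of the electrode-array configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectral import Detection

__all__ = [
    "DistanceConfig",
    "ErrorCalibration",
    "frequency_difference",
    "frequency_error",
    "spatial_profile",
    "field_difference",
    "calibrate_field_error",
    "select_calibration_window",
    "field_error",
    "signal_distance",
    "detection_distance",
]


@dataclass
class DistanceConfig:
    """Thresholds and parameters of the combined signal distance.

    ``dt_thresh`` / ``df_thresh`` limit which detection pairs are compared at
    all; ``f0`` / ``df_slope`` shape the logistic frequency error;
    ``weight_freq`` / ``weight_field`` must sum to one.  ``cal_window``
    is the length in seconds of the field-error calibration window.
    """

    dt_thresh: float = 10.0
    df_thresh: float = 2.5
    f0: float = 0.35
    df_slope: float = 0.08
    weight_freq: float = 1.0 / 3.0
    weight_field: float = 2.0 / 3.0
    cal_window: float = 30.0

    def __post_init__(self) -> None:
        if not np.isclose(self.weight_freq + self.weight_field, 1.0):
            raise ValueError("weight_freq + weight_field must equal 1")
        for name in ("dt_thresh", "df_thresh", "f0", "df_slope", "cal_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ErrorCalibration:
    """Empirical distribution of field differences of one recording.

    ``sorted_differences`` holds the ascending field differences collected
    from all detection pairs within ``+-dt_thresh`` inside a single
    calibration window starting at ``window_start`` seconds.
    """

    sorted_differences: np.ndarray
    window_start: float = 0.0

    def __post_init__(self) -> None:
        self.sorted_differences = np.asarray(self.sorted_differences, dtype=float)
        if self.sorted_differences.size == 0:
            raise ValueError("calibration requires at least one field difference")
        if np.any(np.diff(self.sorted_differences) < 0):
            raise ValueError("calibration differences must be sorted ascending")
        if self.sorted_differences[0] < 0:
            raise ValueError("field differences must be non-negative")


def frequency_difference(fa: float, fb: float) -> float:
    """Absolute EOD frequency difference |fa - fb| in Hz."""
    if fa <= 0 or fb <= 0:
        raise ValueError("EOD frequencies must be positive")
    return abs(fa - fb)


def frequency_error(df, cfg: DistanceConfig = DistanceConfig()):
    """Logistic frequency error eps_f(df) = 1 / (1 + exp(-(df - f0)/slope)).

    Strictly increasing in ``df``, equal to 0.5 at ``df = cfg.f0``.
    Accepts scalars or arrays.
    """
    df = np.asarray(df, dtype=float)
    if np.any(df < 0):
        raise ValueError("frequency difference must be non-negative")
    ef = 1.0 / (1.0 + np.exp(-(df - cfg.f0) / cfg.df_slope))
    return float(ef) if ef.ndim == 0 else ef


def spatial_profile(powers: np.ndarray) -> np.ndarray:
    """Min-max rescale electrode powers to the spatial profile S(x) in [0, 1].

    The smallest power maps to 0, the largest to 1; a flat power vector
    (no spatial structure) maps to all zeros.
    """
    powers = np.asarray(powers, dtype=float)
    if powers.ndim != 1 or powers.size < 2:
        raise ValueError("powers must be a vector of at least two electrodes")
    lo = powers.min()
    hi = powers.max()
    if hi == lo:
        return np.zeros_like(powers)
    return (powers - lo) / (hi - lo)


def field_difference(sa: np.ndarray, sb: np.ndarray) -> float:
    """Euclidean distance between two spatial profiles."""
    sa = np.asarray(sa, dtype=float)
    sb = np.asarray(sb, dtype=float)
    if sa.shape != sb.shape:
        raise ValueError("spatial profiles must have equal length")
    return float(np.sqrt(np.sum((sa - sb) ** 2)))


def select_calibration_window(detections: list[Detection],
                              cfg: DistanceConfig = DistanceConfig()) -> float:
    """Pick the start of the calibration window with most detections.

    Scans candidate windows of ``cfg.cal_window`` seconds starting at every
    detection time and returns the start of the busiest one (earliest on
    ties) — a proxy for a period of high fish activity.
    """
    if not detections:
        raise ValueError("no detections to select a calibration window from")
    times = np.sort(np.array([d.time for d in detections]))
    counts = np.searchsorted(times, times + cfg.cal_window, side="right") - np.arange(len(times))
    return float(times[int(np.argmax(counts))])


def calibrate_field_error(detections: list[Detection],
                          window_start: float,
                          cfg: DistanceConfig = DistanceConfig()) -> ErrorCalibration:
    """Collect the field-difference distribution from one calibration window.

    Takes every unordered pair of detections inside
    ``[window_start, window_start + cal_window)`` whose time difference is at
    most ``dt_thresh`` — regardless of frequency difference — and stores the
    sorted field differences of their spatial profiles.
    """
    window = [
        d for d in detections
        if window_start <= d.time < window_start + cfg.cal_window
    ]
    if len(window) < 2:
        raise ValueError("calibration window must contain at least two detections")
    profiles = [spatial_profile(d.powers) for d in window]
    diffs = []
    for a in range(len(window)):
        for b in range(a + 1, len(window)):
            if abs(window[b].time - window[a].time) <= cfg.dt_thresh:
                diffs.append(field_difference(profiles[a], profiles[b]))
    if not diffs:
        raise ValueError("no detection pairs within dt_thresh in calibration window")
    return ErrorCalibration(np.sort(diffs), window_start=window_start)


def field_error(ds, cal: ErrorCalibration):
    """Empirical-CDF field error eps_S in [0, 1].

    Evaluates the cumulative distribution of the calibration differences at
    ``ds``, linearly interpolated between the sorted calibration values
    (plotting positions 0 .. 1).  Values at or below the smallest calibration
    difference map to 0, values at or above the largest to 1; in particular
    ``ds = 0`` always gives 0.  Accepts scalars or arrays.
    """
    ds = np.asarray(ds, dtype=float)
    if np.any(ds < 0):
        raise ValueError("field difference must be non-negative")
    v = cal.sorted_differences
    if v.size == 1:
        es = np.where(ds >= v[0], 1.0, 0.0) * np.where(ds > 0, 1.0, 0.0)
    else:
        es = np.interp(ds, v, np.linspace(0.0, 1.0, v.size))
        es = np.where(ds <= v[0], 0.0, es)
        es = np.where(ds >= v[-1], 1.0, es)
    return float(es) if es.ndim == 0 else es


def signal_distance(ef: float, es: float,
                    cfg: DistanceConfig = DistanceConfig()) -> float:
    """Weighted combination eps = w_f * eps_f + w_S * eps_S in [0, 1]."""
    if not (0.0 <= ef <= 1.0 and 0.0 <= es <= 1.0):
        raise ValueError("frequency and field errors must lie in [0, 1]")
    return cfg.weight_freq * ef + cfg.weight_field * es


def detection_distance(a: Detection, b: Detection,
                       cal: ErrorCalibration,
                       cfg: DistanceConfig = DistanceConfig()) -> float:
    """Combined signal distance between two detections."""
    ef = frequency_error(frequency_difference(a.eodf, b.eodf), cfg)
    ds = field_difference(spatial_profile(a.powers), spatial_profile(b.powers))
    es = field_error(ds, cal)
    return signal_distance(ef, es, cfg)
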