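"""Spectral front end: multichannel voltages -> per-time-step signal detections.

Wave-type electric fish emit continuous quasi-sinusoidal electric organ
discharges (EODs) whose fundamental frequency (~600-1000 Hz) is individual
specific.  This module turns raw electrode-array voltages into a sequence of
:class:`Detection` objects, one per fish signal per spectrogram time step,
each carrying the fundamental EOD frequency and the logarithmic signal power
on every electrode.

Processing stages
-----------------
1. Per-electrode power spectral densities of overlapping snippets
   (Hann-windowed periodograms, density scaling, hop ~0.3 s).
2. Summation of PSDs over electrodes (linear power domain).
3. Decibel transform relative to a reference power ``P0``.
4. Peak detection in each summed log spectrum (prominence above a robust
   noise-spread threshold).
5. Greedy grouping of peaks into harmonic stacks; a group needs a fundamental
   plus at least two harmonics to count as a fish.
6. Per-electrode power read-out at the fundamental -> detections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, spectrogram

__all__ = [
    "SpectralConfig",
    "SpectrogramStack",
    "HarmonicGroup",
    "Detection",
    "compute_spectrograms",
    "sum_spectrograms",
    "to_decibel",
    "detect_peaks",
    "extract_harmonic_groups",
    "build_detections",
    "detect_recording",
]

#: decibel level assigned to zero power, to keep arithmetic finite
DB_FLOOR = -120.0


@dataclass
class SpectralConfig:
    """Parameters of the spectral analysis.

    Attributes
    ----------
    samplerate:
        Sampling rate of the recording in Hz.
    nfft:
        FFT window size in samples; must be a power of two.  ``2**15`` at
        20 kHz gives 0.61 Hz resolution (1.64 s windows), ``2**16`` gives
        0.31 Hz (3.28 s windows).
    hop:
        Snippet shift in seconds (default 0.3 s).
    reference_power:
        Reference power ``P0`` for the decibel transform, in mV^2/Hz.
    peak_threshold_factor:
        Peak prominence must exceed this factor times the interdecile range
        of the log spectrum.
    min_prominence:
        Lower bound (dB) on the prominence threshold; takes over when the
        spectrum has no noise floor to estimate a spread from (e.g., clean
        synthetic signals whose off-peak bins all sit at the decibel floor).
    max_harmonics:
        Highest harmonic order considered when building harmonic groups.
    harmonic_tolerance:
        Allowed mismatch between a peak and an integer multiple of the
        fundamental, as a fraction of the fundamental (one bin width is
        always added on top).
    eodf_band:
        Plausible band (Hz) for fundamental EOD frequencies.
    freq_limit:
        Spectrogram rows above this frequency (Hz) are discarded to bound
        memory; must cover the harmonics needed for grouping.
    """

    samplerate: float = 20_000.0
    nfft: int = 2 ** 16
    hop: float = 0.3
    reference_power: float = 1.0
    peak_threshold_factor: float = 3.0
    min_prominence: float = 10.0
    max_harmonics: int = 5
    harmonic_tolerance: float = 0.01
    eodf_band: tuple[float, float] = (400.0, 1200.0)
    freq_limit: float = 4000.0

    def __post_init__(self) -> None:
        if self.nfft <= 0 or (self.nfft & (self.nfft - 1)) != 0:
            raise ValueError(f"nfft must be a positive power of two, got {self.nfft}")
        if self.hop <= 0:
            raise ValueError("hop must be positive")
        if self.samplerate <= 0:
            raise ValueError("samplerate must be positive")

    @property
    def freq_resolution(self) -> float:
        """Width of one frequency bin in Hz (samplerate / nfft)."""
        return self.samplerate / self.nfft

    @property
    def window_duration(self) -> float:
        """Duration of one FFT window in seconds (nfft / samplerate)."""
        return self.nfft / self.samplerate


@dataclass
class SpectrogramStack:
    """Per-electrode and summed spectrograms of one recording.

    ``per_electrode_psd`` has shape (n_freq, n_time, n_electrodes) and holds
    linear power densities in mV^2/Hz; ``summed_psd`` is their sum over the
    electrode axis.  ``freq_axis`` is in Hz, ``time_axis`` in seconds from
    recording start (snippet centers).
    """

    per_electrode_psd: np.ndarray
    summed_psd: np.ndarray
    freq_axis: np.ndarray
    time_axis: np.ndarray

    @property
    def n_electrodes(self) -> int:
        return self.per_electrode_psd.shape[2]


@dataclass
class HarmonicGroup:
    """A fundamental frequency plus the harmonics attributed to it."""

    fundamental: float
    harmonic_freqs: list[float] = field(default_factory=list)
    harmonic_powers: list[float] = field(default_factory=list)

    @property
    def n_members(self) -> int:
        return len(self.harmonic_freqs)


@dataclass
class Detection:
    """One extracted fish signal at one spectrogram time step.

    The feature vector of the tracking algorithm: the fundamental EOD
    frequency ``eodf`` together with the decibel powers on all electrodes.
    """

    time_index: int
    time: float
    eodf: float
    powers: np.ndarray  # dB, one entry per electrode


def compute_spectrograms(raw: np.ndarray, cfg: SpectralConfig) -> SpectrogramStack:
    """Compute per-electrode PSD spectrograms of a multichannel recording.

    Parameters
    ----------
    raw:
        Array of shape (n_electrodes, n_samples) in mV.  A 1-D array is
        treated as a single channel.
    cfg:
        Spectral parameters.

    Returns
    -------
    SpectrogramStack
        Hann-windowed periodograms of snippets of ``cfg.nfft`` samples
        shifted by ``cfg.hop`` seconds, density scaling (mV^2/Hz), so that a
        sinusoid of amplitude ``a`` integrates to ``a**2/2`` over its peak.
        Rows above ``cfg.freq_limit`` are discarded.
    """
    raw = np.asarray(raw)
    if raw.ndim == 1:
        raw = raw[np.newaxis, :]
    if raw.ndim != 2 or raw.shape[0] < 1:
        raise ValueError("raw must be a (n_electrodes, n_samples) array")
    if raw.shape[1] < cfg.nfft:
        raise ValueError(
            f"recording too short: {raw.shape[1]} samples < one FFT window of {cfg.nfft}"
        )
    if np.isnan(raw).any():
        raise ValueError("raw recording contains NaN samples")

    hop_samples = int(round(cfg.hop * cfg.samplerate))
    if hop_samples < 1 or hop_samples >= cfg.nfft:
        raise ValueError("hop must be shorter than one FFT window and at least one sample")
    noverlap = cfg.nfft - hop_samples

    psds = []
    freq = times = None
    for channel in raw:
        freq, times, sxx = spectrogram(
            channel,
            fs=cfg.samplerate,
            window="hann",
            nperseg=cfg.nfft,
            noverlap=noverlap,
            detrend=False,
            scaling="density",
            mode="psd",
        )
        keep = freq <= cfg.freq_limit
        psds.append(sxx[keep].astype(np.float32))
    per_electrode = np.stack(psds, axis=2)
    summed = per_electrode.sum(axis=2, dtype=np.float64)
    return SpectrogramStack(
        per_electrode_psd=per_electrode,
        summed_psd=summed,
        freq_axis=freq[freq <= cfg.freq_limit],
        time_axis=times,
    )


def sum_spectrograms(stack: SpectrogramStack) -> np.ndarray:
    """Sum the per-electrode PSDs over electrodes (linear power domain)."""
    return stack.per_electrode_psd.sum(axis=2, dtype=np.float64)


def to_decibel(power, reference_power: float = 1.0, floor: float = DB_FLOOR):
    """Decibel transform ``L = 10 log10(P / P0)``.

    Zero power maps to ``floor`` (default -120 dB) so downstream arithmetic
    stays finite; negative powers are rejected.
    """
    power = np.asarray(power, dtype=float)
    if np.any(power < 0):
        raise ValueError("power must be non-negative")
    with np.errstate(divide="ignore"):
        level = 10.0 * np.log10(power / reference_power)
    level = np.where(power > 0, level, floor)
    level = np.maximum(level, floor)
    if level.ndim == 0:
        return float(level)
    return level


def peak_threshold(log_psd_column: np.ndarray, cfg: SpectralConfig) -> float:
    """Dynamic prominence threshold for one log spectrum (dB).

    ``peak_threshold_factor`` times the interdecile range (90th minus 10th
    percentile) of the column — a robust estimate of the noise-floor spread
    — but never below ``cfg.min_prominence``.
    """
    q10, q90 = np.percentile(np.asarray(log_psd_column, dtype=float), [10.0, 90.0])
    return max(cfg.peak_threshold_factor * (q90 - q10), cfg.min_prominence)


def detect_peaks(log_psd_column: np.ndarray, freq_axis: np.ndarray,
                 cfg: SpectralConfig) -> list[tuple[float, float]]:
    """Detect peaks in one time step of the summed log power spectrum.

    A local maximum counts as a peak when its prominence exceeds the dynamic
    threshold of :func:`peak_threshold`.  Returns ``(frequency, level)``
    tuples sorted by frequency.
    """
    column = np.asarray(log_psd_column, dtype=float)
    idx, _ = find_peaks(column, prominence=peak_threshold(column, cfg))
    return [(float(freq_axis[i]), float(column[i])) for i in idx]


def extract_harmonic_groups(peaks: list[tuple[float, float]],
                            cfg: SpectralConfig) -> list[HarmonicGroup]:
    """Group spectral peaks into harmonic stacks of single fish.

    Candidate fundamentals are the peaks inside ``cfg.eodf_band``, visited in
    order of descending level (ties: ascending frequency).  For each
    candidate, unused peaks within ``harmonic_tolerance * fundamental`` plus
    one bin width of an integer multiple ``k * fundamental``
    (``k <= max_harmonics``) are claimed greedily.  A group is kept only with
    at least three members (the fundamental and two harmonics); each peak
    belongs to at most one group.  Returned groups are sorted by fundamental.
    """
    if not peaks:
        return []
    freqs = np.array([p[0] for p in peaks])
    levels = np.array([p[1] for p in peaks])
    if np.any(np.diff(freqs) < 0):
        raise ValueError("peaks must be sorted by frequency")
    used = np.zeros(len(peaks), dtype=bool)
    bin_width = cfg.freq_resolution
    lo, hi = cfg.eodf_band

    candidates = [i for i in range(len(peaks)) if lo <= freqs[i] <= hi]
    candidates.sort(key=lambda i: (-levels[i], freqs[i]))

    groups: list[HarmonicGroup] = []
    for ci in candidates:
        if used[ci]:
            continue
        f1 = freqs[ci]
        tol = cfg.harmonic_tolerance * f1 + bin_width
        members: list[int] = []
        for k in range(1, cfg.max_harmonics + 1):
            target = k * f1
            best = -1
            best_err = tol
            for j in range(len(peaks)):
                if used[j] or j in members:
                    continue
                err = abs(freqs[j] - target)
                if err <= best_err:
                    best_err = err
                    best = j
            if best >= 0:
                members.append(best)
        if len(members) < 3:
            continue
        used[members] = True
        members.sort(key=lambda j: freqs[j])
        groups.append(
            HarmonicGroup(
                fundamental=float(f1),
                harmonic_freqs=[float(freqs[j]) for j in members],
                harmonic_powers=[float(levels[j]) for j in members],
            )
        )
    groups.sort(key=lambda g: g.fundamental)
    return groups


def build_detections(groups_per_step: list[list[HarmonicGroup]],
                     stack: SpectrogramStack,
                     cfg: SpectralConfig) -> list[Detection]:
    """Turn harmonic groups into detections with per-electrode powers.

    For each group's fundamental the power on electrode ``x`` is the decibel
    level of the maximum of the three PSD bins centered on the bin nearest
    the fundamental — robust against sub-bin frequency offsets.
    """
    if len(groups_per_step) != len(stack.time_axis):
        raise ValueError("one group list per spectrogram time step required")
    detections: list[Detection] = []
    n_freq = len(stack.freq_axis)
    for i, groups in enumerate(groups_per_step):
        for group in groups:
            f = group.fundamental
            if f < stack.freq_axis[0] or f > stack.freq_axis[-1]:
                raise ValueError(f"fundamental {f} Hz outside the frequency axis")
            b = int(np.argmin(np.abs(stack.freq_axis - f)))
            sl = slice(max(b - 1, 0), min(b + 2, n_freq))
            power = stack.per_electrode_psd[sl, i, :].max(axis=0)
            detections.append(
                Detection(
                    time_index=i,
                    time=float(stack.time_axis[i]),
                    eodf=f,
                    powers=to_decibel(power, cfg.reference_power),
                )
            )
    return detections


def detect_recording(raw: np.ndarray, cfg: SpectralConfig) -> list[Detection]:
    """Full spectral pipeline: raw voltages -> detections.

    Convenience wrapper chaining spectrogram computation, peak detection on
    every summed log spectrum, harmonic grouping, and power read-out.
    """
    stack = compute_spectrograms(raw, cfg)
    log_summed = to_decibel(stack.summed_psd, cfg.reference_power)
    groups_per_step = [
        extract_harmonic_groups(
            detect_peaks(log_summed[:, i], stack.freq_axis, cfg), cfg
        )
        for i in range(len(stack.time_axis))
    ]
    return build_detections(groups_per_step, stack, cfg)
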