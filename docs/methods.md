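# Methods

This note documents the models, parameters, and numerical choices behind
`eodtrack`, and what the synthetic benchmarks do and do not demonstrate.

## Spectral detection

Per-electrode spectrograms are single-taper (Hann) periodograms of
snippets of `nfft` samples shifted by `hop` (default 0.3 s), computed with
`scipy.signal.spectrogram` using density scaling.  Convention: the PSD is
in mV²/Hz, so a sinusoid of amplitude *a* integrates to *a*²/2 over its
mainlobe (the Hann mainlobe spans ±2 bins; its equivalent noise bandwidth
is 1.5 bins).  Zero power maps to a −120 dB floor so decibel arithmetic
stays finite.  `nfft` must be a power of two; at 20 kHz, 2¹⁵ gives
0.610 Hz bins / 1.64 s windows and 2¹⁶ gives 0.305 Hz / 3.28 s — the
coarse setting suffices for well-separated fish, the fine one is needed
when fish are closer than ~2 Hz.  Spectrogram rows above `freq_limit`
(default 4 kHz) are discarded and stored as float32: a 10-minute,
16-electrode recording then fits comfortably in memory while still
covering ≥3 harmonics for fundamentals up to 1.2 kHz (the summed PSD is
accumulated in float64).

Peaks in each summed log spectrum must exceed a prominence threshold of
`peak_threshold_factor` (default 3) times the interdecile range of the
column — a robust noise-spread estimate that adapts to channel count and
noise level — with a lower bound of `min_prominence` (10 dB) that takes
over for spectra without a stochastic noise floor (clean synthetic
signals, where the interdecile range collapses to zero).  The exact peak
detector of the original tooling is parameterized differently
(threshold-relative-to-noise histogram); the prominence rule used here is
deterministic, testable against a textbook reference, and configurable.

Harmonic grouping is greedy: candidate fundamentals inside `eodf_band`
(400–1200 Hz) are visited strongest-first; each claims, per harmonic order
k ≤ `max_harmonics` (5), the unused peak nearest k·f₁ within
1 % of f₁ plus one bin width.  Groups keep at least three members
(fundamental + two harmonics) or are discarded — the criterion that
separates fish from spurious single peaks.  Fundamentals are extracted
from the summed spectrum only; per-electrode extraction is out of scope.
The per-electrode power at the fundamental is the maximum of the three
bins centered on the fundamental bin (robust to sub-bin offsets; the
single-bin alternative is equivalent for bin-centered frequencies).

## Signal distance

* Frequency error: ε_f(Δf) = 1/(1+e^{−(Δf−f₀)/df}), f₀ = 0.35 Hz,
  df = 0.08 Hz.  ε_f(f₀) = 0.5 exactly; ε_f > 0.995 from Δf ≈ 0.8 Hz on,
  so the error saturates at frequency differences well below the 2.5 Hz
  candidate threshold.
* Spatial profile: powers min–max-rescaled to [0,1]; a flat power vector
  maps to all zeros (degenerate but well-defined).
* Field difference ΔS: Euclidean distance between profiles.
* Field error ε_S: the empirical CDF of calibration field differences
  evaluated at ΔS.  The CDF is piecewise linear through the sorted
  calibration values at plotting positions k/(m−1), clamped to 0 at or
  below the smallest value and 1 at or above the largest.  Interpolation
  (rather than a step function) keeps small differences small; the left
  clamp guarantees ε_S(0) = 0 even when the calibration sample contains
  zeros.  Calibration collects all detection pairs within ±10 s — any
  frequency difference — inside one 30 s window; by default the busiest
  such window in the recording (detection count as an activity proxy for
  a manually chosen active period), overridable via configuration.
* Combined distance: ε = ⅓ ε_f + ⅔ ε_S.  The weights are configurable;
  (1, 0) and (0, 1) give the frequency-only and field-only ablations used
  in the evaluation.

## Tracking

Pairs are forward-only (t_β > t_α, symmetric duplicates are redundant) and
thresholded at Δt ≤ 10 s, Δf ≤ 2.5 Hz.  Within a 30 s window, pairs are
processed in ascending ε; ties break deterministically by (α time,
α frequency, β time, β frequency).  A merge is rejected atomically if any
time step would hold two detections.  Unpaired detections become
singletons, so the output always partitions the window's detections.

Only the window's central 10 s is validated; its traces attach to
established identities via the smallest ε between established signals in
the window's leading 10 s and new central signals, one new trace per
established identity (and vice versa) per window.  Edge handling: the
first window's leading third and the last window's trailing third are
accepted as valid, since no earlier/later candidates exist; dropping them
would discard data.  Pair distances are cached across the three windows
that see each pair, which is the in-place equivalent of incrementally
updating the distance cube.  Identity labels are integers in order of
first appearance.  The whole pipeline is deterministic: identical inputs
and configuration reproduce identical tables byte for byte.

## Evaluation

A tracking conflict is a detection whose threshold-passing forward
candidates span ≥ 2 ground-truth identities; the record keeps the
minimum-ε same-identity candidate (true connection) and minimum-ε
other-identity candidate (false connection); additional identities are
ignored.  Per feature (Δf, ΔS, ε_f, ε_S, ε) we report the fraction of
conflicts with the true value strictly below the false one, and the ROC
AUC of the pooled distributions with smaller = predicted-true and ties
counting one half (Mann–Whitney closed form).  Because ε_f and ε_S are
monotone transforms of Δf and ΔS, the paired fractions coincide — the
transforms matter only for the combination.  Assignment accuracy maps
each trace to its majority ground-truth fish and counts agreeing
detections.

## Synthetic recordings

Each fish is a harmonic stack (relative amplitudes 1, 0.6, 0.35, 0.2)
with phase the analytic integral of baseline frequency plus rises
(amp·e^{−(t−onset)/τ} from onset).  Electrode amplitude falls off as
1/(1+(d/d₀)²) with d₀ = 0.1 m — monotone, bounded at d = 0, and smooth in
position, which is all that tracking needs from the field geometry; fish
orientation and a physical dipole model are deliberately omitted.  White
Gaussian noise (default σ = 0.02 mV) is added per channel; an EOD
amplitude of 1 mV at the fish gives realistic 30–40 dB peak-to-floor
ratios at electrodes ~0.5 m away.  Detection dropout is applied at the
detection level (random deletion) for tracker tests.

Presets define the benchmark conditions: `separated` (3 stationary fish
≥ 5 Hz apart, 10 min, 16 electrodes), `crossing` (2 fish 2 Hz apart,
4 rises of 5 Hz/τ = 15 s carrying one trace across the other, 240 s,
8 electrodes), `close_pair` (2 fish 0.25 m and 1.5 Hz apart, 120 s), and
`dense` (8 fish within 2 Hz, an expected-failure fixture).  Durations and
array sizes are chosen as the smallest scales at which the respective
regime is unambiguous (e.g. `crossing` yields >1000 conflicts and 8 trace
intersections).

What passing these benchmarks does *not* show: real recordings add
powerline hum, moving-fish amplitude modulation, reflections from
boundaries and objects, temperature-driven frequency drift, and far
higher fish densities.  The `dense` preset marks where the method breaks
by construction — superimposed spectral peaks make detections carry mixed
powers, and identities cannot be recovered after traces disentangle.

## Known limitations

* Frequencies closer than ~2 mainlobe widths merge into one peak; during
  crossings the superimposed signal is assigned to one fish and a short
  detection gap appears in the other — consistent with how such moments
  are genuinely ambiguous.
* The calibration window choice affects ε_S globally; the busiest-window
  default is a heuristic and can be overridden when a recording's activity
  pattern makes it unrepresentative.
* The tracker is offline and single-threaded by design; streaming and
  learned distance functions are out of scope.
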