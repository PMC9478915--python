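# eodtrack

Tracking individual wave-type electric fish in electrode-array recordings.

Wave-type gymnotiforms (e.g. *Apteronotus*) continuously emit a
quasi-sinusoidal electric organ discharge (EOD) whose fundamental frequency
(~600–1000 Hz) is individual-specific and stable over minutes to hours.
Submerged electrode arrays record the EODs of whole groups of fish without
catching or tagging them — but turning raw multichannel voltages into
per-fish trajectories requires solving a multi-target tracking problem in
which frequencies drift, fish actively modulate their EOD ("rises"),
frequency traces cross, and detections drop out.  `eodtrack` implements
that pipeline for behavioral researchers working with such grid recordings,
exercised end to end on synthetic recordings with known ground truth.

## Method

1. **Spectral detection.**  Per-electrode power spectral densities of
   overlapping snippets (Hann windows of `nfft` = 2¹⁵ or 2¹⁶ samples at
   20 kHz, i.e. 0.6 / 0.3 Hz resolution, shifted by Δt ≈ 300 ms) are summed
   over electrodes and converted to decibels,
   L(f) = 10 log₁₀(P(f)/P₀) with P₀ = 1 mV²/Hz.  Peaks are detected and
   grouped into harmonic stacks (a fundamental plus at least two
   harmonics); each group yields a detection — a feature vector
   **X** = (f, L(1), …, L(n)) of the fundamental EOD frequency and its
   power on all n electrodes.
2. **Signal distance.**  Detection pairs within Δt ≤ 10 s and Δf ≤ 2.5 Hz
   are scored by ε = ⅓ ε_f + ⅔ ε_S, where the *frequency error*
   ε_f(Δf) = 1/(1 + e^{−(Δf−f₀)/df}) is a logistic transform of the
   frequency difference (f₀ = 0.35 Hz, df = 0.08 Hz), and the *field
   error* ε_S maps the Euclidean distance between min–max-normalized
   spatial power profiles through the empirical cumulative distribution of
   such distances, calibrated once per recording on a 30 s window.  The
   field error gets twice the weight because conflicts typically arise
   between fish of similar frequency.
3. **Window tracking.**  Within sliding 30 s windows all pair distances are
   stored in a distance cube and traversed in ascending order: pairs found
   identities, extend them, or merge them, unless an identity would hold
   two signals at one time step.  Only the central 10 s of each window is
   validated and appended — again by ascending distance — to the identities
   established in earlier windows; the window then slides by 10 s.

A simulator (`eodtrack.simulate`) generates harmonic-stack fish with
trajectories, rises, distance-dependent power falloff, and sensor noise;
`eodtrack.curation` provides programmatic trace edits (connect / cut /
delete) and the conflict-based evaluation (fraction of true connections
scoring below false ones, plus ROC AUC, per feature).

## Worked example

Simulate two spatially distant fish 2 Hz apart where one fish's periodic
rises carry its frequency trace across the other's, then detect, track,
and score against the simulation's ground truth:

```bash
eodtrack simulate --preset crossing --seed 1 --out-dir demo
eodtrack detect demo/recording.raw --nfft 65536 --out demo/detections.tsv
eodtrack track demo/detections.tsv --out demo/identities.tsv
eodtrack evaluate demo/identities.tsv demo/detections.tsv demo/truth.tsv \
    --out demo/report.json
```

The log reports `extracted 1334 detections`, `tracked 1334 detections into
10 identities`, and `fraction correct: 95.47% (1308 conflicts)`;
`demo/report.json` contains (abridged):

```json
{
  "fraction_correct_percent": 95.47,
  "n_conflicts": 1308,
  "conflict_fraction_correct_percent": {"ef": 91.44, "eS": 97.48, "eps": 98.01},
  "conflict_auc_percent":              {"ef": 95.74, "eS": 99.33, "eps": 99.43}
}
```

Reading: of the 1308 tracking conflicts (detections with candidate
partners from both fish), frequency difference alone ranks the correct
partner first in 91.4 % of cases, the spatial field profile in 97.5 %, and
the combined distance ε in 98.0 % — the field outperforms frequency on
crossing traces, and combining both is best, with the same ordering in the
ROC AUC.  The 95.5 % overall assignment accuracy reflects that signals
superimposed at the actual trace intersections are genuinely ambiguous;
the `separated` preset (three fish far apart in frequency) tracks at
100 %.

On easy data the pipeline needs no manual cleanup; for hard cases the
`edit` subcommand applies scripted connect/cut/delete operations to the
identity table.

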