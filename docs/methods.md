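# Methods

## Pipeline

The classifier consumes 2 s windows of 16-channel EEG sampled at 125 Hz.
Offline training: band-power feature extraction → unsupervised SOM
training → supervised Hebbian labeling. Recall: feature extraction →
winner search among enabled neurons → the winner's class. The model
assumes the class-conditional structure of the signal lives in the
per-channel α/β/θ band powers — artifacts included — and that 2 s is long
enough to resolve the slowest band (θ, 4 Hz: eight cycles per window).

## Feature extraction

Band power is estimated from a Welch averaged periodogram: Hann window,
1 s windows (125 samples, 1 Hz bin spacing), 50% overlap, linear
absolute power with density scaling, no detrending. Band power is the
trapezoidal integral of the density over bins whose centers lie in the
closed band interval — α [8, 13], β [14, 30], θ [4, 7] Hz. At the 1 Hz
default resolution no bin is shared between bands, and the printed band
edges are honored exactly. The estimator choice matters only through its
variance; any consistent spectral estimator yields the same classifier
up to noise. Powers are not normalized or log-transformed (a z-score
helper exists but is off by default and excluded from the shipped
experiment configurations). Feature layout is band-major: α ch1..16,
β ch1..16, θ ch1..16, giving D = 48.

Verified analytic identities: a unit-amplitude sinusoid integrates to
A²/2 = 0.5 within 5% (windowing tolerance); ≥ 90% of a 10 Hz tone's
power lands in the α band; white-noise band powers scale with the
integration widths 5 : 16 : 3.

## SOM

Distance is Euclidean; the winner is the argmin with ties broken toward
the lowest (row-major) neuron index. The update uses the Gaussian
neighborhood h = α(t)·exp(−‖r_C − r_k‖²/σ(t)²) — note the plain σ² in
the denominator, no factor 2 — evaluated for every neuron with no cutoff
radius. Because h ∈ (0, α(t)] with α(t) ≤ 1, every update is a convex
combination: weights never overshoot the input and, with data-range
initialisation, remain inside the training data's per-dimension range
(tested at ε = 1e−9).

Schedule defaults (conventional Kohonen practice; the training procedure
itself does not pin them): linear decay, α 0.5 → 0.01, σ M/2 → 0.5,
100 epochs, uniform init within per-dimension data range. `t` is the
presentation counter, so α and σ are interpolated over
`epochs × n_vectors` steps; presentation order is a seeded shuffle per
epoch. All three seeds (generator, init, shuffle) are explicit, and every
pipeline stage is bit-reproducible given them.

## Hebbian labeling

One pass of the labeled training set (the same set used for SOM
training, matching the offline flow); the result is order-independent,
so one pass and several passes differ only by a constant factor on the
counts and produce the same labels. Label ties break toward the lowest
class index for determinism. A neuron with zero wins is disabled; the
recall-phase winner search runs over enabled neurons only.

## Synthetic EEG generator

The generator reproduces the *band-power geometry* the classifier
consumes, not EEG physiology. Each channel is a sum of three sinusoids —
one per band, frequency drawn uniformly inside the band, phase uniform —
whose amplitudes are scaled by the gesture signature and by a lognormal
per-sinusoid jitter (log-sd 0.2) that models trial-to-trial variability.
Clench gestures add white noise band-passed to 14–30 Hz (4th-order
Butterworth, zero-phase) on the clenching-side temporal channel: an EMG
stand-in deliberately confined to the measured β band, since no band
above 30 Hz is extracted. White Gaussian sensor noise (sd 0.5) is added
everywhere. A single sinusoid per band gives the closed-form expected
band power A²/2, which the tests exploit; the trade-off is an
unrealistically sparse spectrum (no 1/f background, no transients), so
passing tests demonstrate the classifier's behavior on the intended
band-power structure, not performance on real recordings.

Channel roles are configuration with defaults frontal {1, 2}, posterior
{7, 8}, left temporal 13, right temporal 14. Default signatures:

| gesture | signature |
|---|---|
| G1 open eyes | baseline (all multipliers 1) |
| G2 closed eyes | posterior α amplitude × 3.5 |
| G3 / G4 clench right/left | EMG gain 3.5 on channel 14 / 13 |
| G5 eyes wide | frontal amplitude × 1.6 (all bands), temporal β × 2.0 |
| G6 / G7 closed + clench | G2 pattern + G3/G4 EMG |

The G5 temporal-β component models the observation that the temporal
electrodes sit near the scalp region activated by opening the eyes wide,
which is what makes the eyes-wide gesture partly confusable with the
clench gestures and reproduces the characteristic error pattern of the
five- and seven-class experiments. Effect sizes are free parameters (the
underlying observations are qualitative bar plots); the defaults above
were fixed once so that the seven-class pipeline sits clearly above 85%
held-out accuracy while preserving the accuracy decline with class count
across independent seed sets, and are not tuned per run.

## Experiment replica

One experiment: 30 training segments per class, a held-out test set of
30 per class (50 for the two-class experiment), 8×8 map, defaults
throughout. The shipped acceptance run averages five seeded replicas per
class subset (2, 4, 5, 7 classes): 20 fitted classifiers, ~15 s on one
CPU. Typical held-out means: ≈100% (2 classes) degrading to ≈90–93%
(7 classes), monotone in the subset size.

## Numerical and degenerate-input choices

- Winner ties: lowest index (exact float ties are measure-zero but occur
  with constant features).
- Single-bin bands integrate as bin power × bin width instead of a zero
  trapezoid; narrower bands raise an error.
- A dimension constant across the training set initialises all map
  weights to that constant (degenerate uniform range).
- Segments must satisfy duration × rate ∈ ℤ exactly; ragged files are
  parse errors with line numbers, not silent truncation.
- Model JSON stores floats via `repr`, so save/load round-trips are
  bit-exact.

## Limitations

- Synthetic data only: the published human-subject accuracies cannot be
  recomputed (the recordings are not public); the replica reproduces the
  protocol and the qualitative trend, not the subject's numbers.
- The SOM objective is non-convex; different schedules or seeds change
  the map layout (though not, in our ranges, the accuracy picture).
- No artifact-removal path and no δ band, by design.
- Real-time/streaming recognition is out of scope; the package is batch.
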