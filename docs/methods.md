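# Methods

## Model and assumptions

CCCA assumes that a multi-channel recording `X` (channels × samples) carries
one component of interest that is (a) common to all channels up to a
positive per-channel gain and (b) confined to a narrow frequency region,
while the rest of each channel is background activity that is weakly
correlated across channels. Under those assumptions, decomposing every
channel into the *same* frequency bands and weighting the bands by a single
shared weight vector `w` turns extraction into a quadratic optimization:
cross-channel covariance `wᵀSw` (with `S = Σ_{k≠l} cov(F_k, F_l)`) is large
only for weight vectors that load on the shared band, and normalizing by the
total within-channel variance `wᵀQw` (with `Q = Σ_i cov(F_i, F_i)`) removes
the scale ambiguity. The stationary points of the resulting Rayleigh
quotient are the generalized eigenvectors of the pencil `(S, Q)`.

Two consequences the test suite exploits:

- For `n_c` identical channels `S = (n_c − 1)·Q`, so the leading eigenvalue
  is exactly `n_c − 1` (unity after dividing by `n_c − 1`). With a single
  band of sample variance `v`, the constraint `wᵀQw = 1` forces
  `w = 1/√(n_c v)` and hence `var(y) = 1/n_c`.
- The eigenvalues are invariant to multiplying every channel by the same
  positive constant, since `S` and `Q` scale identically.

## Empirical wavelet transform

The one-sided spectrum is normalized to `[0, π]` (`w = 2πf/fs`) and split at
boundaries `w_1 < … < w_{N−1}`. The scaling filter is flat below
`w_1 − τ_1`, each wavelet filter is flat between consecutive transition
zones, and the last wavelet stays flat up to `π`. Transitions of half-width
`τ_n = μ·w_n` use `cos(π/2·β(·))` on the upper side of a boundary and
`sin(π/2·β(·))` on the lower side, with the Meyer auxiliary polynomial

    β(x) = x⁴ (35 − 84x + 70x² − 20x³).

Because `β(x) + β(1−x) = 1`, the squared responses satisfy
`cos² + sin² = 1` inside every transition and exactly one filter is flat at
every other frequency, so the squared magnitudes are a partition of unity.
A variant of this polynomial with linear coefficient 85 circulates in the
literature; it gives `β(1) = 0`, which breaks the continuity of the
transitions and the frame property, so this package uses the standard
coefficient 84.

Filters are applied *twice* (analysis inner product, then synthesis
convolution with the same real, even filter), implemented as one FFT, a
multiplication by the squared response evaluated analytically at the
signal's own frequency grid, and an inverse FFT. Evenness in `w` preserves
conjugate symmetry, so band components are real; the partition of unity
makes their sum reproduce the input to machine precision, and since every
response is bounded by 1 the decomposition never expands energy.

### Boundary detection

No canonical segmentation rule exists, so the package uses inter-peak
minima: the channel-averaged magnitude spectrum is smoothed with a 5-point
moving average, the `N` largest local maxima are kept, and each boundary is
placed at the global minimum between consecutive maxima. If fewer than `N`
local maxima exist (e.g. a monotone spectrum), the axis is split into `N`
equal-width segments and a warning is emitted. Explicit boundaries can
always be passed instead; detection is run once, on the channel-averaged
spectrum, so band `j` denotes the same frequency range in every channel —
without that, a single weight per band would be meaningless.

### Transition parameter μ

`τ_n = μ·w_n` must keep adjacent transition zones disjoint
(`w_n + τ_n < w_{n+1} − τ_{n+1}`) and the last zone below `π`. The automatic
rule takes a quarter of the tightest admissible ratio,

    μ = 0.25 · min( (w_{n+1} − w_n)/(w_{n+1} + w_n),  (π − w_{N−1})/w_{N−1} ),

clipped to `(0, 0.5)`, which is admissible by construction for any strictly
increasing boundary set. A user-supplied μ is validated and rejected with
the offending boundary pair named if zones would overlap.

## Numerical choices

- **Covariances** are sample covariances about the mean with denominator
  `T − 1`; band rows are mean-centered when stacked.
- **S is symmetrized** as `(S + Sᵀ)/2` to remove floating-point asymmetry
  (it is symmetric in exact arithmetic).
- **Ridge**: when `Q`'s eigenvalue spread exceeds `1e10`, a diagonal ridge
  `1e−8·trace(Q)/m` is added before inversion and recorded in the outputs.
  `Q` is only positive *semi*-definite in general (a selected band can be
  numerically empty), and the generalized eigensolver needs a definite
  right-hand matrix.
- **Eigensolver**: `scipy.linalg.eigh(S, Q)`, the symmetric-definite driver,
  whose eigenvectors come back `Q`-orthonormal; columns are re-sorted by
  descending eigenvalue. Repeated eigenvalues leave the corresponding
  columns arbitrary within their eigenspace; they are reported in the
  solver's stable order and are not individually identifiable.
- **Sign conventions**: eigenvectors are flipped so each column's
  largest-magnitude entry is positive; the extracted `y` (and the `s_i` with
  it) is additionally flipped so it correlates non-negatively with the
  channel-averaged raw signal. Both are needed because eigenvectors are
  sign-ambiguous and downstream similarity metrics are signed.
- **Degenerate inputs**: a channel whose selected bands are all
  zero-variance is rejected; individual zero-variance bands only warn.
  Single-channel recordings are rejected (cross-channel covariance is
  undefined). Frequency-recognition ties break toward the lower candidate
  frequency.

## Parameters that matter

| Parameter | Default | Meaning |
|---|---|---|
| `n_bands` (N) | 5 | EWT layers; 5 matches typical EEG usage where the low layers hold ERP content |
| `band_indices` | all | which layers enter the pencil; ERP analyses typically restrict to the three lowest-frequency layers (layers 3–5 of 5, i.e. indices 2–4) |
| `mu` | auto | transition half-width factor, in (0, 0.5) |
| `grid_size` | 1024 | tabulation resolution of the filter bank (decomposition itself evaluates filters analytically on the signal grid) |
| `weight_set` | 0 | which eigenvector extracts `y`; the first (largest λ) is the shared component |

## Synthetic data

The generator produces `channel_i = gain_i · shared(t) + noise_i(t)` with
independent per-channel noise scaled to an exact per-channel SNR (dB);
`snr_db = inf` disables noise. Shared kinds: a Gaussian-windowed positive
deflection (default latency 0.4 s, width 0.1 s — a P300-like transient with
>90 % of its energy below 8 Hz), a sinusoid plus harmonics at a steady-state
stimulation frequency (defaults: 10 Hz, 2 harmonics, amplitudes 1/h), and
band-limited Gaussian noise confined to a chosen passband (used when the
shared component must occupy one known band of an equal-split bank). Noise
is white or pink (1/f amplitude shaping). ERP sessions add per-trial
latency/amplitude jitter and support a trials-as-channels layout for
analyzing repeated trials of one electrode as a multi-channel signal.

What the generator does **not** emulate: volume conduction and realistic
channel covariance structure (noise is independent across channels),
ocular/muscle artifacts, non-stationarity within a trial, and inter-subject
variability. Passing tests therefore demonstrate that the algorithm
recovers a shared band-limited component under its own model assumptions —
not that it attains any particular accuracy on recorded EEG, where
correlated noise can leak into `S`.

## Experiment sizes

The packaged experiments use 8 channels at 250 Hz: 1 s trials for SSVEP
recognition (candidates 8–15 Hz, 0 dB SNR, 100 seeded trials) and 4 s trials
for band-recovery (band-limited shared source at 0 dB, 100 seeds) — the
longer epoch keeps the band covariance estimates stable at `m = 5` bands.
Solver checks run on 100 seeded random symmetric/SPD pencils with
`m ∈ [2, 6]`, cross-validated for `m ∈ {2, 3}` against brute-force Rayleigh
maximization over 10⁵ random `Q`-normalized directions.

## Known limitations

- Boundary detection is heuristic; on spectra without clear peaks the
  equal-width fallback may split a narrow component across two bands, which
  dilutes its weight.
- The per-band weights are global over the analysis window; slowly drifting
  shared components violate the stationary-covariance assumption.
- ICA baseline component selection (maximal |correlation| with a reference)
  is an evaluation convenience of this package, not a property of ICA.
- Absolute recognition accuracies on real benchmark datasets depend on the
  recording hardware, channel selection and preprocessing; the packaged
  accuracy table is shipped as data for the bookkeeping operations, not
  recomputed from raw recordings.
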