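# ccca-eeg

Channel component correlation analysis (CCCA) for multi-channel EEG: extract
the feature component that is *common* to all channels of a recording by
combining an adaptive frequency-band decomposition with a cross-channel
covariance-maximization criterion.

## Who this is for

EEG researchers and BCI engineers who need to pull a shared component —
a P300-like event-related potential, or a steady-state visual evoked
potential (SSVEP) — out of a multi-channel recording without averaging away
single-trial dynamics, and who want a reproducible, scriptable alternative
to PCA/ICA component extraction.

## The method

Given a recording `X = [x_1, …, x_nc]` (channels × samples):

1. **Empirical wavelet transform (EWT).** The channel-averaged magnitude
   spectrum is segmented into `N` bands at detected boundaries
   `w_1 < … < w_{N−1}` on the normalized axis `[0, π]`. Meyer-type filters
   with transition zones `τ_n = μ·w_n` shaped by the auxiliary polynomial
   `β(x) = x⁴(35 − 84x + 70x² − 20x³)` form a tight frame
   (`ϕ̂₁² + Σ γ̂_n² = 1` at every frequency), so each channel decomposes into
   band components `F_i = [f_{i,1}, …, f_{i,m}]` that sum back to the
   channel exactly.
2. **Covariance pencil.** One weight per band, shared across channels,
   defines per-channel components `s_i = Σ_j w_j f_{i,j}`. The objective sums
   cross-channel covariances, `S = Σ_{k≠l} cov(F_k, F_l)`, normalized by the
   within-channel total `Q = Σ_i cov(F_i, F_i)`:

       max_w  wᵀ S w   subject to   wᵀ Q w = 1.

3. **Generalized eigendecomposition.** The Lagrangian yields
   `S w = λ Q w`; the leading eigenvector gives the largest weight to the
   band shared most strongly across channels, and the common component is
   `y = w₁ᵀ · (1/n_c) Σ_i F_i`.

PCA and ICA (FastICA, negentropy/log-cosh, deflationary) comparators, the
evaluation criteria (power-spectrum-argmax SSVEP frequency recognition,
Pearson similarity to a superposition-averaged reference), and a seeded
synthetic EEG generator are included, so the whole pipeline is testable
offline.

## Worked example

```python
import numpy as np
from ccca import ccca_pipeline, power_spectrum, recognize_frequency
from ccca.synthetic import SyntheticSpec, generate

# 8 channels, 1 s at 250 Hz: a shared 10 Hz SSVEP (plus 2 harmonics)
# buried in channel-specific white noise at 0 dB SNR
trial = generate(SyntheticSpec(
    n_channels=8, fs=250.0, duration=1.0, seed=42,
    shared_kind="ssvep_tone",
    shared_params={"frequency_hz": 10.0, "n_harmonics": 2},
    snr_db=0.0))

result = ccca_pipeline(trial.recording, n_bands=5)
print("boundaries (Hz):", np.round(result.filter_bank.boundaries_hz(250.0), 1))
print("eigenvalues:", np.round(result.solution.eigenvalues, 3))
print("leading weights:", np.round(result.solution.W[:, 0], 3))

spectrum = power_spectrum(result.component.y, fs=250.0)
print("recognized:", recognize_frequency(spectrum, list(range(8, 16))), "Hz")
```

Output:

```
boundaries (Hz): [11. 13. 19. 25.]
eigenvalues: [6.303 5.663 0.629 0.474 0.008]
leading weights: [ 0.463 -0.115  0.003 -0.     0.   ]
recognized: 10.0 Hz
```

The detected boundaries bracket the 10 Hz fundamental and its harmonics; the
leading eigenvalue (6.30, out of a maximum of `n_c − 1 = 7` for perfectly
identical channels) says the weighted combination is shared across nearly
all channels, the largest weight selects the band holding the fundamental,
and the power spectrum of the extracted component `y` peaks at the true
stimulation frequency.

The same pipeline is available from a shell:

```sh
ccca simulate --kind ssvep --out sim/ --seed 42 --channels 8 --fs 250
ccca extract  --input sim/recording.csv --fs 250 --n-bands 5 --out out/
ccca evaluate --mode ssvep --input out/y.csv --fs 250 --out eval.json
```

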