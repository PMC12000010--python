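"""Seeded generators of multi-channel signals with a shared component.

The statistical structure mirrors what channel-component extraction assumes:
every channel records the same band-limited source, scaled by a per-channel
gain, buried in channel-specific noise at a controlled SNR.  Three source
kinds are provided:

``erp_bump``
    A Gaussian-windowed positive deflection emulating a P300-like transient
    (default latency 0.4 s, width 0.1 s), whose energy sits below ~8 Hz.
``ssvep_tone``
    A sinusoid plus harmonics at a steady-state stimulation frequency, with
    optional small per-channel phase jitter.
``band_noise``
    Band-pass filtered noise confined to a chosen passband — useful when the
    shared component must live in one known band of a filter bank.

Noise is white or pink (1/f amplitude-shaped) Gaussian, drawn independently
per channel and scaled so the shared-to-noise power ratio matches ``snr_db``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .types import MultiChannelRecording


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic multi-channel trial.

    ``shared_params`` keys by kind —
    erp_bump: latency_s (0.4), width_s (0.1), amplitude (1.0);
    ssvep_tone: frequency_hz (10.0), n_harmonics (2), phase_jitter_rad (0.0);
    band_noise: passband_hz ((8.0, 12.0)).
    """

    n_channels: int = 8
    fs: float = 250.0
    duration: float = 1.0
    seed: int = 0
    shared_kind: Literal["erp_bump", "ssvep_tone", "band_noise"] = "erp_bump"
    shared_params: dict = field(default_factory=dict)
    channel_gains: np.ndarray | None = None
    snr_db: float = 0.0
    noise_kind: Literal["white", "pink"] = "white"

    def __post_init__(self) -> None:
        if self.n_channels < 1 or self.fs <= 0 or self.duration <= 0:
            raise ValueError("n_channels, fs and duration must be positive")
        if self.channel_gains is None:
            self.channel_gains = np.ones(self.n_channels)
        self.channel_gains = np.asarray(self.channel_gains, dtype=float)
        if self.channel_gains.size != self.n_channels:
            raise ValueError("one gain per channel required")
        if np.any(self.channel_gains <= 0):
            raise ValueError("channel gains must be positive")
        fmax = self._max_frequency()
        if fmax is not None and self.fs <= 2.0 * fmax:
            raise ValueError(
                f"fs={self.fs} too low for content up to {fmax} Hz"
            )

    def _max_frequency(self) -> float | None:
        p = self.shared_params
        if self.shared_kind == "ssvep_tone":
            return p.get("frequency_hz", 10.0) * (1 + p.get("n_harmonics", 2))
        if self.shared_kind == "band_noise":
            return p.get("passband_hz", (8.0, 12.0))[1]
        return None

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))


@dataclass
class SyntheticTrial:
    """A generated recording plus its noise-free shared component."""

    recording: MultiChannelRecording
    truth: np.ndarray
    truth_band: int

    def __post_init__(self) -> None:
        if self.truth.size != self.recording.n_samples:
            raise ValueError("truth length must match recording length")


def erp_bump(t, latency_s: float = 0.4, width_s: float = 0.1,
             amplitude: float = 1.0) -> np.ndarray:
    """Gaussian-windowed positive deflection centered at ``latency_s``."""
    return amplitude * np.exp(-0.5 * ((t - latency_s) / width_s) ** 2)


def _shared_signal(spec: SyntheticSpec, rng: np.random.Generator,
                   phase_offset: float = 0.0) -> np.ndarray:
    t = np.arange(spec.n_samples) / spec.fs
    p = spec.shared_params
    if spec.shared_kind == "erp_bump":
        return erp_bump(t, p.get("latency_s", 0.4), p.get("width_s", 0.1),
                        p.get("amplitude", 1.0))
    if spec.shared_kind == "ssvep_tone":
        f0 = p.get("frequency_hz", 10.0)
        nh = p.get("n_harmonics", 2)
        sig = np.zeros_like(t)
        for h in range(1, nh + 2):  # fundamental + nh harmonics
            sig += (1.0 / h) * np.sin(2 * np.pi * h * f0 * t
                                      + h * phase_offset)
        return sig
    if spec.shared_kind == "band_noise":
        lo, hi = p.get("passband_hz", (8.0, 12.0))
        if not 0 <= lo < hi:
            raise ValueError("passband must satisfy 0 <= lo < hi")
        white = rng.standard_normal(spec.n_samples)
        f = np.fft.rfftfreq(spec.n_samples, 1.0 / spec.fs)
        mask = (f >= lo) & (f <= hi)
        shaped = np.fft.irfft(np.fft.rfft(white) * mask, n=spec.n_samples)
        rms = np.sqrt(np.mean(shaped**2))
        return shaped / rms if rms > 0 else shaped
    raise ValueError(f"unknown shared_kind {spec.shared_kind!r}")


def _noise(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(spec.n_samples)
    if spec.noise_kind == "white":
        return white
    if spec.noise_kind == "pink":
        f = np.fft.rfftfreq(spec.n_samples, 1.0 / spec.fs)
        shaping = np.zeros_like(f)
        shaping[1:] = 1.0 / np.sqrt(f[1:])
        pink = np.fft.irfft(np.fft.rfft(white) * shaping, n=spec.n_samples)
        return pink / np.sqrt(np.mean(pink**2))
    raise ValueError(f"unknown noise_kind {spec.noise_kind!r}")


def _default_band_index(spec: SyntheticSpec, n_bands: int = 5) -> int:
    """EWT band of a 5-band equal split of [0, fs/2] carrying the source."""
    p = spec.shared_params
    if spec.shared_kind == "erp_bump":
        # lowpass bump: dominant energy near DC
        f_center = 0.0
    elif spec.shared_kind == "ssvep_tone":
        f_center = p.get("frequency_hz", 10.0)
    else:
        lo, hi = p.get("passband_hz", (8.0, 12.0))
        f_center = 0.5 * (lo + hi)
    width = (spec.fs / 2.0) / n_bands
    return min(int(f_center // width), n_bands - 1)


def generate(spec: SyntheticSpec) -> SyntheticTrial:
    """Generate one trial: channel_i = gain_i * shared + noise_i at snr_db.

    Fully deterministic given ``spec.seed``.  The noise of each channel is
    scaled so that the per-channel shared-to-noise power ratio (before the
    gain is applied to the shared part) equals ``snr_db``; ``snr_db = inf``
    disables noise.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.shared_params
    jitter = p.get("phase_jitter_rad", 0.0)
    phases = (rng.uniform(-jitter, jitter, spec.n_channels)
              if (spec.shared_kind == "ssvep_tone" and jitter > 0)
              else np.zeros(spec.n_channels))
    truth = _shared_signal(spec, rng)
    shared_power = float(np.mean(truth**2))
    if shared_power == 0:
        raise ValueError("shared component has zero power; SNR undefined")

    data = np.empty((spec.n_channels, spec.n_samples))
    for i in range(spec.n_channels):
        shared_i = (truth if phases[i] == 0.0
                    else _shared_signal(spec, rng, phases[i]))
        sig = spec.channel_gains[i] * shared_i
        if np.isinf(spec.snr_db):
            data[i] = sig
            continue
        noise = _noise(spec, rng)
        target_noise_power = (spec.channel_gains[i] ** 2 * shared_power
                              / 10.0 ** (spec.snr_db / 10.0))
        noise *= np.sqrt(target_noise_power / np.mean(noise**2))
        data[i] = sig + noise
    rec = MultiChannelRecording(data, spec.fs)
    return SyntheticTrial(rec, truth, _default_band_index(spec))


def generate_erp_session(n_trials: int, spec: SyntheticSpec,
                         latency_jitter_s: float = 0.0,
                         amplitude_jitter: float = 0.0,
                         trials_as_channels: bool = False):
    """Generate a session of ERP trials sharing one bump template.

    Per-trial latency and amplitude jitter are drawn uniformly in
    [-latency_jitter_s, +latency_jitter_s] and [1 - a, 1 + a].  With
    ``trials_as_channels`` the first channel of every trial is stacked into a
    single recording (one row per trial), the layout used when analyzing
    repeated trials of one electrode as a multi-channel signal.

    Returns a list of :class:`SyntheticTrial`, or a single
    :class:`SyntheticTrial` whose recording has ``n_trials`` rows when
    ``trials_as_channels`` is set.
    """
    if n_trials < 1:
        raise ValueError("need at least one trial")
    if spec.shared_kind != "erp_bump":
        raise ValueError("erp sessions require shared_kind='erp_bump'")
    base = dict(spec.shared_params)
    latency = base.get("latency_s", 0.4)
    amplitude = base.get("amplitude", 1.0)
    if latency_jitter_s < 0 or amplitude_jitter < 0:
        raise ValueError("jitters must be nonnegative")
    if (latency + latency_jitter_s >= spec.duration
            or latency - latency_jitter_s <= 0):
        raise ValueError("latency jitter pushes the bump outside the epoch")

    rng = np.random.default_rng(spec.seed)
    trials = []
    for k in range(n_trials):
        params = dict(base)
        if latency_jitter_s > 0:
            params["latency_s"] = latency + rng.uniform(
                -latency_jitter_s, latency_jitter_s)
        if amplitude_jitter > 0:
            params["amplitude"] = amplitude * rng.uniform(
                1 - amplitude_jitter, 1 + amplitude_jitter)
        sub = SyntheticSpec(
            n_channels=spec.n_channels, fs=spec.fs, duration=spec.duration,
            seed=int(rng.integers(0, 2**31 - 1)), shared_kind="erp_bump",
            shared_params=params, channel_gains=spec.channel_gains,
            snr_db=spec.snr_db, noise_kind=spec.noise_kind,
        )
        trials.append(generate(sub))

    if not trials_as_channels:
        return trials
    data = np.array([tr.recording.data[0] for tr in trials])
    clean = erp_bump(np.arange(spec.n_samples) / spec.fs, latency,
                     base.get("width_s", 0.1), amplitude)
    rec = MultiChannelRecording(data, spec.fs)
    return SyntheticTrial(rec, clean, trials[0].truth_band)
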