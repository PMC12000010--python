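"""Evaluation procedures: spectra, frequency recognition, waveform similarity,
superposition averaging, and recognition-accuracy bookkeeping.

Frequency recognition follows the standard SSVEP power-spectrum rule: the
stimulation frequency is read off as the candidate whose power-spectrum
amplitude is highest.  Waveform similarity is Pearson correlation against a
reference obtained by superposing and averaging repeated trials.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import signal as sps

METHODS = ("pca", "ica", "ccca")


@dataclass
class SpectrumEstimate:
    """One-sided power spectrum on an ascending Hz grid."""

    freqs: np.ndarray
    power: np.ndarray
    method_params: dict

    def __post_init__(self) -> None:
        if self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must have equal length")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly ascending")
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")


def power_spectrum(signal, fs: float, nfft: int | None = None,
                   window: str = "boxcar") -> SpectrumEstimate:
    """Periodogram power spectrum, optionally zero-padded to ``nfft``."""
    x = np.asarray(signal, dtype=float).ravel()
    if x.size < 8:
        raise ValueError("signal too short for a spectrum estimate")
    if nfft is None:
        nfft = x.size
    freqs, power = sps.periodogram(x, fs=fs, window=window, nfft=nfft)
    return SpectrumEstimate(freqs, power,
                            {"nfft": nfft, "window": window, "fs": fs})


def recognize_frequency(spectrum: SpectrumEstimate, candidates) -> float:
    """Pick the candidate frequency with maximal power-spectrum amplitude.

    Each candidate is mapped to its nearest grid point; ties break toward the
    lower frequency.
    """
    cands = np.asarray(candidates, dtype=float)
    if cands.size == 0:
        raise ValueError("candidate list is empty")
    if cands.min() < spectrum.freqs[0] or cands.max() > spectrum.freqs[-1]:
        raise ValueError("candidates outside the spectrum's frequency range")
    order = np.argsort(cands)
    idx = np.abs(spectrum.freqs[None, :] - cands[order, None]).argmin(axis=1)
    powers = spectrum.power[idx]
    return float(cands[order][int(np.argmax(powers))])  # argmax takes first max


def average_reference(trials) -> np.ndarray:
    """Superpose and average repeated trials into a reference waveform."""
    arrs = [np.asarray(t, dtype=float).ravel() for t in trials]
    if not arrs:
        raise ValueError("no trials given")
    lengths = {a.size for a in arrs}
    if len(lengths) != 1:
        raise ValueError(f"trials have mismatched lengths: {sorted(lengths)}")
    return np.mean(arrs, axis=0)


def similarity(extracted, reference) -> float:
    """Pearson correlation between an extracted waveform and a reference."""
    x = np.asarray(extracted, dtype=float).ravel()
    y = np.asarray(reference, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("waveforms must have equal length")
    if x.size < 3:
        raise ValueError("waveforms too short for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("similarity undefined for a constant waveform")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class RecognitionTable:
    """Per-subject recognition accuracies for the three methods."""

    table: pd.DataFrame  # columns: subject, pca, ica, ccca

    def __post_init__(self) -> None:
        missing = [c for c in ("subject", *METHODS) if c not in self.table.columns]
        if missing:
            raise ValueError(f"table missing columns: {missing}")
        accs = self.table[list(METHODS)].to_numpy(dtype=float)
        if np.any((accs < 0) | (accs > 1)) or not np.isfinite(accs).all():
            raise ValueError("accuracies must lie in [0, 1]")

    def accuracy(self, subject: str, method: str) -> float:
        if method not in METHODS:
            raise KeyError(f"unknown method {method!r}")
        rows = self.table.loc[self.table["subject"] == subject]
        if rows.empty:
            raise KeyError(f"unknown subject {subject!r}")
        return float(rows.iloc[0][method])


def load_ssvep_accuracy_table() -> RecognitionTable:
    """Packaged per-subject SSVEP recognition accuracies (34 subjects)."""
    path = resources.files("ccca.data") / "table1_ssvep_accuracy.csv"
    with resources.as_file(path) as p:
        return RecognitionTable(pd.read_csv(p))


def best_method_count(table: RecognitionTable) -> int:
    """Number of subjects whose best accuracy is reached by ccca.

    Ties count for ccca: a subject where ccca equals the best competitor is
    still credited to ccca.
    """
    df = table.table
    ccca = df["ccca"].to_numpy(dtype=float)
    others = df[["pca", "ica"]].to_numpy(dtype=float).max(axis=1)
    return int(np.sum(ccca >= others))


def accuracy_difference(table: RecognitionTable, subject: str,
                        method_a: str, method_b: str) -> float:
    """Accuracy difference in percentage points, rounded to 2 decimals."""
    diff = table.accuracy(subject, method_a) - table.accuracy(subject, method_b)
    return round(diff * 100.0, 2)
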