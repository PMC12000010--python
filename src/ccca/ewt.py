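"""Empirical wavelet transform with Meyer-type filters.

The EWT partitions the normalized one-sided spectrum [0, pi] into N bands at
data-driven boundaries w_1 < ... < w_{N-1} and builds a tight filter bank:
one scaling (low-pass) filter and N-1 wavelet (band-pass) filters whose
squared magnitudes sum to one at every frequency.  Analysis and synthesis
reuse the same real, even filters, so the transform is applied twice and the
band components still sum exactly to the input signal.

Transitions of half-width tau_n = mu * w_n around each boundary are shaped by
the Meyer auxiliary polynomial beta(x) = x^4 (35 - 84 x + 70 x^2 - 20 x^3),
which rises smoothly from 0 to 1 and satisfies beta(x) + beta(1-x) = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks


def beta(x):
    """Meyer auxiliary polynomial, clamped to [0, 1] outside its domain.

    beta(x) = x^4 (35 - 84 x + 70 x^2 - 20 x^3) on [0, 1]; 0 below, 1 above.
    Satisfies beta(0) = 0, beta(1) = 1 and beta(x) + beta(1 - x) = 1, which
    makes the cos/sin filter transitions join continuously and keeps the
    squared responses a partition of unity.
    """
    x = np.clip(np.asarray(x, dtype=float), 0.0, 1.0)
    out = x**4 * (35.0 - 84.0 * x + 70.0 * x**2 - 20.0 * x**3)
    if out.ndim == 0:
        return float(out)
    return out


def detect_boundaries(magnitude_spectrum, n_bands: int, smooth: int = 5):
    """Segment a one-sided magnitude spectrum into ``n_bands`` bands.

    The spectrum is lightly smoothed with a moving average, its ``n_bands``
    largest local maxima are located, and each boundary is placed at the
    global minimum of the (smoothed) spectrum between consecutive retained
    maxima.  If fewer than ``n_bands`` local maxima exist the spectrum is
    split into equal-width segments of [0, pi] and a warning is emitted.

    Parameters
    ----------
    magnitude_spectrum : array-like
        Non-negative magnitudes on a uniform grid spanning [0, pi].
    n_bands : int
        Number of bands N >= 1; returns N - 1 boundaries.

    Returns
    -------
    ndarray of N - 1 strictly increasing normalized frequencies in (0, pi).
    """
    spec = np.asarray(magnitude_spectrum, dtype=float)
    if n_bands < 1:
        raise ValueError("n_bands must be >= 1")
    if spec.ndim != 1 or spec.size < 2 * n_bands:
        raise ValueError(
            f"spectrum length {spec.size} too short for {n_bands} bands"
        )
    if n_bands == 1:
        return np.empty(0)

    grid = np.linspace(0.0, np.pi, spec.size)
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        smoothed = np.convolve(spec, kernel, mode="same")
    else:
        smoothed = spec

    # interior local maxima; endpoints are handled by find_peaks' definition
    peaks, props = find_peaks(smoothed, height=0.0)
    if peaks.size < n_bands:
        warnings.warn(
            f"only {peaks.size} local maxima found for {n_bands} bands; "
            "falling back to equal-width segmentation",
            stacklevel=2,
        )
        return np.pi * np.arange(1, n_bands) / n_bands

    order = np.argsort(props["peak_heights"])[::-1][:n_bands]
    kept = np.sort(peaks[order])
    bounds = np.empty(n_bands - 1)
    for i in range(n_bands - 1):
        lo, hi = kept[i], kept[i + 1]
        bounds[i] = grid[lo + np.argmin(smoothed[lo : hi + 1])]
    return bounds


def auto_mu(boundaries) -> float:
    """Transition parameter guaranteeing non-overlapping transition zones.

    Takes a quarter of the tightest admissible ratio: for adjacent boundary
    pairs mu must satisfy mu < (w_{n+1} - w_n) / (w_{n+1} + w_n), and the last
    transition must stay below pi, mu < (pi - w_last) / w_last.  The result is
    clipped to (0, 0.5).
    """
    w = np.asarray(boundaries, dtype=float)
    if w.size == 0:
        return 0.25
    ratios = [(np.pi - w[-1]) / w[-1]]
    if w.size > 1:
        ratios.extend((w[1:] - w[:-1]) / (w[1:] + w[:-1]))
    mu = 0.25 * min(ratios)
    return float(np.clip(mu, 1e-6, 0.4999))


def _phi_response(w, w1: float, tau1: float):
    """Scaling (low-pass) filter magnitude at normalized frequencies |w|."""
    aw = np.abs(np.asarray(w, dtype=float))
    out = np.zeros_like(aw)
    out[aw <= w1 - tau1] = 1.0
    trans = (aw >= w1 - tau1) & (aw <= w1 + tau1)
    out[trans] = np.cos(
        0.5 * np.pi * beta((aw[trans] - w1 + tau1) / (2.0 * tau1))
    )
    return out


def _gamma_response(w, wn: float, taun: float, wup, tauup):
    """Wavelet (band-pass) filter between boundary wn and wup.

    ``wup`` is None for the last band, whose response stays flat up to pi.
    """
    aw = np.abs(np.asarray(w, dtype=float))
    out = np.zeros_like(aw)
    lower = (aw >= wn - taun) & (aw <= wn + taun)
    out[lower] = np.sin(
        0.5 * np.pi * beta((aw[lower] - wn + taun) / (2.0 * taun))
    )
    if wup is None:
        out[aw >= wn + taun] = 1.0
    else:
        out[(aw >= wn + taun) & (aw <= wup - tauup)] = 1.0
        upper = (aw >= wup - tauup) & (aw <= wup + tauup)
        out[upper] = np.cos(
            0.5 * np.pi * beta((aw[upper] - wup + tauup) / (2.0 * tauup))
        )
    return out


@dataclass
class EWTFilterBank:
    """Meyer-type empirical filter bank on the normalized grid [0, pi].

    Attributes
    ----------
    boundaries : ndarray, length N - 1
        Strictly increasing normalized boundary frequencies in (0, pi).
    mu : float
        Transition parameter in (0, 0.5); tau_n = mu * w_n.
    grid_size : int
        Number of samples of the tabulated responses.
    phi_hat : ndarray
        Tabulated scaling-filter magnitude response.
    gamma_hats : ndarray, shape (N - 1, grid_size)
        Tabulated wavelet-filter magnitude responses, low to high frequency.
    """

    boundaries: np.ndarray
    mu: float
    grid_size: int = 1024
    phi_hat: np.ndarray = field(init=False, repr=False)
    gamma_hats: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.boundaries, dtype=float).ravel()
        if w.size and (np.any(w <= 0) or np.any(w >= np.pi)):
            raise ValueError("boundaries must lie strictly inside (0, pi)")
        if w.size > 1 and np.any(np.diff(w) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        if not (0.0 < self.mu < 0.5):
            raise ValueError(f"mu must lie in (0, 0.5), got {self.mu}")
        taus = self.mu * w
        for n in range(w.size - 1):
            if w[n] + taus[n] >= w[n + 1] - taus[n + 1]:
                raise ValueError(
                    "transition zones overlap between boundaries "
                    f"{n} (w={w[n]:.4f}) and {n + 1} (w={w[n + 1]:.4f}); "
                    "reduce mu"
                )
        if w.size and w[-1] + taus[-1] > np.pi:
            raise ValueError(
                f"last transition zone exceeds pi (w={w[-1]:.4f}, mu={self.mu})"
            )
        self.boundaries = w
        grid = self.grid
        self.phi_hat = self._eval_filter(0, grid)
        self.gamma_hats = np.array(
            [self._eval_filter(k, grid) for k in range(1, self.n_bands)]
        ).reshape(self.n_bands - 1, self.grid_size)

    @property
    def n_bands(self) -> int:
        return self.boundaries.size + 1

    @property
    def taus(self) -> np.ndarray:
        return self.mu * self.boundaries

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(0.0, np.pi, self.grid_size)

    def _eval_filter(self, k: int, w) -> np.ndarray:
        """Magnitude response of band ``k`` at normalized frequencies ``w``."""
        bnd, taus = self.boundaries, self.taus
        if bnd.size == 0:  # single band: identity filter
            return np.ones_like(np.asarray(w, dtype=float))
        if k == 0:
            return _phi_response(w, bnd[0], taus[0])
        if k == self.n_bands - 1:
            return _gamma_response(w, bnd[k - 1], taus[k - 1], None, None)
        return _gamma_response(w, bnd[k - 1], taus[k - 1], bnd[k], taus[k])

    def responses_at(self, w) -> np.ndarray:
        """All band responses evaluated at normalized frequencies ``w``.

        Returns an array of shape (n_bands, len(w)); rows are ordered low to
        high frequency and their squares sum to one at every point.
        """
        w = np.asarray(w, dtype=float)
        return np.array([self._eval_filter(k, w) for k in range(self.n_bands)])

    def boundaries_hz(self, fs: float) -> np.ndarray:
        """Boundaries converted to Hz for a sampling rate ``fs``."""
        return self.boundaries * fs / (2.0 * np.pi)


def build_filter_bank(boundaries, mu: float | None = None,
                      grid_size: int = 1024) -> EWTFilterBank:
    """Construct an admissible Meyer-type filter bank.

    Parameters
    ----------
    boundaries : array-like
        Strictly increasing normalized boundaries in (0, pi); empty for a
        single all-pass band.
    mu : float, optional
        Transition parameter; defaults to :func:`auto_mu` of the boundaries.
    grid_size : int
        Resolution of the tabulated responses.
    """
    if mu is None:
        mu = auto_mu(boundaries)
    return EWTFilterBank(np.asarray(boundaries, dtype=float), mu, grid_size)


@dataclass
class EWTComponents:
    """Band components of one signal: (n_bands x T), low to high frequency."""

    components: np.ndarray
    filter_bank: EWTFilterBank
    source_length: int

    def __post_init__(self) -> None:
        if self.components.shape[0] != self.filter_bank.n_bands:
            raise ValueError("component count does not match filter bank")


def _signal_grid(n: int) -> np.ndarray:
    """Normalized frequencies of the length-n DFT, folded to [0, pi]."""
    k = np.arange(n)
    k = np.minimum(k, n - k)
    return 2.0 * np.pi * k / n


def ewt_decompose(signal, filter_bank: EWTFilterBank) -> EWTComponents:
    """Decompose a real signal into its empirical wavelet band components.

    Each component is obtained by multiplying the signal spectrum with the
    band's real, even filter response twice (analysis inner product followed
    by synthesis convolution with the same filter) and inverting the
    transform, so the outputs are real and sum back to the input exactly.
    """
    x = np.asarray(signal, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("signal must have at least two samples")
    spec = np.fft.fft(x)
    w = _signal_grid(x.size)
    resp = filter_bank.responses_at(w)
    comps = np.fft.ifft(spec[None, :] * resp**2, axis=1).real
    return EWTComponents(comps, filter_bank, x.size)


def ewt_reconstruct(components: EWTComponents) -> np.ndarray:
    """Sum the band components back into the original signal.

    Exact up to floating-point because the squared filter responses form a
    partition of unity on the signal's frequency grid.
    """
    return components.components.sum(axis=0)
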