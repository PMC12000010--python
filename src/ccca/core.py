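"""Channel component correlation analysis (CCCA).

Given n_c channels each decomposed into the same m frequency bands, CCCA
finds one weight per band, shared across channels, that maximizes the summed
cross-channel covariance of the weighted band combinations

    max_w  w' S w   s.t.  w' Q w = 1,

where S sums the cross-covariance matrices cov(F_k, F_l) over ordered channel
pairs k != l and Q sums the within-channel covariances cov(F_i, F_i).  The
Lagrangian turns this into the symmetric-definite generalized eigenproblem
S w = lambda Q w; the leading eigenvector weights the band shared most
strongly across channels, and projecting the channel-averaged band stack onto
it yields the common component y.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .ewt import (
    EWTComponents,
    auto_mu,
    build_filter_bank,
    detect_boundaries,
    ewt_decompose,
)
from .types import MultiChannelRecording

_RIDGE_COND = 1e-10     # Q eigenvalue ratio below which a ridge is added
_RIDGE_SCALE = 1e-8     # ridge = _RIDGE_SCALE * trace(Q) / m


@dataclass
class BandStack:
    """Per-channel band matrices F_i (m bands x T samples), mean-centered.

    All channels share the same filter bank, so band row j means the same
    frequency range in every channel.
    """

    per_channel: list[np.ndarray]
    band_indices: list[int]
    fs: float

    def __post_init__(self) -> None:
        shapes = {f.shape for f in self.per_channel}
        if len(shapes) != 1:
            raise ValueError(f"channels have mismatched band shapes: {shapes}")
        if self.n_channels < 2:
            raise ValueError("band stack needs at least two channels")
        if self.n_bands < 1:
            raise ValueError("band stack needs at least one band")

    @property
    def n_channels(self) -> int:
        return len(self.per_channel)

    @property
    def n_bands(self) -> int:
        return self.per_channel[0].shape[0]

    @property
    def n_samples(self) -> int:
        return self.per_channel[0].shape[1]

    def channel_average(self) -> np.ndarray:
        """Element-wise mean of the F_i (m x T)."""
        return np.mean(self.per_channel, axis=0)


@dataclass
class CovariancePencil:
    """The matrices of the generalized eigenproblem S w = lambda Q w.

    S : summed cross-channel band covariances (the objective, symmetric).
    Q : summed within-channel band covariances (the normalizer, symmetric
        positive semi-definite).
    ridge : nonnegative diagonal regularizer added to Q when near-singular.
    """

    S: np.ndarray
    Q: np.ndarray
    ridge: float = 0.0

    def __post_init__(self) -> None:
        for name, mat in (("S", self.S), ("Q", self.Q)):
            if not np.isfinite(mat).all():
                raise ValueError(f"{name} contains non-finite entries")
            if not np.allclose(mat, mat.T, atol=1e-12 * max(1.0, np.abs(mat).max())):
                raise ValueError(f"{name} is not symmetric")

    @property
    def m(self) -> int:
        return self.S.shape[0]

    @property
    def Q_regularized(self) -> np.ndarray:
        return self.Q + self.ridge * np.eye(self.m)


@dataclass
class WeightSolution:
    """Generalized eigenvectors (band weight sets) of the covariance pencil.

    Columns of W are Q-normalized (w' Q w = 1) and sorted by descending
    eigenvalue; the first column is the weight set that extracts the most
    strongly shared band combination.
    """

    W: np.ndarray
    eigenvalues: np.ndarray
    pencil: CovariancePencil


@dataclass
class ExtractedComponent:
    """The common component y and the per-channel components s_i."""

    y: np.ndarray
    per_channel_s: np.ndarray
    weight_set_used: int = 0


def stack_bands(decompositions: list[EWTComponents],
                band_indices: list[int] | None = None,
                fs: float = 1.0) -> BandStack:
    """Assemble selected EWT layers of every channel into a band stack.

    Rows are the selected layers in ascending frequency order and are
    mean-centered over time (covariances are computed about the mean, and a
    shared DC offset carries no cross-channel timing information).
    """
    if not decompositions:
        raise ValueError("no decompositions given")
    n_bands_total = decompositions[0].filter_bank.n_bands
    if band_indices is None:
        band_indices = list(range(n_bands_total))
    for j in band_indices:
        if not 0 <= j < n_bands_total:
            raise IndexError(
                f"band index {j} out of range for {n_bands_total} bands"
            )
    per_channel = []
    for d in decompositions:
        if d.filter_bank.n_bands != n_bands_total:
            raise ValueError("channels decomposed with different filter banks")
        rows = d.components[sorted(band_indices), :]
        per_channel.append(rows - rows.mean(axis=1, keepdims=True))
    return BandStack(per_channel, sorted(band_indices), fs)


def compute_pencil(stack: BandStack) -> CovariancePencil:
    """Build the covariance pencil (S, Q) from a band stack.

    S(g,h) = sum over ordered channel pairs k != l of cov(f_{k,g}, f_{l,h});
    Q      = sum over channels of cov(F_i, F_i).
    Sample covariances use denominator T - 1.  S is symmetrized to remove
    floating-point asymmetry; a small ridge is added to Q's diagonal when its
    eigenvalue spread exceeds 1e10.
    """
    T = stack.n_samples
    if T <= stack.n_bands:
        raise ValueError("need more samples than bands for covariance")
    denom = T - 1
    centered = [F - F.mean(axis=1, keepdims=True) for F in stack.per_channel]
    variances = np.array([(F**2).sum(axis=1) / denom for F in centered])
    zero_rows = variances <= 0
    if zero_rows.all(axis=1).any():
        raise ValueError("a channel has only zero-variance bands after centering")
    if zero_rows.any():
        warnings.warn("zero-variance band(s) detected after centering",
                      stacklevel=2)

    total = np.sum(centered, axis=0)          # sum_k F_k, shape (m, T)
    autos = sum(F @ F.T for F in centered) / denom
    S = total @ total.T / denom - autos       # = sum_{k != l} cov(F_k, F_l)
    S = 0.5 * (S + S.T)
    Q = 0.5 * (autos + autos.T)

    eigvals = linalg.eigvalsh(Q)
    ridge = 0.0
    if eigvals[0] < _RIDGE_COND * max(eigvals[-1], np.finfo(float).tiny):
        ridge = _RIDGE_SCALE * np.trace(Q) / stack.n_bands
    return CovariancePencil(S, Q, ridge)


def solve_weights(pencil: CovariancePencil) -> WeightSolution:
    """Solve S w = lambda Q w for all m weight sets.

    Uses the symmetric-definite generalized eigensolver; columns come back
    Q-orthonormal (w' Q w = 1), are sorted by descending eigenvalue, and each
    column's sign is fixed so its largest-magnitude entry is positive.
    """
    if not (np.isfinite(pencil.S).all() and np.isfinite(pencil.Q).all()):
        raise ValueError("pencil contains non-finite entries")
    lam, W = linalg.eigh(pencil.S, pencil.Q_regularized)
    order = np.argsort(lam)[::-1]
    lam, W = lam[order], W[:, order]
    for j in range(W.shape[1]):
        if W[np.argmax(np.abs(W[:, j])), j] < 0:
            W[:, j] = -W[:, j]
    return WeightSolution(W, lam, pencil)


def extract_component(solution: WeightSolution, stack: BandStack,
                      weight_set: int = 0,
                      sign_reference: np.ndarray | None = None
                      ) -> ExtractedComponent:
    """Project the band stack onto one weight set.

    y = w' (mean over channels of F_i); s_i = w' F_i.  The sign of the whole
    solution is flipped if needed so that y correlates non-negatively with
    ``sign_reference`` (default: the channel-averaged stack sum), since
    generalized eigenvectors are only defined up to sign.
    """
    m = solution.W.shape[1]
    if not 0 <= weight_set < m:
        raise IndexError(f"weight_set {weight_set} out of range for {m} sets")
    w = solution.W[:, weight_set]
    y = w @ stack.channel_average()
    s = np.array([w @ F for F in stack.per_channel])
    if sign_reference is None:
        sign_reference = stack.channel_average().sum(axis=0)
    ref = sign_reference - sign_reference.mean()
    if ref.shape != y.shape:
        raise ValueError("sign reference length does not match component")
    if float(np.dot(y - y.mean(), ref)) < 0:
        y, s = -y, -s
    return ExtractedComponent(y, s, weight_set)


@dataclass
class CCCAResult:
    """Full pipeline output with every intermediate stage retrievable."""

    component: ExtractedComponent
    solution: WeightSolution
    stack: BandStack
    filter_bank: object
    decompositions: list = field(repr=False, default_factory=list)


def ccca_pipeline(recording: MultiChannelRecording,
                  n_bands: int = 5,
                  band_indices: list[int] | None = None,
                  mu: float | str = "auto",
                  boundaries: np.ndarray | None = None,
                  grid_size: int = 1024,
                  weight_set: int = 0) -> CCCAResult:
    """Run the full extraction: segment, filter, decompose, solve, project.

    Boundaries are detected once from the channel-averaged magnitude spectrum
    (so band j means the same frequency range in every channel) unless given
    explicitly; the same bank is applied to all channels.

    Parameters
    ----------
    recording : MultiChannelRecording
        At least two channels.
    n_bands : int
        Number of EWT layers N.
    band_indices : list of int, optional
        Which layers enter the covariance analysis (default: all).
    mu : float or "auto"
        Transition parameter; "auto" derives a non-overlapping value from
        the detected boundaries.
    boundaries : array-like, optional
        Explicit normalized boundaries in (0, pi), bypassing detection.
    """
    if recording.n_channels < 2:
        raise ValueError(
            "ccca needs at least two channels: cross-channel covariance is "
            "undefined for a single channel"
        )
    try:
        if boundaries is None:
            spec = np.abs(np.fft.rfft(recording.data, axis=1)).mean(axis=0)
            boundaries = detect_boundaries(spec, n_bands)
        mu_val = auto_mu(boundaries) if mu == "auto" else float(mu)
        bank = build_filter_bank(boundaries, mu_val, grid_size)
    except Exception as e:
        raise type(e)(f"[segmentation] {e}") from e
    try:
        decomps = [ewt_decompose(ch, bank) for ch in recording.data]
    except Exception as e:
        raise type(e)(f"[decomposition] {e}") from e
    try:
        stack = stack_bands(decomps, band_indices, fs=recording.fs)
        pencil = compute_pencil(stack)
        solution = solve_weights(pencil)
    except Exception as e:
        raise type(e)(f"[solver] {e}") from e
    component = extract_component(
        solution, stack, weight_set, sign_reference=recording.channel_mean()
    )
    return CCCAResult(component, solution, stack, bank, decomps)
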