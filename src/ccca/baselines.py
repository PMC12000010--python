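"""PCA and ICA comparators for multi-channel component extraction.

Both operate directly on the channels-by-samples matrix: PCA returns the
orthogonal directions of maximal variance of the channel covariance; ICA
whitens and then maximizes negentropy (FastICA, log-cosh contrast,
deflationary) to unmix statistically independent sources.  ICA has no
intrinsic ordering, so a component-selection rule is needed: the component
with maximal absolute correlation to a caller-supplied reference (or, absent
one, to the channel mean) is reported.  That selection rule is an evaluation
convenience of this package, not part of either classical method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .types import MultiChannelRecording


@dataclass
class BaselineResult:
    """Extracted sources (k x T), their unmixing weights, and bookkeeping."""

    components: np.ndarray
    mixing_info: np.ndarray
    method_tag: str
    selected_index: int = 0
    converged: bool = True

    @property
    def selected(self) -> np.ndarray:
        return self.components[self.selected_index]


def _align_signs(components: np.ndarray, reference: np.ndarray) -> np.ndarray:
    ref = reference - reference.mean()
    comps = components.copy()
    for i in range(comps.shape[0]):
        c = comps[i] - comps[i].mean()
        if float(c @ ref) < 0:
            comps[i] = -comps[i]
    return comps


def pca_extract(recording: MultiChannelRecording, k: int = 1) -> BaselineResult:
    """Top-k principal component time courses of the channel covariance.

    Channels are mean-centered, the channel-by-channel covariance is
    eigendecomposed, and the k leading component time courses are returned in
    descending-variance order, sign-aligned to the channel mean.  Rank
    deficiency yields fewer components with a warning.
    """
    if recording.n_channels < 2:
        raise ValueError("pca needs at least two channels")
    if not 1 <= k <= recording.n_channels:
        raise ValueError(f"k={k} outside [1, {recording.n_channels}]")
    X = recording.data - recording.data.mean(axis=1, keepdims=True)
    cov = X @ X.T / (recording.n_samples - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    rank = int(np.sum(eigvals > 1e-12 * max(eigvals[0], 1e-300)))
    if rank < k:
        warnings.warn(
            f"input has rank {rank} < k={k}; returning {rank} components",
            stacklevel=2,
        )
        k = max(rank, 1)
    weights = eigvecs[:, :k].T                      # k x n_c
    comps = _align_signs(weights @ X, recording.channel_mean())
    return BaselineResult(comps, weights, "pca", 0)


def ica_extract(recording: MultiChannelRecording, k: int | None = None,
                reference: np.ndarray | None = None,
                seed: int = 0, max_iter: int = 500,
                tol: float = 1e-6) -> BaselineResult:
    """Negentropy-maximization ICA (FastICA, log-cosh, deflationary).

    The selected component maximizes |correlation| with ``reference`` when
    one is supplied, else with the channel mean.  Non-convergence returns the
    best iterate with ``converged=False``.
    """
    if recording.n_channels < 2:
        raise ValueError("ica needs at least two channels")
    if k is None:
        k = recording.n_channels
    if not 1 <= k <= recording.n_channels:
        raise ValueError(f"k={k} outside [1, {recording.n_channels}]")
    ica = FastICA(
        n_components=k, algorithm="deflation", fun="logcosh",
        whiten="unit-variance", max_iter=max_iter, tol=tol,
        random_state=seed,
    )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        sources = ica.fit_transform(recording.data.T).T    # k x T
        converged = not any(
            issubclass(w.category, ConvergenceWarning) for w in caught
        )
    ref = recording.channel_mean() if reference is None else np.asarray(reference)
    if ref.shape[0] != recording.n_samples:
        raise ValueError("reference length does not match recording")
    refc = ref - ref.mean()
    corrs = np.array([
        abs(float(np.corrcoef(src, refc)[0, 1])) for src in sources
    ])
    selected = int(np.argmax(corrs))
    comps = _align_signs(sources, refc)
    return BaselineResult(comps, ica.components_, "ica", selected, converged)
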