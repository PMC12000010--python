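import numpy as np
import pytest

from ccca import build_filter_bank, ewt_decompose
from ccca.core import stack_bands


EQUAL_SPLIT_5 = np.pi * np.arange(1, 5) / 5  # 5-band equal split of [0, pi]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def bank5():
    """Five-band equal-split bank; at fs=250 the bands are 25 Hz wide."""
    return build_filter_bank(EQUAL_SPLIT_5)


def make_band_stack(recording_data, bank, fs=250.0, band_indices=None):
    decomps = [ewt_decompose(ch, bank) for ch in recording_data]
    return stack_bands(decomps, band_indices, fs=fs)


def brute_force_rayleigh(S, Q, n_dirs=100_000, seed=0):
    """Independent oracle: max of w'Sw over random Q-normalized directions."""
    m = S.shape[0]
    rng = np.random.default_rng(seed)
    V = rng.standard_normal((n_dirs, m))
    qn = np.einsum("ij,jk,ik->i", V, Q, V)
    V = V / np.sqrt(qn)[:, None]
    vals = np.einsum("ij,jk,ik->i", V, S, V)
    best = int(np.argmax(vals))
    return float(vals[best]), V[best]


def pencil_by_direct_summation(per_channel):
    """Independent oracle for (S, Q): explicit loops over channel pairs."""
    n_c = len(per_channel)
    m = per_channel[0].shape[0]
    S = np.zeros((m, m))
    Q = np.zeros((m, m))
    covs = {}
    for k in range(n_c):
        for l in range(n_c):
            Fk = per_channel[k] - per_channel[k].mean(axis=1, keepdims=True)
            Fl = per_channel[l] - per_channel[l].mean(axis=1, keepdims=True)
            covs[k, l] = Fk @ Fl.T / (Fk.shape[1] - 1)
    for k in range(n_c):
        Q += covs[k, k]
        for l in range(n_c):
            if k != l:
                S += covs[k, l]
    return 0.5 * (S + S.T), 0.5 * (Q + Q.T)
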