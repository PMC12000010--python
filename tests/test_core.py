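"""CCCA solver: band stacking, covariance pencil, eigenproblem, extraction."""

import numpy as np
import pytest

from ccca import MultiChannelRecording, build_filter_bank, ewt_decompose
from ccca.core import (
    CovariancePencil,
    ccca_pipeline,
    compute_pencil,
    extract_component,
    solve_weights,
    stack_bands,
)
from ccca.evaluation import power_spectrum, recognize_frequency, similarity
from ccca.synthetic import SyntheticSpec, generate

from conftest import (
    EQUAL_SPLIT_5,
    brute_force_rayleigh,
    make_band_stack,
    pencil_by_direct_summation,
)


def random_spd(m, rng):
    A = rng.standard_normal((m, m))
    return A @ A.T + m * np.eye(m)


class TestStackBands:
    def test_selected_layers_shape(self, bank5, rng):
        decomps = [ewt_decompose(rng.standard_normal(400), bank5)
                   for _ in range(2)]
        stack = stack_bands(decomps, [2, 3, 4], fs=250.0)
        assert stack.n_channels == 2
        assert all(F.shape == (3, 400) for F in stack.per_channel)

    def test_out_of_range_band_index_named(self, bank5, rng):
        decomps = [ewt_decompose(rng.standard_normal(100), bank5)
                   for _ in range(2)]
        with pytest.raises(IndexError, match="7"):
            stack_bands(decomps, [0, 7])

    def test_rows_are_mean_centered(self, bank5, rng):
        decomps = [ewt_decompose(rng.standard_normal(200) + 5.0, bank5)
                   for _ in range(2)]
        stack = stack_bands(decomps)
        for F in stack.per_channel:
            np.testing.assert_allclose(F.mean(axis=1), 0, atol=1e-12)

    def test_single_channel_rejected(self, bank5, rng):
        d = ewt_decompose(rng.standard_normal(100), bank5)
        with pytest.raises(ValueError, match="two channels"):
            stack_bands([d])


class TestComputePencil:
    def test_identical_channels_make_s_equal_q(self, bank5, rng):
        x = rng.standard_normal(500)
        stack = make_band_stack([x, x], bank5)
        p = compute_pencil(stack)
        np.testing.assert_allclose(p.S, p.Q, atol=1e-10 * np.abs(p.Q).max())

    def test_negated_channel_makes_s_equal_minus_q(self, bank5, rng):
        x = rng.standard_normal(500)
        stack = make_band_stack([x, -x], bank5)
        p = compute_pencil(stack)
        np.testing.assert_allclose(p.S, -p.Q, atol=1e-10 * np.abs(p.Q).max())

    def test_matches_direct_summation_oracle(self, bank5, rng):
        stack = make_band_stack(rng.standard_normal((4, 600)), bank5)
        S_ref, Q_ref = pencil_by_direct_summation(stack.per_channel)
        p = compute_pencil(stack)
        np.testing.assert_allclose(p.S, S_ref, atol=1e-10 * np.abs(S_ref).max())
        np.testing.assert_allclose(p.Q, Q_ref, atol=1e-10 * np.abs(Q_ref).max())

    def test_independent_noise_has_small_cross_covariance(self):
        # cross-covariances of independent channels shrink as 1/sqrt(T)
        rng = np.random.default_rng(7)
        bank = build_filter_bank([np.pi / 2])
        stack = make_band_stack(rng.standard_normal((3, 20000)), bank)
        p = compute_pencil(stack)
        scale = np.sqrt(np.outer(np.diag(p.Q), np.diag(p.Q)))
        assert np.all(np.abs(p.S) <= 0.05 * scale)

    def test_symmetry_invariants(self, bank5, rng):
        stack = make_band_stack(rng.standard_normal((3, 400)), bank5)
        p = compute_pencil(stack)
        np.testing.assert_allclose(p.S, p.S.T, atol=1e-12 * np.abs(p.S).max())
        np.testing.assert_allclose(p.Q, p.Q.T, atol=1e-12 * np.abs(p.Q).max())
        assert np.linalg.eigvalsh(p.Q_regularized).min() > 0


class TestSolveWeights:
    def test_equal_pencil_gives_all_unit_eigenvalues(self, rng):
        Q = random_spd(4, rng)
        sol = solve_weights(CovariancePencil(Q.copy(), Q))
        np.testing.assert_allclose(sol.eigenvalues, 1.0, atol=1e-9)

    def test_diagonal_problem(self):
        sol = solve_weights(CovariancePencil(
            np.array([[1.0, 0.0], [0.0, 0.0]]), np.eye(2)))
        np.testing.assert_allclose(sol.eigenvalues, [1.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(sol.W[:, 0], [1.0, 0.0], atol=1e-12)

    @pytest.mark.parametrize("m", [2, 3])
    def test_leading_eigenvalue_matches_brute_force_oracle(self, m):
        rng = np.random.default_rng(m)
        A = rng.standard_normal((m, m))
        S = 0.5 * (A + A.T)
        Q = random_spd(m, rng)
        sol = solve_weights(CovariancePencil(S, Q))
        lam_bf, w_bf = brute_force_rayleigh(S, Q, n_dirs=100_000, seed=m)
        assert sol.eigenvalues[0] == pytest.approx(lam_bf, rel=1e-3)
        # direction agreement up to sign
        w1 = sol.W[:, 0]
        cos = abs(w1 @ w_bf) / (np.linalg.norm(w1) * np.linalg.norm(w_bf))
        assert cos >= 0.99

    def test_constraint_residual_and_ordering(self, rng):
        for _ in range(20):
            m = int(rng.integers(2, 7))
            A = rng.standard_normal((m, m))
            S = 0.5 * (A + A.T)
            Q = random_spd(m, rng)
            sol = solve_weights(CovariancePencil(S, Q))
            assert np.all(np.diff(sol.eigenvalues) <= 1e-12)
            for j in range(m):
                w = sol.W[:, j]
                assert abs(w @ Q @ w - 1.0) <= 1e-10
                resid = np.linalg.norm(S @ w - sol.eigenvalues[j] * Q @ w)
                assert resid <= 1e-8 * np.linalg.norm(S, "fro")
                assert w[np.argmax(np.abs(w))] > 0

    def test_rayleigh_ritz_bound_holds(self, rng):
        S0 = rng.standard_normal((3, 3))
        S = 0.5 * (S0 + S0.T)
        Q = random_spd(3, rng)
        sol = solve_weights(CovariancePencil(S, Q))
        V = rng.standard_normal((10_000, 3))
        V /= np.sqrt(np.einsum("ij,jk,ik->i", V, Q, V))[:, None]
        vals = np.einsum("ij,jk,ik->i", V, S, V)
        assert vals.max() <= sol.eigenvalues[0] + 1e-9

    def test_non_finite_pencil_rejected(self):
        S = np.array([[np.nan, 0.0], [0.0, 1.0]])
        with pytest.raises(ValueError, match="non-finite"):
            solve_weights(CovariancePencil(S, np.eye(2)))


class TestExtractComponent:
    def test_single_band_identical_channels_variance(self, rng):
        # w'Qw = 1 forces w = 1/sqrt(n_c v), so var(y) = 1/n_c
        bank = build_filter_bank([], mu=0.25)
        x = rng.standard_normal(500)
        for n_c in (2, 4):
            stack = make_band_stack([x] * n_c, bank)
            sol = solve_weights(compute_pencil(stack))
            comp = extract_component(sol, stack)
            assert np.var(comp.y, ddof=1) == pytest.approx(1.0 / n_c,
                                                           abs=1e-9)

    def test_weight_set_out_of_range(self, bank5, rng):
        stack = make_band_stack(rng.standard_normal((2, 300)), bank5)
        sol = solve_weights(compute_pencil(stack))
        with pytest.raises(IndexError):
            extract_component(sol, stack, weight_set=5)

    def test_sign_aligned_to_reference(self, bank5, rng):
        data = rng.standard_normal((3, 400))
        stack = make_band_stack(data, bank5)
        sol = solve_weights(compute_pencil(stack))
        comp = extract_component(sol, stack, sign_reference=data.mean(axis=0))
        ref = data.mean(axis=0) - data.mean(axis=0).mean()
        assert (comp.y - comp.y.mean()) @ ref >= 0

    def test_recovers_shared_band_noise_component(self):
        # shared source confined to band 2 at 0 dB: leading weights select
        # that band and y correlates strongly with the clean source
        bank = build_filter_bank(EQUAL_SPLIT_5)
        hits, corrs = 0, []
        for seed in range(20):
            spec = SyntheticSpec(
                n_channels=8, fs=250.0, duration=4.0, seed=seed,
                shared_kind="band_noise",
                shared_params={"passband_hz": (55.0, 70.0)}, snr_db=0.0)
            trial = generate(spec)
            stack = make_band_stack(trial.recording.data, bank)
            sol = solve_weights(compute_pencil(stack))
            hits += int(np.argmax(np.abs(sol.W[:, 0])) == trial.truth_band)
            comp = extract_component(
                sol, stack, sign_reference=trial.recording.channel_mean())
            corrs.append(abs(similarity(comp.y, trial.truth)))
        assert hits >= 19
        assert np.median(corrs) >= 0.9


class TestPipeline:
    def test_ssvep_component_peaks_at_stimulation_frequency(self):
        spec = SyntheticSpec(
            n_channels=8, fs=250.0, duration=1.0, seed=42,
            shared_kind="ssvep_tone",
            shared_params={"frequency_hz": 10.0, "n_harmonics": 2},
            snr_db=0.0)
        trial = generate(spec)
        result = ccca_pipeline(trial.recording, n_bands=5)
        ps = power_spectrum(result.component.y, 250.0)
        assert recognize_frequency(ps, list(range(8, 16))) == 10.0

    def test_single_channel_rejected(self):
        rec = MultiChannelRecording(np.random.default_rng(0)
                                    .standard_normal((1, 100)), 100.0)
        with pytest.raises(ValueError, match="two channels"):
            ccca_pipeline(rec)

    def test_duplicated_channels_make_pencil_proportional(self, rng):
        x = rng.standard_normal((1, 500))
        rec = MultiChannelRecording(np.repeat(x, 4, axis=0), 100.0)
        result = ccca_pipeline(rec, n_bands=3,
                               boundaries=[np.pi / 3, 2 * np.pi / 3])
        # S = (n_c - 1) Q, so the scaled leading eigenvalue is exactly 1
        lam1 = result.solution.eigenvalues[0] / (4 - 1)
        assert lam1 == pytest.approx(1.0, abs=1e-9)

    def test_scale_invariance_of_weights_and_eigenvalues(self, rng):
        data = rng.standard_normal((4, 600))
        bounds = [np.pi / 3, 2 * np.pi / 3]
        r1 = ccca_pipeline(MultiChannelRecording(data, 100.0),
                           n_bands=3, boundaries=bounds)
        r2 = ccca_pipeline(MultiChannelRecording(7.5 * data, 100.0),
                           n_bands=3, boundaries=bounds)
        np.testing.assert_allclose(r1.solution.eigenvalues,
                                   r2.solution.eigenvalues, atol=1e-9)
        for j in range(3):
            a, b = r1.solution.W[:, j], r2.solution.W[:, j]
            cos = abs(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
            assert cos == pytest.approx(1.0, abs=1e-9)

    def test_stage_errors_name_the_stage(self):
        rec = MultiChannelRecording(np.zeros((3, 100)) + 1.0, 100.0)
        with pytest.raises(ValueError, match=r"\[solver\]"):
            # constant channels: every band has zero variance
            ccca_pipeline(rec, n_bands=2, boundaries=[np.pi / 2])
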