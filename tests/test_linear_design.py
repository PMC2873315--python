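"""Gramian initial-condition design and frequency-domain input design."""

import numpy as np
import pytest

from discrimdesign import (
    DegenerateDesignError,
    build_near_optimal_input,
    compute_steady_state,
    concatenate_models,
    frequency_peak,
    linearize,
    observability_gramian,
    optimal_common_initial_direction,
)


class TestGramian:
    def test_lyapunov_residual_tiny(self, gramian, lin):
        CtC = lin.C.T @ lin.C
        res = np.linalg.norm(lin.A.T @ gramian.P + gramian.P @ lin.A + CtC)
        assert res / np.linalg.norm(CtC) < 1e-10

    def test_gramian_psd(self, gramian):
        assert np.linalg.eigvalsh(gramian.P).min() > -1e-12

    def test_restricted_matrix_blocks(self, gramian):
        P11, P12, P21, P22 = gramian.blocks
        assert np.allclose(P11 + P12 + P21 + P22, gramian.R)

    def test_optimal_direction_is_first_axis(self, gramian):
        v, lam = optimal_common_initial_direction(gramian)
        assert lam > 0
        assert abs(v[0]) > 0.999
        assert np.isclose(np.linalg.norm(v), 1.0)
        # energy of the direction equals the top eigenvalue
        assert np.isclose(v @ gramian.R @ v, lam, rtol=1e-12)

    def test_identical_models_degenerate(self, models):
        s = compute_steady_state(models[0], initial_guess=[0.3, 2.0, 0.1])
        lin_same = linearize(concatenate_models(s, s))
        gd = observability_gramian(lin_same)
        with pytest.raises(DegenerateDesignError):
            optimal_common_initial_direction(gd)


class TestFrequencyPeak:
    def test_peak_refined_beyond_grid(self, fp_full, lin):
        # the refined peak must beat both grid neighbours
        k = int(np.argmax(fp_full.grid_gains))
        assert fp_full.gain >= fp_full.grid_gains[k] - 1e-15
        for w in (fp_full.omega0 * 0.99, fp_full.omega0 * 1.01):
            assert lin.gain(w) <= fp_full.gain + 1e-12

    def test_single_output_peak_below_full(self, fp_full, fp_rstar):
        assert fp_rstar.gain < fp_full.gain

    def test_gain_at_omega_matches_transfer(self, lin, fp_full):
        G = lin.transfer(fp_full.omega0)
        assert np.isclose(np.linalg.svd(G, compute_uv=False)[0], fp_full.gain)


class TestNearOptimalInput:
    def test_energy_normalized(self, fp_full):
        sig = build_near_optimal_input(fp_full.omega0)
        assert np.isclose(sig.quadrature_energy(), 1.0, rtol=1e-6)

    def test_zero_decay_is_cosine(self, fp_full):
        sig = build_near_optimal_input(fp_full.omega0, decay=0.0)
        t = np.linspace(0.0, 10.0, 7)
        expected = sig.amplitude * np.cos(fp_full.omega0 * t)
        assert np.allclose(sig(t), expected)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            build_near_optimal_input(-1.0)
        with pytest.raises(ValueError):
            build_near_optimal_input(1.0, T_active=0.0)
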