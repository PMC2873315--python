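"""Nonlinear simulation, input signals, and brute-force searches."""

import numpy as np
import pytest

from discrimdesign import (
    brute_force_ic_search,
    make_input_signal,
    optimal_common_initial_direction,
    signal_l2_norm,
    simulate_difference_system,
)


class TestInputSignals:
    @pytest.mark.parametrize("kind", ["constant", "sine", "cosine", "square", "sinc", "eq10"])
    def test_energy_exact(self, kind):
        sig = make_input_signal(kind, omega=0.447, T_active=60.0, energy=1.0)
        assert np.isclose(sig.quadrature_energy(), 1.0, rtol=1e-6)
        assert np.isclose(signal_l2_norm(sig), 1.0, rtol=1e-6)

    def test_signal_vanishes_after_window(self):
        sig = make_input_signal("sine", omega=1.0, T_active=10.0)
        assert sig(10.5) == 0.0 and sig(-1.0) == 0.0

    def test_square_wave_discontinuities(self):
        w = 0.5
        sig = make_input_signal("square", omega=w, T_active=20.0)
        pts = sig.discontinuities()
        assert np.isclose(pts[0], np.pi / w)
        assert pts[-1] == 20.0

    def test_zero_signal(self):
        sig = make_input_signal("zero")
        assert sig(3.0) == 0.0 and sig.energy == 0.0

    def test_invalid_requests_rejected(self):
        with pytest.raises(ValueError):
            make_input_signal("sine", omega=0.0)
        with pytest.raises(ValueError):
            make_input_signal("constant", energy=-1.0)
        with pytest.raises(ValueError):
            make_input_signal("warble")


class TestSimulation:
    def test_zero_ic_zero_input_is_silent(self, ds):
        traj = simulate_difference_system(ds, store=False)
        assert traj.l2_norm < 1e-12

    def test_energy_identity_linear_regime(self, ds, gramian):
        """Output energy == x0' R x0 in the linear regime (< 0.1 % error)."""
        v, lam = optimal_common_initial_direction(gramian)
        beta = 1e-3
        traj = simulate_difference_system(ds, common_ic=beta * v, store=False)
        assert traj.l2_norm == pytest.approx(beta * np.sqrt(lam), rel=1e-3)

    def test_tail_bound_small(self, ds):
        traj = simulate_difference_system(ds, common_ic=[1.0, 0.0, 0.0], store=False)
        assert traj.tail_bound <= 1e-6 * traj.cumulative_energy[-1] + 1e-14

    def test_trajectory_storage_consistent(self, ds):
        traj = simulate_difference_system(ds, common_ic=[0.3, 0.2, 0.1])
        assert traj.x.shape[0] == 6 and traj.y.shape[0] == 3
        assert traj.t[0] == 0.0 and traj.t[-1] == traj.T_end
        assert np.all(np.diff(traj.cumulative_energy) >= -1e-15)

    def test_output_selector_reduces_energy(self, ds):
        full = simulate_difference_system(ds, common_ic=[1.0, 0.0, 0.0], store=False)
        only_r = simulate_difference_system(
            ds, common_ic=[1.0, 0.0, 0.0], output_selector=[2], store=False
        )
        assert only_r.l2_norm < full.l2_norm

    def test_stacked_ic_accepted(self, ds):
        common = simulate_difference_system(ds, common_ic=[0.1, 0.0, 0.0], store=False)
        stacked = simulate_difference_system(
            ds, common_ic=[0.1, 0.0, 0.0, 0.1, 0.0, 0.0], store=False
        )
        assert np.isclose(common.l2_norm, stacked.l2_norm, rtol=1e-9)

    def test_bad_ic_length_rejected(self, ds):
        with pytest.raises(ValueError):
            simulate_difference_system(ds, common_ic=[1.0, 0.0])


class TestBruteForce:
    def test_ic_search_finds_first_axis(self, ds):
        v, val = brute_force_ic_search(ds, grid_size=60)
        assert abs(v[0]) > 0.99
        assert val == pytest.approx(0.7281, abs=0.002)

    def test_ic_search_deterministic(self, ds):
        r1 = brute_force_ic_search(ds, grid_size=40, refine=False)
        r2 = brute_force_ic_search(ds, grid_size=40, refine=False)
        assert np.array_equal(r1[0], r2[0]) and r1[1] == r2[1]

    def test_invalid_beta_rejected(self, ds):
        with pytest.raises(ValueError):
            brute_force_ic_search(ds, beta=0.0)
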