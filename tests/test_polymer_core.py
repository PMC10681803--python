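"""Bead-spring force field, integrator and structural observables."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from parbcond.polymer_core import (ChainState, ForceField, bend_energy,
                                   equilibrate_chain, fene_energy,
                                   gyration_radius_sq, init_wlc_chain,
                                   langevin_step, lj_energy,
                                   persistence_length, run_steps,
                                   total_potential_energy)
from parbcond import _kernels


RC = 2.0 ** (1.0 / 6.0)


class TestPotentials:
    @pytest.mark.parametrize("r, expected", [
        (RC, 0.0),                       # shifted so the minimum sits at 0
        (1.5, 0.0),                      # beyond cutoff
        (1.0, 1.0),                      # 4(1 - 1 + 1/4) at r = sigma
    ])
    def test_lj_values(self, ff, r, expected):
        assert lj_energy(r, ff) == pytest.approx(expected, abs=1e-12)

    def test_lj_continuous_at_cutoff(self, ff):
        eps = 1e-9
        assert abs(lj_energy(RC - eps, ff) - lj_energy(RC + eps, ff)) < 1e-6

    def test_lj_rejects_nonpositive_r(self, ff):
        with pytest.raises(ValueError):
            lj_energy(0.0, ff)

    def test_fene_values(self, ff):
        assert fene_energy(0.0, ff) == 0.0
        # hand evaluation of -0.5 k R0^2 log(1 - (r/R0)^2) at r = 0.96
        r = 0.96
        expected = -0.5 * 30.0 * 1.5 ** 2 * np.log(1 - (r / 1.5) ** 2)
        assert fene_energy(r, ff) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(17.8, rel=0.02)

    def test_fene_domain_error_at_R0(self, ff):
        with pytest.raises(ValueError):
            fene_energy(ff.R0, ff)

    @pytest.mark.parametrize("theta, expected", [
        (0.0, 0.0), (np.pi / 2, 10.0), (np.pi, 20.0)])
    def test_bend_values(self, ff, theta, expected):
        assert bend_energy(theta, ff) == pytest.approx(expected, abs=1e-12)

    @given(r=st.floats(0.01, 3.0))
    @settings(max_examples=50, deadline=None)
    def test_lj_nonnegative_and_zero_beyond_cutoff(self, r):
        ff = ForceField()
        u = lj_energy(r, ff)
        assert u >= 0.0
        if r > ff.rc_lj:
            assert u == 0.0


class TestForceField:
    def test_rc_is_exact(self, ff):
        assert ff.rc_lj == 2.0 ** (1.0 / 6.0) * ff.sigma

    def test_rejects_nonpositive_parameters(self):
        with pytest.raises(ValueError):
            ForceField(sigma=0.0)
        with pytest.raises(ValueError):
            ForceField(R0=0.9)  # must exceed sigma


class TestIntegration:
    def test_zero_dt_is_identity(self, ff, thermal_chain):
        state = thermal_chain.copy()
        out = langevin_step(state, ForceField(dt=0.0))
        assert np.array_equal(out.positions, thermal_chain.positions)

    def test_deterministic_given_seed(self, ff, thermal_chain):
        a, b = thermal_chain.copy(), thermal_chain.copy()
        run_steps(a, ff, 500, seed=77)
        run_steps(b, ff, 500, seed=77)
        assert np.array_equal(a.positions, b.positions)

    def test_energy_conservation_microcanonical(self):
        """gamma = 0, kBT -> 0: velocity-Verlet drift < 1e-6 eps/step."""
        ff0 = ForceField(kBT=1e-300, gamma=0.0, k_theta=0.0)
        pos = np.array([[0, 0, 0], [1.0, 0, 0], [2.0, 0, 0.0]])
        vel = np.zeros((3, 3))
        vel[1, 0] = 0.05
        state = ChainState(pos, vel)

        def etot(s):
            return 0.5 * np.sum(s.velocities ** 2) \
                + total_potential_energy(s, ff0)

        e0 = etot(state)
        run_steps(state, ff0, 10000, seed=1)
        assert abs(etot(state) - e0) / 10000 < 1e-6

    def test_equipartition(self, ff):
        """<v^2> per component = kBT/m within 3% after thermalization."""
        state = init_wlc_chain(200, ff, seed=5)
        run_steps(state, ff, 5000, seed=11)
        rng = np.random.default_rng(0)
        acc = []
        for _ in range(120):
            run_steps(state, ff, 250, seed=int(rng.integers(2 ** 31)))
            acc.append(np.mean(state.velocities ** 2))
        assert np.mean(acc) == pytest.approx(ff.kBT / ff.mass, rel=0.03)

    def test_blowup_reported_with_step_index(self, ff):
        pos = np.array([[0, 0, 0], [1.49, 0, 0], [2.5, 0, 0.0]])
        state = ChainState(pos, np.zeros((3, 3)))
        big = ForceField(dt=0.05)  # reckless timestep: bond will overstretch
        with pytest.raises(RuntimeError, match="step"):
            run_steps(state, big, 2000, seed=1)

    def test_forces_match_potential_gradient(self, ff):
        """Kernel forces vs central finite differences of the from-scratch
        potential (covers LJ, FENE, bending and Morse routing)."""
        from parbcond.bridge_model import BridgeParams, morse_energy
        state = init_wlc_chain(15, ff, seed=3)
        bp = BridgeParams(D0=7.0)
        bi = np.array([2, 5], dtype=np.int64)
        bj = np.array([9, 12], dtype=np.int64)
        f = _kernels.compute_forces(state.positions, ff.sigma, ff.eps,
                                    ff.k_fene, ff.R0, ff.k_theta,
                                    bp.D0, bp.alpha_morse, bp.rc_bridge,
                                    bi, bj)
        pairs = np.column_stack([bi, bj])

        def U(pos):
            return total_potential_energy(
                ChainState(pos, np.zeros_like(pos)), ff, pairs,
                lambda r: morse_energy(r, bp))

        h = 1e-6
        num = np.zeros_like(f)
        for i in range(15):
            for d in range(3):
                p = state.positions.copy()
                p[i, d] += h
                up = U(p)
                p[i, d] -= 2 * h
                um = U(p)
                num[i, d] = -(up - um) / (2 * h)
        assert np.allclose(f, num, atol=5e-5)


class TestEquilibrationAndObservables:
    def test_trimer_is_trivially_converged(self, ff):
        state = equilibrate_chain(3, ff, seed=1)
        assert state.n_beads == 3
        assert np.all(state.bond_lengths() < ff.R0)

    def test_equilibrated_chain_invariants(self, ff):
        state = equilibrate_chain(60, ff, seed=4, window_tauB=50)
        assert np.all(state.bond_lengths() < ff.R0)
        assert np.all(state.bond_lengths() > 0)
        assert np.isfinite(gyration_radius_sq(state))

    def test_two_seeds_differ(self, ff):
        a = equilibrate_chain(40, ff, seed=1, window_tauB=30)
        b = equilibrate_chain(40, ff, seed=2, window_tauB=30)
        assert not np.allclose(a.positions, b.positions)

    def test_gyration_trivial_cases(self):
        pos = np.ones((7, 3))
        assert gyration_radius_sq(ChainState(pos, pos * 0)) == 0.0
        # straight rod with spacing sigma: Rg^2 = sigma^2 (N^2 - 1)/12
        n = 11
        rod = np.zeros((n, 3))
        rod[:, 0] = np.arange(n)
        expected = (n ** 2 - 1) / 12.0
        assert gyration_radius_sq(rod) == pytest.approx(expected, rel=1e-12)

    def test_persistence_on_constructed_correlations(self):
        """Frames built with exact exp(-n/10) bond correlations return 10."""
        lp = 10.0
        n_bonds = 200
        rng = np.random.default_rng(8)
        frames = []
        for _ in range(12):
            # planar chain whose bond angles are increments of sd 1/sqrt(lp)
            steps = rng.normal(0.0, np.sqrt(1.0 / lp), size=n_bonds)
            ang = np.cumsum(steps)
            bonds = np.column_stack([np.cos(ang), np.sin(ang),
                                     np.zeros(n_bonds)])
            pos = np.vstack([[0, 0, 0], np.cumsum(bonds, axis=0)])
            frames.append(pos)
        # planar decorrelation: <cos(theta_n)> = exp(-n/(2 lp_2d))
        est = persistence_length(frames, n_max=30)
        assert est == pytest.approx(2 * lp, rel=0.15)

    def test_rod_limit_reported(self):
        rod = np.zeros((100, 3))
        rod[:, 0] = np.arange(100)
        with pytest.raises(ValueError, match="rod"):
            persistence_length([rod] * 12)

    def test_freely_jointed_limit(self):
        """k_theta = 0 chain decorrelates within ~1.5 bonds."""
        ff0 = ForceField(k_theta=1e-9)
        state = init_wlc_chain(80, ff0, seed=6)
        run_steps(state, ff0, 10000, seed=2)
        rng = np.random.default_rng(1)
        frames = []
        for _ in range(15):
            run_steps(state, ff0, 2500, seed=int(rng.integers(2 ** 31)))
            frames.append(state.positions.copy())
        assert persistence_length(frames, n_max=10) < 1.5
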