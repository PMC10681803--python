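"""Stochastic ParB layer: loading, unloading, sliding, recruitment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from parbcond.parb_kinetics import (KineticParams, OccupancyState,
                                    attempt_diffusion, attempt_parS_loading,
                                    attempt_recruitment, attempt_unloading,
                                    kinetic_sweep, trans_neighbor_list)
from parbcond.synthetic_data import gen_test_chain, hairpin_contact_pair


class TestParams:
    def test_probability_partition(self):
        kp = KineticParams()
        assert kp.p_cis + kp.p_trans == pytest.approx(1.0)
        assert kp.p_trans / kp.p_cis == pytest.approx(11.0, rel=0.05)

    def test_kappa_ratio_and_residence(self):
        kp = KineticParams(kappa_on=0.008)
        assert kp.kappa_ratio == pytest.approx(8.0)
        assert kp.mean_residence_tauB == pytest.approx(1000.0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            KineticParams(kappa_on=-1.0)
        with pytest.raises(ValueError):
            KineticParams(p_move=0.6)


class TestLoading:
    def test_zero_rate_never_loads(self, rng):
        occ = OccupancyState.empty(50)
        kp = KineticParams(kappa_on=0.0)
        for _ in range(500):
            attempt_parS_loading(occ, kp, rng)
        assert occ.n_bound == 0

    def test_occupied_parS_rejects(self, rng):
        occ = OccupancyState.empty(50)
        occ.occupied[occ.parS_index] = True
        kp = KineticParams(kappa_on=1.0)
        attempt_parS_loading(occ, kp, rng)
        assert occ.n_bound == 1
        assert len(occ.event_log) == 0

    def test_loading_rate_binomial(self, rng):
        """p = 0.01/sweep over 1e4 sweeps with immediate removal: ~100 loads."""
        occ = OccupancyState.empty(11)
        kp = KineticParams(kappa_on=0.01)
        loads = 0
        for _ in range(10000):
            attempt_parS_loading(occ, kp, rng)
            if occ.occupied[occ.parS_index]:
                loads += 1
                occ.occupied[occ.parS_index] = False
        assert 70 <= loads <= 130  # ~100 +- a few Poisson SDs


class TestUnloading:
    def test_empty_chain_noop(self, rng):
        occ = OccupancyState.empty(20)
        attempt_unloading(occ, KineticParams(), rng)
        assert occ.n_bound == 0

    def test_exponential_survival(self, rng):
        """kappa_off = 0.001: survival after 1000 sweeps ~ 1/e."""
        survivors = 0
        n_rep = 3000
        p_off = 0.001
        kp = KineticParams(kappa_off=p_off)
        # vectorized replica of the per-sweep Bernoulli process
        alive = np.ones(n_rep, dtype=bool)
        for _ in range(1000):
            alive &= rng.random(n_rep) >= p_off
        frac = alive.mean()
        assert frac == pytest.approx(np.exp(-1.0), abs=0.03)
        # and the operation itself implements that Bernoulli draw
        occ = OccupancyState.empty(10)
        occ.occupied[5] = True
        removed = 0
        for _ in range(2000):
            occ.occupied[5] = True
            attempt_unloading(occ, KineticParams(kappa_off=0.5), rng)
            removed += not occ.occupied[5]
        assert removed / 2000 == pytest.approx(0.5, abs=0.05)


class TestDiffusion:
    def test_reflecting_ends_and_exclusion(self, rng):
        occ = OccupancyState.empty(4)
        occ.occupied[[0, 1]] = True
        kp = KineticParams(p_move=0.5)  # always attempts a move
        for _ in range(200):
            before = occ.n_bound
            attempt_diffusion(occ, kp, rng)
            assert occ.n_bound == before  # conserved
            assert occ.occupied.sum() == 2
        # bead cannot have left through the boundary and both remain distinct

    def test_msd_free_walker(self, rng):
        """Mid-chain ParB: MSD(t) = 2 * 0.125 * t within a few percent."""
        kp = KineticParams()
        n_rep, t = 4000, 400
        # direct simulation of the drawn process on a long empty chain
        pos = np.zeros(n_rep, dtype=int)
        for _ in range(t):
            u = rng.random(n_rep)
            pos -= u < kp.p_move
            pos += (u >= kp.p_move) & (u < 2 * kp.p_move)
        msd = np.mean(pos.astype(float) ** 2)
        assert msd == pytest.approx(2 * 0.125 * t, rel=0.05)

    def test_single_walker_operation_msd(self, rng):
        kp = KineticParams()
        n = 2001
        disp2 = []
        for rep in range(200):
            occ = OccupancyState.empty(n)
            start = n // 2
            occ.occupied[start] = True
            for _ in range(100):
                attempt_diffusion(occ, kp, rng)
            disp2.append(float((np.flatnonzero(occ.occupied)[0] - start) ** 2))
        assert np.mean(disp2) == pytest.approx(2 * 0.125 * 100, rel=0.25)


class TestTransNeighbors:
    def test_straight_chain_empty(self):
        state = gen_test_chain(40, "straight")
        occ = OccupancyState.empty(40)
        occ.occupied[10] = True
        assert len(trans_neighbor_list(state.positions, occ, 10,
                                       KineticParams())) == 0

    def test_hairpin_designed_contact(self):
        state = gen_test_chain(40, "hairpin")
        i, j = hairpin_contact_pair(40)
        occ = OccupancyState.empty(40)
        occ.occupied[i] = True
        assert list(trans_neighbor_list(state.positions, occ, i,
                                        KineticParams())) == [j]

    def test_occupied_candidates_excluded(self):
        state = gen_test_chain(40, "hairpin")
        i, j = hairpin_contact_pair(40)
        occ = OccupancyState.empty(40)
        occ.occupied[[i, j]] = True
        assert len(trans_neighbor_list(state.positions, occ, i,
                                       KineticParams())) == 0

    def test_unloaded_query_rejected(self):
        state = gen_test_chain(40, "straight")
        occ = OccupancyState.empty(40)
        with pytest.raises(ValueError):
            trans_neighbor_list(state.positions, occ, 10, KineticParams())


class TestRecruitment:
    def test_straight_chain_only_cis(self, rng):
        state = gen_test_chain(60, "straight")
        occ = OccupancyState.empty(60)
        occ.occupied[30] = True
        kp = KineticParams(kappa_on=1.0)
        for _ in range(300):
            attempt_recruitment(state.positions, occ, kp, rng)
        kinds = {e[1] for e in occ.event_log}
        assert "recruit_trans" not in kinds
        assert "recruit_cis" in kinds

    def test_blocked_cis_fails(self, rng):
        state = gen_test_chain(60, "straight")
        occ = OccupancyState.empty(60)
        occ.occupied[[29, 30, 31]] = True
        kp = KineticParams(kappa_on=1.0, p_cis=1.0)
        before = occ.n_bound
        # bead 30's both neighbours occupied; 29/31 can still extend outward
        for _ in range(5):
            attempt_recruitment(state.positions, occ, kp, rng)
        cis_from_30 = [e for e in occ.event_log
                       if e[1] == "recruit_cis" and e[2] == 30]
        assert not cis_from_30

    def test_globule_trans_to_cis_ratio(self, rng):
        """With trans targets always available the success ratio ~ 11."""
        state = gen_test_chain(343, "globule")
        occ = OccupancyState.empty(343)
        center = 171
        kp = KineticParams(kappa_on=1.0)
        n_cis = n_trans = 0
        for _ in range(4000):
            occ.occupied[:] = False
            occ.occupied[center] = True
            occ.event_log.clear()
            attempt_recruitment(state.positions, occ, kp, rng)
            for e in occ.event_log:
                n_cis += e[1] == "recruit_cis"
                n_trans += e[1] == "recruit_trans"
        assert n_trans / max(n_cis, 1) == pytest.approx(11.0, rel=0.25)


class TestSweep:
    def test_all_rates_zero_identity(self, rng):
        state = gen_test_chain(30, "straight")
        occ = OccupancyState.empty(30)
        occ.occupied[15] = True
        kp = KineticParams(kappa_on=0.0, kappa_off=0.0, p_move=0.0)
        before = occ.occupied.copy()
        kinetic_sweep(state.positions, occ, kp, rng)
        assert np.array_equal(occ.occupied, before)
        assert len(occ.event_log) == 0

    def test_occupancy_bounded_and_logged(self, rng):
        """Exclusion and bookkeeping: <=1 ParB per bead and every n_bound
        change maps to a logged load/unload/recruit event."""
        state = gen_test_chain(64, "globule")
        occ = OccupancyState.empty(64)
        kp = KineticParams(kappa_on=0.5, kappa_off=0.05)
        prev = 0
        for sweep in range(400):
            n0 = len(occ.event_log)
            kinetic_sweep(state.positions, occ, kp, rng, sweep=sweep)
            assert occ.occupied.sum() <= 64
            delta = occ.n_bound - prev
            gains = sum(1 for e in occ.event_log[n0:]
                        if e[1] in ("load", "recruit_cis", "recruit_trans"))
            losses = sum(1 for e in occ.event_log[n0:] if e[1] == "unload")
            assert delta == gains - losses
            prev = occ.n_bound

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_diffusion_conserves_n_bound(self, seed):
        rng = np.random.default_rng(seed)
        occ = OccupancyState.empty(30)
        occ.occupied[rng.choice(30, size=8, replace=False)] = True
        attempt_diffusion(occ, KineticParams(), rng)
        assert occ.n_bound == 8
        assert np.all(occ.occupied.sum() == 8)

    def test_parS_only_birth_death_occupancy(self, rng):
        """Without recruitment/diffusion the parS site is a two-state
        birth-death process: occupancy p_on/(p_on + p_off)."""
        kp = KineticParams(kappa_on=0.02, kappa_off=0.01, p_move=0.0)
        state = gen_test_chain(21, "straight")
        occ = OccupancyState.empty(21)
        occupied_frac = 0
        n_sweeps = 30000
        for sweep in range(n_sweeps):
            attempt_unloading(occ, kp, rng)
            attempt_parS_loading(occ, kp, rng)
            occupied_frac += occ.occupied[occ.parS_index]
        expected = kp.kappa_on / (kp.kappa_on + kp.kappa_off)
        assert occupied_frac / n_sweeps == pytest.approx(expected, rel=0.05)
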