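"""Condensation drivers and summary analyses.

`run_condensation` couples the three layers: 500-step Langevin blocks
(polymer_core) alternate with kinetic sweeps (parb_kinetics) and a refresh of
the valence-capped bridge set (bridge_model), whose Morse forces act during
the next block.  On top sit the observables of the phase diagram: late-time
Rg^2 vs the bare chain, occupied-span fraction, three-class conformational
labels, occupancy-vs-kappa curves with a Hill fit, and simulated kymographs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .polymer_core import (ChainState, ForceField, UnitMap, equilibrate_chain,
                           gyration_radius_sq, run_steps)
from .parb_kinetics import KineticParams, OccupancyState, kinetic_sweep
from .bridge_model import BridgeParams, BridgeSet, update_bridges

__all__ = [
    "CondensationResult",
    "run_condensation",
    "bare_chain_rg2",
    "classify_conformation",
    "occupancy_vs_kappa",
    "HillFit",
    "hill_fit",
    "SimKymograph",
    "simulated_kymograph",
    "PhaseGrid",
    "run_phase_grid",
]


@dataclass
class CondensationResult:
    """Per-sweep observables plus occupancy/bridge snapshots of one run."""

    times_tauB: np.ndarray          # sweep index (1 sweep = 1 tau_B)
    rg2: np.ndarray
    n_bound: np.ndarray
    n_bridges: np.ndarray
    frame_times: np.ndarray
    occupancy_frames: np.ndarray    # (n_frames, n_beads) bool
    bridge_frames: list             # list of (k, 2) index arrays
    position_frames: list           # list of (n_beads, 3) arrays
    final_state: ChainState
    occ: OccupancyState
    seed: int
    n_beads: int

    def late_window(self, fraction: float = 1.0 / 3.0) -> slice:
        start = int(len(self.times_tauB) * (1.0 - fraction))
        return slice(start, None)

    @property
    def late_rg2(self) -> float:
        return float(np.mean(self.rg2[self.late_window()]))

    @property
    def late_n_bound(self) -> float:
        return float(np.mean(self.n_bound[self.late_window()]))

    def occupied_span_fraction(self, late_fraction: float = 1.0 / 3.0) -> float:
        """Mean fraction of the chain spanned by occupied beads, late window."""
        n_frames = len(self.frame_times)
        start = int(n_frames * (1.0 - late_fraction))
        spans = []
        for fr in self.occupancy_frames[start:]:
            idx = np.flatnonzero(fr)
            spans.append(0.0 if len(idx) == 0
                         else (idx[-1] - idx[0] + 1) / self.n_beads)
        return float(np.mean(spans)) if spans else 0.0

    def observables_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_tauB": self.times_tauB,
            "rg2": self.rg2,
            "n_bound": self.n_bound,
            "n_bridges": self.n_bridges,
        })


def run_condensation(n_beads: int, ff: ForceField, kp: KineticParams,
                     bp: BridgeParams, n_sweeps: int, seed: int,
                     dump_interval: int = 100,
                     initial_state: ChainState | None = None,
                     initial_occupancy: np.ndarray | None = None,
                     store_positions: bool = False,
                     um: UnitMap = UnitMap()) -> CondensationResult:
    """Full coupled run: fully reproducible from (parameters, seed).

    One sweep = one tau_B = `um.tauB_steps` integrator steps.  Occupancy and
    bridge snapshots (and optionally positions) are dumped every
    `dump_interval` sweeps.

    `initial_state` / `initial_occupancy` allow warm starts, e.g. on the
    condensed branch of the bistable transition (occupied compact chain), to
    measure stationary observables without waiting out the stochastic
    nucleation of condensation, which can take >1e5 tau_B near the critical
    kappa.
    """
    rng = np.random.default_rng(seed)
    state = initial_state.copy() if initial_state is not None \
        else equilibrate_chain(n_beads, ff, seed)
    occ = OccupancyState.empty(n_beads)
    bridges = BridgeSet(n_beads)
    if initial_occupancy is not None:
        occ.occupied[:] = np.asarray(initial_occupancy, dtype=bool)
        update_bridges(state.positions, occ, bridges, bp, rng)

    rg2 = np.empty(n_sweeps)
    nb = np.empty(n_sweeps, dtype=np.int64)
    nbr = np.empty(n_sweeps, dtype=np.int64)
    frame_times, occ_frames, bridge_frames, pos_frames = [], [], [], []

    for sweep in range(n_sweeps):
        bi, bj = bridges.pair_arrays()
        run_steps(state, ff, um.tauB_steps, int(rng.integers(2**31)),
                  bridge=(bp.D0, bp.alpha_morse, bp.rc_bridge, bi, bj))
        kinetic_sweep(state.positions, occ, kp, rng, sweep=sweep,
                      bridges=bridges)
        update_bridges(state.positions, occ, bridges, bp, rng)
        rg2[sweep] = gyration_radius_sq(state)
        nb[sweep] = occ.n_bound
        nbr[sweep] = len(bridges)
        if (sweep + 1) % dump_interval == 0:
            frame_times.append(sweep + 1)
            occ_frames.append(occ.occupied.copy())
            bi, bj = bridges.pair_arrays()
            bridge_frames.append(np.column_stack([bi, bj]))
            if store_positions:
                pos_frames.append(state.positions.copy())

    return CondensationResult(
        times_tauB=np.arange(1, n_sweeps + 1, dtype=float),
        rg2=rg2, n_bound=nb, n_bridges=nbr,
        frame_times=np.asarray(frame_times, dtype=float),
        occupancy_frames=np.asarray(occ_frames, dtype=bool).reshape(
            len(occ_frames), n_beads) if occ_frames
        else np.zeros((0, n_beads), dtype=bool),
        bridge_frames=bridge_frames, position_frames=pos_frames,
        final_state=state, occ=occ, seed=seed, n_beads=n_beads)


def condensed_start(n_beads: int, occupied_fraction: float = 1.0,
                    seed: int = 0):
    """Warm-start condition on the condensed branch: a compact (lattice-snake)
    conformation plus an occupancy block of `occupied_fraction` of the chain
    centred on parS.  Returns (ChainState, occupancy array)."""
    from .synthetic_data import gen_test_chain
    state = gen_test_chain(n_beads, "globule", seed=seed)
    occ = np.zeros(n_beads, dtype=bool)
    k = int(round(n_beads * occupied_fraction))
    lo = max(0, n_beads // 2 - k // 2)
    occ[lo:lo + k] = True
    return state, occ


def bare_chain_rg2(n_beads: int, ff: ForceField, seeds,
                   n_sweeps: int = 500,
                   um: UnitMap = UnitMap()) -> tuple[float, float]:
    """Mean and SD of equilibrium Rg^2 of the bare chain over replicas."""
    vals = []
    for seed in seeds:
        res = run_condensation(n_beads, ff, KineticParams(kappa_on=0.0),
                               BridgeParams(D0=0.0), n_sweeps, seed, um=um)
        vals.append(res.late_rg2)
    return float(np.mean(vals)), float(np.std(vals))


def classify_conformation(result: CondensationResult, bare_rg2: float,
                          theta_c: float = 0.5, theta_s: float = 0.5,
                          min_sweeps: int = 30) -> str:
    """Three-class label: collapsed / spread / localized.

    Collapsed if the late-window mean Rg^2 is below theta_c times the
    bare-chain mean; otherwise spread if occupied beads span more than
    theta_s of the chain; otherwise localized.  The late window is the final
    third of the run."""
    if len(result.times_tauB) < min_sweeps:
        raise ValueError("insufficient sampling window for classification")
    if result.late_rg2 < theta_c * bare_rg2:
        return "collapsed"
    if result.occupied_span_fraction() > theta_s:
        return "spread"
    return "localized"


def occupancy_vs_kappa(kappa_values, eps: float, n_beads: int,
                       replicas: int, n_sweeps: int, seed: int,
                       valency: int = 2, kappa_off: float = 0.001,
                       ff: ForceField = ForceField(),
                       um: UnitMap = UnitMap()) -> pd.DataFrame:
    """Steady-state time-averaged bound counts over a kappa sweep.

    kappa is swept by varying kappa_on at fixed kappa_off.  Returns a frame
    with columns kappa, n_bound_mean, n_bound_sd (replica scatter)."""
    kappa_values = np.asarray(sorted(kappa_values), dtype=float)
    if len(kappa_values) < 5:
        raise ValueError("need >= 5 kappa values spanning the transition")
    bp = BridgeParams(D0=eps, valency=valency)
    rows = []
    base = np.random.default_rng(seed).integers(2**20, size=(len(kappa_values),
                                                             replicas))
    for ki, kappa in enumerate(kappa_values):
        kp = KineticParams(kappa_on=kappa * kappa_off, kappa_off=kappa_off)
        means = []
        for r in range(replicas):
            res = run_condensation(n_beads, ff, kp, bp, n_sweeps,
                                   int(base[ki, r]), um=um)
            means.append(res.late_n_bound)
        rows.append({"kappa": kappa, "n_bound_mean": float(np.mean(means)),
                     "n_bound_sd": float(np.std(means))})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class HillFit:
    H: float
    K_half: float
    N_max: float
    H_stderr: float
    K_stderr: float
    N_stderr: float


def _hill(k, nmax, khalf, h):
    return nmax * k ** h / (khalf ** h + k ** h)


def hill_fit(kappa, n_bound) -> HillFit:
    """Least-squares fit of the Hill function N_max k^H / (K^H + k^H).

    Raises RuntimeError with the residuals if the fit does not converge."""
    k = np.asarray(kappa, dtype=float)
    n = np.asarray(n_bound, dtype=float)
    if len(k) < 5:
        raise ValueError("need >= 5 points bracketing the half-maximum")
    nmax0 = float(n.max())
    khalf0 = float(k[np.argmin(np.abs(n - 0.5 * nmax0))])
    try:
        popt, pcov = curve_fit(_hill, k, n, p0=[nmax0, max(khalf0, 1e-6), 2.0],
                               bounds=([0, 1e-9, 0.1], [np.inf, np.inf, 50.0]),
                               maxfev=20000)
    except RuntimeError as err:
        resid = n - _hill(k, nmax0, khalf0, 2.0)
        raise RuntimeError(f"Hill fit failed: {err}; residuals {resid}") from err
    perr = np.sqrt(np.diag(pcov))
    return HillFit(H=float(popt[2]), K_half=float(popt[1]), N_max=float(popt[0]),
                   H_stderr=float(perr[2]), K_stderr=float(perr[1]),
                   N_stderr=float(perr[0]))


@dataclass
class SimKymograph:
    """Bead-index x time binary occupancy matrix."""

    matrix: np.ndarray          # (n_beads or n_bins, n_frames), uint8
    frame_interval_tauB: float
    bin_beads: int = 1


def simulated_kymograph(occupancy_frames: np.ndarray,
                        frame_interval_tauB: float,
                        bin_beads: int = 1) -> SimKymograph:
    """Stack occupancy snapshots into a position x time matrix, optionally
    coarse-grained to `bin_beads`-bead genomic bins (bin value = any bead
    occupied)."""
    occ = np.asarray(occupancy_frames, dtype=bool)
    if occ.ndim != 2:
        raise ValueError("occupancy_frames must be (n_frames, n_beads)")
    mat = occ.T.astype(np.uint8)
    if bin_beads > 1:
        n_beads = mat.shape[0]
        n_bins = int(np.ceil(n_beads / bin_beads))
        pad = n_bins * bin_beads - n_beads
        padded = np.pad(mat, ((0, pad), (0, 0)))
        mat = padded.reshape(n_bins, bin_beads, -1).max(axis=1)
    return SimKymograph(matrix=mat, frame_interval_tauB=frame_interval_tauB,
                        bin_beads=bin_beads)


@dataclass
class PhaseGrid:
    """Classification and summary observables over an (eps, kappa) sweep."""

    eps_values: np.ndarray
    kappa_values: np.ndarray
    table: pd.DataFrame  # columns: eps, kappa, replica, rg2, n_bound, span, label


def run_phase_grid(eps_values, kappa_values, n_beads: int, replicas: int,
                   n_sweeps: int, seed: int, valency: int = 2,
                   kappa_off: float = 0.001, ff: ForceField = ForceField(),
                   theta_c: float = 0.5, theta_s: float = 0.5,
                   um: UnitMap = UnitMap()) -> PhaseGrid:
    """Sweep the (eps, kappa) grid with `replicas` seeds per cell and label
    each run localized/spread/collapsed against a bare-chain baseline."""
    bare_seeds = np.random.default_rng(seed).integers(2**20, size=3)
    bare, _ = bare_chain_rg2(n_beads, ff, bare_seeds,
                             n_sweeps=max(200, n_sweeps // 4), um=um)
    rows = []
    rng = np.random.default_rng(seed + 1)
    for eps in eps_values:
        bp = BridgeParams(D0=float(eps), valency=valency)
        for kappa in kappa_values:
            kp = KineticParams(kappa_on=float(kappa) * kappa_off,
                               kappa_off=kappa_off)
            for rep in range(replicas):
                res = run_condensation(n_beads, ff, kp, bp, n_sweeps,
                                       int(rng.integers(2**20)), um=um)
                rows.append({
                    "eps": float(eps), "kappa": float(kappa), "replica": rep,
                    "rg2": res.late_rg2, "n_bound": res.late_n_bound,
                    "span": res.occupied_span_fraction(),
                    "label": classify_conformation(res, bare, theta_c, theta_s),
                })
    return PhaseGrid(np.asarray(eps_values, dtype=float),
                     np.asarray(kappa_values, dtype=float),
                     pd.DataFrame(rows))
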