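"""Bead-spring DNA polymer: force field, Langevin integration, observables.

The DNA is a semiflexible chain of spherical beads (1 bead = 5.5 nm = 16 bp).
Beads repel through a purely repulsive (shifted/truncated) Lennard-Jones
potential, consecutive beads are bonded by FENE springs summed with the LJ
term, and chain stiffness enters through a cosine bending potential
U = k_theta (1 - cos theta) acting on consecutive bond pairs, giving a
persistence length of ~k_theta/k_BT beads.  Dynamics follow an NVT Langevin
heat bath integrated with velocity-Verlet at dt = 0.002 tau_MD; the Brownian
time tau_B = 500 dt is the clock tick of the kinetic ParB layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from . import _kernels

__all__ = [
    "ForceField",
    "UnitMap",
    "ChainState",
    "lj_energy",
    "fene_energy",
    "bend_energy",
    "total_potential_energy",
    "langevin_step",
    "run_steps",
    "init_wlc_chain",
    "equilibrate_chain",
    "sample_conformations",
    "gyration_radius_sq",
    "bond_correlation",
    "persistence_length",
]

_NO_BRIDGES = np.empty(0, dtype=np.int64)


@dataclass(frozen=True)
class ForceField:
    """Force-field and integrator constants in reduced units.

    sigma is the bead diameter (the simulation length unit, 5.5 nm = 16 bp),
    eps the LJ energy unit (1 k_BT).  rc_lj is pinned to 2^(1/6) sigma so the
    LJ term is purely repulsive (WCA).
    """

    sigma: float = 1.0
    eps: float = 1.0
    k_fene: float = 30.0       # eps / sigma^2
    R0: float = 1.5            # sigma; FENE divergence length
    k_theta: float = 10.0      # k_BT; bending stiffness
    kBT: float = 1.0
    gamma: float = 1.0         # Langevin damping
    mass: float = 1.0
    dt: float = 0.002          # tau_MD

    def __post_init__(self):
        for name in ("sigma", "eps", "k_fene", "R0", "kBT", "mass"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.k_theta < 0 or self.gamma < 0 or self.dt < 0:
            raise ValueError("k_theta, gamma and dt must be non-negative")
        if self.R0 <= self.sigma:
            raise ValueError("R0 must exceed sigma")

    @property
    def rc_lj(self) -> float:
        """LJ cutoff, exactly 2^(1/6) sigma."""
        return 2.0 ** (1.0 / 6.0) * self.sigma


@dataclass(frozen=True)
class UnitMap:
    """Mapping between reduced simulation units and physical units."""

    sigma_nm: float = 5.5
    bp_per_bead: int = 16
    tauB_steps: int = 500      # integrator steps per Brownian time
    tauB_us: float = 0.5
    eta_solvent_cP: float = 1.0

    @property
    def beads_per_um(self) -> int:
        return round(1000.0 / self.sigma_nm)

    def tauB_to_ms(self, n_tauB: float) -> float:
        return n_tauB * self.tauB_us * 1e-3

    def beads_to_kb(self, n_beads: float) -> float:
        return n_beads * self.bp_per_bead * 1e-3


@dataclass
class ChainState:
    """Bead positions/velocities (n_beads x 3, sigma units) plus the RNG seed
    the conformation originated from."""

    positions: np.ndarray
    velocities: np.ndarray
    rng_seed: int = 0

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (n_beads, 3)")
        if self.velocities.shape != self.positions.shape:
            raise ValueError("velocities must match positions shape")

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "ChainState":
        return ChainState(self.positions.copy(), self.velocities.copy(),
                          self.rng_seed)

    def bond_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.positions, axis=0), axis=1)


# ---------------------------------------------------------------- potentials

def lj_energy(r, ff: ForceField):
    """Shifted, truncated LJ: 4 eps [(s/r)^12 - (s/r)^6 + 1/4] for r <= rc, else 0."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("center distance must be positive")
    s6 = (ff.sigma / r) ** 6
    u = np.where(r <= ff.rc_lj, 4.0 * ff.eps * (s6 * s6 - s6 + 0.25), 0.0)
    return u if u.ndim else float(u)


def fene_energy(r, ff: ForceField):
    """FENE bond energy -0.5 k R0^2 ln(1 - (r/R0)^2); diverges at R0."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= ff.R0):
        raise ValueError("bond length must satisfy 0 <= r < R0")
    u = -0.5 * ff.k_fene * ff.R0 ** 2 * np.log1p(-((r / ff.R0) ** 2))
    return u if u.ndim else float(u)


def bend_energy(theta, ff: ForceField):
    """Bending energy k_theta (1 - cos theta); theta = 0 for collinear bonds."""
    theta = np.clip(np.asarray(theta, dtype=float), 0.0, np.pi)
    u = ff.k_theta * (1.0 - np.cos(theta))
    return u if u.ndim else float(u)


def total_potential_energy(state: ChainState, ff: ForceField,
                           bridge_pairs: np.ndarray | None = None,
                           morse_fn=None) -> float:
    """From-scratch potential (pure numpy, O(N^2)); the independent check for
    the kernel's force routing.

    Sums LJ over non-bonded pairs, FENE+LJ over bonds, bending over triplets
    and, if given, `morse_fn(r)` over the active bridge pairs.
    """
    pos = state.positions
    n = state.n_beads
    e = 0.0
    # bonds: FENE + LJ of the same pair
    b = state.bond_lengths()
    e += float(np.sum(fene_energy(b, ff)) + np.sum(lj_energy(b, ff)))
    # non-bonded LJ, excluding 1-2
    d = np.linalg.norm(pos[None, :, :] - pos[:, None, :], axis=-1)
    iu, ju = np.triu_indices(n, k=2)
    e += float(np.sum(lj_energy(np.maximum(d[iu, ju], 1e-12), ff)))
    # bending
    bonds = np.diff(pos, axis=0)
    u = bonds / np.linalg.norm(bonds, axis=1, keepdims=True)
    cos_t = np.clip(np.sum(u[:-1] * u[1:], axis=1), -1.0, 1.0)
    e += float(np.sum(ff.k_theta * (1.0 - cos_t)))
    if bridge_pairs is not None and len(bridge_pairs) and morse_fn is not None:
        bp = np.asarray(bridge_pairs, dtype=int)
        r = np.linalg.norm(pos[bp[:, 0]] - pos[bp[:, 1]], axis=1)
        e += float(np.sum(morse_fn(r)))
    return e


# --------------------------------------------------------------- integration

def _kernel_args(ff: ForceField, bridge=None):
    if bridge is None:
        return (0.0, 0.5, 2.0 * ff.sigma, _NO_BRIDGES, _NO_BRIDGES)
    d0, alpha, rc, bi, bj = bridge
    return (d0, alpha, rc,
            np.ascontiguousarray(bi, dtype=np.int64),
            np.ascontiguousarray(bj, dtype=np.int64))


def run_steps(state: ChainState, ff: ForceField, n_steps: int, seed: int,
              extra_forces: np.ndarray | None = None,
              bridge=None) -> ChainState:
    """Advance `n_steps` Langevin velocity-Verlet steps in place.

    `bridge`, if given, is a tuple (D0, alpha, rc_bridge, idx_i, idx_j) of
    active Morse pairs whose forces are recomputed every step.  Raises
    RuntimeError with the offending step index if the integration blows up
    (FENE bond reaching R0 or non-finite coordinates).
    """
    if extra_forces is None:
        ext = np.zeros_like(state.positions)
    else:
        ext = np.ascontiguousarray(extra_forces, dtype=np.float64)
        if ext.shape != state.positions.shape:
            raise ValueError("extra_forces must be (n_beads, 3)")
        if not np.all(np.isfinite(ext)):
            raise ValueError("extra_forces must be finite")
    d0, alpha, rc, bi, bj = _kernel_args(ff, bridge)
    status = _kernels.run_block(
        state.positions, state.velocities, n_steps, ff.dt, ff.gamma, ff.mass,
        ff.kBT, ff.sigma, ff.eps, ff.k_fene, ff.R0, ff.k_theta,
        d0, alpha, rc, bi, bj, ext, seed % 2**31)
    if status != 0:
        raise RuntimeError(
            f"integration blew up at step {status}: bond reached R0 or "
            "non-finite coordinates")
    return state


def langevin_step(state: ChainState, ff: ForceField,
                  extra_forces: np.ndarray | None = None,
                  seed: int = 0) -> ChainState:
    """Single dt velocity-Verlet Langevin step (deterministic given seed)."""
    if ff.dt == 0.0:
        return state
    return run_steps(state, ff, 1, seed, extra_forces=extra_forces)


# ------------------------------------------------------------ initialization

def init_wlc_chain(n_beads: int, ff: ForceField, seed: int,
                   bond_length: float | None = None,
                   min_dist: float = 0.8,
                   max_tries: int = 60) -> ChainState:
    """Self-avoiding discrete worm-like-chain conformation.

    Bond directions are drawn from the Boltzmann weight of the bending
    potential (exactly stationary local statistics), and a bead is resampled
    if it lands within `min_dist` sigma of any earlier bead.  This puts the
    chain close to conformational equilibrium immediately, which matters
    because relaxing a long stiff chain from a straight line would take
    >1e5 tau_B.  Velocities are Maxwell-Boltzmann at kBT.
    """
    if n_beads < 3:
        raise ValueError("need at least 3 beads")
    rng = np.random.default_rng(seed)
    b = bond_length if bond_length is not None else 0.965 * ff.sigma
    k = ff.k_theta / ff.kBT if ff.kBT > 0 else ff.k_theta
    pos = np.zeros((n_beads, 3))
    u = np.array([1.0, 0.0, 0.0])
    pos[1] = pos[0] + b * u
    for i in range(2, n_beads):
        placed = False
        for _ in range(max_tries):
            if k > 1e-9:
                # cos(theta) ~ exp(k cos) on [-1, 1]
                v = rng.random()
                c = 1.0 + np.log(v + (1.0 - v) * np.exp(-2.0 * k)) / k
            else:
                c = rng.uniform(-1.0, 1.0)
            s = np.sqrt(max(0.0, 1.0 - c * c))
            phi = rng.uniform(0.0, 2.0 * np.pi)
            # orthonormal frame around current direction u
            a = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
            e1 = np.cross(u, a)
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(u, e1)
            new_u = c * u + s * (np.cos(phi) * e1 + np.sin(phi) * e2)
            new_u /= np.linalg.norm(new_u)
            cand = pos[i - 1] + b * new_u
            d2 = np.sum((pos[: i - 1] - cand) ** 2, axis=1)
            if d2.min() > (min_dist * ff.sigma) ** 2:
                pos[i] = cand
                u = new_u
                placed = True
                break
        if not placed:
            # dead end: back off a few beads and retry
            i0 = max(2, i - 5)
            return init_wlc_chain(n_beads, ff,
                                  seed=int(rng.integers(2**31)), bond_length=b,
                                  min_dist=min_dist, max_tries=max_tries)
    vel = rng.normal(0.0, np.sqrt(ff.kBT / ff.mass), size=(n_beads, 3))
    return ChainState(pos, vel, rng_seed=seed)


def equilibrate_chain(n_beads: int, ff: ForceField, seed: int,
                      window_tauB: int = 200, rel_tol: float = 0.02,
                      max_windows: int = 25,
                      um: UnitMap = UnitMap()) -> ChainState:
    """Equilibrate until the windowed mean Rg^2 is stationary.

    Runs `window_tauB`-long Langevin blocks from a WLC-sampled start and stops
    when consecutive window means of Rg^2 agree to `rel_tol` (with at least
    two windows run).  Raises RuntimeError on non-convergence.
    """
    state = init_wlc_chain(n_beads, ff, seed)
    if n_beads == 3:
        return state
    rng = np.random.default_rng(seed + 7)
    steps = window_tauB * um.tauB_steps
    prev = None
    for _ in range(max_windows):
        vals = []
        n_sub = 10
        for _ in range(n_sub):
            run_steps(state, ff, steps // n_sub, int(rng.integers(2**31)))
            vals.append(gyration_radius_sq(state))
        mean_rg2 = float(np.mean(vals))
        # converged when consecutive window means agree within rel_tol or
        # within the window's own sampling noise (single-chain Rg^2
        # fluctuations are large for short chains)
        sem = float(np.std(vals)) / np.sqrt(n_sub)
        if prev is not None and abs(mean_rg2 - prev) < max(rel_tol * prev,
                                                           2.0 * sem):
            return state
        prev = mean_rg2
    raise RuntimeError(
        f"Rg^2 not stationary to {rel_tol:.0%} within "
        f"{max_windows * window_tauB} tau_B")


def sample_conformations(state: ChainState, ff: ForceField, n_frames: int,
                         interval_tauB: int, seed: int,
                         um: UnitMap = UnitMap()) -> list[np.ndarray]:
    """Production sampling: positions snapshot every `interval_tauB`."""
    rng = np.random.default_rng(seed)
    frames = []
    for _ in range(n_frames):
        run_steps(state, ff, interval_tauB * um.tauB_steps,
                  int(rng.integers(2**31)))
        frames.append(state.positions.copy())
    return frames


# ---------------------------------------------------------------- observables

def gyration_radius_sq(state_or_positions) -> float:
    """Mean squared bead distance from the chain centroid (sigma^2)."""
    pos = getattr(state_or_positions, "positions", state_or_positions)
    pos = np.asarray(pos, dtype=float)
    com = pos.mean(axis=0)
    return float(np.mean(np.sum((pos - com) ** 2, axis=1)))


def bond_correlation(frames: Sequence[np.ndarray], n_max: int = 30) -> np.ndarray:
    """Ensemble-averaged bond-vector correlation <u_i . u_{i+n}>, n = 1..n_max."""
    acc = np.zeros(n_max)
    cnt = np.zeros(n_max)
    for pos in frames:
        pos = getattr(pos, "positions", pos)
        bonds = np.diff(np.asarray(pos, dtype=float), axis=0)
        u = bonds / np.linalg.norm(bonds, axis=1, keepdims=True)
        nb = len(u)
        for n in range(1, min(n_max, nb - 1) + 1):
            acc[n - 1] += np.sum(u[:-n] * u[n:]) / (nb - n)
            cnt[n - 1] += 1.0
    if np.any(cnt == 0):
        raise ValueError("frames too short for requested n_max")
    return acc / cnt


def persistence_length(trajectory: Sequence, n_max: int = 30) -> float:
    """Persistence length (beads) from exp(-n/l_p) fit of bond correlations.

    Requires decorrelated frames; raises if the correlations do not decay
    appreciably over n_max separations (rod limit, out of fit range).
    """
    frames = [getattr(s, "positions", s) for s in trajectory]
    if len(frames) < 10:
        raise ValueError("need at least 10 decorrelated frames")
    corr = bond_correlation(frames, n_max=n_max)
    if corr[-1] > 0.8:
        raise ValueError("correlations do not decay: rod limit, out of fit range")
    n = np.arange(1, n_max + 1, dtype=float)
    # positive correlations only (log-fit would fail on noise about zero)
    mask = corr > 0.02
    p0 = [max(1.0, -1.0 / np.log(max(min(corr[0], 0.999), 1e-3)))]
    popt, _ = curve_fit(lambda x, lp: np.exp(-x / lp), n[mask], corr[mask],
                        p0=p0, maxfev=10000)
    return float(popt[0])
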