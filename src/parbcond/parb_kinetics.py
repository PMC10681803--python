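"""Implicit-ParB stochastic layer: loading, unloading, 1D sliding, recruitment.

ParB is not a 3D particle here: it is a per-bead occupancy flag on the DNA
lattice.  Once per Brownian time tau_B (i.e. between 500-step Langevin blocks)
a kinetic sweep applies, in fixed order: unloading -> 1D diffusion -> loading
at parS -> cis/trans recruitment.  Rates are quoted per tau_B and converted to
per-sweep probabilities as p = min(rate, 1).

Hard-core exclusion holds throughout: at most one ParB per bead, moves onto an
occupied bead or beyond a chain end are rejected, and loading at an occupied
parS is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KineticParams",
    "OccupancyState",
    "attempt_parS_loading",
    "attempt_unloading",
    "attempt_diffusion",
    "trans_neighbor_list",
    "attempt_recruitment",
    "kinetic_sweep",
]


@dataclass(frozen=True)
class KineticParams:
    """Per-tau_B rates and geometric rules of the ParB layer.

    kappa_on is the loading/recruitment attempt rate (the concentration
    proxy); kappa_off the unloading rate (0.001/tau_B, i.e. a residence
    timescale of 1000 tau_B = 0.5 ms in mapped units).  p_move = 0.125 per
    direction encodes the 1D diffusion constant D = 0.125 sigma^2/tau_B
    (MSD = 2 D t).  Recruitment is in-cis with probability p_cis = 0.083 and
    otherwise in-trans, to unoccupied beads within recruit_cutoff = 2 sigma
    that are at least min_1d_separation = 3 beads away along the chain.
    """

    kappa_on: float = 0.0
    kappa_off: float = 0.001
    p_move: float = 0.125
    p_cis: float = 0.083
    recruit_cutoff: float = 2.0
    min_1d_separation: int = 3

    def __post_init__(self):
        if self.kappa_on < 0 or self.kappa_off < 0:
            raise ValueError("rates must be non-negative")
        if not 0 <= self.p_cis <= 1:
            raise ValueError("p_cis must lie in [0, 1]")
        if 2 * self.p_move > 1:
            raise ValueError("2*p_move must not exceed 1")

    @property
    def p_trans(self) -> float:
        return 1.0 - self.p_cis

    @property
    def kappa_ratio(self) -> float:
        if self.kappa_off == 0:
            raise ZeroDivisionError("kappa_off is zero")
        return self.kappa_on / self.kappa_off

    @property
    def mean_residence_tauB(self) -> float:
        return 1.0 / self.kappa_off


@dataclass
class OccupancyState:
    """Per-bead ParB occupancy with event bookkeeping.

    parS sits at the chain midpoint (floor(n/2)).  Every change of occupancy
    goes through a logged event: (sweep, kind, bead_from, bead_to) with kind
    in {load, unload, hop, recruit_cis, recruit_trans}.
    """

    occupied: np.ndarray
    parS_index: int
    event_log: list = field(default_factory=list)

    @classmethod
    def empty(cls, n_beads: int) -> "OccupancyState":
        return cls(np.zeros(n_beads, dtype=bool), n_beads // 2)

    @property
    def n_beads(self) -> int:
        return len(self.occupied)

    @property
    def n_bound(self) -> int:
        return int(np.count_nonzero(self.occupied))

    def bound_beads(self) -> np.ndarray:
        return np.flatnonzero(self.occupied)

    def log(self, sweep, kind, b_from, b_to):
        self.event_log.append((sweep, kind, b_from, b_to))


def _p(rate: float) -> float:
    return min(rate, 1.0)


def attempt_parS_loading(occ: OccupancyState, kp: KineticParams,
                         rng: np.random.Generator,
                         sweep: int = 0) -> OccupancyState:
    """Load one ParB at parS with probability min(kappa_on, 1) per sweep.

    The attempt is rejected if parS is already occupied (exclusion extends to
    the loading site)."""
    if kp.kappa_on > 0 and rng.random() < _p(kp.kappa_on):
        if not occ.occupied[occ.parS_index]:
            occ.occupied[occ.parS_index] = True
            occ.log(sweep, "load", -1, occ.parS_index)
    return occ


def attempt_unloading(occ: OccupancyState, kp: KineticParams,
                      rng: np.random.Generator, sweep: int = 0,
                      bridges=None) -> OccupancyState:
    """Remove each loaded ParB independently with probability kappa_off.

    Unloading a bead also deletes every bridge anchored at it (the energy term
    only exists between occupied beads)."""
    bound = occ.bound_beads()
    if len(bound) == 0 or kp.kappa_off == 0:
        return occ
    gone = bound[rng.random(len(bound)) < _p(kp.kappa_off)]
    for b in gone:
        occ.occupied[b] = False
        occ.log(sweep, "unload", int(b), -1)
        if bridges is not None:
            bridges.drop_bead(int(b))
    return occ


def attempt_diffusion(occ: OccupancyState, kp: KineticParams,
                      rng: np.random.Generator, sweep: int = 0,
                      positions: np.ndarray | None = None,
                      bridges=None) -> OccupancyState:
    """One sliding attempt per loaded ParB, in random order.

    Each ParB hops left/right/stays with probabilities p_move/p_move/rest.
    Moves onto an occupied bead or beyond a chain end are rejected; n_bound is
    conserved.  A bridged ParB that hops drags its bridge anchors along if the
    partner is still within the interaction cutoff, otherwise that bridge is
    dropped.
    """
    bound = occ.bound_beads()
    if len(bound) == 0 or kp.p_move == 0:
        return occ
    draws = rng.random(len(bound))
    movers = np.flatnonzero(draws < 2 * kp.p_move)
    if len(movers) == 0:
        return occ
    order = movers[rng.permutation(len(movers))]
    n = occ.n_beads
    for idx in order:
        b = int(bound[idx])
        tgt = b - 1 if draws[idx] < kp.p_move else b + 1
        if tgt < 0 or tgt >= n or occ.occupied[tgt]:
            continue
        occ.occupied[b] = False
        occ.occupied[tgt] = True
        occ.log(sweep, "hop", b, tgt)
        if bridges is not None and bridges.per_bead_count[b] > 0:
            bridges.move_anchor(b, tgt, positions, kp.recruit_cutoff)
    return occ


def trans_neighbor_list(positions: np.ndarray, occ: OccupancyState,
                        bead: int, kp: KineticParams) -> np.ndarray:
    """Unoccupied beads within the Euclidean cutoff (2 sigma) of `bead` that
    are at least min_1d_separation (3) beads away along the chain."""
    if not occ.occupied[bead]:
        raise ValueError("query bead is not loaded")
    pos = np.asarray(positions, dtype=float)
    d2 = np.sum((pos - pos[bead]) ** 2, axis=1)
    idx = np.arange(len(pos))
    mask = (~occ.occupied) \
        & (d2 <= kp.recruit_cutoff ** 2) \
        & (np.abs(idx - bead) >= kp.min_1d_separation)
    return np.flatnonzero(mask)


def attempt_recruitment(positions: np.ndarray, occ: OccupancyState,
                        kp: KineticParams, rng: np.random.Generator,
                        sweep: int = 0) -> OccupancyState:
    """Each loaded ParB attempts recruitment with probability min(kappa_on, 1).

    A successful attempt picks the cis branch with probability p_cis (one of
    the two 1D-adjacent beads, uniformly; loads if unoccupied and in range)
    and otherwise the trans branch (uniform choice from the trans neighbour
    list; empty list means the attempt fails).  ParBs recruited this sweep do
    not themselves recruit until the next sweep.
    """
    bound = occ.bound_beads()  # snapshot: recruits act from the next sweep
    if len(bound) == 0 or kp.kappa_on == 0:
        return occ
    p = _p(kp.kappa_on)
    attempt = rng.random(len(bound)) < p
    if not np.any(attempt):
        return occ
    n = occ.n_beads
    for b in bound[attempt]:
        b = int(b)
        if rng.random() < kp.p_cis:
            tgt = b + (1 if rng.random() < 0.5 else -1)
            if 0 <= tgt < n and not occ.occupied[tgt]:
                occ.occupied[tgt] = True
                occ.log(sweep, "recruit_cis", b, tgt)
        else:
            cands = trans_neighbor_list(positions, occ, b, kp)
            if len(cands):
                tgt = int(cands[rng.integers(len(cands))])
                occ.occupied[tgt] = True
                occ.log(sweep, "recruit_trans", b, tgt)
    return occ


def kinetic_sweep(positions: np.ndarray, occ: OccupancyState,
                  kp: KineticParams, rng: np.random.Generator,
                  sweep: int = 0, bridges=None) -> OccupancyState:
    """One tau_B worth of kinetics in fixed order:
    unload -> diffuse -> parS load -> recruit.

    `positions` may be a ChainState or an (n, 3) array.  The ordering is a
    convention (rates are all << 1 per sweep, so ordering effects are
    O(rate^2)); it is fixed for reproducible random streams.
    """
    pos = getattr(positions, "positions", positions)
    attempt_unloading(occ, kp, rng, sweep, bridges=bridges)
    attempt_diffusion(occ, kp, rng, sweep, positions=pos, bridges=bridges)
    attempt_parS_loading(occ, kp, rng, sweep)
    attempt_recruitment(pos, occ, kp, rng, sweep)
    return occ
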