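"""Valence-controlled ParB-ParB bridging via a Morse potential.

Occupied beads within rc = 2 sigma of each other may form an attractive
bridge, U(r) = D0 (exp(-2 a r) - 2 exp(-a r)) with a = 0.5/sigma, cut at rc.
The per-bead number of simultaneous bridges is capped by the valency:
1 reproduces the dimer-of-dimers (DoD) mode where each ParB forms at most one
one-to-one bridge, 2 the multimer-of-dimers (MoD) mode where chains of
bridges (oligomers) can percolate and collapse the DNA.

The reference implementation is valence-capped isotropic bonding between bead
centers with explicit bookkeeping of the active pair set; the controlled
quantity is the valency, not the (unspecified) patch geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["BridgeParams", "BridgeSet", "morse_energy", "update_bridges",
           "bridge_forces"]


@dataclass(frozen=True)
class BridgeParams:
    """Morse well depth D0 (the interaction strength eps of the phase
    diagram, in k_BT), range alpha = 0.5/sigma, cutoff 2 sigma, and valency
    (1 = DoD, 2 = MoD).  Bridging between 1D first/second neighbours is
    excluded, mirroring the trans-recruitment rule."""

    D0: float = 10.0
    alpha_morse: float = 0.5
    rc_bridge: float = 2.0
    valency: int = 2
    min_1d_separation: int = 3

    def __post_init__(self):
        if self.valency not in (1, 2):
            raise ValueError("valency must be 1 (DoD) or 2 (MoD)")
        if self.D0 < 0:
            raise ValueError("D0 must be non-negative")


@dataclass
class BridgeSet:
    """Active bridge pairs with per-bead partner counts."""

    n_beads: int
    active_pairs: set = field(default_factory=set)
    per_bead_count: np.ndarray = None

    def __post_init__(self):
        if self.per_bead_count is None:
            self.per_bead_count = np.zeros(self.n_beads, dtype=np.int64)
        self._partners = {}  # bead -> set of partner beads

    def __len__(self):
        return len(self.active_pairs)

    def partners_of(self, b: int):
        return self._partners.get(b, ())

    def add(self, i: int, j: int):
        pair = (min(i, j), max(i, j))
        if pair not in self.active_pairs:
            self.active_pairs.add(pair)
            self.per_bead_count[pair[0]] += 1
            self.per_bead_count[pair[1]] += 1
            self._partners.setdefault(i, set()).add(j)
            self._partners.setdefault(j, set()).add(i)

    def remove(self, i: int, j: int):
        pair = (min(i, j), max(i, j))
        if pair in self.active_pairs:
            self.active_pairs.discard(pair)
            self.per_bead_count[pair[0]] -= 1
            self.per_bead_count[pair[1]] -= 1
            self._partners[i].discard(j)
            self._partners[j].discard(i)

    def drop_bead(self, b: int):
        """Delete every bridge anchored at bead b (e.g. after unloading)."""
        for partner in list(self.partners_of(b)):
            self.remove(b, partner)

    def move_anchor(self, b_from: int, b_to: int,
                    positions: np.ndarray | None, cutoff: float):
        """Re-anchor bridges of a ParB that hopped from b_from to b_to.

        Each bridge follows the protein only if the partner remains within
        `cutoff`; otherwise it is dropped (keeps the pair list consistent with
        the energy term)."""
        for partner in list(self.partners_of(b_from)):
            self.remove(b_from, partner)
            if positions is None:
                continue
            r = float(np.linalg.norm(positions[partner] - positions[b_to]))
            if r <= cutoff and abs(partner - b_to) >= 1:
                self.add(partner, b_to)

    def pair_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        if not self.active_pairs:
            e = np.empty(0, dtype=np.int64)
            return e, e
        arr = np.array(sorted(self.active_pairs), dtype=np.int64)
        return np.ascontiguousarray(arr[:, 0]), np.ascontiguousarray(arr[:, 1])

    def validate(self):
        """Raise if per-bead counts disagree with the active pair set (a
        contract violation by the caller)."""
        counts = np.zeros(self.n_beads, dtype=np.int64)
        for i, j in self.active_pairs:
            counts[i] += 1
            counts[j] += 1
        if not np.array_equal(counts, self.per_bead_count):
            raise ValueError("per_bead_count inconsistent with active_pairs")


def morse_energy(r, bp: BridgeParams):
    """U(r) = D0 (e^(-2 a r) - 2 e^(-a r)) for r < rc, else 0."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance must be non-negative")
    ea = np.exp(-bp.alpha_morse * r)
    u = np.where(r < bp.rc_bridge, bp.D0 * (ea * ea - 2.0 * ea), 0.0)
    return u if u.ndim else float(u)


def update_bridges(positions: np.ndarray, occ, bridges: BridgeSet,
                   bp: BridgeParams, rng: np.random.Generator) -> BridgeSet:
    """Refresh the active bridge set for the current conformation/occupancy.

    Drops pairs separated beyond rc_bridge or whose ParB unloaded, then
    activates new eligible pairs (both occupied, r < rc, 1D separation >= 3)
    subject to the per-bead valency cap.  When more candidates compete than
    the cap allows, candidates are scanned in random order (no positional
    bias).  Raises ValueError if the incoming bridge bookkeeping is
    inconsistent (bridge on an unoccupied bead with stale counts).
    """
    pos = getattr(positions, "positions", positions)
    occupied = getattr(occ, "occupied", occ)
    bridges.validate()

    if bridges.active_pairs:
        arr = np.array(list(bridges.active_pairs), dtype=np.int64)
        r = np.linalg.norm(pos[arr[:, 0]] - pos[arr[:, 1]], axis=1)
        stale = (r >= bp.rc_bridge) | ~(occupied[arr[:, 0]]
                                        & occupied[arr[:, 1]])
        for i, j in arr[stale]:
            bridges.remove(int(i), int(j))

    bound = np.flatnonzero(occupied)
    if len(bound) < 2:
        return bridges
    tree = cKDTree(pos[bound])
    pairs = tree.query_pairs(bp.rc_bridge, output_type="ndarray")
    if len(pairs) == 0:
        return bridges
    ii = bound[pairs[:, 0]]
    jj = bound[pairs[:, 1]]
    counts = bridges.per_bead_count
    keep = (np.abs(ii - jj) >= bp.min_1d_separation) \
        & (counts[ii] < bp.valency) & (counts[jj] < bp.valency)
    ii, jj = ii[keep], jj[keep]
    cand = [(min(a, b), max(a, b)) for a, b in zip(ii.tolist(), jj.tolist())
            if (min(a, b), max(a, b)) not in bridges.active_pairs]
    if not cand:
        return bridges
    order = rng.permutation(len(cand))
    for k in order:
        i, j = cand[k]
        if counts[i] < bp.valency and counts[j] < bp.valency:
            bridges.add(i, j)
    return bridges


def bridge_forces(positions: np.ndarray, bridges: BridgeSet,
                  bp: BridgeParams) -> np.ndarray:
    """Equal-and-opposite Morse pair forces over the active set (N x 3)."""
    pos = getattr(positions, "positions", positions)
    f = np.zeros_like(pos, dtype=float)
    a = bp.alpha_morse
    for i, j in bridges.active_pairs:
        d = pos[i] - pos[j]
        r = float(np.linalg.norm(d))
        if r >= bp.rc_bridge or r < 1e-12:
            continue
        ea = np.exp(-a * r)
        fmag = 2.0 * a * bp.D0 * (ea * ea - ea) / r  # -dU/dr / r
        f[i] += fmag * d
        f[j] -= fmag * d
    return f
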