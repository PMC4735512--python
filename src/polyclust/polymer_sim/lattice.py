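"""Self-avoiding lattice polymer and its Monte-Carlo move set.

The chromatin fibre is a string of ``n_nodes`` beads on the simple cubic
lattice with unit bonds, evolved by pivot moves (rotate/reflect one chain arm
about a pivot bead through one of the 47 non-identity octahedral symmetries)
with single-bead local displacements as a fallback when a pivot is
geometrically rejected.  Local moves follow a relaxed-bond dialect of the
bond-fluctuation scheme: a displaced bead keeps its bonds within length
{1, sqrt(2)}.  Excluded volume is exact site exclusion: no two beads may
occupy the same lattice site.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LatticePolymer",
    "MoveProposal",
    "OCTAHEDRAL_SYMMETRIES",
    "NONIDENTITY_SYMMETRIES",
    "init_polymer",
    "assign_affinities",
    "propose_pivot",
    "propose_local_move",
    "has_self_collision",
    "chain_is_connected",
]

# Allowed squared bond lengths after local moves (unit bonds relaxed to sqrt(2)).
ALLOWED_BOND_SQ = (1, 2)

# Unit displacements on the cubic lattice.
UNIT_STEPS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=np.int64,
)


def _octahedral_matrices() -> np.ndarray:
    mats = []
    for perm in itertools.permutations(range(3)):
        for signs in itertools.product((1, -1), repeat=3):
            m = np.zeros((3, 3), dtype=np.int64)
            for row, (col, s) in enumerate(zip(perm, signs)):
                m[row, col] = s
            mats.append(m)
    return np.stack(mats)


OCTAHEDRAL_SYMMETRIES = _octahedral_matrices()
_identity_idx = int(
    np.flatnonzero((OCTAHEDRAL_SYMMETRIES == np.eye(3, dtype=np.int64)).all(axis=(1, 2)))[0]
)
NONIDENTITY_SYMMETRIES = np.delete(OCTAHEDRAL_SYMMETRIES, _identity_idx, axis=0)
assert len(NONIDENTITY_SYMMETRIES) == 47


@dataclass
class LatticePolymer:
    """Ordered integer 3D coordinates of the chromatin beads."""

    coords: np.ndarray  # (n_nodes, 3) int64

    @property
    def n_nodes(self) -> int:
        return int(self.coords.shape[0])

    def copy(self) -> "LatticePolymer":
        return LatticePolymer(self.coords.copy())


@dataclass
class MoveProposal:
    """A candidate polymer update.

    ``valid`` is False when the proposed coordinates would collide with the
    unmoved part of the chain (or, for local moves, violate the allowed bond
    lengths).  ``moved`` marks which beads change position.
    """

    kind: str  # "pivot" | "local"
    new_coords: np.ndarray
    moved: np.ndarray  # boolean mask over beads
    valid: bool
    pivot_index: int | None = None
    symmetry: np.ndarray | None = field(default=None, repr=False)
    node_index: int | None = None


def _encode(coords: np.ndarray) -> np.ndarray:
    """Pack 3D integer sites into scalar keys for fast collision checks."""
    c = coords.astype(np.int64)
    # Coordinates stay within +-2*n of the origin for any chain history we
    # generate; 2**20 offset keeps packing collision-free far beyond that.
    off = 1 << 20
    return ((c[:, 0] + off) << 42) | ((c[:, 1] + off) << 21) | (c[:, 2] + off)


def has_self_collision(coords: np.ndarray) -> bool:
    keys = _encode(coords)
    return len(np.unique(keys)) != len(keys)


def chain_is_connected(coords: np.ndarray, allowed_sq=ALLOWED_BOND_SQ) -> bool:
    if len(coords) < 2:
        return True
    d = np.diff(coords, axis=0)
    sq = (d * d).sum(axis=1)
    return bool(np.isin(sq, allowed_sq).all())


def assign_affinities(n_nodes: int, seed: int) -> np.ndarray:
    """Per-bead binding affinities A_node, i.i.d. uniform on [0, 1].

    Affinities model the observation that genomic sites differ in their
    intrinsic strength as Polycomb recruitment sites; they are drawn once at
    initialization and never mutated during a run.
    """
    if n_nodes < 1:
        raise ValueError(f"n_nodes must be >= 1, got {n_nodes}")
    rng = np.random.default_rng(seed)
    return rng.uniform(0.0, 1.0, size=n_nodes)


def propose_pivot(
    polymer: LatticePolymer, rng: np.random.Generator | int
) -> MoveProposal:
    """Propose a pivot move: apply a random non-identity octahedral symmetry
    to the chain tail beyond a uniformly chosen pivot bead.

    Bond lengths are preserved exactly (lattice symmetries are isometries),
    so the only way a proposal can fail is a site collision between the moved
    arm and the fixed arm; such proposals are returned with ``valid=False``.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    coords = polymer.coords
    n = len(coords)
    if n < 2:
        return MoveProposal("pivot", coords.copy(), np.zeros(n, bool), True, 0,
                            OCTAHEDRAL_SYMMETRIES[_identity_idx])
    p = int(rng.integers(0, n - 1))  # pivot bead; tail p+1..n-1 moves
    sym = NONIDENTITY_SYMMETRIES[int(rng.integers(0, 47))]
    return _apply_pivot(coords, p, sym)


def _apply_pivot(coords: np.ndarray, pivot_index: int, sym: np.ndarray) -> MoveProposal:
    n = len(coords)
    origin = coords[pivot_index]
    tail = coords[pivot_index + 1:]
    new_tail = (tail - origin) @ sym.T + origin
    new_coords = coords.copy()
    new_coords[pivot_index + 1:] = new_tail
    moved = np.zeros(n, dtype=bool)
    moved[pivot_index + 1:] = (new_tail != tail).any(axis=1)
    # The moved arm cannot self-collide (isometry of a collision-free arm),
    # so a whole-chain uniqueness check is sufficient and fast.
    keys = _encode(new_coords)
    keys.sort()
    valid = bool((np.diff(keys) != 0).all()) if n > 1 else True
    return MoveProposal("pivot", new_coords, moved, bool(valid),
                        pivot_index=pivot_index, symmetry=sym)


def propose_local_move(
    polymer: LatticePolymer, node_index: int, rng: np.random.Generator | int
) -> MoveProposal:
    """Propose a one-lattice-unit displacement of a single bead.

    The proposal is valid only if both bonds to chain neighbours stay within
    the allowed length set {1, sqrt(2)} and the target site is unoccupied.
    """
    coords = polymer.coords
    n = len(coords)
    if not 0 <= node_index < n:
        raise IndexError(f"node_index {node_index} out of range for {n} beads")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    step = UNIT_STEPS[int(rng.integers(0, 6))]
    return _apply_local(coords, node_index, step)


def _apply_local(coords: np.ndarray, node_index: int, step: np.ndarray) -> MoveProposal:
    n = len(coords)
    new_pos = coords[node_index] + step
    valid = True
    for nb in (node_index - 1, node_index + 1):
        if 0 <= nb < n:
            sq = int(((new_pos - coords[nb]) ** 2).sum())
            if sq not in ALLOWED_BOND_SQ:
                valid = False
    if valid:
        others = np.delete(coords, node_index, axis=0)
        valid = not (others == new_pos).all(axis=1).any()
    new_coords = coords.copy()
    new_coords[node_index] = new_pos
    moved = np.zeros(n, dtype=bool)
    moved[node_index] = True
    return MoveProposal("local", new_coords, moved, bool(valid), node_index=node_index)


def init_polymer(n_nodes: int, seed: int, burn_in_factor: int = 3) -> LatticePolymer:
    """Build a self-avoiding starting configuration.

    The chain starts as a straight rod along x (trivially self-avoiding and
    connected) and is equilibrated by ``burn_in_factor * n_nodes`` accepted
    pivot moves; the pivot algorithm decorrelates global observables within
    a handful of accepted moves, so a few moves per bead is ample.
    """
    if n_nodes < 1:
        raise ValueError(f"n_nodes must be >= 1, got {n_nodes}")
    coords = np.zeros((n_nodes, 3), dtype=np.int64)
    coords[:, 0] = np.arange(n_nodes)
    polymer = LatticePolymer(coords)
    if n_nodes < 3:
        return polymer
    rng = np.random.default_rng(seed)
    target = burn_in_factor * n_nodes
    accepted = 0
    while accepted < target:
        prop = propose_pivot(polymer, rng)
        if prop.valid:
            polymer.coords = prop.new_coords
            accepted += 1
    return polymer
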