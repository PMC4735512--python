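"""Binder kinetics on the lattice polymer: spreading, bridging and capping.

Diffusing Polyhomeotic (Ph) molecules are a well-mixed reservoir.  Each bead
of the polymer is a genomic site with a fixed affinity A in [0, 1].  Binders
associate to a site by mass action -- every bound molecule whose SAM surface
is free presents one additional independent surface for association, so a
site with k free-surface residents makes ``k + 1`` association attempts per
step, each succeeding with probability ``k_a * A * f`` where ``f`` is the
free-pool fraction (wild-type variants share one pool across endogenous and
exogenous Ph; mutant variants keep per-species pools).  Bound molecules
dissociate independently with probability ``k_d``.
Occupancy at one site is capped at ``n_max`` copies (spreading limit) unless
the model variant lifts the cap.

Each Ph-type binder carries one bridging surface.  Binders with a free
surface sitting at distinct beads within ``neighbor_radius`` in 3D may form a
bond (probability ``k_join``); existing bonds break with probability
``k_break``, when either partner dissociates, or when a polymer move pulls
the two beads farther apart than the radius.  Breaking bonds by a polymer
move costs ``E_bond`` per bond and is filtered by the Metropolis rule.

Model variants map the Ph SAM perturbations:

* ``baseline`` / ``wt_limited``  -- exogenous binder is wild-type Ph,
  spreading capped at ``n_max``.
* ``wt_unlimited``               -- wild-type Ph, no spreading cap.
* ``weak_binding_ML``            -- exogenous binder is Ph-ML modelled as a
  weak binder (k_d 10x endogenous unless overridden), otherwise Ph-like.
* ``capping_ML``                 -- exogenous Ph-ML carries no bridging
  surface and, on joining a cluster, removes one interaction surface from a
  resident wild-type Ph; a cluster whose wild-type members are all capped
  accepts no further members of either type.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .lattice import (
    LatticePolymer,
    MoveProposal,
    assign_affinities,
    init_polymer,
    propose_local_move,
    propose_pivot,
)

__all__ = [
    "SimParams",
    "SimState",
    "MODEL_VARIANTS",
    "init_state",
    "metropolis_accept",
    "move_energy_delta",
    "polymer_step",
    "binding_step",
    "bridging_step",
    "cluster_census",
    "binder_components",
    "bound_counts",
]

MODEL_VARIANTS = (
    "baseline",
    "weak_binding_ML",
    "capping_ML",
    "wt_unlimited",
    "wt_limited",
)

ENDOG = 0  # endogenous Ph
EXOG = 1   # exogenous Ph or Ph-ML, per variant


@dataclass
class SimParams:
    """Simulation configuration.

    Rates are per-step probabilities.  ``e_bond`` is in units of thermal
    energy kT.  ``n_max`` is the spreading saturation (copies of Ph per
    bead); ``None`` lifts the cap.  ``k_a_exog``/``k_d_exog`` default to the
    endogenous values; the weak-binding variant multiplies the exogenous
    ``k_d`` by 10 unless it was set explicitly.
    """

    n_nodes: int = 400
    n_endog: int = 100
    n_exog: int = 0
    k_a_endog: float = 0.02
    k_d_endog: float = 0.002
    k_a_exog: float | None = None
    k_d_exog: float | None = None
    k_join: float = 0.1
    k_break: float = 0.01
    e_bond: float = 1.0
    n_max: int | None = 15
    neighbor_radius: float = math.sqrt(3)
    model_variant: str = "baseline"
    n_steps: int = 5000
    n_iterations: int = 50
    snapshot_every: int = 50
    burn_in_fraction: float = 0.5
    diameter_scale: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_variant not in MODEL_VARIANTS:
            raise ValueError(
                f"unknown model_variant {self.model_variant!r}; "
                f"expected one of {MODEL_VARIANTS}"
            )
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.e_bond < 0:
            raise ValueError("e_bond must be >= 0")
        if self.n_endog < 0 or self.n_exog < 0:
            raise ValueError("binder counts must be >= 0")
        for name in ("k_a_endog", "k_d_endog", "k_join", "k_break"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("k_a_exog", "k_d_exog"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_max is not None and self.n_max < 1:
            raise ValueError("n_max must be >= 1 or None")

    # -- resolved, variant-aware kinetics ---------------------------------
    @property
    def resolved_k_a(self) -> np.ndarray:
        ka_x = self.k_a_exog if self.k_a_exog is not None else self.k_a_endog
        return np.array([self.k_a_endog, ka_x])

    @property
    def resolved_k_d(self) -> np.ndarray:
        if self.k_d_exog is not None:
            kd_x = self.k_d_exog
        elif self.model_variant == "weak_binding_ML":
            kd_x = min(1.0, 10.0 * self.k_d_endog)
        else:
            kd_x = self.k_d_endog
        return np.array([self.k_d_endog, kd_x])

    @property
    def capping(self) -> bool:
        return self.model_variant == "capping_ML"

    @property
    def effective_n_max(self) -> int | None:
        return None if self.model_variant == "wt_unlimited" else self.n_max

    @property
    def surfaces0(self) -> np.ndarray:
        """Initial bridging surfaces per species (capping Ph-ML carries none)."""
        return np.array([1, 0 if self.capping else 1], dtype=np.int8)


@dataclass
class SimState:
    """Full mutable simulation state for one iteration."""

    params: SimParams
    polymer: LatticePolymer
    affinity: np.ndarray          # (n_nodes,)
    species: np.ndarray           # (n_binders,) int8, ENDOG / EXOG
    node_of: np.ndarray           # (n_binders,) int64, -1 when free
    partner: np.ndarray           # (n_binders,) int64, bonded binder or -1
    capped: np.ndarray            # (n_binders,) bool, Ph that lost a surface
    cap_target: np.ndarray        # (n_binders,) int64, Ph capped by this ML

    @property
    def n_binders(self) -> int:
        return len(self.species)

    def surfaces_free(self) -> np.ndarray:
        s0 = self.params.surfaces0[self.species].astype(np.int64)
        return s0 - (self.partner >= 0).astype(np.int64) - self.capped.astype(np.int64)

    def occupancy(self) -> np.ndarray:
        bound = self.node_of >= 0
        return np.bincount(self.node_of[bound], minlength=self.params.n_nodes)

    def bond_pairs(self) -> np.ndarray:
        """Current bonds as an (m, 2) array with i < j."""
        i = np.flatnonzero(self.partner > np.arange(len(self.partner)))
        return np.stack([i, self.partner[i]], axis=1) if len(i) else np.zeros((0, 2), dtype=np.int64)


def init_state(params: SimParams, rng: np.random.Generator) -> SimState:
    polymer = init_polymer(params.n_nodes, int(rng.integers(0, 2**31 - 1)))
    affinity = assign_affinities(params.n_nodes, int(rng.integers(0, 2**31 - 1)))
    n = params.n_endog + params.n_exog
    species = np.concatenate(
        [np.zeros(params.n_endog, np.int8), np.ones(params.n_exog, np.int8)]
    )
    return SimState(
        params=params,
        polymer=polymer,
        affinity=affinity,
        species=species,
        node_of=np.full(n, -1, dtype=np.int64),
        partner=np.full(n, -1, dtype=np.int64),
        capped=np.zeros(n, dtype=bool),
        cap_target=np.full(n, -1, dtype=np.int64),
    )


def bound_counts(state: SimState) -> tuple[int, int]:
    """(bound, free) totals over all species; their sum is conserved."""
    b = int((state.node_of >= 0).sum())
    return b, state.n_binders - b


# ---------------------------------------------------------------------------
# Metropolis polymer moves
# ---------------------------------------------------------------------------

def metropolis_accept(delta_energy: float, rng: np.random.Generator | int) -> bool:
    """Accept with probability min(1, exp(-dE)); energies in kT units."""
    if delta_energy <= 0:
        return True
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    return bool(rng.random() < math.exp(-delta_energy))


def _broken_bonds(state: SimState, new_coords: np.ndarray) -> np.ndarray:
    """Bonds whose bead-bead distance exceeds the radius under new_coords."""
    pairs = state.bond_pairs()
    if not len(pairs):
        return pairs
    a = new_coords[state.node_of[pairs[:, 0]]]
    b = new_coords[state.node_of[pairs[:, 1]]]
    d2 = ((a - b) ** 2).sum(axis=1)
    r2 = state.params.neighbor_radius**2 + 1e-9
    return pairs[d2 > r2]


def move_energy_delta(state: SimState, proposal: MoveProposal) -> float:
    """Energy change of a geometrically valid move.

    Each binder-binder bond contributes -E_bond while intact; a move that
    separates bonded beads beyond the neighbour radius pays +E_bond per bond
    broken.  Moves never create bonds (bond formation is a kinetic step), so
    dE = E_bond * n_broken >= 0.
    """
    return state.params.e_bond * len(_broken_bonds(state, proposal.new_coords))


def polymer_step(state: SimState, rng: np.random.Generator) -> bool:
    """One pivot attempt with bond-fluctuation fallback; returns acceptance."""
    prop = propose_pivot(state.polymer, rng)
    if not prop.valid:
        idx = int(rng.integers(0, state.params.n_nodes))
        prop = propose_local_move(state.polymer, idx, rng)
        if not prop.valid:
            return False
    broken = _broken_bonds(state, prop.new_coords)
    de = state.params.e_bond * len(broken)
    if not metropolis_accept(de, rng):
        return False
    state.polymer.coords = prop.new_coords
    for i, j in broken:
        state.partner[i] = -1
        state.partner[j] = -1
    return True


# ---------------------------------------------------------------------------
# Cluster bookkeeping (co-occupancy + bridges)
# ---------------------------------------------------------------------------

def binder_components(state: SimState) -> np.ndarray:
    """Component label per binder (-1 when free).

    A cluster is a maximal set of bound binders connected by sharing a bead
    or by a bridge bond.  Since co-resident binders are always connected,
    the union-find runs over beads (linked by bonds), then labels binders by
    their bead's component.
    """
    n_nodes = state.params.n_nodes
    parent = np.arange(n_nodes)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in state.bond_pairs():
        ra, rb = find(int(state.node_of[i])), find(int(state.node_of[j]))
        if ra != rb:
            parent[rb] = ra

    labels = np.full(state.n_binders, -1, dtype=np.int64)
    bound = np.flatnonzero(state.node_of >= 0)
    roots = np.array([find(int(nd)) for nd in state.node_of[bound]])
    labels[bound] = roots
    return labels


def cluster_census(state: SimState) -> list[int]:
    """Molecule counts of all clusters (sorted descending)."""
    labels = binder_components(state)
    bound = labels[labels >= 0]
    if not len(bound):
        return []
    _, counts = np.unique(bound, return_counts=True)
    return sorted((int(c) for c in counts), reverse=True)


# ---------------------------------------------------------------------------
# Binding / unbinding
# ---------------------------------------------------------------------------

def _open_nodes(state: SimState, labels: np.ndarray) -> np.ndarray:
    """Per-node mask: True where association is allowed under capping.

    Empty beads are always open.  An occupied bead is open iff its cluster
    still holds at least one uncapped wild-type Ph surface donor; once the
    resident Ph are all capped (equal Ph-ML joins), association of either
    type to that cluster stops.
    """
    n_nodes = state.params.n_nodes
    open_mask = np.ones(n_nodes, dtype=bool)
    bound = np.flatnonzero(state.node_of >= 0)
    if not len(bound):
        return open_mask
    donor = (state.params.surfaces0[state.species] == 1) & ~state.capped
    open_labels = set(labels[bound[donor[bound]]].tolist())
    for i in bound:
        if labels[i] not in open_labels:
            open_mask[state.node_of[i]] = False
    return open_mask


def binding_step(state: SimState, rng: np.random.Generator) -> None:
    """Mass-action association then dissociation, one sweep over beads.

    Association: a bead with k free-surface residents makes k+1 independent
    attempts per species, each with probability ``k_a * A * f`` (f = free
    pool fraction; the wild-type variants share one pool across endogenous
    and exogenous Ph), gated by the spreading cap and, in the capping
    variant, by cluster openness.  Dissociation: each bound binder leaves
    with probability ``k_d``, taking its bonds and cap bookkeeping with it.
    Total binders per species are conserved.
    """
    p = state.params
    k_a = p.resolved_k_a
    k_d = p.resolved_k_d
    n_max = p.effective_n_max

    occ = state.occupancy()
    if p.capping:
        labels = binder_components(state)
        open_mask = _open_nodes(state, labels)
    else:
        labels = None
        open_mask = None

    # association surfaces: the bead itself plus every resident whose SAM
    # surface is free (not engaged in a bridge, not capped)
    surf = state.surfaces_free() > 0
    donor_nodes = state.node_of[(state.node_of >= 0) & surf]
    trials = np.bincount(donor_nodes, minlength=p.n_nodes) + 1

    # exogenous wild-type Ph is the same molecule as endogenous Ph: the two
    # draw on one shared free pool; mutant (ML) binders keep their own pool
    exog_is_ml = p.model_variant in ("weak_binding_ML", "capping_ML")
    shared_fraction = None
    if not exog_is_ml:
        n_total = state.n_binders
        if n_total:
            shared_fraction = (state.node_of < 0).sum() / n_total

    for sp in (ENDOG, EXOG):
        total = int((state.species == sp).sum())
        if total == 0 or k_a[sp] == 0.0:
            continue
        free_ids = np.flatnonzero((state.species == sp) & (state.node_of < 0))
        n_free = len(free_ids)
        if n_free == 0:
            continue
        frac = shared_fraction if shared_fraction is not None else n_free / total
        prob = np.clip(k_a[sp] * state.affinity * frac, 0.0, 1.0)
        wants = rng.binomial(trials, prob)
        if n_max is not None:
            wants = np.minimum(wants, np.maximum(n_max - occ, 0))
        if open_mask is not None:
            wants = np.where(open_mask, wants, 0)
        total_wanted = int(wants.sum())
        if total_wanted == 0:
            continue
        target_nodes = np.repeat(np.arange(p.n_nodes), wants)
        if total_wanted > n_free:
            target_nodes = rng.permutation(target_nodes)[:n_free]
        movers = free_ids if len(target_nodes) == n_free else rng.choice(
            free_ids, size=len(target_nodes), replace=False
        )
        if p.capping and sp == EXOG:
            for binder, node in zip(movers, target_nodes):
                _bind_one(state, int(binder), int(node), labels, rng)
        else:
            state.node_of[movers] = target_nodes
        occ = state.occupancy()

    # dissociation (vectorized; a leaver takes its bond and cap records along)
    bound_ids = np.flatnonzero(state.node_of >= 0)
    if len(bound_ids):
        leavers = bound_ids[rng.random(len(bound_ids)) < k_d[state.species[bound_ids]]]
        if len(leavers):
            was_capped = state.capped[leavers].copy()
            partners = state.partner[leavers]
            state.partner[partners[partners >= 0]] = -1
            state.partner[leavers] = -1
            targets = state.cap_target[leavers]
            state.capped[targets[targets >= 0]] = False
            state.cap_target[leavers] = -1
            capped_leavers = leavers[was_capped]
            if len(capped_leavers):
                cappers = np.flatnonzero(np.isin(state.cap_target, capped_leavers))
                state.cap_target[cappers] = -1
                state.capped[capped_leavers] = False
            state.node_of[leavers] = -1


def _bind_one(
    state: SimState,
    binder: int,
    node: int,
    labels: np.ndarray | None,
    rng: np.random.Generator,
) -> None:
    is_ml_capper = state.params.capping and state.species[binder] == EXOG
    if is_ml_capper and labels is not None:
        # Capping: an ML joining an existing cluster removes one interaction
        # surface from a resident uncapped Ph, chosen uniformly.  Joining an
        # empty bead founds a new (closed) cluster and caps nothing.
        residents = np.flatnonzero(state.node_of == node)
        if len(residents):
            cluster = labels == labels[residents[0]]
            donors = np.flatnonzero(
                cluster
                & (state.params.surfaces0[state.species] == 1)
                & ~state.capped
            )
            if len(donors):
                target = int(rng.choice(donors))
                # The ML occupies the donor's single interaction surface; a
                # bridge bond held through that surface is displaced.
                q = state.partner[target]
                if q >= 0:
                    state.partner[q] = -1
                    state.partner[target] = -1
                state.capped[target] = True
                state.cap_target[binder] = target
    state.node_of[binder] = node


# ---------------------------------------------------------------------------
# Bridging
# ---------------------------------------------------------------------------

def bridging_step(state: SimState, rng: np.random.Generator) -> None:
    """Break existing bonds with probability k_break, then form new bonds.

    Bond formation is an encounter event between beads: for every pair of
    beads within ``neighbor_radius`` in 3D (excluding chain-adjacent beads
    -- bridges are long-range contacts) that both hold at least one binder
    with a free interaction surface, one new bond forms with probability
    ``k_join`` between a uniformly chosen free-surface binder on each side.
    The encounter rate is thus set by the polymer geometry, while the free
    surfaces cap the number of bonds two clusters can share at the size of
    the smaller one.  Spreading saturation does not block bridging.
    """
    p = state.params
    pairs = state.bond_pairs()
    if len(pairs):
        cut = rng.random(len(pairs)) < p.k_break
        broken = pairs[cut]
        state.partner[broken[:, 0]] = -1
        state.partner[broken[:, 1]] = -1

    if p.k_join <= 0.0:
        return
    free = state.surfaces_free() > 0
    eligible = np.flatnonzero(free & (state.node_of >= 0))
    if len(eligible) < 2:
        return
    nodes = state.node_of[eligible]
    uniq, inv = np.unique(nodes, return_inverse=True)
    if len(uniq) < 2:
        return
    coords = state.polymer.coords[uniq]
    diff = coords[:, None, :] - coords[None, :, :]
    d2 = (diff * diff).sum(axis=2)
    r2 = p.neighbor_radius**2 + 1e-9
    sep = np.abs(uniq[:, None] - uniq[None, :])
    adjacent = (d2 <= r2) & (sep >= 2)
    close = np.argwhere(adjacent)
    close = close[close[:, 0] < close[:, 1]]
    if not len(close):
        return
    coins = np.flatnonzero(rng.random(len(close)) < p.k_join)
    if not len(coins):
        return

    # free-surface binders grouped by bead for partner sampling
    order = np.argsort(inv, kind="stable")
    grouped = eligible[order]
    bounds = np.searchsorted(inv[order], np.arange(len(uniq) + 1))
    partner = state.partner
    for k in rng.permutation(coins):
        a, b = close[k]
        pool_a = [int(i) for i in grouped[bounds[a]: bounds[a + 1]] if partner[i] < 0]
        if not pool_a:
            continue
        pool_b = [int(j) for j in grouped[bounds[b]: bounds[b + 1]] if partner[j] < 0]
        if not pool_b:
            continue
        i = pool_a[int(rng.integers(0, len(pool_a)))]
        j = pool_b[int(rng.integers(0, len(pool_b)))]
        partner[i] = j
        partner[j] = i
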