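"""Core two-dimensional bond fluctuation model (BFM) engine.

In the 2D BFM every monomer occupies a 2x2 plaquette of lattice sites and
bonds between adjacent chain monomers fluctuate over a finite set of allowed
vectors (lengths 2, sqrt(5), 2*sqrt(2), 3, sqrt(10), sqrt(13)).  Excluded
volume is enforced as an unconditional rejection of any move that would make
two plaquettes share a site; together with the bond-length cap of sqrt(13)
this guarantees self-avoiding, non-crossing chains.

Energetics are short-ranged: two monomers are *in contact* when their anchor
offset lies within a Chebyshev radius of 2 (a 24-offset shell, the lattice
coordination number z = 24), and each contacting pair contributes one
species-pair energy from an :class:`InteractionTable` (units of kBT = 1).
Dynamics are single-monomer unit steps accepted with the Metropolis rule
P = min(1, exp(-dE)).

The module provides both a transparent pure-Python reference path
(:func:`metropolis_step`, :func:`local_energy`, :class:`VerletList`) used by
the tests, and numba-jitted bulk kernels (``_mc_kernel``, ``_sediment_kernel``)
that the builder and swelling engine use for long runs.  Both paths implement
identical physics; the jitted kernels evaluate contact energies through an
anchor-occupancy grid, which is exactly equivalent to an all-pairs scan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "CHAIN",
    "DRUG",
    "SOLVENT",
    "BOND_LENGTHS_SQ",
    "SHORT_BOND_LENGTHS_SQ",
    "enumerate_bond_vectors",
    "bond_vector_table",
    "nn_shell_offsets",
    "InteractionTable",
    "System",
    "RunState",
    "steric_free",
    "local_energy",
    "count_contacts",
    "metropolis_step",
    "attempt_move",
    "VerletList",
    "verlet_refresh",
    "seed_kernel_rng",
]

# ---------------------------------------------------------------------------
# Species codes and lattice constants
# ---------------------------------------------------------------------------

CHAIN, DRUG, SOLVENT = 0, 1, 2
SPECIES_NAMES = {CHAIN: "chain", DRUG: "drug", SOLVENT: "solvent"}

#: squared lengths of the allowed 2D BFM bond vectors
BOND_LENGTHS_SQ = frozenset({4, 5, 8, 9, 10, 13})
#: the two shortest allowed lengths (2 and sqrt(5)), used for compact seeding
SHORT_BOND_LENGTHS_SQ = frozenset({4, 5})

#: unit-step proposal directions (+x, -x, +y, -y)
_KDX = np.array([1, -1, 0, 0], dtype=np.int64)
_KDY = np.array([0, 0, 1, -1], dtype=np.int64)

#: Chebyshev radius of the nearest-neighbour contact shell
NN_RADIUS = 2


def enumerate_bond_vectors(bond_lengths_sq=BOND_LENGTHS_SQ):
    """All integer offsets (dx, dy) whose squared length is in the given set.

    The result is closed under negation and 90-degree rotation.  For the full
    2D BFM set {4, 5, 8, 9, 10, 13} there are exactly 36 vectors.
    """
    lengths = {int(v) for v in bond_lengths_sq}
    if not lengths:
        raise ValueError("bond length set must not be empty")
    if any(v <= 0 for v in lengths):
        raise ValueError("squared bond lengths must be positive integers")
    rmax = math.isqrt(max(lengths))
    vectors = frozenset(
        (dx, dy)
        for dx in range(-rmax, rmax + 1)
        for dy in range(-rmax, rmax + 1)
        if dx * dx + dy * dy in lengths
    )
    if not vectors:
        raise ValueError(f"no integer vectors realize squared lengths {sorted(lengths)}")
    return vectors


def bond_vector_table(bond_lengths_sq=BOND_LENGTHS_SQ):
    """Boolean 7x7 lookup, indexed ``table[dx + 3, dy + 3]``, of allowed bonds.

    All BFM bond components satisfy |dx|, |dy| <= 3; the fixed-size table is
    what the jitted kernels consume.
    """
    vectors = enumerate_bond_vectors(bond_lengths_sq)
    if any(abs(dx) > 3 or abs(dy) > 3 for dx, dy in vectors):
        raise ValueError("bond components beyond |3| are not representable")
    table = np.zeros((7, 7), dtype=np.bool_)
    for dx, dy in vectors:
        table[dx + 3, dy + 3] = True
    return table


def nn_shell_offsets():
    """The 24 anchor offsets defining nearest-neighbour contact (z = 24)."""
    return tuple(
        (dx, dy)
        for dx in range(-NN_RADIUS, NN_RADIUS + 1)
        for dy in range(-NN_RADIUS, NN_RADIUS + 1)
        if (dx, dy) != (0, 0)
    )


# ---------------------------------------------------------------------------
# Interactions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InteractionTable:
    """The six symmetric species-pair contact energies, in units of kBT = 1.

    Steric overlap is never encoded here: it is an unconditional rejection
    (conceptually an infinite energy).
    """

    ecc: float = 0.0  # chain-chain
    ecd: float = 0.0  # chain-drug
    ecs: float = 0.0  # chain-solvent
    edd: float = 0.0  # drug-drug
    eds: float = 0.0  # drug-solvent
    ess: float = 0.0  # solvent-solvent

    def matrix(self):
        """3x3 symmetric matrix indexed by (species, species)."""
        return np.array(
            [
                [self.ecc, self.ecd, self.ecs],
                [self.ecd, self.edd, self.eds],
                [self.ecs, self.eds, self.ess],
            ],
            dtype=np.float64,
        )

    def pair(self, species_a, species_b):
        for s in (species_a, species_b):
            if s not in (CHAIN, DRUG, SOLVENT):
                raise ValueError(f"unknown species code {s!r}")
        return float(self.matrix()[species_a, species_b])


# ---------------------------------------------------------------------------
# Lattice system
# ---------------------------------------------------------------------------


class System:
    """A hard-walled lattice box populated with plaquette monomers.

    Anchors (x, y) cover sites (x, y), (x+1, y), (x, y+1), (x+1, y+1) and must
    satisfy 0 <= x <= W-2, 0 <= y <= hy-2 (no periodic images; the box is a
    tablet-in-container geometry).  Two occupancy grids are maintained:
    ``site_grid`` maps every lattice site to the id of the monomer whose
    plaquette covers it, and ``anchor_grid`` maps anchor sites to monomer ids
    (used for O(1) contact-shell energy evaluation).

    Chain topology is stored as doubly linked bonds (``bond_prev`` /
    ``bond_next``); drug and solvent monomers carry no bonds.
    """

    def __init__(self, width, height):
        if width < 2 or height < 2:
            raise ValueError("box must be at least 2x2 lattice sites")
        self.W = int(width)
        self.hy = int(height)
        self.site_grid = np.full((self.W, self.hy), -1, dtype=np.int64)
        self.anchor_grid = np.full((self.W, self.hy), -1, dtype=np.int64)
        self.x = np.empty(0, dtype=np.int64)
        self.y = np.empty(0, dtype=np.int64)
        self.species = np.empty(0, dtype=np.int64)
        self.chain_id = np.empty(0, dtype=np.int64)
        self.index_in_chain = np.empty(0, dtype=np.int64)
        self.bond_prev = np.empty(0, dtype=np.int64)
        self.bond_next = np.empty(0, dtype=np.int64)
        self.bond_table = bond_vector_table()

    # -- population --------------------------------------------------------

    @property
    def n(self):
        return self.x.size

    @property
    def n_chains(self):
        return int(self.chain_id.max() + 1) if (self.chain_id >= 0).any() else 0

    def species_counts(self):
        return {s: int(np.count_nonzero(self.species == s)) for s in (CHAIN, DRUG, SOLVENT)}

    def add_monomer(self, x, y, species, chain_id=-1, index_in_chain=-1, bond_to=None):
        """Place a new monomer; returns its id.  Raises on steric violation."""
        if species not in (CHAIN, DRUG, SOLVENT):
            raise ValueError(f"unknown species code {species!r}")
        if species != CHAIN and (chain_id != -1 or bond_to is not None):
            raise ValueError("drug/solvent monomers carry no chain id or bonds")
        anchor = (int(x), int(y))
        if not self.steric_free(-1, anchor):
            raise ValueError(f"anchor {anchor} is sterically blocked or out of bounds")
        mid = self.n
        if bond_to is not None:
            bx, by = anchor[0] - int(self.x[bond_to]), anchor[1] - int(self.y[bond_to])
            if abs(bx) > 3 or abs(by) > 3 or not self.bond_table[bx + 3, by + 3]:
                raise ValueError(f"bond vector ({bx}, {by}) not in the allowed set")
            if self.bond_next[bond_to] != -1:
                raise ValueError("bond partner already has a successor")
        self.x = np.append(self.x, anchor[0])
        self.y = np.append(self.y, anchor[1])
        self.species = np.append(self.species, species)
        self.chain_id = np.append(self.chain_id, chain_id)
        self.index_in_chain = np.append(self.index_in_chain, index_in_chain)
        self.bond_prev = np.append(self.bond_prev, bond_to if bond_to is not None else -1)
        self.bond_next = np.append(self.bond_next, -1)
        if bond_to is not None:
            self.bond_next[bond_to] = mid
        self.site_grid[anchor[0] : anchor[0] + 2, anchor[1] : anchor[1] + 2] = mid
        self.anchor_grid[anchor[0], anchor[1]] = mid
        return mid

    def remove_monomer(self, mid):
        """Remove the most recently added monomer (placement backtracking).

        If it is the tail of a chain, the bond to its predecessor is unlinked.
        """
        if mid != self.n - 1:
            raise ValueError("only the most recently added monomer can be removed")
        if self.bond_next[mid] != -1:
            raise ValueError("cannot remove a monomer with a successor bond")
        if self.bond_prev[mid] != -1:
            self.bond_next[self.bond_prev[mid]] = -1
        ax, ay = int(self.x[mid]), int(self.y[mid])
        self.site_grid[ax : ax + 2, ay : ay + 2] = -1
        self.anchor_grid[ax, ay] = -1
        for name in ("x", "y", "species", "chain_id", "index_in_chain", "bond_prev", "bond_next"):
            setattr(self, name, getattr(self, name)[:-1])

    # -- geometry ----------------------------------------------------------

    def steric_free(self, monomer_id, anchor):
        """True iff the plaquette at ``anchor`` is inside the box and free.

        Sites covered by ``monomer_id`` itself do not block (pass -1 when
        testing a fresh placement).
        """
        ax, ay = anchor
        if ax < 0 or ax > self.W - 2 or ay < 0 or ay > self.hy - 2:
            return False
        block = self.site_grid[ax : ax + 2, ay : ay + 2]
        return bool(np.all((block == -1) | (block == monomer_id)))

    def move(self, mid, new_anchor):
        """Relocate a monomer's plaquette (no legality checks)."""
        ox, oy = int(self.x[mid]), int(self.y[mid])
        nx_, ny_ = int(new_anchor[0]), int(new_anchor[1])
        self.site_grid[ox : ox + 2, oy : oy + 2] = -1
        self.anchor_grid[ox, oy] = -1
        self.site_grid[nx_ : nx_ + 2, ny_ : ny_ + 2] = mid
        self.anchor_grid[nx_, ny_] = mid
        self.x[mid] = nx_
        self.y[mid] = ny_

    def chain_members(self, cid):
        return np.flatnonzero(self.chain_id == cid)

    def bond_vectors(self):
        """(dx, dy) of every bond, one row per bonded pair."""
        has_next = self.bond_next >= 0
        i = np.flatnonzero(has_next)
        j = self.bond_next[i]
        return np.column_stack([self.x[j] - self.x[i], self.y[j] - self.y[i]])

    def copy(self):
        out = System(self.W, self.hy)
        out.site_grid = self.site_grid.copy()
        out.anchor_grid = self.anchor_grid.copy()
        for name in ("x", "y", "species", "chain_id", "index_in_chain", "bond_prev", "bond_next"):
            setattr(out, name, getattr(self, name).copy())
        return out

    # -- consistency -------------------------------------------------------

    def check_invariants(self):
        """Assert occupancy consistency, zero overlaps, in-bounds anchors and
        allowed bond vectors.  Raises AssertionError on any violation."""
        assert np.all(self.x >= 0) and np.all(self.x <= self.W - 2), "anchor x out of bounds"
        assert np.all(self.y >= 0) and np.all(self.y <= self.hy - 2), "anchor y out of bounds"
        site = np.full((self.W, self.hy), -1, dtype=np.int64)
        for mid in range(self.n):
            ax, ay = self.x[mid], self.y[mid]
            block = site[ax : ax + 2, ay : ay + 2]
            assert np.all(block == -1), f"plaquette overlap at monomer {mid}"
            block[:] = mid
        assert np.array_equal(site, self.site_grid), "site grid inconsistent with particle list"
        for dx, dy in self.bond_vectors():
            assert self.bond_table[dx + 3, dy + 3], f"illegal bond vector ({dx}, {dy})"


# ---------------------------------------------------------------------------
# Energetics
# ---------------------------------------------------------------------------


def steric_free(system, monomer_id, anchor):
    """True iff ``monomer_id`` could occupy ``anchor``: plaquette fully inside
    the box and free of any other monomer (see :meth:`System.steric_free`)."""
    return system.steric_free(monomer_id, anchor)


def local_energy(system, monomer_id, anchor, interactions):
    """Contact energy of ``monomer_id`` hypothetically placed at ``anchor``.

    Sums the species-pair energy over all *other* monomers whose anchor lies
    in the 24-offset contact shell; each pair is counted once.
    """
    sp = int(system.species[monomer_id])
    if sp not in (CHAIN, DRUG, SOLVENT):
        raise ValueError(f"unknown species code {sp!r}")
    etab = interactions.matrix()
    ax, ay = int(anchor[0]), int(anchor[1])
    grid = system.anchor_grid
    energy = 0.0
    for dx, dy in nn_shell_offsets():
        xx, yy = ax + dx, ay + dy
        if 0 <= xx < system.W and 0 <= yy < system.hy:
            j = grid[xx, yy]
            if j != -1 and j != monomer_id:
                energy += etab[sp, system.species[j]]
    return energy


def count_contacts(system, species_a, species_b):
    """Number of distinct nearest-neighbour contact pairs between two species."""
    total = 0
    for mid in np.flatnonzero(system.species == species_a):
        ax, ay = int(system.x[mid]), int(system.y[mid])
        for dx, dy in nn_shell_offsets():
            xx, yy = ax + dx, ay + dy
            if 0 <= xx < system.W and 0 <= yy < system.hy:
                j = system.anchor_grid[xx, yy]
                if j != -1 and j != mid and system.species[j] == species_b:
                    total += 1
    return total // 2 if species_a == species_b else total


# ---------------------------------------------------------------------------
# Verlet neighbour lists
# ---------------------------------------------------------------------------


class VerletList:
    """Cached candidate-neighbour lists for contact-energy evaluation.

    Candidates are all monomers within Chebyshev distance ``NN_RADIUS + skin``
    of each anchor at build time.  The list auto-rebuilds whenever any monomer
    has drifted more than ``skin // 2`` since the last build, so energies
    computed through the list are always exactly equal to an all-pairs scan.
    A periodic refresh interval (default 100 attempted moves) is applied by
    the callers on top of this safety condition.
    """

    def __init__(self, system, skin=4):
        if skin < 2:
            raise ValueError("skin must be >= 2 to survive a refresh interval")
        self.skin = int(skin)
        self.refresh(system)

    def refresh(self, system):
        self._ref_x = system.x.copy()
        self._ref_y = system.y.copy()
        cutoff = NN_RADIUS + self.skin
        n = system.n
        self._lists = []
        for i in range(n):
            dx = np.abs(system.x - system.x[i])
            dy = np.abs(system.y - system.y[i])
            mask = (np.maximum(dx, dy) <= cutoff)
            mask[i] = False
            self._lists.append(np.flatnonzero(mask))
        self.n_refreshes = getattr(self, "n_refreshes", 0) + 1

    def needs_refresh(self, system):
        if system.n != self._ref_x.size:
            return True
        if system.n == 0:
            return False
        drift = np.maximum(np.abs(system.x - self._ref_x), np.abs(system.y - self._ref_y))
        return bool(drift.max() > self.skin // 2)

    def neighbors(self, mid):
        return self._lists[mid]

    def energy(self, system, monomer_id, anchor, interactions):
        """Contact energy via the cached candidate list (auto-refreshing)."""
        if self.needs_refresh(system):
            self.refresh(system)
        sp = int(system.species[monomer_id])
        etab = interactions.matrix()
        ax, ay = int(anchor[0]), int(anchor[1])
        energy = 0.0
        for j in self._lists[monomer_id]:
            if max(abs(int(system.x[j]) - ax), abs(int(system.y[j]) - ay)) <= NN_RADIUS:
                energy += etab[sp, system.species[j]]
        return energy


def verlet_refresh(system, state):
    """Rebuild the run state's neighbour lists and reset its staleness clock."""
    if state.verlet is None:
        state.verlet = VerletList(system)
    else:
        state.verlet.refresh(system)
    state.moves_since_refresh = 0
    return state.verlet


# ---------------------------------------------------------------------------
# Run state and the Metropolis step (reference path)
# ---------------------------------------------------------------------------


@dataclass
class RunState:
    """Bookkeeping for a Monte Carlo run: RNG, counters, neighbour lists.

    The contract is bitwise reproducibility: an identical seed and
    configuration yields an identical trajectory.  One generator drives, in
    fixed order, (1) mobile-entity selection, (2) direction selection and
    (3) the acceptance uniform (drawn only when dE > 0).
    """

    seed: int
    rng: np.random.Generator = None
    attempted: int = 0
    accepted: int = 0
    rejected_steric: int = 0
    rejected_bond: int = 0
    rejected_energy: int = 0
    verlet: VerletList = None
    verlet_interval: int = 100
    moves_since_refresh: int = 0

    def __post_init__(self):
        if self.rng is None:
            self.rng = np.random.default_rng(self.seed)

    @property
    def acceptance_rate(self):
        return self.accepted / self.attempted if self.attempted else 0.0


def attempt_move(system, state, mid, direction, interactions, use_verlet=False):
    """Attempt one unit-step move of ``mid``; returns True iff accepted.

    Rejection order: wall/steric first, then chain-bond legality, then the
    Metropolis criterion on the contact-energy change.
    """
    state.attempted += 1
    dx, dy = int(_KDX[direction]), int(_KDY[direction])
    ox, oy = int(system.x[mid]), int(system.y[mid])
    nx_, ny_ = ox + dx, oy + dy
    if not system.steric_free(mid, (nx_, ny_)):
        state.rejected_steric += 1
        return False
    for partner in (system.bond_prev[mid], system.bond_next[mid]):
        if partner != -1:
            bx = int(system.x[partner]) - nx_
            by = int(system.y[partner]) - ny_
            if abs(bx) > 3 or abs(by) > 3 or not system.bond_table[bx + 3, by + 3]:
                state.rejected_bond += 1
                return False
    if use_verlet:
        if state.verlet is None or state.moves_since_refresh >= state.verlet_interval:
            verlet_refresh(system, state)
        e_old = state.verlet.energy(system, mid, (ox, oy), interactions)
        e_new = state.verlet.energy(system, mid, (nx_, ny_), interactions)
    else:
        e_old = local_energy(system, mid, (ox, oy), interactions)
        e_new = local_energy(system, mid, (nx_, ny_), interactions)
    d_e = e_new - e_old
    if d_e > 0 and state.rng.random() >= math.exp(-d_e):
        state.rejected_energy += 1
        return False
    system.move(mid, (nx_, ny_))
    state.accepted += 1
    state.moves_since_refresh += 1
    return True


def metropolis_step(system, state, mobile_ids, interactions, use_verlet=False):
    """One attempted move: uniform mobile-monomer and direction selection,
    then :func:`attempt_move`.  The attempted-move counter increments whether
    or not the move is accepted."""
    if len(mobile_ids) == 0:
        raise ValueError("at least one mobile entity is required")
    mid = mobile_ids[int(state.rng.integers(len(mobile_ids)))]
    direction = int(state.rng.integers(4))
    return attempt_move(system, state, mid, direction, interactions, use_verlet=use_verlet)


# ---------------------------------------------------------------------------
# Jitted bulk kernels
# ---------------------------------------------------------------------------
# Shared layout: counters = [n_mobile, accepted, attempted, rej_steric,
# rej_bond, rej_energy] (int64).  Numba's global np.random state is used;
# seed it once per run via seed_kernel_rng().


@njit(cache=True)
def _nb_seed(seed):
    np.random.seed(seed)


def seed_kernel_rng(seed):
    """Seed the jitted kernels' RNG stream (kept below 2**31)."""
    _nb_seed(int(seed) % 2147483647)


@njit(cache=True)
def _energy_at(mid, ax, ay, x, y, species, anchor_grid, etab):
    W, hy = anchor_grid.shape
    sp = species[mid]
    e = 0.0
    x0 = ax - 2 if ax >= 2 else 0
    x1 = ax + 3 if ax + 3 <= W else W
    y0 = ay - 2 if ay >= 2 else 0
    y1 = ay + 3 if ay + 3 <= hy else hy
    for xx in range(x0, x1):
        for yy in range(y0, y1):
            j = anchor_grid[xx, yy]
            if j != -1 and j != mid and not (xx == ax and yy == ay):
                e += etab[sp, species[j]]
    return e


@njit(cache=True)
def _mc_kernel(
    n_moves,
    x,
    y,
    species,
    chain_id,
    bond_prev,
    bond_next,
    site_grid,
    anchor_grid,
    etab,
    allowed_bond,
    mobile,
    is_mobile,
    counters,
    chain_active,
    chain_activation_time,
    chain_len,
    activation,
):
    """Single-monomer Metropolis moves over the mobile set.

    With ``activation`` set, an accepted solvent move scans the contact shell
    of the new anchor and permanently activates (mobilizes) any inactive
    chain found there, stamping the current attempted-move count.
    """
    W, hy = site_grid.shape
    n_mobile = counters[0]
    for _ in range(n_moves):
        counters[2] += 1
        if n_mobile == 0:
            continue
        m = mobile[np.random.randint(n_mobile)]
        d = np.random.randint(4)
        dx = _KDX[d]
        dy = _KDY[d]
        ox = x[m]
        oy = y[m]
        nx_ = ox + dx
        ny_ = oy + dy
        if nx_ < 0 or nx_ > W - 2 or ny_ < 0 or ny_ > hy - 2:
            counters[3] += 1
            continue
        blocked = False
        for a in range(2):
            for b in range(2):
                occ = site_grid[nx_ + a, ny_ + b]
                if occ != -1 and occ != m:
                    blocked = True
        if blocked:
            counters[3] += 1
            continue
        if chain_id[m] != -1:
            bond_ok = True
            p = bond_prev[m]
            if p != -1:
                bx = x[p] - nx_
                by = y[p] - ny_
                if bx < -3 or bx > 3 or by < -3 or by > 3 or not allowed_bond[bx + 3, by + 3]:
                    bond_ok = False
            q = bond_next[m]
            if bond_ok and q != -1:
                bx = x[q] - nx_
                by = y[q] - ny_
                if bx < -3 or bx > 3 or by < -3 or by > 3 or not allowed_bond[bx + 3, by + 3]:
                    bond_ok = False
            if not bond_ok:
                counters[4] += 1
                continue
        e_old = _energy_at(m, ox, oy, x, y, species, anchor_grid, etab)
        e_new = _energy_at(m, nx_, ny_, x, y, species, anchor_grid, etab)
        d_e = e_new - e_old
        if d_e > 0.0 and np.random.random() >= math.exp(-d_e):
            counters[5] += 1
            continue
        # apply
        for a in range(2):
            for b in range(2):
                site_grid[ox + a, oy + b] = -1
        anchor_grid[ox, oy] = -1
        for a in range(2):
            for b in range(2):
                site_grid[nx_ + a, ny_ + b] = m
        anchor_grid[nx_, ny_] = m
        x[m] = nx_
        y[m] = ny_
        counters[1] += 1
        if activation and species[m] == SOLVENT:
            x0 = nx_ - 2 if nx_ >= 2 else 0
            x1 = nx_ + 3 if nx_ + 3 <= W else W
            y0 = ny_ - 2 if ny_ >= 2 else 0
            y1 = ny_ + 3 if ny_ + 3 <= hy else hy
            for xx in range(x0, x1):
                for yy in range(y0, y1):
                    j = anchor_grid[xx, yy]
                    if j != -1 and species[j] == CHAIN:
                        c = chain_id[j]
                        if not chain_active[c]:
                            chain_active[c] = True
                            chain_activation_time[c] = counters[2]
                            for k in range(c * chain_len, (c + 1) * chain_len):
                                if not is_mobile[k]:
                                    mobile[n_mobile] = k
                                    is_mobile[k] = True
                                    n_mobile += 1
    counters[0] = n_mobile


@njit(cache=True)
def _sediment_kernel(
    n_moves,
    x,
    y,
    chain_id,
    bond_prev,
    bond_next,
    site_grid,
    anchor_grid,
    allowed_bond,
    n_chains,
    chain_len,
    counters,
):
    """Gravity-biased sedimentation: equal-probability single-monomer and
    whole-chain centre-of-mass unit moves.

    The moved entity carries the potential E_j = y_j / (2 * hy) (y_j = its
    vertical coordinate: monomer y, or chain centre-of-mass y).  An ascending
    move is accepted with exp(-E_j) evaluated at the destination; descending
    and lateral moves cost nothing (dE_j = -E_j or 0).  This is the reading
    of the move-related energy under which chains actually settle within the
    10^6-move budget; the literal per-step potential difference (1/(2*hy)
    per unit) is far too weak to sediment anything.
    """
    W, hy = site_grid.shape
    inv2h = 1.0 / (2.0 * hy)
    n_mono = n_chains * chain_len
    for _ in range(n_moves):
        counters[2] += 1
        d = np.random.randint(4)
        dx = _KDX[d]
        dy = _KDY[d]
        if np.random.random() < 0.5:
            # single-monomer move
            m = np.random.randint(n_mono)
            ox = x[m]
            oy = y[m]
            nx_ = ox + dx
            ny_ = oy + dy
            if nx_ < 0 or nx_ > W - 2 or ny_ < 0 or ny_ > hy - 2:
                counters[3] += 1
                continue
            blocked = False
            for a in range(2):
                for b in range(2):
                    occ = site_grid[nx_ + a, ny_ + b]
                    if occ != -1 and occ != m:
                        blocked = True
            if blocked:
                counters[3] += 1
                continue
            bond_ok = True
            p = bond_prev[m]
            if p != -1:
                bx = x[p] - nx_
                by = y[p] - ny_
                if bx < -3 or bx > 3 or by < -3 or by > 3 or not allowed_bond[bx + 3, by + 3]:
                    bond_ok = False
            q = bond_next[m]
            if bond_ok and q != -1:
                bx = x[q] - nx_
                by = y[q] - ny_
                if bx < -3 or bx > 3 or by < -3 or by > 3 or not allowed_bond[bx + 3, by + 3]:
                    bond_ok = False
            if not bond_ok:
                counters[4] += 1
                continue
            if dy > 0:
                d_e = ny_ * inv2h
                if np.random.random() >= math.exp(-d_e):
                    counters[5] += 1
                    continue
            for a in range(2):
                for b in range(2):
                    site_grid[ox + a, oy + b] = -1
            anchor_grid[ox, oy] = -1
            for a in range(2):
                for b in range(2):
                    site_grid[nx_ + a, ny_ + b] = m
            anchor_grid[nx_, ny_] = m
            x[m] = nx_
            y[m] = ny_
            counters[1] += 1
        else:
            # whole-chain centre-of-mass move (rigid unit translation)
            c = np.random.randint(n_chains)
            lo = c * chain_len
            hi = lo + chain_len
            ok = True
            for k in range(lo, hi):
                nx_ = x[k] + dx
                ny_ = y[k] + dy
                if nx_ < 0 or nx_ > W - 2 or ny_ < 0 or ny_ > hy - 2:
                    ok = False
                    break
                for a in range(2):
                    for b in range(2):
                        occ = site_grid[nx_ + a, ny_ + b]
                        if occ != -1 and chain_id[occ] != c:
                            ok = False
                if not ok:
                    break
            if not ok:
                counters[3] += 1
                continue
            if dy > 0:
                com_y = 0.0
                for k in range(lo, hi):
                    com_y += y[k]
                d_e = (com_y / chain_len + dy) * inv2h
                if np.random.random() >= math.exp(-d_e):
                    counters[5] += 1
                    continue
            for k in range(lo, hi):
                for a in range(2):
                    for b in range(2):
                        site_grid[x[k] + a, y[k] + b] = -1
                anchor_grid[x[k], y[k]] = -1
            for k in range(lo, hi):
                x[k] += dx
                y[k] += dy
                for a in range(2):
                    for b in range(2):
                        site_grid[x[k] + a, y[k] + b] = k
                anchor_grid[x[k], y[k]] = k
            counters[1] += 1


@njit(cache=True)
def _chain_solvent_contacts(x, y, species, chain_id, anchor_grid, n_chains):
    """Per-chain count of chain-solvent contact pairs in the current state."""
    W, hy = anchor_grid.shape
    counts = np.zeros(n_chains, dtype=np.int64)
    for m in range(x.size):
        if species[m] != CHAIN:
            continue
        ax = x[m]
        ay = y[m]
        x0 = ax - 2 if ax >= 2 else 0
        x1 = ax + 3 if ax + 3 <= W else W
        y0 = ay - 2 if ay >= 2 else 0
        y1 = ay + 3 if ay + 3 <= hy else hy
        for xx in range(x0, x1):
            for yy in range(y0, y1):
                j = anchor_grid[xx, yy]
                if j != -1 and j != m and species[j] == SOLVENT:
                    counts[chain_id[m]] += 1
    return counts
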