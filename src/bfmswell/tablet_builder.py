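"""Construction of the initial drug-loaded tablet immersed in solvent.

The build pipeline mirrors how a matrix tablet forms in the model: compact
("globular") chains are seeded on an even grid across the box, sedimented to
the bottom under a gravity-like potential E_j = y_j / (2*hy), consolidated by
a pore-formation stage with an attractive chain-chain energy (Ecc = -2.0 by
default) that produces dense nucleation nodes and interstitial vacancies,
and finally populated with drug monomers below the tablet's superficial
layer and solvent monomers above it (steric rejection sampling, no contact
energetics).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import bfm_core as core
from .bfm_core import (
    CHAIN,
    DRUG,
    SOLVENT,
    SHORT_BOND_LENGTHS_SQ,
    InteractionTable,
    System,
    bond_vector_table,
    enumerate_bond_vectors,
    seed_kernel_rng,
)

__all__ = [
    "BuilderParams",
    "generate_globular_chains",
    "sediment",
    "form_pores",
    "surface_profile",
    "place_drug",
    "place_solvent",
    "build_tablet",
]


@dataclass
class BuilderParams:
    """Tablet composition and build-stage move budgets.

    Defaults follow the full-scale study system: Nc=45 chains of Nm=30
    monomers, Nd=200 drug and Ns=1000 solvent monomers in a 256x256 box,
    with 10^6 attempted moves each for sedimentation and pore formation.
    """

    nc: int = 45
    nm: int = 30
    nd: int = 200
    ns: int = 1000
    width: int = 256
    height: int = 256
    sediment_moves: int = 10**6
    pore_moves: int = 10**6
    pore_ecc: float = -2.0
    seed: int = 0

    def __post_init__(self):
        for name in ("nc", "nm", "nd", "ns"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.nc > 0 and self.nm < 1:
            raise ValueError("chains need at least one monomer")
        # the matrix (chains + drug) must fit the lower half with vacancies
        if (self.nc * self.nm + self.nd) * 4 > self.width * self.height / 2:
            raise ValueError(
                "matrix does not fit: need (nc*nm + nd)*4 <= width*height/2"
            )

    @property
    def n_total(self):
        return self.nc * self.nm + self.nd + self.ns


def _seed_streams(seed):
    """Derive independent child seeds for the build stages."""
    ss = np.random.SeedSequence(seed)
    return ss.generate_state(4).tolist()  # chains, sediment, pores, placement


# ---------------------------------------------------------------------------
# Stage 1: globular chain seeding
# ---------------------------------------------------------------------------


def generate_globular_chains(params, rng=None):
    """Seed ``nc`` compact chains of ``nm`` monomers on an even grid.

    Chains are grown as self-avoiding walks restricted to the two shortest
    allowed bond vectors (squared lengths 4 and 5), with growth steps biased
    toward the chain's seed point so each chain stays globular.  Dead-ended
    growth restarts the chain; repeated failure raises an error naming the
    offending chain.
    """
    if rng is None:
        rng = np.random.default_rng(_seed_streams(params.seed)[0])
    system = System(params.width, params.height)
    if params.nc == 0:
        return system
    short_vecs = sorted(enumerate_bond_vectors(SHORT_BOND_LENGTHS_SQ))
    n_cols = int(np.ceil(np.sqrt(params.nc)))
    n_rows = int(np.ceil(params.nc / n_cols))
    for c in range(params.nc):
        col, row = c % n_cols, c // n_cols
        sx = int((col + 0.5) * params.width / n_cols)
        sy = int((row + 0.5) * params.height / n_rows)
        sx = min(max(sx, 0), params.width - 2)
        sy = min(max(sy, 0), params.height - 2)
        placed = _grow_chain(system, c, params.nm, (sx, sy), short_vecs, rng)
        if not placed:
            raise RuntimeError(
                f"failed to place chain {c} (nm={params.nm}) after bounded retries"
            )
    return system


def _grow_chain(system, cid, nm, seed_anchor, vectors, rng, max_restarts=200):
    sx, sy = seed_anchor
    for _ in range(max_restarts):
        start = _find_free_near(system, sx, sy, rng)
        if start is None:
            continue
        ids = [system.add_monomer(start[0], start[1], CHAIN, chain_id=cid, index_in_chain=0)]
        ok = True
        for k in range(1, nm):
            tail = ids[-1]
            tx, ty = int(system.x[tail]), int(system.y[tail])
            # compact growth: prefer candidates closest to the seed point
            cands = []
            for dx, dy in vectors:
                ax, ay = tx + dx, ty + dy
                if system.steric_free(-1, (ax, ay)):
                    d2 = (ax - sx) ** 2 + (ay - sy) ** 2
                    cands.append((d2, rng.random(), ax, ay))
            if not cands:
                ok = False
                break
            cands.sort()
            _, _, ax, ay = cands[0]
            ids.append(
                system.add_monomer(ax, ay, CHAIN, chain_id=cid, index_in_chain=k, bond_to=tail)
            )
        if ok:
            return True
        for mid in reversed(ids):
            system.remove_monomer(mid)
    return False


def _find_free_near(system, sx, sy, rng, radius=6):
    """A steric-free anchor near (sx, sy), searched over a jittered disk."""
    offsets = [(0, 0)] + [
        (int(dx), int(dy))
        for dx in range(-radius, radius + 1)
        for dy in range(-radius, radius + 1)
    ]
    rng.shuffle(offsets)
    for dx, dy in sorted(offsets, key=lambda o: (o[0] ** 2 + o[1] ** 2, rng.random())):
        ax, ay = sx + dx, sy + dy
        if system.steric_free(-1, (ax, ay)):
            return ax, ay
    return None


# ---------------------------------------------------------------------------
# Stage 2: sedimentation
# ---------------------------------------------------------------------------


def sediment(system, params, kernel_seed=None):
    """Sediment the chains under E_j = y_j / (2*hy) for ``sediment_moves``
    attempted moves, alternating (p = 1/2 each) between single-monomer unit
    moves and whole-chain centre-of-mass unit moves.  Steric and bond rules
    are always enforced; downhill moves are always accepted."""
    if system.species_counts()[DRUG] or system.species_counts()[SOLVENT]:
        raise ValueError("sedimentation must run before drug/solvent placement")
    if params.nc == 0 or params.sediment_moves == 0:
        return system
    if kernel_seed is None:
        kernel_seed = _seed_streams(params.seed)[1]
    seed_kernel_rng(kernel_seed)
    counters = np.zeros(6, dtype=np.int64)
    core._sediment_kernel(
        params.sediment_moves,
        system.x,
        system.y,
        system.chain_id,
        system.bond_prev,
        system.bond_next,
        system.site_grid,
        system.anchor_grid,
        system.bond_table,
        params.nc,
        params.nm,
        counters,
    )
    return system


# ---------------------------------------------------------------------------
# Stage 3: pore formation
# ---------------------------------------------------------------------------


def form_pores(system, params, kernel_seed=None):
    """Consolidate the sedimented matrix with attractive chain-chain contacts
    (Ecc = ``pore_ecc``, all other pair energies zero) over ``pore_moves``
    single-monomer Metropolis moves."""
    if params.nc == 0 or params.pore_moves == 0:
        return system
    if kernel_seed is None:
        kernel_seed = _seed_streams(params.seed)[2]
    seed_kernel_rng(kernel_seed)
    n_chain_monomers = params.nc * params.nm
    etab = InteractionTable(ecc=params.pore_ecc).matrix()
    mobile = np.arange(system.n, dtype=np.int64)  # chains only exist at this stage
    is_mobile = np.ones(system.n, dtype=np.bool_)
    counters = np.zeros(6, dtype=np.int64)
    counters[0] = n_chain_monomers
    chain_active = np.zeros(max(params.nc, 1), dtype=np.bool_)
    chain_activation_time = np.full(max(params.nc, 1), -1, dtype=np.int64)
    core._mc_kernel(
        params.pore_moves,
        system.x,
        system.y,
        system.species,
        system.chain_id,
        system.bond_prev,
        system.bond_next,
        system.site_grid,
        system.anchor_grid,
        etab,
        system.bond_table,
        mobile,
        is_mobile,
        counters,
        chain_active,
        chain_activation_time,
        params.nm,
        False,
    )
    return system


# ---------------------------------------------------------------------------
# Stage 4: superficial layer and drug/solvent population
# ---------------------------------------------------------------------------


def surface_profile(system):
    """Per-column tablet height: the maximum y covered by any chain plaquette
    in that column (0 where the column holds no chain sites)."""
    heights = np.zeros(system.W, dtype=np.int64)
    for mid in np.flatnonzero(system.species == CHAIN):
        ax, ay = int(system.x[mid]), int(system.y[mid])
        top = ay + 1
        for col in (ax, ax + 1):
            if heights[col] < top:
                heights[col] = top
    return heights


def _populate(system, species, n_wanted, region_ok, rng):
    """Rejection-sample ``n_wanted`` anchors among steric-valid positions in a
    region; raises reporting the achievable count when the region is too full."""
    candidates = [
        (ax, ay)
        for ax in range(system.W - 1)
        for ay in range(system.hy - 1)
        if region_ok(ax, ay)
    ]
    rng.shuffle(candidates)
    placed = 0
    for ax, ay in candidates:
        if placed == n_wanted:
            break
        if system.steric_free(-1, (ax, ay)):
            system.add_monomer(ax, ay, species)
            placed += 1
    if placed < n_wanted:
        raise ValueError(
            f"insufficient vacancies for {core.SPECIES_NAMES[species]}: "
            f"requested {n_wanted}, achievable {placed}"
        )
    return system


def place_drug(system, nd, seed=0, profile=None, rng=None):
    """Distribute ``nd`` drug monomers uniformly among steric-valid anchors
    strictly below the surface profile (plaquette topmost row below the
    profile in both covered columns).  No contact energetics."""
    if nd == 0:
        return system
    if profile is None:
        profile = surface_profile(system)
    if rng is None:
        rng = np.random.default_rng(seed)

    def below(ax, ay):
        return ay + 1 < profile[ax] and ay + 1 < profile[ax + 1]

    return _populate(system, DRUG, nd, below, rng)


def place_solvent(system, ns, seed=0, profile=None, rng=None):
    """Distribute ``ns`` solvent monomers uniformly among steric-valid anchors
    strictly above the surface profile (plaquette bottommost row above the
    profile in both covered columns)."""
    if ns == 0:
        return system
    if profile is None:
        profile = surface_profile(system)
    if rng is None:
        rng = np.random.default_rng(seed)

    def above(ax, ay):
        return ay > profile[ax] and ay > profile[ax + 1]

    return _populate(system, SOLVENT, ns, above, rng)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def build_tablet(params):
    """Run the full build: seed chains, sediment, form pores, compute the
    superficial layer, then place drug below and solvent above it.

    The build is bitwise reproducible from (params, params.seed).
    """
    chain_seed, sed_seed, pore_seed, place_seed = _seed_streams(params.seed)
    rng = np.random.default_rng(chain_seed)
    system = generate_globular_chains(params, rng=rng)
    sediment(system, params, kernel_seed=sed_seed)
    form_pores(system, params, kernel_seed=pore_seed)
    profile = surface_profile(system)
    place_rng = np.random.default_rng(place_seed)
    place_drug(system, params.nd, profile=profile, rng=place_rng)
    place_solvent(system, params.ns, profile=profile, rng=place_rng)
    return system
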