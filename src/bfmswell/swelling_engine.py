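"""Production swelling simulation.

The built tablet starts with immobile polymer chains; drug and solvent
monomers are mobile from the outset.  A chain is activated — permanently
mobilized — the first time any of its monomers has a solvent monomer in its
nearest-neighbour contact shell (checked at t = 0 and after every accepted
solvent move).  The two varied contact energies follow the relative
hydrophobicity H:

    Ecc = eps0 * H          (chain-chain)
    Ecs = eps0 * (1 - H)    (chain-solvent)

with the other four pair energies zero and eps0 = 0.8 by default.  The run
lasts ``tdis`` attempted Metropolis moves with snapshots (and per-chain
hit-by-solvent-rate bookkeeping) every ``snapshot_interval`` moves.  The
final time t_f = tdis / (Nd + Ns + Nc*Nm) converts the move budget to MC
sweeps (attempted moves per monomer).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import bfm_core as core
from .bfm_core import CHAIN, DRUG, SOLVENT, InteractionTable, seed_kernel_rng

__all__ = [
    "SwellingParams",
    "Trajectory",
    "interactions_from_H",
    "final_time",
    "run_swelling",
]

#: HSR is reported per this many attempted MC moves
HSR_NORM_MOVES = 10**5
#: rendering saturation for the hit-by-solvent rate (contacts per 10^5 moves)
HSR_MAX = 50.0


@dataclass
class SwellingParams:
    """Swelling-run control parameters.

    ``h`` is the relative hydrophobicity; ``tdis`` the attempted-move budget
    (default 10^9, the full-scale study value); snapshots are stored every
    ``snapshot_interval`` attempted moves (default 10^5).
    """

    h: float = 0.0
    eps0: float = 0.8
    tdis: int = 10**9
    snapshot_interval: int = 10**5
    hsr_window: int = 10**5
    seed: int = 0

    def __post_init__(self):
        if self.eps0 <= 0:
            raise ValueError("eps0 must be positive")
        if self.tdis < 0:
            raise ValueError("tdis must be >= 0")
        if self.snapshot_interval <= 0:
            raise ValueError("snapshot_interval must be positive")
        if self.tdis % self.snapshot_interval != 0:
            raise ValueError("snapshot_interval must divide tdis")
        if self.hsr_window % self.snapshot_interval != 0:
            raise ValueError("hsr_window must be a multiple of snapshot_interval")


def interactions_from_H(h, eps0=0.8):
    """Contact energies for relative hydrophobicity ``h``:
    Ecc = eps0*h, Ecs = eps0*(1-h), all other pair energies zero."""
    return InteractionTable(ecc=eps0 * h, ecs=eps0 * (1.0 - h))


def final_time(tdis, nd, ns, nc, nm):
    """Final simulation time in MC sweeps: t_f = tdis / (nd + ns + nc*nm)."""
    total = nd + ns + nc * nm
    if total <= 0:
        raise ValueError("total monomer count must be positive")
    return tdis / total


@dataclass
class Trajectory:
    """Time-stamped snapshots of a swelling run.

    Positions are stored per snapshot; species, chain topology and membership
    are static.  ``chain_active`` and ``hsr`` are per-snapshot, per-chain
    (HSR = chain-solvent contact events per 10^5 attempted moves, accumulated
    over the HSR window at snapshot boundaries).
    """

    stamps: np.ndarray  # (n_snap,) attempted-move counts
    pos: np.ndarray  # (n_snap, n, 2) int32 anchors
    species: np.ndarray  # (n,)
    chain_id: np.ndarray  # (n,)
    index_in_chain: np.ndarray  # (n,)
    chain_active: np.ndarray  # (n_snap, nc) bool
    chain_activation_time: np.ndarray  # (nc,), -1 if never activated
    hsr: np.ndarray  # (n_snap, nc) float
    meta: dict = field(default_factory=dict)

    @property
    def n_snapshots(self):
        return int(self.stamps.size)

    @property
    def n_particles(self):
        return int(self.species.size)

    @property
    def n_chains(self):
        return int(self.chain_active.shape[1])

    @property
    def chain_length(self):
        nc = self.n_chains
        return int(np.count_nonzero(self.species == CHAIN) // nc) if nc else 0

    def activated_fraction(self, snap=-1):
        if self.n_chains == 0:
            return 0.0
        return float(np.count_nonzero(self.chain_active[snap]) / self.n_chains)

    def chain_positions(self, snap):
        """(nc, nm, 2) anchor array for one snapshot (chains are contiguous)."""
        nc, nm = self.n_chains, self.chain_length
        return self.pos[snap, : nc * nm].reshape(nc, nm, 2).astype(np.float64)

    def final_time(self):
        m = self.meta
        return final_time(m["tdis"], m["nd"], m["ns"], m["nc"], m["nm"])


def snapshot_trajectory(system, params=None):
    """A one-snapshot Trajectory of the current system state (t = 0 only;
    chains in solvent contact are marked activated, as at a run start)."""
    if params is None:
        params = SwellingParams(tdis=0)
    nc, nm = _infer_chain_layout(system)
    counts = system.species_counts()
    contacts0 = core._chain_solvent_contacts(
        system.x, system.y, system.species, system.chain_id, system.anchor_grid, max(nc, 1)
    )
    chain_active = (contacts0 > 0)[:nc]
    activation_time = np.where(chain_active, 0, -1).astype(np.int64)
    hsr = contacts0[:nc].astype(np.float64) * (HSR_NORM_MOVES / params.hsr_window)
    meta = {
        "W": system.W,
        "hy": system.hy,
        "nc": nc,
        "nm": nm,
        "nd": counts[DRUG],
        "ns": counts[SOLVENT],
        "h": params.h,
        "eps0": params.eps0,
        "tdis": 0,
        "snapshot_interval": params.snapshot_interval,
        "hsr_window": params.hsr_window,
        "seed": params.seed,
    }
    pos = np.zeros((1, system.n, 2), dtype=np.int32)
    pos[0, :, 0] = system.x
    pos[0, :, 1] = system.y
    return Trajectory(
        stamps=np.zeros(1, dtype=np.int64),
        pos=pos,
        species=system.species.copy(),
        chain_id=system.chain_id.copy(),
        index_in_chain=system.index_in_chain.copy(),
        chain_active=chain_active.reshape(1, nc),
        chain_activation_time=activation_time,
        hsr=hsr.reshape(1, nc),
        meta=meta,
    )


def _infer_chain_layout(system):
    """Chains must occupy ids [c*nm, (c+1)*nm); the builder guarantees it."""
    nc = system.n_chains
    n_chain_monomers = int(np.count_nonzero(system.species == CHAIN))
    if nc == 0:
        return 0, 0
    nm = n_chain_monomers // nc
    expected = np.repeat(np.arange(nc), nm)
    if n_chain_monomers != nc * nm or not np.array_equal(
        system.chain_id[: nc * nm], expected
    ):
        raise ValueError("chain monomers must be contiguous and ordered by chain")
    return nc, nm


def run_swelling(system, params, check_invariants_every=0):
    """Run the swelling simulation on a built tablet and return a Trajectory.

    ``check_invariants_every`` > 0 re-verifies the full steric/bond/occupancy
    invariant suite every that-many snapshots (debug mode).
    """
    counts = system.species_counts()
    if counts[SOLVENT] == 0 and counts[DRUG] == 0:
        raise ValueError("no mobile entities: the system has no solvent or drug")
    nc, nm = _infer_chain_layout(system)
    n = system.n
    etab = interactions_from_H(params.h, params.eps0).matrix()

    chain_active = np.zeros(max(nc, 1), dtype=np.bool_)
    chain_activation_time = np.full(max(nc, 1), -1, dtype=np.int64)

    mobile = np.zeros(n, dtype=np.int64)
    is_mobile = np.zeros(n, dtype=np.bool_)
    free_ids = np.flatnonzero(system.species != CHAIN)
    n_mobile = free_ids.size
    mobile[:n_mobile] = free_ids
    is_mobile[free_ids] = True

    # t = 0 activation sweep: chains already in contact with solvent
    contacts0 = core._chain_solvent_contacts(
        system.x, system.y, system.species, system.chain_id, system.anchor_grid, max(nc, 1)
    )
    for c in range(nc):
        if contacts0[c] > 0:
            chain_active[c] = True
            chain_activation_time[c] = 0
            members = np.arange(c * nm, (c + 1) * nm)
            mobile[n_mobile : n_mobile + nm] = members
            is_mobile[members] = True
            n_mobile += nm

    counters = np.zeros(6, dtype=np.int64)
    counters[0] = n_mobile
    seed_kernel_rng(params.seed)

    n_chunks = params.tdis // params.snapshot_interval
    n_snap = n_chunks + 1
    stamps = np.zeros(n_snap, dtype=np.int64)
    pos = np.zeros((n_snap, n, 2), dtype=np.int32)
    active_hist = np.zeros((n_snap, max(nc, 1)), dtype=np.bool_)
    contact_hist = np.zeros((n_snap, max(nc, 1)), dtype=np.int64)

    def record(k):
        stamps[k] = counters[2]
        pos[k, :, 0] = system.x
        pos[k, :, 1] = system.y
        active_hist[k] = chain_active
        contact_hist[k] = core._chain_solvent_contacts(
            system.x, system.y, system.species, system.chain_id, system.anchor_grid, max(nc, 1)
        )

    record(0)
    for k in range(1, n_snap):
        core._mc_kernel(
            params.snapshot_interval,
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
            max(nm, 1),
            True,
        )
        record(k)
        if check_invariants_every and k % check_invariants_every == 0:
            system.check_invariants()

    hsr = _hsr_from_contacts(contact_hist, params)
    meta = {
        "W": system.W,
        "hy": system.hy,
        "nc": nc,
        "nm": nm,
        "nd": counts[DRUG],
        "ns": counts[SOLVENT],
        "h": params.h,
        "eps0": params.eps0,
        "tdis": params.tdis,
        "snapshot_interval": params.snapshot_interval,
        "hsr_window": params.hsr_window,
        "seed": params.seed,
    }
    return Trajectory(
        stamps=stamps,
        pos=pos,
        species=system.species.copy(),
        chain_id=system.chain_id.copy(),
        index_in_chain=system.index_in_chain.copy(),
        chain_active=active_hist[:, :nc] if nc else active_hist[:, :0],
        chain_activation_time=chain_activation_time[:nc] if nc else chain_activation_time[:0],
        hsr=hsr[:, :nc] if nc else hsr[:, :0],
        meta=meta,
    )


def _hsr_from_contacts(contact_hist, params):
    """Hit-by-solvent rate per chain: contact events accumulated over the HSR
    window at snapshot boundaries, normalized per 10^5 attempted moves."""
    boundaries_per_window = max(params.hsr_window // params.snapshot_interval, 1)
    n_snap = contact_hist.shape[0]
    hsr = np.zeros(contact_hist.shape, dtype=np.float64)
    scale = HSR_NORM_MOVES / params.hsr_window
    for k in range(n_snap):
        lo = max(k - boundaries_per_window + 1, 0)
        window = contact_hist[lo : k + 1]
        hsr[k] = window.sum(axis=0) * scale / max(window.shape[0], 1) * boundaries_per_window
    return hsr
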