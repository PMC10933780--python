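import numpy as np
import pytest

from bfmswell import (
    BuilderParams,
    SwellingParams,
    Trajectory,
    build_tablet,
    run_swelling,
)


@pytest.fixture(scope="session")
def mini_params():
    """An 8-chain tablet small enough for second-scale runs."""
    return BuilderParams(nc=8, nm=10, nd=30, ns=150, width=64, height=64, seed=1)


@pytest.fixture(scope="session")
def mini_tablet(mini_params):
    return build_tablet(mini_params)


@pytest.fixture(scope="session")
def mini_trajectory(mini_tablet):
    params = SwellingParams(h=0.3, tdis=10**6, snapshot_interval=5 * 10**4, seed=1)
    return run_swelling(mini_tablet.copy(), params)


@pytest.fixture
def make_traj():
    return synthetic_trajectory


def synthetic_trajectory(pos, species, chain_id, index_in_chain, chain_active=None,
                         stamps=None, width=64, height=64, meta_extra=None):
    """Assemble a Trajectory from raw arrays (test-only constructor)."""
    pos = np.asarray(pos, dtype=np.int32)
    n_snap = pos.shape[0]
    species = np.asarray(species, dtype=np.int64)
    chain_id = np.asarray(chain_id, dtype=np.int64)
    nc = int(chain_id.max() + 1) if (chain_id >= 0).any() else 0
    if chain_active is None:
        chain_active = np.ones((n_snap, nc), dtype=bool)
    if stamps is None:
        stamps = np.arange(n_snap, dtype=np.int64)
    activation_time = np.zeros(nc, dtype=np.int64)
    meta = {"W": width, "hy": height, "nc": nc,
            "nm": int(np.count_nonzero(species == 0) // nc) if nc else 0,
            "nd": int(np.count_nonzero(species == 1)),
            "ns": int(np.count_nonzero(species == 2)),
            "h": 0.0, "eps0": 0.8, "tdis": int(stamps[-1]),
            "snapshot_interval": 1, "hsr_window": 1, "seed": 0}
    if meta_extra:
        meta.update(meta_extra)
    return Trajectory(
        stamps=np.asarray(stamps, dtype=np.int64),
        pos=pos,
        species=species,
        chain_id=chain_id,
        index_in_chain=np.asarray(index_in_chain, dtype=np.int64),
        chain_active=np.asarray(chain_active, dtype=bool),
        chain_activation_time=activation_time,
        hsr=np.zeros((n_snap, nc)),
        meta=meta,
    )
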