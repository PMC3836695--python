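import numpy as np
import pytest

from cleftsim.core import (IPC, MATRIX, OCC, ContactEnergyTable, LatticeState)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_lattice(rng, width=24, height=20, n_cells=5, with_links=False,
                   lam_area=1.5, lam_perim=0.8):
    """Random multi-cell state: Voronoi-ish seeded blobs in matrix."""
    state = LatticeState(width, height)
    seeds = []
    for i in range(n_cells):
        ctype = OCC if i % 2 == 0 else IPC
        cid = state.new_cell(ctype, target_area=20.0, lam_area=lam_area,
                             target_perim=18.0, lam_perim=lam_perim)
        seeds.append((cid, rng.integers(2, width - 2),
                      rng.integers(2, height - 2)))
    ys, xs = np.mgrid[0:height, 0:width]
    dist = np.full((height, width), np.inf)
    for cid, cx, cy in seeds:
        d = (xs - cx) ** 2 + (ys - cy) ** 2
        take = (d < dist) & (d < 30)
        state.owner[take] = cid
        dist[take] = d[take]
    state.owner[0, :] = 0
    state.owner[-1, :] = 0
    state.owner[:, 0] = 0
    state.owner[:, -1] = 0
    state.refresh_cache()
    if with_links:
        from cleftsim.core import FppLink
        alive = [c for c in state.cell_ids() if c != 0]
        for a, b in zip(alive, alive[1:]):
            state.add_link(FppLink(int(a), int(b), 5.0,
                                   float(rng.uniform(2, 10)), "lateral_occ"))
    return state


def random_table(rng, neighbor_order=2):
    n = 6
    J = rng.uniform(1, 10, size=(n, n))
    J = (J + J.T) / 2
    J[0, 0] = 0.0
    return ContactEnergyTable(J, neighbor_order=neighbor_order)


@pytest.fixture
def small_state(rng):
    return random_lattice(rng)
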