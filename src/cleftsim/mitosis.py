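"""Cell proliferation: selection, growth and division on a 100-MCS cycle.

At each cycle boundary a deterministic count of epithelial cells
(round-half-up on rate * population) is flagged mitotic, split between
the outer columnar and inner polymorphic compartments by the configured
fraction.  Flagged cells double their target area (and scale the target
perimeter by sqrt(2)); the area constraint grows them over the following
cycle, after which they are split into two equal connected halves along
a random axis through the centroid.  Daughters are re-typed by location:
matrix-touching daughters become OCC, interior daughters IPC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import CLEFT_TYPES, IPC, MATRIX, MITOTIC, OCC, LatticeState

logger = logging.getLogger(__name__)

_SQRT2 = float(np.sqrt(2.0))


@dataclass
class MitosisSchedule:
    """Mitosis bookkeeping: rate, compartment split, and pending flags."""

    rate: float = 1.0              # % of epithelial cells per cycle
    occ_fraction: float = 50.0     # % of the mitotic draw taken from OCC
    cycle_length: int = 100        # MCS between division rounds
    include_cleft: bool = False    # cleft-wall cells keep the link topology
    mode: str = "expected"         # 'expected' (rounded count) or 'bernoulli'
    completion_slack: float = 4.0  # px^2 short of 2x area still divides
    pending: dict[int, tuple[int, int]] = field(default_factory=dict)
    events: list[tuple] = field(default_factory=list)  # (mcs, parent, d1, d2)

    def __post_init__(self):
        if not 0 <= self.occ_fraction <= 100:
            raise ValueError("occ_fraction must be in [0, 100]")
        if self.rate < 0:
            raise ValueError("rate must be >= 0")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def select_mitotic(state: LatticeState, schedule: MitosisSchedule,
                   rng: np.random.Generator) -> list[int]:
    """Flag this cycle's mitotic cells and double their target area.

    Returns the selected cell ids.  Matrix and (by default) cleft-wall
    cells are never eligible; if a compartment cannot supply its share
    the shortfall is taken as-is and logged.
    """
    occ_pool = list(state.cell_ids(types=(OCC,)))
    ipc_pool = list(state.cell_ids(types=(IPC,)))
    extra = (list(state.cell_ids(types=CLEFT_TYPES))
             if schedule.include_cleft else [])
    ipc_pool += extra
    occ_pool = [c for c in occ_pool if c not in schedule.pending]
    ipc_pool = [c for c in ipc_pool if c not in schedule.pending]
    n_epith = len(occ_pool) + len(ipc_pool) + len(schedule.pending)
    if schedule.mode == "bernoulli":
        p = schedule.rate / 100.0
        chosen = [c for c in occ_pool + ipc_pool if rng.random() < p]
    else:
        # floor + Bernoulli on the fractional part: unbiased at small
        # populations, where plain rounding would bias the realized rate
        k_float = schedule.rate * n_epith / 100.0
        k = int(np.floor(k_float))
        if rng.random() < k_float - k:
            k += 1
        k_occ = _round_half_up(schedule.occ_fraction * k / 100.0)
        k_ipc = k - k_occ
        if k_occ > len(occ_pool):
            logger.warning("requested %d OCC mitotic cells, only %d available",
                           k_occ, len(occ_pool))
            k_occ = len(occ_pool)
        if k_ipc > len(ipc_pool):
            logger.warning("requested %d IPC mitotic cells, only %d available",
                           k_ipc, len(ipc_pool))
            k_ipc = len(ipc_pool)
        chosen = []
        if k_occ:
            chosen += [int(c) for c in rng.choice(occ_pool, size=k_occ,
                                                  replace=False)]
        if k_ipc:
            chosen += [int(c) for c in rng.choice(ipc_pool, size=k_ipc,
                                                  replace=False)]
    for cid in chosen:
        schedule.pending[cid] = (int(state.area[cid]), int(state.ctype[cid]))
        state.ctype[cid] = MITOTIC
        state.target_area[cid] *= 2.0
        state.target_perim[cid] *= _SQRT2
    return chosen


def divide(state: LatticeState, cell_id: int,
           rng: np.random.Generator) -> tuple[int, int]:
    """Split a grown cell into two equal halves along a random axis.

    The parent keeps its id for one half; the other half becomes a new
    cell.  Both daughters revert to the parent's original targets and are
    re-typed by location (OCC if touching matrix, else IPC).  Lateral
    boundary links of an OCC parent follow the matrix-touching daughter.
    """
    sites = state.sites_of(cell_id)
    if len(sites) < 2:
        raise ValueError(f"cell {cell_id} too small to divide")
    theta = rng.random() * np.pi
    axis = np.array([np.cos(theta), np.sin(theta)])
    proj = (sites - sites.mean(axis=0)) @ axis
    order = np.lexsort((sites[:, 0], sites[:, 1], proj))
    half = len(sites) // 2
    sites_b = sites[order[half:]]
    daughter = state.new_cell(state.ctype[cell_id],
                              state.target_area[cell_id],
                              state.lam_area[cell_id],
                              state.target_perim[cell_id],
                              state.lam_perim[cell_id])
    state.owner[sites_b[:, 1], sites_b[:, 0]] = daughter
    _refresh_two(state, cell_id, daughter)
    return cell_id, daughter


def _refresh_two(state: LatticeState, a: int, b: int) -> None:
    """Recompute caches for two cells from the grid (local, exact)."""
    for cid in (a, b):
        mask = state.owner == cid
        ys, xs = np.nonzero(mask)
        state.area[cid] = len(xs)
        state.sum_x[cid] = xs.sum()
        state.sum_y[cid] = ys.sum()
        p = 0
        o = state.owner
        for dy, dx in ((0, 1), (1, 0)):
            s1 = o[dy:, dx:] if (dy or dx) else o
            s2 = o[: o.shape[0] - dy, : o.shape[1] - dx]
            p += int(np.sum((s1 == cid) & (s2 != cid)))
            p += int(np.sum((s2 == cid) & (s1 != cid)))
        state.perim[cid] = p


def _touches_matrix(state: LatticeState, cid: int) -> bool:
    o = state.owner
    mask = o == cid
    for dy, dx in ((0, 1), (1, 0)):
        a = o[dy:, dx:] if (dy or dx) else o
        m1 = mask[dy:, dx:]
        b = o[: o.shape[0] - dy, : o.shape[1] - dx]
        m2 = mask[: o.shape[0] - dy, : o.shape[1] - dx]
        if np.any(m1 & (b == 0)) or np.any(m2 & (a == 0)):
            return True
    return False


class MitosisHook:
    """MCS hook running the grow-and-divide cycle every ``cycle_length`` MCS."""

    def __init__(self, schedule: MitosisSchedule, rng: np.random.Generator):
        self.schedule = schedule
        self.rng = rng
        self.cadence = schedule.cycle_length

    def __call__(self, state: LatticeState) -> None:
        sched = self.schedule
        # 1. divide cells flagged in the previous cycle that completed growth
        for cid, (orig_area, orig_type) in list(sched.pending.items()):
            if state.area[cid] == 0:
                del sched.pending[cid]  # fluctuated away before dividing
                continue
            if state.area[cid] < 2 * orig_area - sched.completion_slack:
                logger.info("division of cell %d deferred at MCS %d "
                            "(area %d < 2x%d)", cid, state.step,
                            state.area[cid], orig_area)
                continue
            pa, pb = divide(state, cid, self.rng)
            for d in (pa, pb):
                state.target_area[d] = float(orig_area)
                touches = _touches_matrix(state, d)
                state.ctype[d] = OCC if touches else IPC
                cfg = state.meta.get("config")
                if cfg is not None:
                    state.target_perim[d] = (cfg.occ_perimeter_target if touches
                                             else cfg.ipc_perimeter_target)
                else:
                    state.target_perim[d] /= _SQRT2
            if orig_type == OCC and state.links:
                keeper = pa if _touches_matrix(state, pa) else pb
                other = pb if keeper == pa else pa
                for link in state.links:
                    if link.cell_a == other:
                        link.cell_a = keeper
                    if link.cell_b == other:
                        link.cell_b = keeper
                state.links = [l for l in state.links
                               if l.cell_a != l.cell_b]
                state.invalidate_links()
            del sched.pending[cid]
            sched.events.append((state.step, cid, pa, pb))
        # 2. flag the next round
        select_mitotic(state, sched, self.rng)
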