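"""Lattice engine for the 2D Glazier-Graner-Hogeweg (cellular Potts) model.

A tissue is a grid of integer cell identifiers plus per-cell bookkeeping
(type, area, perimeter, centroid, constraint strengths).  The effective
energy is the sum of four terms:

* contact energy ``J(tau_a, tau_b)`` over neighbouring site pairs that
  belong to different cells (differential adhesion),
* an area constraint ``lambda_a (a - A)^2`` per cell,
* a perimeter constraint ``lambda_p (p - P)^2`` per cell,
* focal point plasticity, a spring term ``lambda (l - L)^2`` over linked
  cell pairs measured between centroids (used to represent actomyosin
  contractility).

Dynamics are Metropolis copy attempts: a random interior site is
overwritten by a random neighbour's identifier with probability
``min(1, exp(-dH / T))``.  One Monte Carlo step (MCS) is ``width*height``
attempts.  The matrix compartment (cell 0) carries no area or perimeter
constraint and a one-site frame around the lattice is frozen so that the
matrix cannot wrap around grid edges.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from . import _kernels

# Cell types (indices into the contact-energy matrix).  The two cleft
# walls are distinct types so that contact energies and link topology can
# distinguish the seam between opposing walls (where the adhesion loss of
# the localized EMT acts) from cohesion within a wall.
MATRIX, OCC, IPC, CLEFT, MITOTIC, CLEFT_R = 0, 1, 2, 3, 4, 5
CLEFT_TYPES = (CLEFT, CLEFT_R)
N_TYPES = 6
TYPE_NAMES = ("MATRIX", "OCC", "IPC", "CLEFT", "MITOTIC", "CLEFT_R")

_OFFSETS_1 = np.array([(1, 0), (-1, 0), (0, 1), (0, -1)], dtype=np.int64)
_OFFSETS_2 = np.array(
    [(1, 0), (-1, 0), (0, 1), (0, -1), (1, 1), (1, -1), (-1, 1), (-1, -1)],
    dtype=np.int64,
)


def neighborhood_offsets(order: int) -> np.ndarray:
    """(dx, dy) offsets of the order-1 (4-site) or order-2 (8-site) neighbourhood."""
    if order == 1:
        return _OFFSETS_1
    if order == 2:
        return _OFFSETS_2
    raise ValueError(f"unsupported neighbourhood order {order}")


class ContactEnergyTable:
    """Symmetric contact-energy matrix J(tau_a, tau_b) over the five cell types."""

    def __init__(self, J: np.ndarray | None = None, neighbor_order: int = 2):
        if J is None:
            J = np.zeros((N_TYPES, N_TYPES))
        J = np.asarray(J, dtype=float)
        if J.shape != (N_TYPES, N_TYPES):
            raise ValueError(f"J must be {N_TYPES}x{N_TYPES}")
        if not np.allclose(J, J.T):
            raise ValueError("contact energies must be symmetric")
        self.J = J.copy()
        self.neighbor_order = neighbor_order

    def set(self, ta: int, tb: int, value: float) -> None:
        self.J[ta, tb] = value
        self.J[tb, ta] = value

    def get(self, ta: int, tb: int) -> float:
        return float(self.J[ta, tb])

    def copy(self) -> "ContactEnergyTable":
        return ContactEnergyTable(self.J, self.neighbor_order)


@dataclass
class FppLink:
    """Elastic link between two cells: energy ``lambda (l - L)^2``."""

    cell_a: int
    cell_b: int
    lambda_fpp: float
    target_length: float
    orientation: str = "lateral_occ"  # lateral_occ | lateral_cleft | vertical_cleft
    rank: int = 0        # depth rank for cleft links (0 = mouth)
    cleft_index: int = 0  # which cleft the link belongs to

    def __post_init__(self):
        if self.cell_a == self.cell_b:
            raise ValueError("a link must join two distinct cells")
        if self.target_length < 0 or self.lambda_fpp < 0:
            raise ValueError("link target length and lambda must be >= 0")


@dataclass
class DynamicsParams:
    """Metropolis parameters: T is the fluctuation amplitude (default 10)."""

    temperature: float = 10.0
    mcs_limit: int = 1500
    rng_seed: int = 0
    copy_neighbor_order: int = 1

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


class CellRecord:
    """Read-mostly view of one cell's bookkeeping inside a LatticeState."""

    __slots__ = ("_s", "id")

    def __init__(self, state: "LatticeState", cid: int):
        self._s = state
        self.id = cid

    @property
    def type(self) -> int:
        return int(self._s.ctype[self.id])

    @property
    def area(self) -> int:
        return int(self._s.area[self.id])

    @property
    def target_area(self) -> float:
        return float(self._s.target_area[self.id])

    @property
    def lambda_area(self) -> float:
        return float(self._s.lam_area[self.id])

    @property
    def perimeter(self) -> int:
        return int(self._s.perim[self.id])

    @property
    def target_perimeter(self) -> float:
        return float(self._s.target_perim[self.id])

    @property
    def lambda_perimeter(self) -> float:
        return float(self._s.lam_perim[self.id])

    @property
    def centroid(self) -> tuple[float, float]:
        a = self._s.area[self.id]
        if a == 0:
            return (float("nan"), float("nan"))
        return (self._s.sum_x[self.id] / a, self._s.sum_y[self.id] / a)

    @property
    def alive(self) -> bool:
        return self._s.area[self.id] > 0

    @property
    def constrained(self) -> bool:
        return self.type != MATRIX


class LatticeState:
    """Owner grid plus per-cell caches; the simulation's single source of truth.

    ``owner[y, x]`` maps every lattice site to a cell id; cell 0 is the
    matrix compartment and initially owns the whole grid.
    """

    def __init__(self, width: int, height: int):
        self.width = int(width)
        self.height = int(height)
        self.owner = np.zeros((self.height, self.width), dtype=np.int32)
        self.step = 0
        n0 = 64
        self.ctype = np.zeros(n0, dtype=np.int8)
        self.area = np.zeros(n0, dtype=np.int64)
        self.target_area = np.zeros(n0, dtype=np.float64)
        self.lam_area = np.zeros(n0, dtype=np.float64)
        self.perim = np.zeros(n0, dtype=np.int64)
        self.target_perim = np.zeros(n0, dtype=np.float64)
        self.lam_perim = np.zeros(n0, dtype=np.float64)
        self.sum_x = np.zeros(n0, dtype=np.float64)
        self.sum_y = np.zeros(n0, dtype=np.float64)
        self.n_cells = 1  # matrix
        self.ctype[0] = MATRIX
        self.links: list[FppLink] = []
        self._link_cache: tuple | None = None
        self.meta: dict = {}
        self.refresh_cache()

    # -- cell management -------------------------------------------------
    def _grow(self, n: int) -> None:
        cap = len(self.ctype)
        if n <= cap:
            return
        new = max(2 * cap, n)
        for name in ("ctype", "area", "target_area", "lam_area", "perim",
                     "target_perim", "lam_perim", "sum_x", "sum_y"):
            arr = getattr(self, name)
            out = np.zeros(new, dtype=arr.dtype)
            out[:cap] = arr
            setattr(self, name, out)

    def new_cell(self, ctype: int, target_area: float = 0.0,
                 lam_area: float = 0.0, target_perim: float = 0.0,
                 lam_perim: float = 0.0) -> int:
        cid = self.n_cells
        self._grow(cid + 1)
        self.n_cells += 1
        self.ctype[cid] = ctype
        self.target_area[cid] = target_area
        self.lam_area[cid] = lam_area
        self.target_perim[cid] = target_perim
        self.lam_perim[cid] = lam_perim
        self._link_cache = None
        return cid

    def cell(self, cid: int) -> CellRecord:
        if cid < 0 or cid >= self.n_cells:
            raise KeyError(f"no cell {cid}")
        return CellRecord(self, cid)

    def cells(self) -> Iterable[CellRecord]:
        for cid in range(self.n_cells):
            yield CellRecord(self, cid)

    def cell_ids(self, types: Sequence[int] | None = None,
                 alive_only: bool = True) -> np.ndarray:
        ids = np.arange(self.n_cells)
        keep = np.ones(self.n_cells, dtype=bool)
        if alive_only:
            keep &= self.area[: self.n_cells] > 0
        if types is not None:
            keep &= np.isin(self.ctype[: self.n_cells], list(types))
        return ids[keep]

    def sites_of(self, cid: int) -> np.ndarray:
        """(n, 2) array of (x, y) site coordinates owned by a cell."""
        ys, xs = np.nonzero(self.owner == cid)
        return np.column_stack([xs, ys])

    # -- links -----------------------------------------------------------
    def add_link(self, link: FppLink) -> None:
        for cid in (link.cell_a, link.cell_b):
            if cid < 0 or cid >= self.n_cells:
                raise ValueError(f"link references unknown cell {cid}")
        self.links.append(link)
        self._link_cache = None

    def clear_links(self) -> None:
        self.links = []
        self._link_cache = None

    def invalidate_links(self) -> None:
        """Must be called after mutating link targets or endpoints in place."""
        self._link_cache = None

    def link_arrays(self):
        """CSR view of the link set keyed by cell id (built lazily)."""
        if self._link_cache is None:
            n = len(self.links)
            la = np.array([l.cell_a for l in self.links], dtype=np.int32)
            lb = np.array([l.cell_b for l in self.links], dtype=np.int32)
            lam = np.array([l.lambda_fpp for l in self.links], dtype=np.float64)
            L = np.array([l.target_length for l in self.links], dtype=np.float64)
            counts = np.zeros(self.n_cells + 1, dtype=np.int64)
            for i in range(n):
                counts[la[i] + 1] += 1
                counts[lb[i] + 1] += 1
            ptr = np.cumsum(counts)
            idx = np.zeros(ptr[-1], dtype=np.int64)
            fill = ptr[:-1].copy()
            for i in range(n):
                idx[fill[la[i]]] = i
                fill[la[i]] += 1
                idx[fill[lb[i]]] = i
                fill[lb[i]] += 1
            self._link_cache = (ptr, idx, la, lb, lam, L)
        return self._link_cache

    # -- cache maintenance and validation --------------------------------
    def recount_areas(self) -> np.ndarray:
        return np.bincount(self.owner.ravel(), minlength=self.n_cells)[: self.n_cells]

    def recount_perimeters(self) -> np.ndarray:
        """Edge-count perimeter: unit edges between a cell and other owners."""
        p = np.zeros(self.n_cells, dtype=np.int64)
        o = self.owner
        for axis in (0, 1):
            a = np.take(o, range(o.shape[axis] - 1), axis=axis)
            b = np.take(o, range(1, o.shape[axis]), axis=axis)
            mism = a != b
            np.add.at(p, a[mism], 1)
            np.add.at(p, b[mism], 1)
        return p

    def recount_centroid_sums(self) -> tuple[np.ndarray, np.ndarray]:
        ys, xs = np.mgrid[0: self.height, 0: self.width]
        sx = np.bincount(self.owner.ravel(), weights=xs.ravel(),
                         minlength=self.n_cells)[: self.n_cells]
        sy = np.bincount(self.owner.ravel(), weights=ys.ravel(),
                         minlength=self.n_cells)[: self.n_cells]
        return sx, sy

    def refresh_cache(self) -> None:
        """Recompute areas, perimeters and centroid sums from the owner grid."""
        n = self.n_cells
        self.area[:n] = self.recount_areas()
        self.perim[:n] = self.recount_perimeters()
        sx, sy = self.recount_centroid_sums()
        self.sum_x[:n] = sx
        self.sum_y[:n] = sy

    def validate(self, tol: float = 1e-9) -> None:
        """Raise if any cached quantity disagrees with a full recount."""
        n = self.n_cells
        if self.owner.min() < 0 or self.owner.max() >= n:
            raise AssertionError("owner grid references a non-existent cell")
        if not np.array_equal(self.area[:n], self.recount_areas()):
            raise AssertionError("cached areas disagree with recount")
        if not np.array_equal(self.perim[:n], self.recount_perimeters()):
            raise AssertionError("cached perimeters disagree with recount")
        sx, sy = self.recount_centroid_sums()
        if not (np.allclose(self.sum_x[:n], sx, atol=tol)
                and np.allclose(self.sum_y[:n], sy, atol=tol)):
            raise AssertionError("cached centroid sums disagree with recount")
        for l in self.links:
            if self.area[l.cell_a] == 0 or self.area[l.cell_b] == 0:
                raise AssertionError(
                    f"dangling link {l.cell_a}-{l.cell_b}: endpoint has no sites")

    def copy(self) -> "LatticeState":
        return _copy.deepcopy(self)

    def fragment_counts(self) -> dict[int, int]:
        """Connected components (8-conn) per live non-matrix cell; >1 = fragmented."""
        from scipy import ndimage
        out = {}
        struct = np.ones((3, 3), dtype=bool)
        for cid in self.cell_ids():
            if cid == 0:
                continue
            _, ncomp = ndimage.label(self.owner == cid, structure=struct)
            out[int(cid)] = int(ncomp)
        return out


# ---------------------------------------------------------------------------
# Hamiltonian terms
# ---------------------------------------------------------------------------

def contact_energy(state: LatticeState, table: ContactEnergyTable) -> float:
    """Sum of J(tau_i, tau_j) over unordered neighbouring hetero-cell site pairs."""
    o = state.owner
    t = state.ctype[o]
    total = 0.0
    half = [(0, 1), (1, 0)] if table.neighbor_order == 1 else \
           [(0, 1), (1, 0), (1, 1), (1, -1)]
    for dy, dx in half:
        h, w = o.shape
        ys = slice(max(dy, 0), h + min(dy, 0))
        xs = slice(max(dx, 0), w + min(dx, 0))
        ys2 = slice(max(-dy, 0), h + min(-dy, 0))
        xs2 = slice(max(-dx, 0), w + min(-dx, 0))
        a, b = o[ys, xs], o[ys2, xs2]
        mism = a != b
        total += table.J[t[ys, xs][mism], t[ys2, xs2][mism]].sum()
    return float(total)


def area_energy(cell: CellRecord) -> float:
    """``lambda_a (a - A)^2`` for constrained cells; 0 for the matrix."""
    if cell.type == MATRIX:
        return 0.0
    return cell.lambda_area * (cell.area - cell.target_area) ** 2


def perimeter_energy(cell: CellRecord) -> float:
    """``lambda_p (p - P)^2`` for constrained cells; 0 for the matrix."""
    if cell.type == MATRIX:
        return 0.0
    return cell.lambda_perimeter * (cell.perimeter - cell.target_perimeter) ** 2


def fpp_energy(state: LatticeState) -> float:
    """Sum of ``lambda (l - L)^2`` over links; l is the centroid distance."""
    total = 0.0
    for l in state.links:
        if state.area[l.cell_a] == 0 or state.area[l.cell_b] == 0:
            raise ValueError(
                f"dangling link {l.cell_a}-{l.cell_b}: endpoint cell is dead")
        ax, ay = state.cell(l.cell_a).centroid
        bx, by = state.cell(l.cell_b).centroid
        d = float(np.hypot(ax - bx, ay - by))
        total += l.lambda_fpp * (d - l.target_length) ** 2
    return total


def total_energy(state: LatticeState, table: ContactEnergyTable) -> float:
    """Full Hamiltonian: contact + area + perimeter + focal point plasticity."""
    e = contact_energy(state, table)
    for cid in range(state.n_cells):
        if state.area[cid] == 0:
            continue
        c = state.cell(cid)
        e += area_energy(c) + perimeter_energy(c)
    e += fpp_energy(state)
    return e


def delta_energy(state: LatticeState, table: ContactEnergyTable,
                 source_site: tuple[int, int],
                 target_site: tuple[int, int]) -> float:
    """Exact change in total_energy if the target site were overwritten
    by the source site's owner (0 for a same-owner pair)."""
    sx, sy = source_site
    tx, ty = target_site
    ptr, idx, la, lb, lam, L = state.link_arrays()
    return float(_kernels._delta_H(
        state.owner, state.ctype, state.area, state.target_area,
        state.lam_area, state.perim, state.target_perim, state.lam_perim,
        state.sum_x, state.sum_y, table.J,
        neighborhood_offsets(table.neighbor_order),
        ptr, idx, la, lb, lam, L, sx, sy, tx, ty))


# ---------------------------------------------------------------------------
# Dynamics
# ---------------------------------------------------------------------------

def attempt_copy(state: LatticeState, table: ContactEnergyTable,
                 params: DynamicsParams, rng: np.random.Generator,
                 detail: bool = False):
    """One Metropolis copy attempt; returns True if the copy was accepted.

    With ``detail=True`` returns ``(accepted, dH)`` instead (dH is None
    for a same-owner draw), which lets callers verify the acceptance law.
    """
    copy_off = neighborhood_offsets(params.copy_neighbor_order)
    tx = 1 + int(rng.random() * (state.width - 2))
    ty = 1 + int(rng.random() * (state.height - 2))
    k = int(rng.random() * len(copy_off))
    sx, sy = tx + int(copy_off[k, 0]), ty + int(copy_off[k, 1])
    so = state.owner[sy, sx]
    if so == state.owner[ty, tx]:
        return (False, None) if detail else False
    dH = delta_energy(state, table, (sx, sy), (tx, ty))
    accepted = dH <= 0.0 or rng.random() < np.exp(-dH / params.temperature)
    if accepted:
        _kernels._apply_copy(state.owner, state.area, state.perim,
                             state.sum_x, state.sum_y, tx, ty, so)
    return (accepted, dH) if detail else accepted


def run_mcs(state: LatticeState, table: ContactEnergyTable,
            params: DynamicsParams, n_steps: int,
            hooks: Sequence[Callable] = (),
            rng: np.random.Generator | None = None,
            log: list | None = None) -> LatticeState:
    """Advance the simulation by ``n_steps`` MCS (width*height attempts each).

    ``hooks`` are callables invoked as ``hook(state)`` after every MCS
    whose index is a multiple of ``hook.cadence`` (default 1).  All
    randomness flows through ``rng`` (seeded from params if omitted).
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    contact_off = neighborhood_offsets(table.neighbor_order)
    copy_off = neighborhood_offsets(params.copy_neighbor_order)
    n_attempts = state.width * state.height
    for _ in range(n_steps):
        ptr, idx, la, lb, lam, L = state.link_arrays()
        accepted = _kernels._run_attempts(
            state.owner, state.ctype, state.area, state.target_area,
            state.lam_area, state.perim, state.target_perim, state.lam_perim,
            state.sum_x, state.sum_y, table.J, contact_off, copy_off,
            ptr, idx, la, lb, lam, L,
            params.temperature, n_attempts, rng)
        state.step += 1
        if log is not None:
            log.append({"mcs": state.step, "accepted": int(accepted),
                        "attempts": n_attempts})
        for hook in hooks:
            cadence = getattr(hook, "cadence", 1)
            if state.step % cadence == 0:
                try:
                    hook(state)
                except Exception as exc:  # surface the MCS index
                    raise RuntimeError(
                        f"hook {hook!r} failed at MCS {state.step}") from exc
    return state


class EnergyLogger:
    """MCS hook recording per-term energies and totals."""

    def __init__(self, table: ContactEnergyTable, cadence: int = 10):
        self.table = table
        self.cadence = cadence
        self.records: list[dict] = []

    def __call__(self, state: LatticeState) -> None:
        c = contact_energy(state, self.table)
        a = sum(area_energy(state.cell(i)) for i in state.cell_ids())
        p = sum(perimeter_energy(state.cell(i)) for i in state.cell_ids())
        f = fpp_energy(state)
        self.records.append({"mcs": state.step, "contact": c, "area": a,
                             "perimeter": p, "fpp": f, "total": c + a + p + f})
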