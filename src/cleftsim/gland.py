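"""Initial configurations of the salivary-gland cleft model.

Builds the single-cleft and three-cleft (organ-level) epithelium, assigns
cell types (outer columnar cells, inner polymorphic cells, cleft-wall
cells, matrix), wires the focal-point-plasticity link topology with
depth-dependent target distances, and packages the named parameter sets
used throughout the study (base, ROCK-knockdown mimic, blebbistatin
mimic, no-FPP ablation).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (CLEFT, CLEFT_R, CLEFT_TYPES, IPC, MATRIX, MITOTIC, OCC,
                   ContactEnergyTable,
                   DynamicsParams, FppLink, LatticeState, run_mcs)


@dataclass
class WidthDepthRule:
    """Target lateral cleft width as a function of depth: W = num/(D+off) - sub.

    Derived from segmented ex-vivo cleft profiles; strictly decreasing in
    D, clamped below at ``floor`` so targets never go negative.
    """

    numerator: float = 402.0
    offset: float = 11.0
    subtrahend: float = 5.0
    floor: float = 8.0

    def __call__(self, depth: float) -> float:
        return max(self.numerator / (depth + self.offset) - self.subtrahend,
                   self.floor)


@dataclass
class ParameterSet:
    """One named experimental condition of the cleft model."""

    name: str = "base"
    mitosis_rate: float = 1.0          # % of epithelial cells per 100-MCS cycle
    occ_mitosis_fraction: float = 50.0  # % of mitotic cells placed in the OCC layer
    fpp_lambda_cleft: float = 10.0     # lateral cleft links (the swept knob)
    fpp_lambda_vertical: float = 10.0  # vertical intra-wall links (fixed)
    fpp_lambda_occ: float = 10.0
    cc_cleft: float = 10.0              # cleft-wall cell-cell contact energy
    cm_cleft: float = 3.0               # cleft cell-matrix contact energy
    fpp_enabled: bool = True

    def __post_init__(self):
        for v in (self.mitosis_rate, self.fpp_lambda_cleft,
                  self.fpp_lambda_vertical, self.fpp_lambda_occ,
                  self.cc_cleft, self.cm_cleft):
            if v < 0:
                raise ValueError("parameter values must be >= 0")
        if not 0 <= self.occ_mitosis_fraction <= 100:
            raise ValueError("occ_mitosis_fraction must be in [0, 100]")


_PRESETS = {
    "base": ParameterSet("base"),
    # ROCK-I knockdown mimic: reduced cleft contractility plus halved mitosis.
    "rock_kd": ParameterSet("rock_kd", mitosis_rate=0.5, fpp_lambda_cleft=1.0),
    # Blebbistatin mimic: contractility alone is reduced.
    "blebbistatin": ParameterSet("blebbistatin", fpp_lambda_cleft=1.0),
    # Ablation: no focal-point-plasticity links at all.
    "no_fpp": ParameterSet("no_fpp", fpp_enabled=False),
}


def preset(name: str) -> ParameterSet:
    """Named parameter sets: base, rock_kd, blebbistatin, no_fpp."""
    try:
        return replace(_PRESETS[name])
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; "
                       f"choose from {sorted(_PRESETS)}") from None


@dataclass
class GlandConfig:
    """Geometry and baseline energies of the model epithelium.

    Cells are ``cell_side`` x ``cell_side`` squares on a regular grid; the
    cleft wall is ``cleft_wall_cells`` cells deep so the designed total
    cleft depth is their product (6 * 6 = 36 px).  Baseline contact
    energies encode the epithelial ordering: OCC-OCC below the epithelial
    baseline (stronger adhesion), IPC-IPC above it, and IPC-matrix well
    above OCC-matrix so the inner cells stay interior.
    """

    cell_side: int = 6
    cleft_wall_cells: int = 6
    cleft_depth_target: int = 36
    epithelium_rows: int = 10
    epithelium_cols: int = 15
    lattice_width: int = 160
    lattice_height: int = 124
    target_area: float = 36.0
    lambda_area: float = 8.0
    occ_perimeter_target: float = 24.0
    ipc_perimeter_target: float = 28.0
    cleft_perimeter_target: float = 24.0
    lambda_perimeter: float = 2.0
    cleft_lambda_perimeter: float = 2.0
    j_baseline: float = 5.0
    j_occ_occ: float = 4.0
    j_ipc_ipc: float = 6.0
    j_occ_matrix: float = 4.0
    j_ipc_matrix: float = 12.0
    notch_width: int = 2     # initiated indentation, clamped W(0)
    contact_neighbor_order: int = 2
    n_clefts: int = 1
    organ_cleft_spacing_cells: int = 10

    def __post_init__(self):
        if self.cleft_wall_cells * self.cell_side != self.cleft_depth_target:
            raise ValueError("cleft_wall_cells * cell_side must equal "
                             "cleft_depth_target")
        if self.epithelium_cols * self.cell_side + 2 > self.lattice_width or \
           self.epithelium_rows * self.cell_side + 2 > self.lattice_height:
            raise ValueError("lattice too small for the configured epithelium")
        if self.n_clefts not in (1, 3):
            raise ValueError("n_clefts must be 1 or 3")

    def contact_table(self, params: ParameterSet) -> ContactEnergyTable:
        """Contact-energy matrix for a parameter set.

        Mitotic cells keep the epithelial baseline so flagging a cell for
        division does not perturb its adhesion.
        """
        t = ContactEnergyTable(neighbor_order=self.contact_neighbor_order)
        b = self.j_baseline
        for ta, tb in itertools.combinations_with_replacement(
                (OCC, IPC, CLEFT, MITOTIC, CLEFT_R), 2):
            t.set(ta, tb, b)
        t.set(OCC, OCC, self.j_occ_occ)
        t.set(IPC, IPC, self.j_ipc_ipc)
        t.set(MATRIX, MATRIX, 0.0)
        t.set(OCC, MATRIX, self.j_occ_matrix)
        t.set(IPC, MATRIX, self.j_ipc_matrix)
        t.set(MITOTIC, MATRIX, self.j_occ_matrix)
        # the swept cleft cell-cell energy acts across the seam between
        # the two opposing walls; within a wall cohesion stays at baseline
        t.set(CLEFT, CLEFT_R, params.cc_cleft)
        t.set(CLEFT, MATRIX, params.cm_cleft)
        t.set(CLEFT_R, MATRIX, params.cm_cleft)
        return t


def _epithelium_origin(config: GlandConfig) -> tuple[int, int]:
    ew = config.epithelium_cols * config.cell_side
    eh = config.epithelium_rows * config.cell_side
    x0 = (config.lattice_width - ew) // 2
    y0 = (config.lattice_height - eh) // 2
    return x0, y0


def _carve_cleft(state: LatticeState, config: GlandConfig, x0: int, y0: int,
                 grid_ids: np.ndarray, wall_left_col: int,
                 cleft_index: int) -> dict:
    """Retype two facing cell columns as CLEFT and carve the initiated notch."""
    side = config.cell_side
    wall = config.cleft_wall_cells
    left_ids, right_ids = [], []
    for r in range(wall):
        left_ids.append(int(grid_ids[r, wall_left_col]))
        right_ids.append(int(grid_ids[r, wall_left_col + 1]))
    for cid in left_ids:
        state.ctype[cid] = CLEFT
    for cid in right_ids:
        state.ctype[cid] = CLEFT_R
    for cid in left_ids + right_ids:
        state.target_perim[cid] = config.cleft_perimeter_target
        state.lam_perim[cid] = config.cleft_lambda_perimeter
    # Initiated indentation: a notch_width-wide matrix finger one
    # cell-side deep between the topmost cleft pair.
    xc = x0 + (wall_left_col + 1) * side
    half = config.notch_width // 2
    state.owner[y0: y0 + side, xc - half: xc - half + config.notch_width] = 0
    return {"left": left_ids, "right": right_ids, "mouth_x": xc,
            "surface_y": y0, "index": cleft_index,
            "x_window": (xc - 3 * side, xc + 3 * side)}


def _build_epithelium(state: LatticeState, config: GlandConfig,
                      x0: int, y0: int, rows: int, cols: int) -> np.ndarray:
    """Lay down a rows x cols grid of square cells; boundary OCC, interior IPC."""
    side = config.cell_side
    grid_ids = np.zeros((rows, cols), dtype=np.int64)
    for r in range(rows):
        for c in range(cols):
            boundary = r in (0, rows - 1) or c in (0, cols - 1)
            ctype = OCC if boundary else IPC
            tp = (config.occ_perimeter_target if ctype == OCC
                  else config.ipc_perimeter_target)
            cid = state.new_cell(ctype, config.target_area, config.lambda_area,
                                 tp, config.lambda_perimeter)
            ys, xs = y0 + r * side, x0 + c * side
            state.owner[ys: ys + side, xs: xs + side] = cid
            grid_ids[r, c] = cid
    return grid_ids


def build_single_cleft(config: GlandConfig | None = None,
                       params: ParameterSet | None = None) -> LatticeState:
    """Initial state: rectangular epithelium in matrix with one initiated cleft.

    The cleft is two facing columns of ``cleft_wall_cells`` CLEFT-typed
    cells descending from the centre of the top (matrix-facing) edge,
    with a shallow one-cell-deep notch already carved between the top
    pair so the simulation starts from an initiated, un-progressed cleft.
    """
    config = config or GlandConfig()
    params = params or preset("base")
    state = LatticeState(config.lattice_width, config.lattice_height)
    x0, y0 = _epithelium_origin(config)
    rows, cols = config.epithelium_rows, config.epithelium_cols
    grid_ids = _build_epithelium(state, config, x0, y0, rows, cols)
    cleft = _carve_cleft(state, config, x0, y0, grid_ids,
                         cols // 2 - 1, cleft_index=0)
    state.refresh_cache()
    state.meta = {"config": config, "params": params, "grid_ids": grid_ids,
                  "clefts": [cleft], "origin": (x0, y0)}
    return state


def build_organ_model(config: GlandConfig | None = None,
                      params: ParameterSet | None = None) -> LatticeState:
    """Organ-level state: one wide bud with three equally spaced clefts.

    The clefts descend from the matrix-facing edge of a single epithelial
    bud at equal spacing (``organ_cleft_spacing_cells`` cell columns
    between adjacent cleft centres), each with its own wall and link set.
    """
    config = config or GlandConfig(n_clefts=3)
    if config.n_clefts != 3:
        raise ValueError("organ model requires n_clefts = 3")
    params = params or preset("base")
    spacing = config.organ_cleft_spacing_cells
    if spacing < 3 + 1:
        raise ValueError("bud too small to space three clefts apart")
    side = config.cell_side
    cols = 3 * spacing + 1
    rows = config.epithelium_rows
    width = cols * side + 2 * 35
    height = config.lattice_height
    config = replace(config, epithelium_cols=cols, lattice_width=width,
                     lattice_height=height)
    state = LatticeState(config.lattice_width, config.lattice_height)
    x0, y0 = _epithelium_origin(config)
    grid_ids = _build_epithelium(state, config, x0, y0, rows, cols)
    clefts = []
    first = spacing // 2
    for k in range(3):
        wall_left = first + k * spacing
        clefts.append(_carve_cleft(state, config, x0, y0, grid_ids,
                                   wall_left, cleft_index=k))
    state.refresh_cache()
    state.meta = {"config": config, "params": params, "grid_ids": grid_ids,
                  "clefts": clefts, "origin": (x0, y0)}
    return state


def assign_fpp_links(state: LatticeState, params: ParameterSet,
                     rule: WidthDepthRule | None = None) -> list[FppLink]:
    """Create the focal-point-plasticity topology on a freshly built state.

    * lateral links between adjacent OCC cells along the boundary ring
      (target = cell side) constrain the epithelial outline;
    * vertical links down each cleft wall (target = cell side);
    * lateral links across the cleft joining opposing wall cells at equal
      rank, with target W(D_k) from the width-depth rule where D_k is the
      rank's depth below the surface (k * cell_side), so targets narrow
      with depth to form the wedge that drives progression.
    """
    rule = rule or WidthDepthRule()
    config: GlandConfig = state.meta["config"]
    side = config.cell_side
    state.clear_links()
    if not params.fpp_enabled:
        return []
    grid_ids = state.meta["grid_ids"]
    rows, cols = grid_ids.shape
    cleft_ids = {cid for cl in state.meta["clefts"]
                 for cid in cl["left"] + cl["right"]}

    # boundary ring in order: top row, right column, bottom row, left column
    ring: list[int] = []
    ring += [int(grid_ids[0, c]) for c in range(cols)]
    ring += [int(grid_ids[r, cols - 1]) for r in range(1, rows)]
    ring += [int(grid_ids[rows - 1, c]) for c in range(cols - 2, -1, -1)]
    ring += [int(grid_ids[r, 0]) for r in range(rows - 2, 0, -1)]
    links: list[FppLink] = []
    for a, b in zip(ring, ring[1:] + ring[:1]):
        if a in cleft_ids and b in cleft_ids:
            continue  # the mouth pair is joined by the W-rule lateral link
        links.append(FppLink(a, b, params.fpp_lambda_occ, float(side),
                             "lateral_occ"))
    for cl in state.meta["clefts"]:
        left, right = cl["left"], cl["right"]
        if len(left) != len(right):
            raise ValueError("unmatched cleft wall pair")
        for wall_ids in (left, right):
            for k in range(len(wall_ids) - 1):
                links.append(FppLink(wall_ids[k], wall_ids[k + 1],
                                     params.fpp_lambda_vertical, float(side),
                                     "vertical_cleft", rank=k,
                                     cleft_index=cl["index"]))
        for k, (a, b) in enumerate(zip(left, right)):
            links.append(FppLink(a, b, params.fpp_lambda_cleft,
                                 rule(k * side), "lateral_cleft", rank=k,
                                 cleft_index=cl["index"]))
    for l in links:
        state.add_link(l)
    return links


def measured_finger_depth(state: LatticeState, cleft: dict) -> float:
    """Depth of the matrix finger below the epithelial surface for one cleft.

    A cheap geometric proxy (deepest matrix site within the cleft's
    x-window) used by the dynamic target-update hook; full morphometrics
    are applied to snapshots, not inside the MCS loop.
    """
    xlo, xhi = cleft["x_window"]
    y0 = cleft["surface_y"]
    sub = state.owner[y0:, max(xlo, 0): xhi] == 0
    # contiguous matrix run from the surface downwards, per column
    runs = np.cumprod(sub, axis=0).sum(axis=0)
    return float(runs.max())


class CleftTargetUpdater:
    """MCS hook: retarget the lateral cleft links from the measured depth.

    Rank k's depth is ``k/(n-1)`` of the effective cleft span, where the
    span starts at the designed wall extent and ratchets up as the
    measured finger depth exceeds it.  Targets therefore never increase
    while the cleft deepens.
    """

    def __init__(self, rule: WidthDepthRule | None = None, cadence: int = 10):
        self.rule = rule or WidthDepthRule()
        self.cadence = cadence
        self._span: dict[int, float] = {}

    def __call__(self, state: LatticeState) -> None:
        config: GlandConfig = state.meta["config"]
        side = config.cell_side
        n = config.cleft_wall_cells
        changed = False
        for cl in state.meta["clefts"]:
            idx = cl["index"]
            span0 = self._span.get(idx, (n - 1) * side)
            span = max(span0, measured_finger_depth(state, cl))
            self._span[idx] = span
            for link in state.links:
                if link.orientation == "lateral_cleft" and \
                        link.cleft_index == idx:
                    new_L = self.rule(span * link.rank / (n - 1))
                    if new_L != link.target_length:
                        link.target_length = new_L
                        changed = True
        if changed:
            state.invalidate_links()


def update_cleft_targets(state: LatticeState,
                         rule: WidthDepthRule | None = None) -> None:
    """One-shot form of :class:`CleftTargetUpdater` (same retargeting rule)."""
    CleftTargetUpdater(rule)(state)


# ---------------------------------------------------------------------------
# Two-cell calibration (reduced model for the lambda / D / CM interplay)
# ---------------------------------------------------------------------------

def two_cell_calibration(D_grid, CM_grid, lambda_grid, mcs: int = 1000,
                         cc: float = 10.0, replicates: int = 1,
                         seed: int = 0,
                         config: GlandConfig | None = None
                         ) -> tuple[pd.DataFrame, np.ndarray]:
    """Two linked 6x6 cells in matrix: which (D, CM, lambda) separate them?

    For every triple, runs the reduced simulation and records whether the
    cells lose all shared contact edges within ``mcs`` steps and the final
    centroid distance.  Returns the outcome table and least-squares
    coefficients of a smooth surface ``lambda*(D, CM) = c0 + c1 D + c2 CM
    + c3 D*CM`` fitted to the separation frontier (minimal separating
    lambda per (D, CM) column).
    """
    config = config or GlandConfig()
    side = config.cell_side
    rows = []
    ss = np.random.SeedSequence(seed)
    for D in D_grid:
        for CM in CM_grid:
            for lam in lambda_grid:
                for rep in range(replicates):
                    child = np.random.SeedSequence(
                        entropy=ss.entropy,
                        spawn_key=(int(D * 16), int(CM * 16),
                                   int(lam * 16), rep))
                    rng = np.random.default_rng(child)
                    st = LatticeState(8 * side, 6 * side)
                    ca = st.new_cell(CLEFT, side * side, config.lambda_area,
                                     4 * side, config.lambda_perimeter)
                    cb = st.new_cell(CLEFT, side * side, config.lambda_area,
                                     4 * side, config.lambda_perimeter)
                    yc = (st.height - side) // 2
                    xa = st.width // 2 - side
                    st.owner[yc: yc + side, xa: xa + side] = ca
                    st.owner[yc: yc + side, xa + side: xa + 2 * side] = cb
                    st.refresh_cache()
                    st.add_link(FppLink(ca, cb, float(lam), float(D),
                                        "lateral_cleft"))
                    table = ContactEnergyTable(neighbor_order=
                                               config.contact_neighbor_order)
                    table.set(CLEFT, CLEFT, cc)
                    table.set(CLEFT, MATRIX, CM)
                    run_mcs(st, table, DynamicsParams(), mcs, rng=rng)
                    sep = _no_shared_edge(st, ca, cb)
                    ax, ay = st.cell(ca).centroid
                    bx, by = st.cell(cb).centroid
                    rows.append({"D": D, "CM": CM, "lam": lam, "rep": rep,
                                 "separated": sep,
                                 "distance": float(np.hypot(ax - bx,
                                                            ay - by))})
    df = pd.DataFrame(rows)
    coefs = _fit_separation_surface(df)
    return df, coefs


def _no_shared_edge(state: LatticeState, ca: int, cb: int) -> bool:
    o = state.owner
    for dy, dx in ((0, 1), (1, 0)):
        a = o[dy:, dx:] if (dy or dx) else o
        b = o[:o.shape[0] - dy, :o.shape[1] - dx]
        if np.any((a == ca) & (b == cb)) or np.any((a == cb) & (b == ca)):
            return False
    return True


def _fit_separation_surface(df: pd.DataFrame) -> np.ndarray:
    maj = (df.groupby(["D", "CM", "lam"])["separated"].mean() > 0.5)
    pts = []
    for (D, CM), sub in maj.groupby(level=[0, 1]):
        lams = sub[sub].index.get_level_values("lam")
        if len(lams):
            pts.append((D, CM, lams.min()))
    if len(pts) < 4:
        return np.full(4, np.nan)
    pts = np.asarray(pts, dtype=float)
    X = np.column_stack([np.ones(len(pts)), pts[:, 0], pts[:, 1],
                         pts[:, 0] * pts[:, 1]])
    coefs, *_ = np.linalg.lstsq(X, pts[:, 2], rcond=None)
    return coefs
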