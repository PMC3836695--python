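"""Cleft morphometrics on label masks: depth, spanning angle, tilt angle.

The epithelium-matrix boundary is traced as an ordered 8-connected pixel
contour.  The cleft centre is the boundary point whose angle subtended by
its 8-distance trace neighbours is smallest; the extrema are found by
growing a straight-line fit away from the centre on each side until the
mean squared perpendicular residual exceeds a threshold.  From centre C
and extrema E1, E2:

* depth  = |C - midpoint(E1, E2)|,
* spanning angle = angle at C between C->E1 and C->E2,
* tilt angle = smaller angle between the extrema segment and the depth
  segment (90 deg = cleft perpendicular to the surface).

Filters follow the ex-vivo analysis: clefts shallower than 5 px or wider
than 160 deg in spanning angle are discarded; tilt below 45 deg marks a
failed cleft.  These functions accept any integer label mask (0 =
matrix/background), so they apply equally to simulation snapshots and
segmented micrographs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .core import MATRIX, LatticeState

VALID = "valid"
DISCARD_SHALLOW = "discarded_shallow"
DISCARD_WIDE = "discarded_wide"
FAILED_TILT = "failed_tilt"
INVALID = "invalid"


@dataclass
class UnitConversions:
    """Spatial and temporal calibration constants of the model."""

    um_per_px: float = 1.06
    seconds_per_mcs: float = 48.0

    def __post_init__(self):
        if self.um_per_px <= 0 or self.seconds_per_mcs <= 0:
            raise ValueError("conversions must be positive")

    def mcs_to_hours(self, mcs: float) -> float:
        return mcs * self.seconds_per_mcs / 3600.0

    def px_to_um(self, px: float) -> float:
        return px * self.um_per_px


@dataclass
class BoundaryTrace:
    """Ordered (x, y) pixel coordinates along the epithelium-matrix interface."""

    points: np.ndarray  # (n, 2) int, consecutive points 8-connected
    closed: bool = True
    mask: np.ndarray | None = None  # the epithelial mask that was traced

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class CleftMeasurement:
    """One detected cleft with its three indices and filter status."""

    center: tuple[float, float]
    extrema: tuple[tuple[float, float], tuple[float, float]]
    depth_px: float
    spanning_deg: float
    tilt_deg: float
    depth_um: float = float("nan")
    status: str = VALID
    center_index: int = -1
    extrema_indices: tuple[int, int] = (-1, -1)


# Moore neighbourhood in clockwise order starting east (x right, y down).
_MOORE = np.array([(1, 0), (1, 1), (0, 1), (-1, 1),
                   (-1, 0), (-1, -1), (0, -1), (1, -1)], dtype=int)


def epithelial_mask(source, epithelial_types=None) -> np.ndarray:
    """Boolean mask of epithelial sites from a LatticeState or label mask."""
    if isinstance(source, LatticeState):
        types = np.asarray(source.ctype[: source.n_cells])
        if epithelial_types is None:
            epi = types != MATRIX
        else:
            epi = np.isin(types, list(epithelial_types))
        return epi[source.owner]
    arr = np.asarray(source)
    if arr.dtype == bool:
        return arr
    return arr > 0


def trace_boundary(source, epithelial_types=None,
                   largest_component: bool = False) -> BoundaryTrace:
    """Ordered contour of epithelial pixels adjacent to the matrix.

    Uses Moore-neighbour tracing with Jacob's stopping criterion.  The
    input must contain exactly one 8-connected epithelial component;
    anything else raises ``ValueError`` with the component count, unless
    ``largest_component`` is set (then the main mass is traced, which
    tolerates the occasional cell that detaches into the matrix).
    """
    mask = epithelial_mask(source, epithelial_types)
    lab, ncomp = ndimage.label(mask, structure=np.ones((3, 3), bool))
    if ncomp != 1:
        if not largest_component or ncomp == 0:
            raise ValueError(
                f"expected one epithelial component, found {ncomp}")
        sizes = np.bincount(lab.ravel())[1:]
        mask = lab == (int(np.argmax(sizes)) + 1)
    padded = np.zeros((mask.shape[0] + 2, mask.shape[1] + 2), bool)
    padded[1:-1, 1:-1] = mask
    ys, xs = np.nonzero(padded)
    i0 = np.lexsort((xs, ys))[0]  # topmost, then leftmost foreground pixel
    start = (int(xs[i0]), int(ys[i0]))
    cur = start
    back = (start[0] - 1, start[1])  # background pixel west of the start
    points = [start]
    second = None
    dir_of = {tuple(v): k for k, v in enumerate(_MOORE)}
    while True:
        d_back = dir_of[(back[0] - cur[0], back[1] - cur[1])]
        nxt = None
        for j in range(1, 9):
            d = (d_back + j) % 8
            nx, ny = cur[0] + int(_MOORE[d, 0]), cur[1] + int(_MOORE[d, 1])
            if padded[ny, nx]:
                nxt = (nx, ny)
                prev_d = (d_back + j - 1) % 8
                back = (cur[0] + int(_MOORE[prev_d, 0]),
                        cur[1] + int(_MOORE[prev_d, 1]))
                break
        if nxt is None:  # single-pixel component
            break
        if second is None:
            second = nxt
        elif cur == start and nxt == second:  # Jacob's stopping criterion
            points.pop()  # start was re-appended on the previous iteration
            break
        points.append(nxt)
        cur = nxt
        if len(points) > 4 * padded.size:
            raise RuntimeError("boundary tracing failed to terminate")
    pts = np.asarray(points, dtype=int) - 1  # undo padding
    return BoundaryTrace(points=pts, closed=True, mask=mask)


def _angle_at(trace: BoundaryTrace, i: int, offset: int) -> float:
    """Interior angle (deg) at point i subtended by its +-offset neighbours."""
    pts = trace.points
    n = len(pts)
    if trace.closed:
        a = pts[(i - offset) % n]
        b = pts[(i + offset) % n]
    else:
        a = pts[max(i - offset, 0)]
        b = pts[min(i + offset, n - 1)]
    p = pts[i]
    u = a - p
    v = b - p
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 180.0
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def boundary_angles(trace: BoundaryTrace, offset: int = 8) -> np.ndarray:
    return np.array([_angle_at(trace, i, offset) for i in range(len(trace))])


def find_cleft_center(trace: BoundaryTrace, offset: int = 8,
                      max_angle_deg: float = 150.0,
                      exclude: np.ndarray | None = None) -> int | None:
    """Index of the sharpest boundary point (lowest subtended angle).

    Returns None when no candidate falls below ``max_angle_deg`` (a flat
    boundary has no cleft).  ``exclude`` masks indices of already
    extracted clefts in multi-cleft snapshots.
    """
    if len(trace) <= 2 * offset:
        raise ValueError("trace too short for the requested angle offset")
    angles = boundary_angles(trace, offset).copy()
    if exclude is not None:
        angles[exclude] = np.inf
    if trace.mask is not None:
        # a cleft centre is concave: the chord between the two offset
        # neighbours must cross the matrix, not the tissue (this rejects
        # sharp convex corners of the bud outline)
        pts = trace.points
        n = len(pts)
        h, w = trace.mask.shape
        for i in range(n):
            if not np.isfinite(angles[i]):
                continue
            a = pts[(i - offset) % n]
            b = pts[(i + offset) % n]
            mx, my = int(round((a[0] + b[0]) / 2)), int(round((a[1] + b[1]) / 2))
            if 0 <= mx < w and 0 <= my < h and trace.mask[my, mx]:
                angles[i] = np.inf
    i = int(np.argmin(angles))
    if not np.isfinite(angles[i]) or angles[i] >= max_angle_deg:
        return None
    return i


def _line_mse(pts: np.ndarray) -> float:
    """Mean squared perpendicular residual of a total-least-squares line."""
    if len(pts) < 3:
        return 0.0
    c = pts.mean(axis=0)
    d = pts - c
    cov = d.T @ d
    evals, evecs = np.linalg.eigh(cov)
    normal = evecs[:, 0]  # eigenvector of the smaller eigenvalue
    res = d @ normal
    return float(np.mean(res ** 2))


def find_extrema(trace: BoundaryTrace, center_idx: int,
                 mse_threshold: float = 3.0,
                 max_window: tuple[int, int] | None = None,
                 corner_snap: bool = True) -> tuple[int, int]:
    """Grow a straight-line fit away from the centre on each side.

    Points are included one at a time; the extremum on each side is the
    last index before the fit's mean squared perpendicular error first
    exceeds the threshold (the whole half-trace if it never does).
    ``max_window`` optionally caps the number of points taken on the
    (backward, forward) side, e.g. to keep one cleft's wall from running
    into a neighbouring cleft in multi-cleft snapshots.
    """
    pts = trace.points
    n = len(pts)
    limit = n // 2 - 1 if trace.closed else None
    out = []
    for side, sign in enumerate((-1, +1)):
        m = 2
        last_ok = 2
        stopped = False
        while True:
            hi = limit if limit is not None else \
                (center_idx if sign < 0 else n - 1 - center_idx)
            if max_window is not None:
                hi = min(hi, max_window[side])
            if m > hi:
                break
            idx = [(center_idx + sign * k) % n for k in range(m + 1)]
            if _line_mse(pts[idx].astype(float)) > mse_threshold:
                stopped = True
                break
            last_ok = m
            m += 1
        if stopped and corner_snap:
            # a mean-squared criterion overshoots a sharp mouth corner
            # (the long straight wall dilutes the residual); snap back to
            # the nearest strong local turn of the boundary
            k = min(last_ok + 2,
                    max_window[side] if max_window is not None else 10 ** 9,
                    limit if limit is not None else 10 ** 9)
            best = None
            while k > 2:
                turn = 180.0 - _angle_at(trace, (center_idx + sign * k) % n,
                                         3)
                if turn >= 35.0:
                    if best is None or turn > best[1]:
                        best = (k, turn)
                elif best is not None:
                    break  # passed the corner region
                k -= 1
            if best is not None:
                last_ok = best[0]
        out.append((center_idx + sign * last_ok) % n)
    return out[0], out[1]


def measure_cleft(center, extrema) -> CleftMeasurement:
    """Depth, spanning angle and tilt angle from three boundary points."""
    c = np.asarray(center, dtype=float)
    e1 = np.asarray(extrema[0], dtype=float)
    e2 = np.asarray(extrema[1], dtype=float)
    mid = (e1 + e2) / 2.0
    depth_vec = mid - c
    depth = float(np.linalg.norm(depth_vec))
    u, v = e1 - c, e2 - c
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    span_vec = e2 - e1
    ns = np.linalg.norm(span_vec)
    if nu == 0 or nv == 0 or ns == 0 or depth == 0:
        return CleftMeasurement(tuple(c), (tuple(e1), tuple(e2)),
                                depth, float("nan"), float("nan"),
                                status=INVALID)
    spanning = float(np.degrees(np.arccos(
        np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))))
    ang = float(np.degrees(np.arccos(
        np.clip(abs(np.dot(span_vec, depth_vec)) / (ns * depth), 0.0, 1.0))))
    tilt = min(ang, 180.0 - ang)  # smaller of the complementary angles
    return CleftMeasurement(tuple(c), (tuple(e1), tuple(e2)),
                            depth, spanning, tilt)


def apply_filters(m: CleftMeasurement, min_depth_px: float = 5.0,
                  max_spanning_deg: float = 160.0,
                  min_tilt_deg: float = 45.0) -> str:
    """Discard/failed rules, in precedence order shallow -> wide -> tilt."""
    if m.status == INVALID:
        return INVALID
    if m.depth_px < min_depth_px:
        status = DISCARD_SHALLOW
    elif m.spanning_deg > max_spanning_deg:
        status = DISCARD_WIDE
    elif m.tilt_deg < min_tilt_deg:
        status = FAILED_TILT
    else:
        status = VALID
    m.status = status
    return status


def convert_units(m: CleftMeasurement,
                  conv: UnitConversions | None = None) -> CleftMeasurement:
    """Fill depth_um = depth_px * um_per_px (default calibration 1.06)."""
    conv = conv or UnitConversions()
    m.depth_um = conv.px_to_um(m.depth_px)
    return m


def candidate_centers(trace: BoundaryTrace, offset: int = 8,
                      max_angle_deg: float = 150.0) -> list[int]:
    """Concave candidate centres, sharpest first, non-maximum suppressed
    so that no two candidates lie within 2*offset of each other."""
    n = len(trace)
    angles = boundary_angles(trace, offset).copy()
    if trace.mask is not None:
        pts = trace.points
        h, w = trace.mask.shape
        for i in range(n):
            a = pts[(i - offset) % n]
            b = pts[(i + offset) % n]
            mx = int(round((a[0] + b[0]) / 2))
            my = int(round((a[1] + b[1]) / 2))
            if 0 <= mx < w and 0 <= my < h and trace.mask[my, mx]:
                angles[i] = np.inf
    order = np.argsort(angles, kind="stable")
    kept: list[int] = []
    for i in order:
        if not np.isfinite(angles[i]) or angles[i] >= max_angle_deg:
            break
        if all(_arc_dist(i, j, n) >= 2 * offset for j in kept):
            kept.append(int(i))
    return kept


def _arc_dist(i: int, j: int, n: int) -> int:
    d = abs(i - j) % n
    return min(d, n - d)


def measure_clefts(source, n_clefts: int = 1, offset: int = 8,
                   mse_threshold: float = 3.0, max_angle_deg: float = 150.0,
                   conv: UnitConversions | None = None,
                   epithelial_types=None,
                   largest_component: bool = False,
                   corner_snap: bool = True) -> list[CleftMeasurement]:
    """Detect and measure up to ``n_clefts`` clefts in one snapshot.

    Candidate centres (sharp concave boundary points) are taken sharpest
    first; each cleft's extrema search is capped at the nearest other
    candidate so neighbouring clefts stay independent.  Returns
    measurements with filters and unit conversion applied; an empty list
    when no cleft is found.
    """
    trace = trace_boundary(source, epithelial_types,
                           largest_component=largest_component)
    n = len(trace)
    cands = candidate_centers(trace, offset, max_angle_deg)[:n_clefts]
    results: list[CleftMeasurement] = []
    for ci in cands:
        others = [j for j in cands if j != ci]
        if others:
            back = min(((ci - j) % n) for j in others)
            fwd = min(((j - ci) % n) for j in others)
            cap = (max(back - offset, 2), max(fwd - offset, 2))
        else:
            cap = None
        li, ri = find_extrema(trace, ci, mse_threshold, max_window=cap,
                              corner_snap=corner_snap)
        m = measure_cleft(trace.points[ci], (trace.points[li],
                                             trace.points[ri]))
        m.center_index = ci
        m.extrema_indices = (li, ri)
        apply_filters(m)
        convert_units(m, conv)
        results.append(m)
    return results
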