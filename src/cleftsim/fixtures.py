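"""Parametric synthetic cleft shapes with known ground-truth geometry.

Generates label masks containing a rasterized epithelium whose surface
carries a V- or U-shaped indentation with a configurable apex position,
mouth width, depth and tilt, plus optional raster noise.  Because the
generating parameters are known analytically, these shapes serve as
ground truth for the morphometric indices (depth, spanning angle, tilt).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class SyntheticCleft:
    """A generated mask plus the analytic values of the three indices."""

    mask: np.ndarray          # bool, True = epithelium
    apex: tuple[float, float]
    mouth_left: tuple[float, float]
    mouth_right: tuple[float, float]
    depth_px: float
    spanning_deg: float
    tilt_deg: float


def make_cleft_mask(width: int = 120, height: int = 90,
                    surface_y: int = 25, apex_x: int | None = None,
                    depth: float = 30.0, mouth_half_width: float = 15.0,
                    profile: str = "v", tilt_deg: float = 90.0,
                    noise: float = 0.0, seed: int = 0,
                    shoulder_slope: float = 0.0,
                    shoulder_height: float = 12.0) -> SyntheticCleft:
    """Rasterize an epithelial slab with one cleft of known geometry.

    ``tilt_deg`` is the angle between the cleft axis and the surface
    (90 = perpendicular).  The apex sits ``depth`` pixels along the
    tilted axis below the mouth midpoint.  With ``profile='u'`` the
    half-width follows a square-root profile (blunt tip) instead of the
    linear V.  ``shoulder_slope`` raises the surface on both sides of
    the mouth (as the bud shoulders do around a real cleft), so the
    mouth corners are well-defined kinks of the boundary.
    """
    if apex_x is None:
        apex_x = width // 2
    rng = np.random.default_rng(seed)
    mask = np.zeros((height, width), dtype=bool)
    for x in range(width):
        rise = shoulder_slope * max(0.0, abs(x - apex_x) - mouth_half_width)
        ys = surface_y - int(round(min(rise, shoulder_height)))
        mask[max(ys, 2):, x] = True
    # unit vector along the cleft axis, pointing into the tissue
    ang = np.radians(tilt_deg)
    axis = np.array([np.cos(ang), np.sin(ang)])  # (dx, dy), y down
    mouth_mid = np.array([apex_x, surface_y], dtype=float)
    apex = mouth_mid + depth * axis
    for yi in range(surface_y, height):
        # distance along the axis from the mouth for this row
        t = (yi - surface_y) / axis[1] if axis[1] > 0 else 0.0
        if t >= depth:
            continue
        frac = 1.0 - t / depth
        if profile == "u":
            hw = mouth_half_width * np.sqrt(frac)
        else:
            hw = mouth_half_width * frac
        if noise > 0:
            hw = max(hw + rng.normal(0.0, noise), 0.0)
        cx = mouth_mid[0] + t * axis[0]
        # carve the open interval so the remaining epithelial corner
        # pixels sit exactly at cx -/+ hw
        lo = int(np.floor(cx - hw)) + 1
        hi = int(np.ceil(cx + hw)) - 1
        if hi >= lo:
            mask[yi, max(lo, 0): min(hi + 1, width)] = False
    ml = (apex_x - mouth_half_width, float(surface_y))
    mr = (apex_x + mouth_half_width, float(surface_y))
    # analytic indices from apex + mouth corners
    c = apex
    e1 = np.array(ml)
    e2 = np.array(mr)
    mid = (e1 + e2) / 2
    dvec = mid - c
    d = float(np.linalg.norm(dvec))
    u, v = e1 - c, e2 - c
    spanning = float(np.degrees(np.arccos(
        np.clip(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)),
                -1, 1))))
    span_vec = e2 - e1
    a = float(np.degrees(np.arccos(
        np.clip(abs(np.dot(span_vec, dvec))
                / (np.linalg.norm(span_vec) * d), 0, 1))))
    tilt = min(a, 180 - a)
    return SyntheticCleft(mask=mask, apex=(float(apex[0]), float(apex[1])),
                          mouth_left=ml, mouth_right=mr, depth_px=d,
                          spanning_deg=spanning, tilt_deg=tilt)


def make_double_cleft_mask(width: int = 200, height: int = 90,
                           surface_y: int = 25,
                           apex_angles=(60.0, 120.0),
                           depth: float = 25.0) -> np.ndarray:
    """Two V clefts with the given apex angles on one boundary."""
    mask = np.zeros((height, width), dtype=bool)
    mask[surface_y:, :] = True
    xs = (width // 3, 2 * width // 3)
    for x0, apex_angle in zip(xs, apex_angles):
        half = depth * np.tan(np.radians(apex_angle / 2.0))
        sub = make_cleft_mask(width, height, surface_y, x0, depth,
                              half, "v")
        mask &= sub.mask
    return mask
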