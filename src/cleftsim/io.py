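"""Persistence and rendering: text snapshots, CSV tables, PNG renders.

The snapshot format is plain text: a one-line JSON header (geometry,
cell table, links, step) followed by the owner grid as whitespace-
separated integers.  It round-trips losslessly through
``save_snapshot`` / ``load_snapshot``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .core import (CLEFT, CLEFT_R, IPC, MATRIX, MITOTIC, OCC, FppLink,
                   LatticeState)
from .gland import GlandConfig, ParameterSet

SNAPSHOT_MAGIC = "# cleftsim snapshot v1"

# Fixed type -> colour map: OCC dark green, IPC light green, cleft blue,
# mitotic yellow, matrix cyan.
TYPE_COLORS = {
    MATRIX: (0, 200, 200),
    OCC: (0, 100, 0),
    IPC: (144, 238, 144),
    CLEFT: (70, 130, 180),
    MITOTIC: (255, 215, 0),
    CLEFT_R: (120, 170, 220),
}


def _meta_header(state: LatticeState) -> dict:
    header = {
        "width": state.width,
        "height": state.height,
        "step": state.step,
        "n_cells": state.n_cells,
        "cells": [
            [int(cid), int(state.ctype[cid]), float(state.target_area[cid]),
             float(state.lam_area[cid]), float(state.target_perim[cid]),
             float(state.lam_perim[cid])]
            for cid in range(state.n_cells)
        ],
        "links": [
            [l.cell_a, l.cell_b, l.lambda_fpp, l.target_length,
             l.orientation, l.rank, l.cleft_index]
            for l in state.links
        ],
    }
    meta = state.meta
    if meta:
        serial = {}
        for k, v in meta.items():
            if k == "config":
                serial["config"] = dataclasses.asdict(v)
            elif k == "params":
                serial["params"] = dataclasses.asdict(v)
            elif k == "grid_ids":
                serial["grid_ids"] = np.asarray(v).tolist()
            elif k == "clefts":
                serial["clefts"] = v
            elif k == "origin":
                serial["origin"] = list(v)
        header["meta"] = serial
    return header


def save_snapshot(state: LatticeState, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(SNAPSHOT_MAGIC + "\n")
        fh.write(json.dumps(_meta_header(state)) + "\n")
        np.savetxt(fh, state.owner, fmt="%d")


def load_snapshot(path) -> LatticeState:
    path = Path(path)
    with path.open() as fh:
        magic = fh.readline().strip()
        if magic != SNAPSHOT_MAGIC:
            raise ValueError(f"{path} is not a cleftsim snapshot")
        header = json.loads(fh.readline())
        owner = np.loadtxt(fh, dtype=np.int32)
    state = LatticeState(header["width"], header["height"])
    for cid, ctype, ta, la, tp, lp in header["cells"]:
        if cid == 0:
            continue
        got = state.new_cell(ctype, ta, la, tp, lp)
        assert got == cid
    state.owner[:] = owner.reshape(state.height, state.width)
    state.step = header["step"]
    state.refresh_cache()
    for a, b, lam, L, orient, rank, ci in header["links"]:
        state.add_link(FppLink(a, b, lam, L, orient, rank, ci))
    meta = header.get("meta", {})
    out_meta = {}
    if "config" in meta:
        out_meta["config"] = GlandConfig(**meta["config"])
    if "params" in meta:
        out_meta["params"] = ParameterSet(**meta["params"])
    if "grid_ids" in meta:
        out_meta["grid_ids"] = np.asarray(meta["grid_ids"], dtype=np.int64)
    if "clefts" in meta:
        clefts = []
        for cl in meta["clefts"]:
            cl = dict(cl)
            cl["x_window"] = tuple(cl["x_window"])
            clefts.append(cl)
        out_meta["clefts"] = clefts
    if "origin" in meta:
        out_meta["origin"] = tuple(meta["origin"])
    state.meta = out_meta
    return state


def render_snapshot(state: LatticeState, path, scale: int = 3,
                    draw_links: bool = False) -> None:
    """PNG render with the fixed type colour map; optional white FPP links."""
    from PIL import Image, ImageDraw
    rgb = np.zeros((state.height, state.width, 3), dtype=np.uint8)
    types = state.ctype[state.owner]
    for t, color in TYPE_COLORS.items():
        rgb[types == t] = color
    img = Image.fromarray(rgb, "RGB")
    if scale != 1:
        img = img.resize((state.width * scale, state.height * scale),
                         Image.NEAREST)
    if draw_links and state.links:
        draw = ImageDraw.Draw(img)
        for l in state.links:
            if state.area[l.cell_a] == 0 or state.area[l.cell_b] == 0:
                continue
            ax, ay = state.cell(l.cell_a).centroid
            bx, by = state.cell(l.cell_b).centroid
            draw.line([(ax * scale, ay * scale), (bx * scale, by * scale)],
                      fill=(255, 255, 255), width=1)
    img.save(Path(path))


def write_manifest(path, config=None, params=None, master_seed=None,
                   derived_seeds=None, outputs=None) -> dict:
    """Write an experiment manifest tying artifacts to their provenance.

    Derived seeds must be a pure function of (master seed, condition,
    replicate); callers pass the realized list so reruns can be checked.
    """
    import datetime
    from . import __version__
    manifest = {
        "cleftsim_version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc)
            .isoformat(timespec="seconds"),
        "master_seed": master_seed,
        "derived_seeds": list(derived_seeds) if derived_seeds else None,
        "config": dataclasses.asdict(config) if config is not None else None,
        "params": dataclasses.asdict(params) if params is not None else None,
        "outputs": [str(p) for p in (outputs or [])],
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def read_label_mask(path) -> "np.ndarray":
    """Load a label mask: plain-text integer matrix, or PNG/TIFF image
    (0 = matrix/background)."""
    path = Path(path)
    if path.suffix.lower() in (".png", ".tif", ".tiff"):
        from PIL import Image
        arr = np.asarray(Image.open(path))
        if arr.ndim == 3:
            arr = arr[..., 0]
        return arr.astype(np.int64)
    return np.loadtxt(path, dtype=np.int64)


def measurements_to_frame(measurements, mcs: int | None = None):
    """Flatten CleftMeasurement objects into a tidy table."""
    import pandas as pd
    rows = []
    for i, m in enumerate(measurements):
        rows.append({
            "mcs": mcs, "cleft": i,
            "depth_px": m.depth_px, "depth_um": m.depth_um,
            "spanning_deg": m.spanning_deg, "tilt_deg": m.tilt_deg,
            "status": m.status,
        })
    return pd.DataFrame(rows)
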