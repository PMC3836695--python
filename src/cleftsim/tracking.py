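"""Per-cell centroid trajectories and motility statistics.

Centroids are sampled every ``cadence`` MCS.  A track ends when its cell
divides (daughter tracks are opened fresh, never stitched) or dies.  The
summary statistics follow the conventions of time-lapse cell tracking:
net displacement (first to last sample), total path length (sum of
inter-sample steps -- cadence-dependent, so the cadence is reported with
it), velocity = path length / elapsed time, and meandering index =
displacement / path length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CLEFT, CLEFT_R, IPC, MITOTIC, OCC, LatticeState
from .morphometrics import UnitConversions


@dataclass
class Track:
    cell_id: int
    samples: list = field(default_factory=list)  # (mcs, x, y)

    def append(self, mcs: int, x: float, y: float) -> None:
        self.samples.append((mcs, x, y))


class CentroidRecorder:
    """MCS hook appending each live epithelial cell's centroid.

    Pass the mitosis schedule (if any) so parent tracks are closed at
    division; daughters open new tracks at the next sample.
    """

    tracked_types = (OCC, IPC, CLEFT, MITOTIC, CLEFT_R)

    def __init__(self, cadence: int = 10, schedule=None):
        self.cadence = cadence
        self.schedule = schedule
        self.finished: list[Track] = []
        self.active: dict[int, Track] = {}
        self._seen_events = 0

    def __call__(self, state: LatticeState) -> None:
        if self.schedule is not None:
            for ev in self.schedule.events[self._seen_events:]:
                _, parent, d1, d2 = ev
                for cid in (parent, d1, d2):
                    if cid in self.active:
                        self.finished.append(self.active.pop(cid))
            self._seen_events = len(self.schedule.events)
        for cid in state.cell_ids(types=self.tracked_types):
            cid = int(cid)
            x, y = state.cell(cid).centroid
            if cid not in self.active:
                self.active[cid] = Track(cid)
            self.active[cid].append(state.step, x, y)

    def tracks(self) -> list[Track]:
        return self.finished + list(self.active.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, t in enumerate(self.tracks()):
            for mcs, x, y in t.samples:
                rows.append({"track": k, "cell_id": t.cell_id,
                             "mcs": mcs, "x": x, "y": y})
        return pd.DataFrame(rows)


def motility_stats(tracks: list[Track],
                   conv: UnitConversions | None = None
                   ) -> tuple[pd.DataFrame, dict]:
    """Per-track displacement/path/velocity/meandering plus population means.

    Single-sample tracks are excluded and counted in the summary.
    Velocity is total path length over elapsed time (the path-based
    convention), in um/hour.
    """
    conv = conv or UnitConversions()
    rows = []
    excluded = 0
    for t in tracks:
        if len(t.samples) < 2:
            excluded += 1
            continue
        s = np.asarray(t.samples, dtype=float)
        xy = s[:, 1:3]
        net_px = float(np.linalg.norm(xy[-1] - xy[0]))
        path_px = float(np.sum(np.linalg.norm(np.diff(xy, axis=0), axis=1)))
        hours = conv.mcs_to_hours(s[-1, 0] - s[0, 0])
        net = conv.px_to_um(net_px)
        path = conv.px_to_um(path_px)
        rows.append({
            "cell_id": t.cell_id,
            "n_samples": len(t.samples),
            "net_displacement_um": net,
            "path_length_um": path,
            "velocity_um_per_h": path / hours if hours > 0 else np.nan,
            "meandering_index": net / path if path > 0 else np.nan,
        })
    df = pd.DataFrame(rows)
    summary = {"n_tracks": len(df), "n_excluded": excluded}
    if len(df):
        for col in ("net_displacement_um", "path_length_um",
                    "velocity_um_per_h", "meandering_index"):
            summary["mean_" + col] = float(df[col].mean())
    return df, summary
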