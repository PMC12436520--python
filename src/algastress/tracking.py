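"""Frame-to-frame trajectory linking with bounded displacement and gap memory.

Detections are linked frame by frame.  Within each frame the assignment of
new detections to active tracks minimises the total squared displacement
over all candidate pairs closer than ``max_disp`` (Hungarian algorithm on
the gated cost matrix, via :func:`scipy.optimize.linear_sum_assignment`).
Unmatched detections open new tracks; a track that misses a frame stays
linkable for ``memory`` further frames (so the frame-index gap between two
linked detections is at most ``memory + 1``) and is then closed.  Linking
is deterministic given the input order: track ids are assigned in order of
creation and the assignment solver is deterministic.

Gap frames are never interpolated: downstream step statistics use only
consecutive-frame pairs, because the finite-difference velocity assumes a
unit frame spacing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

TRACK_COLUMNS = ["track_id", "frame", "x_um", "y_um"]

_INF = 1.0e12


@dataclass(frozen=True)
class LinkingParams:
    """Linker parameters: search radius (um), gap memory (frames) and the
    minimum retained track length (frames) applied after linking.

    Defaults follow the video analysis protocol: max_disp = 6 um
    (15 px at 0.4 um/px), memory = 3 frames; min_length = 10 keeps tracks
    long enough to yield at least eight turning-angle samples.
    """

    max_disp: float = 6.0
    memory: int = 3
    min_length: int = 10

    def __post_init__(self) -> None:
        if not self.max_disp > 0:
            raise ValueError("max_disp must be positive")
        if self.memory < 0:
            raise ValueError("memory must be non-negative")
        if self.min_length < 2:
            raise ValueError("min_length must be at least 2")


def link(detections: pd.DataFrame, params: LinkingParams = LinkingParams()) -> pd.DataFrame:
    """Link a detections table (frame, x_um, y_um) into trajectories.

    Returns a tracks table (track_id, frame, x_um, y_um) sorted by
    (track_id, frame), filtered to tracks with at least
    ``params.min_length`` retained frames.
    """
    if detections.empty:
        return pd.DataFrame(columns=TRACK_COLUMNS)
    xy = detections[["x_um", "y_um"]].to_numpy(dtype=float)
    if not np.isfinite(xy).all():
        raise ValueError("detections contain NaN/inf coordinates")
    frames = detections["frame"].to_numpy()

    # active track state
    track_pos: list[np.ndarray] = []   # last position per track
    track_last: list[int] = []         # last linked frame per track
    rows_id: list[int] = []
    rows_frame: list[int] = []
    rows_xy: list[np.ndarray] = []

    order = np.argsort(frames, kind="stable")
    max_cost = params.max_disp**2

    for f in np.unique(frames):
        idx = order[frames[order] == f]
        det = xy[idx]
        nd = len(det)
        active = [
            i
            for i in range(len(track_pos))
            if 0 < f - track_last[i] <= params.memory + 1
        ]
        assigned_det = np.full(nd, -1, dtype=int)
        if active and nd:
            tp = np.stack([track_pos[i] for i in active])
            d2 = ((tp[:, None, :] - det[None, :, :]) ** 2).sum(axis=2)
            gated = np.where(d2 <= max_cost, d2, _INF)
            nt = len(active)
            # pad to allow unmatched tracks / unmatched detections
            skip = max_cost * 1.0001  # cost of leaving a track/detection unmatched
            big = np.full((nt + nd, nd + nt), _INF)
            big[:nt, :nd] = gated
            big[:nt, nd:] = np.where(np.eye(nt, dtype=bool), skip, _INF)
            big[nt:, :nd] = np.where(np.eye(nd, dtype=bool), skip, _INF)
            big[nt:, nd:] = 0.0
            r, c = linear_sum_assignment(big)
            for ri, ci in zip(r, c):
                if ri < nt and ci < nd and big[ri, ci] < _INF:
                    ti = active[ri]
                    assigned_det[ci] = ti
                    track_pos[ti] = det[ci]
                    track_last[ti] = int(f)
        for k in range(nd):
            ti = assigned_det[k]
            if ti < 0:
                ti = len(track_pos)
                track_pos.append(det[k])
                track_last.append(int(f))
            rows_id.append(ti)
            rows_frame.append(int(f))
            rows_xy.append(det[k])

    out = pd.DataFrame(
        {
            "track_id": rows_id,
            "frame": rows_frame,
            "x_um": [p[0] for p in rows_xy],
            "y_um": [p[1] for p in rows_xy],
        }
    ).sort_values(["track_id", "frame"], kind="stable", ignore_index=True)
    return filter_tracks(out, params.min_length)


def filter_tracks(tracks: pd.DataFrame, min_length: int) -> pd.DataFrame:
    """Keep tracks with at least ``min_length`` retained frames, stable order."""
    if tracks.empty:
        return tracks.copy()
    counts = tracks.groupby("track_id")["frame"].transform("size")
    return tracks[counts >= min_length].reset_index(drop=True)


def total_link_cost(tracks: pd.DataFrame) -> float:
    """Sum of squared displacements over all linked consecutive positions
    (any frame gap), for comparison against exhaustive-assignment oracles."""
    cost = 0.0
    for _, tr in tracks.groupby("track_id"):
        xy = tr.sort_values("frame")[["x_um", "y_um"]].to_numpy()
        cost += float((np.diff(xy, axis=0) ** 2).sum())
    return cost
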