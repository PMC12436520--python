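"""Per-step swimming statistics: speeds, turning angles, summaries, QC.

Velocities are finite differences over consecutive-frame pairs,
v(t) = (r(t + dt) - r(t)) / dt with dt the frame interval (0.0396 s for
the study videos); pairs across track gaps are skipped.  The directional
change per frame is the unsigned angle between consecutive step vectors,

    dtheta = arccos( v(t) . v(t+dt) / (|v(t)| |v(t+dt)|) )  in [0, pi],

with the arccos argument clamped to [-1, 1] against float error and pairs
with a zero-length step dropped (the angle is undefined there).  The
signed variant carries the sign of the 2-D cross product
vx(t) vy(t+dt) - vy(t) vx(t+dt) (positive = counter-clockwise in the
image frame), with exact reversals assigned +pi.

Condition summaries follow a fixed averaging hierarchy: steps are pooled
within a replicate video, replicate means are averaged into the condition
mean, and the reported dispersion is the SD across replicate means —
matching the error-bar scale of replicate-level experiments.

Also provided: fixed-bin histograms of speed and angle distributions, an
opt-in penalised-spline track smoother for robustness checks, and a
Rayleigh-test heading-uniformity QC gate that flags directional drift or
flow in a video.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

STEP_COLUMNS = ["track_id", "t", "vx", "vy", "speed"]
ANGLE_COLUMNS = ["track_id", "t", "dtheta", "dtheta_signed"]

#: default histogram bins: 5 um/s on [0, 150] for speeds, pi/20 on [0, pi]
SPEED_BIN_WIDTH = 5.0
SPEED_RANGE = (0.0, 150.0)
ANGLE_BIN_WIDTH = math.pi / 20
ANGLE_RANGE = (0.0, math.pi)


def _steps_of(track: pd.DataFrame, dt: float) -> tuple[np.ndarray, ...]:
    """Consecutive-frame step vectors of one track; gaps skipped."""
    tr = track.sort_values("frame")
    frames = tr["frame"].to_numpy()
    xy = tr[["x_um", "y_um"]].to_numpy(dtype=float)
    consec = np.diff(frames) == 1
    d = np.diff(xy, axis=0)[consec] / dt
    t = frames[:-1][consec] * dt
    return t, d


def step_velocities(track: pd.DataFrame, dt: float) -> pd.DataFrame:
    """Finite-difference velocities of one track (columns track_id, t, vx,
    vy, speed); only frame-difference-1 pairs contribute."""
    if not dt > 0:
        raise ValueError("dt must be positive")
    if len(track) < 2:
        raise ValueError("track needs at least 2 frames")
    t, v = _steps_of(track, dt)
    tid = track["track_id"].iloc[0] if "track_id" in track.columns else 0
    return pd.DataFrame(
        {
            "track_id": tid,
            "t": t,
            "vx": v[:, 0],
            "vy": v[:, 1],
            "speed": np.hypot(v[:, 0], v[:, 1]),
        },
        columns=STEP_COLUMNS,
    )


def directional_changes(track: pd.DataFrame, dt: float) -> pd.DataFrame:
    """Turning angles between consecutive steps of one track.

    Steps must share a middle frame (three consecutive frames); pairs with
    a zero-length flanking step are dropped.  Returns columns track_id, t,
    dtheta (unsigned, [0, pi]) and dtheta_signed ((-pi, pi], reversal tie
    broken to +pi).
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    tr = track.sort_values("frame")
    frames = tr["frame"].to_numpy()
    xy = tr[["x_um", "y_um"]].to_numpy(dtype=float)
    consec = np.diff(frames) == 1
    steps = np.diff(xy, axis=0) / dt
    # consecutive step pairs sharing the middle frame
    pair = consec[:-1] & consec[1:]
    a = steps[:-1][pair]
    b = steps[1:][pair]
    t_mid = frames[1:-1][pair] * dt
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    ok = (na > 0) & (nb > 0)
    a, b, na, nb, t_mid = a[ok], b[ok], na[ok], nb[ok], t_mid[ok]
    cosang = np.clip((a * b).sum(axis=1) / (na * nb), -1.0, 1.0)
    dtheta = np.arccos(cosang)
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    sign = np.where(cross >= 0, 1.0, -1.0)  # exact reversal (cross==0) -> +pi
    tid = track["track_id"].iloc[0] if "track_id" in track.columns else 0
    return pd.DataFrame(
        {
            "track_id": tid,
            "t": t_mid,
            "dtheta": dtheta,
            "dtheta_signed": sign * dtheta,
        },
        columns=ANGLE_COLUMNS,
    )


def steps_table(tracks: pd.DataFrame, dt: float) -> pd.DataFrame:
    """Step velocities for every track in a tracks table."""
    parts = [
        step_velocities(tr, dt)
        for _, tr in tracks.groupby("track_id")
        if len(tr) >= 2
    ]
    if not parts:
        return pd.DataFrame(columns=STEP_COLUMNS)
    return pd.concat(parts, ignore_index=True)


def angles_table(tracks: pd.DataFrame, dt: float) -> pd.DataFrame:
    """Turning angles for every track in a tracks table."""
    parts = [
        directional_changes(tr, dt)
        for _, tr in tracks.groupby("track_id")
        if len(tr) >= 3
    ]
    if not parts:
        return pd.DataFrame(columns=ANGLE_COLUMNS)
    return pd.concat(parts, ignore_index=True)


@dataclass(frozen=True)
class MotilitySummary:
    """Condition-level summary: mean of replicate means +/- SD across
    replicates, for speed (um/s) and directional change (rad/frame)."""

    condition: float
    exposure_min: float
    mean_speed: float
    sd_speed: float
    mean_dtheta: float
    sd_dtheta: float
    n_replicates: int
    n_tracks: int
    n_steps: int


def summarize_condition(
    replicate_steps: list[pd.DataFrame],
    replicate_angles: list[pd.DataFrame],
    condition: float = 0.0,
    exposure_min: float = 0.0,
) -> MotilitySummary:
    """Summarise one (concentration, exposure) condition over replicates.

    Each element of ``replicate_steps`` / ``replicate_angles`` holds the
    pooled steps/angles of one replicate video.  Replicates with zero
    steps are excluded with a warning.
    """
    if len(replicate_steps) == 0:
        raise ValueError("need at least one replicate")
    sp_means, an_means = [], []
    n_tracks = n_steps = 0
    for i, (st, an) in enumerate(zip(replicate_steps, replicate_angles)):
        if len(st) == 0:
            warnings.warn(f"replicate {i}: no steps; excluded from summary")
            continue
        sp_means.append(float(st["speed"].mean()))
        an_means.append(float(an["dtheta"].mean()) if len(an) else np.nan)
        n_tracks += st["track_id"].nunique()
        n_steps += len(st)
    if not sp_means:
        raise ValueError("no replicate contributed any steps")
    return MotilitySummary(
        condition=condition,
        exposure_min=exposure_min,
        mean_speed=float(np.mean(sp_means)),
        sd_speed=float(np.std(sp_means, ddof=1)) if len(sp_means) > 1 else 0.0,
        mean_dtheta=float(np.nanmean(an_means)),
        sd_dtheta=float(np.nanstd(an_means, ddof=1)) if len(an_means) > 1 else 0.0,
        n_replicates=len(sp_means),
        n_tracks=int(n_tracks),
        n_steps=int(n_steps),
    )


def percent_change(before: float, after: float) -> float:
    """Signed percent change 100*(after - before)/before."""
    if before == 0:
        raise ValueError("percent change undefined for before == 0")
    return 100.0 * (after - before) / before


def histogram(
    values,
    bin_width: float,
    value_range: tuple[float, float],
) -> pd.DataFrame:
    """Fixed-bin histogram with counts and normalised frequencies.

    Returns columns bin_left, bin_center, bin_right, count, frequency
    (frequency sums to 1 over in-range values).  Empty input yields an
    empty table.
    """
    if not bin_width > 0:
        raise ValueError("bin_width must be positive")
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return pd.DataFrame(
            columns=["bin_left", "bin_center", "bin_right", "count", "frequency"]
        )
    lo, hi = value_range
    edges = np.arange(lo, hi + bin_width * 0.5, bin_width)
    if edges[-1] < hi:
        edges = np.append(edges, edges[-1] + bin_width)
    counts, edges = np.histogram(values, bins=edges)
    total = counts.sum()
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_center": 0.5 * (edges[:-1] + edges[1:]),
            "bin_right": edges[1:],
            "count": counts,
            "frequency": counts / total if total else 0.0,
        }
    )


def speed_histogram(steps: pd.DataFrame) -> pd.DataFrame:
    """Speed histogram on the default 5 um/s bins over [0, 150]."""
    return histogram(steps["speed"], SPEED_BIN_WIDTH, SPEED_RANGE)


def angle_histogram(angles: pd.DataFrame) -> pd.DataFrame:
    """Unsigned-angle histogram on the default pi/20 bins over [0, pi]."""
    return histogram(angles["dtheta"], ANGLE_BIN_WIDTH, ANGLE_RANGE)


def modal_bin_center(hist: pd.DataFrame) -> float:
    """Center of the most populated bin (first on ties)."""
    return float(hist.loc[hist["count"].idxmax(), "bin_center"])


def smooth_track(track: pd.DataFrame, reg: float, dt: float = 1.0) -> pd.DataFrame:
    """Penalised cubic-spline smoothing of x(t) and y(t), independently.

    ``reg`` is the roughness-penalty weight (0 reproduces the raw track).
    Frames are unchanged; only positions are replaced.  Requires at least
    4 points.
    """
    if reg < 0:
        raise ValueError("regularization weight must be non-negative")
    if len(track) < 4:
        raise ValueError("smoothing needs a track of length >= 4")
    tr = track.sort_values("frame").reset_index(drop=True)
    t = tr["frame"].to_numpy(dtype=float) * dt
    out = tr.copy()
    if reg == 0:
        return out
    for col in ("x_um", "y_um"):
        spl = make_smoothing_spline(t, tr[col].to_numpy(dtype=float), lam=reg)
        out[col] = spl(t)
    return out


def heading_uniformity(steps: pd.DataFrame) -> tuple[float, float]:
    """Mean resultant length R and Rayleigh-test p of step headings.

    Headings are atan2(vy, vx) of each step.  Small R with large p means
    no directional drift (QC pass); a flow or drift in the video gives
    R significantly above zero (small p).  Uses the standard Rayleigh
    approximation p = exp(sqrt(1 + 4n + 4(n^2 - Rn^2)) - (1 + 2n)).
    """
    if len(steps) < 10:
        raise ValueError("need at least 10 steps")
    theta = np.arctan2(steps["vy"].to_numpy(), steps["vx"].to_numpy())
    n = len(theta)
    C = np.cos(theta).sum()
    S = np.sin(theta).sum()
    Rn = np.hypot(C, S)
    R = Rn / n
    p = math.exp(math.sqrt(1 + 4 * n + 4 * (n**2 - Rn**2)) - (1 + 2 * n))
    return float(R), float(min(max(p, 0.0), 1.0))
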