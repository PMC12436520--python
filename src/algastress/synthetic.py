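"""Synthetic data generator for the growth, pigment and motility assays.

The generator produces four kinds of ground-truth data:

* **swimmers** — 2-D trajectories of motile cells in a square field, with a
  two-state (swimming / stalled) response to Ag+ exposure;
* **videos** — phase-contrast-like frame stacks rendered from the swimmers,
  with the true positions attached for detector/tracker scoring;
* **growth curves** — replicated sigmoidal OD750 time series from the
  Gompertz model, with optional no-growth replicates emulating the
  heterogeneous response near the lethal concentration;
* **absorbance triplets** — 663/645/750 nm absorbances obtained by
  inverting the chlorophyll a/b equations, so the pigments module recovers
  the generating concentrations exactly at zero noise.

Swimmer model
-------------
Each cell draws a constant speed from a Gamma distribution parameterised by
its mode ``v_mode`` and shape ``v_shape`` (positive support, single peak —
the measured control speed distributions are single-peaked).  The heading
performs a wrapped Gaussian random walk with per-step standard deviation
``sigma_rot``.  Boundaries are reflective.

Ag+ stress enters through a swim→stall transition: at each step a swimming
cell stalls with probability ``1 - exp(-(r0 + g*C*f(E)) * dt)`` where ``C``
is the Ag+ concentration (uM), ``E`` the exposure time (min) and
``f(E) = min(E/45, 1)`` a saturating onset ramp.  The stall is absorbing
within one video (the 40 s observation window is short against recovery).
A stalled cell keeps a fixed anchor position and jitters around it,
predominantly along its body axis at the moment of stalling with a small
transverse component.  Near-colinear jitter steps make consecutive-step
turning angles pile up at 0 and pi — the signature the turning-angle
analysis reports for stalled cells — whereas isotropic jitter would put all
the mass at pi alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import pigments as _pig
from .growth import gompertz

#: frame interval of the motility videos, seconds
DEFAULT_DT = 0.0396
#: pixel size of the rendered videos, um/px
DEFAULT_PX_SIZE = 0.4
#: field of view, pixels per side
DEFAULT_FIELD_PX = 512

EXPOSURE_RAMP_MIN = 45.0  # minutes to full stall-rate onset


def _exposure_ramp(exposure_min: float) -> float:
    """Saturating onset f(E) = min(E/45, 1) of the stall response."""
    return min(max(exposure_min, 0.0) / EXPOSURE_RAMP_MIN, 1.0)


@dataclass(frozen=True)
class SwimmerParams:
    """Generative parameters for a population of swimmers under Ag+ stress.

    Attributes
    ----------
    n_cells : int
        Number of cells in the field.
    v_mode : float
        Mode of the per-cell speed distribution, um/s.
    v_shape : float
        Gamma shape of the speed distribution (>1); larger is narrower.
    sigma_rot : float
        Rotational diffusion, rad per frame step.
    stall_rate_0 : float
        Baseline stall-entry rate, 1/s (unexposed cells).
    stall_gain : float
        Stall-rate increment per uM of Ag+, 1/s/uM, at full exposure ramp.
    ag_conc : float
        Ag+ concentration, uM.
    exposure_min : float
        Minutes since Ag+ addition (sets the onset ramp).
    jitter_sd : float
        Axial positional jitter of stalled cells, um.
    duration_frames : int
        Number of frames to simulate.
    dt : float
        Frame interval, s.
    """

    n_cells: int = 40
    v_mode: float = 45.0
    v_shape: float = 25.0
    sigma_rot: float = 0.25
    stall_rate_0: float = 0.001
    stall_gain: float = 0.06
    ag_conc: float = 0.0
    exposure_min: float = 0.0
    jitter_sd: float = 0.05
    duration_frames: int = 1000
    dt: float = DEFAULT_DT

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        if self.duration_frames <= 0:
            raise ValueError("duration_frames must be positive")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if not self.v_mode > 0:
            raise ValueError("v_mode must be positive")
        if not self.v_shape > 1:
            raise ValueError("v_shape must exceed 1 (mode parameterisation)")
        if self.sigma_rot < 0:
            raise ValueError("sigma_rot must be non-negative")
        if self.stall_rate_0 < 0 or self.stall_gain < 0 or self.ag_conc < 0:
            raise ValueError("stall rates and concentration must be non-negative")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")

    @property
    def stall_rate(self) -> float:
        """Effective stall-entry rate (1/s) at this concentration/exposure."""
        return self.stall_rate_0 + self.stall_gain * self.ag_conc * _exposure_ramp(
            self.exposure_min
        )

    @property
    def stall_prob_per_step(self) -> float:
        """Per-frame stall-entry probability, 1 - exp(-rate * dt)."""
        return float(1.0 - np.exp(-self.stall_rate * self.dt))


@dataclass(frozen=True)
class GroundTruthSet:
    """True trajectories and per-frame motility states of simulated cells.

    ``positions`` has shape (n_frames, n_cells, 2) in um; ``stalled`` has
    shape (n_frames, n_cells) and is True where the cell is in the stalled
    state at that frame.
    """

    positions: np.ndarray
    stalled: np.ndarray
    params: SwimmerParams
    field_um: float

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_cells(self) -> int:
        return self.positions.shape[1]

    def stalled_fraction(self) -> float:
        """Fraction of cell-frames spent in the stalled state."""
        return float(self.stalled.mean())

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy table (frame, cell_id, x_um, y_um, state)."""
        nf, nc = self.n_frames, self.n_cells
        frames = np.repeat(np.arange(nf), nc)
        cells = np.tile(np.arange(nc), nf)
        xy = self.positions.reshape(-1, 2)
        state = np.where(self.stalled.reshape(-1), "stalled", "swimming")
        return pd.DataFrame(
            {
                "frame": frames,
                "cell_id": cells,
                "x_um": xy[:, 0],
                "y_um": xy[:, 1],
                "state": state,
            }
        )


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect coordinates into [lo, hi] (single reflection is enough for
    steps much smaller than the field)."""
    x = np.where(x < lo, 2 * lo - x, x)
    x = np.where(x > hi, 2 * hi - x, x)
    return np.clip(x, lo, hi)


#: transverse-to-axial ratio of stalled-cell jitter
STALL_TRANSVERSE_FRACTION = 0.2


def simulate_swimmers(
    params: SwimmerParams,
    seed: int,
    field_um: float = DEFAULT_FIELD_PX * DEFAULT_PX_SIZE,
) -> GroundTruthSet:
    """Simulate a population of swimmers; deterministic given (params, seed).

    Returns a :class:`GroundTruthSet` with positions in um on
    [0, field_um]^2 and per-frame swim/stall states.
    """
    rng = np.random.default_rng(seed)
    n, nf = params.n_cells, params.duration_frames

    # Per-cell speed: Gamma with mode v_mode -> scale = mode / (shape - 1).
    scale = params.v_mode / (params.v_shape - 1.0)
    speeds = rng.gamma(params.v_shape, scale, size=n)
    pos = rng.uniform(0.0, field_um, size=(n, 2))
    heading = rng.uniform(0.0, 2 * np.pi, size=n)

    p_stall = params.stall_prob_per_step
    positions = np.empty((nf, n, 2))
    stalled_mask = np.zeros((nf, n), dtype=bool)

    stalled = np.zeros(n, dtype=bool)
    anchor = np.zeros((n, 2))
    axis = np.zeros((n, 2))

    positions[0] = pos
    for t in range(1, nf):
        # swim -> stall transitions (absorbing within the video)
        newly = (~stalled) & (rng.uniform(size=n) < p_stall)
        if newly.any():
            anchor[newly] = pos[newly]
            axis[newly, 0] = np.cos(heading[newly])
            axis[newly, 1] = np.sin(heading[newly])
            stalled |= newly

        # heading random walk for swimmers
        if params.sigma_rot > 0:
            heading = heading + rng.normal(0.0, params.sigma_rot, size=n)
        step = speeds[:, None] * params.dt * np.c_[np.cos(heading), np.sin(heading)]
        new_pos = pos + step

        # stalled cells: anisotropic jitter around the anchor
        if stalled.any():
            eta_par = rng.normal(0.0, params.jitter_sd, size=n)
            eta_perp = rng.normal(
                0.0, STALL_TRANSVERSE_FRACTION * params.jitter_sd, size=n
            )
            perp = np.c_[-axis[:, 1], axis[:, 0]]
            jitter_pos = anchor + eta_par[:, None] * axis + eta_perp[:, None] * perp
            new_pos = np.where(stalled[:, None], jitter_pos, new_pos)

        # reflective boundaries (also flip heading component for swimmers)
        out_lo = new_pos < 0.0
        out_hi = new_pos > field_um
        if (out_lo | out_hi).any():
            bounce_x = out_lo[:, 0] | out_hi[:, 0]
            bounce_y = out_lo[:, 1] | out_hi[:, 1]
            vx = np.cos(heading)
            vy = np.sin(heading)
            vx = np.where(bounce_x, -vx, vx)
            vy = np.where(bounce_y, -vy, vy)
            heading = np.arctan2(vy, vx)
            new_pos[:, 0] = _reflect(new_pos[:, 0], 0.0, field_um)
            new_pos[:, 1] = _reflect(new_pos[:, 1], 0.0, field_um)

        pos = new_pos
        positions[t] = pos
        stalled_mask[t] = stalled

    return GroundTruthSet(
        positions=positions, stalled=stalled_mask, params=params, field_um=field_um
    )


@dataclass(frozen=True)
class RenderParams:
    """Rendering parameters for synthetic phase-contrast-like videos.

    ``snr`` is the ratio of the spot peak amplitude to the additive noise
    standard deviation.  ``cell_sigma`` is the Gaussian spot width in um.
    """

    field_px: int = DEFAULT_FIELD_PX
    px_size: float = DEFAULT_PX_SIZE
    cell_sigma: float = 0.8
    snr: float = 10.0
    background: float = 100.0
    bit_depth: int = 16
    amplitude: float = 1000.0

    def __post_init__(self) -> None:
        if self.field_px <= 0:
            raise ValueError("field_px must be positive")
        if not self.px_size > 0:
            raise ValueError("px_size must be positive")
        if not self.snr > 0:
            raise ValueError("snr must be positive")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.cell_sigma < 0.5 * self.px_size:
            raise ValueError(
                "cell_sigma below half a pixel renders undetectable spots"
            )


def render_video(
    gt: GroundTruthSet, rp: RenderParams, seed: int
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a ground-truth set into a frame stack plus true-position table.

    Each cell becomes a Gaussian spot of sd ``cell_sigma`` and peak
    ``amplitude`` on a flat background; i.i.d. Gaussian noise of sd
    ``amplitude / snr`` is added and the frame quantised to the requested
    bit depth.  For 8-bit output the intensity scale is compressed so the
    signal still spans the dynamic range.

    Returns
    -------
    stack : ndarray, shape (n_frames, field_px, field_px), uint8 or uint16
    truth : DataFrame with frame, cell_id, x_um, y_um, x_px, y_px, state
    """
    rng = np.random.default_rng(seed)
    nf, nc = gt.n_frames, gt.n_cells
    L = rp.field_px
    sigma_px = rp.cell_sigma / rp.px_size
    noise_sd = rp.amplitude / rp.snr
    half = max(int(np.ceil(4 * sigma_px)), 2)
    win = np.arange(-half, half + 1)

    if rp.bit_depth == 8:
        # compress to 8-bit range: background 10, amplitude scaled by 255/2000
        intensity_scale = 255.0 / (rp.background + rp.amplitude + 5 * noise_sd)
        dtype = np.uint8
        vmax = 255
    else:
        intensity_scale = 1.0
        dtype = np.uint16
        vmax = 65535

    stack = np.empty((nf, L, L), dtype=dtype)
    for t in range(nf):
        frame = np.full((L, L), rp.background, dtype=np.float64)
        for c in range(nc):
            x_px = gt.positions[t, c, 0] / rp.px_size
            y_px = gt.positions[t, c, 1] / rp.px_size
            cx, cy = int(round(x_px)), int(round(y_px))
            xs = cx + win
            ys = cy + win
            mx = (xs >= 0) & (xs < L)
            my = (ys >= 0) & (ys < L)
            if not mx.any() or not my.any():
                continue
            gx = np.exp(-((xs[mx] - x_px) ** 2) / (2 * sigma_px**2))
            gy = np.exp(-((ys[my] - y_px) ** 2) / (2 * sigma_px**2))
            frame[np.ix_(ys[my], xs[mx])] += rp.amplitude * np.outer(gy, gx)
        frame += rng.normal(0.0, noise_sd, size=(L, L))
        np.clip(frame * intensity_scale, 0, vmax, out=frame)
        stack[t] = frame.astype(dtype)

    truth = gt.to_dataframe()
    truth["x_px"] = truth["x_um"] / rp.px_size
    truth["y_px"] = truth["y_um"] / rp.px_size
    return stack, truth


@dataclass(frozen=True)
class GrowthSimParams:
    """Parameters of the replicated Gompertz growth-curve simulator.

    Defaults are the control (0 uM Ag+) condition of the growth assay:
    asymptote A = 0.54 OD750, maximum growth rate mu_m = 0.0084 1/hr,
    lag = 45.6 hr, initial OD750 = 0.01, six replicates sampled every
    12 h for 188 h with OD noise sd 0.02.
    """

    A: float = 0.54
    mu_m: float = 0.0084
    lag: float = 45.6
    noise_sd: float = 0.02
    n_reps: int = 6
    t_grid: Sequence[float] = field(default_factory=lambda: tuple(np.arange(0.0, 188.1, 12.0)))
    od0: float = 0.01
    p_no_growth: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.t_grid, dtype=float)
        if t.ndim != 1 or len(t) < 2 or not np.all(np.diff(t) > 0):
            raise ValueError("t_grid must be strictly increasing with >=2 points")
        if not (self.A > self.od0 >= 0):
            raise ValueError("require A > od0 >= 0")
        if not self.mu_m > 0:
            raise ValueError("mu_m must be positive")
        if self.lag < 0:
            raise ValueError("lag must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_reps <= 0:
            raise ValueError("n_reps must be positive")
        if not 0 <= self.p_no_growth <= 1:
            raise ValueError("p_no_growth must be in [0, 1]")


def simulate_growth_curves(p: GrowthSimParams, seed: int) -> pd.DataFrame:
    """Simulate replicated OD750 growth curves.

    Each replicate is ``od0 + gompertz(t; A - od0 ... )``... precisely:
    ``od0 + gompertz(t; A, mu_m, lag) + N(0, noise_sd)`` independently per
    time point; with probability ``p_no_growth`` the replicate never leaves
    the baseline (``od0`` + noise).  Columns are ``time_hr, rep1..repN``.
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(p.t_grid, dtype=float)
    out = {"time_hr": t}
    signal = gompertz(t, p.A, p.mu_m, p.lag)
    for r in range(p.n_reps):
        grows = rng.uniform() >= p.p_no_growth
        base = p.od0 + (signal if grows else 0.0)
        noise = rng.normal(0.0, p.noise_sd, size=t.shape) if p.noise_sd > 0 else 0.0
        out[f"rep{r + 1}"] = base + noise
    return pd.DataFrame(out)


def simulate_pigment_absorbances(
    chl_a: float,
    chl_b: float,
    volume_ml: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    a750: float = 0.02,
) -> tuple[float, float, float]:
    """Absorbance triplet (A663, A645, A750) consistent with given pigments.

    Inverts the 2x2 linear system of the chlorophyll a/b equations for the
    baseline-corrected absorbances, adds the A750 baseline to all three
    channels, then optional Gaussian noise.  At zero noise the pigments
    module recovers (chl_a, chl_b) exactly.
    """
    if chl_a < 0 or chl_b < 0:
        raise ValueError("chlorophyll concentrations must be non-negative")
    if not volume_ml > 0:
        raise ValueError("volume_ml must be positive")
    coef = np.array(
        [
            [_pig.COEF_A_663, _pig.COEF_A_645],
            [_pig.COEF_B_663, _pig.COEF_B_645],
        ]
    )
    e663, e645 = np.linalg.solve(coef, np.array([chl_a, chl_b]) * volume_ml)
    triplet = np.array([e663 + a750, e645 + a750, a750])
    if noise_sd > 0:
        triplet = triplet + np.random.default_rng(seed).normal(0, noise_sd, 3)
    return float(triplet[0]), float(triplet[1]), float(triplet[2])
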