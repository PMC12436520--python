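"""Spot detection of microalga-like cells in grayscale video frames.

Cells imaged in phase contrast appear as bright, roughly Gaussian spots.
The detector is a classical multi-scale Laplacian-of-Gaussian (LoG) blob
detector: each frame is normalised to zero mean and unit variance (making
the response threshold transferable across bit depths and illumination),
scale-normalised LoG responses are computed over a small range of blob
widths, local maxima above threshold are kept, merged by a distance-based
non-maximum suppression, and refined to sub-pixel accuracy by an
intensity-weighted centroid in a local window.

Detection quality against rendered ground truth is scored by one-to-one
greedy nearest matching within a match radius (default 2 um, the cell
radius scale): matched ground truth = true positive, unmatched ground
truth = false negative, unmatched detection = false positive.  True
negatives are structurally zero for an object detector on dense frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .synthetic import DEFAULT_PX_SIZE

DETECTION_COLUMNS = ["frame", "x_um", "y_um", "area_um2", "score"]


def _empty_detections() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "frame": pd.Series(dtype="int64"),
            "x_um": pd.Series(dtype="float64"),
            "y_um": pd.Series(dtype="float64"),
            "area_um2": pd.Series(dtype="float64"),
            "score": pd.Series(dtype="float64"),
        }
    )


@dataclass(frozen=True)
class DetectionParams:
    """Blob-detector parameters.

    Attributes
    ----------
    sigma_min, sigma_max : float
        Blob width range searched, um (Gaussian sd of the spot model).
    n_scales : int
        Number of LoG scales between sigma_min and sigma_max.
    threshold : float
        Cutoff on the scale-normalised LoG response expressed as a
        z-score against the robust (MAD) noise level of each scale.  The
        default was set on rendered fixtures so that pure-noise frames
        yield essentially no detections while spots at SNR >= 5 are kept.
    min_separation : float
        Non-maximum-suppression radius, um; of two maxima closer than
        this only the stronger is kept.
    """

    sigma_min: float = 0.6
    sigma_max: float = 1.0
    n_scales: int = 3
    threshold: float = 8.0
    min_separation: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.sigma_min <= self.sigma_max:
            raise ValueError("require 0 < sigma_min <= sigma_max")
        if not self.threshold > 0:
            raise ValueError("threshold must be positive")
        if self.n_scales < 1:
            raise ValueError("n_scales must be >= 1")
        if not self.min_separation >= 0:
            raise ValueError("min_separation must be non-negative")


@dataclass(frozen=True)
class DetectionMetrics:
    """Detection-quality rates against ground truth.

    tp_rate and fn_rate are fractions of ground-truth objects
    (tp_rate + fn_rate = 1); fp_rate is the fraction of detections that
    matched no ground-truth object.  tn_rate is structurally zero.
    """

    tp_rate: float
    fp_rate: float
    fn_rate: float
    n_gt: int
    n_det: int

    @property
    def tn_rate(self) -> float:
        return 0.0


def _normalize(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame, dtype=np.float64)
    sd = frame.std()
    if sd == 0:
        return np.zeros_like(frame)
    return (frame - frame.mean()) / sd


def _refine_centroid(
    frame: np.ndarray, row: int, col: int, sigma_px: float
) -> tuple[float, float]:
    """Intensity-weighted centroid in a (2r+1)^2 window, background-
    subtracted by the window minimum; falls back to the peak pixel if the
    window has no positive mass."""
    r = max(int(round(2.0 * sigma_px)), 2)
    r0, r1 = max(row - r, 0), min(row + r + 1, frame.shape[0])
    c0, c1 = max(col - r, 0), min(col + r + 1, frame.shape[1])
    win = frame[r0:r1, c0:c1] - frame[r0:r1, c0:c1].min()
    total = win.sum()
    if total <= 0:
        return float(row), float(col)
    rows, cols = np.mgrid[r0:r1, c0:c1]
    return float((rows * win).sum() / total), float((cols * win).sum() / total)


def detect_cells(
    frame: np.ndarray,
    params: DetectionParams = DetectionParams(),
    px_size: float = DEFAULT_PX_SIZE,
    frame_index: int = 0,
) -> pd.DataFrame:
    """Detect cell-like blobs in one grayscale frame.

    Returns a DataFrame with columns frame, x_um, y_um, area_um2, score
    (x rightward, y downward, origin at the top-left pixel center).
    A constant (degenerate) frame yields zero detections.
    """
    if not np.isfinite(np.asarray(frame, dtype=np.float64)).all():
        raise ValueError("frame contains non-finite values")
    norm = _normalize(frame).astype(np.float32)
    if norm.std() == 0:
        return _empty_detections()

    # scale-normalised LoG response stack (bright blobs -> positive peaks),
    # each scale standardised by its own robust noise level so the threshold
    # is a z-score: the raw LoG noise response scales as 1/sigma and a flat
    # threshold would otherwise flood the small scales with false peaks
    if params.n_scales == 1:
        sigmas = np.array([0.5 * (params.sigma_min + params.sigma_max)])
    else:
        sigmas = np.linspace(params.sigma_min, params.sigma_max, params.n_scales)
    sigmas_px = sigmas / px_size
    smoothed = [ndimage.gaussian_filter(norm, s, truncate=3.0) for s in sigmas_px]
    responses = []
    for s, g in zip(sigmas_px, smoothed):
        r = -(s**2) * ndimage.laplace(g)
        mad = np.median(np.abs(r - np.median(r)))
        responses.append(r / max(1.4826 * mad, 1e-12))
    responses = np.stack(responses)
    resp_max = responses.max(axis=0)
    best_scale = responses.argmax(axis=0)

    # local maxima of the max-over-scales response above threshold
    footprint = ndimage.maximum_filter(resp_max, size=3, mode="nearest")
    peaks = (resp_max == footprint) & (resp_max > params.threshold)
    ys, xs = np.nonzero(peaks)
    if len(ys) == 0:
        return _empty_detections()
    resp = resp_max[ys, xs]

    # distance NMS: keep the strongest peak within min_separation
    order = np.argsort(-resp, kind="stable")
    min_sep_px = params.min_separation / px_size
    kept: list[int] = []
    kept_yx = np.empty((0, 2))
    for i in order:
        yx = np.array([ys[i], xs[i]], dtype=float)
        if len(kept) == 0 or (
            np.hypot(*(kept_yx - yx).T).min() >= min_sep_px
        ):
            kept.append(i)
            kept_yx = np.vstack([kept_yx, yx])
    kept = sorted(kept)

    smooth = smoothed[0]
    rows = []
    for i in kept:
        sigma = sigmas_px[best_scale[ys[i], xs[i]]]
        yc, xc = _refine_centroid(smooth, int(ys[i]), int(xs[i]), sigma)
        radius_um = np.sqrt(2.0) * sigma * px_size
        rows.append(
            {
                "frame": frame_index,
                "x_um": xc * px_size,
                "y_um": yc * px_size,
                "area_um2": np.pi * radius_um**2,
                "score": float(resp[i] / (resp[i] + params.threshold)),
            }
        )
    return pd.DataFrame(rows, columns=DETECTION_COLUMNS)


def detect_stack(
    stack: np.ndarray,
    params: DetectionParams = DetectionParams(),
    px_size: float = DEFAULT_PX_SIZE,
) -> pd.DataFrame:
    """Run :func:`detect_cells` on every frame of a stack; concatenated table."""
    frames = [
        detect_cells(stack[t], params, px_size=px_size, frame_index=t)
        for t in range(stack.shape[0])
    ]
    out = pd.concat(frames, ignore_index=True)
    out["frame"] = out["frame"].astype(int)
    return out


def _match_frame(
    det_xy: np.ndarray, gt_xy: np.ndarray, match_radius: float
) -> int:
    """One-to-one greedy nearest matching; returns number of matches."""
    if len(det_xy) == 0 or len(gt_xy) == 0:
        return 0
    d = np.linalg.norm(det_xy[:, None, :] - gt_xy[None, :, :], axis=2)
    n_matches = 0
    d = d.copy()
    while True:
        i, j = np.unravel_index(np.argmin(d), d.shape)
        if d[i, j] > match_radius:
            break
        n_matches += 1
        d[i, :] = np.inf
        d[:, j] = np.inf
        if not np.isfinite(d).any():
            break
    return n_matches


def evaluate_detections(
    dets: pd.DataFrame,
    truth: pd.DataFrame,
    match_radius: float = 2.0,
) -> DetectionMetrics:
    """Score detections against a ground-truth position table.

    Both tables need columns frame, x_um, y_um.  Matching is one-to-one
    greedy by distance within ``match_radius`` (um), per frame.
    """
    if not match_radius > 0:
        raise ValueError("match_radius must be positive")
    n_gt = len(truth)
    n_det = len(dets)
    tp = 0
    det_by_frame = dict(tuple(dets.groupby("frame"))) if n_det else {}
    for f, gt_f in truth.groupby("frame"):
        det_f = det_by_frame.get(f)
        if det_f is None:
            continue
        tp += _match_frame(
            det_f[["x_um", "y_um"]].to_numpy(),
            gt_f[["x_um", "y_um"]].to_numpy(),
            match_radius,
        )
    fn = n_gt - tp
    fp = n_det - tp
    return DetectionMetrics(
        tp_rate=tp / n_gt if n_gt else 0.0,
        fp_rate=fp / n_det if n_det else 0.0,
        fn_rate=fn / n_gt if n_gt else 0.0,
        n_gt=n_gt,
        n_det=n_det,
    )
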