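import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from algastress.detection import detect_stack
from algastress.synthetic import (
    RenderParams,
    SwimmerParams,
    render_video,
    simulate_swimmers,
)
from algastress.tracking import link

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

DT = 0.0396


def gt_tracks(gt) -> pd.DataFrame:
    """Ground-truth positions as a tracks table (cell_id -> track_id)."""
    df = gt.to_dataframe().rename(columns={"cell_id": "track_id"})
    return df[["track_id", "frame", "x_um", "y_um"]]


@pytest.fixture(scope="session")
def control_video_suite():
    """Standard detection suite: 5 rendered control videos, 40 cells,
    200 frames, snr 10, with ground truth."""
    out = []
    for i in range(5):
        gt = simulate_swimmers(
            SwimmerParams(n_cells=40, duration_frames=200), seed=100 + i
        )
        stack, truth = render_video(gt, RenderParams(snr=10.0), seed=200 + i)
        dets = detect_stack(stack)
        out.append((dets, truth))
    return out


@pytest.fixture(scope="session")
def control_pipeline_tracks():
    """Control fixture run through render -> detect -> link (500 frames)."""
    gt = simulate_swimmers(
        SwimmerParams(n_cells=40, v_mode=45.0, duration_frames=500), seed=7
    )
    stack, _ = render_video(gt, RenderParams(snr=10.0), seed=8)
    return link(detect_stack(stack))


@pytest.fixture(scope="session")
def stalled_pipeline_tracks():
    """Strong-stall fixture (2.35 uM, 60 min) through the same pipeline."""
    gt = simulate_swimmers(
        SwimmerParams(
            n_cells=40, duration_frames=300, ag_conc=2.35, exposure_min=60.0
        ),
        seed=11,
    )
    stack, _ = render_video(gt, RenderParams(snr=10.0), seed=12)
    return link(detect_stack(stack))
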