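"""End-to-end pipeline: simulate -> render -> detect -> link -> motility,
growth simulate -> fit -> hormesis report, and a pigment round trip.

The pipeline runs from a single nested configuration (see
:data:`DEFAULT_CONFIG`), writes every intermediate table as CSV plus a
YAML manifest echoing the full configuration and seeds, and is
deterministic: the same config reproduces the same output bundle bit for
bit.  Per-stage seeds are derived from the top-level seed and the
condition grid position, so each (concentration, exposure, replicate)
video gets an independent but reproducible stream.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as aio
from .detection import DetectionParams, detect_stack, evaluate_detections
from .growth import compare_conditions, fit_gompertz
from .motility import angles_table, steps_table, summarize_condition
from .synthetic import (
    GrowthSimParams,
    RenderParams,
    SwimmerParams,
    render_video,
    simulate_growth_curves,
    simulate_pigment_absorbances,
    simulate_swimmers,
)
from .pigments import chlorophyll_concentrations
from .tracking import LinkingParams, link

log = logging.getLogger("algastress.pipeline")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "output_dir": "pipeline_out",
    "imaging": {"px_size": 0.4, "dt": 0.0396, "field_px": 512},
    "motility": {
        "conditions_um": [0.0, 1.77, 2.35],
        "exposures_min": [0.0, 15.0, 30.0, 45.0, 60.0],
        "n_replicates": 5,
        "n_cells": 40,
        "duration_frames": 200,
        "snr": 10.0,
        "write_stacks": False,
    },
    "detection": {
        "sigma_min": 0.6,
        "sigma_max": 1.0,
        "threshold": 8.0,
        "min_separation": 1.0,
    },
    "linking": {"max_disp": 6.0, "memory": 3, "min_length": 10},
    "growth": {
        "baseline": 0.01,
        "no_growth_threshold": 0.05,
        "conditions": {
            "0.0": {"A": 0.54, "mu_m": 0.0084, "lag": 45.6},
            "0.29": {"A": 0.87, "mu_m": 0.0096, "lag": 82.6},
        },
        "noise_sd": 0.02,
        "n_reps": 6,
    },
    "pigments": {"chl_a": 2.8, "chl_b": 1.4, "volume_ml": 1.0},
}

REQUIRED_KEYS = ["seed", "output_dir", "imaging", "motility", "detection", "linking", "growth"]


def validate_config(cfg: dict) -> None:
    """Raise ValueError listing every missing required key."""
    missing = [k for k in REQUIRED_KEYS if k not in cfg]
    if missing:
        raise ValueError(f"config is missing key(s): {', '.join(missing)}")
    if "seed" in cfg and not isinstance(cfg["seed"], (int, np.integer)):
        raise ValueError("config key 'seed' must be an integer")


def _stage_seed(base: int, *indices: int) -> int:
    # independent, reproducible per-stage streams below 2**31
    h = int(base) & 0xFFFFFFFF
    for i in indices:
        h = (h * 2654435761 + int(i) + 0x9E3779B9) & 0xFFFFFFFF
    return h % (2**31 - 1)


def run_pipeline(cfg: dict | None = None) -> dict:
    """Run the full synthetic-study pipeline; returns the result bundle.

    The bundle maps stage names to DataFrames / objects; everything is
    also written under ``cfg['output_dir']`` together with a
    ``manifest.yaml`` echoing the configuration.
    """
    if cfg is None:
        cfg = DEFAULT_CONFIG
    validate_config(cfg)
    out_dir = Path(cfg["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    imaging = cfg["imaging"]
    dt = float(imaging["dt"])
    px = float(imaging["px_size"])
    field_px = int(imaging["field_px"])

    det_params = DetectionParams(**cfg["detection"])
    link_params = LinkingParams(**cfg["linking"])
    mot = cfg["motility"]
    rp = RenderParams(field_px=field_px, px_size=px, snr=float(mot.get("snr", 10.0)))

    # --- motility arm -----------------------------------------------------
    summaries = []
    detection_scores = []
    all_steps = []
    for ic, conc in enumerate(mot["conditions_um"]):
        for ie, expo in enumerate(mot["exposures_min"]):
            rep_steps, rep_angles = [], []
            for ir in range(int(mot["n_replicates"])):
                s = _stage_seed(seed, ic, ie, ir)
                params = SwimmerParams(
                    n_cells=int(mot["n_cells"]),
                    ag_conc=float(conc),
                    exposure_min=float(expo),
                    duration_frames=int(mot["duration_frames"]),
                    dt=dt,
                )
                gt = simulate_swimmers(params, seed=s, field_um=field_px * px)
                stack, truth = render_video(gt, rp, seed=s + 1)
                if mot.get("write_stacks", False):
                    aio.write_stack(
                        out_dir / f"video_c{conc}_e{expo}_r{ir}.tif", stack
                    )
                dets = detect_stack(stack, det_params, px_size=px)
                detection_scores.append(
                    {
                        "condition": conc,
                        "exposure_min": expo,
                        "replicate": ir,
                        **evaluate_detections(dets, truth).__dict__,
                    }
                )
                tracks = link(dets, link_params)
                st = steps_table(tracks, dt)
                an = angles_table(tracks, dt)
                st["condition"], st["exposure_min"], st["replicate"] = conc, expo, ir
                all_steps.append(st)
                rep_steps.append(st)
                rep_angles.append(an)
                log.info(
                    "cond %.2f uM, %s min, rep %d: %d detections, %d tracks, %d steps",
                    conc, expo, ir, len(dets), tracks["track_id"].nunique() if len(tracks) else 0, len(st),
                )
            summaries.append(
                summarize_condition(rep_steps, rep_angles, condition=conc, exposure_min=expo).__dict__
            )
    summary_df = pd.DataFrame(summaries)
    det_df = pd.DataFrame(detection_scores)
    steps_df = pd.concat(all_steps, ignore_index=True) if all_steps else pd.DataFrame()
    aio.write_table(out_dir / "motility_summary.csv", summary_df)
    aio.write_table(out_dir / "detection_metrics.csv", det_df)
    aio.write_table(out_dir / "steps.csv", steps_df)

    # --- growth arm -------------------------------------------------------
    g = cfg["growth"]
    fits = {}
    growth_rows = []
    for ig, (cond, p) in enumerate(g["conditions"].items()):
        gp = GrowthSimParams(
            A=float(p["A"]), mu_m=float(p["mu_m"]), lag=float(p["lag"]),
            noise_sd=float(g.get("noise_sd", 0.02)), n_reps=int(g.get("n_reps", 6)),
            od0=float(g.get("baseline", 0.01)),
            p_no_growth=float(p.get("p_no_growth", 0.0)),
        )
        curves = simulate_growth_curves(gp, seed=_stage_seed(seed, 1000, ig))
        res = fit_gompertz(
            curves,
            baseline=float(g.get("baseline", 0.01)),
            condition=cond,
            no_growth_threshold=float(g.get("no_growth_threshold", 0.05)),
        )
        fits[cond] = res
        growth_rows.append(res.to_frame())
    fits_df = pd.concat(growth_rows, ignore_index=True)
    aio.write_table(out_dir / "growth_fits.csv", fits_df)
    control_key = min(g["conditions"], key=lambda k: float(k))
    report = compare_conditions(fits, control_key)
    aio.write_table(out_dir / "hormesis_report.csv", report.to_frame())

    # --- pigments round trip ---------------------------------------------
    pg = cfg.get("pigments", DEFAULT_CONFIG["pigments"])
    a663, a645, a750 = simulate_pigment_absorbances(
        float(pg["chl_a"]), float(pg["chl_b"]), float(pg["volume_ml"])
    )
    chl = chlorophyll_concentrations(a663, a645, a750, float(pg["volume_ml"]))
    pig_df = pd.DataFrame(
        [
            {
                "A663": a663, "A645": a645, "A750": a750,
                "chl_a": chl.chl_a, "chl_b": chl.chl_b, "chl_total": chl.chl_total,
            }
        ]
    )
    aio.write_table(out_dir / "pigments.csv", pig_df)

    aio.save_config(out_dir / "manifest.yaml", cfg)
    return {
        "motility_summary": summary_df,
        "detection_metrics": det_df,
        "steps": steps_df,
        "growth_fits": fits_df,
        "hormesis_report": report,
        "pigments": pig_df,
    }
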