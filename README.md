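# algastress

Quantitative analysis of microalgal stress responses to silver ions
(Ag⁺), covering the three assays of a single-cell toxicology study on
*Chlamydomonas reinhardtii*:

* **Population growth** — Gompertz fits of replicated OD750 growth
  curves, extracting the lag time λ, maximum growth rate μₘ and
  asymptote A per condition, and flagging hormesis (a low dose that
  *raises* the plateau density while still elongating the lag);
* **Chlorophyll content** — spectrophotometric chlorophyll a/b
  quantification from 663/645/750 nm absorbance triplets, with per-cell
  normalisation via 1 OD750 ≈ 10⁷ cells/mL;
* **Swimming motility** — spot detection in phase-contrast video frames,
  trajectory linking with bounded displacement and gap memory, and
  per-step statistics: instantaneous speed |Δr|/Δt and directional change
  δθ = arccos(v̂(t)·v̂(t+Δt)) per frame, summarised per condition.

The package is aimed at quantitative biologists and biophysicists who
need a reproducible desk-scale version of this analysis chain. Because
raw study videos are not redistributable, `algastress.synthetic`
generates ground-truth swimmers (with a two-state swim/stall response to
Ag⁺), rendered videos, Gompertz growth curves and consistent absorbance
triplets, so every stage can be validated end to end. The growth module
follows the familiar model/results pattern:
`GompertzModel.from_dataframe(df).fit()` returns a `GompertzResults` with
parameters, uncertainties and a `summary()`.

## The core models

Growth is the modified Gompertz curve (Zwietering parameterisation)

    y(t) = A · exp{ −exp[ (μₘ·e/A)·(λ − t) + 1 ] },

fitted per replicate by bounded nonlinear least squares on
baseline-subtracted OD750; condition values are the mean ± SD across
replicates. Chlorophyll follows the standard acetone/methanol extraction
equations, e.g. chl a (μg/mL) = (12.25·E₆₆₃ − 2.55·E₆₄₅)/V with
E = A − A₇₅₀. The motility chain is: multi-scale Laplacian-of-Gaussian
blob detection with sub-pixel centroid refinement → per-frame Hungarian
assignment within a 6 μm search radius and 3-frame gap memory → speed and
turning-angle distributions (5 μm/s and π/20 bins). See
`docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
from algastress import (GrowthSimParams, simulate_growth_curves,
                        fit_gompertz, compare_conditions)

ctrl = fit_gompertz(simulate_growth_curves(GrowthSimParams(), seed=1),
                    condition=0.0)
low = fit_gompertz(simulate_growth_curves(
    GrowthSimParams(A=0.87, mu_m=0.0096, lag=82.6), seed=2),
    condition=0.29)
print(ctrl.summary())
report = compare_conditions({0.0: ctrl, 0.29: low}, control_id=0.0)
print(report.to_frame()[["condition", "A", "lag",
                         "hormetic_asymptote", "elongated_lag"]])
```

prints

```
Gompertz growth fit
condition: 0.0
replicates: 6 (no growth: 0)
  A     = 0.5468 +/- 0.011 OD750
  mu_m  = 0.007942 +/- 0.00037 1/hr
  lag   = 44.61 +/- 1.6 hr
   condition         A        lag  hormetic_asymptote  elongated_lag
0       0.29  0.875436  82.619854                True           True
```

The control fit recovers the generating parameters (A = 0.54,
μₘ = 0.0084/hr, λ = 45.6 hr) within noise, and the 0.29 μM-like condition
is flagged hormetic: its plateau (0.88 OD750) exceeds the control's by
more than the combined replicate SD while its lag is elongated
(82.6 vs 44.6 hr).

The motility arm runs the same way from simulation to statistics:

```python
from algastress import (SwimmerParams, RenderParams, simulate_swimmers,
                        render_video, detect_stack, link)
from algastress.motility import steps_table, speed_histogram, modal_bin_center

gt = simulate_swimmers(SwimmerParams(n_cells=40, duration_frames=300), seed=3)
stack, truth = render_video(gt, RenderParams(snr=10.0), seed=4)
steps = steps_table(link(detect_stack(stack)), dt=0.0396)
print(len(steps), steps["speed"].mean(), modal_bin_center(speed_histogram(steps)))
```

recovers 11 849 steps with mean speed 46.1 μm/s and the modal 5 μm/s bin
at 47.5 μm/s — the generator's 45 μm/s speed mode, within one bin.
Setting `ag_conc=2.35, exposure_min=60` instead collapses the speed mode
to the 0-bin and makes the turning-angle distribution bimodal at 0 and π,
the signature of stalled cells.

A `algastress` command-line interface mirrors the stages
(`simulate`, `detect`, `link`, `motility`, `growth`, `pigments`,
`run-all`); `run-all` executes the full synthetic study grid from a YAML
config and writes all tables plus a reproducibility manifest.

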