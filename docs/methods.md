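# Methods

This note documents the models, numerical choices and limitations behind
`algastress`. The package analyses three assays of microalgal response to
silver ions — population growth, chlorophyll content, and single-cell
swimming motility — and ships a synthetic-data generator that emulates the
statistical structure of each assay so the full analysis chain can be
validated end to end against known ground truth.

## Growth: the Gompertz model

OD750 growth curves are fitted with the modified Gompertz model in the
Zwietering parameterisation,

    y(t) = A · exp{ −exp[ (μm·e/A)·(λ − t) + 1 ] },

whose parameters are directly interpretable: `A` is the stationary-phase
plateau (OD750 above baseline), `μm` (1/hr) the maximum slope, attained at
the inflection, and `λ` (hr) the lag time, defined as the time-axis
intercept of the inflection tangent. Useful identities used in the tests:
`y(λ) = A·e^(−e) ≈ 0.066·A` and `max_t dy/dt = μm`.

Fitting choices:

* **Baseline.** The inoculation density (OD750 = 0.01 by default) is
  subtracted before fitting, because the Gompertz form tends to 0 at
  t → −∞.
* **Per-replicate fitting.** Each replicate column is fitted separately by
  bounded nonlinear least squares (`scipy.optimize.curve_fit`); condition
  estimates are the mean ± SD of per-replicate estimates. Fitting the mean
  curve instead would hide the large between-replicate heterogeneity that
  appears near inhibitory concentrations, which is a finding, not noise.
* **Initialisation and bounds.** A₀ = max(od), μ₀ = max discrete slope,
  λ₀ = the time-axis intercept of the max-slope tangent; bounds
  A ∈ (0, 2·max(od)], μm > 0, λ ∈ [0, max(t)]. Non-convergence is reported
  via a `converged=False` flag with NaN parameters, never an exception.
* **No-growth screening.** Replicates whose OD never rises more than
  0.05 above baseline are flagged `no_growth` and excluded from the
  aggregate (the threshold is exposed; setting it to 0 disables screening,
  in which case flat replicates produce essentially arbitrary lag
  estimates and inflate the across-replicate SD — the signature of
  heterogeneous response that the simulator's `p_no_growth` reproduces).
* **Hormesis comparison.** A treated condition is flagged
  `hormetic_asymptote` when its fitted A exceeds the control's by more
  than the combined SD `sqrt(sd_c² + sd_t²)`, and `elongated_lag`
  analogously. Conditions that never grow are reported as such and carry
  no flags.

Curves that have not plateaued within the observation window are fitted
anyway; the asymptote then carries a large standard error, which is
reported rather than suppressed.

## Chlorophyll spectrophotometry

Absorbances at 663 and 645 nm are corrected by the 750 nm reading
(`E = A − A750`) and converted to concentrations (μg/mL) with the
acetone/methanol extraction coefficients: chl a = (12.25·E663 −
2.55·E645)/V, chl b = (20.31·E645 − 4.91·E663)/V, total = (17.76·E645 +
7.34·E663)/V. The total equation is the exact coefficient-wise sum of the
other two, so `chl_a + chl_b == chl_total` is an identity; the package
asserts it property-wise. Negative computed concentrations (possible with
noisy near-zero readings) are flagged, not clamped — clamping would
silently break the identity. Per-cell content uses 1 OD750 ≈ 10⁷ cells/mL
and is reported in pg/cell.

The synthetic generator inverts the 2×2 linear system of the a/b
equations, so a noiseless round trip through the analysis reproduces the
generating concentrations to machine precision.

## Swimmer simulation

The generator is a two-state active-particle model on a square field
(defaults: 512 px × 0.4 μm/px = 204.8 μm, frame interval dt = 0.0396 s):

* **Swimming.** Each cell draws a constant speed from a Gamma
  distribution parameterised by mode `v_mode` (45 μm/s for controls) and
  shape `v_shape` (default 25, giving a single-peaked distribution with
  ~9 μm/s spread, matching the single-peak control speed histograms).
  The heading performs a wrapped-Gaussian walk with per-step sd
  `sigma_rot` (default 0.25 rad). Boundaries are reflective, which avoids
  truncation artifacts in the small field.
* **Stalling.** At each step a swimming cell enters an absorbing stalled
  state with probability `1 − exp(−(r0 + g·C·f(E))·dt)`, where `C` is the
  Ag⁺ concentration (μM), `E` the exposure time (min), and
  `f(E) = min(E/45, 1)` a saturating onset ramp. Defaults r0 = 0.001 /s
  and g = 0.06 /s/μM make ~80 % of cell-time stalled at 2.35 μM after
  60 min — reproducing a strong speed collapse — while controls stay
  ~96 % motile over a 40 s video. The stall is absorbing within a single
  video because the observation window (≤40 s) is short against any
  plausible recovery; there is deliberately no recovery rate parameter.
* **Stalled jitter.** A stalled cell keeps a fixed anchor and jitters
  around it with sd `jitter_sd` (default 0.05 μm) **along its body axis at
  the moment of stalling**, with a 5× smaller transverse component. The
  anisotropy matters: consecutive steps of isotropic anchored jitter have
  correlation −1/2 and produce turning angles unimodal at π, whereas
  near-colinear axial jitter yields the 0-and-π bimodal turning-angle
  distribution characteristic of stalled cells. Axial jitter is also
  physically sensible for a cell whose residual flagellar activity acts
  along its body axis.

The stall kinetics are a stand-in: rate constants were chosen once to
reproduce the qualitative dose/exposure phenomenology (progressive
dominance of the 0-speed peak, monotone speed decrease and turning-angle
increase), not fitted to any measured time course.

## Video rendering

Cells are rendered as Gaussian spots (sd `cell_sigma`, default 0.8 μm) of
fixed peak amplitude on a flat background with additive white Gaussian
noise; `snr` is peak amplitude over noise sd. The spot models the compact
bright core a phase-contrast objective produces for an in-focus cell; halo
rings, defocus and cell-shape detail are deliberately out of scope. The
spot width sets the fundamental two-point resolution of the scene: two
cells closer than roughly twice the effective blur width merge into a
single intensity maximum and one of them is necessarily missed. At the
default density (40 cells in a 205 μm field) this proximity-driven miss
floor is ≈0.6 % of cell-frames, which is what the detector's false-negative
rate on the standard suite reflects. 16-bit output is default; 8-bit
output compresses the same scene into the smaller dynamic range and yields
identical detections after frame normalisation.

## Detection

A classical multi-scale Laplacian-of-Gaussian blob detector takes the
place of the trained-network detectors such studies use, and is held to
the same accuracy contract (≥96 % true positives, <1 % false positives
and false negatives on the standard suite). Steps: (1) normalise the frame to zero
mean, unit variance — this makes thresholds transferable across bit depths
and illumination; (2) compute scale-normalised LoG responses
(−σ²∇²G_σ) over `n_scales` widths in [`sigma_min`, `sigma_max`]
(defaults 0.6–1.0 μm); (3) standardise each scale by its robust noise
level (1.4826·MAD), because white-noise LoG response scales as 1/σ and a
flat threshold would flood the small scales with false peaks — the
threshold is therefore a z-score (default 8); (4) keep 3×3 local maxima
above threshold, apply distance non-maximum suppression at
`min_separation` (default 1 μm); (5) refine each peak by an
intensity-weighted centroid in a ±2σ window of the smoothed frame
(sub-pixel, ≈0.15 px typical error at snr 10).

Scoring against ground truth uses one-to-one greedy nearest matching
within 2 μm (the cell-radius scale). TP and FN rates are fractions of
ground-truth objects (they sum to 1); FP is a fraction of detections.
True negatives are structurally zero for an object detector.

## Tracking

Detections are linked frame by frame. Candidate (track, detection) pairs
within `max_disp` = 6 μm are assigned by minimising total squared
displacement with the Hungarian algorithm
(`scipy.optimize.linear_sum_assignment` on a gated, padded cost matrix).
Unmatched detections open tracks; a track missing from a frame stays
linkable for `memory` = 3 further frames (frame-index gaps up to
`memory`+1), then closes. Tracks shorter than `min_length` = 10 frames are
dropped — long enough to contribute at least eight turning-angle samples.
Per-frame optimal assignment is verified in the tests against exhaustive
enumeration over all feasible assignment chains for small scenes (≤4
cells, ≤6 frames). Gap frames are never interpolated; all step statistics
use strictly consecutive frames, because the finite-difference velocity
presumes unit frame spacing.

## Motility statistics

Instantaneous velocity is v(t) = (r(t+Δt) − r(t))/Δt with Δt = 0.0396 s;
the directional change per frame is the arccos of the normalised dot
product of consecutive step vectors, clamped to [−1, 1] against float
error, with pairs containing a zero-length step dropped (the angle is
undefined there; stalled-cell jitter steps are almost never exactly zero,
so the π-peak phenomenology survives this rule). The signed variant takes
the sign of the 2-D cross product, with exact reversals broken to +π.

Averaging hierarchy, declared explicitly: steps pool within a replicate
video → replicate means average into the condition mean → dispersion is
the SD across replicate means. Distributions use fixed bins: 5 μm/s on
[0, 150] for speeds, π/20 on [0, π] for angles.

Smoothing is opt-in only (statistics default to raw tracks): independent
penalised cubic smoothing splines for x(t) and y(t)
(`scipy.interpolate.make_smoothing_spline`) with roughness weight λ; the
robustness check asserts the treated-vs-control ordering of speed and
turning-angle means is identical for raw data and λ ∈ {0.1, 1, 10}.

Drift/flow QC: step headings atan2(vy, vx) are tested for circular
uniformity via the mean resultant length R and the Rayleigh test (Zar's
approximation, cross-checked against `pingouin.circ_rayleigh`). A
directed flow of 10 μm/s on top of normal swimming is reliably flagged.
Note the Rayleigh p-value assumes independent headings; pooled steps from
persistent swimmers are autocorrelated, so the gate should be read on R
and used comparatively, not as a calibrated false-positive rate.

## Problem sizes and determinism

Default validation fixtures: 5 videos × 200 frames × 40 cells for the
detection contract, 500–1000 frames for distribution-shape checks, 6
replicates × 16 time points for growth fits. These sizes keep every
statistic well-resolved (≥40 000 ground-truth objects for detection rates,
≥10⁴ steps for histogram modes) while running on a laptop-class machine.
All generators take explicit integer seeds (`numpy.random.default_rng`)
and identical seeds give bit-identical outputs; the pipeline derives
per-stage seeds from one top-level seed so any intermediate file can be
reproduced from the manifest.

## Known limitations

* The swimmer model has no hydrodynamics, phototaxis, cell division, or
  helical-path wobble; its rotational-noise scale is a design default, so
  absolute turning-angle magnitudes of real cells are not reproduced —
  only the dose- and exposure-dependent contrasts.
* Rendering omits phase-contrast halos, defocus blur and intensity
  variation between cells; detector accuracy on real videos will be lower
  than on the synthetic suite, and the printed contract should be read as
  a pipeline regression bound, not a claim about arbitrary microscopes.
* The 2-D simulation confines all cells to one focal plane, which makes
  proximity-driven detection misses more frequent than in a 3-D sample;
  the spot width partially compensates (see above).
* Gompertz fits of curves that end before the plateau extrapolate A; the
  reported uncertainty covers this but no stationary-phase claim should
  be made from such fits.
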