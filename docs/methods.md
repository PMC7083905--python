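# Methods

This note documents the model behind `dwellkit`, the generative
assumptions of its synthetic data, the numerical choices in the fitting
code, and what the test suite does and does not demonstrate.

## Observation model

A fluorescent focus reports a DNA-bound molecule.  The focus disappears
when the molecule dissociates (rate `k_off`, per second of real time) or
when the fluorophore photobleaches (rate `k_b`, per second of
*illuminated* time).  Acquisition is two-phase: a bleach-down phase of
`n_bleach_frames` continuous frames that empties the bright fluorophore
pool, then a single-molecule phase of `n_frames` frames in which each
frame is an exposure of `tau_int` followed by a dark interval `tau_d`
(`tau_d = 0` encodes continuous imaging).  The frame period is
`tau_tl = tau_int + tau_d`.

For a condition with frame period `tau_tl`, a bound-and-unbleached
molecule survives one more frame with probability

    p = exp(-k_off * tau_tl) * exp(-k_b * tau_int)

so observed frame counts are geometric, and the cumulative residence time
distribution (CRTD) — the number of events lasting at least
`t_m = m * tau_tl` — decays with the effective rate

    k_eff = k_b * tau_int / tau_tl + k_off.

Acquiring the same sample over a series of `tau_d` spanning two orders of
magnitude of `tau_tl` makes `k_b` and `k_off` separately identifiable:
`k_eff * tau_tl` is linear in `tau_tl` with slope `k_off` and intercept
`k_b * tau_int` (the package's `linearized_estimate` computes exactly this
classical two-step estimator as a cross-check).

With two dissociation components the predicted relative survival is

    S(t) = sum_i A_i * exp(-(k_b * tau_int / tau_tl + k_off_i) * t),

with amplitudes `A_i > 0`, `sum A_i = 1` shared across conditions.

### Why the fit grid is t_m = m·tau_tl

Frame-quantised geometric survival among *observed* events is
`p_i^(m-1)`, not `p_i^m`, which looks like a one-frame offset against
`S(t_m)`.  But an event is only observed at all if it survives one full
frame, so component `i`'s share of observed events is re-weighted by
exactly `p_i`.  The product `A_i p_i * p_i^(m-1) = A_i p_i^m` lands back
on the absolute grid, and the remaining per-condition normalisation is
absorbed by the free scale.  Evaluating the model at `t_m = m * tau_tl`
is therefore exactly consistent with frame-counted data for every
component simultaneously — including mixtures, where anchoring survival
at the first observed frame instead would bias amplitudes
condition-dependently (this failure mode is reproduced easily in
simulation: a 26 s / 1.1 s mixture refits at ~44 s with the wrong
amplitudes under the shifted grid).

## Global fit

`CRTDGlobalModel.fit()` minimises the summed squared residuals of the
per-condition normalised CRTDs (`N(t_m)/N(t_1)`) against
`c_j * S(t_m)` with `k_b`, `k_off_i`, `A_i` shared and one free scale
`c_j` per condition:

* **Optimizer** — `scipy.optimize.least_squares`, trust-region reflective
  (`trf`), bound-constrained (`k_b, k_off in [0, 100] /s`,
  `A_1 in (0, 1)`, `c_j in (0, 100]`), `ftol = xtol = gtol = 1e-6`.
* **Multistart** — the linearized estimate seeds one start; additional
  starts take `k_off` from a log-spaced grid (1e-3…10 /s; rate pairs with
  `A = 0.5` for the bi-exponential).  The best converged start wins;
  non-convergence is flagged on the results object, never silent.
* **Residual weighting** — unweighted by default (plain least squares);
  `weighted=True` multiplies residuals by `sqrt(N(t_m))` for users who
  want tail de-emphasis.  On the simulated regimes the unweighted
  estimator recovers 18–188 s lifetimes within 4–10% at ~3×10⁴ events,
  and 304 s within ~13% worst-case — the information about very slow
  dissociation lives in a small excess decay over bleaching at the
  longest `tau_d`.
* **Identifiability guard** — fewer than 3 conditions, or under a decade
  of `tau_tl` span, triggers a warning at model construction.

Amplitude ordering is by lifetime, slow (long-lived) component first.

## Bootstrap

Uncertainties are the mean ± SD of refits on random subsamples:
10 replicates, each drawing `floor(0.8 * n)` events without replacement
within every condition, rebuilding the CRTDs and repeating the global
fit.  The resampling unit is the event.  Subsampling (without
replacement) at 80% underestimates the full-data SD by a known constant
factor relative to a classical n-out-of-n bootstrap; it is kept because
it is the convention this analysis reports, and the test suite verifies
the convention (replicate count, subsample sizes, seeded
reproducibility) rather than frequentist coverage.  Non-converged
replicates are excluded from the summary with a warning.

## Model-order selection

`select_model` compares the single- and bi-exponential fits by BIC
computed from the **event-level likelihood**: observed frame counts are
censored-geometric per component, with observed-mixture weights
`A_i p_i / sum_k A_k p_k`, and `n` = number of events (the per-condition
scales do not enter the likelihood and are not counted as parameters;
censoring at the 100th frame is ignored — a `p^99` tail).  A Gaussian
BIC on the CRTD points is also reported for reference, but it is not used
for selection: cumulative survival counts are strongly correlated along
the curve, so the point count grossly overstates the information and the
point-BIC selects a spurious second component on single-component data in
roughly half of simulated datasets.  The event-level criterion selects
the generative order in 10/10 seeded replicates for both the
single-component and the well-separated two-component scenarios.  Ties
and degenerate fits (components collapsing to equal rates) fall back to
the single exponential by parsimony.

## Synthetic data

The generator emulates the study conditions end to end:

* **Schedule** — 11 conditions: continuous plus
  `tau_d = 0.1, 0.2, 0.3, 0.5, 0.9, 1.9, 2.9, 4.9, 7.9, 9.9 s`;
  `tau_int = 0.1 s`; 50 bleach-down frames + 100 single-molecule frames;
  512×512 px field at 106 nm/px (tests use 128×128 for speed).
* **Events** — dwells from the exponential mixture; binding starts
  uniform over phase II (or at frame boundaries in the fast dwell-table
  path); static positions (no diffusion while bound).  An event is
  counted in a frame only if bound for the whole frame period; partial
  frames are ignored — a constant one-frame offset rescales amplitudes
  only, and the generator and fitter are tested as a consistent pair.
  Photobleaching consumes an exponential budget of illuminated time,
  advancing only during exposures; dark intervals are bleach-free by
  construction (this is the premise that lets interval imaging work).
  Zero-frame events are dropped; events reaching the final frame are
  flagged censored and retained by default.
* **Rendering** — each visible molecule adds a symmetric Gaussian spot
  (σ = 1.2 px) of integrated intensity 800 photons on a 20-photon/px
  background; pixel values are Poisson counts plus a 100-count camera
  offset and 2-count Gaussian read noise.  The phase-I frames carry a
  decaying pool of extra emitters purely for realism; it never enters
  the ground truth.  Blinking/photoreactivation is not modelled (the fit
  model has no blinking term).  The defaults put the filtered spot
  response ~20× the filtered background SD — chosen for testability;
  real data SNR statistics are not reproduced, so detection scores on
  fixtures bound algorithmic correctness, not real-data performance.

## Detection and tracking

* **Flattening** — subtraction of a wide median-filtered copy (radius
  10 px).  Because the background is smooth on the kernel scale by
  assumption, the median is evaluated on a stride-decimated grid
  (stride = radius//3) and bilinearly interpolated; `stride=1` gives the
  exact dense median.
* **Discoidal average filter** — mean over the inner disc (radius 1 px,
  Euclidean pixel-centre distance, `<=` comparisons, centre included)
  minus mean over the annulus (1 < d <= 3 px); reflected borders.  The
  exact masks are pinned by a brute-force double-loop oracle test at
  1e-10 on 16×16 images.
* **Threshold** — "8 above background" is implemented as 8 × the robust
  SD (median absolute deviation × 1.4826) of the filtered frame; robust
  statistics resist contamination by the spots themselves.  Connected
  components (8-connectivity) above threshold become one focus each at
  their intensity-weighted centroid; no Gaussian PSF fitting (the 3-px
  linking gate does not require sub-pixel precision).
* **Linking** — greedy nearest-pair matching within 3 px between
  consecutive frames, each focus used at most once; strictly consecutive
  (a single missed frame splits an event — no gap closing).  At sparse
  focus densities greedy coincides with the optimal assignment, which
  the tests verify against exhaustive matching on small instances.
* **Dwells** — `n_frames × tau_tl`; single-frame and censored events are
  kept by default (`min_frames`, `drop_censored` to change).

## Degenerate inputs and edge behaviour

Zero-variance frames yield zero foci (not an error); empty dwell tables
are rejected with a named-column schema error; a movie without its YAML
metadata sidecar produces an error explaining how to supply the
protocol; infinite dwell durations (zero-rate components) are capped at
the phase end before frame quantisation; `k_b = k_off = 0` is rejected
where a finite effective lifetime is required.

## Problem sizes used in validation

Fitting experiments use ~3×10⁴ events over the 11 conditions (2 727 per
condition), matching the order of magnitude of a real multi-repeat
dataset; rendering tests use 60–150 molecules on a 128×128 field.
Recovery performance at these sizes: single-component lifetimes 18–188 s
within 10% in ≥ 10/10 seeds, 304 s within 10% in 8/10 seeds (the
hardest regime: `k_off·tau_tl ≤ 0.03` even at the longest interval);
mixture (26 s / 1.1 s at 32/68%) lifetimes within 20% and slow fraction
within ±0.05 in 10/10 seeds.

## Known limitations

* No correction for undersampling of sub-frame events, no
  hidden-Markov/Bayesian dwell inference, no blinking correction.
* Amplitudes are shared across conditions; the detectability-driven
  depletion of fast components at long `tau_tl` is part of the fitted
  observation model (see the grid discussion above), but real
  condition-to-condition variation in detection efficiency is only
  absorbed by the per-condition scale.
* The bootstrap quantifies estimator spread under resampling of events,
  not biological repeat-to-repeat variability.
* Synthetic movies contain no cell outlines, no diffusing background
  molecules and no drift; detection/tracking scores on them are upper
  bounds relative to real data.
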