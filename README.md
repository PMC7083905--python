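# dwellkit

Residence-time kinetics from single-molecule interval imaging.

`dwellkit` measures how long a fluorescently tagged DNA-binding protein
stays bound in live cells, from time-lapse fluorescence movies.  The
difficulty is that a fluorescent focus disappears for two reasons —
the protein dissociates, or the fluorophore photobleaches — and under
continuous illumination bleaching dominates, hiding any binding that lasts
longer than a few seconds.  Interval imaging solves this by inserting a
dark interval τ_d between fixed 0.1-s exposures τ_int: bleaching advances
only with *illuminated* time while dissociation advances with *real* time,
so acquiring the same sample at many different τ_d separates the two rates.

The package implements the full analysis chain, plus a synthetic-data
generator that stands in for raw microscope movies so that every stage can
be validated against known ground truth:

1. **simulate** — exponential-mixture binding events, geometric
   frame-count observation model, rendered TIFF movies (Gaussian spots,
   Poisson + camera noise, 50-frame bleach-down phase + 100-frame
   single-molecule phase).
2. **detect** — background flattening, discoidal average filter
   (inner radius 1 px, outer radius 3 px), thresholding at 8 robust
   background SDs, centroid localization.
3. **track** — greedy nearest-pair linking of foci within 3 px in strictly
   consecutive frames; apparent dwell = n_frames × (τ_int + τ_d).
4. **kinetics** — cumulative residence time distributions (CRTDs) per
   condition and a global photobleaching-corrected fit.

## The model

For each condition with frame period τ_tl = τ_int + τ_d, the number of
events surviving to time t = m·τ_tl is fit with

    S(t) = c · Σᵢ Aᵢ · exp(−k_eff,i · t),   k_eff,i = k_b·τ_int/τ_tl + k_off,i

where k_b is the photobleaching rate (per second of illuminated exposure),
k_off,i the dissociation rate of component i (one or two exponential
components), Aᵢ the mixture amplitudes (ΣAᵢ = 1), and c a free
per-condition scale.  k_b, k_off,i and Aᵢ are **shared across all
conditions** and estimated by bound-constrained trust-region least squares
(tolerance 1e-6, multistart).  Lifetimes are reported as 1/k_off with
uncertainties from an event-level bootstrap: 10 replicates, each refit on
a random 80% of events per condition, reported as mean ± SD.  Model order
(single vs. bi-exponential) is chosen by BIC on the event-level likelihood.

## Worked example

Simulate the standard protocol (11 conditions, τ_d = 0 … 9.9 s, ~30 000
events) for a protein with a 139-s bound lifetime and a 1/s bleach rate,
then refit:

```python
from dwellkit import (AcquisitionProtocol, KineticModel,
                      CRTDGlobalModel, simulate_dwell_dataset)

protocol = AcquisitionProtocol()                      # 0.1-s frames, 11 tau_d
truth = KineticModel.from_lifetimes(139.0, k_b=1.0)   # 139 s lifetime, k_b = 1/s
dwells = simulate_dwell_dataset(truth, protocol, 2727, seed=0)

model = CRTDGlobalModel.from_dwell_tables(dwells, protocol, order=1)
print(model.fit().summary())
print(model.bootstrap(n_boot=10, fraction=0.8, seed=0).summary())
```

prints

```
Global CRTD fit
==============================================
components:        1
conditions:        11
CRTD points:       885
converged:         True (Both `ftol` and `xtol` termination conditions are satisfied.)
RSS:               0.0149864
BIC:               -9634.57
k_b (bleach rate): 1.003 /s
 slow component:    lifetime 139.8 s (k_off 0.007152 /s), fraction 1.000

                       mean        sd
k_b                1.002724  0.003206
lifetime_slow_s  139.864301  2.111014
fraction_slow      1.000000  0.000000
```

The fitted bound lifetime (139.8 ± 2.1 s, bootstrap mean ± SD) recovers
the generative 139 s, and the bleach rate comes back as 1.00/s — the
separation of the two rates is what the τ_d series buys.  Note the
continuous-imaging condition alone would only measure
k_b + k_off ≈ 1.007/s, i.e. an apparent lifetime of ~1 s.

The same fit runs from rendered movies via the CLI
(`dwellkit simulate / detect / track / fit / report`, or `dwellkit
pipeline --config cfg.yaml` for all stages at once), and accepts
pre-computed CRTD tables (`condition_id, tau_int_s, tau_d_s, t_s, count`
CSV) in place of raw data.

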