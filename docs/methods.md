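# Methods

This note documents the models behind `pascan`, the defaults that matter,
and what the synthetic experiments do and do not show.

## Skin and secretion forward model

The probed quantity is a scalar absorption field evaluated at an effective
probing depth — a linear mixture, with no radiative-transfer or layered
optics:

```
a(x, y, ν, t) = c(x, y) · [ s(x, y, t) · S_sec(ν) + e^{−κ s} · Σ_k conc_k · S_k(ν) ]
```

* **Ridge topography.** `ridge_height(x, y) ∈ [0, 1]` is a cosine stripe
  pattern with period 450 µm (typical adult ridge spacing; configurable),
  optionally bent into concentric arcs ("u" pattern).  The acoustic/contact
  coupling factor is `c = floor + (1 − floor)·ridge` with `coupling_floor =
  0.35`: ridge tops contact the photoacoustic cell, valley floors couple
  weakly, which is what makes valleys dark in the 1040 cm⁻¹ images.
* **Pores.** Pore count is Poisson with mean `density × area` (default
  350 glands/cm²); positions are rejection-sampled onto ridge tops
  (`ridge_height ≥ 0.8`) with ≥ 120 µm mutual spacing.  Each pore has a
  Gaussian secretion footprint (σ = 35 µm), a saturation amplitude
  `s_max ~ N(1.2, 0.3)` in absorption units, and a time constant
  `τ ~ N(15, 3)` min, so secretion is > 98 % saturated after ~4τ ≈ 1 h.
* **Secretion interference** acts twice, following the physical picture
  that the sweat film both absorbs and shields the tissue beneath: it adds
  the surface spectrum `S_sec = S_lactate + S_water` and attenuates the
  sub-surface (skin baseline + glucose) absorption by `e^{−κs}` with
  κ = 1.0 per secretion unit.  A per-acquisition multiplicative fluctuation
  (sd 0.10 per pore) models pulsatile gland activity; it is drawn from the
  acquisition seed, so noiseless configurations remain deterministic.
* **Component spectra** are sums of Gaussian bands (center, σ, height).
  Sodium lactate carries the 1070/1105/1140 cm⁻¹ triplet (σ ≈ 12 cm⁻¹,
  narrow enough that the three local maxima stay on the nearest grid
  points).  Glucose bands sit at 1035/1080/1110 cm⁻¹ with σ = 25 cm⁻¹ —
  plausible C–H–O band positions in the 800–1200 cm⁻¹ window; no measured
  glucose or skin-baseline band shapes were available to copy, so these
  defaults are only qualitatively realistic and are fully configurable.
* **Glucose** enters as `glucose_per_mgdl = 3·10⁻⁴` absorption units per
  mg/dl, putting the glucose contribution near 3 % of the skin baseline at
  100 mg/dl.  That scale was fixed by a forward signal-to-noise
  calculation: with the default instrument noise it leaves a ~2 mg/dl
  spectral-model error at the valley site, so the reference meter's 5 %
  error dominates the achievable MARD — a regime in which calibration
  succeeds but is not trivially noise-free.

## Instrument model

* Beam: rotationally symmetric Gaussian, "90 µm diameter" interpreted as
  the 1/e² intensity diameter (σ = 22.5 µm); kernels are truncated at 3σ
  and renormalized.
* Raster: pixel centers at `origin + step·(k + ½)`, default 30 px × 44 µm
  (1.32 mm field of view, displayed as 1.3 mm at one decimal).
* Resonance: a single Lorentzian gain evaluated at the repetition rate
  (peak Q = 17 at 47.5 kHz, half-power width f₀/Q); acoustic transients are
  out of scope.
* Pulse energy: a smooth Gaussian tuning curve peaking at 1000 cm⁻¹ with
  the 44.2 nJ maximum (a tabulated CSV curve can replace it).  Spectra are
  acquired raw and divided by this curve in `normalize_by_pulse_energy`.
* Noise: additive Gaussian per effective pulse, i.i.d. across wavenumbers —
  the simplest model consistent with lock-in averaging; the std scales as
  `noise_sigma / sqrt(pulses_per_tc · n_repeats)` (1425 pulses per 30 ms
  time constant at 47.5 kHz; 16 repeats by default).
* Resolution criterion: a bar target counts as resolved when the
  across-line modulation contrast reaches 0.10; the width scan uses a
  sampling pitch of min(width/6, σ).  The criterion value is a package
  convention — only the resolved/unresolved outcome at 90 µm is anchored.

## Protocol and chemometrics

The default experiment: hand wash at t = 0 resets secretion; the position
scan and site selection happen at t = 10 min (washing, mounting, frequency
response, and the 2-min scan occupy the first minutes; the exact stage
timing is a package choice); 23 pairs follow on a 5-min cadence (last at
t = 120 min), with the 75 g glucose drink at 20 min so two pre-intake
baseline pairs exist.  Both sites are probed in the same slot and share one
meter reading.  The simulated finger is rigidly fixed, so the closing scan
trivially verifies zero displacement.

The OGTT profile is a Bateman rise-and-decay (absorption rate 0.040 min⁻¹,
elimination 1/70 min⁻¹, peak ~40 min post-intake, default rise 60 mg/dl
over a 90 mg/dl baseline) plus a small smoothed random-walk drift.  The
reference meter applies multiplicative Gaussian error with σ_rel = 0.05,
which reproduces the 68 % within-5 % specification exactly; the implied
95.4 % within 10 % overshoots the stated 93 %, a mismatch accepted in
exchange for a one-parameter model.

Calibration is PLS1 via NIPALS with mean centering only (no further
preprocessing); PCR is provided with the identical prediction contract.
LOO-CV re-centers inside every fold to avoid leakage, caps the candidate
count (default 1..10) at the per-fold usable rank, and selects the global
RMSE-CV minimum, breaking ties toward fewer components.  Numerical
safeguards: Krylov breakdown (‖Xᵀy‖ ≤ 1e−12) stops extraction early;
requested counts beyond `min(n − 1, rank)` are rejected with the attainable
maximum.

## Evaluation

MARD/MAD spreads are population standard deviations (n divisor) of the
per-pair deviations; `ddof=1` switches to the sample convention.  The
Clarke grid uses the standard piecewise 1987 boundaries, evaluated in the
precedence order A → E → C → D → B with inclusive boundaries, so points on
a boundary classify deterministically.

## What the synthetic experiments show — and what they cannot

The generator reproduces the *structure* of the measurement: ridge/valley
contrast, ridge-top secretion blobs growing on a ~15-min time constant,
spectral interference concentrated at the lactate triplet, an OGTT glucose
swing, and meter-limited references.  It does not emulate real skin's
inter-subject variability, sebum chemistry, probe repositioning error,
temperature drift, or depth-dependent optics.  Consequently the synthetic
clinical numbers (MARD ≈ 5 % at the valley site) are not comparable in
magnitude to in-vivo results; only *directional* conclusions transfer, and
the acceptance suite therefore tests direction: the secreting site's MARD
exceeds the valley site's in essentially every replicate (one-sided sign
test over 50 runs), and valley-site MARD stays below 10 % in ≥ 90 % of
replicates under default noise.

Problem sizes used by the test and acceptance runs: 50 replicate
experiments of 23 pairs × 2 sites on the 210-point grid, 2000-draw noise
statistics, 10⁵ meter draws, and a 29-width bar-target scan — chosen as the
smallest sizes at which the Monte-Carlo tolerances above are meaningful.

## Known limitations

* Valley identification is intensity-based (darkest eligible pixel), not
  ridge-model-based; with several near-equal minima the row-major tie-break
  is a repository convention.
* The secreting "bright" site falls back to the whole-image maximum when no
  blob clears the median + 3·MAD threshold (e.g. very early scans), which
  on pore-free maps makes the "bright" series effectively non-secreting.
* Scan timing (8.4 s sweeps, 2-min images) is not simulated; time advances
  only on the protocol cadence.
* PLSR ≥ PCR accuracy is a tendency, not a guarantee, and is not asserted.
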