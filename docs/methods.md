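# Methods

## Measurement model

The package models an amperometric somatic-cell-count measurement with three
physical ingredients.

**Current–concentration proportionality.** A platinum microelectrode held at
an oxygen-reduction potential draws a cathodic current proportional to the
local dissolved-oxygen concentration, `I = I_bulk · C/C*`, where `I_bulk`
(negative by convention) is the current read far from any oxygen sink and
`C*` the bulk oxygen concentration. All |ΔI| quantities are reported as
magnitudes; currents themselves stay signed. A measured surface–bulk current
difference therefore converts linearly: `ΔC = (|ΔI|/|I_bulk|)·C*`.

**Hemispherical steady-state diffusion.** Cells confined behind a square
detection port act as an oxygen sink. The port is replaced by an equivalent
hemisphere of radius `r_s` (default: half the port side, 100 μm for the
200 × 200 μm port — this choice, rather than the area-equivalent ≈113 μm,
reproduces the published respiration rates; it is configurable). With
boundary conditions `C = C_s` on the hemisphere and `C → C*` far away, the
steady state is

    C(R) = C* − (C* − C_s) · r_s / R,   R = r_s + r,

and the total consumption rate through the hemisphere is
`F = 2π·r_s·D·(C* − C_s)`. Only the steady state is implemented: the
transient problem is never needed because every derived quantity (ΔC, F,
calibration, imaging radii) follows from the steady-state formula. The
inverse map `ΔC = F/(2π·r_s·D)` is exact, so forward/inverse round-trips
hold to machine precision.

**Per-cell normalisation.** The well holds
`N · V_well · cell_fraction` cells (the suspension is diluted 1:9 into
collagen, so `cell_fraction = 0.1` by default), giving a per-cell rate
`F / (N·V·fraction)` of order 10⁻¹⁶ mol/s for clinical-level samples.

### Default constants

| parameter | default | units | meaning |
|---|---|---|---|
| D | 2.18e-5 | cm²/s | oxygen diffusion coefficient |
| C* | 248 | μM | bulk dissolved oxygen (air-saturated PBS, 25 °C) |
| I_bulk | −1.7 (chip), −1.76 (cone well) | nA | bulk reduction current |
| r_s | 100 | μm | equivalent hemisphere radius of the port |
| V_well | 1.5 | μL | chip well volume |
| cell_fraction | 0.1 | — | cell-suspension fraction of the collagen mix |
| thresholds | 1e5 / 2e5 | cells/mL | normal/subclinical and subclinical/clinical bounds |

The two bulk-current contexts exist because the cone-well and chip
measurement series were referenced to slightly different bulk readings; both
are exposed through `MediumConstants.cone_well()` / `.chip()` and the JSON
config. Internally all physics is evaluated in CGS-style units (cm, cm²/s,
mol/cm³, A); interfaces use μm, μM, pA/nA, μL with converters in
`secmscc.units`. The diffusion field stores the depletion depth ΔC rather
than C_s: ΔC is what every equation consumes, and reconstructing it from
`C* − C_s` would lose all precision for weak fields.

## Scan processing

A z-scan reciprocates the electrode between a surface position (offset
`surface_offset` above the sample, 30 μm on the chip, 20 μm in the cone
well) and a bulk position one scan span higher. With leg duration
`L = span/rate`, surface turnarounds fall at 0, 2L, 4L, … and bulk
turnarounds at L, 3L, …. Cycle *k* pairs the bulk reading at `(2k−1)·L`
with the surface reading at `2k·L`; the t = 0 reading is therefore never
used — scans start immediately after the working potential is applied and
the current is still settling (~20% high) there.

Turnaround readings are taken from a window of ±0.5 s (cone) / ±0.2 s
(chip) around the turnaround. The default estimator fits the current
linearly against |t − t_turnaround| within the window and evaluates the fit
at the turnaround. The reasoning: on a triangular trajectory the electrode
moves through the window, so the current inside it varies with height; a
plain median effectively reads the trace half a window away from the
turnaround and underestimates |ΔI| by several percent (a multiplicative
bias — harmless for calibration, but a real bias on ΔC and F). The linear
fit is unbiased to curvature order (<0.1% on chip geometry) while still
averaging noise across the window. `reading="median"` and `"nearest"` are
available when single-point read-off behaviour is wanted.

When the trace carries a height channel, turnarounds are located at the
height extremum nearest the scheduled time (robust to clock offsets); the
schedule is the fallback. The per-cycle standard deviation is reported
(sample sd, n−1) but never used for exclusion; there is no outlier
rejection and no drift or fouling compensation during analysis — fouling is
an experimental problem solved by collagen embedding, and the simulator can
inject it to demonstrate its effect.

## XY imaging

A raster image at electrode height Z′ shows the depleted patch over the
port. Depletion *reduces* the current magnitude, so a pixel is inside the
diffusion layer when `|I| ≤ |threshold|` (e.g. −1.2 nA is inside a −1.4 nA
threshold, −1.7 nA outside). The half-width L is half the distance between
the outermost passing samples of a fixed-x line profile — an overall
diameter, chosen over the longest contiguous run because noise can split
the run. For a hemispherical layer whose threshold isosurface has radius ρ,
the imaging plane cuts a circle of radius `√(ρ² − Z′²)`, so
`r′ = √(L² + Z′²)` recovers ρ; agreement of r′ across heights (relative
spread from `hemisphericity_check`) is the hemisphericity test. The known
x-direction scan distortion of real SECM images is neither modelled nor
corrected; profiles are taken along y at fixed x.

`z_profile_saturation` finds, on a stepwise vertical profile, the smallest
distance beyond which successive current steps stay below a tolerance
(default 5 pA) — the minimum height that can serve as the bulk position.

## Calibration and classification

Calibration is unweighted OLS of |ΔI| (pA) on cell concentration, with
intercept. The intercept is kept because forcing the line through the
origin does not reproduce inverse estimates from real calibration tables;
measured sd values are carried but not used as weights. Fitting on |ΔI|
rather than ΔC avoids committing to a bulk-current constant; the two differ
by a fixed rescaling and give identical estimates. Inverse prediction
`N = (|ΔI| − b)/a` requires a positive slope; estimates outside the fitted
concentration range are returned but flagged (the line is only validated
over roughly 10⁴–10⁶ cells/mL), and negative estimates clamp to zero with a
warning. No inverse-prediction confidence intervals are computed.

Classification bands: `< low` normal, `[low, high)` subclinical, `>= high`
clinical, with boundaries belonging to the higher band (exactly 1e5 →
subclinical, exactly 2e5 → clinical). Presets substitute the EU (4e5) or US
(7.5e5) regulatory limits for the upper bound.

The respiratory-burst ratio is simply stimulated |ΔI| over control |ΔI|;
immune cells stimulated with PMA show ratios around five.

## The simulator

`simulate_z_scan` / `simulate_xy_scan` run the model forwards:
cells → total rate F (= N·V·fraction·per-cell-rate·burst) → depletion field
→ current along the electrode trajectory, then settling excess (first 5% of
the first leg, ×1.20 by default), multiplicative fouling sensitivity, and
additive white Gaussian noise (default sd 2 pA), all seeded and bit-
reproducible. The default per-cell rate is 1.4×10⁻¹⁶ mol/s, the value the
chip measurements imply. Fouling decays exponentially with
`s(600 s) = retained fraction`: 0.10 bare, 0.99 with collagen embedding;
the cleaning-pulse recovery dynamics of a fouled electrode are not
simulated, only these endpoint retentions.

Off-axis, the field law `R = r_s + r` is generalised by replacing r with
the Euclidean distance from the port centre to the electrode tip. This is a
modelling choice, not a derived result: it reduces to the on-axis law over
the port centre, keeps `C = C_s` on the port, and makes the layer exactly
hemispherical. The true field over a square port is not hemispherical near
the port edge; hemisphericity is adopted globally because the imaging
geometry supports it at the heights of interest.

What the simulator does **not** emulate — and hence what passing tests do
not demonstrate about real data: square-port edge effects, transient
(pre-steady-state) diffusion, 1/f or drift noise (noise is white), the
x-direction raster distortion, electrode kinetics, and any cell biology
beyond a constant per-cell consumption rate. Tests against the simulator
verify the analysis implements the stated model correctly, not that the
model captures every property of a real milk measurement.

## Numerical choices and degenerate inputs

* Turnaround windows clip to the trace; an empty window falls back to the
  nearest sample; a constant window short-circuits the linear fit.
* Traces shorter than one full cycle raise `InsufficientDataError`; partial
  traces use only the complete cycles they cover.
* A profile that never crosses the imaging threshold yields L = 0 with a
  warning; a z-profile that never saturates returns its last distance with
  a warning.
* A demanded respiration rate requiring ΔC > C* raises
  `InfeasibleRateError` (the steady state cannot supply it).
* Calibration needs ≥2 distinct concentrations; a non-positive slope
  produces an inspectable but non-invertible curve.
* JSON configs reject unknown keys by name; reports carry a sha256 config
  hash and the package version for provenance.

## Problem sizes

All analyses and simulations are desk-scale by construction: a 3-cycle chip
trace is 601 samples, a 500 × 500 μm image at 10 μm resolution is 51 × 51
pixels, and calibration involves three points. The full test suite and the
reproduction script each run in seconds on one CPU.

## Known limitations

* The equivalent-radius treatment of the square port and the global
  hemisphericity assumption are approximations inherited from the method
  itself.
* Whether stated sample concentrations refer to the suspension before or
  after collagen mixing is ambiguous in practice; `cell_fraction` is
  exposed rather than hard-coded so either convention can be expressed.
* The calibration line is validated over 10⁴–10⁶ cells/mL only;
  extrapolation is flagged, not forbidden.
* Only live, respiring cells contribute to |ΔI|; counts of samples with
  many dead cells will underestimate the true SCC.
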