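# Methods

## Physical model

Both tracers are treated as strictly intravascular at equilibrium: the
⁹⁹ᵐTc activity resides entirely in red blood cells and the ¹²⁵I activity
entirely in plasma. All activity concentrations are stated at the
reference time t = 0 (euthanasia / tissue freezing) and all exposure
times are hours after t = 0. A phosphor-plate pixel integrates decays
over its exposure window, so the expected photostimulated luminescence is

    PSL(w) = Σ_iso gain_iso · C_iso · m_px · D_iso(w),
    D_iso(w) = (T½/ln 2) · 2^(−t₀/T½) · (1 − 2^(−Δt/T½)),

with `D` the "effective hours" of t = 0 activity deposited in window
`w = [t₀, t₀+Δt]`. `D` is evaluated with `expm1` so the long-half-life
limit `D → Δt` is reached without cancellation; it is verified against
adaptive quadrature at 1e−10 relative tolerance.

In a tissue pixel the concentrations follow from the ground truth:
`C_Tc = (Vrbc/100)·c_Tc,RBC` and `C_I = (Vp/100)·c_I,plasma`, with
`Vrbc = tHct·Vv` and `Vp = (1−tHct)·Vv`. The diluted-blood spot carries
whole-blood concentrations over the dilution factor (50 by default); the
pure-iodine drop carries a configurable stock concentration and no
technetium.

## Default study conditions

- Half-lives: ¹²⁵I 59.4 d, ⁹⁹ᵐTc 6.0 h (overridable).
- Windows: Exp1 = [2, 18] h (an overnight exposure starting once sections
  are cut and plated), Exp2 = [170, 338] h (one week later, one week
  long). Only qualitative durations are known for the original protocol;
  these are fixed, configurable assumptions. With them the theoretical
  iodine window ratio is ≈ 9.33 and the residual technetium fraction in
  Exp2 is < 1e−6 of its Exp1 contribution.
- Blood panel: whole-blood concentrations 2.26 MBq/g (Tc) and
  0.195 MBq/g (I) — a 45.2 MBq RBC dose and a 3.9 MBq albumin dose
  distributed in the ≈ 20 g blood pool of a ≈ 270 g rat — and capillary
  bHct 0.401. Fraction references default to whole blood split by bHct
  (`c_Tc,RBC = c_Tc,blood/bHct`, `c_I,plasma = c_I,blood/(1−bHct)`) and
  may be set explicitly to emulate separately counted centrifuged
  fractions.
- Plate: 50 µm pixels (a configurable assumption; the imager's scan
  resolution is not part of the protocol description), 100 µm section
  thickness, density 1.04 g/mL, and deliberately different per-isotope
  gains (2.0e9 and 1.5e9 PSL per MBq·h) so that any failure to calibrate
  the two channels independently is caught by the recovery tests.
- Phantom: a 200×300 px scene with an elliptical "coronal section"
  (cortical shell tHct 0.296 / Vv 3.5 %, white-matter shell 0.280 / 2.0 %,
  striatal core 0.288 / 3.0 %), three large-vessel disks (Vv 30 %,
  hematocrit inherited from the surrounding tissue), a pure-iodine drop
  and a diluted-blood spot. Lesion overlays (stroke, glioma) can be added
  with their own Vv/tHct. Truth maps carry smooth within-region
  heterogeneity (Gaussian random fields, σ = 4 px; Vv relative SD 10 %,
  tHct absolute SD 0.005) emulating biological texture; both SDs can be
  set to zero for piecewise-constant truth.
- Noise: expected PSL is converted to photostimulated counts (0.5 PSL per
  count), Poisson-sampled, and Gaussian read noise (SD 2 PSL) plus a
  uniform fog offset (10 PSL) are added. Phosphor plates are
  quantum-limited; the parameters are chosen to give tissue SNR ≈ 20 in
  Exp1, comparable to a clean overnight exposure.

## Analysis chain and numerical choices

Order of operations: fog subtraction (median over the background mask) →
inter-exposure intensity correction (mean-ratio over the pure-iodine
spot, a scalar — a single reference drop cannot support a spatially
varying correction) → rigid co-registration → subtraction. Residual
technetium in Exp2 is ignored (bounded < 1e−6 for default timing).
Negative pixels after subtraction are clamped to zero and the clamped
fraction is reported; in a technetium-free scene symmetric noise clamps
≈ 50 % of tissue pixels, which the tests use as a sanity check.

Registration estimates translation by spectral cross-correlation with
upsampled-DFT sub-pixel refinement and rotation by a coarse-to-fine grid
search (±5°, 0.25° then 0.05° steps), each candidate scored by the
correlation residual. Intensities are log-compressed first: the reference
spots are orders of magnitude brighter than tissue and would otherwise
dominate the correlation while being nearly rotation-invariant.
Log-compression restores the tissue structure's weight and brings the
recovery error to ≈ 0.07 px / 0.1° at default noise. The returned
parameters are those of the forward offset (rotation about the image
centre, then translation, in (x, y) = (column, row) axes, row-major
origin top-left); the subtraction stage resamples Exp2 by the exact
inverse. The zero transform is a bit-identical no-op and integer pure
translations are applied exactly; other transforms use cubic spline
interpolation with zero fill.

Calibration and map composition are exact algebra; `tHct = Vrbc/Vv` is
masked (NaN) where `Vv < 0.5 %` to avoid 0/0 in avascular background.
The Vv and tHct composition rules are the only forms consistent with the
distribution-volume definitions and with the whole-blood spot returning
the systemic hematocrit; no small-vessel correction factor is applied —
reported values are direct ratios. Because every instrument factor
appears identically in tissue and reference pixels, the noise-free
pipeline recovers the truth maps to ≈ 1e−9 relative (limited only by the
residual technetium in Exp2), independent of gains, thickness, windows
and hematocrit — the property the acceptance suite checks at 1e−6.

ROI statistics use sample SD (n−1) and report mean ± SD; NaN pixels are
excluded and their fraction reported. Agreement between hematocrit
estimators is summarized by Pearson r and the ordinary least-squares line
of estimate on truth. Histograms use 1-percentage-point bins over
[0, 60] % hematocrit, normalized over defined pixels.

## What the simulator does and does not emulate

It emulates: dual-tracer decay physics, window integration, per-isotope
plate response, internal reference spots, quantum-limited noise, fog,
rigid inter-exposure misalignment, within-region biological texture, and
(optionally) albumin extravasation as a uniform additive plasma-volume
term, which demonstrably depresses recovered hematocrit. It does not
emulate plate fading between exposure and scan, dead-time or scatter,
chemography, 3-D sectioning artifacts, elastic tissue deformation between
exposures, or kinetic tracer equilibration — equilibrium at injection-
to-euthanasia delay is assumed achieved. Passing tests therefore validate
the arithmetic and the separation/calibration logic under realistic
counting statistics, not the biology or chemistry of a real experiment.

## Problem sizes

The test suite runs most scenarios on a 100×140 px scaled copy of the
default phantom (identical anatomy and physics) and the full 200×300 px
scene for registration studies; the acceptance script uses the full
scene, 24 simulated animals for the hematocrit agreement study and 8 for
the control group. These sizes give sub-percent statistical uncertainty
on every reported quantity.

## Known limitations

- The exposure start/duration values are assumptions constrained only by
  "overnight" and "one week"; all derived constants (e.g. the ≈ 9.33
  correction factor) follow from them.
- A scalar inter-exposure correction cannot capture spatial plate-response
  drift between exposures.
- Clamping negatives after subtraction biases the technetium image
  upward in very-low-signal regions; the bias is visible in the
  technetium-free tests and is below the noise floor elsewhere.
- The blood-spot hematocrit estimator assumes the spot is well mixed;
  real diluted-blood standards can sediment before freezing.
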