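# Methods

This note documents the models behind each stage, the defaults and why
they were chosen, what the synthetic generators do and do not emulate,
and the numerical decisions that were genuinely open.

## GUV electrodeformation capacitance

**Model.** The prolate→oblate transition frequency of a quasispherical
vesicle of radius r in a more conductive exterior is
f_cr = λ_in/(2π r C̄_m)·[(1 − Λ)(Λ + 3)]^(−1/2), with Λ = λ_in/λ_out the
interior/exterior conductivity ratio. The formula is taken as given; the
electrohydrodynamic theory behind it is out of scope. The model is valid
only for 0 < Λ < 1 (a more conductive exterior), and the code rejects
anything else as a domain error rather than extrapolating.

**Fit.** f_cr is linear in x = 1/r with zero intercept, so the estimator
is the closed-form through-origin ordinary-least-squares slope
k = Σx_i y_i/Σx_i². No weighting is applied: per-vesicle frequency
uncertainties are rarely recorded, and the multiplicative-noise model
below gives nearly homoscedastic relative errors, which unweighted OLS on
this near-one-decade radius range handles with negligible efficiency
loss. The standard error of C̄_m follows from the exact Jacobian of
C̄_m ∝ 1/k. "GF" is reported as the coefficient of determination R² with
a centred total sum of squares; the convention is recorded in the result
record (`gf_definition`) because other definitions exist. A batch of one
vesicle yields a point estimate only when explicitly requested, with NaN
uncertainty and NaN GF — flagged, never silent.

**Double layers.** Each aqueous side contributes a diffuse-layer
capacitance modelled as a planar capacitor of thickness
λ_D = 0.303/√c nm (1:1 electrolyte, molarity c) and permittivity
ε_r = 80. Concentrations are the nominal NaCl molarities (inner
1.0 mmol/L, outer 1.1 mmol/L by the standard 0.1 mmol/L conductivity
offset); sugars are non-electrolytes and do not enter c. Both
concentrations, ε_r and ε_0 are arguments, not constants buried in code:
ε_0 defaults to 8.854187e−12 F/m, with the two-decimal rounded value
available for compatibility with work that used it. The bare capacitance
is C_m = (1/C̄_m − 1/C_D,in − 1/C_D,ex)^(−1); its SD uses the delta
method with the double layers held fixed, sd(C_m) = sd(C̄_m)·(C_m/C̄_m)².
An effective capacitance too large for the stated double layers is a
physical inconsistency and raises rather than returning a negative value.

## FFT impedance spectroscopy

**Circuit.** Z(ω) = R_s + [jω(C_BLM + C_TM) + 1/R_BLM]^(−1): bilayer
capacitance and resistance in parallel, shunted by the Teflon-film
capacitance C_TM (56.33 pF measured independently — comparable to C_BLM
itself, so omitting it biases C_BLM upward by almost exactly C_TM, as a
dedicated test demonstrates), fed through the solution resistance R_s.
Defaults: aperture area S_m = 8×10⁻⁵ cm² (100 µm hole) and
R_s = 100 kΩ, inside the 36–136 kΩ range typical of these cells.

**Acquisition model.** The simulated instrument applies a coherent
multisine (~10 mV peak-to-peak) over 1.5 Hz–50 kHz: 30 quasi-log-spaced
tones snapped to exact FFT bins (bin width 0.5 Hz at the default
131 072 Hz / 262 144-sample record), Schroeder phases for low crest
factor (random phases with a recorded seed are available). Coherent
sampling makes the excited bins leakage-free, so the frequency-domain
current response is exact for a linear circuit; the simulation still
round-trips through the time domain as the instrument does. Measurement
noise is proportional complex Gaussian on Z (σ = noise_frac·|Z| on real
and imaginary parts independently, default 1%); no published noise
characterization exists for these spectra, and a proportional model is
the standard assumption when |Z| spans five decades. An independent
state-space time-domain simulation (scipy.signal.lsim of the circuit ODE)
cross-checks the FFT path in the test suite to <0.1%.

**Fit.** Complex nonlinear least squares over (C_BLM, R_BLM, R_s) with
C_TM fixed, minimising Σ w_k|Z_k − Ẑ_k|² with modulus weighting
w_k = 1/|Z_k|² — without it the low-frequency points (|Z| ~ 10⁹ Ω)
dominate the megaohm-scale high-frequency region entirely. Parameters
are log-transformed, which enforces positivity without constraints;
initialisation takes R_s from the high-frequency Re Z plateau, total
capacitance from the highest-frequency −Im Z point, and R_BLM from
low-frequency extrapolation or 10× the largest |Z| when the arc is
truncated (at the defaults the Nyquist apex lies near 0.075 Hz, far below
the 1.5 Hz window edge, so the arc is always truncated). Levenberg–
Marquardt with three perturbed restarts on failure; standard errors from
the Jacobian at the optimum, transformed back from log space. GF is
1 − (weighted RSS)/(weighted TSS). Per-condition summaries use the
inverse-variance weighted mean with standard error (Σ1/σ²)^(−1/2).

## Fluorescence metrics

GP, anisotropy and the grating factor are exact ratios of the recorded
intensities; both GP and r are invariant under overall intensity scaling,
which the property tests enforce. Band intensities for GP are read at
the grid point nearest 440/490 nm by default; a ±boxcar average is
available since no bandwidth convention is universal (instrument slits
here are 5 nm). Ordered-phase Laurdan emission is described at
430–440 nm depending on context; the GP definition fixes the evaluation
band at 440 nm while the generator's ordered-peak centre is configurable.
Background subtraction is a paired-blank operation when a blank is
supplied, otherwise a no-op. The di-8-ANEPPS map
Ψ_d = (R_ex + 0.3)/0.0043 uses published calibration constants treated
as configurable defaults; potentials are kept at full precision
internally and rounded to integer mV only for table presentation.

## Permittivity decomposition

ε_rm = C_m·d/ε_0 needs a total bilayer thickness, which is a user input
(the default worked-example value 4.17 nm is reverse-engineered from
ε_rm ≈ 2.4 at C_m = 0.51 µF/cm² and is close to 2·0.9 + 2.71 = 4.51 nm
from the layer geometry). The three-layer split uses per-leaflet
headgroup thickness 0.9 nm, capacitance 15 µF/cm² (ε_head ≈ 30) and
hydrophobic thickness 2.71 nm — literature values for PC bilayers; every
field is overridable per condition because sugar-thinned core thicknesses
come from external scattering work and are not derivable here. With the
unthinned defaults, the sucrose capacitance increase (0.51 → 0.65 µF/cm²)
maps to a ≈30% core-permittivity increase; the published ~14% figure used
condition-specific thinned thicknesses, so it is not reproduced by the
defaults and the package makes no claim to it.

## Synthetic data

Each generator inverts its analysis operation and adds a documented noise
process; all are deterministic functions of (parameters, seed).

* **Vesicle batches** — radii from a truncated lognormal on 5–25 µm
  (median 12 µm, log-σ 0.35; GUV preparations produce tens-of-µm vesicles
  with a right-skewed size distribution) or a uniform law for controlled
  recovery studies; exact f_cr from the transition-frequency model; unit-
  mean multiplicative lognormal noise, default CV 3% — consistent with
  the ~5–10% per-batch capacitance SDs such campaigns report at n = 6–15.
* **Impedance spectra** — either the full multisine/FFT chain or a fast
  analytic path on the same grid (both exposed; they agree to <0.1% at
  zero noise), with the proportional complex noise model above.
* **Laurdan spectra** — two unit-height Gaussian peaks (centres 440 and
  490 nm, σ 30 nm) mixed by a weight w(T) that interpolates affine-
  logistically (midpoint 40 °C, scale 10 °C) between endpoint weights
  solved in closed form so the band-centre GP equals the calibrated
  endpoints: control 0.05 at 20 °C, −0.35 at 60 °C. Requested GPs outside
  the achievable range of the peak shapes raise rather than clip.
* **DPH quadruples** — I_VV = S(1+2r)/3, I_VH = S(1−r)/(3G), with the
  horizontal pair carrying the grating factor; exact inversion at zero
  noise.
* **ANEPPS pairs** — the inverse calibration R_ex = 0.0043·Ψ_d − 0.3
  scaled to intensities; potentials implying non-positive ratios are
  rejected as unphysical.

**What the generators do not emulate:** vesicle contour extraction and
image noise, drift/stationarity violations during an EIS acquisition,
electrode double layers, spectral instrument-response curves, dipolar
relaxation kinetics, or any mechanistic sugar–lipid interaction (sugar
effects enter only as configured parameter offsets). Passing recovery
tests therefore demonstrates correctness of the estimators under the
stated statistical models, not robustness to these real-world effects.

## Problem sizes and tolerances

Recovery studies use 200 batches × 7 vesicles (GUV) and 100 spectra × 30
frequencies (EIS), sizes at which the Monte-Carlo error of the mean is
comfortably below the 2% bias bounds being checked while the whole suite
runs in well under a minute. Zero-noise closed-loop identities are
asserted at 1e−12 relative (exact algebraic inversions) or 1e−6–1e−8
(through the optimiser/FFT). Known degenerate inputs — identical radii,
fewer than two vesicles, fewer than four frequencies, Λ outside (0, 1),
non-coherent multisine tones, unreachable GP targets — all raise typed
errors with the offending values named.
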