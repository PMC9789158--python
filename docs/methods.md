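# Methods

This note documents the models implemented in `rotorscan`, the choices made
where the underlying physics or procedure admitted more than one reasonable
design, and what the synthetic tests do and do not demonstrate about real
measurements.

## 1. Geometric-optics depth response

### Model

The instrument is reduced to an ideal aplanatic objective (Abbe sine
condition) of numerical aperture NA and magnification M, perfectly corrected
for the design coverslip (thickness and index enter only through that
assumption), with a circular pinhole of physical diameter d at the image
plane, i.e. radius `r_p = d/(2M)` in object space.  The single aberration
source is Snell refraction at the coverslip/sample interface.  The stage
coordinate z_F follows the stage readout: after focusing on the interface, a
displacement z_F moves the unaberrated convergence point z_F beyond the
interface; the physical caustic in the sample is whatever refraction of the
aperture cone produces.  `design_aberration_free=True` suppresses the
interface refraction (equivalently, fills the sample half-space with
coverslip glass), defining the "index-matched" reference.

Two ray families are traced per focus position, each sampled with the
seeded PCG64 generator:

- **Excitation.**  Rays uniform in pupil area (`sin θ_air = NA·√u`), aimed
  at the nominal focus through the coverslip-side angles, refracted at the
  interface (`n_cs sin θ_cs = n_s sin θ_s`), then binned as radial fluence
  on an (r, z) grid with track-length weight 1/cos θ_s.
- **Detection.**  Rays launched backwards from the pinhole: uniform over the
  pinhole disc in object space and uniform over pupil area, through the
  conjugate plane at z_F, refracted at the interface, binned identically.
  Because uniform (pinhole area × pupil area) sampling realises a uniform-
  radiance source, this reverse fluence is proportional to the fraction of
  an isotropic emitter's 4π photons accepted by the pinhole — the detection
  efficiency D(r, z).  This estimator was cross-checked against a direct
  per-emitter acceptance-cone Monte Carlo and agrees; its variance at large
  defocus is orders of magnitude lower, which matters for the far-field
  1/z_F² law.

The axial origin density follows per slice as
`φ(z|z_F) ∝ Σ_r I_ex(r,z)·D(r,z)·2πr Δr`, evaluated at the z-grid nodes
(no slice-averaging; the surface value φ(0,·) is a point evaluation at
z = 0, well inside the 0.25 µm resolution the surface estimate requires).

### Numerical choices

- Radial bins 0.1 µm.  Depth grid: 0.25 µm steps to 5 µm, 0.5 µm to just
  past the deepest focus, then geometric widening (factor 1.1) to roughly
  three times the deepest focus — resolution near the caustic, reach in the
  far field.
- Normalisation integrates the grid by trapezoid and appends the analytic
  far-field tail `c/(z−z_F)²` beyond the last node, with c fitted on the
  outer decade of the grid.  The tail is a small (< 5%) correction.
- Default 10⁶ rays per family per focus position; the per-z_F RNG streams
  are spawned from one seed, so identical seed + configuration reproduce the
  response bit for bit.
- Configuration validation rejects total internal reflection of any
  aperture ray (NA ≥ min(n_coverslip, n_sample)), zero pinholes and
  non-monotone grids.

### Behaviour and limitations

For the 20x/NA 0.75, 56.6 µm pinhole, water-sample configuration the model
gives φ(0,0) ≈ 0.27 µm⁻¹, R_th decaying to ~0.01 by 20 µm of defocus, and a
log–log far-field slope of −2.0 for φ(0, z_F).  In index-matched mode
H(z_F) rises monotonically and saturates just below 2, the exact geometric
bound for a half-space emitter.

Two caveats follow from the strictly geometric treatment.  First, the focus
is a perfect point at z_F = 0, so the axial response lacks the ~2 µm
diffraction broadening of the real instrument; φ(0,0) is correspondingly at
the high end of what a wave-optics treatment would give.  Second, under
index mismatch the model redistributes detected photons across depth but
barely changes their total, so the measured decline of H at large depth in
strongly mismatched samples — an interference/apodisation effect — is not
reproduced; H under mismatch is nearly indistinguishable from the matched
curve here.  Neither caveat affects the quantities the analysis consumes
(φ(0,0), R_th normalised shapes) at the level of the recovery tests below,
but absolute comparisons of φ(0,0) with diffraction-aware simulations
should expect differences of order 10–30%.

## 2. Surface-density estimation

`U(z_F) = I_N/H` obeys `U = (1 + Kφ00 R_th)/(1 + Kφ00)`.  Two estimators of
K are provided:

- **asymptotic** — `K_i = (1−U_i)/(φ00 U_i)` at each analysis depth,
  treating U there as the asymptote.  This is exact only where R_th has
  fully decayed; at the default depth set {5, 7, 10, 20, 30} µm the residual
  R_th (≈ 0.2 at 5 µm) biases K_i low by the factor
  `(1−R_th)/(1+Kφ00 R_th)`.
- **corrected** (default in `SurfaceAdsorptionModel.fit`) — the exact
  inversion `K_i = (1−U_i)/(φ00 (U_i − R_th,i))` using the ray-traced R_th
  at each depth.  Noiseless, this recovers K at machine precision at any
  depth.

Under multiplicative intensity noise the information content varies wildly
across depths (shallow depths carry almost none when K is large), so the
corrected estimator combines the per-depth K_i with inverse-variance
weights from first-order propagation, `w_i ∝ [(1−U)(U−R)/(U(1−R))]²`
evaluated at a median pilot estimate.  The reported `k_sd` stays the plain
standard deviation of the K_i over depths — the spread a per-depth error
bar would show — and σ's uncertainty is propagated linearly from it.
Noisy U values above 1 are flagged and mapped to K_i = 0 (K is
non-negative by construction); U below R_th (possible only through noise)
excludes that depth with a warning.

Unit conventions: lengths in µm, σ in µm⁻², ρ accepted in molarity and
converted via N_A = 6.02214076×10²³ (1 M = 6.02214×10⁸ µm⁻³).  Monolayer
coverage is σ·s_mol with s_mol defaulting to 1 nm²; the tube partition
ratio 2σ/(rρ) uses the same conversion.

The lifetime route is implemented alongside: the empirical collapse
`R_τ = (⟨τ⟩−τ_B)/(⟨τ⟩(0)−τ_B)` and, for monoexponential surface and bulk
species, the identity
`R_th/R_τ = φ00⁻¹/(φ00⁻¹ + (τ_B/τ_S)K(1−R_τ))`, which the tests verify
exactly against a two-species mixture oracle.  It is a consistency check,
not the primary estimator, because real rotor decays are biexponential.

## 3. TCSPC decay analysis

Histograms are fitted by Poisson maximum likelihood (counts are Poisson,
and tail bins hold few of them) with a biexponential-plus-background model.
Without an IRF width the fit is a tail fit from the bin after the histogram
maximum — matching practice when the instrument response is not
deconvolved — with every component carrying the periodic-excitation factor
`1/(1−e^(−T/τ))` for repetition period T.  Supplying `irf_fwhm` switches to
Gaussian-IRF reconvolution over the whole record (stable
exponential-Gaussian branches via erfcx) with the IRF centre fitted as a
free parameter.  Optimisation runs Nelder–Mead then BFGS from three
heuristic starts (two-segment log-slope initialisation), in log-parameter
space with soft box penalties; covariance comes from a central-difference
Hessian of the NLL at the optimum.

A nested monoexponential fit is always evaluated; if the second component
fails a likelihood-ratio test (Δ2NLL < 5.99, the 95% point of χ²₂) the
monoexponential result is reported with A₂ = 0.  This avoids the
degenerate, seed-dependent amplitude splits a forced two-component fit
produces on truly single-exponential data.  Components are ordered
τ₁ ≤ τ₂, and ⟨τ⟩ = (A₁τ₁+A₂τ₂)/(A₁+A₂) always lies between them.

The Förster–Hoffman calibration `τ = C η^α` is fitted by least squares in
log–log space (exact on noiseless power-law data, scale-equivariant by
construction).  Its inversion `η_I = (τ_plateau/C)^(1/α)` locates the
viscosity where the bulk lifetime reaches the surface plateau; the quantum
yield there comes from a user-supplied Φ(η) table or, by default, a power
law through the single documented anchor Φ(2×10⁴ mPa·s) = 0.15 sharing the
fitted exponent (both lifetime and yield being governed by the same
non-radiative TICT channel).

## 4. Synthetic data

The generator emulates the study conditions: 10⁻⁷ M dye in glycerol/water
from 0 to 99 wt%, hydrophobic surfaces carrying σ of order 3×10³ µm⁻² in
water (≈ 0.3% of a monolayer) falling roughly tenfold in concentrated
glycerol, hydrophilic surfaces carrying none.  Default photophysics are
anchored to measured values only: τ_B(1 mPa·s) = 0.12 ns, surface plateau
τ_S = 1.7 ns, and the common intersection (2×10⁴ mPa·s, Φ = 0.15), which
fix α ≈ 0.2675 and Φ_B(η) = 0.15(η/2×10⁴)^α — in water Φ_B ≈ 0.011, so
σ = 3300 µm⁻² corresponds to K ≈ 7.8×10² µm.

Solvent viscosity follows the Cheng (2008) glycerol/water correlation at a
default 22.5 °C: room temperature, chosen because it reproduces the studied
viscosity span (1–900 mPa·s for 0–99 wt%; at 20 °C the correlation would
put 99 wt% near 1140 mPa·s, outside that span).  Refractive index
interpolates linearly from 1.333 (water) to 1.473 (glycerol).

Z-scan intensities are the closed-form signal model
`I ∝ H(z_F)(1+Kφ(0,z_F))/(1+Kφ00)` times multiplicative lognormal noise of
chosen coefficient of variation (a proxy for shot noise and slow drift; the
default 1% matches a well-averaged scan).  Per-depth lifetimes mix the two
species with amplitudes proportional to intensity/τ — the same
two-monoexponential simplification underlying the R_th/R_τ relation; real
decays are biexponential per species, so synthetic ⟨τ⟩ profiles are cleaner
than measured ones.  Decay histograms are Poisson draws from the
(optionally IRF-convolved, wrap-around-corrected) expected profile.

What passing tests show: the estimators invert the forward model they
assume, exactly without noise and within a few percent at 1% noise, across
two decades of σ, and the fitting machinery recovers known decay
parameters within their confidence intervals.  What they do not show:
correctness of the geometric φ(0,0) against a diffraction-aware treatment,
robustness to drifts that are not multiplicative lognormal (bleaching,
stage drift), or the behaviour of the hydrophilic-side scan through the
droplet, which is outside the model.

## 5. Problem sizes

Default test and script sizes are chosen for desk-scale runs: 1–4×10⁵ rays
per focus position in the shared test fixtures (Monte Carlo error on
φ(0,0) of a few percent), 10⁶ rays for the headline φ(0,0) computation,
10⁵–10⁶ photons per synthetic decay.  The full suite runs in about a
minute on one CPU; the acceptance script in well under one.
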