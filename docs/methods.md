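# Methods

## The kinetic model

All modalities share one kinetic descriptor: a sum of logistic terms plus
a constant background,

    f(t) = b + Σᵢ f0ᵢ / (1 + exp(−(t − t0ᵢ)/Δtᵢ)),

with amplitudes f0 in the observable's units (negative for a vanishing
contribution such as a dissolving gel-like intermediate phase),
inflection times t0 and characteristic times Δt in hours.  Two exact
identities anchor the parameterization and are asserted in the tests:
f(t0) = b + f0/2 per component, and the maximum growth rate
f′(t0) = f0/(4Δt).

Fitting is weighted least squares (`scipy.optimize.least_squares`,
trust-region reflective with Jacobian-based parameter scaling).  Starting
points come from the data: t0 at the steepest finite-difference slope,
Δt = span/10, f0 = data range; multi-component fits add five jittered
restarts (deterministic auxiliary RNG) to escape label switching, and
components are reported sorted by t0 with the covariance permuted
accordingly.  Bounds keep fits identifiable on finite windows: Δt ∈ (0,
span], t0 within one span of the observation window.  Uncertainties come
from (JᵀWJ)⁻¹ scaled by the reduced chi-square, with per-column
equilibration of the Jacobian so that parameters of wildly different
magnitude (diffusion coefficients ~1e−11 m²/s next to times ~1e2 h)
do not defeat the pseudo-inverse.  Non-convergence and degenerate
(constant) inputs set flags on the result, never silent.

Error weighting is applied when per-point uncertainties are available
and the fit is unweighted otherwise; both modes exist because the
original fits' weighting convention is not recoverable.

## DLS

The normalized intensity correlation is fitted as the Siegert-squared
double exponential g₂−1 = β[a e^(−Γ₁τ) + (1−a) e^(−Γ₂τ)]² with
a ∈ [0, 1], β the intercept and Γ₁ ≤ Γ₂ enforced by relabelling (slow:
crystals/precursors; fast: dissolved protein).  An unsquared variant is
available as a sensitivity switch, because the printed form of the
correlation model (squared field correlation vs plain sum, presence of
β) is ambiguous in the source material; the squared form is the default
since g₂−1 is what the correlator measures.  The fit uses an analytic
Jacobian and an unconstrained MINPACK fast path with a bounded
trust-region fallback; when a pins at a bound the result collapses to
the canonical single-decay form (a = 1, Γ₁ = Γ₂ = rate, flagged).
Within a dataset, each angle's fit warm-starts from the previous age.

Repeat correlograms are averaged after dust rejection: residuals about
the per-lag median are compared against 5× a robust noise model
σ(lag) = c_mult·|signal| + c_floor pooled over all lags (a per-lag MAD
from ≤5 repeats is itself too noisy and rejects ~4% of clean points;
the pooled model keeps false rejection below 1%, the level reported for
the real data, while still catching isolated spikes).

Decay rates convert to diffusion coefficients by weighted straight-line
fits of Γ against q² through the origin (pure Fickian; a diagnostic
intercept is deliberately not part of the default).  The q values come
from q = (4πn/λ) sin(θ/2) with λ = 633 nm and n(D₂O) = 1.333
(configurable; not stated in the source).  D₂(t) is fitted with two
sigmoids plus a constant background — the background carries the
pre-growth diffusion level.

## NSE

Polarized spin echo sees coherent and spin-incoherent scattering with
opposite signs, so the normalized ISF is modelled as
I(τ) = a_coh e^(−γ_coh τ) − a_inc e^(−γ_inc τ); with γ_inc > γ_coh this
reproduces the initial rise at sub-nanosecond Fourier times seen above
q ≈ 0.2 Å⁻¹.  Because the signal may have partially decayed before the
first measured τ, the amplitudes are not fixed from theory: the
difference a_coh − a_inc is pinned to the measured value at τ < 15 ps.
(The source text is contradictory — it speaks both of fixing the "sum"
and of a fixed a_coh − a_inc; with the minus sign in the model only the
difference is the short-time limit, so the difference convention is the
default and the sum convention sits behind a switch.)

At the Bragg position the coherent part becomes s + (1−s)e^(−γ_free τ):
crystals are immobile on the accessible timescale, so their
contribution does not decay.  γ_free is held fixed (not co-fitted, to
avoid the s/γ degeneracy) from a D q² interpolation of the *adjacent*
non-Bragg q values only — incoherent-dominated high-q curves have
ill-determined coherent rates and would bias the interpolation; the two
nearest neighbours, error-weighted, are used.

The series s(t) is baseline-subtracted at t = 0, normalized to unit
maximum, and fitted with a sigmoid with free amplitude *and* a free
constant background: simulation shows that subtracting the single noisy
t = 0 point otherwise biases Δt low by about 1 h.

## NBS fixed-window scans

Under a single-Lorentzian quasielastic assumption the two inelastic
channels (offsets ω₁ = 1, ω₃ = 3 µeV) invert in closed form,
γ = √((ω₃² − Rω₁²)/(R − 1)), valid for 1 < R < (ω₃/ω₁)²; ratios outside
that window (motion too slow or too fast for the offsets) are masked or
raised depending on the entry point.  When a resolution model is
supplied the convolved ratio is inverted numerically instead; the
convolution of the Lorentzian with the unit-area Gaussian resolution
(FWHM 0.9 µeV — only the width is documented, the Gaussian shape is a
modelling choice) is the Voigt profile and is evaluated with
`scipy.special.voigt_profile`, cross-checked against direct quadrature
in the tests.

γ(q) = ħDq² + c is fitted over 0.4 < q < 1.4 Å⁻¹ (ħ = 0.6582119569
µeV·ns) for the effective short-time self-diffusion D and the offset c
absorbing localized internal motions.  A saturating jump-diffusion
alternative was considered and rejected as the default: the linear form
is what the offset-c wording implies.

The elastic amplitude extraction solves the exact two-component forward
model per q — measured channel = c_e R(ω) + s_FWS (L⊗R)(ω) at ω ∈ {0,
ω₁, ω₃} — as a weighted linear least-squares problem in (c_e, s_FWS).
Solving jointly rather than sequentially matters: a 0.9 µeV FWHM
Gaussian still places ≈3% of the elastic line at 1 µeV, and as the
elastic fraction grows during crystallization that leak contaminates
the ratio and biases D(t) and the kinetic times.  The pipeline therefore
iterates (four passes): subtract the current elastic estimate's leak
from the inelastic channels, re-invert γ, re-solve the amplitudes.
c_e(t), averaged over 1.1 < q < 1.8 Å⁻¹, baseline-subtracted at t = 0
and normalized to the final value, is the crystal fraction c_NBS(t),
fitted with a sigmoid plus free background.  Solvent frames can be
subtracted channel-wise with a configurable scale (default rationale:
1 − protein volume fraction ≈ 0.945 at 75 mg/ml).

## Diffraction

Per frame, the dissolved-protein signal across an exclusion window
|q − q_Bragg| ≤ h (default h = 3× the fitted peak width of the final
frame) is estimated by linear interpolation between the means of three
flanking points per side, and the summed excess above it is the crystal
signal.  The integrated excess (not the peak height) is the default
observable — more robust under wavelength-spread smearing; any baseline
shared by all frames cancels exactly in the subtract-and-normalize step,
which the tests assert.  Peak location refines the grid maximum with a
local quadratic; a peak below 3σ of the flanking scatter raises
not-found, and a maximum on the window boundary is returned unrefined.
Optional Gaussian q-smearing with Δλ/λ = 8% broadens the peak but leaves
the fitted kinetics unchanged.  The low-q channel I(q₀, t)/I(q₀, 0) at
q₀ = 0.096 Å⁻¹ is fitted with a sigmoid plus constant background and
needs no Bragg peak at all.

## Microscopy

Each crystal's 2D-projected area A(t) is fitted independently (≥5
points; failures are counted, not silently dropped).  The population is
summarized by Freedman–Diaconis histograms (edges recorded for
reproducibility) and error-weighted means m = Σ(x/σ²)/Σ(1/σ²).  Volumes
assume cubic crystallites, V = A^{3/2}, with linear error propagation
floored at σ^{3/2} so zero-area points keep positive uncertainty; the
volume refit gives the surface-to-volume-corrected parameters.  This
naive conversion is a documented default: it sharpens Δt (a power of a
sigmoid is steeper) but does not by itself reproduce the much larger
t0 shift that the original volume correction (whose details are in
unavailable supplementary material) produced.  The synthetic-image
segmenter (threshold, connected components, centroid tracking) exists
only to close the loop on generated image stacks; it is not a real
micrograph-analysis tool.

## Synthetic data: what it emulates, and what it does not

The generators reproduce each modality's forward model with the study's
sampling cadences (2 h for spin echo, 30 min otherwise) and noise
defaults chosen to match the scatter of the published data: 1%
multiplicative (DLS), 3% of the short-time plateau additive (NSE),
Poisson at ~10⁴ elastic counts (NBS), 3% additive (diffraction,
microscopy).  Kinetic ground truths use the experiment's fitted values
(e.g. Bragg-peak growth t0 = 48.98 h, Δt = 7.15 h; elastic fraction
t0 = 40.0 h, Δt = 11.48 h; DLS double sigmoid 96.93/108.19 h).
Observation windows are 0–80 h for the neutron probes (beamtime-limited
in the real experiment), 0–150 h for DLS and 0–120 h for the slow low-q
process, each long enough to pass the corresponding inflection.

Deliberately not emulated: multiple scattering and turbidity in early
DLS frames, sedimentation of crystals out of the beam, internal protein
dynamics in the NSE signal, coherent contamination of the NBS signal,
container-specific surface nucleation differences, and any
crystallographic structure (the Bragg peak is a Gaussian, not a
structure factor).  Passing recovery tests therefore demonstrate that
the *inference chain* is unbiased and correctly weighted under the
stated noise — not that these real-data complications are handled.

## Known limitations

* The spin-echo immobile-fraction chain is information-limited: at 3%
  ISF noise the per-curve estimator for s is already at the Cramér–Rao
  bound (sd ≈ 0.04), and with 41 two-hourly points the s(t) sigmoid fit
  cannot determine t0 better than ±1.7 h (1σ).  The package reports
  honest uncertainties of that size; demanding sub-hour recovery from
  this modality at these conditions is not achievable, which matches the
  ±1.8 h uncertainty the real experiment reported for it.
* The closed-form ratio inversion ignores resolution convolution by
  design (the offsets sit outside the resolution function); the
  convolved numeric inversion is available and used wherever a
  resolution model is given.
* Sums of sigmoids are descriptive, not mechanistic: no classical
  nucleation theory, no population-balance model.
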