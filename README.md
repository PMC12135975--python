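# crystalkin

Kinetic analysis of salt-induced protein crystallization followed *in
situ* by several techniques at once: optical microscopy, dynamic light
scattering (DLS), neutron spin echo (NSE), neutron backscattering
fixed-window scans (NBS/FWS) and time-resolved diffraction.  The package
is aimed at scattering and soft-matter groups who track a crystallizing
protein solution (e.g. serum albumin with a trivalent salt in D₂O) with
complementary probes and want one consistent kinetic description across
all of them.

## The model

Every observable that tracks crystal growth — a crystal's projected area,
the immobile fraction at a Bragg peak, the elastic fraction of the
incoherent signal, the Bragg-peak intensity — is described by logistic
(sigmoid) kinetics

    f(t) = f0 / (1 + exp(−(t − t0)/Δt)),

where *t₀* is the time of fastest growth and the maximum growth rate is
*f₀*/(4Δt).  Multi-step processes use sums of sigmoids (a dissolving
intermediate phase enters with *f₀* < 0).  Around that shared model sit
the technique-specific reductions:

* **DLS** — the intensity correlation is decomposed as
  g₂−1 = β[a e^(−Γ₁τ) + (1−a) e^(−Γ₂τ)]² (slow: crystals/precursors,
  fast: dissolved protein); Γ = D q² across angles gives the collective
  long-time coefficients D₁(t), D₂(t).
* **NSE** — the intermediate scattering function is
  I(q,τ) = a_coh I_coh(τ) − a_inc I_inc(τ) with a_coh − a_inc pinned at
  the shortest Fourier time; at the Bragg position
  I_coh = s + (1−s) e^(−γ_free τ) with γ_free fixed by Fickian
  interpolation from adjacent q, and the immobile fraction s(t) tracks
  the crystals.
* **NBS** — the two inelastic fixed-window intensities invert to a
  Lorentzian linewidth, γ = √((ω₃² − Rω₁²)/(R − 1)) with R = I(ω₁)/I(ω₃);
  γ(q) = ħDq² + c gives the short-time self-diffusion D(t), and the
  elastic amplitude c_e(t), q-averaged and normalized, gives the crystal
  fraction c_NBS(t).
* **Diffraction** — the dissolved-protein signal under the Bragg peak is
  interpolated from flanking q and subtracted; the normalized excess is
  the crystal fraction c_Diff(t).
* **Microscopy** — per-crystal sigmoid fits of area traces, population
  histograms and error-weighted means; V = A^{3/2} (cubic crystallites)
  for volume-corrected kinetics.

A seeded synthetic generator (`crystalkin.synthetic`) emulates each
modality with known ground truth, so every pipeline is verifiable by
parameter recovery.

## Worked example

Simulate a backscattering run and analyze it:

```sh
crystalkin simulate nbs --seed 4 --out sim_nbs
crystalkin nbs sim_nbs/fws_frames.csv --out nbs_out
```

which prints

```
NBS c_NBS(t): f0_1=1.064+-0.0011, t0_1=40.03+-0.022, dt_1=11.5+-0.024, background=-0.03286+-0.00064
```

— the crystal fraction rises as a single sigmoid with inflection at
t₀ ≈ 40.0 h and characteristic time Δt ≈ 11.5 h, matching the generator's
ground truth (40.0 h, 11.48 h) closely.  The full
cross-technique comparison (the multi-method kinetic table) is one
command:

```sh
crystalkin report --seed 1 --out report_out
```

```
| Technique         | t0 (h)          | dt (h)         |
|---|---|---|
| DLS first         | 97.02 +- 0.06   | 3.20 +- 0.08   |
| DLS second        | 108.37 +- 0.29  | 14.95 +- 0.18  |
| NSE               | 44.80 +- 2.02   | 11.11 +- 2.09  |
| NBS               | 40.00 +- 0.02   | 11.49 +- 0.03  |
| Diffraction       | 48.59 +- 0.22   | 6.78 +- 0.19   |
| Diffraction low-q | 72.56 +- 3.04   | 11.76 +- 2.80  |
| Microscopy        | 30.98 +- 0.04   | 7.05 +- 0.03   |
| Microscopy corr.  | 34.62 +- 0.05   | 5.70 +- 0.03   |
```

Each row is one technique's sigmoid fit of its crystal-growth observable
on the synthetic run; structural probes (diffraction) lag the
dynamic/elastic probes (NSE, NBS), reproducing the ordering seen when
disordered aggregates immobilize protein before lattice order appears.

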