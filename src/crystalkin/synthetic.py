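"""Seeded forward models for every measurement modality.

Each generator produces data in exactly the containers the analysis
pipelines consume, together with a :class:`GroundTruthBundle` recording
every parameter used, the seed and the noise model — so each
generate/analyze pair closes into a parameter-recovery test without any
instrument data.

Default parameters emulate the study conditions of a salt-induced
crystallizing protein solution (human serum albumin at 75 mg/ml with a
trivalent salt in heavy water, and a related two-phase system): sigmoid
crystal-fraction kinetics with inflection times of tens of hours,
Fickian q² decay-rate scaling, opposite-sign coherent/incoherent
spin-echo contributions, Lorentzian quasielastic broadening under a
0.9 µeV FWHM Gaussian resolution, a Gaussian Bragg peak growing on a
smooth baseline, and per-crystal sigmoid area growth.  Sampling cadences
default to 2 h for spin echo and 30 min for the other techniques.

Noise defaults: multiplicative Gaussian 1% (DLS), additive Gaussian 3% of
the short-time plateau (NSE), Poisson counting with ~1e4 counts at the
elastic line (backscattering), additive Gaussian 3% (diffraction and
microscopy areas).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .core_models import KineticModel, SigmoidComponent
from .dls import Correlogram, q_from_angle_light
from .diffraction import DiffractionFrame
from .microscopy import CrystalTrace
from .nbs import FWSFrame, ResolutionModel
from .nse import ISFCurve

__all__ = [
    "GroundTruthBundle",
    "gen_kinetic_trace",
    "gen_dls_dataset",
    "gen_nse_dataset",
    "gen_fws_dataset",
    "gen_diffraction_series",
    "gen_microscopy",
]


@dataclass
class GroundTruthBundle:
    """What a generator actually used: parameters, seed, noise model."""

    modality: str
    params: dict = field(default_factory=dict)
    seed: int | None = None
    noise: str = ""


def _sig(t, f0, t0, dt):
    return f0 * expit((np.asarray(t, dtype=float) - t0) / dt)


# -- generic kinetic traces ---------------------------------------------------


def gen_kinetic_trace(components, background: float = 0.0,
                      noise: float = 0.03, n_points: int = 60,
                      span: tuple[float, float] = (0.0, 100.0),
                      seed: int | None = None):
    """Sample a sum-of-sigmoids trace with additive Gaussian noise.

    ``components`` is a sequence of (f0, t0, dt) tuples or
    :class:`SigmoidComponent`; a negative f0 gives a decaying term (e.g. a
    dissolving intermediate phase preceding crystal growth).  Returns
    ``(t, y, sigma, truth)``.
    """
    comps = tuple(c if isinstance(c, SigmoidComponent) else SigmoidComponent(*c)
                  for c in components)
    model = KineticModel(comps, background)
    t = np.linspace(span[0], span[1], n_points)
    clean = model(t)
    rng = np.random.default_rng(seed)
    scale = noise * max(abs(model.total_amplitude), 1e-12)
    y = clean + rng.normal(0.0, scale, t.shape) if noise > 0 else clean.copy()
    sigma = np.full_like(t, scale) if noise > 0 else None
    truth = GroundTruthBundle(
        "kinetic_trace",
        {"components": [(c.f0, c.t0, c.dt) for c in comps],
         "background": background, "n_points": n_points, "span": span},
        seed, f"additive Gaussian, sigma = {noise} * |total amplitude|")
    return t, y, sigma, truth


# -- dynamic light scattering -------------------------------------------------

DLS_D2_COMPONENTS = ((0.5e-11, 96.93, 3.21), (1.0e-11, 108.19, 14.65))
DLS_D2_BASE = 3.0e-11  # m²/s, dissolved-protein collective D before growth


def default_dls_d2(t):
    """Monomer collective diffusion rising in two sigmoid steps (inverse
    crowding as crystals deplete the solution)."""
    out = np.full_like(np.asarray(t, dtype=float), DLS_D2_BASE)
    for f0, t0, dt in DLS_D2_COMPONENTS:
        out = out + _sig(t, f0, t0, dt)
    return out


def default_dls_d1(t):
    """Cluster/precursor collective diffusion, slowly decreasing."""
    return 5.0e-12 - _sig(t, 2.0e-12, 100.0, 10.0)


def gen_dls_dataset(ages_h=None, d1_of_t=default_dls_d1,
                    d2_of_t=default_dls_d2, a_of_t=None,
                    angles_deg=None, wavelength_m: float = 633e-9,
                    refractive_index: float = 1.333,
                    lag_s=None, noise: float = 0.01, beta: float = 0.95,
                    seed: int | None = None):
    """Correlograms across angles and ages from two Fickian decays.

    g2 - 1 is built with the Siegert-squared double exponential with
    rates Gamma_i = D_i q², weight ``a`` on the slow branch, and
    multiplicative Gaussian noise.  Returns ``(correlograms, truth)``.
    """
    if ages_h is None:
        ages_h = np.arange(0.0, 150.0 + 1e-9, 0.5)  # 30 min cadence
    if angles_deg is None:
        angles_deg = np.arange(30.0, 151.0, 10.0)
    if lag_s is None:
        lag_s = np.geomspace(1e-6, 1.0, 56)
    if a_of_t is None:
        a_of_t = lambda t: np.full_like(np.asarray(t, dtype=float), 0.3)
    ages_h = np.asarray(ages_h, dtype=float)
    rng = np.random.default_rng(seed)
    out = []
    d1 = np.atleast_1d(d1_of_t(ages_h))
    d2 = np.atleast_1d(d2_of_t(ages_h))
    if np.any(d1 <= 0) or np.any(d2 < d1):
        raise ValueError("need D2 >= D1 > 0 at every age")
    a = np.atleast_1d(a_of_t(ages_h))
    for i, age in enumerate(ages_h):
        for angle in angles_deg:
            q = q_from_angle_light(angle, wavelength_m, refractive_index)
            g1, g2_ = d1[i] * q**2, d2[i] * q**2
            fc = a[i] * np.exp(-g1 * lag_s) + (1 - a[i]) * np.exp(-g2_ * lag_s)
            clean = beta * fc**2
            g = clean * (1.0 + rng.normal(0.0, noise, lag_s.shape))
            err = np.maximum(noise * clean, noise * 1e-3)
            out.append(Correlogram(angle, lag_s, g, err, age,
                                   wavelength_m, refractive_index))
    truth = GroundTruthBundle(
        "dls",
        {"D1": d1, "D2": d2, "a": a, "ages_h": ages_h,
         "angles_deg": np.asarray(angles_deg, dtype=float), "beta": beta,
         "wavelength_m": wavelength_m, "refractive_index": refractive_index,
         "d2_components": DLS_D2_COMPONENTS
         if d2_of_t is default_dls_d2 else None},
        seed, f"multiplicative Gaussian, {noise:.3%}")
    return out, truth


# -- neutron spin echo --------------------------------------------------------

NSE_S_TRUTH = (0.6, 45.24, 11.65)  # plateau, t0 (h), dt (h) of s(t)


def default_nse_s(t):
    """Immobile fraction at the Bragg position growing sigmoidally."""
    return _sig(t, *NSE_S_TRUTH)


def gen_nse_dataset(ages_h=None, q_values=None, bragg_q: float = 0.149,
                    D_coh: float = 3.5, D_inc: float = 3.5,
                    gamma_internal: float = 5.0,
                    s_of_t=default_nse_s, tau_ns=None,
                    noise: float = 0.03, seed: int | None = None):
    """Intermediate scattering functions with mixed-sign contributions.

    Per q: amplitudes a_coh (decreasing with q) and a_inc (increasing) so
    that curves above q ≈ 0.3 Å⁻¹ are incoherent-dominated; decay rates
    gamma_coh = D_coh q² and gamma_inc = D_inc q² + gamma_internal (ns⁻¹),
    the latter fast enough to produce the subnanosecond initial rise.
    The Bragg curve mixes the immobile fraction s(t) into the coherent
    part.  Additive Gaussian noise of ``noise`` times the short-time
    plateau.  Returns ``(curves, truth)``.
    """
    if ages_h is None:
        ages_h = np.arange(0.0, 80.0 + 1e-9, 2.0)  # 2 h cadence
    if q_values is None:
        q_values = [0.10, 0.13, bragg_q, 0.17, 0.21, 0.30]
    if tau_ns is None:
        tau_ns = np.geomspace(0.01, 10.0, 25)
    rng = np.random.default_rng(seed)
    curves = []
    s_vals = np.atleast_1d(s_of_t(np.asarray(ages_h, dtype=float)))
    for i, age in enumerate(ages_h):
        for q in q_values:
            a_coh = 0.9 * np.exp(-((q / 0.22) ** 2))
            a_inc = 0.05 + 0.5 * q
            g_coh = D_coh * q**2
            g_inc = D_inc * q**2 + gamma_internal
            is_bragg = abs(q - bragg_q) < 1e-9
            s = s_vals[i] if is_bragg else 0.0
            coh = s + (1 - s) * np.exp(-g_coh * tau_ns)
            clean = a_coh * coh - a_inc * np.exp(-g_inc * tau_ns)
            sigma = noise * abs(a_coh - a_inc)
            isf = clean + rng.normal(0.0, sigma, tau_ns.shape)
            curves.append(ISFCurve(q, tau_ns, isf,
                                   np.full_like(tau_ns, sigma), age, is_bragg))
    truth = GroundTruthBundle(
        "nse",
        {"ages_h": np.asarray(ages_h, dtype=float), "q_values": list(q_values),
         "bragg_q": bragg_q, "D_coh": D_coh, "D_inc": D_inc,
         "gamma_internal": gamma_internal, "s": s_vals,
         "s_sigmoid": NSE_S_TRUTH if s_of_t is default_nse_s else None},
        seed, f"additive Gaussian, sigma = {noise} * plateau")
    return curves, truth


# -- neutron backscattering fixed window scans --------------------------------

NBS_CE_TRUTH = (0.5, 40.0, 11.48)  # plateau, t0 (h), dt (h) of phi(t)


def default_nbs_phi(t):
    """Elastic (immobilized) fraction of the protein signal."""
    return _sig(t, *NBS_CE_TRUTH)


def default_nbs_d(t):
    """Effective short-time diffusion, slightly slowing as monomers
    leave the solution (Å²/ns)."""
    return 5.0 - _sig(t, 0.5, 40.0, 11.48)


def gen_fws_dataset(times_h=None, q_grid=None, D_of_t=default_nbs_d,
                    phi_of_t=default_nbs_phi, c_offset: float = 0.3,
                    container: float = 0.1, amplitude: float = 1.0,
                    offsets=(1.0, 3.0), resolution: ResolutionModel | None = None,
                    counts_scale: float | None = None,
                    target_counts: float = 1e4,
                    seed: int | None = None):
    """Fixed-window-scan frames at offsets {0, 1, 3} µeV with Poisson noise.

    Per q and time: spectrum = (phi·A + container)·R(omega) +
    (1 - phi)·A·Voigt(omega; resolution, gamma) with gamma = hbar D q² +
    c_offset.  Counts are scaled so the elastic channel starts near
    ``target_counts`` and Poisson-sampled.  Returns ``(frames, truth)``.
    """
    from .core_models import HBAR_UEV_NS
    from .nbs import convolved_lorentzian

    if times_h is None:
        times_h = np.arange(0.0, 80.0 + 1e-9, 0.5)  # 30 min cadence
    if q_grid is None:
        q_grid = np.arange(0.2, 1.901, 0.05)
    resolution = resolution or ResolutionModel()
    times_h = np.asarray(times_h, dtype=float)
    q_grid = np.asarray(q_grid, dtype=float)
    rng = np.random.default_rng(seed)
    phis = np.atleast_1d(phi_of_t(times_h))
    Ds = np.atleast_1d(D_of_t(times_h))
    omega1, omega3 = offsets

    def spectrum(omega, phi, gamma):
        elastic = (phi * amplitude + container) * resolution(omega)
        quasi = (1 - phi) * amplitude * convolved_lorentzian(omega, gamma,
                                                             resolution)
        return elastic + quasi

    if counts_scale is None:
        g0 = HBAR_UEV_NS * Ds[0] * q_grid**2 + c_offset
        counts_scale = target_counts / float(np.mean(spectrum(0.0, phis[0], g0)))

    frames = []
    for i, t in enumerate(times_h):
        gamma = HBAR_UEV_NS * Ds[i] * q_grid**2 + c_offset
        I0 = counts_scale * spectrum(0.0, phis[i], gamma)
        I1 = counts_scale * spectrum(omega1, phis[i], gamma)
        I3 = counts_scale * spectrum(omega3, phis[i], gamma)
        c0 = rng.poisson(I0).astype(float)
        c1 = rng.poisson(I1).astype(float)
        c3 = rng.poisson(I3).astype(float)
        frames.append(FWSFrame(t, q_grid, c0, c1, c3,
                               np.sqrt(np.maximum(c0, 1.0)),
                               np.sqrt(np.maximum(c1, 1.0)),
                               np.sqrt(np.maximum(c3, 1.0)),
                               omega1, omega3))
    truth = GroundTruthBundle(
        "nbs",
        {"times_h": times_h, "q_grid": q_grid, "D": Ds, "phi": phis,
         "c_offset": c_offset, "container": container,
         "counts_scale": counts_scale, "resolution_fwhm": resolution.fwhm,
         "phi_sigmoid": NBS_CE_TRUTH if phi_of_t is default_nbs_phi else None},
        seed, f"Poisson counting, ~{target_counts:g} counts at the elastic line")
    return frames, truth


# -- diffraction --------------------------------------------------------------

DIFF_PEAK_TRUTH = (48.98, 7.15)  # t0 (h), dt (h) of the Bragg-peak area
LOWQ_TRUTH = (74.20, 13.47)  # t0 (h), dt (h) of the low-q intensity rise


def default_baseline(q):
    """Smooth dissolved-protein baseline (power law + constant)."""
    q = np.asarray(q, dtype=float)
    return 0.3 * (q / 0.1) ** -2 + 1.0


def gen_diffraction_series(times_h=None, q_grid=None, baseline=default_baseline,
                           peak_center: float = 0.149, peak_sigma: float = 0.004,
                           peak_area_max: float = 0.02,
                           peak_t0: float = DIFF_PEAK_TRUTH[0],
                           peak_dt: float = DIFF_PEAK_TRUTH[1],
                           lowq_amp: float = 0.0,
                           lowq_t0: float = LOWQ_TRUTH[0],
                           lowq_dt: float = LOWQ_TRUTH[1],
                           smear_dl_over_l: float | None = None,
                           noise: float = 0.03, seed: int | None = None):
    """I(q, t) frames: a Gaussian Bragg peak with sigmoid-growing area on
    a static smooth baseline, optionally a sigmoid-growing low-q excess,
    optional wavelength-spread Gaussian q-smearing, additive Gaussian
    noise proportional to intensity.  Returns ``(frames, truth)``.
    """
    if times_h is None:
        times_h = np.arange(0.0, 80.0 + 1e-9, 2.0)
    if q_grid is None:
        q_grid = np.arange(0.08, 0.2501, 0.0025)
    times_h = np.asarray(times_h, dtype=float)
    q_grid = np.asarray(q_grid, dtype=float)
    rng = np.random.default_rng(seed)
    base = np.atleast_1d(baseline(q_grid))
    frames = []
    for t in times_h:
        area = _sig(t, peak_area_max, peak_t0, peak_dt)
        peak = area / (peak_sigma * np.sqrt(2 * np.pi)) * np.exp(
            -0.5 * ((q_grid - peak_center) / peak_sigma) ** 2)
        if smear_dl_over_l:
            # wavelength spread -> Gaussian smearing with dq = q * dl/l (FWHM)
            sig_q = np.maximum(peak_center * smear_dl_over_l / 2.355, 1e-9)
            kernel_half = int(np.ceil(4 * sig_q / (q_grid[1] - q_grid[0])))
            kq = np.arange(-kernel_half, kernel_half + 1) * (q_grid[1] - q_grid[0])
            ker = np.exp(-0.5 * (kq / sig_q) ** 2)
            ker /= ker.sum()
            peak = np.convolve(peak, ker, mode="same")
        I = base + peak
        if lowq_amp:
            I = I + _sig(t, lowq_amp, lowq_t0, lowq_dt) * np.exp(-((q_grid / 0.11) ** 4))
        sig = noise * I
        frames.append(DiffractionFrame(
            t, q_grid, np.clip(I + rng.normal(0.0, sig), 0.0, None), sig))
    truth = GroundTruthBundle(
        "diffraction",
        {"times_h": times_h, "q_grid": q_grid, "peak_center": peak_center,
         "peak_sigma": peak_sigma, "peak_area_max": peak_area_max,
         "peak_t0": peak_t0, "peak_dt": peak_dt, "lowq_amp": lowq_amp,
         "lowq_t0": lowq_t0, "lowq_dt": lowq_dt,
         "smear_dl_over_l": smear_dl_over_l},
        seed, f"additive Gaussian, {noise:.1%} of intensity")
    return frames, truth


# -- microscopy ---------------------------------------------------------------

MICRO_TRUTH = {"mu_t0": 32.0, "sd_t0": 5.0, "mu_dt": 7.0, "sd_dt": 1.0,
               "lognorm_mean": 5.0, "lognorm_sigma": 0.8}


def gen_microscopy(n_crystals: int = 20, times_h=None,
                   mu_t0: float = MICRO_TRUTH["mu_t0"],
                   sd_t0: float = MICRO_TRUTH["sd_t0"],
                   mu_dt: float = MICRO_TRUTH["mu_dt"],
                   sd_dt: float = MICRO_TRUTH["sd_dt"],
                   lognorm_mean: float = MICRO_TRUTH["lognorm_mean"],
                   lognorm_sigma: float = MICRO_TRUTH["lognorm_sigma"],
                   noise: float = 0.03, seed: int | None = None,
                   render_images: bool = False, image_shape=(160, 160),
                   pixel_area_um2: float = 4.0):
    """Per-crystal sigmoid area growth with population scatter.

    t0 ~ Normal(mu_t0, sd_t0), dt ~ Normal(mu_dt, sd_dt) (clipped
    positive), A0 ~ LogNormal — a right-skewed size distribution dominated
    by small crystals.  Additive Gaussian noise of ``noise`` times each
    crystal's plateau area.  Optionally renders square crystals into an
    image stack for the synthetic segmenter.  Returns ``(traces, truth)``
    or ``(traces, images, truth)``.
    """
    if times_h is None:
        times_h = np.arange(0.0, 70.0 + 1e-9, 0.5)  # 30 min cadence
    times_h = np.asarray(times_h, dtype=float)
    rng = np.random.default_rng(seed)
    t0s = rng.normal(mu_t0, sd_t0, n_crystals)
    dts = np.clip(rng.normal(mu_dt, sd_dt, n_crystals), 0.5, None)
    a0s = rng.lognormal(lognorm_mean, lognorm_sigma, n_crystals)
    traces = []
    for i in range(n_crystals):
        clean = _sig(times_h, a0s[i], t0s[i], dts[i])
        sig = noise * a0s[i]
        area = np.clip(clean + rng.normal(0.0, sig, times_h.shape), 0.0, None)
        traces.append(CrystalTrace(i, times_h, area,
                                   np.full_like(times_h, sig)))
    truth = GroundTruthBundle(
        "microscopy",
        {"n_crystals": n_crystals, "t0": t0s, "dt": dts, "A0": a0s,
         "mu_t0": mu_t0, "sd_t0": sd_t0, "mu_dt": mu_dt, "sd_dt": sd_dt,
         "times_h": times_h},
        seed, f"additive Gaussian, sigma = {noise} * plateau area")
    if not render_images:
        return traces, truth
    ny, nx = image_shape
    # place crystals on a sparse grid so squares never touch
    n_side = int(np.ceil(np.sqrt(n_crystals)))
    cell = min(ny, nx) // n_side
    images = np.zeros((times_h.size, ny, nx), dtype=np.uint16)
    for i in range(n_crystals):
        cy = (i // n_side) * cell + cell // 2
        cx = (i % n_side) * cell + cell // 2
        for fi, t in enumerate(times_h):
            area_px = _sig(t, a0s[i], t0s[i], dts[i]) / pixel_area_um2
            half = int(np.floor(np.sqrt(max(area_px, 0.0)) / 2))
            if half > 0:
                images[fi, cy - half:cy + half, cx - half:cx + half] = 1000
    return traces, images, truth
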