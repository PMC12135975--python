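"""Neutron backscattering fixed-window-scan (FWS) ratio analysis.

A backscattering spectrometer sampling the spectrum at fixed energy
transfers (elastic 0, inelastic 1 and 3 µeV here) follows crystallization
with minute-scale time resolution.  Under a single-Lorentzian quasielastic
assumption, the ratio R = I(omega1)/I(omega3) of the two inelastic
channels inverts in closed form to the Lorentzian linewidth

    gamma = sqrt((omega3^2 - R omega1^2) / (R - 1)),

valid for 1 < R < (omega3/omega1)^2; a resolution-convolved numeric
inversion (root-finding on the Voigt ratio) is used when a
:class:`ResolutionModel` is supplied.  The q dependence of the linewidth,

    gamma(q) = hbar D q^2 + c,

yields an effective short-time self-diffusion coefficient D (Å²/ns) and an
offset c (µeV) absorbing localized internal motions.  Scaling a
resolution-convolved Lorentzian to both inelastic channels (weight s_FWS)
and subtracting its elastic-channel contribution from I(0) isolates the
strictly elastic fraction c_e; its growth, q-averaged over 1.1-1.8 Å⁻¹,
baseline-subtracted and normalized, is the crystal fraction c_NBS(t).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import voigt_profile

from .core_models import HBAR_UEV_NS, FitResult, fit_kinetics

__all__ = [
    "ResolutionModel",
    "FWSFrame",
    "LinewidthProfile",
    "NBSKinetics",
    "lorentzian",
    "convolved_lorentzian",
    "ratio_from_gamma",
    "gamma_from_ratio",
    "linewidth_profile",
    "fit_gamma_q",
    "elastic_fraction",
    "nbs_crystal_fraction",
    "subtract_solvent",
    "analyze_fws_dataset",
    "read_fws_frames",
    "write_fws_frames",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class ResolutionModel:
    """Unit-area Gaussian instrument resolution (energy domain, µeV)."""

    fwhm: float = 0.9

    @property
    def sigma(self) -> float:
        return self.fwhm * _FWHM_TO_SIGMA

    def __call__(self, omega):
        omega = np.asarray(omega, dtype=float)
        s = self.sigma
        out = np.exp(-0.5 * (omega / s) ** 2) / (s * math.sqrt(2.0 * math.pi))
        return out if out.ndim else float(out)


def lorentzian(omega, gamma):
    """Unit-area Lorentzian with half-width ``gamma`` (µeV)."""
    omega = np.asarray(omega, dtype=float)
    out = gamma / math.pi / (gamma**2 + omega**2)
    return out if out.ndim else float(out)


def convolved_lorentzian(omega, gamma, resolution: ResolutionModel):
    """Lorentzian convolved with the Gaussian resolution (a Voigt profile)."""
    omega = np.asarray(omega, dtype=float)
    out = voigt_profile(omega, resolution.sigma, gamma)
    return out if out.ndim else float(out)


def ratio_from_gamma(gamma, omega1: float = 1.0, omega3: float = 3.0,
                     resolution: ResolutionModel | None = None):
    """Forward map: inelastic intensity ratio I(omega1)/I(omega3) for a
    (possibly resolution-convolved) Lorentzian of half-width ``gamma``."""
    if resolution is None:
        gamma = np.asarray(gamma, dtype=float)
        out = (gamma**2 + omega3**2) / (gamma**2 + omega1**2)
        return out if out.ndim else float(out)
    num = convolved_lorentzian(omega1, gamma, resolution)
    den = convolved_lorentzian(omega3, gamma, resolution)
    return num / den


def gamma_from_ratio(I1, I3, omega1: float = 1.0, omega3: float = 3.0,
                     resolution: ResolutionModel | None = None,
                     out_of_window: str = "raise"):
    """Invert the inelastic FWS ratio to a Lorentzian linewidth (µeV).

    Closed form by default; with a ``resolution`` model the convolved
    ratio is inverted numerically by root-finding.  The ratio is only
    informative for 1 < R < (omega3/omega1)^2 (closed form): outside that
    window the motion is too slow/fast for the chosen offsets and the
    function raises, or returns NaN with ``out_of_window="nan"``.
    """
    I1 = np.asarray(I1, dtype=float)
    I3 = np.asarray(I3, dtype=float)
    scalar = I1.ndim == 0
    I1, I3 = np.atleast_1d(I1), np.atleast_1d(I3)
    if np.any(I1 <= 0) or np.any(I3 <= 0):
        bad = (I1 <= 0) | (I3 <= 0)
        if out_of_window == "raise" and np.any(bad):
            raise ValueError("intensities must be positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        R = I1 / I3

    if resolution is None:
        r_max = (omega3 / omega1) ** 2
        valid = (R > 1.0) & (R < r_max) & np.isfinite(R)
        if not np.all(valid) and out_of_window == "raise":
            raise ValueError(
                f"ratio outside the invertible window (1, {r_max:g}): "
                "motion too slow or too fast for these offsets")
        gamma = np.full_like(R, np.nan)
        gamma[valid] = np.sqrt(
            (omega3**2 - R[valid] * omega1**2) / (R[valid] - 1.0))
    else:
        r_lo = float(ratio_from_gamma(1e3, omega1, omega3, resolution))
        r_hi = float(ratio_from_gamma(1e-6, omega1, omega3, resolution))
        valid = (R > r_lo) & (R < r_hi) & np.isfinite(R)
        if not np.all(valid) and out_of_window == "raise":
            raise ValueError(
                f"ratio outside the invertible window ({r_lo:g}, {r_hi:g})")
        gamma = np.full_like(R, np.nan)
        flat = np.where(valid.ravel())[0]
        g = gamma.ravel()
        Rf = R.ravel()
        for i in flat:
            g[i] = optimize.brentq(
                lambda x: ratio_from_gamma(x, omega1, omega3, resolution) - Rf[i],
                1e-6, 1e3, xtol=1e-12, rtol=1e-14)
        gamma = g.reshape(R.shape)
    return float(gamma[0]) if scalar else gamma


@dataclass
class FWSFrame:
    """One time frame of elastic/inelastic FWS intensities on a q grid."""

    time_h: float
    q: np.ndarray
    I0: np.ndarray
    I1: np.ndarray
    I3: np.ndarray
    sigma0: np.ndarray | None = None
    sigma1: np.ndarray | None = None
    sigma3: np.ndarray | None = None
    omega1: float = 1.0
    omega3: float = 3.0

    def __post_init__(self):
        for name in ("q", "I0", "I1", "I3"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        for name in ("sigma0", "sigma1", "sigma3"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))
        if np.any(self.I0 < 0) or np.any(self.I1 < 0) or np.any(self.I3 < 0):
            raise ValueError("intensities must be non-negative")


@dataclass
class LinewidthProfile:
    """Per-q Lorentzian linewidths at one time, with validity mask."""

    time_h: float
    q: np.ndarray
    gamma: np.ndarray
    sigma: np.ndarray | None = None
    valid: np.ndarray | None = None

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.valid is None:
            self.valid = np.isfinite(self.gamma) & (self.gamma > 0)


def linewidth_profile(frame: FWSFrame,
                      resolution: ResolutionModel | None = None) -> LinewidthProfile:
    """Ratio-method linewidths gamma(q) for one frame (invalid points
    masked, not raised)."""
    gamma = gamma_from_ratio(frame.I1, frame.I3, frame.omega1, frame.omega3,
                             resolution, out_of_window="nan")
    sigma = None
    if frame.sigma1 is not None and frame.sigma3 is not None:
        # first-order propagation through the closed form
        with np.errstate(all="ignore"):
            R = frame.I1 / frame.I3
            dR = R * np.sqrt((frame.sigma1 / frame.I1) ** 2
                             + (frame.sigma3 / frame.I3) ** 2)
            dgdR = np.abs((frame.omega1**2 - frame.omega3**2)
                          / (2 * gamma * (R - 1.0) ** 2))
            sigma = dgdR * dR
    return LinewidthProfile(frame.time_h, frame.q, gamma, sigma)


def fit_gamma_q(profile: LinewidthProfile,
                q_range: tuple[float, float] = (0.4, 1.4)) -> dict:
    """Weighted fit of gamma(q) = hbar D q^2 + c over ``q_range``.

    Returns D (Å²/ns), the offset c (µeV) and their 1-sigma errors.
    """
    m = (profile.valid & (profile.q > q_range[0]) & (profile.q < q_range[1]))
    if np.count_nonzero(m) < 4:
        raise ValueError("need at least 4 valid q points in the fit range")
    q2 = profile.q[m] ** 2
    g = profile.gamma[m]
    if profile.sigma is not None and np.all(profile.sigma[m] > 0):
        w = 1.0 / profile.sigma[m] ** 2
    else:
        w = np.ones_like(g)
    # weighted linear LS on (hbar*q^2, 1)
    X = np.column_stack([HBAR_UEV_NS * q2, np.ones_like(q2)])
    WX = X * w[:, None]
    A = X.T @ WX
    b = WX.T @ g
    theta = np.linalg.solve(A, b)
    cov = np.linalg.inv(A)
    if profile.sigma is None:
        resid = g - X @ theta
        ndof = max(g.size - 2, 1)
        cov = cov * float(resid @ resid) / ndof
    err = np.sqrt(np.diag(cov))
    out = {"D": float(theta[0]), "D_err": float(err[0]),
           "c": float(theta[1]), "c_err": float(err[1]), "flags": []}
    if theta[0] < 0:
        out["flags"].append("negative-D")
    return out


def elastic_fraction(frame: FWSFrame, gamma, resolution: ResolutionModel):
    """Per-q quasielastic weight s_FWS and elastic amplitude c_e.

    The measured spectrum is the resolution image of an elastic line plus
    a Lorentzian of known width ``gamma``:

        I(omega) = c_e R(omega) + s_FWS (L ⊗ R)(omega),

    so the three fixed-window channels (0, omega1, omega3) overdetermine
    the two amplitudes, which are obtained by weighted linear least
    squares per q.  Including the elastic term at the inelastic offsets
    matters: a Gaussian resolution still places a few per cent of the
    elastic line at 1 µeV, which would otherwise contaminate the
    quasielastic scale as the crystals grow.  Negative amplitudes are
    clipped to zero and flagged.
    """
    gamma = np.atleast_1d(np.asarray(gamma, dtype=float))
    V0 = voigt_profile(0.0, resolution.sigma, gamma)
    V1 = voigt_profile(frame.omega1, resolution.sigma, gamma)
    V3 = voigt_profile(frame.omega3, resolution.sigma, gamma)
    R0 = resolution(0.0)
    R1 = resolution(frame.omega1)
    R3 = resolution(frame.omega3)
    w0 = (1.0 / frame.sigma0**2 if frame.sigma0 is not None
          else np.ones_like(frame.I0))
    w1 = (1.0 / frame.sigma1**2 if frame.sigma1 is not None
          else np.ones_like(frame.I1))
    w3 = (1.0 / frame.sigma3**2 if frame.sigma3 is not None
          else np.ones_like(frame.I3))
    # per-q 2x2 normal equations for (c_e, s_FWS)
    a11 = w0 * R0**2 + w1 * R1**2 + w3 * R3**2
    a12 = w0 * R0 * V0 + w1 * R1 * V1 + w3 * R3 * V3
    a22 = w0 * V0**2 + w1 * V1**2 + w3 * V3**2
    b1 = w0 * frame.I0 * R0 + w1 * frame.I1 * R1 + w3 * frame.I3 * R3
    b2 = w0 * frame.I0 * V0 + w1 * frame.I1 * V1 + w3 * frame.I3 * V3
    with np.errstate(all="ignore"):
        det = a11 * a22 - a12**2
        c_e = (b1 * a22 - b2 * a12) / det
        s_fws = (b2 * a11 - b1 * a12) / det
    flags = np.zeros(c_e.shape, dtype=bool)
    neg = (c_e < 0) | (s_fws < 0)
    if np.any(neg):
        flags |= neg
        c_e = np.clip(c_e, 0.0, None)
        s_fws = np.clip(s_fws, 0.0, None)
    return s_fws, c_e, flags


def subtract_solvent(sample: FWSFrame, solvent: FWSFrame,
                     scale: float = 1.0) -> FWSFrame:
    """Channel-wise solvent subtraction: I_sample - scale * I_solvent.

    ``scale`` is typically 1 minus the protein volume fraction.  Negative
    results are clipped to zero (flag recorded on the returned frame as
    attribute ``clipped``).
    """
    if sample.q.shape != solvent.q.shape or not np.allclose(sample.q, solvent.q):
        raise ValueError("sample and solvent frames must share the q grid")
    chans = {}
    clipped = False
    for name in ("I0", "I1", "I3"):
        v = getattr(sample, name) - scale * getattr(solvent, name)
        if np.any(v < 0):
            clipped = True
            v = np.clip(v, 0.0, None)
        chans[name] = v
    out = FWSFrame(sample.time_h, sample.q.copy(), chans["I0"], chans["I1"],
                   chans["I3"], sample.sigma0, sample.sigma1, sample.sigma3,
                   sample.omega1, sample.omega3)
    out.clipped = clipped
    return out


def nbs_crystal_fraction(times, c_e_matrix, q,
                         q_window: tuple[float, float] = (1.1, 1.8)):
    """Crystal fraction c_NBS(t) from the elastic amplitudes.

    ``c_e_matrix`` has shape (n_times, n_q).  The elastic fraction is
    averaged over ``q_window``, the t = 0 value (sample container plus any
    initially immobile protein) subtracted, and the series normalized to
    its final value, mapping the kinetics onto [0, 1].  Returns
    ``(c_nbs, fit_result)`` with a single-sigmoid fit attached.
    """
    times = np.asarray(times, dtype=float)
    q = np.asarray(q, dtype=float)
    m = (q >= q_window[0]) & (q <= q_window[1])
    if not np.any(m):
        raise ValueError("no q points inside the averaging window")
    ce = np.asarray(c_e_matrix, dtype=float)[:, m].mean(axis=1)
    base = ce - ce[0]
    flags = []
    if abs(base[-1]) <= 0 or not np.isfinite(base[-1]):
        flags.append("degenerate-normalization")
        c_nbs = base
    else:
        c_nbs = base / base[-1]
    # the free background absorbs the (small but nonzero) immobile fraction
    # already present at t = 0, which the subtraction cannot remove exactly
    fit = fit_kinetics(times, c_nbs, n_components=1, with_background=True)
    fit.flags.extend(flags)
    return c_nbs, fit


@dataclass
class NBSKinetics:
    """Outputs of the FWS pipeline versus time."""

    time_h: np.ndarray
    D: np.ndarray
    D_err: np.ndarray
    c: np.ndarray
    c_err: np.ndarray
    c_nbs: np.ndarray
    fit: FitResult
    flags: list = field(default_factory=list)


def analyze_fws_dataset(frames, resolution: ResolutionModel | None = None,
                        fit_q_range: tuple[float, float] = (0.4, 1.4),
                        elastic_q_range: tuple[float, float] = (1.1, 1.8),
                        ) -> NBSKinetics:
    """Full pipeline: FWS frames -> gamma(q, t) by the ratio method ->
    D(t), c(t) from gamma = hbar D q^2 + c -> per-q elastic amplitudes ->
    q-averaged, normalized crystal fraction c_NBS(t) with sigmoid fit.
    """
    resolution = resolution or ResolutionModel()
    times, Ds, Derrs, cs, cerrs, ce_rows = [], [], [], [], [], []
    r1, r3 = resolution(frames[0].omega1), resolution(frames[0].omega3)
    for frame in frames:
        # iterate the elastic-leak correction: the elastic line contributes
        # c_e * R(omega) to the inelastic channels, which must be removed
        # before the ratio inversion; c_e itself needs gamma.  Converges in
        # a few passes because the leak is a small fraction of I1.
        c_e = np.zeros_like(frame.q)
        prof = None
        res = None
        for _ in range(4):
            corr = FWSFrame(frame.time_h, frame.q,
                            frame.I0,
                            np.clip(frame.I1 - c_e * r1, 1e-12, None),
                            np.clip(frame.I3 - c_e * r3, 1e-12, None),
                            frame.sigma0, frame.sigma1, frame.sigma3,
                            frame.omega1, frame.omega3)
            prof = linewidth_profile(corr, resolution)
            res = fit_gamma_q(prof, fit_q_range)
            gamma_model = HBAR_UEV_NS * res["D"] * frame.q**2 + res["c"]
            gamma_use = np.where(prof.valid, prof.gamma, gamma_model)
            _, c_e, _ = elastic_fraction(frame, gamma_use, resolution)
        times.append(frame.time_h)
        Ds.append(res["D"])
        Derrs.append(res["D_err"])
        cs.append(res["c"])
        cerrs.append(res["c_err"])
        ce_rows.append(c_e)
    times = np.array(times)
    order = np.argsort(times)
    ce_mat = np.stack(ce_rows)[order]
    c_nbs, fit = nbs_crystal_fraction(times[order], ce_mat, frames[0].q,
                                      elastic_q_range)
    return NBSKinetics(times[order], np.array(Ds)[order], np.array(Derrs)[order],
                       np.array(cs)[order], np.array(cerrs)[order], c_nbs, fit)


# -- external interfaces ------------------------------------------------------


def write_fws_frames(path, frames) -> None:
    """CSV dialect (long form): time_h, q_A_inv, offset_ueV, intensity, error."""
    rows = []
    for f in frames:
        for offset, I, s in ((0.0, f.I0, f.sigma0), (f.omega1, f.I1, f.sigma1),
                             (f.omega3, f.I3, f.sigma3)):
            err = s if s is not None else np.full_like(f.q, np.nan)
            for qi, Ii, ei in zip(f.q, I, err):
                rows.append((f.time_h, qi, offset, Ii, ei))
    pd.DataFrame(rows, columns=["time_h", "q_A_inv", "offset_ueV",
                                "intensity", "error"]).to_csv(path, index=False)


def read_fws_frames(path):
    df = pd.read_csv(path)
    frames = []
    for t, grp in df.groupby("time_h", sort=True):
        offsets = sorted(grp["offset_ueV"].unique())
        if len(offsets) != 3 or offsets[0] != 0.0:
            raise ValueError("expect exactly offsets {0, omega1, omega3}")
        chans, errs = {}, {}
        for off in offsets:
            sub = grp[grp["offset_ueV"] == off].sort_values("q_A_inv")
            chans[off] = sub["intensity"].to_numpy(float)
            errs[off] = sub["error"].to_numpy(float)
            qgrid = sub["q_A_inv"].to_numpy(float)
        def _err(off):
            e = errs[off]
            return None if np.all(np.isnan(e)) else e
        frames.append(FWSFrame(float(t), qgrid, chans[offsets[0]],
                               chans[offsets[1]], chans[offsets[2]],
                               _err(offsets[0]), _err(offsets[1]),
                               _err(offsets[2]), float(offsets[1]),
                               float(offsets[2])))
    return frames
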