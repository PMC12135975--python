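"""Dynamic light scattering: double-exponential decomposition and
diffusion-coefficient kinetics.

During crystallization the intensity correlation function g2 - 1 develops a
clear shoulder: a slow decay (rate Gamma_1) from small crystals/precursors
coexists with a fast decay (rate Gamma_2) from dissolved proteins.  We fit
the Siegert-squared double exponential

    g2(tau) - 1 = beta * [ a exp(-Gamma_1 tau) + (1 - a) exp(-Gamma_2 tau) ]^2

per scattering angle, convert rates to collective diffusion coefficients
via the Fickian relation Gamma = D q^2 across angles, and describe the time
evolution of D_2(t) (and D_1(t)) by sums of sigmoids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .core_models import FitResult, fit_kinetics

__all__ = [
    "Correlogram",
    "DLSDecayFit",
    "DiffusionSeries",
    "q_from_angle_light",
    "preprocess_correlograms",
    "fit_correlogram",
    "diffusion_from_rates",
    "dls_kinetics",
    "analyze_dls_dataset",
    "read_correlograms",
    "write_correlograms",
]

D2O_REFRACTIVE_INDEX = 1.333  # at 633 nm, configurable in all entry points


def q_from_angle_light(theta: float, wavelength: float = 633e-9,
                       n: float = D2O_REFRACTIVE_INDEX) -> float:
    """q = (4 pi n / lambda) sin(theta/2) for light scattering.

    ``theta`` in degrees (0 < theta < 180), ``wavelength`` in metres;
    returns q in m^-1.
    """
    theta = float(theta)
    if not (0.0 < theta < 180.0):
        raise ValueError(f"scattering angle must be in (0, 180), got {theta}")
    if n < 1.0 or wavelength <= 0:
        raise ValueError("need n >= 1 and positive wavelength")
    return 4.0 * math.pi * n / wavelength * math.sin(math.radians(theta) / 2.0)


@dataclass
class Correlogram:
    """One normalized DLS measurement: g2 - 1 versus lag time at one angle."""

    angle_deg: float
    lag_s: np.ndarray
    g2m1: np.ndarray
    error: np.ndarray | None = None
    age_h: float = 0.0
    wavelength_m: float = 633e-9
    refractive_index: float = D2O_REFRACTIVE_INDEX

    def __post_init__(self):
        self.lag_s = np.asarray(self.lag_s, dtype=float)
        self.g2m1 = np.asarray(self.g2m1, dtype=float)
        if self.error is not None:
            self.error = np.asarray(self.error, dtype=float)
        if np.any(self.lag_s <= 0) or np.any(np.diff(self.lag_s) <= 0):
            raise ValueError("lag times must be positive and strictly increasing")

    @property
    def q(self) -> float:
        """Scattering vector magnitude in m^-1."""
        return q_from_angle_light(self.angle_deg, self.wavelength_m,
                                  self.refractive_index)


@dataclass
class DLSDecayFit:
    """Two-decay decomposition of one correlogram.

    ``a`` is the weight of the slow contribution (crystals/precursors,
    rate ``gamma1``); ``1 - a`` the weight of the dissolved proteins
    (rate ``gamma2 >= gamma1``); ``beta`` the Siegert intercept.
    """

    a: float
    gamma1: float
    gamma2: float
    beta: float = 1.0
    stderr: dict = field(default_factory=dict)
    converged: bool = True
    flags: list = field(default_factory=list)

    def __call__(self, lag, squared: bool = True):
        lag = np.asarray(lag, dtype=float)
        g1 = self.a * np.exp(-self.gamma1 * lag)
        g2 = (1.0 - self.a) * np.exp(-self.gamma2 * lag)
        field_corr = g1 + g2
        return self.beta * (field_corr**2 if squared else field_corr)


def preprocess_correlograms(repeats, mad_threshold: float = 5.0):
    """Average repeated correlograms after per-lag outlier rejection.

    Dust produces isolated spikes in individual repeats; a point farther
    than ``mad_threshold`` scaled MADs from the per-lag median (across
    repeats) is excluded from the mean.  Returns the averaged
    :class:`Correlogram` and an info dict with the rejected fraction.
    """
    if len(repeats) < 2:
        raise ValueError("need at least two repeats to average")
    lag = repeats[0].lag_s
    for r in repeats[1:]:
        if r.lag_s.shape != lag.shape or not np.allclose(r.lag_s, lag):
            raise ValueError("repeats must share an identical lag grid")
    data = np.stack([r.g2m1 for r in repeats])  # (n_rep, n_lag)
    med = np.median(data, axis=0)
    resid = data - med
    # Per-lag MADs from a handful of repeats are too noisy and over-reject;
    # instead fit a robust two-parameter noise model pooled over all lags,
    # sigma(lag) = c_mult * |signal| + c_floor, which covers both
    # photon-noise-like (proportional) and additive baseline noise.
    mad = 1.4826 * np.median(np.abs(resid), axis=0)
    absmed = np.abs(med)
    high = absmed > 0.25 * np.max(absmed)
    low = absmed < 0.05 * np.max(absmed)
    c_mult = float(np.median(mad[high] / absmed[high])) if np.any(high) else 0.0
    c_floor = float(np.median(mad[low])) if np.any(low) else 0.0
    scale = c_mult * absmed + c_floor
    # guard: identical repeats have zero scale -> reject nothing
    scale = np.maximum(scale, 1e-12 * np.maximum(absmed, 1.0))
    keep = np.abs(resid) <= mad_threshold * scale
    n_kept = keep.sum(axis=0)
    # never drop every repeat at a lag
    all_bad = n_kept == 0
    keep[:, all_bad] = True
    n_kept = keep.sum(axis=0)
    mean = np.where(keep, data, 0.0).sum(axis=0) / n_kept
    resid = np.where(keep, data - mean, 0.0)
    var = (resid**2).sum(axis=0) / np.maximum(n_kept - 1, 1)
    sem = np.sqrt(var / n_kept)
    rejected = 1.0 - keep.sum() / data.size
    out = Correlogram(
        repeats[0].angle_deg, lag, mean, sem, repeats[0].age_h,
        repeats[0].wavelength_m, repeats[0].refractive_index,
    )
    return out, {"rejected_fraction": float(rejected)}


def _init_rates(lag, g, beta0):
    """Crude fast/slow rate estimates from the early and late decay."""
    g = np.clip(g / max(beta0, 1e-12), 1e-12, None)
    h = np.sqrt(g)  # field correlation estimate
    # fast rate from where h crosses ~0.5, slow rate from the tail
    half = np.searchsorted(-h, -0.5)
    half = min(max(half, 1), lag.size - 1)
    fast = max(-np.log(max(h[half], 1e-6)) / lag[half], 1.0 / lag[-1])
    tail = h > 0.05
    idx = np.where(tail)[0]
    i_last = idx[-1] if idx.size else lag.size - 1
    slow = max(-np.log(max(h[i_last], 1e-6)) / lag[i_last], 1.0 / lag[-1] / 10)
    if slow >= fast:
        slow = fast / 10.0
    return slow, fast


def fit_correlogram(c: Correlogram, squared: bool = True,
                    init: tuple | None = None) -> DLSDecayFit:
    """Fit the (Siegert-squared by default) double exponential to g2 - 1.

    Labels are swapped if needed so that ``gamma1 <= gamma2``.  ``a`` is
    constrained to [0, 1]; a fit pinned at either bound is flagged.
    Setting ``squared=False`` fits a plain sum of two exponentials
    (sensitivity check).
    """
    lag, g = c.lag_s, c.g2m1
    if lag.size < 8:
        raise ValueError("need at least 8 lag points spanning both decays")
    w = 1.0 / c.error if c.error is not None and np.all(c.error > 0) else np.ones_like(g)

    beta0 = float(max(g[0], 1e-6))
    if init is None:
        slow0, fast0 = _init_rates(lag, g, beta0)
        x0 = np.array([beta0, 0.5, slow0, fast0])
    else:
        x0 = np.asarray(init, dtype=float)

    lo = np.array([1e-6, 0.0, 1e-12, 1e-12])
    hi = np.array([10.0, 1.0, np.inf, np.inf])

    def _exp(x):
        return np.exp(np.clip(x, -700.0, 50.0))

    def model(theta, tau):
        beta, a, g1, g2_ = theta
        f = a * _exp(-g1 * tau) + (1 - a) * _exp(-g2_ * tau)
        return beta * (f**2 if squared else f)

    def resid(theta):
        return (g - model(theta, lag)) * w

    def jac(theta):
        beta, a, g1, g2_ = theta
        e1 = _exp(-g1 * lag)
        e2 = _exp(-g2_ * lag)
        f = a * e1 + (1 - a) * e2
        pre = (2.0 * beta * f) if squared else np.ones_like(f)
        d_beta = f**2 if squared else f
        d_a = pre * (e1 - e2)
        d_g1 = pre * (-a * lag * e1)
        d_g2 = pre * (-(1 - a) * lag * e2)
        return -np.column_stack([d_beta, d_a, d_g1, d_g2]) * w[:, None]

    # fast unconstrained path (MINPACK); falls back to a bounded solver if
    # the solution wanders outside the physical box
    theta = cost = cov_scaled = None
    sol_x, cov_x, info, _, ier = optimize.leastsq(
        resid, x0, Dfun=jac, full_output=True)
    ok = (ier in (1, 2, 3, 4) and cov_x is not None
          and -1e-3 <= sol_x[1] <= 1 + 1e-3
          and sol_x[2] > 0 and sol_x[3] > 0 and sol_x[0] > 0)
    if ok:
        theta = np.array(sol_x)
        theta[1] = float(np.clip(theta[1], 0.0, 1.0))
        cost = 0.5 * float(np.sum(resid(theta) ** 2))
        converged = True
        cov_raw = cov_x
    else:
        lo = np.array([1e-6, 0.0, 1e-12, 1e-12])
        hi = np.array([10.0, 1.0, np.inf, np.inf])
        sol = optimize.least_squares(resid, np.clip(x0, lo, hi),
                                     bounds=(lo, hi), method="trf", jac=jac)
        theta = sol.x
        cost = sol.cost
        converged = bool(sol.success)
        try:
            cov_raw = np.linalg.pinv(sol.jac.T @ sol.jac)
        except np.linalg.LinAlgError:
            cov_raw = None

    beta, a, g1, g2_ = theta
    flags = []
    if not converged:
        flags.append("non-convergence")
    swapped = g1 > g2_
    if swapped:
        g1, g2_, a = g2_, g1, 1.0 - a
    if a < 1e-4 or a > 1 - 1e-4:
        flags.append("a-at-bound")
        # canonical single-decay form: all weight on the slow label with
        # both rates equal to the one physical rate
        rate = g2_ if a < 1e-4 else g1
        a, g1, g2_ = 1.0, rate, rate

    ndof = max(lag.size - 4, 1)
    redchi = 2 * cost / ndof
    stderr = {}
    if cov_raw is not None:
        err = np.sqrt(np.clip(np.diag(cov_raw * redchi), 0, None))
        if swapped:
            err = err[[0, 1, 3, 2]]
        stderr = {"beta": err[0], "a": err[1], "gamma1": err[2], "gamma2": err[3]}
    return DLSDecayFit(float(a), float(g1), float(g2_), float(beta),
                       stderr, converged, flags)


@dataclass
class DiffusionSeries:
    """Collective diffusion coefficients versus sample age.

    ``D1`` (slow branch: clusters/precursors) <= ``D2`` (fast branch:
    dissolved proteins), both in m²/s.
    """

    age_h: np.ndarray
    D1: np.ndarray
    D2: np.ndarray
    D1_err: np.ndarray | None = None
    D2_err: np.ndarray | None = None

    def __post_init__(self):
        self.age_h = np.asarray(self.age_h, dtype=float)
        self.D1 = np.asarray(self.D1, dtype=float)
        self.D2 = np.asarray(self.D2, dtype=float)


def diffusion_from_rates(fits_with_q) -> dict:
    """Collective D from the q dependence of the decay rates at one age.

    ``fits_with_q`` is a sequence of ``(q_m_inv, DLSDecayFit)`` pairs for
    different angles.  Each branch is fitted by a weighted straight line
    through the origin, Gamma = D q^2, whose slope is the diffusion
    coefficient.  Returns a dict with D1, D2 (m²/s), their 1-sigma errors
    and flags.
    """
    if len(fits_with_q) < 3:
        raise ValueError("need at least 3 distinct q values")
    q = np.array([p[0] for p in fits_with_q], dtype=float)
    out = {"flags": []}
    for branch in ("gamma1", "gamma2"):
        gam = np.array([getattr(p[1], branch) for p in fits_with_q])
        sig = np.array([p[1].stderr.get(branch, np.nan) for p in fits_with_q])
        if np.any(~np.isfinite(sig)) or np.any(sig <= 0):
            w = np.ones_like(gam)
        else:
            w = 1.0 / sig**2
        q2 = q**2
        denom = np.sum(w * q2 * q2)
        D = np.sum(w * q2 * gam) / denom
        D_err = 1.0 / math.sqrt(denom) if np.all(np.isfinite(sig)) and np.all(sig > 0) else np.nan
        key = "D1" if branch == "gamma1" else "D2"
        out[key] = float(D)
        out[key + "_err"] = float(D_err)
        if D < 0:
            out["flags"].append(f"negative-{key}")
    return out


def dls_kinetics(series: DiffusionSeries, branch: str = "D2",
                 n_components: int = 2) -> FitResult:
    """Sigmoid kinetics of a diffusion-coefficient time series.

    The evolution of the fast (monomer) coefficient D2(t) typically needs
    a sum of two sigmoids on top of the initial diffusion level, so the
    fit includes a constant background.
    """
    y = getattr(series, branch)
    err = getattr(series, branch + "_err")
    if err is not None and np.all(np.isfinite(err)) and np.all(err > 0):
        sigma = err
    else:
        sigma = None
    return fit_kinetics(series.age_h, y, sigma, n_components=n_components,
                        with_background=True)


def analyze_dls_dataset(correlograms, n_components: int = 2):
    """Full pipeline: correlograms (all ages, all angles) -> per-age
    double-exponential fits -> Gamma = D q^2 -> DiffusionSeries -> kinetic
    fit of D2(t).

    Returns ``(series, fit_result)``.
    """
    by_age: dict[float, list[Correlogram]] = {}
    for c in correlograms:
        by_age.setdefault(round(c.age_h, 9), []).append(c)
    ages, d1, d2, e1, e2 = [], [], [], [], []
    warm: dict[float, tuple] = {}  # per-angle warm start from the previous age
    for age in sorted(by_age):
        pairs = []
        for c in by_age[age]:
            fit = fit_correlogram(c, init=warm.get(c.angle_deg))
            warm[c.angle_deg] = (fit.beta, fit.a, fit.gamma1, fit.gamma2)
            pairs.append((c.q, fit))
        res = diffusion_from_rates(pairs)
        ages.append(age)
        d1.append(res["D1"])
        d2.append(res["D2"])
        e1.append(res["D1_err"])
        e2.append(res["D2_err"])
    series = DiffusionSeries(np.array(ages), np.array(d1), np.array(d2),
                             np.array(e1), np.array(e2))
    fit = dls_kinetics(series, n_components=n_components)
    return series, fit


# -- external interfaces ------------------------------------------------------


def write_correlograms(path, correlograms) -> None:
    """CSV dialect: angle_deg, lag_s, g2m1, error, age_h."""
    rows = []
    for c in correlograms:
        err = c.error if c.error is not None else np.full_like(c.lag_s, np.nan)
        for lag, g, e in zip(c.lag_s, c.g2m1, err):
            rows.append((c.angle_deg, lag, g, e, c.age_h))
    pd.DataFrame(rows, columns=["angle_deg", "lag_s", "g2m1", "error", "age_h"]
                 ).to_csv(path, index=False)


def read_correlograms(path, wavelength_m: float = 633e-9,
                      n: float = D2O_REFRACTIVE_INDEX):
    df = pd.read_csv(path)
    out = []
    for (angle, age), grp in df.groupby(["angle_deg", "age_h"], sort=True):
        grp = grp.sort_values("lag_s")
        err = grp["error"].to_numpy(float)
        out.append(Correlogram(
            float(angle), grp["lag_s"].to_numpy(float),
            grp["g2m1"].to_numpy(float),
            None if np.all(np.isnan(err)) else err,
            float(age), wavelength_m, n,
        ))
    return out
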