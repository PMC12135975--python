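"""Neutron spin echo: intermediate scattering functions with mixed
coherent/incoherent decays and the immobile crystal fraction.

Polarized spin-echo measures coherent and spin-incoherent scattering with
opposite signs, so the normalized intermediate scattering function is
modelled as

    I(q, tau) = a_coh * I_coh(tau) - a_inc * I_inc(tau)

with single-exponential decays I_n(tau) = exp(-gamma_n tau).  Because the
signal may have partially decayed before the first measured Fourier time,
the amplitudes cannot be fixed from theory; instead the combination
``a_coh - a_inc`` is pinned to the measured value at the smallest Fourier
time (tau < 15 ps).  At a Bragg position the coherent part gains an
immobile contribution from crystals,

    I_coh(tau) = s + (1 - s) exp(-gamma_free tau),

where ``s`` tracks the fraction of proteins in (static) crystals and
``gamma_free``, the free-protein decay rate, is held fixed from the
adjacent non-Bragg q values assuming Fickian diffusion (gamma = D q^2).
The time series s(t), background-subtracted and normalized to unit
maximum, is the crystal-fraction observable c_NSE(t).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .core_models import FitResult, fit_kinetics

__all__ = [
    "ISFCurve",
    "NSEModelParams",
    "isf_model",
    "fit_isf",
    "fickian_interpolate_rate",
    "nse_crystal_series",
    "analyze_nse_dataset",
    "read_isf_curves",
    "write_isf_curves",
]

TAU_CONSTRAINT_MAX_NS = 0.015  # the amplitude constraint comes from tau < 15 ps


@dataclass
class ISFCurve:
    """One resolution-normalized, buffer-corrected I(q, tau)/I(q, 0) curve."""

    q: float
    tau_ns: np.ndarray
    isf: np.ndarray
    error: np.ndarray | None = None
    age_h: float = 0.0
    is_bragg: bool = False

    def __post_init__(self):
        self.tau_ns = np.asarray(self.tau_ns, dtype=float)
        self.isf = np.asarray(self.isf, dtype=float)
        if self.error is not None:
            self.error = np.asarray(self.error, dtype=float)
        if np.any(self.tau_ns <= 0) or np.any(np.diff(self.tau_ns) <= 0):
            raise ValueError("tau must be positive and strictly increasing")


@dataclass
class NSEModelParams:
    a_coh: float
    a_inc: float
    gamma_coh: float  # ns^-1; at a Bragg q this is gamma_free of the mobile part
    gamma_inc: float  # ns^-1
    s: float = 0.0  # immobile (crystal) fraction; nonzero only at Bragg q
    stderr: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)


def isf_model(tau, params: NSEModelParams):
    """Evaluate the two-contribution ISF model at Fourier times ``tau`` (ns).

    With ``gamma_inc > gamma_coh`` and ``a_inc > 0`` the model first rises
    with tau (the fast incoherent term, entering negatively, dies first)
    and then decays — the fingerprint of incoherent-contaminated curves at
    higher q.
    """
    if params.gamma_coh < 0 or params.gamma_inc < 0:
        raise ValueError("decay rates must be non-negative")
    tau = np.asarray(tau, dtype=float)
    coh = params.s + (1.0 - params.s) * np.exp(-params.gamma_coh * tau)
    inc = np.exp(-params.gamma_inc * tau)
    out = params.a_coh * coh - params.a_inc * inc
    return out if out.ndim else float(out)


def fit_isf(curve: ISFCurve, constraint: float | None = None,
            gamma_free: float | None = None,
            convention: str = "difference") -> tuple[NSEModelParams, FitResult]:
    """Constrained weighted fit of one ISF curve.

    ``constraint`` is the pinned value of ``a_coh - a_inc`` (difference
    convention, default) or ``a_coh + a_inc`` (``convention="sum"``,
    sensitivity switch).  If omitted it is read off the curve's smallest
    Fourier time, which must satisfy tau < 15 ps.

    For a Bragg curve (``curve.is_bragg``) the mobile decay rate is held
    fixed at ``gamma_free`` (from Fickian interpolation of neighbours) and
    the free parameters are the amplitude split and the immobile fraction
    ``s``; otherwise ``s = 0`` and both rates are free.
    """
    tau, y = curve.tau_ns, curve.isf
    if constraint is None:
        if tau[0] >= TAU_CONSTRAINT_MAX_NS:
            raise ValueError(
                "no Fourier time below 15 ps to set the amplitude constraint; "
                "pass `constraint` explicitly")
        constraint = float(y[0])
    if convention not in ("difference", "sum"):
        raise ValueError("convention must be 'difference' or 'sum'")
    if curve.is_bragg and gamma_free is None:
        raise ValueError("Bragg curve needs gamma_free from neighbouring q")

    w = (1.0 / curve.error if curve.error is not None and np.all(curve.error > 0)
         else np.ones_like(y))
    sgn = -1.0 if convention == "sum" else 1.0

    def a_coh_of(a_inc):
        # difference: a_coh = constraint + a_inc;  sum: a_coh = constraint - a_inc
        return constraint + sgn * a_inc

    if curve.is_bragg:
        names = ["a_inc", "gamma_inc", "s"]

        def unpack(theta):
            a_inc, g_inc, s = theta
            return NSEModelParams(a_coh_of(a_inc), a_inc, gamma_free, g_inc, s)

        x0 = np.array([0.2, 5.0, 0.3])
        lo = np.array([0.0, 0.0, 0.0])
        hi = np.array([10.0, 1e3, 1.0])
    else:
        names = ["a_inc", "gamma_coh", "gamma_inc"]

        def unpack(theta):
            a_inc, g_coh, g_inc = theta
            return NSEModelParams(a_coh_of(a_inc), a_inc, g_coh, g_inc, 0.0)

        x0 = np.array([0.2, 0.5, 5.0])
        lo = np.array([0.0, 0.0, 0.0])
        hi = np.array([10.0, 1e3, 1e3])

    def resid(theta):
        return (y - isf_model(tau, unpack(theta))) * w

    sol = optimize.least_squares(resid, x0, bounds=(lo, hi), method="trf",
                                 xtol=1e-14, ftol=1e-14)
    params = unpack(sol.x)
    flags = [] if sol.success else ["non-convergence"]
    ndof = max(tau.size - len(names), 1)
    redchi = 2 * sol.cost / ndof
    try:
        cov = np.linalg.pinv(sol.jac.T @ sol.jac) * redchi
        err = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        cov = np.full((len(names), len(names)), np.nan)
        err = np.full(len(names), np.nan)
        flags.append("singular-covariance")
    params.stderr = dict(zip(names, err))
    params.flags = flags
    fit = FitResult(params, names, sol.x, err, cov, redchi, bool(sol.success), flags)
    return params, fit


def fickian_interpolate_rate(q_bragg: float, neighbor_fits,
                             errors=None) -> float:
    """Free-protein decay rate at the Bragg q from adjacent q values.

    ``neighbor_fits`` is a sequence of ``(q, gamma_coh)`` pairs at non-Bragg
    positions.  A weighted straight line through the origin, gamma = D q^2,
    is fitted and evaluated at ``q_bragg``.
    """
    if len(neighbor_fits) < 2:
        raise ValueError("need at least 2 neighbouring q values")
    q = np.array([p[0] for p in neighbor_fits], dtype=float)
    gam = np.array([p[1] for p in neighbor_fits], dtype=float)
    w = (1.0 / np.asarray(errors, dtype=float) ** 2
         if errors is not None else np.ones_like(gam))
    q2 = q**2
    D = np.sum(w * q2 * gam) / np.sum(w * q2 * q2)
    return float(D * q_bragg**2)


def nse_crystal_series(age_h, s_values, errors=None,
                       redchi_threshold: float = 10.0):
    """Crystal-fraction kinetics c_NSE(t) from the immobile fractions s(t).

    The value at the first time point is subtracted, the series is
    normalized so its maximum is 1 (free scale absorbed by the fit
    amplitude), and a single sigmoid plus a free constant background is
    fitted — the background absorbs the noise of the single subtracted
    t = 0 point, which otherwise biases the characteristic time low.
    Returns ``(times, c_nse, fit_result)``; a degenerate (constant)
    series or a poor fit is flagged on the result.
    """
    t = np.asarray(age_h, dtype=float)
    s = np.asarray(s_values, dtype=float)
    if t.size < 4:
        raise ValueError("need at least 4 time points")
    base = s - s[0]
    peak = np.max(np.abs(base))
    flags = []
    if peak <= 0 or not np.isfinite(peak):
        flags.append("degenerate-normalization")
        c = base
        sigma = None
    else:
        c = base / np.max(base)
        sigma = (np.asarray(errors, dtype=float) / np.max(base)
                 if errors is not None else None)
    fit = fit_kinetics(t, c, sigma, n_components=1, with_background=True)
    fit.flags.extend(flags)
    if fit.redchi > redchi_threshold:
        fit.flags.append("poor-fit")
    return t, c, fit


def analyze_nse_dataset(curves, bragg_q: float | None = None,
                        convention: str = "difference",
                        n_neighbors: int = 2):
    """Full pipeline: ISF curves (all ages and q) -> per-curve constrained
    fits -> Fickian gamma_free at the Bragg q -> s(t) -> c_NSE(t) kinetics.

    Only the ``n_neighbors`` non-Bragg curves closest in q to the Bragg
    position feed the Fickian interpolation: curves far above the Bragg q
    are incoherent-dominated and their coherent rate is poorly determined.

    Returns ``(ages, s_values, fit_result)`` where ``fit_result`` is the
    sigmoid fit of the normalized series.
    """
    by_age: dict[float, list[ISFCurve]] = {}
    for c in curves:
        if bragg_q is not None and abs(c.q - bragg_q) < 1e-9:
            c.is_bragg = True
        by_age.setdefault(round(c.age_h, 9), []).append(c)
    ages, s_vals, s_errs = [], [], []
    for age in sorted(by_age):
        group = by_age[age]
        braggs = [c for c in group if c.is_bragg]
        others = [c for c in group if not c.is_bragg]
        for c in braggs:
            adjacent = sorted(others, key=lambda o: abs(o.q - c.q))
            adjacent = adjacent[:max(n_neighbors, 2)]
            neighbor, nb_err = [], []
            for o in adjacent:
                p, _ = fit_isf(o, convention=convention)
                neighbor.append((o.q, p.gamma_coh))
                nb_err.append(p.stderr.get("gamma_coh", np.nan))
            nb_err = np.asarray(nb_err)
            errs = (nb_err if np.all(np.isfinite(nb_err)) and np.all(nb_err > 0)
                    else None)
            gfree = fickian_interpolate_rate(c.q, neighbor, errs)
            p, _ = fit_isf(c, gamma_free=gfree, convention=convention)
            ages.append(age)
            s_vals.append(p.s)
            s_errs.append(p.stderr.get("s", np.nan))
    ages = np.array(ages)
    s_vals = np.array(s_vals)
    errs = np.array(s_errs)
    errs = errs if np.all(np.isfinite(errs)) and np.all(errs > 0) else None
    t, c, fit = nse_crystal_series(ages, s_vals, errs)
    return ages, s_vals, fit


# -- external interfaces ------------------------------------------------------


def write_isf_curves(path, curves) -> None:
    """CSV dialect: q_A_inv, tau_ns, isf, error, age_h, is_bragg."""
    rows = []
    for c in curves:
        err = c.error if c.error is not None else np.full_like(c.tau_ns, np.nan)
        for tau, v, e in zip(c.tau_ns, c.isf, err):
            rows.append((c.q, tau, v, e, c.age_h, int(c.is_bragg)))
    pd.DataFrame(rows, columns=["q_A_inv", "tau_ns", "isf", "error",
                                "age_h", "is_bragg"]).to_csv(path, index=False)


def read_isf_curves(path):
    df = pd.read_csv(path)
    out = []
    for (q, age, bragg), grp in df.groupby(["q_A_inv", "age_h", "is_bragg"],
                                           sort=True):
        grp = grp.sort_values("tau_ns")
        err = grp["error"].to_numpy(float)
        out.append(ISFCurve(
            float(q), grp["tau_ns"].to_numpy(float), grp["isf"].to_numpy(float),
            None if np.all(np.isnan(err)) else err, float(age), bool(bragg),
        ))
    return out
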