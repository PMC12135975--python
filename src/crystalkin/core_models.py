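"""Shared kinetic model and physical-unit helpers.

All kinetic time series in this package — crystal areas from microscopy,
diffusion coefficients from light scattering, immobile fractions from
spin-echo spectroscopy, elastic fractions from backscattering, Bragg-peak
intensities from diffraction — are described by sums of logistic (sigmoid)
growth terms

    f(t) = f0 / (1 + exp(-(t - t0) / dt))

where ``f0`` is the saturation amplitude, ``t0`` the inflection time (the
moment of fastest growth) and ``dt`` the characteristic time, so that the
maximum growth rate is ``f0 / (4 dt)``.  Amplitudes may be negative to
describe a vanishing contribution (e.g. a dissolving gel phase).

This module owns the model, its weighted least-squares fitting machinery,
and the small set of physical conversions (Stokes-Einstein, scattering
vector from angle, lattice spacing from q) used by the technique-specific
pipelines.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import constants, optimize
from scipy.special import expit

__all__ = [
    "HBAR_UEV_NS",
    "KB_J_PER_K",
    "SigmoidComponent",
    "KineticModel",
    "FitResult",
    "sigmoid_eval",
    "sigmoid_derivative",
    "fit_kinetics",
    "stokes_einstein",
    "hydrodynamic_radius",
    "q_from_angle_neutron",
    "d_spacing",
    "runs_test_pvalue",
    "read_kinetic_trace",
    "write_kinetic_trace",
]

# -- unit conventions ---------------------------------------------------------
# hbar in µeV·ns: converts a diffusion coefficient in Å²/ns times q² in Å⁻²
# into a quasi-elastic linewidth in µeV.
HBAR_UEV_NS: float = 0.6582119569
KB_J_PER_K: float = constants.k


# -- model --------------------------------------------------------------------


@dataclass(frozen=True)
class SigmoidComponent:
    """One logistic growth (or decay, for f0 < 0) term.

    Parameters
    ----------
    f0 : float
        Saturation amplitude in the observable's units.
    t0 : float
        Inflection time in hours — the time of fastest growth.
    dt : float
        Characteristic time in hours; must be positive.
    """

    f0: float
    t0: float
    dt: float

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")

    def __call__(self, t):
        return sigmoid_eval(t, self)

    def derivative(self, t):
        return sigmoid_derivative(t, self)


def sigmoid_eval(t, comp: SigmoidComponent):
    """Evaluate ``f0 * logistic((t - t0)/dt)`` at time(s) ``t`` (hours)."""
    t = np.asarray(t, dtype=float)
    out = comp.f0 * expit((t - comp.t0) / comp.dt)
    return out if out.ndim else float(out)


def sigmoid_derivative(t, comp: SigmoidComponent):
    """Analytic time derivative; equals f0/(4 dt) at t = t0."""
    t = np.asarray(t, dtype=float)
    u = expit((t - comp.t0) / comp.dt)
    out = comp.f0 / comp.dt * u * (1.0 - u)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class KineticModel:
    """Sum of sigmoid components plus a constant background.

    The limits are ``background`` at t -> -inf and ``background + sum(f0)``
    at t -> +inf.
    """

    components: tuple[SigmoidComponent, ...]
    background: float = 0.0

    def __post_init__(self) -> None:
        if len(self.components) == 0:
            raise ValueError("KineticModel needs at least one component")
        object.__setattr__(self, "components", tuple(self.components))

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, self.background, dtype=float)
        for c in self.components:
            out = out + sigmoid_eval(t, c)
        return out if out.ndim else float(out)

    @property
    def total_amplitude(self) -> float:
        return sum(c.f0 for c in self.components)


@dataclass
class FitResult:
    """Weighted least-squares fit outcome.

    Holds the fitted :class:`KineticModel` (or a bare parameter vector for
    non-kinetic fits), per-parameter 1-sigma uncertainties from the local
    covariance, the covariance matrix itself, the reduced chi-square and
    convergence/diagnostic flags.
    """

    model: object
    param_names: list[str]
    params: np.ndarray
    stderr: np.ndarray
    covariance: np.ndarray
    redchi: float
    converged: bool
    flags: list[str] = field(default_factory=list)

    def __getitem__(self, name: str) -> float:
        return float(self.params[self.param_names.index(name)])

    def error(self, name: str) -> float:
        return float(self.stderr[self.param_names.index(name)])

    def to_dict(self) -> dict:
        return {
            "param_names": list(self.param_names),
            "params": [float(p) for p in self.params],
            "stderr": [float(s) for s in self.stderr],
            "covariance": np.asarray(self.covariance).tolist(),
            "redchi": float(self.redchi),
            "converged": bool(self.converged),
            "flags": list(self.flags),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# -- fitting ------------------------------------------------------------------


def _kinetic_params_to_model(theta, n_components, with_background):
    comps = tuple(
        SigmoidComponent(theta[3 * i], theta[3 * i + 1], theta[3 * i + 2])
        for i in range(n_components)
    )
    bg = theta[3 * n_components] if with_background else 0.0
    return KineticModel(comps, bg)


def _kinetic_eval(theta, t, n_components, with_background):
    out = np.zeros_like(t)
    for i in range(n_components):
        f0, t0, dt = theta[3 * i : 3 * i + 3]
        out = out + f0 * expit((t - t0) / dt)
    if with_background:
        out = out + theta[3 * n_components]
    return out


def _default_inits(t, y, n_components, with_background, rng):
    """Heuristic starting points: t0 at the steepest finite-difference
    slope, dt = span/10, f0 = data range; multi-component inits jitter t0
    across the observation window."""
    span = float(t[-1] - t[0])
    dy = np.gradient(y, t)
    t0_guess = float(t[int(np.argmax(np.abs(dy)))])
    f0_guess = float(y[-1] - y[0]) or float(np.ptp(y)) or 1.0
    dt_guess = span / 10.0
    inits = []
    base = []
    for i in range(n_components):
        shift = 0.0 if n_components == 1 else (i - (n_components - 1) / 2) * span / 4
        base += [f0_guess / n_components, t0_guess + shift, dt_guess]
    if with_background:
        base.append(float(y[0]))
    inits.append(np.array(base))
    n_starts = 1 if n_components == 1 else 5
    for _ in range(n_starts - 1):
        jit = np.array(base)
        for i in range(n_components):
            jit[3 * i] *= rng.uniform(0.3, 2.0) * rng.choice([1.0, 1.0, -1.0])
            jit[3 * i + 1] = t[0] + rng.uniform(0, 1) * span
            jit[3 * i + 2] = dt_guess * rng.uniform(0.3, 3.0)
        inits.append(jit)
    return inits


def _covariance_from_jacobian(J, redchi):
    """(J^T J)^-1 * redchi with per-column equilibration for numerical
    stability across badly mixed parameter scales."""
    J = np.atleast_2d(np.asarray(J, dtype=float))
    scale = np.linalg.norm(J, axis=0)
    scale[scale == 0] = 1.0
    Js = J / scale
    try:
        core = np.linalg.pinv(Js.T @ Js)
    except np.linalg.LinAlgError:
        return None, None
    cov = (core / np.outer(scale, scale)) * redchi
    return cov, np.sqrt(np.clip(np.diag(cov), 0, None))


def fit_kinetics(
    t,
    y,
    sigma=None,
    n_components: int = 1,
    with_background: bool = False,
    init=None,
    free_scale: bool = True,
) -> FitResult:
    """Fit a sum of ``n_components`` sigmoids (plus optional constant
    background) to a kinetic trace by weighted least squares.

    Components are returned sorted by t0.  Non-convergence and degenerate
    (constant) input are flagged on the result, never silent.  ``sigma``
    weights the residuals when given; otherwise the fit is unweighted.
    ``free_scale`` is only documentation of intent — the amplitude f0 of
    every component is always a free parameter.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if sigma is not None:
        sigma = np.asarray(sigma, dtype=float)
        if np.any(sigma <= 0):
            raise ValueError("sigma must be positive where given")
    n_par = 3 * n_components + (1 if with_background else 0)
    if t.size < n_par + 1:
        raise ValueError(f"need at least {n_par + 1} points for {n_par} parameters")

    flags: list[str] = []
    if np.ptp(y) == 0 or (np.std(y) < 1e-14 * max(1.0, abs(float(np.mean(y))))):
        flags.append("degenerate-data")

    span = float(t[-1] - t[0])
    lo, hi = [], []
    for _ in range(n_components):
        lo += [-np.inf, t[0] - span, 1e-9 * max(span, 1.0)]
        hi += [np.inf, t[-1] + span, span if span > 0 else np.inf]
    if with_background:
        lo.append(-np.inf)
        hi.append(np.inf)
    lo, hi = np.array(lo), np.array(hi)

    w = 1.0 / sigma if sigma is not None else np.ones_like(y)

    def resid(theta):
        return (y - _kinetic_eval(theta, t, n_components, with_background)) * w

    rng = np.random.default_rng(12345)
    inits = (
        [np.clip(np.asarray(init, dtype=float), lo, hi)]
        if init is not None
        else _default_inits(t, y, n_components, with_background, rng)
    )

    best = None
    for x0 in inits:
        x0 = np.clip(x0, lo + 1e-12, hi - 1e-12)
        try:
            sol = optimize.least_squares(resid, x0, bounds=(lo, hi),
                                         method="trf", x_scale="jac")
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("kinetic fit failed from every starting point")

    converged = bool(best.success)
    if not converged:
        flags.append("non-convergence")

    theta = best.x
    ndof = max(t.size - n_par, 1)
    redchi = 2 * best.cost / ndof
    # covariance (J^T J)^-1 scaled by reduced chi-square, from the solver's
    # Jacobian at the solution; columns are rescaled first so that wildly
    # different parameter magnitudes (e.g. amplitudes in m²/s next to times
    # in hours) do not defeat the pseudo-inverse
    cov, stderr = _covariance_from_jacobian(best.jac, redchi)
    if cov is None:
        cov = np.full((n_par, n_par), np.nan)
        stderr = np.full(n_par, np.nan)
        flags.append("singular-covariance")

    # sort components by t0 (label order is arbitrary in a sum); permute the
    # covariance consistently
    order = np.argsort([theta[3 * i + 1] for i in range(n_components)])
    idx = [3 * o + k for o in order for k in range(3)]
    if with_background:
        idx.append(3 * n_components)
    theta = theta[idx]
    stderr = stderr[idx]
    cov = cov[np.ix_(idx, idx)]

    names = []
    for i in range(n_components):
        names += [f"f0_{i + 1}", f"t0_{i + 1}", f"dt_{i + 1}"]
    if with_background:
        names.append("background")

    model = _kinetic_params_to_model(theta, n_components, with_background)
    return FitResult(model, names, theta, stderr, cov, redchi, converged, flags)


# -- physical conversions -----------------------------------------------------


def stokes_einstein(T: float, eta: float, Rh: float) -> float:
    """Translational diffusion coefficient D = kB T / (6 pi eta Rh).

    T in kelvin, eta in Pa·s, Rh in metres; returns D in m²/s.
    """
    if T <= 0 or eta <= 0 or Rh <= 0:
        raise ValueError("T, eta and Rh must be strictly positive")
    return KB_J_PER_K * T / (6.0 * math.pi * eta * Rh)


def hydrodynamic_radius(T: float, eta: float, D: float) -> float:
    """Inverse Stokes-Einstein: Rh from D (m²/s), in metres."""
    if T <= 0 or eta <= 0 or D <= 0:
        raise ValueError("T, eta and D must be strictly positive")
    return KB_J_PER_K * T / (6.0 * math.pi * eta * D)


def q_from_angle_neutron(two_theta: float, wavelength: float) -> float:
    """Scattering vector magnitude q = (4 pi / lambda) sin(2theta / 2).

    ``two_theta`` is the full scattering angle in degrees, ``wavelength``
    in Å; returns q in Å⁻¹.
    """
    two_theta = float(two_theta)
    if not (0.0 <= two_theta < 180.0):
        raise ValueError(f"two_theta must be in [0, 180), got {two_theta}")
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    return 4.0 * math.pi / wavelength * math.sin(math.radians(two_theta) / 2.0)


def d_spacing(q: float) -> float:
    """Lattice spacing d = 2 pi / q, with q in Å⁻¹ and d returned in nm."""
    if q <= 0:
        raise ValueError("q must be positive")
    return 2.0 * math.pi / q * 0.1


# -- small statistics helper --------------------------------------------------


def runs_test_pvalue(residuals) -> float:
    """Wald-Wolfowitz runs test on residual signs (normal approximation).

    A small p-value indicates structured (non-random) residuals, i.e. a
    systematically wrong model.  Zero residuals are dropped.
    """
    r = np.asarray(residuals, dtype=float)
    s = np.sign(r[r != 0])
    n1 = int(np.sum(s > 0))
    n2 = int(np.sum(s < 0))
    n = n1 + n2
    if n1 == 0 or n2 == 0:
        return 0.0
    runs = 1 + int(np.sum(s[1:] != s[:-1]))
    mu = 2.0 * n1 * n2 / n + 1.0
    var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n**2 * (n - 1.0))
    if var <= 0:
        return 1.0
    from scipy.stats import norm

    z = (runs - mu) / math.sqrt(var)
    return float(2.0 * norm.sf(abs(z)))


# -- external interfaces ------------------------------------------------------


def read_kinetic_trace(path):
    """Read a kinetic trace CSV with columns time_h, value[, error]."""
    df = pd.read_csv(path)
    t = df["time_h"].to_numpy(float)
    y = df["value"].to_numpy(float)
    sigma = df["error"].to_numpy(float) if "error" in df.columns else None
    return t, y, sigma


def write_kinetic_trace(path, t, y, sigma=None) -> None:
    data = {"time_h": np.asarray(t), "value": np.asarray(y)}
    if sigma is not None:
        data["error"] = np.asarray(sigma)
    pd.DataFrame(data).to_csv(path, index=False)
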