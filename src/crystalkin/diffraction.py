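"""In situ diffraction kinetics: Bragg-peak crystal fraction and low-q
intensity kinetics.

The dissolved-protein signal under the Bragg peak is estimated per frame
by linear interpolation across an exclusion window from flanking points
(the mean of three points on each side); the summed excess above that
baseline tracks the crystal amount.  Assuming no crystals in the first
frame and full crystallization in the last, subtracting the t = 0 value
and normalizing by the final frame yields the crystal fraction c_Diff(t).
The lowest-q intensity, normalized to its initial value, provides a
Bragg-peak-independent kinetic observable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_models import FitResult, fit_kinetics

__all__ = [
    "DiffractionFrame",
    "CrystalFractionSeries",
    "find_bragg_peak",
    "bragg_crystal_fraction",
    "lowq_kinetics",
    "read_diffraction_frames",
    "write_diffraction_frames",
]


@dataclass
class DiffractionFrame:
    """One I(q) snapshot at a sample age."""

    time_h: float
    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q grid must be strictly ascending")
        if np.any(self.I < 0):
            raise ValueError("intensities must be non-negative")


@dataclass
class CrystalFractionSeries:
    """Normalized crystal-fraction time series from one technique."""

    time_h: np.ndarray
    fraction: np.ndarray
    sigma: np.ndarray | None = None
    label: str = "c_Diff"
    fit: FitResult | None = None
    flags: list = field(default_factory=list)


def _baseline_under_window(frame: DiffractionFrame, lo_idx: int, hi_idx: int,
                           n_flank: int = 3):
    """Linear-in-q baseline across [lo_idx, hi_idx) from the mean of
    ``n_flank`` points on each side."""
    q, I = frame.q, frame.I
    if lo_idx - n_flank < 0 or hi_idx + n_flank > q.size:
        raise ValueError("exclusion window touches the grid edge")
    ql = q[lo_idx - n_flank:lo_idx].mean()
    qr = q[hi_idx:hi_idx + n_flank].mean()
    Il = I[lo_idx - n_flank:lo_idx].mean()
    Ir = I[hi_idx:hi_idx + n_flank].mean()
    slope = (Ir - Il) / (qr - ql)
    return Il + slope * (q[lo_idx:hi_idx] - ql)


def find_bragg_peak(frame: DiffractionFrame,
                    window: tuple[float, float],
                    n_flank: int = 3,
                    min_significance: float = 3.0) -> float:
    """Locate the Bragg peak inside ``window`` (q units).

    The baseline interpolated from flanking points is subtracted; the
    maximum of the excess, refined by a local quadratic through its three
    neighbouring points, is returned.  Raises if no point exceeds
    ``min_significance`` baseline standard deviations.
    """
    q = frame.q
    lo_idx = int(np.searchsorted(q, window[0], side="left"))
    hi_idx = int(np.searchsorted(q, window[1], side="right"))
    if hi_idx - lo_idx < 3:
        raise ValueError("window must contain at least 3 grid points")
    base = _baseline_under_window(frame, lo_idx, hi_idx, n_flank)
    excess = frame.I[lo_idx:hi_idx] - base
    flank = np.concatenate([frame.I[lo_idx - n_flank:lo_idx],
                            frame.I[hi_idx:hi_idx + n_flank]])
    noise = max(float(np.std(flank)), 1e-300)
    if frame.sigma is not None:
        noise = max(noise, float(np.median(frame.sigma[lo_idx:hi_idx])))
    k = int(np.argmax(excess))
    if excess[k] < min_significance * noise:
        raise ValueError("no peak above the baseline significance threshold")
    if k == 0 or k == excess.size - 1:
        # peak sits at the window edge: return the grid point, unrefined
        return float(q[lo_idx + k])
    # local quadratic refinement
    y0, y1, y2 = excess[k - 1], excess[k], excess[k + 1]
    denom = y0 - 2 * y1 + y2
    shift = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    x = q[lo_idx + k - 1:lo_idx + k + 2]
    step = 0.5 * (x[2] - x[0])
    return float(q[lo_idx + k] + np.clip(shift, -1, 1) * step)


def bragg_crystal_fraction(frames, q_bragg: float, half_width: float,
                           n_flank: int = 3) -> CrystalFractionSeries:
    """Crystal fraction c_Diff(t) from the integrated Bragg excess.

    Per frame, the dissolved-protein baseline under the peak is linearly
    interpolated from flanking points and subtracted; the summed excess
    over the exclusion window |q - q_bragg| <= half_width is the crystal
    signal.  The series is baseline-subtracted at t = 0 and normalized by
    the final frame, then fitted with a single sigmoid.
    """
    if len(frames) < 3:
        raise ValueError("need at least 3 frames")
    times, excess = [], []
    for frame in sorted(frames, key=lambda f: f.time_h):
        q = frame.q
        lo_idx = int(np.searchsorted(q, q_bragg - half_width, side="left"))
        hi_idx = int(np.searchsorted(q, q_bragg + half_width, side="right"))
        base = _baseline_under_window(frame, lo_idx, hi_idx, n_flank)
        times.append(frame.time_h)
        excess.append(float(np.sum(frame.I[lo_idx:hi_idx] - base)))
    times = np.array(times)
    excess = np.array(excess)
    series = excess - excess[0]
    flags = []
    if series[-1] != 0 and np.isfinite(series[-1]):
        series = series / series[-1]
    else:
        flags.append("degenerate-normalization")
    if times.size >= 5:
        fit = fit_kinetics(times, series, n_components=1)
        fit.flags.extend(flags)
    else:
        fit = None
        flags.append("too-few-frames-for-kinetic-fit")
    return CrystalFractionSeries(times, series, None, "c_Diff", fit, flags)


def lowq_kinetics(frames, q0: float = 0.096,
                  q_tol: float = 0.01) -> CrystalFractionSeries:
    """Kinetics of the lowest-q diffraction intensity, I(q0, t)/I(q0, 0).

    Fitted with a single sigmoid plus a constant background; independent
    of any Bragg peak in the observed range.
    """
    frames = sorted(frames, key=lambda f: f.time_h)
    idx = int(np.argmin(np.abs(frames[0].q - q0)))
    if abs(frames[0].q[idx] - q0) > q_tol:
        raise ValueError(f"q0={q0} not on the grid within tolerance {q_tol}")
    times = np.array([f.time_h for f in frames])
    I = np.array([f.I[idx] for f in frames])
    if I[0] <= 0:
        raise ValueError("initial intensity at q0 must be positive")
    ratio = I / I[0]
    fit = fit_kinetics(times, ratio, n_components=1, with_background=True)
    return CrystalFractionSeries(times, ratio, None, "lowq", fit, list(fit.flags))


# -- external interfaces ------------------------------------------------------


def write_diffraction_frames(path, frames) -> None:
    """CSV dialect: time_h, q_A_inv, intensity, error."""
    rows = []
    for f in frames:
        err = f.sigma if f.sigma is not None else np.full_like(f.q, np.nan)
        for qi, Ii, ei in zip(f.q, f.I, err):
            rows.append((f.time_h, qi, Ii, ei))
    pd.DataFrame(rows, columns=["time_h", "q_A_inv", "intensity", "error"]
                 ).to_csv(path, index=False)


def read_diffraction_frames(path):
    df = pd.read_csv(path)
    frames = []
    for t, grp in df.groupby("time_h", sort=True):
        grp = grp.sort_values("q_A_inv")
        err = grp["error"].to_numpy(float)
        frames.append(DiffractionFrame(
            float(t), grp["q_A_inv"].to_numpy(float),
            grp["intensity"].to_numpy(float),
            None if np.all(np.isnan(err)) else err))
    return frames
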