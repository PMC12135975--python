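"""Optical-microscopy crystal growth: per-crystal sigmoid fits of
2D-projected areas, population summaries, and the area-to-volume
correction.

Each tracked crystal contributes a time series A(t) of its projected area
(µm²), fitted individually with a single sigmoid to obtain the maximum
area A0, the time of fastest growth t0 and the characteristic time dt.
The population is summarized by histograms and error-weighted means of
these parameters.  Assuming cubic crystallites, V = A^{3/2} converts the
projected-face area to a volume; refitting V(t) gives the
surface-to-volume-corrected kinetic parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_models import fit_kinetics

__all__ = [
    "CrystalTrace",
    "PopulationSummary",
    "fit_area_traces",
    "area_to_volume",
    "segment_synthetic_frames",
    "read_traces",
    "write_traces",
]


@dataclass
class CrystalTrace:
    """Projected area of one crystal versus time."""

    crystal_id: int
    time_h: np.ndarray
    area: np.ndarray  # µm², 2D projection
    sigma: np.ndarray | None = None
    censored: bool = False  # crystal left the field of view

    def __post_init__(self):
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.area = np.asarray(self.area, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(np.diff(self.time_h) <= 0):
            raise ValueError("times must be ascending")


def _weighted_mean(x, sigma):
    w = 1.0 / np.asarray(sigma, dtype=float) ** 2
    m = float(np.sum(w * x) / np.sum(w))
    return m, float(1.0 / np.sqrt(np.sum(w)))


@dataclass
class PopulationSummary:
    """Per-crystal sigmoid parameters and their population statistics."""

    crystal_ids: list
    A0: np.ndarray
    t0: np.ndarray
    dt: np.ndarray
    A0_err: np.ndarray
    t0_err: np.ndarray
    dt_err: np.ndarray
    n_failed: int = 0
    histograms: dict = field(default_factory=dict)

    @property
    def weighted_means(self) -> dict:
        out = {}
        for name in ("A0", "t0", "dt"):
            m, e = _weighted_mean(getattr(self, name), getattr(self, name + "_err"))
            out[name] = m
            out[name + "_err"] = e
        return out


def fit_area_traces(traces, min_points: int = 5) -> PopulationSummary:
    """Fit A(t) of every crystal with a single sigmoid and summarize.

    Traces with fewer than ``min_points`` points or failing to converge
    are excluded and counted in ``n_failed``.  Histograms use
    Freedman-Diaconis binning; the recorded bin edges make them
    reproducible.
    """
    ids, a0, t0, dt = [], [], [], []
    a0e, t0e, dte = [], [], []
    n_failed = 0
    for tr in traces:
        if tr.time_h.size < min_points:
            n_failed += 1
            continue
        try:
            fit = fit_kinetics(tr.time_h, tr.area, tr.sigma, n_components=1)
        except (ValueError, RuntimeError):
            n_failed += 1
            continue
        if not fit.converged or "degenerate-data" in fit.flags:
            n_failed += 1
            continue
        ids.append(tr.crystal_id)
        a0.append(fit["f0_1"])
        t0.append(fit["t0_1"])
        dt.append(fit["dt_1"])
        a0e.append(max(fit.error("f0_1"), 1e-12))
        t0e.append(max(fit.error("t0_1"), 1e-12))
        dte.append(max(fit.error("dt_1"), 1e-12))
    if not ids:
        raise ValueError("every trace failed to fit")
    summary = PopulationSummary(ids, np.array(a0), np.array(t0), np.array(dt),
                                np.array(a0e), np.array(t0e), np.array(dte),
                                n_failed)
    for name in ("A0", "t0", "dt"):
        counts, edges = np.histogram(getattr(summary, name), bins="fd")
        summary.histograms[name] = {"edges": edges, "counts": counts}
    return summary


def area_to_volume(trace: CrystalTrace) -> CrystalTrace:
    """Cubic-crystallite conversion V = A^{3/2} (µm³).

    The projected face of a cube of side L has area A = L², so its volume
    is L³ = A^{3/2}.  Errors propagate as dV = 1.5 sqrt(A) dA.
    """
    if np.any(trace.area < 0):
        raise ValueError("areas must be non-negative")
    vol = trace.area ** 1.5
    if trace.sigma is not None:
        # linear propagation, floored by the direct noise scale sigma^{3/2}
        # so points at zero area keep a positive uncertainty
        sig = np.maximum(1.5 * np.sqrt(trace.area) * trace.sigma,
                         trace.sigma ** 1.5)
    else:
        sig = None
    return CrystalTrace(trace.crystal_id, trace.time_h.copy(), vol, sig,
                        trace.censored)


def segment_synthetic_frames(stack, threshold: float,
                             pixel_area_um2: float = 1.0,
                             times_h=None,
                             max_match_dist_px: float = 10.0):
    """Threshold-and-label segmentation of synthetic image stacks.

    ``stack`` is (n_frames, ny, nx).  Per frame, pixels above ``threshold``
    are labelled into connected components (scikit-image); crystals are
    tracked across frames by nearest-centroid matching within
    ``max_match_dist_px``.  Returns a list of :class:`CrystalTrace`; a
    trace whose component merged with another is flagged as censored.
    """
    from scipy import ndimage

    stack = np.asarray(stack)
    n = stack.shape[0]
    times = (np.asarray(times_h, dtype=float) if times_h is not None
             else np.arange(n, dtype=float))
    tracks: list[dict] = []  # {centroid, times, areas, censored}
    for fi in range(n):
        labels, n_lab = ndimage.label(stack[fi] > threshold)
        if n_lab == 0:
            continue
        idx = np.arange(1, n_lab + 1)
        areas = ndimage.sum_labels(np.ones_like(labels), labels, idx)
        cents = ndimage.center_of_mass(stack[fi], labels, idx)
        used = set()
        for area_px, cent in zip(areas, cents):
            cent = np.asarray(cent)
            best, best_d = None, max_match_dist_px
            for k, tr in enumerate(tracks):
                d = float(np.hypot(*(cent - tr["centroid"])))
                if d < best_d:
                    best, best_d = k, d
            if best is not None and best in used:
                tracks[best]["censored"] = True  # two components merged
                best = None
            if best is None:
                tracks.append({"centroid": cent, "times": [], "areas": [],
                               "censored": False})
                best = len(tracks) - 1
            used.add(best)
            tracks[best]["centroid"] = cent
            tracks[best]["times"].append(times[fi])
            tracks[best]["areas"].append(float(area_px) * pixel_area_um2)
    return [CrystalTrace(i, np.array(tr["times"]), np.array(tr["areas"]),
                         None, tr["censored"])
            for i, tr in enumerate(tracks)]


# -- external interfaces ------------------------------------------------------


def write_traces(path, traces) -> None:
    """CSV dialect: crystal_id, time_h, area_um2, error."""
    rows = []
    for tr in traces:
        err = tr.sigma if tr.sigma is not None else np.full_like(tr.time_h, np.nan)
        for t, a, e in zip(tr.time_h, tr.area, err):
            rows.append((tr.crystal_id, t, a, e))
    pd.DataFrame(rows, columns=["crystal_id", "time_h", "area_um2", "error"]
                 ).to_csv(path, index=False)


def read_traces(path):
    df = pd.read_csv(path)
    out = []
    for cid, grp in df.groupby("crystal_id", sort=True):
        grp = grp.sort_values("time_h")
        err = grp["error"].to_numpy(float)
        out.append(CrystalTrace(int(cid), grp["time_h"].to_numpy(float),
                                grp["area_um2"].to_numpy(float),
                                None if np.all(np.isnan(err)) else err))
    return out
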