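"""CASA motility metrics computed from head trajectories.

Given the time-stamped head positions of one tracked spermatozoon (in um),
this module computes the standard computer-aided sperm analysis (CASA)
kinematic parameters:

========  =====  ==========================================================
metric    units  meaning
========  =====  ==========================================================
VCL       um/s   curvilinear velocity along the raw sampled path
VSL       um/s   straight-line velocity, first to last head position
VAP       um/s   velocity along a smoothed "average path"
ALH       um     amplitude of lateral head displacement about the average
                 path (max or mean of the perpendicular deviation)
LIN       --     linearity, VSL/VCL
WOB       --     wobble, VAP/VCL
STR       --     straightness, VSL/VAP
BCF       Hz     beat-cross frequency: rate at which the raw path crosses
                 the average path
MAD       deg    mean absolute turning angle between successive steps
========  =====  ==========================================================

The average path is a centered moving average whose window shrinks
symmetrically toward the trajectory ends, so the smoothed path shares the
raw endpoints.  Smoothing is the one genuinely under-determined choice in
CASA (commercial systems use proprietary algorithms and are not mutually
comparable), so the window is configuration-exposed and recorded in the
analysis output.

Ratio metrics are reported as NaN when their denominator is zero.
Trajectory points that were only predicted by the tracker (never matched to
a detection) are excluded by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .core import CalibrationProfile

__all__ = [
    "Trajectory",
    "SmoothingSpec",
    "average_path",
    "vcl",
    "vsl",
    "vsl_windowed",
    "vap",
    "alh",
    "lin",
    "wob",
    "straightness",
    "bcf",
    "mad",
    "analyze",
]


@dataclass
class Trajectory:
    """Time-stamped head positions (um) of one track."""

    track_id: int
    times: np.ndarray  # (N,) seconds, strictly increasing
    positions: np.ndarray  # (N, 2) micrometres
    observed: np.ndarray | None = None  # (N,) bool; None means all observed
    fps: float = 10.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (self.times.size, 2):
            raise ValueError("positions must be (N, 2) matching times")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.observed is None:
            self.observed = np.ones(self.times.size, dtype=bool)
        else:
            self.observed = np.asarray(self.observed, dtype=bool)
            if self.observed.shape != self.times.shape:
                raise ValueError("observed flags must match times")

    def samples(self, include_unobserved: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """Return (times, positions), restricted to observed samples by default."""
        if include_unobserved:
            return self.times, self.positions
        m = self.observed
        return self.times[m], self.positions[m]


@dataclass(frozen=True)
class SmoothingSpec:
    """Average-path smoother: centered moving average over ``window`` samples.

    ``window=None`` derives the default from the frame rate as
    ``round(fps / 2)`` forced odd (about half a second of samples), with a
    floor of 3.
    """

    method: str = "moving_average"
    window: int | None = None

    def __post_init__(self) -> None:
        if self.method != "moving_average":
            raise ValueError(f"unknown smoothing method {self.method!r}")
        if self.window is not None:
            if self.window < 3 or self.window % 2 == 0:
                raise ValueError("window must be odd and >= 3")

    def resolve_window(self, fps: float) -> int:
        if self.window is not None:
            return self.window
        w = int(round(fps / 2.0))
        if w % 2 == 0:
            w += 1
        return max(w, 3)


def average_path(points: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with symmetrically shrinking end windows.

    The half-width at index i is ``min((window-1)//2, i, N-1-i)``, so the
    first and last smoothed points equal the raw endpoints exactly.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    half = (window - 1) // 2
    out = np.empty_like(pts)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = pts[i - h : i + h + 1].mean(axis=0)
    return out


def _path(traj: Trajectory, include_unobserved: bool) -> tuple[np.ndarray, np.ndarray]:
    t, p = traj.samples(include_unobserved)
    if t.size < 2:
        raise ValueError("velocity metrics need at least 2 observed samples")
    return t, p


def vcl(traj: Trajectory, include_unobserved: bool = False) -> float:
    """Curvilinear velocity: total sampled path length / elapsed time (um/s)."""
    t, p = _path(traj, include_unobserved)
    seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
    return float(seg.sum() / (t[-1] - t[0]))


def vsl(traj: Trajectory, include_unobserved: bool = False) -> float:
    """Straight-line velocity: |last - first| / elapsed time (um/s)."""
    t, p = _path(traj, include_unobserved)
    return float(np.linalg.norm(p[-1] - p[0]) / (t[-1] - t[0]))


def vsl_windowed(
    traj: Trajectory, window: float = 1.0, include_unobserved: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Windowed straight-line speed: |p(t + window) - p(t)| / window.

    Returns (times, speeds) for every sample whose window endpoint exists
    (within half a frame period) and is observed; a trajectory shorter than
    the window yields empty arrays.
    """
    t, p = traj.samples(include_unobserved)
    if t.size == 0:
        return np.empty(0), np.empty(0)
    tol = 0.5 / traj.fps
    out_t, out_v = [], []
    j = 0
    for i in range(t.size):
        target = t[i] + window
        j = int(np.searchsorted(t, target - tol, side="left"))
        if j >= t.size or abs(t[j] - target) > tol:
            continue
        out_t.append(t[i])
        out_v.append(np.linalg.norm(p[j] - p[i]) / window)
    return np.asarray(out_t), np.asarray(out_v)


def vap(traj: Trajectory, spec: SmoothingSpec | None = None,
        include_unobserved: bool = False) -> float:
    """Average-path velocity: VCL of the smoothed trajectory (um/s)."""
    spec = spec or SmoothingSpec()
    t, p = _path(traj, include_unobserved)
    sm = average_path(p, spec.resolve_window(traj.fps))
    seg = np.linalg.norm(np.diff(sm, axis=0), axis=1)
    return float(seg.sum() / (t[-1] - t[0]))


def _lateral_deviation(p: np.ndarray, sm: np.ndarray) -> np.ndarray:
    """Signed perpendicular deviation of each raw point from the average
    path, using the local smoothed-path tangent as the reference direction."""
    tangent = np.gradient(sm, axis=0)
    norm = np.linalg.norm(tangent, axis=1)
    norm[norm == 0] = 1.0
    tx, ty = tangent[:, 0] / norm, tangent[:, 1] / norm
    dev = p - sm
    return tx * dev[:, 1] - ty * dev[:, 0]


def alh(traj: Trajectory, spec: SmoothingSpec | None = None, mode: str = "max",
        include_unobserved: bool = False) -> float:
    """Amplitude of lateral head displacement (um): deviation of the head
    from its average path, reduced by ``max`` or ``mean``."""
    if mode not in ("max", "mean"):
        raise ValueError("mode must be 'max' or 'mean'")
    spec = spec or SmoothingSpec()
    _, p = _path(traj, include_unobserved)
    sm = average_path(p, spec.resolve_window(traj.fps))
    lat = np.abs(_lateral_deviation(p, sm))
    return float(lat.max() if mode == "max" else lat.mean())


def _ratio(num: float, den: float) -> float:
    return float(num / den) if den > 0 else float("nan")


def lin(traj: Trajectory, include_unobserved: bool = False) -> float:
    """Linearity VSL/VCL."""
    return _ratio(vsl(traj, include_unobserved), vcl(traj, include_unobserved))


def wob(traj: Trajectory, spec: SmoothingSpec | None = None,
        include_unobserved: bool = False) -> float:
    """Wobble VAP/VCL."""
    return _ratio(vap(traj, spec, include_unobserved), vcl(traj, include_unobserved))


def straightness(traj: Trajectory, spec: SmoothingSpec | None = None,
                 include_unobserved: bool = False) -> float:
    """Straightness VSL/VAP (the CASA "STR" parameter)."""
    return _ratio(vsl(traj, include_unobserved), vap(traj, spec, include_unobserved))


def bcf(traj: Trajectory, spec: SmoothingSpec | None = None,
        include_unobserved: bool = False) -> float:
    """Beat-cross frequency (Hz): sign changes of the lateral deviation of
    the raw path about the average path, divided by elapsed time."""
    spec = spec or SmoothingSpec()
    t, p = _path(traj, include_unobserved)
    sm = average_path(p, spec.resolve_window(traj.fps))
    lat = _lateral_deviation(p, sm)
    # deadband: numerically-collinear paths must not register crossings
    tol = 1e-9 * max(1.0, float(np.abs(p).max()))
    lat = np.where(np.abs(lat) < tol, 0.0, lat)
    s = np.sign(lat)
    s = s[s != 0]
    crossings = int(np.sum(s[1:] != s[:-1])) if s.size > 1 else 0
    return float(crossings / (t[-1] - t[0]))


def mad(traj: Trajectory, include_unobserved: bool = False) -> float:
    """Mean angular displacement (degrees): mean absolute turning angle
    between successive displacement vectors; zero-length steps are skipped."""
    _, p = _path(traj, include_unobserved)
    v = np.diff(p, axis=0)
    lengths = np.linalg.norm(v, axis=1)
    v = v[lengths > 0]
    if len(v) < 2:
        return float("nan") if len(v) == 0 else 0.0
    a, b = v[:-1], v[1:]
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    dot = np.sum(a * b, axis=1)
    ang = np.degrees(np.abs(np.arctan2(cross, dot)))
    return float(ang.mean())


def analyze(
    trajectories: Iterable[Trajectory],
    spec: SmoothingSpec | None = None,
    alh_mode: str = "max",
    vsl_window: float = 1.0,
    include_unobserved: bool = False,
) -> pd.DataFrame:
    """Per-track kinematic report.

    Returns one row per trajectory with the nine CASA metrics plus a
    windowed-VSL summary (mean and max over valid windows).  Tracks with
    fewer than 2 observed samples are flagged ``insufficient`` and carry
    NaN metrics.  The smoothing window actually used is recorded in the
    ``smooth_window`` column so reports are self-describing.
    """
    spec = spec or SmoothingSpec()
    rows = []
    for traj in trajectories:
        t_obs, _ = traj.samples(include_unobserved)
        window = spec.resolve_window(traj.fps)
        row: dict[str, float] = {
            "id": traj.track_id,
            "n_samples": int(t_obs.size),
            "insufficient": t_obs.size < 2,
            "smooth_window": window,
        }
        if t_obs.size < 2:
            for k in ("VCL", "VSL", "VAP", "ALH", "LIN", "WOB", "STR", "BCF", "MAD",
                      "VSL1s_mean", "VSL1s_max"):
                row[k] = float("nan")
        else:
            row["VCL"] = vcl(traj, include_unobserved)
            row["VSL"] = vsl(traj, include_unobserved)
            row["VAP"] = vap(traj, spec, include_unobserved)
            row["ALH"] = alh(traj, spec, alh_mode, include_unobserved)
            row["LIN"] = _ratio(row["VSL"], row["VCL"])
            row["WOB"] = _ratio(row["VAP"], row["VCL"])
            row["STR"] = _ratio(row["VSL"], row["VAP"])
            row["BCF"] = bcf(traj, spec, include_unobserved)
            row["MAD"] = mad(traj, include_unobserved)
            _, wv = vsl_windowed(traj, vsl_window, include_unobserved)
            row["VSL1s_mean"] = float(wv.mean()) if wv.size else float("nan")
            row["VSL1s_max"] = float(wv.max()) if wv.size else float("nan")
        rows.append(row)
    columns = ["id", "n_samples", "insufficient", "smooth_window",
               "VCL", "VSL", "VAP", "ALH", "LIN", "WOB", "STR", "BCF", "MAD",
               "VSL1s_mean", "VSL1s_max"]
    return pd.DataFrame(rows, columns=columns)
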