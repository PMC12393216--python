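"""Trajectory metrics and rheotaxis classifiers for single-cell tracks.

A :class:`Track` is a uniformly sampled planar trajectory of one
surface-attached cell (μm, seconds).  All directional quantities are taken
relative to a :class:`FlowFrame`; *upstream* is the direction opposite the
flow and positive displacement rates mean upstream movement.

Two classifiers are provided:

* the three-class rule (positive / negative / random rheotaxis) applied to
  1-min displacement windows: positive if the net rate is ≥ 1 μm/min with
  a trajectory angle ≤ 60° from upstream, negative if ≥ 1 μm/min at
  ≥ 120°, random otherwise;
* the five-class flow-response rule (rheotaxis / dragged / detached /
  stationary / free) applied to 3-min windows with the documented
  precedence detached > dragged > rheotaxis > stationary > free.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    InsufficientDataError,
    InsufficientDurationError,
    InvalidSpecificationError,
    UndefinedAngleError,
)

__all__ = [
    "Track", "FlowFrame", "RheotaxisClass", "FlowResponseClass",
    "net_displacement_rate", "trajectory_angle", "classify_rheotaxis",
    "classify_flow_response", "diffusion_coefficient", "msd_fit",
    "DiffusionFit", "reversal_rate", "count_reversals",
    "population_summary", "read_tracks_csv", "write_tracks_csv",
]


class RheotaxisClass(str, enum.Enum):
    """Three-class trajectory label relative to flow."""

    POSITIVE = "positive"
    NEGATIVE = "negative"
    RANDOM = "random"


class FlowResponseClass(str, enum.Enum):
    """Five-class flow-response label for vertical cells."""

    RHEOTAXIS = "rheotaxis"
    DRAGGED = "dragged"
    DETACHED = "detached"
    STATIONARY = "stationary"
    FREE = "free"


@dataclass(frozen=True)
class FlowFrame:
    """Flow direction in the x–y plane; upstream is its negation."""

    flow_direction: tuple

    def __post_init__(self) -> None:
        d = np.asarray(self.flow_direction, dtype=float)
        if d.shape != (2,):
            raise InvalidSpecificationError("flow_direction must be a 2-vector")
        norm = float(np.hypot(*d))
        if norm == 0.0:
            raise InvalidSpecificationError("flow_direction must be non-zero")
        object.__setattr__(self, "flow_direction", tuple(d / norm))

    @property
    def upstream(self) -> np.ndarray:
        return -np.asarray(self.flow_direction)

    @classmethod
    def from_name(cls, name: str) -> "FlowFrame":
        """Build from a compass-style name: '+x', '-x', '+y' or '-y'."""
        table = {"+x": (1.0, 0.0), "-x": (-1.0, 0.0),
                 "+y": (0.0, 1.0), "-y": (0.0, -1.0)}
        try:
            return cls(table[name])
        except KeyError:
            raise InvalidSpecificationError(f"unknown flow direction {name!r}")


@dataclass(frozen=True)
class Track:
    """Time-stamped planar positions of one cell.

    ``t_s`` strictly increasing and uniformly spaced (within 1e-6 relative
    tolerance); positions in μm.  ``orientation`` is the manual vertical /
    horizontal / unknown annotation carried through from the experiment —
    it is an input label, never computed here.
    """

    cell_id: str
    t_s: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    orientation: str = "unknown"

    def __post_init__(self) -> None:
        t = np.asarray(self.t_s, dtype=float)
        x = np.asarray(self.x_um, dtype=float)
        y = np.asarray(self.y_um, dtype=float)
        if not (t.shape == x.shape == y.shape) or t.ndim != 1:
            raise InvalidSpecificationError("t, x, y must be equal-length 1-D")
        if t.size < 2:
            raise InvalidSpecificationError("a track needs ≥ 2 samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise InvalidSpecificationError("time must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise InvalidSpecificationError("sampling must be uniform")
        if self.orientation not in ("vertical", "horizontal", "unknown"):
            raise InvalidSpecificationError(
                f"orientation must be vertical/horizontal/unknown, "
                f"got {self.orientation!r}")
        object.__setattr__(self, "t_s", t)
        object.__setattr__(self, "x_um", x)
        object.__setattr__(self, "y_um", y)

    @property
    def dt(self) -> float:
        return float(self.t_s[1] - self.t_s[0])

    @property
    def duration_s(self) -> float:
        return float(self.t_s[-1] - self.t_s[0])

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) position array, μm."""
        return np.column_stack([self.x_um, self.y_um])


def _require_duration(track: Track, min_s: float) -> None:
    if track.duration_s < min_s - 1e-9:
        raise InsufficientDurationError(
            f"track {track.cell_id}: duration {track.duration_s:.1f} s "
            f"< required {min_s:.0f} s")


def _net_vector(track: Track) -> np.ndarray:
    return track.xy[-1] - track.xy[0]


def net_displacement_rate(track: Track, frame: FlowFrame,
                          min_duration_s: float = 60.0) -> float:
    """Signed net displacement rate along the upstream axis, μm/min.

    Endpoint displacement (not path length) projected on upstream, divided
    by the track duration; positive values mean upstream movement.
    """
    _require_duration(track, min_duration_s)
    along = float(_net_vector(track) @ frame.upstream)
    return along / track.duration_s * 60.0


def trajectory_angle(track: Track, frame: FlowFrame) -> float:
    """Angle (degrees, [0, 180]) between net displacement and upstream."""
    d = _net_vector(track)
    norm = float(np.hypot(*d))
    if norm == 0.0:
        raise UndefinedAngleError("zero net displacement has no direction")
    cosang = float(d @ frame.upstream) / norm
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def classify_rheotaxis(track: Track, frame: FlowFrame,
                       min_rate_um_min: float = 1.0,
                       positive_max_angle_deg: float = 60.0,
                       negative_min_angle_deg: float = 120.0,
                       min_duration_s: float = 60.0) -> RheotaxisClass:
    """Three-class rheotaxis label from net displacement rate and angle."""
    _require_duration(track, min_duration_s)
    d = _net_vector(track)
    speed = float(np.hypot(*d)) / track.duration_s * 60.0
    if speed < min_rate_um_min:
        return RheotaxisClass.RANDOM
    angle = trajectory_angle(track, frame)
    if angle <= positive_max_angle_deg:
        return RheotaxisClass.POSITIVE
    if angle >= negative_min_angle_deg:
        return RheotaxisClass.NEGATIVE
    return RheotaxisClass.RANDOM


def classify_flow_response(track: Track, frame: FlowFrame,
                           min_duration_s: float = 180.0) -> FlowResponseClass:
    """Five-class flow-response label, evaluated in fixed precedence.

    Rules on the net displacement over the (≥ 3 min) window, rates in
    μm/min along the upstream axis (negative = downstream):

    1. detached  — downstream rate ≥ 13 at trajectory angle ≥ 120°;
    2. dragged   — downstream rate ≥ 1 at angle ≥ 120°, qualified by
       attachment persistence: over the window the downstream displacement
       is ≥ 3 μm per 3 min with perpendicular excursion ≤ 10 μm per 3 min
       (a cell violating this is not considered surface-associated and
       falls through to *free*);
    3. rheotaxis — upstream rate ≥ 1 at angle ≤ 60°;
    4. stationary — |along-flow rate| ≤ 1 and |perpendicular rate| ≤ 5;
    5. free      — anything else.
    """
    _require_duration(track, min_duration_s)
    d = _net_vector(track)
    minutes = track.duration_s / 60.0
    along_up = float(d @ frame.upstream) / minutes         # μm/min, + = upstream
    perp_axis = np.array([-frame.upstream[1], frame.upstream[0]])
    perp = float(d @ perp_axis) / minutes
    speed = float(np.hypot(*d)) / minutes

    angle: Optional[float]
    try:
        angle = trajectory_angle(track, frame)
    except UndefinedAngleError:
        angle = None

    downstream = -along_up
    if angle is not None and speed >= 1.0 and angle >= 120.0:
        if downstream >= 13.0:
            return FlowResponseClass.DETACHED
        # attachment-persistence qualifier on "dragged" (per-3-min amounts)
        if downstream * 3.0 >= 3.0 and abs(perp) * 3.0 <= 10.0:
            return FlowResponseClass.DRAGGED
    if angle is not None and speed >= 1.0 and angle <= 60.0 and along_up >= 1.0:
        return FlowResponseClass.RHEOTAXIS
    if abs(along_up) <= 1.0 and abs(perp) <= 5.0:
        return FlowResponseClass.STATIONARY
    return FlowResponseClass.FREE


# ---------------------------------------------------------------------------
# Mean-squared-displacement diffusion estimation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiffusionFit:
    """Result of the pooled time-averaged MSD fit MSD(τ) = 4Dτ."""

    D_um2_s: float
    lags_s: np.ndarray
    msd_um2: np.ndarray
    n_pairs: np.ndarray
    #: True when a quadratic (drift) term dominates the MSD at the longest
    #: fitted lag — the linear Brownian model is then unreliable.
    drift_dominated: bool


def msd_fit(tracks: Sequence[Track], max_lag_fraction: float = 0.25,
            min_tracks: int = 5, min_samples: int = 20,
            remove_drift: bool = False) -> DiffusionFit:
    """Pooled time-averaged MSD over tracks and weighted through-origin fit.

    Lags are multiples of the frame interval up to ``max_lag_fraction`` of
    the shortest track duration; each lag's MSD is the average over every
    (start, start+τ) pair in every track, weighted in the fit by its pair
    count.  With ``remove_drift`` each track's best-fit constant velocity
    is subtracted first, so purely ballistic tracks give D ≈ 0.

    A quadratic term is also fitted as a diagnostic: when its contribution
    at the longest lag exceeds the linear one, ``drift_dominated`` is set.
    """
    tracks = list(tracks)
    if len(tracks) < min_tracks:
        raise InsufficientDataError(f"need ≥ {min_tracks} tracks")
    for tr in tracks:
        if tr.t_s.size < min_samples:
            raise InsufficientDataError(
                f"track {tr.cell_id}: need ≥ {min_samples} samples")
    dt = tracks[0].dt
    if not all(np.isclose(tr.dt, dt, rtol=1e-6) for tr in tracks):
        raise InvalidSpecificationError("all tracks must share a frame interval")

    shortest = min(tr.duration_s for tr in tracks)
    max_lag = max(1, int(np.floor(max_lag_fraction * shortest / dt)))
    lags = np.arange(1, max_lag + 1)

    sums = np.zeros(max_lag)
    counts = np.zeros(max_lag, dtype=int)
    for tr in tracks:
        xy = tr.xy
        if remove_drift:
            v = (xy[-1] - xy[0]) / tr.duration_s
            xy = xy - np.outer(tr.t_s - tr.t_s[0], v)
        for i, lag in enumerate(lags):
            if lag >= xy.shape[0]:
                continue
            disp = xy[lag:] - xy[:-lag]
            sums[i] += float(np.sum(disp[:, 0] ** 2 + disp[:, 1] ** 2))
            counts[i] += disp.shape[0]
    valid = counts > 0
    tau = lags[valid] * dt
    msd = sums[valid] / counts[valid]
    w = counts[valid].astype(float)

    # weighted through-origin linear fit: MSD = 4 D τ
    D = float(np.sum(w * tau * msd) / (4.0 * np.sum(w * tau ** 2)))
    D = max(D, 0.0)

    # drift diagnostic: weighted fit MSD = a τ + b τ²
    drift_dominated = False
    if tau.size >= 2:
        A = np.column_stack([tau, tau ** 2]) * np.sqrt(w)[:, None]
        coef, *_ = np.linalg.lstsq(A, msd * np.sqrt(w), rcond=None)
        a, b = coef
        tmax = tau[-1]
        if b * tmax ** 2 > max(a, 0.0) * tmax:
            drift_dominated = True

    return DiffusionFit(D_um2_s=D, lags_s=tau, msd_um2=msd, n_pairs=counts[valid],
                        drift_dominated=drift_dominated)


def diffusion_coefficient(tracks: Sequence[Track], **kwargs) -> float:
    """Apparent diffusion coefficient D (μm²/s) from the pooled MSD fit."""
    return msd_fit(tracks, **kwargs).D_um2_s


# ---------------------------------------------------------------------------
# Direction reversals
# ---------------------------------------------------------------------------

def _persistent_direction_runs(sign: np.ndarray, min_run: int) -> list:
    """Signs of runs with length ≥ min_run, in order (zeros dropped)."""
    runs = []
    i = 0
    n = sign.size
    while i < n:
        s = sign[i]
        j = i
        while j < n and sign[j] == s:
            j += 1
        if s != 0 and (j - i) >= min_run:
            if not runs or runs[-1] != s:
                runs.append(s)
        i = j
    return runs


def count_reversals(track: Track, frame: FlowFrame,
                    smooth_window_s: float = 30.0,
                    persistence_s: float = 30.0) -> int:
    """Number of persistent direction reversals along the upstream axis.

    The frame-to-frame velocity projected on upstream is smoothed with a
    moving average of ``smooth_window_s``; a reversal is a sign change of
    the smoothed velocity where the new direction persists for at least
    ``persistence_s``.  Brief excursions shorter than the persistence
    window are ignored.
    """
    proj = track.xy @ frame.upstream
    v = np.diff(proj) / track.dt
    win = max(1, int(round(smooth_window_s / track.dt)))
    kernel = np.ones(win) / win
    smooth = np.convolve(v, kernel, mode="valid")
    min_run = max(1, int(round(persistence_s / track.dt)))
    runs = _persistent_direction_runs(np.sign(smooth).astype(int), min_run)
    return max(0, len(runs) - 1)


def reversal_rate(track: Track, frame: FlowFrame,
                  min_duration_s: float = 600.0, **kwargs) -> float:
    """Persistent direction reversals per minute for one track."""
    _require_duration(track, min_duration_s)
    return count_reversals(track, frame, **kwargs) / (track.duration_s / 60.0)


def pooled_reversal_rate(tracks: Iterable[Track], frame: FlowFrame,
                         min_duration_s: float = 600.0, **kwargs) -> float:
    """Total reversals over total track time (per minute), pooled."""
    total_rev = 0
    total_min = 0.0
    for tr in tracks:
        _require_duration(tr, min_duration_s)
        total_rev += count_reversals(tr, frame, **kwargs)
        total_min += tr.duration_s / 60.0
    if total_min == 0.0:
        raise InsufficientDataError("no track time supplied")
    return total_rev / total_min


# ---------------------------------------------------------------------------
# Population summaries and CSV interchange
# ---------------------------------------------------------------------------

def population_summary(tracks: Sequence[Track], frame: FlowFrame,
                       min_duration_s: float = 60.0) -> pd.DataFrame:
    """Per-orientation class proportions and displacement-rate moments.

    Returns a tidy frame with one row per (orientation, class): the class
    proportion within that orientation group and the mean ± SD of the net
    upstream displacement rate of the group's members.  Proportions within
    each orientation sum to 1.
    """
    if not tracks:
        raise InsufficientDataError("need at least one track")
    rows = []
    for tr in tracks:
        rows.append({
            "cell_id": tr.cell_id,
            "orientation": tr.orientation,
            "rheotaxis_class": classify_rheotaxis(
                tr, frame, min_duration_s=min_duration_s).value,
            "net_rate_um_min": net_displacement_rate(
                tr, frame, min_duration_s=min_duration_s),
        })
    per_cell = pd.DataFrame(rows)
    out = []
    for orientation, grp in per_cell.groupby("orientation"):
        n = len(grp)
        for cls in RheotaxisClass:
            sub = grp[grp["rheotaxis_class"] == cls.value]
            out.append({
                "orientation": orientation,
                "rheotaxis_class": cls.value,
                "n": len(sub),
                "proportion": len(sub) / n,
                "mean_rate_um_min": sub["net_rate_um_min"].mean()
                if len(sub) else np.nan,
                "sd_rate_um_min": sub["net_rate_um_min"].std(ddof=1)
                if len(sub) > 1 else (0.0 if len(sub) == 1 else np.nan),
            })
    return pd.DataFrame(out)


TRACK_CSV_COLUMNS = ["cell_id", "t_s", "x_um", "y_um", "orientation"]


def write_tracks_csv(tracks: Iterable[Track], path) -> None:
    """Write tracks in the package CSV dialect (long format)."""
    frames = []
    for tr in tracks:
        frames.append(pd.DataFrame({
            "cell_id": tr.cell_id, "t_s": tr.t_s,
            "x_um": tr.x_um, "y_um": tr.y_um,
            "orientation": tr.orientation,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.17g")


def read_tracks_csv(path, column_map: Optional[dict] = None) -> list:
    """Read tracks from CSV; ``column_map`` renames foreign dialects
    (e.g. TrackMate exports) onto ``cell_id,t_s,x_um,y_um[,orientation]``."""
    df = pd.read_csv(path, float_precision="round_trip")
    if column_map:
        df = df.rename(columns=column_map)
    missing = {"cell_id", "t_s", "x_um", "y_um"} - set(df.columns)
    if missing:
        raise InvalidSpecificationError(f"track CSV missing columns {missing}")
    tracks = []
    for cid, grp in df.groupby("cell_id", sort=False):
        grp = grp.sort_values("t_s")
        orientation = "unknown"
        if "orientation" in grp.columns and len(grp):
            orientation = str(grp["orientation"].iloc[0])
        tracks.append(Track(cell_id=str(cid),
                            t_s=grp["t_s"].to_numpy(float),
                            x_um=grp["x_um"].to_numpy(float),
                            y_um=grp["y_um"].to_numpy(float),
                            orientation=orientation))
    return tracks
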