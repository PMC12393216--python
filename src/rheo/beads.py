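"""Bead-assay trace segmentation and velocity statistics.

A :class:`BeadTrace` is the distance r(t) of a pilus-bound bead to the cell
pole, sampled at 0.1 s.  Directional constant-velocity runs in r(t) are the
observable proxy of pilus retraction (bead moving toward the pole, negative
velocity) and extension (away, positive velocity).

Segmentation (the trace-level analysis is not prescribed beyond "directional
movements of more than 0.5 s", so the algorithm is the package's own):
slide a 0.5-s window along the trace and fit a line in each; windows whose
|slope| ≥ ``v_min`` and whose residual RMS ≤ ``max_rms`` mark directional
samples with the slope's sign; maximal same-sign runs of marked samples
become segments, runs shorter than the minimum duration are discarded, and
each kept segment's velocity is refit over its full extent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    InsufficientDurationError,
    InvalidSpecificationError,
    NoEventsError,
    NonUniformSamplingError,
)

__all__ = [
    "BeadTrace", "MovementSegment", "SegmentationConfig",
    "segment_directional_movements", "segment_velocities",
    "event_frequency", "read_bead_csv", "write_bead_csv",
]

BEAD_CSV_COLUMNS = ["cell_id", "pole", "t_s", "r_um"]


@dataclass(frozen=True)
class BeadTrace:
    """Bead-to-pole distance trace at uniform (default 0.1 s) sampling."""

    cell_id: str
    t_s: np.ndarray
    r_um: np.ndarray
    pole: str = "leading"

    def __post_init__(self) -> None:
        t = np.asarray(self.t_s, dtype=float)
        r = np.asarray(self.r_um, dtype=float)
        if t.shape != r.shape or t.ndim != 1 or t.size < 2:
            raise InvalidSpecificationError("t and r must be equal-length 1-D, n ≥ 2")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise InvalidSpecificationError("time must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise NonUniformSamplingError("bead trace must be uniformly sampled")
        if np.any(r < 0):
            raise InvalidSpecificationError("bead-to-pole distance must be ≥ 0")
        if self.pole not in ("leading", "lagging"):
            raise InvalidSpecificationError("pole must be 'leading' or 'lagging'")
        object.__setattr__(self, "t_s", t)
        object.__setattr__(self, "r_um", r)

    @property
    def dt(self) -> float:
        return float(self.t_s[1] - self.t_s[0])

    @property
    def duration_s(self) -> float:
        return float(self.t_s[-1] - self.t_s[0])


@dataclass(frozen=True)
class MovementSegment:
    """One directional constant-velocity movement.

    ``velocity_um_s`` is signed: negative = toward the pole (retraction),
    positive = away (extension).  ``rms_um`` is the residual RMS of the
    per-segment linear fit.
    """

    start_s: float
    end_s: float
    velocity_um_s: float
    rms_um: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class SegmentationConfig:
    window_s: float = 0.5       # sliding fit window
    v_min_um_s: float = 0.2     # minimum |velocity| to call directional
    max_rms_um: float = 0.05    # residual RMS ceiling (50 nm)
    min_duration_s: float = 0.5  # discard shorter runs


def _window_fits(r: np.ndarray, dt: float, w: int):
    """Slope and residual RMS of the LSQ line in every length-w window.

    Vectorized over windows via a strided view; windows are short (a few
    samples), traces can be long.
    """
    n = r.size - w + 1
    t0 = (np.arange(w) - (w - 1) / 2.0) * dt      # centred window times
    denom = float(np.sum(t0 ** 2))
    windows = np.lib.stride_tricks.sliding_window_view(r, w)  # (n, w)
    means = windows.mean(axis=1)
    slopes = windows @ t0 / denom
    resid = windows - means[:, None] - slopes[:, None] * t0[None, :]
    rms = np.sqrt(np.mean(resid ** 2, axis=1))
    return slopes, rms


def segment_directional_movements(
        trace: BeadTrace,
        config: Optional[SegmentationConfig] = None) -> list:
    """Detect maximal directional constant-velocity runs in a bead trace.

    Deterministic and idempotent for a fixed config; returns
    non-overlapping :class:`MovementSegment` objects in time order.
    """
    cfg = config or SegmentationConfig()
    if trace.duration_s < 1.0 - 1e-9:
        raise InsufficientDurationError("bead trace must cover ≥ 1 s")
    dt = trace.dt
    w = int(round(cfg.window_s / dt)) + 1   # samples spanning window_s
    if w < 3:
        w = 3
    r = trace.r_um
    if r.size < w:
        return []
    slopes, rms = _window_fits(r, dt, w)

    # each sample is judged by the best-fitting (lowest-RMS) window that
    # covers it: near a kink the flat-side window wins for pause samples
    # and the in-run window wins for run samples, keeping boundaries sharp
    n_win = slopes.size
    pad = np.full(w - 1, np.inf)
    rms_padded = np.concatenate([pad, rms, pad])
    cover = np.lib.stride_tricks.sliding_window_view(rms_padded, w)[:r.size]
    best = cover.argmin(axis=1)                 # offset into covering windows
    win_idx = np.clip(np.arange(r.size) - (w - 1) + best, 0, n_win - 1)
    best_slope = slopes[win_idx]
    best_rms = rms[win_idx]
    directional = (np.abs(best_slope) >= cfg.v_min_um_s) & \
                  (best_rms <= cfg.max_rms_um)
    mark = np.where(directional, np.sign(best_slope).astype(int), 0)

    segments = []
    i = 0
    n = r.size
    while i < n:
        s = mark[i]
        if s == 0:
            i += 1
            continue
        j = i
        while j < n and mark[j] == s:
            j += 1
        dur = (j - 1 - i) * dt
        if dur >= cfg.min_duration_s - 1e-9:
            t_seg = trace.t_s[i:j]
            r_seg = r[i:j]
            coef = np.polyfit(t_seg, r_seg, 1)
            resid = r_seg - np.polyval(coef, t_seg)
            segments.append(MovementSegment(
                start_s=float(t_seg[0]), end_s=float(t_seg[-1]),
                velocity_um_s=float(coef[0]),
                rms_um=float(np.sqrt(np.mean(resid ** 2)))))
        i = j
    return segments


def segment_velocities(segments: Sequence[MovementSegment]) -> dict:
    """Signed velocity summaries split by direction.

    Toward-pole (negative) and away-from-pole (positive) means ± SD over
    segments; empty directions report ``nan`` with n = 0.
    """
    v = np.array([s.velocity_um_s for s in segments], dtype=float)
    out = {}
    for name, sel in (("toward", v < 0), ("away", v > 0)):
        vals = v[sel]
        out[f"{name}_mean_um_s"] = float(vals.mean()) if vals.size else float("nan")
        out[f"{name}_sd_um_s"] = (float(vals.std(ddof=1)) if vals.size > 1
                                  else (0.0 if vals.size == 1 else float("nan")))
        out[f"{name}_n"] = int(vals.size)
    return out


def event_frequency(trace: BeadTrace,
                    config: Optional[SegmentationConfig] = None,
                    window_s: float = 10.0) -> int:
    """Directional movements starting within ``window_s`` of the first one.

    Counts segments whose start lies in [t₀, t₀ + window), where t₀ is the
    first detected segment's start.  Raises :class:`NoEventsError` when no
    directional movement exists at all — a trace with zero events has an
    undefined frequency, which is distinct from a frequency of zero.
    """
    segments = segment_directional_movements(trace, config)
    if not segments:
        raise NoEventsError(f"trace {trace.cell_id}: no directional movements")
    t0 = segments[0].start_s
    return sum(1 for s in segments if t0 <= s.start_s < t0 + window_s)


def write_bead_csv(traces: Iterable[BeadTrace], path) -> None:
    frames = []
    for tr in traces:
        frames.append(pd.DataFrame({
            "cell_id": tr.cell_id, "pole": tr.pole,
            "t_s": tr.t_s, "r_um": tr.r_um,
        }))
    pd.concat(frames, ignore_index=True)[BEAD_CSV_COLUMNS].to_csv(
        path, index=False, float_format="%.17g")


def read_bead_csv(path) -> list:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(BEAD_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidSpecificationError(f"bead CSV missing columns {missing}")
    traces = []
    for cid, grp in df.groupby("cell_id", sort=False):
        grp = grp.sort_values("t_s")
        traces.append(BeadTrace(cell_id=str(cid),
                                t_s=grp["t_s"].to_numpy(float),
                                r_um=grp["r_um"].to_numpy(float),
                                pole=str(grp["pole"].iloc[0])))
    return traces
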