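"""Seed-controlled generators for every input the pipeline consumes.

Each generator is a pure function of (spec, seed): identical arguments give
identical outputs (and identical CSV bytes after writing).  Families are
moment-matched to the measured population statistics they emulate:

* drift–diffusion surface tracks with three behavioural classes
  (upstream drift 17.1 ± 11.0 μm/min, downstream −9.3 ± 18.0 μm/min,
  no-flow diffusion D = 1.7 μm²/s) and Poisson direction reversals
  (default 1 per 100 min);
* Gaussian flapping traces of the free pole of a tethered vertical cell in
  thermal equilibrium at a given spring constant and temperature;
* bead-assay traces built from alternating pauses and constant-velocity
  runs with localization noise;
* per-cell pilus filament sets (truncated-gamma lengths, integer counts,
  upstream-concentrated or uniform angles).

Where a printed SD is large relative to its mean, plain normal families
would put appreciable mass on the wrong side of a defining threshold, so
bounded families (shifted gammas) are used with parameters solved in
closed form so the *realized* moments match the printed ones.

Class archetypes: under flow the drifting classes are near-rectilinear
(small residual wander ``D_res``), and the "random" class is a confined
wiggler at the flapping amplitude scale; the free-Brownian no-flow
condition is a separate preset (:meth:`CohortSpec.no_flow`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .beads import BeadTrace
from .chamber import BOLTZMANN_J_PER_K, DEFAULT_TEMPERATURE_K
from .errors import InvalidSpecificationError
from .pili import filament_frame
from .tracks import FlowFrame, Track

__all__ = [
    "CohortSpec", "FlappingSpec", "BeadAssaySpec", "FilamentSpec",
    "make_tracks", "make_flapping", "make_bead_traces", "make_filaments",
    "write_flapping_csv", "read_flapping_csv",
    "DEFAULT_FLOW_FRAME",
]

#: Flow arrives from the +x side and runs toward −x, so upstream is +x.
DEFAULT_FLOW_FRAME = FlowFrame((-1.0, 0.0))


def _sample_bounded(rng: np.random.Generator, mean: float, sd: float,
                    lower: float, size) -> np.ndarray:
    """Samples ≥ ``lower`` with exact moments (mean, sd): shifted gamma.

    X = lower + Gamma(shape, scale) with shape = ((mean − lower)/sd)² and
    scale = sd²/(mean − lower) has mean/SD exactly equal to the targets
    for any admissible pair — including printed SDs that exceed the mean,
    which no truncated normal can reach.  With sd = 0 the value is
    deterministic.
    """
    if sd == 0.0:
        return np.full(size, mean)
    excess = mean - lower
    if excess <= 0:
        raise InvalidSpecificationError(
            "target mean must exceed the lower bound")
    shape = (excess / sd) ** 2
    scale = sd ** 2 / excess
    return lower + rng.gamma(shape, scale, size=size)


# ---------------------------------------------------------------------------
# Drift–diffusion track cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a synthetic track cohort.

    ``weights`` are the mixture proportions of the behavioural classes
    (positive, negative, random).  Drift moments are the printed net
    displacement rates; drifting cells carry the residual wander ``D_res``
    while the random class either diffuses freely at ``D`` (no-flow
    condition, ``confinement_radius_um=None``) or wiggles inside a confined
    spot (flow condition).
    """

    n_cells: int = 200
    weights: tuple = (0.5, 0.4, 0.1)
    drift_pos_mean: float = 17.1      # μm/min, upstream
    drift_pos_sd: float = 11.0
    drift_neg_mean: float = 9.3       # μm/min, downstream (magnitude)
    drift_neg_sd: float = 18.0
    diffusion_D: float = 1.7          # μm²/s, free (no-flow) diffusion
    D_res: float = 0.02               # μm²/s, residual wander of drifting cells
    reversal_rate_per_min: float = 0.01
    confinement_radius_um: Optional[float] = 0.3
    duration_s: float = 60.0
    dt_s: float = 1.0
    #: archetypal drifting cells are unambiguous movers: the class floor
    #: sits ~2× above the endpoint-noise rms of a 1-min window at D_res,
    #: so class identity survives measurement noise
    min_drift_um_min: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        w = tuple(float(x) for x in self.weights)
        if len(w) != 3 or any(x < 0 for x in w) or abs(sum(w) - 1.0) > 1e-9:
            raise InvalidSpecificationError(
                "weights must be three non-negatives summing to 1")
        for name in ("duration_s", "dt_s"):
            if not getattr(self, name) > 0:
                raise InvalidSpecificationError(f"{name} must be positive")
        for name in ("diffusion_D", "D_res", "reversal_rate_per_min"):
            if getattr(self, name) < 0:
                raise InvalidSpecificationError(f"{name} must be non-negative")
        if self.n_cells < 1:
            raise InvalidSpecificationError("n_cells must be ≥ 1")
        object.__setattr__(self, "weights", w)

    # -- condition presets -------------------------------------------------
    @classmethod
    def flow_mixture(cls, n_cells: int = 200, seed: int = 0,
                     **overrides) -> "CohortSpec":
        """In-flow population: 50/40/10 positive/negative/random."""
        return cls(n_cells=n_cells, seed=seed, **overrides)

    @classmethod
    def no_flow(cls, n_cells: int = 50, duration_s: float = 60.0,
                seed: int = 0, **overrides) -> "CohortSpec":
        """No-flow condition: every cell diffuses freely at D."""
        return cls(n_cells=n_cells, weights=(0.0, 0.0, 1.0),
                   confinement_radius_um=None, duration_s=duration_s,
                   seed=seed, **overrides)

    @classmethod
    def reversal_cohort(cls, n_cells: int = 100, duration_s: float = 6000.0,
                        seed: int = 0, **overrides) -> "CohortSpec":
        """Persistent upstream movers for reversal-rate recovery.

        Every cell drifts at the class-mean 17.1 μm/min (drift SD 0) with
        Poisson direction reversals; 100 cells × 100 min gives the
        10⁴ track-minutes of the pooled-rate study condition.
        """
        return cls(n_cells=n_cells, weights=(1.0, 0.0, 0.0),
                   drift_pos_sd=0.0, duration_s=duration_s, seed=seed,
                   **overrides)


def _class_labels(rng: np.random.Generator, spec: CohortSpec) -> np.ndarray:
    return rng.choice(3, size=spec.n_cells, p=spec.weights)


def make_tracks(spec: CohortSpec, seed: Optional[int] = None,
                frame: FlowFrame = DEFAULT_FLOW_FRAME) -> List[Track]:
    """Generate a track cohort under the given study conditions.

    Each drifting cell moves along ±upstream at a per-cell rate drawn from
    the class's moment-matched bounded family, plus isotropic Brownian
    steps at ``D_res``; direction flips at Poisson reversal times.  The
    random class is either confined (flow condition) or freely diffusive at
    ``D`` (no-flow condition).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    up = np.asarray(frame.upstream, dtype=float)
    n_steps = int(round(spec.duration_s / spec.dt_s))
    t = np.arange(n_steps + 1) * spec.dt_s
    labels = _class_labels(rng, spec)
    orientations = {0: "vertical", 1: "horizontal", 2: "unknown"}
    class_names = {0: "positive", 1: "negative", 2: "random"}

    tracks = []
    for i, lab in enumerate(labels):
        if lab == 2 and spec.confinement_radius_um is not None:
            # confined wiggler: i.i.d. jitter at the flapping-amplitude scale
            xy = rng.normal(0.0, spec.confinement_radius_um,
                            size=(n_steps + 1, 2))
        elif lab == 2:
            steps = rng.normal(0.0, math.sqrt(2.0 * spec.diffusion_D * spec.dt_s),
                               size=(n_steps, 2))
            xy = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        else:
            if lab == 0:
                rate = _sample_bounded(rng, spec.drift_pos_mean,
                                         spec.drift_pos_sd,
                                         spec.min_drift_um_min, 1)[0]
                sign0 = 1.0
            else:
                rate = _sample_bounded(rng, spec.drift_neg_mean,
                                         spec.drift_neg_sd,
                                         spec.min_drift_um_min, 1)[0]
                sign0 = -1.0
            v = rate / 60.0                       # μm/s along upstream
            # Poisson reversal times flip the drift sign
            sign = np.full(n_steps, sign0)
            if spec.reversal_rate_per_min > 0:
                rate_s = spec.reversal_rate_per_min / 60.0
                tau = 0.0
                s = sign0
                while True:
                    tau += rng.exponential(1.0 / rate_s)
                    if tau >= spec.duration_s:
                        break
                    s = -s
                    sign[int(tau / spec.dt_s):] = s
            noise = rng.normal(0.0, math.sqrt(2.0 * spec.D_res * spec.dt_s),
                               size=(n_steps, 2))
            steps = np.outer(sign * v * spec.dt_s, up) + noise
            xy = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        tracks.append(Track(
            cell_id=f"{class_names[lab]}_{i:04d}",
            t_s=t, x_um=xy[:, 0], y_um=xy[:, 1],
            orientation=orientations[lab]))
    return tracks


# ---------------------------------------------------------------------------
# Flapping traces (equipartition)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FlappingSpec:
    """Thermal flapping of the free pole of a tethered vertical cell."""

    k_pn_per_nm: float
    temperature_k: float = DEFAULT_TEMPERATURE_K
    n_samples: int = 5000
    dt_s: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.k_pn_per_nm > 0:
            raise InvalidSpecificationError("spring constant must be positive")
        if not self.temperature_k > 0:
            raise InvalidSpecificationError("temperature must be positive")
        if self.n_samples < 2:
            raise InvalidSpecificationError("need ≥ 2 samples")

    @property
    def variance_um2(self) -> float:
        """Equipartition positional variance per axis, μm²."""
        k_si = self.k_pn_per_nm * 1e-3            # N/m
        return BOLTZMANN_J_PER_K * self.temperature_k / k_si * 1e12


def make_flapping(spec: FlappingSpec, seed: Optional[int] = None) -> np.ndarray:
    """(n, 2) free-pole positions (μm): independent Gaussian per axis with
    the equipartition variance k_B·T/k."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    sd = math.sqrt(spec.variance_um2)
    return rng.normal(0.0, sd, size=(spec.n_samples, 2))


def write_flapping_csv(trace_um: np.ndarray, path, dt_s: float = 1.0) -> None:
    n = trace_um.shape[0]
    pd.DataFrame({"t_s": np.arange(n) * dt_s,
                  "x_um": trace_um[:, 0],
                  "y_um": trace_um[:, 1]}).to_csv(path, index=False,
                                                  float_format="%.17g")


def read_flapping_csv(path) -> np.ndarray:
    df = pd.read_csv(path, float_precision="round_trip")
    return df[["x_um", "y_um"]].to_numpy(float)


# ---------------------------------------------------------------------------
# Bead-assay traces
# ---------------------------------------------------------------------------

#: Printed bead-run velocity moments per strain: (toward mean, toward SD,
#: away mean, away SD), μm/s (magnitudes; toward-pole runs are negative).
BEAD_PRESETS = {
    "wt": (3.04, 0.81, 1.01, 0.62),
    "pilt2": (1.27, 0.41, 0.65, 0.57),
}


@dataclass(frozen=True)
class BeadAssaySpec:
    """Piecewise-constant-velocity bead traces for one strain preset.

    Each trace is pause / away run / pause / toward run / … repeated
    ``runs_per_trace`` times.  Run speeds are bounded draws
    (|v| ≥ ``v_floor``) moment-matched to the printed per-direction
    statistics — the printed values are themselves computed over detected
    directional movements, which are bounded away from zero the same way.
    """

    preset: str = "wt"
    n_traces: int = 30
    runs_per_trace: int = 1           # away/toward pairs per trace
    dt_s: float = 0.1
    noise_sd_um: float = 0.02         # bead localization noise (20 nm)
    #: runs are drawn comfortably above the segmentation threshold
    #: (v_min + ~1.5 σ of window-slope noise at 20 nm localization noise)
    #: and well clear of the 0.5-s duration cutoff, so the emulated
    #: detected movements are actually detectable
    run_duration_range_s: tuple = (0.8, 1.6)
    pause_duration_range_s: tuple = (0.5, 1.5)
    v_floor_um_s: float = 0.35
    pole: str = "leading"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.preset not in BEAD_PRESETS:
            raise InvalidSpecificationError(
                f"unknown preset {self.preset!r}; available {list(BEAD_PRESETS)}")
        if self.n_traces < 1 or self.runs_per_trace < 1:
            raise InvalidSpecificationError("n_traces and runs_per_trace ≥ 1")


def make_bead_traces(spec: BeadAssaySpec,
                     seed: Optional[int] = None) -> List[BeadTrace]:
    """Generate bead-to-pole distance traces for the strain preset."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    t_mean, t_sd, a_mean, a_sd = BEAD_PRESETS[spec.preset]
    traces = []
    for i in range(spec.n_traces):
        # draw the whole run/pause program first
        pieces = []                       # (duration_s, velocity_um_s)
        for _ in range(spec.runs_per_trace):
            pieces.append((rng.uniform(*spec.pause_duration_range_s), 0.0))
            va = _sample_bounded(rng, a_mean, a_sd, spec.v_floor_um_s, 1)[0]
            pieces.append((rng.uniform(*spec.run_duration_range_s), va))
            pieces.append((rng.uniform(*spec.pause_duration_range_s), 0.0))
            vt = _sample_bounded(rng, t_mean, t_sd, spec.v_floor_um_s, 1)[0]
            pieces.append((rng.uniform(*spec.run_duration_range_s), -vt))
        pieces.append((rng.uniform(*spec.pause_duration_range_s), 0.0))

        # piecewise-linear noiseless path, then offset to keep r > 0
        durations = np.array([d for d, _ in pieces])
        velocities = np.array([v for _, v in pieces])
        n_steps = np.maximum(1, np.round(durations / spec.dt_s).astype(int))
        slopes = np.repeat(velocities, n_steps)
        r = np.concatenate([[0.0], np.cumsum(slopes * spec.dt_s)])
        r += 0.3 - min(0.0, float(r.min()))
        if spec.noise_sd_um > 0:
            r = r + rng.normal(0.0, spec.noise_sd_um, size=r.size)
        r = np.maximum(r, 0.0)
        t = np.arange(r.size) * spec.dt_s
        traces.append(BeadTrace(cell_id=f"{spec.preset}_bead_{i:03d}",
                                t_s=t, r_um=r, pole=spec.pole))
    return traces


# ---------------------------------------------------------------------------
# Filament sets
# ---------------------------------------------------------------------------

#: Printed filament statistics per strain: (length mean, length SD,
#: count mean, count SD) and whether angles concentrate upstream.
FILAMENT_PRESETS = {
    "wt": {"length": (2.8, 3.0), "count": (7.6, 2.8), "upstream": True},
    "pilt2": {"length": (4.5, 4.4), "count": (13.4, 5.4), "upstream": False},
}

#: Angular SD (degrees) of the upstream-concentrated wrapped normal,
#: chosen so the expected against/toward orientation ratio is 3
#: (P(|θ| ≤ 90°) = 0.75 ⇒ σ = 90 / Φ⁻¹(0.875)).
UPSTREAM_ANGLE_SD_DEG = 90.0 / float(stats.norm.ppf(0.875))


@dataclass(frozen=True)
class FilamentSpec:
    """Per-cell filament sets for one strain preset."""

    preset: str = "wt"
    n_cells: int = 11
    angle_sd_deg: float = UPSTREAM_ANGLE_SD_DEG
    seed: int = 0

    def __post_init__(self) -> None:
        if self.preset not in FILAMENT_PRESETS:
            raise InvalidSpecificationError(
                f"unknown preset {self.preset!r}; available {list(FILAMENT_PRESETS)}")
        if self.n_cells < 1:
            raise InvalidSpecificationError("n_cells must be ≥ 1")


def make_filaments(spec: FilamentSpec, seed: Optional[int] = None) -> pd.DataFrame:
    """Generate a filament table (``cell_id,strain,theta_deg,length_um``).

    Visible counts per cell are rounded bounded draws (≥ 1); lengths
    are gamma with the printed mean/SD (the printed SD exceeds the mean, so
    a positive-support family is required); angles are wrapped normal about
    the upstream direction for the WT preset and uniform for ΔpilT2.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    cfg = FILAMENT_PRESETS[spec.preset]
    l_mean, l_sd = cfg["length"]
    c_mean, c_sd = cfg["count"]
    shape = (l_mean / l_sd) ** 2
    scale = l_sd ** 2 / l_mean

    counts = np.maximum(1, np.round(
        _sample_bounded(rng, c_mean, c_sd, 1.0, spec.n_cells))).astype(int)
    records = []
    for i, n_fil in enumerate(counts):
        lengths = rng.gamma(shape, scale, size=n_fil)
        lengths = np.maximum(lengths, 1e-3)
        if cfg["upstream"]:
            theta = np.mod(rng.normal(0.0, spec.angle_sd_deg, size=n_fil), 360.0)
        else:
            theta = rng.uniform(0.0, 360.0, size=n_fil)
        for th, ln in zip(theta, lengths):
            records.append({"cell_id": f"{spec.preset}_cell_{i:03d}",
                            "strain": spec.preset,
                            "theta_deg": float(th),
                            "length_um": float(ln)})
    return filament_frame(records)
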