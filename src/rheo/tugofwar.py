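"""Tug-of-war simulator for a pole-attached vertical cell.

The cell body is a rigid prolate spheroid pivoting about its attached pole,
which stays fixed on the plane.  Type IV pili emanate from a point near the
attached pole, anchor to the plane, and act as linear springs whose
equilibrium length is moved by the motor: extension grows it, retraction
shrinks it.  A pilus under tension above the retraction force limit
``F_rmax`` detaches; a fully retracted pilus disappears; new pili nucleate
(replenishing the attached complement), attach with a fixed probability at
a random planar direction, and switch between extension and retraction
after exponential dwells.  The net spring torque about the pivot, plus a
righting torque from the polar adhesion web (proportional to the attached
filament count), drives the tilt angle by overdamped dynamics.

The retraction dwell is what separates the strains mechanically: over one
dwell a retracting filament builds tension ≈ κ_p·v_ret·τ, which exceeds
the force limit for the fast wild-type motor (detachment cascades and
occasional large tilts) but not for the slow ΔpilT2 motor (filaments stay
attached, the web stays balanced, and the cell barely moves).

Geometry: the cell axis is confined to the x–z vertical plane, so the tilt
is one-dimensional; anchors live on the full plane (x, y) and only their
in-plane pull tilts the cell.  The internal tilt coordinate is the angle
``alpha`` of the axis from the +x surface direction (α = 90° vertical,
α ∈ [0°, 180°]); the reported angle between cell body and surface is the
fold θ_c = min(α, 180° − α) ∈ [0°, 90°].

Units: μm, s, pN, angles internal in radians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import circstd

from .errors import InvalidSpecificationError

__all__ = [
    "SimParams", "PilusState", "CellState", "step", "simulate_cell",
    "ensemble_angle_distribution", "EnsembleResult", "monotonicity_sweep",
    "load_preset", "preset_names",
]

EXTENDING = "extending"
RETRACTING = "retracting"


@dataclass(frozen=True)
class SimParams:
    """Mechanical and kinetic parameters of the tug-of-war model.

    Strain-specific fields (filament number, speeds, lengths) default to
    the wild-type measured values; the preset files carry both strains.
    ``nucleation_rate`` may be left ``None``, in which case a feedback
    scheme replenishes lost filaments so the mean attached count stays at
    ``n_pili_mean``.
    """

    n_pili_mean: float = 7.6          # mean attached filaments per pole
    v_ext: float = 1.01               # equilibrium-length growth, μm/s
    v_ret: float = 3.04               # equilibrium-length shrinkage, μm/s
    pilus_length_mean_um: float = 2.8  # sets anchor-distance scale
    kappa_p: float = 50.0             # pilus spring constant, pN/μm
    F_rmax: float = 100.0             # retraction force limit, pN
    attach_prob: float = 0.5          # per-nucleation attachment probability
    nucleation_rate: Optional[float] = None   # fixed rate /s; None = feedback
    nucleation_gain: float = 2.0      # /s per missing filament (feedback mode)
    #: righting stiffness of the polar adhesion web, pN·μm/rad per attached
    #: filament: the taut filament cluster at the pole resists tilting away
    #: from vertical in proportion to its size; with no attached filaments
    #: the angle is frozen
    kappa_tilt: float = 20.0
    rot_mobility: float = 0.3         # rad/(pN·μm·s)
    tau_dwell_s: float = 1.0          # mean extension dwell before retraction
    dt: float = 0.01                  # integration step, s
    out_dt: float = 0.1               # output sampling, s
    duration: float = 100.0           # s
    cell_a: float = 1.25              # prolate semi-major axis, μm
    cell_b: float = 0.5               # prolate semi-minor axis, μm
    pilus_base_offset_um: Optional[float] = None  # emanation point offset (None: cell_b)
    max_eq_length_factor: float = 3.0  # extension cap, × pilus_length_mean
    p_start_extending: float = 0.5    # initial mode of a new filament
    max_step_rad: float = 0.1         # per-step |dα| instability guard
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        positive = ("n_pili_mean", "v_ext", "v_ret", "pilus_length_mean_um",
                    "kappa_p", "F_rmax", "kappa_tilt", "rot_mobility",
                    "tau_dwell_s", "dt", "out_dt", "duration",
                    "cell_a", "cell_b")
        for name in positive:
            if not getattr(self, name) > 0:
                raise InvalidSpecificationError(f"{name} must be positive")
        if not 0.0 < self.attach_prob <= 1.0:
            raise InvalidSpecificationError("attach_prob must be in (0, 1]")
        if self.nucleation_rate is not None and not self.nucleation_rate > 0:
            raise InvalidSpecificationError("nucleation_rate must be positive")
        if self.dt > self.out_dt + 1e-12:
            raise InvalidSpecificationError("dt must not exceed out_dt")

    @property
    def base_offset(self) -> float:
        return (self.cell_b if self.pilus_base_offset_um is None
                else self.pilus_base_offset_um)

    def nucleation_rate_now(self, n_attached: int) -> float:
        """Nucleation attempt rate (/s) given the current attached count.

        With ``nucleation_rate`` set, the rate is constant; otherwise a
        feedback scheme replenishes lost filaments so the mean attached
        count stays at ``n_pili_mean``.
        """
        if self.nucleation_rate is not None:
            return self.nucleation_rate
        deficit = max(0.0, self.n_pili_mean - n_attached)
        return self.nucleation_gain * deficit / self.attach_prob

    @classmethod
    def from_yaml(cls, path) -> "SimParams":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class PilusState:
    """One attached pilus: planar anchor, spring equilibrium length, mode."""

    anchor_x: float
    anchor_y: float
    eq_length: float
    mode: str = EXTENDING
    #: absolute time of the next scheduled mode switch
    switch_t: float = math.inf

    def geometric_length(self, base_x: float, base_z: float) -> float:
        dx = self.anchor_x - base_x
        dz = -base_z
        return math.sqrt(dx * dx + self.anchor_y * self.anchor_y + dz * dz)

    def tension(self, base_x: float, base_z: float, kappa: float) -> float:
        return kappa * max(0.0, self.geometric_length(base_x, base_z)
                           - self.eq_length)


@dataclass
class CellState:
    """Tilt angle and attached pili of one simulated cell.

    The pivot (attached pole) is fixed at the origin; ``alpha_rad`` is the
    axis angle from the +x surface direction.
    """

    alpha_rad: float = math.pi / 2
    pili: List[PilusState] = field(default_factory=list)
    t: float = 0.0

    @property
    def theta_c_deg(self) -> float:
        """Angle between the cell long axis and the surface, ∈ [0, 90]."""
        a = math.degrees(self.alpha_rad)
        return min(a, 180.0 - a)

    def base_point(self, params: SimParams) -> tuple:
        """In-plane coordinates of the pilus emanation point."""
        d = params.base_offset
        return d * math.cos(self.alpha_rad), d * math.sin(self.alpha_rad)


def _new_pilus(state: CellState, params: SimParams,
               rng: np.random.Generator) -> PilusState:
    """Freshly attached pilus: random planar direction, taut, random mode."""
    psi = rng.uniform(0.0, 2.0 * math.pi)
    rho = rng.exponential(params.pilus_length_mean_um)
    bx, bz = state.base_point(params)
    p = PilusState(anchor_x=rho * math.cos(psi), anchor_y=rho * math.sin(psi),
                   eq_length=0.0)
    p.eq_length = p.geometric_length(bx, bz)      # taut, zero tension
    if rng.random() < params.p_start_extending:
        p.mode = EXTENDING
    else:
        p.mode = RETRACTING
    p.switch_t = state.t + rng.exponential(params.tau_dwell_s)
    return p


def _nucleate(state: CellState, params: SimParams, rng: np.random.Generator) -> None:
    """Attempt one nucleation event; attaches with ``attach_prob``."""
    if rng.random() >= params.attach_prob:
        return
    state.pili.append(_new_pilus(state, params, rng))


def initial_state(params: SimParams, rng: np.random.Generator) -> CellState:
    """Vertical cell with a Poisson(n_pili_mean) complement of taut pili."""
    state = CellState()
    n0 = int(rng.poisson(params.n_pili_mean))
    for _ in range(n0):
        # initial pili are already attached: bypass the attachment coin
        state.pili.append(_new_pilus(state, params, rng))
    return state


def step(state: CellState, params: SimParams,
         rng: np.random.Generator) -> CellState:
    """Advance the mechanical state by one integration step ``dt``.

    Order per step: equilibrium-length motor update → tension → force-limit
    detachment → overdamped tilt update (with a final force-limit re-check
    at the new angle, so no output state ever carries tension > F_rmax) →
    nucleation → scheduled mode switching.  Mutates and returns ``state``.
    """
    dt = params.dt
    kappa = params.kappa_p
    max_eq = params.max_eq_length_factor * params.pilus_length_mean_um
    bx, bz = state.base_point(params)

    # (1) motor moves each spring's equilibrium length
    survivors = []
    for p in state.pili:
        if p.mode == EXTENDING:
            p.eq_length += params.v_ext * dt
            if p.eq_length > max_eq:
                p.eq_length = max_eq            # growth saturates
        else:
            p.eq_length -= params.v_ret * dt
            if p.eq_length <= 0.0:
                continue                       # fully retracted: filament gone
        survivors.append(p)

    # (2)+(3) tension and force-limited detachment
    state.pili = [p for p in survivors
                  if p.tension(bx, bz, kappa) <= params.F_rmax]

    # (4) net torque about the pivot → overdamped tilt; the polar adhesion
    # web contributes a righting torque toward vertical per attached pilus
    torque = (params.kappa_tilt * len(state.pili)
              * (math.pi / 2.0 - state.alpha_rad))
    for p in state.pili:
        L = p.geometric_length(bx, bz)
        T = kappa * max(0.0, L - p.eq_length)
        if T == 0.0 or L == 0.0:
            continue
        fx = T * (p.anchor_x - bx) / L
        fz = T * (-bz) / L
        torque += bx * fz - bz * fx            # rotates α upward when > 0
    d_alpha = params.rot_mobility * torque * dt
    if d_alpha > params.max_step_rad:
        d_alpha = params.max_step_rad
    elif d_alpha < -params.max_step_rad:
        d_alpha = -params.max_step_rad
    state.alpha_rad = min(max(state.alpha_rad + d_alpha, 0.0), math.pi)
    state.t += dt

    # force-limit re-check at the new angle
    if state.pili:
        bx, bz = state.base_point(params)
        state.pili = [p for p in state.pili
                      if p.tension(bx, bz, kappa) <= params.F_rmax]

    # (5) nucleation replaces lost filaments
    rate = params.nucleation_rate_now(len(state.pili))
    if rate > 0.0:
        for _ in range(rng.poisson(rate * dt)):
            _nucleate(state, params, rng)

    # (6) scheduled mode switches (exponential dwells, both directions)
    for p in state.pili:
        if state.t >= p.switch_t:
            p.mode = RETRACTING if p.mode == EXTENDING else EXTENDING
            p.switch_t = state.t + rng.exponential(params.tau_dwell_s)
    return state


def simulate_cell(params: SimParams, seed: Optional[int] = None) -> np.ndarray:
    """Simulate one cell; return θ_c (degrees) sampled every ``out_dt``.

    Deterministic for fixed (params, seed); the series has exactly
    ``round(duration / out_dt)`` samples.
    """
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    state = initial_state(params, rng)
    n_out = int(round(params.duration / params.out_dt))
    if n_out < 1:
        raise InvalidSpecificationError("duration must cover ≥ one out_dt")
    stride = int(round(params.out_dt / params.dt))
    out = np.empty(n_out)
    for i in range(n_out):
        for _ in range(stride):
            step(state, params, rng)
        out[i] = state.theta_c_deg
    return out


@dataclass(frozen=True)
class EnsembleResult:
    """Pooled angle samples of an ensemble run with summary statistics."""

    samples_deg: np.ndarray
    hist_counts: np.ndarray
    bin_edges_deg: np.ndarray
    mean_deg: float
    sd_deg: float               # circular SD of θ_c, degrees
    per_cell_sd_deg: np.ndarray
    n_cells: int

    @property
    def n_samples(self) -> int:
        return int(self.samples_deg.size)


def _child_seeds(seed: int, n: int) -> np.ndarray:
    ss = np.random.SeedSequence(seed)
    return np.array([int(s.generate_state(1)[0] % (2 ** 31))
                     for s in ss.spawn(n)])


def ensemble_angle_distribution(params: SimParams, n_cells: int,
                                seed: int = 0,
                                bin_width_deg: float = 1.0) -> EnsembleResult:
    """Angle distribution pooled over ``n_cells`` independent cells.

    Child seeds are derived deterministically from ``seed``; the pooled
    sample count is exactly n_cells × round(duration / out_dt).
    """
    if n_cells < 1:
        raise InvalidSpecificationError("n_cells must be ≥ 1")
    seeds = _child_seeds(seed, n_cells)
    series = [simulate_cell(params, int(s)) for s in seeds]
    samples = np.concatenate(series)
    edges = np.arange(0.0, 90.0 + bin_width_deg, bin_width_deg)
    counts, _ = np.histogram(samples, bins=edges)
    per_cell_sd = np.array([float(circstd(s, high=360.0, low=0.0))
                            for s in series])
    return EnsembleResult(
        samples_deg=samples, hist_counts=counts, bin_edges_deg=edges,
        mean_deg=float(samples.mean()),
        sd_deg=float(circstd(samples, high=360.0, low=0.0)),
        per_cell_sd_deg=per_cell_sd, n_cells=n_cells)


def monotonicity_sweep(base_params: SimParams, axis: str,
                       grid: Sequence[float], n_cells: int = 20,
                       seed: int = 0) -> pd.DataFrame:
    """Angle variability against one model parameter.

    ``axis`` is ``"n_pili_mean"`` or ``"ret_ext_ratio"`` (the latter scales
    ``v_ret`` = ratio × ``v_ext`` at fixed ``v_ext``).  All grid points use
    the same root seed, so cells are matched across the grid.  Returns one
    row per grid point with the pooled circular SD of θ_c and its
    Monte-Carlo standard error (between-cell spread of per-cell SDs).
    """
    if len(grid) < 3:
        raise InvalidSpecificationError("grid needs ≥ 3 points")
    rows = []
    for value in grid:
        if axis == "n_pili_mean":
            p = replace(base_params, n_pili_mean=float(value))
        elif axis == "ret_ext_ratio":
            p = replace(base_params, v_ret=float(value) * base_params.v_ext)
        else:
            raise InvalidSpecificationError(
                "axis must be 'n_pili_mean' or 'ret_ext_ratio'")
        res = ensemble_angle_distribution(p, n_cells=n_cells, seed=seed)
        sd_cells = res.per_cell_sd_deg
        rows.append({
            "axis": axis, "value": float(value),
            "sd_deg": res.sd_deg,
            "mean_cell_sd_deg": float(sd_cells.mean()),
            "mc_se_deg": float(sd_cells.std(ddof=1) / math.sqrt(len(sd_cells))),
            "n_cells": n_cells,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def preset_names() -> list:
    """Available strain preset names."""
    return ["wt", "pilt2"]


def load_preset(name: str, **overrides) -> SimParams:
    """Load a strain preset (``wt`` or ``pilt2``) from the packaged YAML.

    Measured fields (retraction/extension speed, filament number and
    length) come from the respective strain; the remaining mechanical
    parameters are shared package defaults.  Keyword overrides are applied
    on top.
    """
    key = name.lower().replace("δ", "").replace("Δ", "")
    if key not in preset_names():
        raise InvalidSpecificationError(
            f"unknown preset {name!r}; available: {preset_names()}")
    text = (resources.files("rheo") / "presets" / f"{key}.yaml").read_text()
    data = yaml.safe_load(text)
    data.update(overrides)
    return SimParams(**data)
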