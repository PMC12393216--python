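"""Flow-chamber physics and single-cell mechanics estimators.

Closed-form quantities for a shallow rectangular flow channel driven by a
syringe pump, plus the two single-cell estimators used alongside it: the
equipartition (apparent) spring constant of a pole-tethered cell from its
flapping trace, and the maximum attachment force from Stokes-type drag at
the detachment velocity.

Everything internal is SI; stated units are converted at the boundary
(flow rates in μl/s, positions in μm, stiffness reported in pN/nm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import (
    DegenerateFitError,
    InsufficientDataError,
    InvalidArgumentError,
    InvalidSpecificationError,
    ZeroVarianceError,
)

#: Boltzmann constant, J/K.
BOLTZMANN_J_PER_K = 1.380649e-23

#: pN/nm per N/m (1 N/m = 1e12 pN / 1e9 nm = 1e3 pN/nm).
_N_PER_M_TO_PN_PER_NM = 1e3

#: m³/s per μl/s.
UL_PER_S = 1e-9

# Default chamber: 1.5 mm × 0.1 mm × 25 mm channel, water-like viscosity
# at 70 °C, absolute temperature of the heated stage.
DEFAULT_WIDTH_M = 1.5e-3
DEFAULT_HEIGHT_M = 0.1e-3
DEFAULT_LENGTH_M = 25e-3
DEFAULT_VISCOSITY_PA_S = 0.40e-3
DEFAULT_TEMPERATURE_K = 343.15


@dataclass(frozen=True)
class ChamberSpec:
    """Geometry and operating point of the rectangular flow chamber.

    Parameters are SI: metres, m³/s, Pa·s, kelvin.  The shear formula
    assumes a shallow channel, so ``height_h < width_w`` is enforced.
    """

    flow_rate_Q: float
    width_w: float = DEFAULT_WIDTH_M
    height_h: float = DEFAULT_HEIGHT_M
    channel_length: float = DEFAULT_LENGTH_M
    viscosity_mu: float = DEFAULT_VISCOSITY_PA_S
    temperature: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        for name in ("width_w", "height_h", "channel_length", "viscosity_mu",
                     "temperature"):
            if not getattr(self, name) > 0:
                raise InvalidSpecificationError(f"{name} must be positive")
        if self.flow_rate_Q < 0:
            raise InvalidSpecificationError("flow_rate_Q must be non-negative")
        if not self.height_h < self.width_w:
            raise InvalidSpecificationError(
                "shallow-channel assumption requires height_h < width_w")

    @classmethod
    def from_flow_rate_ul_s(cls, flow_rate_ul_s: float, **kwargs) -> "ChamberSpec":
        """Construct from a flow rate in μl/s with default geometry."""
        return cls(flow_rate_Q=flow_rate_ul_s * UL_PER_S, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "ChamberSpec":
        """Load an SI-unit key/value config file."""
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def shear_stress(chamber: ChamberSpec) -> float:
    """Wall shear stress σ_S = 6Qμ/(wh²) of the shallow channel, in Pa.

    At the default geometry and Q = 1.0 μl/s this evaluates to 0.16 Pa.
    """
    return (6.0 * chamber.flow_rate_Q * chamber.viscosity_mu
            / (chamber.width_w * chamber.height_h ** 2))


def mean_flow_velocity(chamber: ChamberSpec) -> float:
    """Cross-section-averaged flow speed Q/(wh), in m/s."""
    return chamber.flow_rate_Q / (chamber.width_w * chamber.height_h)


@dataclass(frozen=True)
class CalibrationSet:
    """Paired (flow rate, detachment velocity) observations.

    Flow rates in μl/s, velocities in μm/s — the units in which the
    near-surface calibration is expressed.
    """

    flow_rates_ul_s: tuple
    detach_velocities_um_s: tuple

    def __post_init__(self) -> None:
        q = np.asarray(self.flow_rates_ul_s, dtype=float)
        v = np.asarray(self.detach_velocities_um_s, dtype=float)
        if q.shape != v.shape or q.ndim != 1:
            raise InvalidSpecificationError("flow rates and velocities must "
                                            "be equal-length 1-D sequences")
        if q.size < 2:
            raise InvalidSpecificationError("need at least 2 calibration pairs")
        if np.any(q < 0):
            raise InvalidSpecificationError("flow rates must be non-negative")
        object.__setattr__(self, "flow_rates_ul_s", tuple(q))
        object.__setattr__(self, "detach_velocities_um_s", tuple(v))


@dataclass(frozen=True)
class NearSurfaceCalibration:
    """Through-origin linear map from flow rate to near-surface speed."""

    slope_um_s_per_ul_s: float

    def predict(self, flow_rate_ul_s: float) -> float:
        """Near-surface flow speed (μm/s) at the given pump rate (μl/s)."""
        return self.slope_um_s_per_ul_s * flow_rate_ul_s


def calibrate_near_surface_velocity(cal: CalibrationSet) -> NearSurfaceCalibration:
    """Fit v = slope·Q through the origin by least squares.

    The zero-intercept constraint encodes the physical boundary condition
    that zero flow produces zero near-surface velocity.  The closed form is
    slope = Σ q·v / Σ q².
    """
    q = np.asarray(cal.flow_rates_ul_s, dtype=float)
    v = np.asarray(cal.detach_velocities_um_s, dtype=float)
    denom = float(np.dot(q, q))
    if denom == 0.0:
        raise DegenerateFitError("all calibration flow rates are zero")
    return NearSurfaceCalibration(slope_um_s_per_ul_s=float(np.dot(q, v)) / denom)


@dataclass(frozen=True)
class SpringConstantEstimate:
    """Equipartition stiffness estimate, reported in pN/nm."""

    k_pn_per_nm: float
    per_axis_pn_per_nm: tuple = field(default_factory=tuple)
    n_samples: int = 0

    def __float__(self) -> float:
        return self.k_pn_per_nm


def apparent_spring_constant(trace_um, temperature_k: float,
                             min_samples: int = 100) -> SpringConstantEstimate:
    """Apparent spring constant of a tethered cell from its flapping trace.

    The free-pole position is treated as a harmonic oscillator in thermal
    equilibrium, so per axis ⟨x²⟩ = k_B·T / k and k = k_B·T / var(x).
    ``trace_um`` is an (n,) array for one axis or (n, d) for d axes (μm);
    the estimate is computed per axis and the arithmetic mean across axes is
    reported, in pN/nm.
    """
    x = np.asarray(trace_um, dtype=float)
    if not temperature_k > 0:
        raise InvalidArgumentError("temperature must be positive")
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2:
        raise InvalidArgumentError("trace must be 1-D or 2-D (samples × axes)")
    n = x.shape[0]
    if n < min_samples:
        raise InsufficientDataError(
            f"need ≥{min_samples} samples for the equipartition estimate, got {n}")
    var_um2 = x.var(axis=0, ddof=1)
    if np.any(var_um2 <= 0):
        raise ZeroVarianceError("flapping trace has zero variance on an axis; "
                                "stiffness would be infinite")
    var_m2 = var_um2 * 1e-12
    k_si = BOLTZMANN_J_PER_K * temperature_k / var_m2          # N/m per axis
    k_axes = tuple(k_si * _N_PER_M_TO_PN_PER_NM)
    return SpringConstantEstimate(k_pn_per_nm=float(np.mean(k_axes)),
                                  per_axis_pn_per_nm=k_axes, n_samples=n)


def max_attachment_force(drag_coefficient_pn_s_per_um: float,
                         detach_velocity_um_s: float) -> float:
    """Maximum attachment force F = γ·v, in pN.

    ``drag_coefficient`` is the translational drag γ of the cell body
    (pN·s/μm) and ``detach_velocity`` the flow speed at which cells detach
    from the surface (μm/s).
    """
    if drag_coefficient_pn_s_per_um < 0 or detach_velocity_um_s < 0:
        raise InvalidArgumentError("drag coefficient and velocity must be "
                                   "non-negative")
    return drag_coefficient_pn_s_per_um * detach_velocity_um_s


def stokes_drag_coefficient(radius_um: float,
                            viscosity_pa_s: float = DEFAULT_VISCOSITY_PA_S) -> float:
    """Stokes drag γ = 6πμr for a sphere of equivalent radius, in pN·s/μm.

    A convenience default for :func:`max_attachment_force`; the cell body is
    rod-shaped, so treat this as an order-of-magnitude bulk estimate (no
    wall correction, no aspect-ratio correction).
    """
    if radius_um <= 0:
        raise InvalidArgumentError("radius must be positive")
    gamma_si = 6.0 * np.pi * viscosity_pa_s * radius_um * 1e-6  # N·s/m
    return gamma_si * 1e6  # → pN·s/μm
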