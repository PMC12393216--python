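"""Flow-chamber physics and single-cell mechanics estimators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rheo.chamber import (
    BOLTZMANN_J_PER_K,
    CalibrationSet,
    ChamberSpec,
    apparent_spring_constant,
    calibrate_near_surface_velocity,
    max_attachment_force,
    mean_flow_velocity,
    shear_stress,
    stokes_drag_coefficient,
)
from rheo.errors import (
    DegenerateFitError,
    InsufficientDataError,
    InvalidArgumentError,
    InvalidSpecificationError,
    ZeroVarianceError,
)


class TestShearStress:
    def test_paper_operating_point(self):
        """Q = 1 μl/s in the 1.5 × 0.1 mm channel gives 0.16 Pa."""
        spec = ChamberSpec.from_flow_rate_ul_s(1.0)
        assert shear_stress(spec) == pytest.approx(0.16, rel=1e-6)

    def test_zero_flow_zero_shear(self):
        assert shear_stress(ChamberSpec.from_flow_rate_ul_s(0.0)) == 0.0

    def test_height_squared_scaling(self):
        base = ChamberSpec.from_flow_rate_ul_s(1.0)
        doubled = ChamberSpec.from_flow_rate_ul_s(1.0, height_h=2 * base.height_h)
        assert shear_stress(doubled) == pytest.approx(shear_stress(base) / 4)

    @pytest.mark.parametrize("kwargs", [
        {"width_w": -1e-3}, {"height_h": 0.0}, {"viscosity_mu": -0.1},
        {"height_h": 2e-3},     # violates shallow-channel assumption
    ])
    def test_invalid_geometry_rejected(self, kwargs):
        with pytest.raises(InvalidSpecificationError):
            ChamberSpec.from_flow_rate_ul_s(1.0, **kwargs)

    @given(q=st.floats(min_value=0.01, max_value=100.0),
           scale=st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=50, deadline=None)
    def test_homogeneous_degree_one_in_q(self, q, scale):
        """σ_S and the mean velocity are exactly proportional to Q."""
        a = ChamberSpec.from_flow_rate_ul_s(q)
        b = ChamberSpec.from_flow_rate_ul_s(q * scale)
        assert shear_stress(b) == pytest.approx(scale * shear_stress(a))
        assert mean_flow_velocity(b) == pytest.approx(
            scale * mean_flow_velocity(a))


class TestMeanFlowVelocity:
    def test_paper_operating_point(self):
        """Q/(wh) at the default geometry is 6.7 mm/s to 2 s.f."""
        v = mean_flow_velocity(ChamberSpec.from_flow_rate_ul_s(1.0))
        assert v * 1e3 == pytest.approx(6.7, abs=0.05)

    def test_halving_width_doubles_velocity(self):
        base = ChamberSpec.from_flow_rate_ul_s(1.0)
        narrow = ChamberSpec.from_flow_rate_ul_s(1.0, width_w=base.width_w / 2)
        assert mean_flow_velocity(narrow) == pytest.approx(
            2 * mean_flow_velocity(base))


class TestNearSurfaceCalibration:
    def test_exact_line_through_origin(self):
        q = np.array([0.25, 0.5, 1.0, 2.0])
        cal = CalibrationSet(tuple(q), tuple(40.0 * q))
        fit = calibrate_near_surface_velocity(cal)
        assert fit.slope_um_s_per_ul_s == pytest.approx(40.0)
        assert fit.predict(1.0) == pytest.approx(40.0)

    def test_repeated_pair(self):
        cal = CalibrationSet((1.0, 1.0), (40.0, 40.0))
        assert calibrate_near_surface_velocity(cal).slope_um_s_per_ul_s == \
            pytest.approx(40.0)

    def test_matches_closed_form_estimator(self):
        rng = np.random.default_rng(42)
        q = rng.uniform(0.1, 3.0, size=30)
        v = 40.0 * q + rng.normal(0, 2.0, size=30)
        fit = calibrate_near_surface_velocity(CalibrationSet(tuple(q), tuple(v)))
        assert fit.slope_um_s_per_ul_s == pytest.approx(
            float(np.sum(q * v) / np.sum(q ** 2)), rel=1e-12)

    def test_noisy_recovery(self):
        """5% multiplicative noise at n = 50 recovers the slope within ±2."""
        rng = np.random.default_rng(7)
        q = rng.uniform(0.2, 2.0, size=50)
        v = 40.0 * q * (1 + rng.normal(0, 0.05, size=50))
        fit = calibrate_near_surface_velocity(CalibrationSet(tuple(q), tuple(v)))
        assert abs(fit.slope_um_s_per_ul_s - 40.0) < 2.0

    def test_degenerate_all_zero_flow(self):
        with pytest.raises(DegenerateFitError):
            calibrate_near_surface_velocity(CalibrationSet((0.0, 0.0), (1.0, 2.0)))

    def test_too_few_pairs(self):
        with pytest.raises(InvalidSpecificationError):
            CalibrationSet((1.0,), (40.0,))


class TestApparentSpringConstant:
    def _trace(self, k_pn_nm, n, seed, temperature=343.15):
        var_um2 = BOLTZMANN_J_PER_K * temperature / (k_pn_nm * 1e-3) * 1e12
        rng = np.random.default_rng(seed)
        return rng.normal(0.0, np.sqrt(var_um2), size=(n, 2))

    @pytest.mark.parametrize("k", [5.9e-5, 3.6e-2])
    def test_recovers_printed_stiffnesses(self, k):
        """Equipartition recovery of both measured spring constants at 343 K."""
        est = apparent_spring_constant(self._trace(k, 5000, seed=1), 343.15)
        assert est.k_pn_per_nm == pytest.approx(k, rel=0.05)

    @pytest.mark.parametrize("k", [1e-5, 1e-3, 1e-1])
    def test_low_bias_across_magnitudes(self, k):
        """Mean relative error < 2% at n = 10⁴ across four decades."""
        errs = [apparent_spring_constant(self._trace(k, 10_000, seed=s),
                                         343.15).k_pn_per_nm / k - 1
                for s in range(5)]
        assert abs(np.mean(errs)) < 0.02

    def test_equipartition_scaling(self):
        """Scaling the positional variance ×4 scales k by 1/4."""
        x = self._trace(1e-3, 5000, seed=3)
        k1 = apparent_spring_constant(x, 343.15).k_pn_per_nm
        k4 = apparent_spring_constant(2.0 * x, 343.15).k_pn_per_nm
        assert k4 == pytest.approx(k1 / 4, rel=1e-9)

    def test_zero_variance_errors(self):
        with pytest.raises(ZeroVarianceError):
            apparent_spring_constant(np.ones((500, 2)), 343.15)

    def test_too_few_samples(self):
        with pytest.raises(InsufficientDataError):
            apparent_spring_constant(np.random.default_rng(0).normal(size=50),
                                     343.15)

    def test_invalid_temperature(self):
        with pytest.raises(InvalidArgumentError):
            apparent_spring_constant(np.zeros(200), -1.0)


class TestMaxAttachmentForce:
    def test_zero_velocity(self):
        assert max_attachment_force(0.066, 0.0) == 0.0

    def test_drag_times_velocity(self):
        """γ back-computed as 132 pN / 2000 μm/s reproduces the WT force."""
        assert max_attachment_force(0.066, 2000.0) == pytest.approx(132.0)

    def test_linear_in_velocity(self):
        assert max_attachment_force(0.05, 2000.0) == pytest.approx(
            2 * max_attachment_force(0.05, 1000.0))

    def test_negative_inputs_rejected(self):
        with pytest.raises(InvalidArgumentError):
            max_attachment_force(-0.1, 10.0)

    def test_stokes_helper_order_of_magnitude(self):
        gamma = stokes_drag_coefficient(0.5)
        assert 1e-3 < gamma < 1e-2   # pN·s/μm for a ~μm cell in hot water
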