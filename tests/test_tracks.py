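"""Trajectory metrics, rheotaxis classifiers, MSD fit, reversal counting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import straight_track
from rheo.errors import (
    InsufficientDataError,
    InsufficientDurationError,
    InvalidSpecificationError,
    UndefinedAngleError,
)
from rheo.synth import CohortSpec, make_tracks
from rheo.tracks import (
    FlowFrame,
    FlowResponseClass,
    RheotaxisClass,
    Track,
    classify_flow_response,
    classify_rheotaxis,
    count_reversals,
    diffusion_coefficient,
    msd_fit,
    net_displacement_rate,
    population_summary,
    reversal_rate,
    trajectory_angle,
)


class TestNetDisplacementRate:
    def test_straight_upstream(self, frame):
        tr = straight_track(17.1, direction=(1, 0))
        assert net_displacement_rate(tr, frame) == pytest.approx(17.1)

    def test_straight_downstream(self, frame):
        tr = straight_track(9.3, direction=(-1, 0))
        assert net_displacement_rate(tr, frame) == pytest.approx(-9.3)

    def test_closed_loop_is_zero(self, frame):
        t = np.arange(0.0, 61.0)
        theta = 2 * np.pi * t / 60.0
        tr = Track("loop", t, 5 * np.cos(theta), 5 * np.sin(theta))
        assert net_displacement_rate(tr, frame) == pytest.approx(0.0, abs=1e-9)

    def test_short_track_rejected(self, frame):
        with pytest.raises(InsufficientDurationError):
            net_displacement_rate(straight_track(5.0, duration_s=30.0), frame)


class TestTrajectoryAngle:
    def test_pure_upstream_is_zero(self, frame):
        assert trajectory_angle(straight_track(5, (1, 0)), frame) == \
            pytest.approx(0.0, abs=1e-9)

    def test_pure_downstream_is_180(self, frame):
        assert trajectory_angle(straight_track(5, (-1, 0)), frame) == \
            pytest.approx(180.0)

    def test_diagonal_displacement(self):
        """Displacement (−1, 1) with flow along +x lies 45° from upstream."""
        frame = FlowFrame((1.0, 0.0))    # upstream = −x
        tr = straight_track(5, (-1, 1))
        assert trajectory_angle(tr, frame) == pytest.approx(45.0)

    def test_zero_displacement_undefined(self, frame):
        tr = Track("still", np.arange(61.0), np.zeros(61), np.zeros(61))
        with pytest.raises(UndefinedAngleError):
            trajectory_angle(tr, frame)


class TestClassifyRheotaxis:
    @pytest.mark.parametrize("rate,direction,expected", [
        (17.0, (np.cos(np.radians(10)), np.sin(np.radians(10))),
         RheotaxisClass.POSITIVE),          # fast, 10° off upstream
        (0.5, (1, 0), RheotaxisClass.RANDOM),   # below displacement threshold
        (5.0, (0, 1), RheotaxisClass.RANDOM),   # 90°, between thresholds
        (5.0, (-1, 0), RheotaxisClass.NEGATIVE),
        (1.0, (1, 0), RheotaxisClass.POSITIVE),  # thresholds are inclusive
    ])
    def test_rule_table(self, frame, rate, direction, expected):
        assert classify_rheotaxis(straight_track(rate, direction), frame) == expected

    @given(phi=st.floats(min_value=0.0, max_value=2 * np.pi))
    @settings(max_examples=40, deadline=None)
    def test_rotation_invariance(self, phi):
        """Jointly rotating track and flow frame preserves the label."""
        c, s = np.cos(phi), np.sin(phi)
        rot = np.array([[c, -s], [s, c]])
        for rate, direction in [(17.0, (1, 0.3)), (5.0, (-1, 0.2)), (0.4, (1, 0))]:
            tr = straight_track(rate, direction)
            base = classify_rheotaxis(tr, FlowFrame((-1.0, 0.0)))
            xy = tr.xy @ rot.T
            tr_rot = Track(tr.cell_id, tr.t_s, xy[:, 0], xy[:, 1])
            frame_rot = FlowFrame(tuple(rot @ np.array([-1.0, 0.0])))
            assert classify_rheotaxis(tr_rot, frame_rot) == base


class TestClassifyFlowResponse:
    def test_detached_fast_downstream(self, frame):
        tr = straight_track(20.0, (-np.cos(np.radians(10)), np.sin(np.radians(10))),
                            duration_s=180.0)
        assert classify_flow_response(tr, frame) == FlowResponseClass.DETACHED

    def test_dragged_slow_downstream(self, frame):
        tr = straight_track(5.0, (-1, 0), duration_s=180.0)
        assert classify_flow_response(tr, frame) == FlowResponseClass.DRAGGED

    def test_rheotaxis_upstream(self, frame):
        tr = straight_track(5.0, (1, 0), duration_s=180.0)
        assert classify_flow_response(tr, frame) == FlowResponseClass.RHEOTAXIS

    def test_stationary_zero_displacement(self, frame):
        t = np.arange(0.0, 181.0)
        tr = Track("still", t, np.zeros(181), np.zeros(181))
        assert classify_flow_response(tr, frame) == FlowResponseClass.STATIONARY

    def test_free_perpendicular_movement(self, frame):
        tr = straight_track(6.0, (0, 1), duration_s=180.0)
        assert classify_flow_response(tr, frame) == FlowResponseClass.FREE

    def test_dragged_persistence_qualifier(self, frame):
        """Downstream at ≥120° but with large perpendicular excursion is
        not surface-associated dragging — it falls through to free."""
        tr = straight_track(10.0, (-1, 0.9), duration_s=180.0)
        assert trajectory_angle(tr, frame) >= 120.0
        assert classify_flow_response(tr, frame) == FlowResponseClass.FREE

    def test_partition_completeness(self, frame):
        """Every track receives exactly one of the five labels."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            rate = rng.uniform(0, 25)
            direction = rng.normal(size=2)
            if not np.any(direction):
                direction = (1.0, 0.0)
            tr = straight_track(rate, tuple(direction), duration_s=180.0)
            assert classify_flow_response(tr, frame) in FlowResponseClass

    def test_short_window_rejected(self, frame):
        with pytest.raises(InsufficientDurationError):
            classify_flow_response(straight_track(5.0, (1, 0)), frame)


class TestDiffusionCoefficient:
    def test_recovers_generating_value(self):
        """50 Brownian tracks × 60 s at D = 1.7 μm²/s recover D ± 0.2."""
        trs = make_tracks(CohortSpec.no_flow(n_cells=50, seed=11))
        assert diffusion_coefficient(trs) == pytest.approx(1.7, abs=0.2)

    def test_doubling_d_doubles_estimate(self):
        d1 = diffusion_coefficient(
            make_tracks(CohortSpec.no_flow(n_cells=50, seed=4)))
        d2 = diffusion_coefficient(
            make_tracks(CohortSpec.no_flow(n_cells=50, seed=4, diffusion_D=3.4)))
        assert d2 / d1 == pytest.approx(2.0, rel=0.15)

    def test_stationary_tracks_give_zero(self):
        t = np.arange(0.0, 60.0)
        trs = [Track(f"s{i}", t, np.zeros(60), np.zeros(60)) for i in range(6)]
        assert diffusion_coefficient(trs) == 0.0

    def test_drift_flag_and_removal(self, frame):
        """Ballistic tracks trip the nonlinearity diagnostic; removing the
        per-track drift sends the estimate to ≈ 0."""
        trs = [straight_track(17.1, (1, 0), duration_s=120.0, cell_id=f"d{i}")
               for i in range(6)]
        fit = msd_fit(trs)
        assert fit.drift_dominated
        fit0 = msd_fit(trs, remove_drift=True)
        assert fit0.D_um2_s == pytest.approx(0.0, abs=1e-9)
        assert not fit0.drift_dominated

    def test_insufficient_tracks(self):
        trs = make_tracks(CohortSpec.no_flow(n_cells=3, seed=0))
        with pytest.raises(InsufficientDataError):
            diffusion_coefficient(trs)


def _piecewise_track(segments, dt=1.0):
    """Track from (duration_s, vx_um_s) pieces."""
    vx = np.concatenate([np.full(int(d / dt), v) for d, v in segments])
    x = np.concatenate([[0.0], np.cumsum(vx * dt)])
    t = np.arange(x.size) * dt
    return Track("pw", t, x, np.zeros_like(x))


class TestReversals:
    def test_monotone_track_has_none(self, frame):
        tr = straight_track(17.1, (1, 0), duration_s=1200.0)
        assert count_reversals(tr, frame) == 0
        assert reversal_rate(tr, frame) == 0.0

    def test_single_persistent_flip(self, frame):
        tr = _piecewise_track([(600, 0.3), (600, -0.3)])
        assert count_reversals(tr, frame) == 1

    def test_k_well_separated_flips(self, frame):
        k = 4
        pieces = [(300, 0.3 if i % 2 == 0 else -0.3) for i in range(k + 1)]
        tr = _piecewise_track(pieces)
        assert count_reversals(tr, frame) == k

    def test_brief_excursion_ignored(self, frame):
        """A 10-s wrong-way excursion is below the persistence window."""
        tr = _piecewise_track([(600, 0.3), (10, -0.3), (600, 0.3)])
        assert count_reversals(tr, frame) == 0

    def test_short_track_rejected(self, frame):
        with pytest.raises(InsufficientDurationError):
            reversal_rate(straight_track(5, (1, 0), duration_s=300.0), frame)


class TestPopulationSummary:
    def test_proportions_sum_to_one_per_orientation(self, frame):
        trs = make_tracks(CohortSpec.flow_mixture(n_cells=60, seed=3))
        out = population_summary(trs, frame)
        sums = out.groupby("orientation")["proportion"].sum()
        assert np.allclose(sums.to_numpy(), 1.0)

    def test_identical_upstream_cohort_all_positive(self, frame):
        trs = [straight_track(17.1, (1, 0), cell_id=f"v{i}",
                              orientation="vertical") for i in range(5)]
        out = population_summary(trs, frame)
        pos = out[(out.orientation == "vertical")
                  & (out.rheotaxis_class == "positive")]
        assert pos["proportion"].iloc[0] == 1.0
        empty = out[(out.orientation == "vertical")
                    & (out.rheotaxis_class == "negative")]
        assert empty["proportion"].iloc[0] == 0.0

    def test_empty_cohort_rejected(self, frame):
        with pytest.raises(InsufficientDataError):
            population_summary([], frame)


class TestTrackValidation:
    def test_non_monotone_time_rejected(self):
        with pytest.raises(InvalidSpecificationError):
            Track("bad", np.array([0.0, 2.0, 1.0]), np.zeros(3), np.zeros(3))

    def test_non_uniform_sampling_rejected(self):
        with pytest.raises(InvalidSpecificationError):
            Track("bad", np.array([0.0, 1.0, 3.0]), np.zeros(3), np.zeros(3))

    def test_unknown_orientation_label_rejected(self):
        with pytest.raises(InvalidSpecificationError):
            Track("bad", np.arange(3.0), np.zeros(3), np.zeros(3),
                  orientation="sideways")
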