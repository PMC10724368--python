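"""Simulated rubber-hand-illusion experiments on the trained model."""

import numpy as np
import pytest

from rhinet import experiments as exp
from rhinet.network import Network, NetworkConfig, NotTrainedError


class TestDriftCurve:
    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            exp.DriftCurve(np.arange(3.0), np.arange(4.0))

    def test_accessors(self):
        c = exp.DriftCurve(np.array([0.0, 3.0, 6.0]), np.array([0.0, 3.0, 0.0]))
        assert c.drift_at(3.0) == 3.0
        assert c.max_abs_drift() == 3.0
        assert c.max_abs_drift(min_disparity=3.0) == 0.0

    def test_frame_round_trip(self):
        c = exp.DriftCurve(np.arange(0.0, 30.0, 3.0), np.arange(10.0),
                           condition="own-hand", n_replicates=5)
        c2 = exp.DriftCurve.from_frame(c.to_frame())
        assert np.array_equal(c.disparities, c2.disparities)
        assert np.array_equal(c.drifts, c2.drifts)
        assert c2.condition == "own-hand" and c2.n_replicates == 5


class TestDriftSweep:
    def test_untrained_network_is_refused(self, default_config):
        with pytest.raises(NotTrainedError):
            exp.proprioceptive_drift_sweep(Network(default_config))

    def test_congruent_input_gives_zero_drift(self, drift_curve):
        assert drift_curve.drift_at(0.0) == 0.0

    def test_drift_rises_with_small_disparities(self, drift_curve):
        """For small disparities vision captures the decision: the drift
        tracks the disparity within one grid step."""
        for d in (3.0, 6.0, 9.0, 12.0, 15.0, 18.0, 21.0):
            assert abs(drift_curve.drift_at(d) - d) <= 3.0

    def test_antisymmetry_within_one_grid_step(self, drift_curve):
        for d in (6.0, 12.0, 21.0, 30.0, 45.0):
            assert abs(drift_curve.drift_at(d) + drift_curve.drift_at(-d)) <= 3.0

    def test_drift_bounded_by_vision_and_proprioception_lines(self, drift_curve):
        pos = drift_curve.disparities >= 0
        d = drift_curve.disparities[pos]
        y = drift_curve.drifts[pos]
        assert np.all(y >= -3.0)
        assert np.all(y <= d + 3.0)


class TestBreakpoint:
    def test_synthetic_saturating_curve(self):
        d = np.arange(0.0, 61.0, 3.0)
        curve = exp.DriftCurve(d, np.minimum(d, 20.0))
        knot, slopes = exp.fit_drift_breakpoint(curve)
        assert knot is not None and abs(knot - 20.0) <= 3.0
        assert slopes[0] == pytest.approx(1.0, abs=0.1)
        assert abs(slopes[1]) < 0.1

    def test_perfectly_linear_curve_has_no_breakpoint(self):
        d = np.arange(0.0, 31.0, 3.0)
        knot, slopes = exp.fit_drift_breakpoint(exp.DriftCurve(d, 0.5 * d))
        assert knot is None
        assert slopes[0] == pytest.approx(0.5)

    def test_constant_curve_has_no_breakpoint(self):
        d = np.arange(0.0, 31.0, 3.0)
        knot, _ = exp.fit_drift_breakpoint(exp.DriftCurve(d, np.zeros_like(d)))
        assert knot is None

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            exp.fit_drift_breakpoint(
                exp.DriftCurve(np.arange(3.0), np.arange(3.0))
            )


class TestAppearance:
    def test_similar_hand_reduces_drift_pointwise(self, trained, drift_curve):
        sim = trained.appearance_replacement("similar")
        pos = sim.disparities >= 0
        assert np.all(np.abs(sim.drifts[pos])
                      <= np.abs(drift_curve.drifts[pos]) + 3.0)
        # the illusion window narrows relative to the own hand
        assert (exp.illusion_half_range(sim)
                < exp.illusion_half_range(drift_curve))

    def test_dissimilar_hand_abolishes_the_illusion(self, trained):
        dis = trained.appearance_replacement("dissimilar")
        assert dis.max_abs_drift() <= 3.0

    def test_full_gain_reproduces_own_hand(self, trained, drift_curve):
        own = trained.appearance_replacement("own")
        assert np.array_equal(own.drifts, drift_curve.drifts)

    def test_unknown_condition_rejected(self, trained):
        with pytest.raises(ValueError):
            trained.appearance_replacement("alien")


class TestAsynchrony:
    def test_zero_delay_matches_default_sweep(self, trained, drift_curve):
        c = trained.asynchrony_experiment((0.0,))[0.0]
        assert np.array_equal(c.drifts, drift_curve.drifts)

    def test_large_delay_abolishes_the_illusion(self, trained):
        c = trained.asynchrony_experiment((500.0,))[500.0]
        assert c.max_abs_drift() == 0.0

    def test_intermediate_delay_reduces_drift(self, trained, drift_curve):
        c = trained.asynchrony_experiment((100.0,))[100.0]
        pos = c.disparities >= 0
        assert np.all(np.abs(c.drifts[pos])
                      <= np.abs(drift_curve.drifts[pos]) + 3.0)

    def test_negative_delay_rejected(self, trained):
        with pytest.raises(ValueError):
            trained.asynchrony_experiment((-10.0,))


class TestUnisensory:
    def test_proprioception_only_yields_ownership(self, trained):
        flags = [exp.unisensory_experiment(n, "proprioception_only")[0]
                 for n in trained.networks]
        assert sum(flags) >= 3  # majority of replicates

    def test_vision_only_yields_no_ownership(self, trained):
        flags = [exp.unisensory_experiment(n, "vision_only")[0]
                 for n in trained.networks]
        assert sum(flags) <= 1

    def test_unknown_mode_rejected(self, trained):
        with pytest.raises(ValueError):
            exp.unisensory_experiment(trained.network, "touch_only")


class TestDisability:
    def test_full_tpj_lesion_abolishes_the_illusion(self, default_config):
        curve = exp.disability_experiment(default_config, "TPJ", 1.0,
                                          n_replicates=2, n_trials=200, seed=11)
        assert curve.max_abs_drift() == 0.0

    def test_full_ai_lesion_leaves_vision_dominated_decisions(self, default_config):
        curve = exp.disability_experiment(default_config, "AI", 1.0,
                                          n_replicates=2, n_trials=200, seed=11)
        pos = (curve.disparities > 0) & (curve.disparities <= 39)
        drifts, disp = curve.drifts[pos], curve.disparities[pos]
        # without the high-level integrator the decision follows the visual
        # hand at most deflection angles: drift toward vision throughout,
        # and at least half-way to the visual hand on average
        assert np.all(drifts >= 0)
        assert (drifts > 0).mean() > 0.9
        assert np.median(drifts / disp) >= 0.5

    def test_invalid_arguments(self, default_config):
        with pytest.raises(ValueError):
            exp.disability_experiment(default_config, "S1", 1.0)
        with pytest.raises(ValueError):
            exp.disability_experiment(default_config, "TPJ", 1.5)


class TestPrecision:
    def test_wider_receptive_fields_strengthen_the_illusion(self, default_config):
        """Lower proprioceptive precision (larger sigma) produces larger
        drift toward the visual hand over the mid-disparity range."""
        disparities = np.arange(0.0, 37.0, 6.0)
        curves = exp.precision_sweep((2.0, 4.0), default_config,
                                     disparities=disparities,
                                     n_replicates=3, n_trials=300, seed=5)
        mid = slice(1, None)
        mean2 = np.abs(curves[2.0].drifts[mid]).mean()
        mean4 = np.abs(curves[4.0].drifts[mid]).mean()
        assert mean4 > mean2

    def test_same_seed_gives_identical_curves(self, default_config):
        d = np.array([0.0, 12.0, 24.0])
        a = exp.precision_sweep((3.0,), default_config, disparities=d,
                                n_replicates=1, n_trials=60, seed=9)[3.0]
        b = exp.precision_sweep((3.0,), default_config, disparities=d,
                                n_replicates=1, n_trials=60, seed=9)[3.0]
        assert np.array_equal(a.drifts, b.drifts)
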