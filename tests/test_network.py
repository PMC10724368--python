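"""Network assembly, trial simulation and unsupervised training."""

import dataclasses

import numpy as np
import pytest

from rhinet.network import (
    AREAS,
    FIXED_PATHWAYS,
    PLASTIC_PATHWAYS,
    Network,
    NetworkConfig,
    TrialRecord,
    TrialSchedule,
    build_network,
    decode_decision,
    ownership_judgment,
)
from rhinet.plasticity import RateTrace


class TestBuild:
    def test_default_network_shape(self, default_config):
        net = build_network(default_config)
        assert default_config.grid.n == 41
        assert set(net.fixed) == set(FIXED_PATHWAYS)
        assert set(net.plastic) == set(PLASTIC_PATHWAYS)
        for syn in net.plastic.values():
            assert syn.W.shape == (41, 41)
            assert np.all(syn.W == 1.0)
            assert np.all(syn.gate == 1.0)

    def test_lesioned_config_scales_pathways(self, default_config):
        cfg = default_config.lesioned(("S1-TPJ", "EBA-TPJ"), 1.0)
        assert cfg.fixed_weights["S1-TPJ"] == 0.0
        assert cfg.fixed_weights["EBA-TPJ"] == 0.0
        assert cfg.fixed_weights["M1-S1"] == 1.0
        half = default_config.lesioned(("S1-TPJ",), 0.5)
        assert half.fixed_weights["S1-TPJ"] == pytest.approx(0.5)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(C_by_area={"M1": 0.04})
        with pytest.raises(ValueError):
            NetworkConfig(fixed_weights={"M1-S1": 1.0})
        with pytest.raises(ValueError):
            NetworkConfig(sigma=-1.0)
        with pytest.raises(ValueError):
            NetworkConfig(plastic_structure="banded")
        with pytest.raises(ValueError):
            NetworkConfig().lesioned(("NOPE",), 1.0)
        with pytest.raises(ValueError):
            NetworkConfig().lesioned(("S1-TPJ",), 1.5)

    def test_identity_plastic_structure(self, default_config):
        cfg = dataclasses.replace(default_config, plastic_structure="identity")
        net = Network(cfg)
        assert np.allclose(net.plastic["S1-AI"].W, np.eye(41))


class TestSchedule:
    def test_from_config_defaults(self, default_config):
        s = TrialSchedule.from_config(default_config, motor_angle=0.0,
                                      visual_angle=12.0)
        assert s.motor_offset_ms == default_config.stimulus_duration_ms
        assert s.visual_onset_ms == default_config.visual_onset_ms
        assert s.trial_length_ms == default_config.trial_length_ms

    def test_delayed_vision_may_fall_outside_trial(self, default_config):
        s = TrialSchedule.from_config(default_config, motor_angle=0.0,
                                      visual_angle=0.0, visual_delay_ms=500.0)
        assert s.visual_onset_ms + s.visual_delay_ms >= s.trial_length_ms

    def test_validation(self):
        with pytest.raises(ValueError):
            TrialSchedule(visual_gain=1.5)
        with pytest.raises(ValueError):
            TrialSchedule(visual_delay_ms=-1.0)
        with pytest.raises(ValueError):
            TrialSchedule(motor_offset_ms=700.0, trial_length_ms=600.0)


class TestTrialDynamics:
    def test_no_stimuli_gives_silent_network(self, default_config):
        net = build_network(default_config)
        rec = net.run_trial(TrialSchedule.from_config(default_config))
        for area in AREAS:
            assert not rec.traces[area].rates.any()
        assert decode_decision(rec) is None
        assert not ownership_judgment(rec)

    def test_s1_peaks_at_stimulated_angle(self, default_config):
        net = build_network(default_config)
        sched = TrialSchedule.from_config(default_config, motor_angle=21.0)
        rec = net.run_trial(sched)
        s1 = rec.traces["S1"].rates
        assert rec.grid.angles[np.argmax(s1.max(axis=0))] == 21.0

    def test_temporal_order_s1_then_eba_then_tpj(self, default_config):
        """Motor leads vision, and the slow TPJ accumulates last."""
        net = build_network(default_config)
        sched = TrialSchedule.from_config(default_config, motor_angle=0.0,
                                          visual_angle=0.0)
        rec = net.run_trial(sched)
        t_peak = {
            a: rec.traces[a].rates.max(axis=1).argmax()
            for a in ("S1", "EBA", "TPJ")
        }
        assert t_peak["S1"] < t_peak["EBA"] < t_peak["TPJ"]

    def test_trials_are_deterministic(self, default_config):
        sched = TrialSchedule.from_config(default_config, motor_angle=9.0,
                                          visual_angle=21.0)
        r1 = build_network(default_config).run_trial(sched)
        r2 = build_network(default_config).run_trial(sched)
        for a in AREAS:
            assert np.array_equal(r1.traces[a].rates, r2.traces[a].rates)

    def test_rates_stay_bounded(self, default_config):
        net = build_network(default_config)
        sched = TrialSchedule.from_config(default_config, motor_angle=-30.0,
                                          visual_angle=30.0)
        rec = net.run_trial(sched)
        for a in AREAS:
            assert np.all(np.abs(rec.traces[a].rates) <= 1.0)


class TestDecode:
    def _record(self, ai, grid, motor=0.0):
        traces = {a: RateTrace(np.zeros_like(ai)) for a in AREAS}
        traces["AI"] = RateTrace(ai)
        return TrialRecord(
            traces=traces,
            schedule=TrialSchedule(motor_angle=motor),
            grid=grid,
        )

    def test_ties_break_toward_motor_angle(self, default_config):
        g = default_config.grid
        ai = np.zeros((10, g.n))
        ai[5, g.index_of(-30.0)] = 0.5
        ai[5, g.index_of(6.0)] = 0.5
        rec = self._record(ai, g, motor=0.0)
        assert decode_decision(rec) == 6.0

    def test_all_zero_trace_is_no_decision(self, default_config):
        g = default_config.grid
        rec = self._record(np.zeros((10, g.n)), g)
        assert decode_decision(rec) is None

    def test_ownership_uses_threshold(self, default_config):
        g = default_config.grid
        ai = np.zeros((10, g.n))
        ai[3, 0] = 0.69
        rec = self._record(ai, g)
        assert not ownership_judgment(rec)
        ai[3, 0] = 0.71
        assert ownership_judgment(self._record(ai, g))


class TestTraining:
    def test_zero_trials_leaves_weights_at_one(self, default_config):
        net = build_network(default_config)
        hist = net.train(0, rng=0)
        assert len(hist) == 0
        for syn in net.plastic.values():
            assert np.all(syn.W == 1.0)
        assert not net.is_trained

    def test_training_is_reproducible_for_a_seed(self, default_config):
        n1 = build_network(default_config)
        n2 = build_network(default_config)
        n1.train(20, rng=123)
        n2.train(20, rng=123)
        for p in PLASTIC_PATHWAYS:
            assert np.array_equal(n1.plastic[p].W, n2.plastic[p].W)
            assert np.array_equal(n1.plastic[p].gate, n2.plastic[p].gate)

    def test_history_tracks_mean_weights(self, default_config):
        net = build_network(default_config)
        hist = net.train(10, rng=0)
        assert len(hist) == 10
        assert "mean_W[S1-AI]" in hist and "mean_W[EBA-AI]" in hist
        m = net.mean_plastic_weights()
        assert hist["mean_W[S1-AI]"].iloc[-1] == pytest.approx(m["S1-AI"])

    def test_weights_flip_from_excitatory_to_inhibitory(self, trained):
        """Unsupervised congruent babbling turns both plastic pathways
        inhibitory, with vision inhibited more strongly than
        proprioception."""
        m = trained.mean_weights
        assert m["S1-AI"] < 0 and m["EBA-AI"] < 0
        assert abs(m["EBA-AI"]) > abs(m["S1-AI"])
        assert trained.converged
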