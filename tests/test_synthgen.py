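"""Generator: protocols, ground-truth statistics, rendering, movies."""

import numpy as np
import pandas as pd
import pytest

from cfcalcium.kernels import cf_kernel
from cfcalcium.synthgen import (GeneratorConfig, GroundTruth, make_protocol,
                                render_movie, render_traces, simulate_events)


class TestProtocol:
    def test_duration_mode_counts(self):
        cfg = GeneratorConfig(trials_per_condition=35)
        prot = make_protocol(cfg, "duration")
        assert len(prot) == 140
        counts = prot.trials["condition"].value_counts()
        assert sorted(counts.index) == ["d1", "d2", "d3", "d4"]
        assert (counts == 35).all()

    def test_zero_trials_gives_empty_protocol(self):
        cfg = GeneratorConfig(trials_per_condition=0)
        prot = make_protocol(cfg, "duration")
        assert len(prot) == 0

    def test_pressure_onset_arithmetic(self):
        cfg = GeneratorConfig(trials_per_condition=10, pre_time_s=0.0)
        prot = make_protocol(cfg, "pressure")
        assert len(prot) == 20
        assert prot.trials["onset_s"].iloc[-1] == pytest.approx(76.0)

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            make_protocol(GeneratorConfig(), "frequency")

    def test_onset_spacing_respects_iti(self):
        prot = make_protocol(GeneratorConfig(trials_per_condition=5), "duration")
        assert np.diff(prot.trials["onset_s"]).min() >= 4.0


class TestSimulateEvents:
    def test_deterministic_given_seed(self):
        cfg = GeneratorConfig(n_dendrites=4, trials_per_condition=5, seed=7)
        prot = make_protocol(cfg, "duration", np.random.default_rng(0))
        a = simulate_events(cfg, prot, np.random.default_rng(42))
        b = simulate_events(cfg, prot, np.random.default_rng(42))
        pd.testing.assert_frame_equal(a.events, b.events)
        pd.testing.assert_frame_equal(a.shared_state, b.shared_state)

    def test_spontaneous_rate_poisson(self):
        # spontaneous-only recording: realized rate compensates the
        # refractory dead time, so pooled counts match the nominal rate
        cfg = GeneratorConfig(n_dendrites=20, trials_per_condition=0,
                              duration_s=600.0, seed=5)
        prot = make_protocol(cfg, "duration")
        truth = simulate_events(cfg, prot)
        lam = 0.7 * 600 * 20
        n = len(truth.events)
        assert abs(n - lam) < 3.0 * np.sqrt(lam)

    def test_evoked_marginal_calibrated_despite_shared_state(self):
        cfg = GeneratorConfig(n_dendrites=2, trials_per_condition=300,
                              graded_fraction=1.0, seed=11)
        prot = make_protocol(cfg, "duration")
        truth = simulate_events(cfg, prot)
        ev = truth.events[truth.events["origin"] == "evoked"]
        for cond in ["d1", "d4"]:
            p_true = cfg.evoked_prob[cond]
            for d in range(2):
                k = len(ev[(ev["condition"] == cond) & (ev["dendrite_id"] == d)])
                se = np.sqrt(p_true * (1 - p_true) / 300)
                assert abs(k / 300 - p_true) < 3.5 * se

    def test_injected_latencies_match_calibration(self):
        cfg = GeneratorConfig(n_dendrites=6, trials_per_condition=200,
                              graded_fraction=1.0, seed=3)
        prot = make_protocol(cfg, "duration")
        truth = simulate_events(cfg, prot)
        onset = dict(zip(prot.trials["trial_id"], prot.trials["onset_s"] * 1e3))
        ev = truth.events[truth.events["condition"] == "d4"]
        lat = ev["time_ms"].to_numpy() - np.array([onset[t] for t in ev["trial_id"]])
        assert np.median(lat) == pytest.approx(80.9, abs=1.5)
        assert np.median(np.abs(lat - np.median(lat))) == pytest.approx(18.0, abs=1.5)

    def test_saturated_probability_gives_full_coactivation(self):
        cfg = GeneratorConfig(n_dendrites=5, trials_per_condition=1,
                              graded_fraction=1.0, seed=1,
                              evoked_prob={c: 1.0 for c in
                                           ["d1", "d2", "d3", "d4", "p1", "p2"]},
                              shared_drive_prob={c: 0.0 for c in
                                                 ["d1", "d2", "d3", "d4",
                                                  "p1", "p2"]})
        prot = make_protocol(cfg, "duration")
        truth = simulate_events(cfg, prot)
        ev = truth.events[truth.events["origin"] == "evoked"]
        for tid in prot.trials["trial_id"]:
            assert ev[ev["trial_id"] == tid]["dendrite_id"].nunique() == 5

    def test_evoked_events_respect_latency_support(self):
        cfg = GeneratorConfig(n_dendrites=4, trials_per_condition=30, seed=9)
        prot = make_protocol(cfg, "duration")
        truth = simulate_events(cfg, prot)
        onset = dict(zip(prot.trials["trial_id"], prot.trials["onset_s"] * 1e3))
        ev = truth.events[truth.events["origin"] == "evoked"]
        lat = ev["time_ms"].to_numpy() - np.array([onset[t] for t in ev["trial_id"]])
        assert lat.min() >= 40.0 and lat.max() < 190.0

    def test_refractory_enforced_per_dendrite(self):
        cfg = GeneratorConfig(n_dendrites=3, trials_per_condition=20, seed=2)
        prot = make_protocol(cfg, "duration")
        truth = simulate_events(cfg, prot)
        for _, grp in truth.events.groupby("dendrite_id"):
            t = np.sort(grp["time_ms"].to_numpy())
            if len(t) > 1:
                assert np.diff(t).min() >= cfg.refractory_ms


def _empty_protocol(cfg):
    return make_protocol(
        GeneratorConfig(trials_per_condition=0, duration_s=cfg.duration_s,
                        seed=cfg.seed), "duration")


def _manual_truth(cfg, times_gains, duration_ms):
    events = pd.DataFrame(
        [{"dendrite_id": 0, "time_ms": t, "gain": g, "origin": "spontaneous",
          "trial_id": -1, "condition": "sp"} for t, g in times_gains],
        columns=["dendrite_id", "time_ms", "gain", "origin", "trial_id",
                 "condition"])
    dendrites = pd.DataFrame({"dendrite_id": [0], "position_um": [0.0],
                              "graded": [True], "threshold_idx": [0],
                              "bilateral": [False]})
    shared = pd.DataFrame(columns=["trial_id", "shared"])
    return GroundTruth(events=events, dendrites=dendrites,
                       shared_state=shared, duration_ms=duration_ms)


class TestRenderTraces:
    def _quiet_config(self, **kw):
        zeros = {c: 0.0 for c in ["d1", "d2", "d3", "d4", "p1", "p2"]}
        return GeneratorConfig(n_dendrites=1, noise_sd=0.0,
                               noncf_integral=zeros, duration_s=5.0,
                               trials_per_condition=0, amp_cv=0.0, **kw)

    def test_no_events_flat_at_f0(self):
        cfg = self._quiet_config(seed=0)
        prot = _empty_protocol(cfg)
        truth = _manual_truth(cfg, [], 5000.0)
        ts = render_traces(truth, cfg, prot, mode="dense")
        assert np.allclose(ts.raw_f, cfg.f0)
        assert np.allclose(ts.dff, 0.0)

    def test_single_event_peak_and_half_decay(self):
        cfg = self._quiet_config(seed=0)
        prot = _empty_protocol(cfg)
        truth = _manual_truth(cfg, [(1000.0, 1.3)], 5000.0)
        ts = render_traces(truth, cfg, prot, mode="dense")
        tr = ts.dff[0]
        pk = np.argmax(tr)
        assert tr[pk] == pytest.approx(1.3 * cfg.event_amp, rel=1e-3)
        assert pk == pytest.approx(1010, abs=1)
        below = np.flatnonzero(tr[pk:] <= 0.5 * tr[pk])
        # post-peak half-decay of the rendered kernel (rise-term corrected)
        assert below[0] * ts.dt_ms == pytest.approx(76.7, abs=1.0)

    def test_two_events_sum_linearly(self):
        cfg = self._quiet_config(seed=0)
        prot = _empty_protocol(cfg)
        both = render_traces(_manual_truth(cfg, [(500.0, 1.0), (800.0, 1.0)],
                                           4000.0), cfg, prot, mode="dense")
        one = render_traces(_manual_truth(cfg, [(500.0, 1.0)], 4000.0),
                            cfg, prot, mode="dense")
        two = render_traces(_manual_truth(cfg, [(800.0, 1.0)], 4000.0),
                            cfg, prot, mode="dense")
        np.testing.assert_allclose(both.dff[0], one.dff[0] + two.dff[0],
                                   atol=1e-12)

    def test_frame_binning_averages_dense(self):
        cfg = self._quiet_config(seed=0)
        prot = _empty_protocol(cfg)
        truth = _manual_truth(cfg, [(1000.0, 1.0)], 5000.0)
        dense = render_traces(truth, cfg, prot, mode="dense")
        frame = render_traces(truth, cfg, prot, mode="frame")
        n = len(frame.dff[0])
        manual = dense.dff[0][:n * 64].reshape(n, 64).mean(axis=1)
        np.testing.assert_allclose(frame.dff[0], manual, atol=1e-12)

    def test_rendering_deterministic(self):
        cfg = GeneratorConfig(n_dendrites=2, trials_per_condition=5, seed=8)
        prot = make_protocol(cfg, "duration", np.random.default_rng(1))
        truth = simulate_events(cfg, prot, np.random.default_rng(2))
        a = render_traces(truth, cfg, prot, rng=np.random.default_rng(3))
        b = render_traces(truth, cfg, prot, rng=np.random.default_rng(3))
        np.testing.assert_array_equal(a.dff, b.dff)


class TestRenderMovie:
    def test_single_dendrite_mask_mean_is_identity(self, frame_session):
        cfg, prot, truth, traces = frame_session
        cfg2 = GeneratorConfig(n_dendrites=1, pixel_noise_sd=0.0, seed=0)
        sub = type(traces)(dff=traces.dff[:1], raw_f=traces.raw_f[:1],
                           dt_ms=traces.dt_ms, positions_um=traces.positions_um[:1],
                           f0=traces.f0)
        movie, labels = render_movie(sub, cfg2)
        mask = labels == 1
        np.testing.assert_allclose(movie[:, mask].mean(axis=1), sub.raw_f[0],
                                   rtol=1e-6)

    def test_fifteen_disjoint_masks(self):
        cfg = GeneratorConfig(n_dendrites=15, seed=0)
        raw = np.full((15, 10), 100.0)
        ts = __import__("cfcalcium.synthgen", fromlist=["TraceSet"]).TraceSet(
            dff=raw / 100 - 1, raw_f=raw, dt_ms=64.0,
            positions_um=np.arange(15.0), f0=100.0)
        movie, labels = render_movie(ts, cfg)
        labs = [l for l in np.unique(labels) if l != 0]
        assert len(labs) == 15
        total = sum((labels == l).sum() for l in labs)
        assert total == (labels > 0).sum()  # disjoint stripes

    def test_too_many_dendrites_rejected(self):
        cfg = GeneratorConfig(n_dendrites=60, seed=0)
        raw = np.full((60, 4), 100.0)
        from cfcalcium.synthgen import TraceSet
        ts = TraceSet(dff=raw / 100 - 1, raw_f=raw, dt_ms=64.0,
                      positions_um=np.arange(60.0), f0=100.0)
        with pytest.raises(ValueError, match="do not fit"):
            render_movie(ts, cfg)

    def test_mask_mean_noise_shrinks_with_mask_size(self):
        from cfcalcium.synthgen import TraceSet
        cfg = GeneratorConfig(n_dendrites=1, pixel_noise_sd=4.0, seed=12)
        raw = np.full((1, 400), 100.0)
        ts = TraceSet(dff=raw / 100 - 1, raw_f=raw, dt_ms=64.0,
                      positions_um=np.zeros(1), f0=100.0)
        movie, labels = render_movie(ts, cfg, stripe_width=2)
        mask = labels == 1
        resid = movie[:, mask].mean(axis=1) - 100.0
        expected_se = 4.0 / np.sqrt(mask.sum())
        assert resid.std() == pytest.approx(expected_se, rel=0.25)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError, match="non-decreasing"):
        cfg = GeneratorConfig()
        cfg.evoked_prob = dict(cfg.evoked_prob, d2=0.1)
        cfg.validate()
    with pytest.raises(ValueError, match="refractory"):
        GeneratorConfig(refractory_ms=5000.0).validate()
    with pytest.raises(ValueError, match="outside"):
        cfg = GeneratorConfig()
        cfg.evoked_prob = dict(cfg.evoked_prob, d4=1.4)
        cfg.validate()
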