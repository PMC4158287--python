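"""Coactivation, joint probabilities, extra synchrony, distance correlation."""

import numpy as np
import pandas as pd
import pytest

from cfcalcium.synchrony import (coactivation_fraction, extra_synchrony,
                                 pair_joint_probability, responsive_dendrites,
                                 spont_distance_correlation)
from cfcalcium.synthgen import (GeneratorConfig, StimulusProtocol,
                                make_protocol, simulate_events)


def _protocol(n=20, cond="d1"):
    rows = [{"trial_id": i, "onset_s": 2.0 + 4.0 * i, "condition": cond,
             "laterality": "ipsi"} for i in range(n)]
    return StimulusProtocol(pd.DataFrame(rows), iti_s=4.0)


def _events(protocol, responses: dict[int, list[int]]):
    """responses: dendrite -> trial ids with an evoked event."""
    onset = dict(zip(protocol.trials["trial_id"], protocol.trials["onset_s"]))
    rows = []
    for did, tids in responses.items():
        for t in tids:
            rows.append({"dendrite_id": did, "peak_index": 0,
                         "peak_time_ms": onset[t] * 1000.0 + 100.0,
                         "peak_amp": 1.0, "template_score": 0.9,
                         "label": "evoked", "trial_id": t, "condition": "d1",
                         "onset_latency_ms": 90.0})
    cols = ["dendrite_id", "peak_index", "peak_time_ms", "peak_amp",
            "template_score", "label", "trial_id", "condition",
            "onset_latency_ms"]
    return pd.DataFrame(rows, columns=cols)


class TestCoactivation:
    def test_three_of_six_gives_half(self):
        prot = _protocol(1)
        ev = _events(prot, {0: [0], 1: [0], 2: [0], 3: [], 4: [], 5: []})
        out = coactivation_fraction(ev, prot, np.arange(6))
        assert out["fraction"].iloc[0] == pytest.approx(0.5)

    def test_no_events_zero(self):
        prot = _protocol(2)
        ev = _events(prot, {i: [] for i in range(6)})
        out = coactivation_fraction(ev, prot, np.arange(6))
        assert (out["fraction"] == 0).all()

    def test_fewer_than_six_responsive_excluded(self):
        prot = _protocol(2)
        ev = _events(prot, {0: [0], 1: [0]})
        with pytest.raises(ValueError, match="excluded"):
            coactivation_fraction(ev, prot, np.arange(5))


class TestJointProbability:
    def test_saturation(self):
        prot = _protocol(10)
        all_trials = list(range(10))
        ev = _events(prot, {0: all_trials, 1: all_trials})
        out = pair_joint_probability(ev, prot, np.array([0, 1]))
        d1 = out[out["condition"] == "d1"].iloc[0]
        assert d1["measured_joint"] == 1.0
        assert d1["independent_joint"] == 1.0

    def test_disjoint_responses(self):
        prot = _protocol(10)
        ev = _events(prot, {0: [0, 1, 2, 3, 4], 1: [5, 6, 7, 8, 9]})
        out = pair_joint_probability(ev, prot, np.array([0, 1]))
        d1 = out[out["condition"] == "d1"].iloc[0]
        assert d1["measured_joint"] == 0.0
        assert d1["independent_joint"] == pytest.approx(0.25)

    def test_frechet_bounds_on_simulation(self, frame_analysis, frame_session):
        cfg, prot, truth, _ = frame_session
        out = pair_joint_probability(frame_analysis.events, prot,
                                     np.arange(cfg.n_dendrites))
        lo = np.maximum(0.0, out["p_i"] + out["p_j"] - 1.0)
        hi = np.minimum(out["p_i"], out["p_j"])
        assert (out["measured_joint"] >= lo - 1e-12).all()
        assert (out["measured_joint"] <= hi + 1e-12).all()


class TestExtraSynchrony:
    def test_perfectly_yoked_pair(self):
        prot = _protocol(10)
        ev = _events(prot, {0: [0, 1, 2, 3, 4], 1: [0, 1, 2, 3, 4]})
        pairs = pair_joint_probability(ev, prot, np.array([0, 1]))
        out = extra_synchrony(pairs)
        d1 = out[out["condition"] == "d1"].iloc[0]
        assert d1["mean_extra_pct"] == pytest.approx(25.0)

    def test_independent_generator_near_zero(self):
        zeros = {c: 0.0 for c in ["d1", "d2", "d3", "d4", "p1", "p2"]}
        cfg = GeneratorConfig(n_dendrites=8, trials_per_condition=100,
                              graded_fraction=1.0, shared_drive_prob=zeros,
                              spont_sync_strength=0.0, seed=31)
        prot = make_protocol(cfg, "duration")
        truth = simulate_events(cfg, prot)
        ev = truth.events[truth.events["origin"] == "evoked"].copy()
        ev["label"] = "evoked"
        ev["peak_time_ms"] = ev["time_ms"] + cfg.kernel_rise_ms
        pairs = pair_joint_probability(ev, prot, np.arange(8))
        out = extra_synchrony(pairs)
        for _, row in out[out["condition"] != "sp"].iterrows():
            assert abs(row["mean_extra_pct"]) < 2.0 * row["sem"] + 0.5

    def test_shared_state_closed_form(self):
        conds = ["d1", "d2", "d3", "d4", "p1", "p2"]
        cfg = GeneratorConfig(
            n_dendrites=2, trials_per_condition=4000, graded_fraction=1.0,
            evoked_prob={c: 0.5 for c in conds},
            shared_drive_prob={c: 0.4 for c in conds}, shared_boost=1.4,
            spont_sync_strength=0.0, spont_rate_hz=1e-6, seed=13)
        prot = make_protocol(cfg, "pressure")
        truth = simulate_events(cfg, prot)
        ev = truth.events[truth.events["origin"] == "evoked"].copy()
        ev["label"] = "evoked"
        ev["peak_time_ms"] = ev["time_ms"] + cfg.kernel_rise_ms
        pairs = pair_joint_probability(ev, prot, np.arange(2))
        out = extra_synchrony(pairs)
        # closed form: q/(1-q) * (boost-1)^2 * p_i p_j = (0.4/0.6)*0.16*0.25
        expected = 100.0 * (0.4 / 0.6) * 0.16 * 0.25
        got = out[out["condition"] != "sp"]["mean_extra_pct"]
        assert got.mean() == pytest.approx(expected, abs=1.2)

    def test_extra_synchrony_increases_with_shared_drive(self):
        conds = ["d1", "d2", "d3", "d4", "p1", "p2"]
        cfg = GeneratorConfig(
            n_dendrites=6, trials_per_condition=800, graded_fraction=1.0,
            evoked_prob={c: 0.6 for c in conds},
            shared_drive_prob=dict(zip(conds, [0.05, 0.2, 0.4, 0.6, 0.1, 0.5])),
            shared_boost=1.5, spont_sync_strength=0.0, spont_rate_hz=1e-6,
            seed=17)
        prot = make_protocol(cfg, "duration")
        truth = simulate_events(cfg, prot)
        ev = truth.events[truth.events["origin"] == "evoked"].copy()
        ev["label"] = "evoked"
        ev["peak_time_ms"] = ev["time_ms"] + cfg.kernel_rise_ms
        pairs = pair_joint_probability(ev, prot, np.arange(6))
        out = extra_synchrony(pairs).set_index("condition")
        vals = [out.loc[c, "mean_extra_pct"] for c in ["d1", "d2", "d3", "d4"]]
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestDistanceCorrelation:
    def _events_from_frames(self, frames_by_dendrite, dt=64.0):
        rows = []
        for did, frames in frames_by_dendrite.items():
            for f in frames:
                rows.append({"dendrite_id": did, "peak_index": f,
                             "peak_time_ms": f * dt, "peak_amp": 1.0,
                             "template_score": 0.9, "label": "spontaneous",
                             "trial_id": -1, "condition": "sp",
                             "onset_latency_ms": np.nan})
        return pd.DataFrame(rows)

    def test_identical_rasters_r_one(self):
        frames = [3, 50, 120, 200, 390]
        ev = self._events_from_frames({0: frames, 1: frames})
        out = spont_distance_correlation(ev, {0: 0.0, 1: 0.0}, 64.0 * 500,
                                         64.0, n_shuffles=5)
        assert out["pearson_r"].iloc[0] == pytest.approx(1.0)

    def test_shuffle_destroys_alignment(self):
        rng = np.random.default_rng(0)
        f0 = sorted(rng.choice(2000, 120, replace=False))
        ev = self._events_from_frames({0: f0, 1: f0})
        out = spont_distance_correlation(ev, {0: 0.0, 1: 30.0}, 64.0 * 2000,
                                         64.0, n_shuffles=200,
                                         rng=np.random.default_rng(1))
        assert abs(out["shuffled_r"].iloc[0]) < 0.02

    def test_correlation_decays_with_distance(self):
        cfg = GeneratorConfig(n_dendrites=10, trials_per_condition=0,
                              duration_s=900.0, spont_sync_scale_um=40.0,
                              spont_sync_strength=0.6, seed=23)
        prot = make_protocol(cfg, "duration")
        truth = simulate_events(cfg, prot)
        ev = truth.events.copy()
        ev["label"] = "spontaneous"
        ev["peak_time_ms"] = ev["time_ms"] + cfg.kernel_rise_ms
        pos = {int(r["dendrite_id"]): float(r["position_um"])
               for _, r in truth.dendrites.iterrows()}
        out = spont_distance_correlation(ev, pos, truth.duration_ms, 64.0,
                                         n_shuffles=5,
                                         rng=np.random.default_rng(2))
        near = out[out["distance_um"] <= 30.0]["pearson_r"].mean()
        far = out[out["distance_um"] >= 100.0]["pearson_r"].mean()
        assert near > far

    def test_responsive_dendrite_screen(self, frame_analysis, frame_session):
        cfg, prot, truth, _ = frame_session
        resp = responsive_dendrites(frame_analysis.events, prot)
        # default config: every dendrite responds at d4 with p >= 0.05 step
        # profile; graded ones respond strongly — most should be responsive
        assert len(resp) >= cfg.n_dendrites - 2
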