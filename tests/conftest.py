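"""Shared fixtures: small synthetic sessions reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from cfcalcium.pipeline import analyze_experiment
from cfcalcium.synthgen import (GeneratorConfig, make_protocol, render_traces,
                                simulate_events)


@pytest.fixture(scope="session")
def frame_session():
    """One frame-rate duration-mode recording with ground truth (6 dendrites)."""
    cfg = GeneratorConfig(n_dendrites=6, trials_per_condition=35, seed=123)
    rng = np.random.default_rng(cfg.seed)
    protocol = make_protocol(cfg, "duration", rng)
    truth = simulate_events(cfg, protocol, rng)
    traces = render_traces(truth, cfg, protocol, mode="frame", rng=rng)
    return cfg, protocol, truth, traces


@pytest.fixture(scope="session")
def frame_analysis(frame_session):
    cfg, protocol, truth, traces = frame_session
    return analyze_experiment(traces, protocol, cfg, truth=truth)


@pytest.fixture(scope="session")
def dense_session():
    """One dense-rendered (1 ms) duration-mode recording with ground truth."""
    cfg = GeneratorConfig(n_dendrites=6, trials_per_condition=35, seed=321)
    rng = np.random.default_rng(cfg.seed)
    protocol = make_protocol(cfg, "duration", rng)
    truth = simulate_events(cfg, protocol, rng)
    traces = render_traces(truth, cfg, protocol, mode="dense", rng=rng)
    return cfg, protocol, truth, traces


@pytest.fixture(scope="session")
def dense_analysis(dense_session):
    cfg, protocol, truth, traces = dense_session
    return analyze_experiment(traces, protocol, cfg, truth=truth)
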