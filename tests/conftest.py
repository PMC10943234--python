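"""Shared fixtures: seeded synthetic sessions reused across test modules.

Everything is generated at run time from fixed seeds; no data files.
"""

import numpy as np
import pytest

from freezescore import FreezingModel, MixtureConfig
from freezescore.synthetic import (
    SceneConfig,
    render_session,
    sample_schedule,
    simulate_trace,
)
from freezescore.trace import compute_similarity_trace


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="module")
def sim_session():
    """A 2-minute simulated (direct-trace) session with ground truth."""
    cfg = SceneConfig(seed=7)
    sched = sample_schedule(cfg, duration_s=120.0)
    trace = simulate_trace(sched, seed=7, source_id="sim7")
    return sched, trace


@pytest.fixture(scope="module")
def sim_results(sim_session):
    """Fitted results for the simulated session (reduced restarts)."""
    _, trace = sim_session
    model = FreezingModel(trace, mixture=MixtureConfig(n_restarts=60, seed=0))
    return model.fit()


@pytest.fixture(scope="session")
def rendered_session():
    """A 60-s rendered session: (schedule, frames, trace)."""
    cfg = SceneConfig(seed=5)
    sched = sample_schedule(cfg, duration_s=60.0)
    seq = render_session(sched, cfg, source_id="rend5")
    trace = compute_similarity_trace(seq)
    return sched, seq, trace
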