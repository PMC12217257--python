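"""Shared fixtures.

The expensive end-to-end artifacts (a trained toy segmenter and the
detection pipeline built on it) are session-scoped so the recovery and
determinism tests share one training run.
"""

from __future__ import annotations

import numpy as np
import pytest

from histodiff.diffusion import linear_schedule


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def schedule_t2():
    """The two-step schedule with β = [0.1, 0.2] (ᾱ = [0.9, 0.72])."""
    return linear_schedule(2, 0.1, 0.2)


@pytest.fixture()
def toy_schedule():
    """Toy-profile schedule: 50 steps, hot enough that ᾱ_T ≈ 0."""
    return linear_schedule(50, 1e-4, 0.3)


@pytest.fixture(scope="session")
def toy_pipeline(tmp_path_factory):
    """One full toy-profile pipeline run: simulate → train-seg →
    segment → train-detect → evaluate, plus the fusion ablation table."""
    from histodiff.config import load_config, run_pipeline

    out = tmp_path_factory.mktemp("toy_run")
    cfg = load_config(None, overrides={"profile": "toy", "seed": 0,
                                       "paths": {"out_dir": str(out)}})
    result = run_pipeline(cfg, include_ablation=True)
    return result
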