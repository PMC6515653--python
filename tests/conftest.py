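"""Shared fixtures: the 20-seed synthetic experiment and hypothesis profile.

The 20-run synthetic experiment is expensive (~2-3 minutes), so it runs
once per session and is shared by every test that scores recovery metrics
against the generators' truth tables.
"""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from sugarminer.pipeline import evaluate_run, run_synthetic
from sugarminer.simulate import SynthConfig

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

N_SEEDS = 20


@pytest.fixture(scope="session")
def twenty_runs():
    """(metrics, result, truth) per seed 0..19 at default SynthConfig."""
    out = []
    for seed in range(N_SEEDS):
        result, truth = run_synthetic(SynthConfig(seed=seed))
        out.append((evaluate_run(result, truth), result, truth))
    return out


@pytest.fixture(scope="session")
def seed0_run(twenty_runs):
    """The seed-0 run: (metrics, RunResult, truth table)."""
    return twenty_runs[0]
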