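"""Shared fixtures: pipeline runs per seed and a small generated study."""

from __future__ import annotations

import time

import pytest
from hypothesis import HealthCheck, settings

from monometh import PipelineConfig, SimConfig, run_pipeline
from monometh.simulate import simulate_all

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

SEEDS = tuple(range(1, 11))


def _run_seed(seed: int):
    t0 = time.monotonic()
    result = run_pipeline(
        PipelineConfig(seed=seed, outdir=f"scratch/_ts{seed}"), write=False)
    return result, time.monotonic() - t0


@pytest.fixture(scope="session")
def default_result():
    """The seed-fixed default study (seed 1)."""
    result, elapsed = _run_seed(1)
    result.elapsed_s = elapsed
    return result


@pytest.fixture(scope="session")
def study_results(default_result):
    """Full in-memory pipeline results for seeds 1..10, with wall times."""
    results = {1: default_result}
    elapsed = {1: default_result.elapsed_s}
    for seed in SEEDS[1:]:
        results[seed], elapsed[seed] = _run_seed(seed)
    results["elapsed"] = elapsed
    return results


def small_sim_config(seed: int = 7) -> SimConfig:
    return SimConfig(
        n_cpgs=300, n_gain_diff=30, n_loss_diff=12,
        activation_counts={"M_LPS_IFNg": (1, 2), "M_IL4": (0, 1),
                           "M_oxLDL": (0, 0), "M_acLDL": (0, 0)},
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_study():
    """A 300-CpG study for fast structural tests."""
    return simulate_all(small_sim_config())
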