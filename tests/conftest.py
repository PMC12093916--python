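"""Shared fixtures: small seeded cohorts reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from cogtrace.decision import Action
from cogtrace.evaluate import (
    ExperimentConfig,
    build_maps,
    trace_cohort,
)
from cogtrace.synthetic import PlayerProfile, simulate_cohort


@pytest.fixture(scope="session")
def fixed_policy_cohort():
    """20 fixed-policy players (10 critical-first, 10 in-order) on a shared
    12-map sequence: the parameter-recovery cohort."""
    seed = 1
    seq = np.random.SeedSequence(seed)
    maps_seed, _, _ = seq.spawn(3)
    maps = build_maps(["easy", "medium", "hard"], 4, np.random.default_rng(maps_seed))
    profiles = [
        PlayerProfile(
            policy="fixed",
            fixed_action=Action.CRITICAL_FIRST if i < 10 else Action.IN_ORDER,
            rehearsal_diligence=0.5,
            player_id=f"player-{i:03d}",
        )
        for i in range(20)
    ]
    return simulate_cohort(maps, profiles, seed=seed)


@pytest.fixture(scope="session")
def fixed_policy_records(fixed_policy_cohort):
    """Model + baseline predictions for the fixed-policy cohort."""
    return trace_cohort(fixed_policy_cohort, ExperimentConfig(seed=1))


@pytest.fixture(scope="session")
def small_experiment():
    """A compact end-to-end experiment bundle (mixed cohort)."""
    from cogtrace.evaluate import run_experiment

    return run_experiment(ExperimentConfig(seed=5, n_players=8, map_cycles=2))
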