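"""Forgetting probability, odds-sum cognitive load, and event-driven
victim memory."""

from __future__ import annotations

import math

import numpy as np
import pytest

from cogtrace.load import (
    EventKind,
    LoadParams,
    VictimEvent,
    VictimMemory,
    apply_event,
    chunk_load,
    correlate,
    count_errors,
    load_series,
    p_forget,
    total_load,
    victim_forgetting_profile,
)

P = LoadParams(tau=0.0, t_scale=0.25)


def ev(time, vid, kind, vtype="noncritical"):
    return VictimEvent(time, vid, vtype, kind, location="r0")


def replay(events):
    memory = VictimMemory()
    for e in sorted(events, key=lambda x: x.time):
        apply_event(memory, e)
    return memory


class TestForgettingProbability:
    def test_half_at_threshold(self):
        assert p_forget(P.tau, P) == 0.5

    def test_one_scale_below_threshold(self):
        assert p_forget(P.tau - P.t_scale, P) == pytest.approx(1 / (1 + math.exp(-1)))

    def test_vanishes_for_strong_memories(self):
        assert p_forget(P.tau + 50.0, P) < 1e-80
        assert p_forget(1e9, P) == 0.0

    def test_strictly_decreasing_in_activation(self):
        grid = np.linspace(-5, 5, 200)
        vals = p_forget(grid, P)
        assert np.all(np.diff(vals) < 0)


class TestChunkLoad:
    def test_unit_load_at_threshold(self):
        for tau, t in [(0.0, 0.25), (1.3, 0.1), (-2.0, 2.0)]:
            params = LoadParams(tau=tau, t_scale=t)
            assert chunk_load(tau, params) == 1.0

    def test_one_scale_above_threshold(self):
        assert chunk_load(P.tau + P.t_scale, P) == pytest.approx(math.exp(-1))

    def test_equals_odds_of_forgetting(self):
        grid = np.linspace(-6, 6, 500)
        p = p_forget(grid, P)
        # retention probability 1 - p equals p_forget of the activation
        # reflected about the threshold (logistic symmetry); evaluating it
        # that way avoids cancellation where p is within 1e-16 of 1
        retained = p_forget(2 * P.tau - grid, P)
        assert np.allclose(chunk_load(grid, P), p / retained, rtol=1e-12, atol=1e-12)


class TestVictimMemoryEvents:
    def test_encounter_then_mark_rehearses(self):
        memory = replay([ev(0.0, "v1", EventKind.ENCOUNTER), ev(5.0, "v1", EventKind.MARK)])
        state = memory.states["v1"]
        assert state.presentation_times == [0.0, 5.0]
        assert state.active

    def test_evacuated_victim_contributes_no_load(self):
        events = [
            ev(0.0, "v1", EventKind.ENCOUNTER),
            ev(5.0, "v1", EventKind.TRIAGE),
            ev(10.0, "v1", EventKind.EVACUATE),
        ]
        memory = replay(events)
        assert total_load(memory, 20.0, P) == 0.0

    def test_processing_before_encounter_rejected(self):
        with pytest.raises(ValueError, match="before ENCOUNTER"):
            replay([ev(1.0, "v1", EventKind.TRIAGE)])

    def test_duplicate_encounter_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            replay([ev(0.0, "v1", EventKind.ENCOUNTER), ev(1.0, "v1", EventKind.ENCOUNTER)])

    def test_event_after_evacuate_rejected(self):
        with pytest.raises(ValueError, match="after EVACUATE"):
            replay(
                [
                    ev(0.0, "v1", EventKind.ENCOUNTER),
                    ev(1.0, "v1", EventKind.EVACUATE),
                    ev(2.0, "v1", EventKind.MARK),
                ]
            )


class TestTotalLoad:
    def test_empty_memory_zero_load(self):
        assert total_load(VictimMemory(), 100.0, P) == 0.0

    def test_two_chunks_at_threshold_sum_to_two(self):
        # single presentation at lag 4 with d=0.5 gives A = ln(4^-0.5)
        activation = math.log(4**-0.5)
        params = LoadParams(tau=activation, t_scale=0.25)
        memory = replay(
            [ev(0.0, "v1", EventKind.ENCOUNTER), ev(0.0, "v2", EventKind.ENCOUNTER)]
        )
        assert total_load(memory, 4.0, params) == pytest.approx(2.0)

    def test_additive_over_disjoint_chunk_sets(self):
        m1 = replay([ev(0.0, "v1", EventKind.ENCOUNTER)])
        m2 = replay([ev(3.0, "v2", EventKind.ENCOUNTER), ev(5.0, "v2", EventKind.MARK)])
        union = replay(
            [
                ev(0.0, "v1", EventKind.ENCOUNTER),
                ev(3.0, "v2", EventKind.ENCOUNTER),
                ev(5.0, "v2", EventKind.MARK),
            ]
        )
        now = 30.0
        assert total_load(union, now, P) == pytest.approx(
            total_load(m1, now, P) + total_load(m2, now, P)
        )

    def test_rehearsal_strictly_lowers_load(self):
        base = [ev(0.0, "v1", EventKind.ENCOUNTER)]
        rehearsed = base + [ev(10.0, "v1", EventKind.MARK)]
        assert total_load(replay(rehearsed), 20.0, P) < total_load(replay(base), 20.0, P)

    def test_evacuation_removes_exactly_that_chunks_term(self):
        events = [
            ev(0.0, "v1", EventKind.ENCOUNTER),
            ev(2.0, "v2", EventKind.ENCOUNTER),
        ]
        now = 50.0
        before = total_load(replay(events), now, P)
        after = total_load(replay(events + [ev(10.0, "v2", EventKind.EVACUATE)]), now, P)
        only_v1 = total_load(replay(events[:1]), now, P)
        assert after == pytest.approx(only_v1)
        assert before > after


class TestLoadSeries:
    def test_empty_stream_all_zero(self):
        series = load_series([], 60.0, P, sample_dt=5.0)
        assert np.all(series.load_values == 0.0)
        assert series.max_load == 0.0 and series.mean_load == 0.0

    def test_load_rises_as_unrehearsed_memory_decays(self):
        series = load_series([ev(0.0, "v1", EventKind.ENCOUNTER)], 120.0, P)
        late = series.load_values[series.sample_times > 10.0]
        assert np.all(np.diff(late) > 0)

    def test_max_at_least_mean(self, small_experiment):
        table = small_experiment.run_table
        assert (table["max_load"] >= table["mean_load"]).all()

    def test_events_beyond_duration_rejected(self):
        with pytest.raises(ValueError, match="beyond run_duration"):
            load_series([ev(10.0, "v1", EventKind.ENCOUNTER)], 5.0, P)


class TestForgettingProfile:
    def test_quickly_evacuated_victim_has_low_mean_p(self):
        fast = [
            ev(0.0, "v1", EventKind.ENCOUNTER),
            ev(1.0, "v1", EventKind.TRIAGE),
            ev(2.0, "v1", EventKind.EVACUATE),
        ]
        slow = [ev(0.0, "v2", EventKind.ENCOUNTER)]
        params = LoadParams(tau=-1.0, t_scale=0.5)
        profile = victim_forgetting_profile(fast + slow, 300.0, params)
        by_id = profile.set_index("victim_id")
        assert by_id.loc["v1", "mean_p_forget"] < by_id.loc["v2", "mean_p_forget"]
        assert bool(by_id.loc["v1", "processed"]) and not bool(by_id.loc["v2", "processed"])

    def test_all_processed_leaves_no_unprocessed_group(self):
        events = [
            ev(0.0, "v1", EventKind.ENCOUNTER),
            ev(1.0, "v1", EventKind.EVACUATE),
        ]
        profile = victim_forgetting_profile(events, 100.0, P)
        assert profile["processed"].all()


class TestErrorsAndCorrelation:
    def test_unevacuated_victims_are_errors(self):
        events = []
        for i in range(5):
            events.append(ev(float(i), f"v{i}", EventKind.ENCOUNTER))
        for i in range(3):
            events.append(ev(10.0 + i, f"v{i}", EventKind.EVACUATE))
        assert count_errors(events, 100.0) == 2
        assert count_errors([], 100.0) == 0

    def test_zero_variance_rejected(self):
        import pandas as pd

        df = pd.DataFrame(
            {"max_load": [1.0] * 5, "mean_load": [1.0] * 5,
             "errors": [2] * 5, "score": [10.0] * 5}
        )
        with pytest.raises(ValueError, match="zero variance"):
            correlate(df)

    def test_too_few_runs_rejected(self):
        import pandas as pd

        df = pd.DataFrame(
            {"max_load": [1.0, 2.0], "mean_load": [1.0, 2.0],
             "errors": [0, 1], "score": [5.0, 6.0]}
        )
        with pytest.raises(ValueError, match="at least 3"):
            correlate(df)
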