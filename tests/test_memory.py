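"""Memory engine: activation, retrieval probabilities, blending."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cogtrace.memory import (
    ActivationResult,
    Instance,
    InstanceStore,
    MemoryParams,
    Probe,
    SimilaritySpec,
    activation,
    base_level_activation,
    blend,
    blend_minimize,
    mismatch_penalty,
    retrieval_probabilities,
)

SIM = SimilaritySpec(
    kinds={"x": "numeric", "a": "symbolic"},
    numeric_ranges={"x": 4.0},
)


def make_instance(x=2.0, a="L", times=(0.0,), points=10.0):
    return Instance({"x": x, "a": a}, {"points": points}, list(times))


def grid_blend(values, probs):
    """Independent oracle: three-stage grid minimization of the blending
    loss sum_i P_i * ((V - v_i)/span)^2."""
    values = np.asarray(values, float)
    probs = np.asarray(probs, float)
    lo, hi = values.min(), values.max()
    if lo == hi:
        return float(lo)
    span = hi - lo
    for _ in range(3):
        grid = np.linspace(lo, hi, 2001)
        obj = probs @ (((grid[None, :] - values[:, None]) / span) ** 2)
        i = int(np.argmin(obj))
        lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, 2000)]
    return float((lo + hi) / 2)


class TestBaseLevel:
    @pytest.mark.parametrize(
        "times, now, expected",
        [
            ([0.0], 1.0, 0.0),  # unit lag, single term
            ([0.0, 3.0], 4.0, math.log(1.0 + 0.5)),  # lags 4 and 1
            ([0.0], 100.0, math.log(100**-0.5)),
        ],
    )
    def test_power_law_values(self, times, now, expected):
        assert base_level_activation(times, now, 0.5) == pytest.approx(expected, abs=1e-12)

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError, match="no presentations"):
            base_level_activation([], 1.0)

    def test_non_causal_presentation_rejected(self):
        with pytest.raises(ValueError, match="non-causal"):
            base_level_activation([2.0], 1.0)

    @given(
        times=st.lists(st.floats(0.0, 99.0), min_size=1, max_size=8),
        extra=st.floats(0.0, 99.0),
    )
    @settings(derandomize=True, max_examples=100)
    def test_rehearsal_raises_activation(self, times, extra):
        now = 100.0
        before = base_level_activation(times, now)
        after = base_level_activation(times + [extra], now)
        assert after > before


class TestPartialMatching:
    def test_exact_match_is_zero(self):
        inst = make_instance()
        probe = Probe({"x": 2.0, "a": "L"}, SIM)
        assert mismatch_penalty(inst, probe, 1.0) == 0.0

    def test_symbolic_mismatch_is_minus_ten(self):
        inst = make_instance(a="L")
        probe = Probe({"a": "R"}, SIM)
        assert mismatch_penalty(inst, probe, 1.0) == -10.0

    def test_numeric_linear_scaling(self):
        inst = make_instance(x=2.0)
        probe = Probe({"x": 4.0}, SIM)
        assert mismatch_penalty(inst, probe, 1.0) == pytest.approx(-0.5)

    def test_numeric_similarity_saturates_at_minus_one(self):
        inst = make_instance(x=0.0)
        probe = Probe({"x": 100.0}, SIM)
        assert mismatch_penalty(inst, probe, 1.0) == -1.0

    def test_missing_attribute_is_incomparable(self):
        inst = Instance({"x": 1.0}, {"points": 0.0}, [0.0])
        probe = Probe({"a": "L"}, SIM)
        with pytest.raises(ValueError, match="incomparable"):
            mismatch_penalty(inst, probe, 1.0)


class TestActivation:
    def test_all_terms_zero(self):
        inst = make_instance(times=[0.0])
        probe = Probe({"x": 2.0, "a": "L"}, SIM)
        params = MemoryParams(noise_s=0.0)
        result = activation(inst, probe, params, now=1.0)
        assert result.total == 0.0
        assert result.noise == 0.0

    def test_components_sum(self):
        inst = make_instance(times=[0.0, 3.0], a="L")
        probe = Probe({"x": 2.0, "a": "R"}, SIM)
        params = MemoryParams(noise_s=0.0)
        result = activation(inst, probe, params, now=4.0)
        assert result.total == pytest.approx(math.log(1.5) - 10.0)
        assert result.total == result.base_level + result.mismatch + result.noise

    def test_noise_follows_logistic_distribution(self):
        inst = make_instance(times=[0.0])
        probe = Probe({"x": 2.0, "a": "L"}, SIM)
        params = MemoryParams(noise_s=0.1)
        rng = np.random.default_rng(7)
        draws = np.array(
            [activation(inst, probe, params, 1.0, noise_source=rng).noise
             for _ in range(10_000)]
        )
        assert abs(draws.mean()) < 0.01
        # quartiles of logistic(0, 0.1) are at +/- 0.1*ln(3)
        q25, q75 = np.quantile(draws, [0.25, 0.75])
        assert q75 == pytest.approx(0.1 * math.log(3), abs=0.01)
        assert q25 == pytest.approx(-0.1 * math.log(3), abs=0.01)
        assert stats.kstest(draws, stats.logistic(scale=0.1).cdf).pvalue > 0.01

    def test_seeded_noise_reproducible(self):
        inst = make_instance(times=[0.0])
        probe = Probe({"x": 2.0, "a": "L"}, SIM)
        params = MemoryParams(noise_s=0.1)
        runs = [
            [activation(inst, probe, params, 1.0,
                        noise_source=np.random.default_rng(3)).total
             for _ in range(5)]
            for _ in range(2)
        ]
        assert runs[0] == runs[1]


class TestRetrievalProbabilities:
    @pytest.mark.parametrize(
        "acts, t, expected",
        [
            ([1.0, 1.0], 1.0, [0.5, 0.5]),
            ([3.0], 1.0, [1.0]),
            ([math.log(2), 0.0], 1.0, [2 / 3, 1 / 3]),
        ],
    )
    def test_boltzmann_values(self, acts, t, expected):
        assert retrieval_probabilities(acts, t) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            retrieval_probabilities([])

    @given(
        acts=st.lists(st.floats(-50, 50), min_size=1, max_size=12),
        shift=st.floats(-100, 100),
    )
    @settings(derandomize=True, max_examples=200)
    def test_normalization_and_shift_invariance(self, acts, shift):
        p = retrieval_probabilities(acts)
        assert abs(p.sum() - 1.0) < 1e-12
        p_shifted = retrieval_probabilities([a + shift for a in acts])
        assert np.allclose(p, p_shifted, atol=1e-12)

    def test_temperature_drives_probabilities_toward_uniform(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            acts = rng.normal(0, 2, size=6)
            gaps = [
                np.ptp(retrieval_probabilities(acts, t))
                for t in (0.5, 1.0, 2.0, 5.0, 20.0)
            ]
            assert all(b <= a + 1e-12 for a, b in zip(gaps, gaps[1:]))


class TestBlending:
    @pytest.mark.parametrize(
        "values, probs, expected",
        [
            ([10.0, 20.0], [0.5, 0.5], 15.0),
            ([7.0, 7.0, 7.0], [0.2, 0.3, 0.5], 7.0),
            ([0.0, 0.0, 30.0], [0.25, 0.25, 0.5], 15.0),
        ],
    )
    def test_weighted_average(self, values, probs, expected):
        assert blend(values, probs) == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length mismatch"):
            blend([1.0], [0.5, 0.5])

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError, match="not normalized"):
            blend([1.0, 2.0], [0.5, 0.6])

    @given(
        values=st.lists(st.floats(-100, 100), min_size=1, max_size=10),
        raw=st.lists(st.floats(0.01, 1.0), min_size=1, max_size=10),
    )
    @settings(derandomize=True, max_examples=200)
    def test_closed_form_matches_grid_oracle(self, values, raw):
        n = min(len(values), len(raw))
        values, raw = values[:n], np.asarray(raw[:n])
        probs = raw / raw.sum()
        closed = blend(values, probs)
        assert closed == pytest.approx(grid_blend(values, probs), abs=1e-4)
        assert blend_minimize(values, probs) == pytest.approx(closed, abs=1e-6)


class TestInstanceStore:
    def test_add_then_reinforce(self):
        store = InstanceStore()
        idx = store.add({"a": "L"}, {"points": 1.0}, now=0.0)
        store.reinforce(idx, now=5.0)
        assert store[idx].presentation_times == [0.0, 5.0]

    def test_reinforce_backwards_in_time_rejected(self):
        store = InstanceStore()
        idx = store.add({"a": "L"}, {"points": 1.0}, now=5.0)
        with pytest.raises(ValueError, match="time regression"):
            store.reinforce(idx, now=1.0)

    def test_identical_experiences_stay_distinct(self):
        store = InstanceStore()
        store.add({"a": "L"}, {"points": 1.0}, now=0.0)
        store.add({"a": "L"}, {"points": 1.0}, now=1.0)
        assert len(store) == 2

    def test_activation_result_invariant(self):
        r = ActivationResult(base_level=0.3, mismatch=-0.2, noise=0.05)
        assert r.total == pytest.approx(0.15)
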