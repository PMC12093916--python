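"""Instance-based declarative memory: activation, retrieval, and blending.

This module implements the subsymbolic memory machinery of an ACT-R style
instance-based learning (IBL) model.  An *instance* (chunk) stores the
context attributes of an experience, the outcomes that followed, and the
times at which the experience was presented or rehearsed.  Three quantities
govern how instances influence later judgements:

* **activation** -- base-level strength from the power law of practice and
  forgetting, ``ln(sum_j (now - t_j)^-d)``, plus a partial-matching penalty
  ``MP * sum_k Sim(v_k, c_k)`` against the current probe, plus transient
  logistic noise;
* **retrieval probability** -- a Boltzmann (softmax) function of activation
  at temperature ``t``;
* **blending** -- the consensus value minimizing the retrieval-probability
  weighted squared similarity loss, which for numeric values under a linear
  similarity reduces to the probability-weighted average.

All functions are pure except for the :class:`InstanceStore` bookkeeping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "MemoryParams",
    "SimilaritySpec",
    "Instance",
    "Probe",
    "ActivationResult",
    "InstanceStore",
    "base_level_activation",
    "mismatch_penalty",
    "activation",
    "retrieval_probabilities",
    "blend",
    "blend_minimize",
    "blended_outcomes",
]

AttributeValue = float | int | str

#: default similarity for two distinct symbolic values (maximal mismatch)
SYMBOLIC_MISMATCH = -10.0


@dataclass(frozen=True)
class MemoryParams:
    """Subsymbolic parameters of the declarative memory.

    decay
        base-level decay exponent ``d`` (default 0.5).
    mismatch_penalty
        scale ``MP`` of the partial-matching term (default 1.0).
    noise_s
        scale of the zero-mean logistic transient activation noise
        (default 0.1); 0 turns retrieval deterministic.
    temperature
        Boltzmann temperature of the retrieval-probability softmax
        (default 1.0).
    rng_seed
        seed for the noise stream when no generator is supplied.
    """

    decay: float = 0.5
    mismatch_penalty: float = 1.0
    noise_s: float = 0.1
    temperature: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.decay > 0:
            raise ValueError("decay must be > 0")
        if self.mismatch_penalty < 0:
            raise ValueError("mismatch_penalty must be >= 0")
        if self.noise_s < 0:
            raise ValueError("noise_s must be >= 0")
        if not self.temperature > 0:
            raise ValueError("temperature must be > 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)


@dataclass(frozen=True)
class SimilaritySpec:
    """Per-attribute similarity definitions used by partial matching.

    ``kinds`` maps each attribute name to ``"numeric"`` or ``"symbolic"``.
    Numeric similarity is linearly scaled from 0.0 (exact match) down to
    -1.0 (maximal mismatch): ``-min(|a - b| / range, 1)``.  Symbolic
    similarity is 0.0 on identity and ``symbolic_mismatch`` otherwise.
    """

    kinds: Mapping[str, str]
    numeric_ranges: Mapping[str, float] = field(default_factory=dict)
    symbolic_mismatch: float = SYMBOLIC_MISMATCH

    def __post_init__(self) -> None:
        for name, kind in self.kinds.items():
            if kind not in ("numeric", "symbolic"):
                raise ValueError(f"unknown similarity kind {kind!r} for {name!r}")
            if kind == "numeric":
                rng = self.numeric_ranges.get(name)
                if rng is None or not rng > 0:
                    raise ValueError(f"numeric attribute {name!r} needs a positive range")
        if self.symbolic_mismatch > 0:
            raise ValueError("symbolic_mismatch must be <= 0")

    def similarity(self, name: str, stored: AttributeValue, probe: AttributeValue) -> float:
        kind = self.kinds.get(name)
        if kind is None:
            raise KeyError(f"no similarity kind for attribute {name!r}")
        if kind == "symbolic":
            return 0.0 if stored == probe else self.symbolic_mismatch
        return -min(abs(float(stored) - float(probe)) / self.numeric_ranges[name], 1.0)


@dataclass
class Instance:
    """One stored experience: context, outcomes, and presentation history."""

    attributes: dict[str, AttributeValue]
    outcomes: dict[str, float]
    presentation_times: list[float]

    def __post_init__(self) -> None:
        if not self.presentation_times:
            raise ValueError("no presentations")
        if any(b < a for a, b in zip(self.presentation_times, self.presentation_times[1:])):
            raise ValueError("presentation times must be non-decreasing")
        for name, value in self.outcomes.items():
            if not math.isfinite(value):
                raise ValueError(f"outcome {name!r} is not finite")


@dataclass(frozen=True)
class Probe:
    """The current context offered for partial matching."""

    attributes: Mapping[str, AttributeValue]
    similarity: SimilaritySpec

    def __post_init__(self) -> None:
        for name in self.attributes:
            if name not in self.similarity.kinds:
                raise ValueError(f"probe attribute {name!r} has no similarity kind")


@dataclass(frozen=True)
class ActivationResult:
    """Decomposed activation of one instance against one probe."""

    base_level: float
    mismatch: float
    noise: float

    @property
    def total(self) -> float:
        return self.base_level + self.mismatch + self.noise


def base_level_activation(
    presentation_times: Sequence[float], now: float, decay: float = 0.5
) -> float:
    """Base-level activation ``ln(sum_j (now - t_j)^-d)``.

    Recency and frequency of presentations enter through the power law of
    practice and forgetting.  Every presentation must strictly precede
    ``now``.
    """
    times = np.asarray(presentation_times, dtype=float)
    if times.size == 0:
        raise ValueError("no presentations")
    lags = now - times
    if np.any(lags <= 0):
        raise ValueError("non-causal presentation")
    return float(np.log(np.sum(lags**-decay)))


def mismatch_penalty(instance: Instance, probe: Probe, mp: float) -> float:
    """Partial-matching term ``MP * sum_k Sim(v_k, c_k)`` (always <= 0)."""
    total = 0.0
    for name, probe_value in probe.attributes.items():
        if name not in instance.attributes:
            raise ValueError(f"incomparable instance: missing attribute {name!r}")
        total += probe.similarity.similarity(name, instance.attributes[name], probe_value)
    return mp * total


def activation(
    instance: Instance,
    probe: Probe,
    params: MemoryParams,
    now: float,
    noise_source: np.random.Generator | None = None,
    noise: float | None = None,
) -> ActivationResult:
    """Full activation: base level + partial matching + transient noise.

    ``noise`` overrides sampling (used when one noise draw must be shared
    across several probes within a single decision); otherwise a fresh value
    is drawn from ``logistic(0, noise_s)``.
    """
    base = base_level_activation(instance.presentation_times, now, params.decay)
    mismatch = mismatch_penalty(instance, probe, params.mismatch_penalty)
    if noise is None:
        if params.noise_s == 0:
            noise = 0.0
        else:
            rng = noise_source if noise_source is not None else params.rng()
            noise = float(rng.logistic(0.0, params.noise_s))
    return ActivationResult(base_level=base, mismatch=mismatch, noise=noise)


def retrieval_probabilities(
    activations: Sequence[float], temperature: float = 1.0
) -> np.ndarray:
    """Boltzmann retrieval probabilities ``e^(A_i/t) / sum_j e^(A_j/t)``.

    Computed with max-activation subtraction, which is algebraically exact
    and overflow-safe.
    """
    acts = np.asarray(activations, dtype=float)
    if acts.size == 0:
        raise ValueError("empty activation list")
    if not temperature > 0:
        raise ValueError("temperature must be > 0")
    scaled = acts / temperature
    scaled -= scaled.max()
    weights = np.exp(scaled)
    return weights / weights.sum()


def _check_blend_args(values: Sequence[float], probabilities: Sequence[float]):
    vals = np.asarray(values, dtype=float)
    probs = np.asarray(probabilities, dtype=float)
    if vals.shape != probs.shape:
        raise ValueError("length mismatch between values and probabilities")
    if vals.size == 0:
        raise ValueError("nothing to blend")
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("probabilities not normalized")
    return vals, probs

def blend(values: Sequence[float], probabilities: Sequence[float]) -> float:
    """Blended (consensus) value of numeric outcomes.

    The blended value minimizes ``sum_i P_i * Sim(V, v_i)^2``.  With a
    linear numeric similarity the minimizer is the retrieval-probability
    weighted average, computed here in closed form.
    """
    vals, probs = _check_blend_args(values, probabilities)
    return float(np.dot(probs, vals))


def blend_minimize(values: Sequence[float], probabilities: Sequence[float]) -> float:
    """Blended value via numeric minimization of the similarity loss.

    Generic path kept alongside :func:`blend`; it must (and does) agree
    with the closed form to high precision for linear numeric similarity.
    """
    vals, probs = _check_blend_args(values, probabilities)
    lo, hi = float(vals.min()), float(vals.max())
    if lo == hi:
        return lo
    span = hi - lo

    def loss(v: float) -> float:
        return float(np.dot(probs, ((v - vals) / span) ** 2))

    res = optimize.minimize_scalar(loss, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    return float(res.x)


class InstanceStore:
    """Ordered collection of instances with add/reinforce bookkeeping.

    Repeated identical experiences deliberately create separate instances
    (no chunk merging); reinforcement appends a presentation to an existing
    instance and is used for rehearsal dynamics.
    """

    def __init__(self) -> None:
        self._instances: list[Instance] = []

    def __len__(self) -> int:
        return len(self._instances)

    def __iter__(self) -> Iterator[Instance]:
        return iter(self._instances)

    def __getitem__(self, idx: int) -> Instance:
        return self._instances[idx]

    @property
    def instances(self) -> list[Instance]:
        return self._instances

    def add(
        self,
        attributes: Mapping[str, AttributeValue],
        outcomes: Mapping[str, float],
        now: float,
    ) -> int:
        """Store a new instance presented at ``now``; returns its id."""
        inst = Instance(dict(attributes), dict(outcomes), [float(now)])
        self._instances.append(inst)
        return len(self._instances) - 1

    def reinforce(self, instance_id: int, now: float) -> None:
        """Append a rehearsal at ``now`` to an existing instance."""
        inst = self._instances[instance_id]
        if now < inst.presentation_times[-1]:
            raise ValueError("time regression: rehearsal precedes last presentation")
        inst.presentation_times.append(float(now))

    def activations(
        self,
        probe: Probe,
        params: MemoryParams,
        now: float,
        noise: np.ndarray | None = None,
        noise_source: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Total activation of every stored instance against ``probe``."""
        if noise is None:
            if params.noise_s == 0:
                noise = np.zeros(len(self._instances))
            else:
                rng = noise_source if noise_source is not None else params.rng()
                noise = rng.logistic(0.0, params.noise_s, size=len(self._instances))
        return np.array(
            [
                activation(inst, probe, params, now, noise=float(eps)).total
                for inst, eps in zip(self._instances, noise)
            ]
        )


def blended_outcomes(
    store: InstanceStore,
    probe: Probe,
    params: MemoryParams,
    now: float,
    outcome_names: Iterable[str],
    noise: np.ndarray | None = None,
    noise_source: np.random.Generator | None = None,
) -> dict[str, float]:
    """Blend each outcome slot independently across all stored instances."""
    if len(store) == 0:
        raise ValueError("empty store")
    acts = store.activations(probe, params, now, noise=noise, noise_source=noise_source)
    probs = retrieval_probabilities(acts, params.temperature)
    return {
        name: blend([inst.outcomes[name] for inst in store], probs)
        for name in outcome_names
    }
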