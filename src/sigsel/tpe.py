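"""A compact tree-structured Parzen estimator (TPE) hyperparameter sampler.

Sequential model-based optimization: after a random start-up phase, the
observed trials are split into a "good" quantile (fraction ``gamma`` with
the lowest objective values) and the rest. Each parameter gets two Parzen
densities, l(x) fitted to good trials and g(x) to the rest (Gaussian
mixtures for numeric parameters, smoothed category counts for categorical
ones, each blended with a uniform prior). Candidates drawn from l(x) are
ranked by the expected-improvement surrogate log l(x) - log g(x), and the
best candidate becomes the next trial. Parameter densities are factorized
independently, the standard TPE simplification.

Deterministic under ``seed``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Union

import numpy as np

from .errors import UsageError


@dataclass(frozen=True)
class Int:
    low: int
    high: int  # inclusive

    def __post_init__(self):
        if self.low > self.high:
            raise UsageError(f"empty Int range ({self.low}, {self.high})")


@dataclass(frozen=True)
class Float:
    low: float
    high: float
    log: bool = False

    def __post_init__(self):
        if not (self.low < self.high):
            raise UsageError(f"empty Float range ({self.low}, {self.high})")
        if self.log and self.low <= 0:
            raise UsageError("log-scaled Float needs a positive lower bound")


@dataclass(frozen=True)
class Categorical:
    choices: tuple

    def __init__(self, choices):
        object.__setattr__(self, "choices", tuple(choices))
        if not self.choices:
            raise UsageError("Categorical needs at least one choice")


ParamSpec = Union[Int, Float, Categorical]
SearchSpace = Mapping[str, ParamSpec]


@dataclass
class Trial:
    params: dict
    value: float
    number: int = 0


@dataclass
class TPEResult:
    best_params: dict
    best_value: float
    trials: list[Trial] = field(default_factory=list)


def _to_unit(spec: ParamSpec, x) -> float:
    if isinstance(spec, Int):
        return (x - spec.low) / max(spec.high - spec.low, 1)
    if spec.log:
        return (math.log(x) - math.log(spec.low)) / (math.log(spec.high) - math.log(spec.low))
    return (x - spec.low) / (spec.high - spec.low)


def _from_unit(spec: ParamSpec, u: float):
    u = min(max(u, 0.0), 1.0)
    if isinstance(spec, Int):
        return int(round(spec.low + u * (spec.high - spec.low)))
    if spec.log:
        return math.exp(math.log(spec.low) + u * (math.log(spec.high) - math.log(spec.low)))
    return spec.low + u * (spec.high - spec.low)


def _sample_uniform(spec: ParamSpec, rng: np.random.Generator):
    if isinstance(spec, Categorical):
        return spec.choices[rng.integers(len(spec.choices))]
    return _from_unit(spec, rng.random())


def _parzen_logpdf(obs: np.ndarray, sigma: float, x: np.ndarray) -> np.ndarray:
    """log density of a unit-interval Parzen mixture with a uniform prior
    component (weight 1/(n+1) each for n observations plus the prior)."""
    n = obs.size
    # uniform prior on [0, 1] has density 1
    comps = np.full((x.size, n + 1), -np.inf)
    comps[:, 0] = 0.0
    if n:
        diff = (x[:, None] - obs[None, :]) / sigma
        comps[:, 1:] = -0.5 * diff**2 - math.log(sigma * math.sqrt(2 * math.pi))
    m = comps.max(axis=1)
    return m + np.log(np.exp(comps - m[:, None]).sum(axis=1)) - math.log(n + 1)


def _bandwidth(obs: np.ndarray) -> float:
    n = obs.size
    spread = max(float(obs.std()), 0.05)
    return max(1.06 * spread * n ** (-0.2), 0.03)


class TPESampler:
    """Minimizing TPE sampler over a factorized search space."""

    def __init__(
        self,
        space: SearchSpace,
        seed: int = 0,
        n_startup: int = 10,
        gamma: float = 0.25,
        n_candidates: int = 24,
    ) -> None:
        if not space:
            raise UsageError("search space is empty")
        self.space = dict(space)
        self.rng = np.random.default_rng(seed)
        self.n_startup = n_startup
        self.gamma = gamma
        self.n_candidates = n_candidates
        self.trials: list[Trial] = []

    def suggest(self) -> dict:
        if len(self.trials) < self.n_startup:
            return {k: _sample_uniform(spec, self.rng) for k, spec in self.space.items()}

        order = sorted(self.trials, key=lambda t: t.value)
        n_good = max(1, math.ceil(self.gamma * len(order)))
        good, bad = order[:n_good], order[n_good:] or order[:1]

        candidates: list[dict] = [{} for _ in range(self.n_candidates)]
        scores = np.zeros(self.n_candidates)
        for name, spec in self.space.items():
            if isinstance(spec, Categorical):
                k = len(spec.choices)
                cg = np.array(
                    [sum(1 for t in good if t.params[name] == c) for c in spec.choices], float
                )
                cb = np.array(
                    [sum(1 for t in bad if t.params[name] == c) for c in spec.choices], float
                )
                pg = (cg + 1) / (cg.sum() + k)
                pb = (cb + 1) / (cb.sum() + k)
                idx = self.rng.choice(k, size=self.n_candidates, p=pg)
                for i, ci in enumerate(idx):
                    candidates[i][name] = spec.choices[ci]
                scores += np.log(pg[idx]) - np.log(pb[idx])
            else:
                og = np.array([_to_unit(spec, t.params[name]) for t in good])
                ob = np.array([_to_unit(spec, t.params[name]) for t in bad])
                sg, sb = _bandwidth(og), _bandwidth(ob)
                # draw from l(x): pick a good observation (or the prior) and jitter
                pick = self.rng.integers(-1, og.size, size=self.n_candidates)
                u = np.where(
                    pick < 0,
                    self.rng.random(self.n_candidates),
                    np.clip(og[np.maximum(pick, 0)] + self.rng.normal(0, sg, self.n_candidates), 0, 1),
                )
                scores += _parzen_logpdf(og, sg, u) - _parzen_logpdf(ob, sb, u)
                for i, ui in enumerate(u):
                    candidates[i][name] = _from_unit(spec, float(ui))
        best = int(np.argmax(scores))
        return candidates[best]

    def tell(self, params: dict, value: float) -> None:
        self.trials.append(Trial(params=dict(params), value=float(value), number=len(self.trials)))


def minimize(
    objective: Callable[[dict], float],
    space: SearchSpace,
    n_trials: int = 50,
    seed: int = 0,
    n_startup: int = 10,
) -> TPEResult:
    """Run ``n_trials`` of TPE minimization of ``objective`` over ``space``."""
    if n_trials < 1:
        raise UsageError("n_trials must be >= 1")
    sampler = TPESampler(space, seed=seed, n_startup=min(n_startup, n_trials))
    for _ in range(n_trials):
        params = sampler.suggest()
        value = objective(params)
        sampler.tell(params, value)
    best = min(sampler.trials, key=lambda t: t.value)
    return TPEResult(best_params=dict(best.params), best_value=best.value, trials=sampler.trials)
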