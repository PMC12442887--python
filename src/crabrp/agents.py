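"""Behavioral decision policies.

Agents turn the observable state of a round into press requests.  Four
policies are provided:

* :class:`IdealObserver` — plays optimally on visible-hider rounds.
* :class:`LapseAgent` — an ideal observer that misses each jump with
  probability ``p_lapse`` and then acts on a stale hider position
  (an attention-failure model of medium-round errors).
* :class:`RandomAgent` — picks a target trail uniformly at random
  (spontaneous decisions with no visual evidence).
* :class:`AccumulatorAgent` — presses when a leaky stochastic evidence
  accumulator crosses threshold; the latent accumulator trajectory is kept
  so the EEG generator can emit a readiness potential time-locked to the
  press.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .game_engine import (
    TRAIL_MIDDLE,
    TRAIL_UPPER,
    ActionRequest,
    GameConfig,
    Observation,
)
from .synthetic_eeg import AccumulatorParams, condition_evidence, simulate_accumulator

__all__ = [
    "AgentParams",
    "IdealObserver",
    "LapseAgent",
    "RandomAgent",
    "AccumulatorAgent",
    "AccumulatorRoundRecord",
    "make_agent",
]


@dataclass
class AgentParams:
    """Parameters shared by the agent policies.

    Reaction times are Gaussian (``rt_mean_ms``, ``rt_sd_ms``) truncated
    below at ``rt_min_ms``, applied after the decisive observation.
    """

    kind: str = "ideal"
    p_lapse: float = 0.1
    rt_mean_ms: float = 400.0
    rt_sd_ms: float = 100.0
    rt_min_ms: float = 100.0
    press_window_ms: Optional[tuple[float, float]] = None  # RandomAgent
    accumulator: AccumulatorParams = field(default_factory=AccumulatorParams)

    def __post_init__(self) -> None:
        if self.kind not in ("ideal", "lapse", "random", "accumulator"):
            raise ValueError(f"unknown agent kind {self.kind!r}")
        if not (0.0 <= self.p_lapse <= 1.0):
            raise ValueError(f"p_lapse must be in [0, 1], got {self.p_lapse}")
        if self.rt_mean_ms <= 0:
            raise ValueError(f"rt_mean_ms must be > 0, got {self.rt_mean_ms}")


def _draw_rt(params: AgentParams, rng: np.random.Generator) -> float:
    """Truncated-Gaussian reaction time (rejection sampling)."""
    for _ in range(1000):
        rt = rng.normal(params.rt_mean_ms, params.rt_sd_ms)
        if rt >= params.rt_min_ms:
            return float(rt)
    return params.rt_min_ms


def _press_toward(trail: int, t_ms: float) -> list[ActionRequest]:
    """Request moving the actor from the middle trail toward ``trail``."""
    if trail == TRAIL_MIDDLE:
        return []
    action = "up" if trail == TRAIL_UPPER else "down"
    return [ActionRequest(t_ms, action)]


class IdealObserver:
    """Optimal policy for rounds with a visible hider.

    Easy: the final location is known at onset, so the press follows one
    reaction time after the round starts (no press if the hider sits on
    the middle trail).  Medium: the agent waits until the last possible
    jump has occurred (the end of the jump window) and presses toward the
    hider's final trail.  Presses are clamped to the walk end, which the
    arbitration still accepts, so this policy wins every round.
    """

    def __init__(self, params: Optional[AgentParams] = None) -> None:
        self.params = params or AgentParams(kind="ideal")

    def requests(self, obs: Observation, config: GameConfig,
                 rng: np.random.Generator) -> list[ActionRequest]:
        if not obs.hider_visible:
            raise ValueError("ideal observer has no policy for invisible hiders")
        rt = _draw_rt(self.params, rng)
        if obs.condition == "easy":
            t = min(rt, obs.walk_duration_ms)
            return _press_toward(obs.initial_hider_trail, t)
        deadline = float(config.jump_window_ms[1])
        t = min(deadline + rt, obs.walk_duration_ms)
        return _press_toward(obs.final_trail(), t)


class LapseAgent:
    """Ideal observer with attention lapses on medium rounds.

    Each jump is missed independently with probability ``p_lapse``; the
    believed hider position is the destination of the last *observed*
    jump (or the initial trail if every jump was missed).
    """

    def __init__(self, params: AgentParams) -> None:
        self.params = params

    def requests(self, obs: Observation, config: GameConfig,
                 rng: np.random.Generator) -> list[ActionRequest]:
        if not obs.hider_visible:
            raise ValueError("lapse agent needs a visible hider")
        believed = obs.initial_hider_trail
        for jump in obs.jump_schedule:
            if rng.random() >= self.params.p_lapse:
                believed = jump.to_trail
        rt = _draw_rt(self.params, rng)
        deadline = float(config.jump_window_ms[1])
        t = min(deadline + rt, obs.walk_duration_ms)
        return _press_toward(believed, t)


class RandomAgent:
    """Uniform spontaneous policy: target trail uniform over the three
    trails (middle means no press), press time uniform over a window."""

    def __init__(self, params: Optional[AgentParams] = None) -> None:
        self.params = params or AgentParams(kind="random")

    def requests(self, obs: Observation, config: GameConfig,
                 rng: np.random.Generator) -> list[ActionRequest]:
        target = int(rng.integers(0, config.n_trails))
        window = self.params.press_window_ms or (0.0, obs.walk_duration_ms)
        t = float(rng.uniform(window[0], window[1]))
        return _press_toward(target, t)


@dataclass
class AccumulatorRoundRecord:
    """Latent accumulator state of one round, kept for EEG synthesis."""

    condition: str
    times_ms: np.ndarray
    trajectory: np.ndarray
    crossing_ms: Optional[float]
    pressed: bool


class AccumulatorAgent:
    """Evidence-accumulation policy.

    The accumulator integrates the condition's evidence input (strong step
    in easy rounds, discrete pulses at onset and at each jump in medium
    rounds, nothing beyond baseline urgency in hard rounds).  A press is
    issued at the first threshold crossing; the button (what-decision)
    follows the observed hider trail when visible, otherwise a fair coin.
    If the accumulator never crosses before the walk ends, no press is
    made (a press-free round).

    Latent trajectories are appended to :attr:`rounds` in play order.
    """

    def __init__(self, params: AgentParams) -> None:
        self.params = params
        self.rounds: list[AccumulatorRoundRecord] = []

    def requests(self, obs: Observation, config: GameConfig,
                 rng: np.random.Generator) -> list[ActionRequest]:
        acc = self.params.accumulator
        evidence = condition_evidence(obs, acc)
        times, x, crossing = simulate_accumulator(
            acc, evidence, obs.walk_duration_ms, rng
        )
        requests: list[ActionRequest] = []
        pressed = False
        if crossing is not None:
            if obs.hider_visible:
                target = obs.trail_at(crossing)
                requests = _press_toward(target, crossing)
            else:
                action = "up" if rng.random() < 0.5 else "down"
                requests = [ActionRequest(crossing, action)]
            pressed = bool(requests)
        self.rounds.append(
            AccumulatorRoundRecord(obs.condition, times, x, crossing, pressed)
        )
        return requests


def make_agent(params: AgentParams):
    """Instantiate the policy selected by ``params.kind``."""
    return {
        "ideal": IdealObserver,
        "lapse": LapseAgent,
        "random": RandomAgent,
        "accumulator": AccumulatorAgent,
    }[params.kind](params)
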