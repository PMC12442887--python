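"""Hide-and-seek game engine: trial generation, hider dynamics, action
arbitration and scoring.

The game is a series of rounds in which an actor avatar walks for a fixed
duration (default 5,000 ms) from the middle of three parallel trails toward
one of three hiding spots, while a hider character sits on one trail and —
depending on condition — may jump between neighboring trails.  The player
(an agent policy, see :mod:`crabrp.agents`) may change the actor's
trajectory from the middle trail to the upper or lower trail, but only a
limited number of times per round (default once).

Conditions:

``easy``
    Hider visible and static: its final location is known from round onset.
``medium``
    Hider visible but jumps up to ``max_jumps`` times between neighboring
    trails at random times; the final location is only certain after the
    last possible jump.
``hard``
    Hider invisible: the player must decide with no visual evidence.

Everything is deterministic given a :class:`numpy.random.Generator`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "CONDITIONS",
    "TRAIL_UPPER",
    "TRAIL_MIDDLE",
    "TRAIL_LOWER",
    "EVENT_CODES",
    "GameConfig",
    "TrialSpec",
    "Jump",
    "RoundResult",
    "Event",
    "EventStream",
    "SessionResult",
    "ConfigError",
    "make_trial",
    "hider_trail_at",
    "run_round",
    "run_session",
]

CONDITIONS = ("easy", "medium", "hard")

# Trail indices. The actor starts on the middle trail every round.
TRAIL_UPPER = 0
TRAIL_MIDDLE = 1
TRAIL_LOWER = 2

# Trigger codes embedded in event streams and EEG marker files.
# TRIAL_ONSET is 10 + condition index (easy=0, medium=1, hard=2).
EVENT_CODES = {
    "TRIAL_ONSET_EASY": 10,
    "TRIAL_ONSET_MEDIUM": 11,
    "TRIAL_ONSET_HARD": 12,
    "JUMP": 20,
    "PRESS_UP": 31,
    "PRESS_DOWN": 32,
    "WALK_END": 40,
    "LOSS": 50,
    "WIN": 51,
}

ONSET_CODE_BY_CONDITION = {c: 10 + i for i, c in enumerate(CONDITIONS)}
CONDITION_BY_ONSET_CODE = {v: k for k, v in ONSET_CODE_BY_CONDITION.items()}
PRESS_CODES = (EVENT_CODES["PRESS_UP"], EVENT_CODES["PRESS_DOWN"])


class ConfigError(ValueError):
    """Raised when a configuration value violates an invariant."""


@dataclass
class GameConfig:
    """Game rules and timing constants.

    Parameters
    ----------
    walk_duration_ms
        Duration of the actor's walk in each round (the round length).
    n_trails
        Number of trails; the paradigm is defined for exactly 3.
    max_jumps
        Maximum number of hider jumps in medium/hard rounds.
    jump_window_ms
        (earliest, latest) time a jump may occur.
    min_interjump_ms
        Minimum spacing between consecutive jumps.
    allow_zero_jumps
        If True the medium/hard jump count is drawn from {0..max_jumps};
        by default from {1..max_jumps} so a medium round is never
        indistinguishable from an easy one.
    max_trajectory_changes
        Number of accepted trajectory changes per round (default 1).
    trials_per_condition
        Rounds per condition in a session.
    iti_ms
        Inter-trial interval separating consecutive rounds.
    seed
        Default seed used when no generator is supplied.
    """

    walk_duration_ms: int = 5000
    n_trails: int = 3
    max_jumps: int = 3
    jump_window_ms: tuple[int, int] = (500, 4500)
    min_interjump_ms: int = 300
    allow_zero_jumps: bool = False
    max_trajectory_changes: int = 1
    trials_per_condition: int = 80
    iti_ms: int = 3000
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.walk_duration_ms <= 0:
            raise ConfigError(f"walk_duration_ms must be > 0, got {self.walk_duration_ms}")
        if self.n_trails != 3:
            raise ConfigError(f"n_trails must be 3, got {self.n_trails}")
        lo, hi = self.jump_window_ms
        if not (0 <= lo < hi <= self.walk_duration_ms):
            raise ConfigError(
                f"jump_window_ms must satisfy 0 <= earliest < latest <= "
                f"walk_duration_ms, got {self.jump_window_ms}"
            )
        if self.max_jumps < 0:
            raise ConfigError(f"max_jumps must be >= 0, got {self.max_jumps}")
        if self.min_interjump_ms < 0:
            raise ConfigError(f"min_interjump_ms must be >= 0, got {self.min_interjump_ms}")
        if self.max_trajectory_changes < 0:
            raise ConfigError(
                f"max_trajectory_changes must be >= 0, got {self.max_trajectory_changes}"
            )
        if self.trials_per_condition < 0:
            raise ConfigError(
                f"trials_per_condition must be >= 0, got {self.trials_per_condition}"
            )
        if self.iti_ms < 0:
            raise ConfigError(f"iti_ms must be >= 0, got {self.iti_ms}")
        # The largest jump count must fit in the window with min spacing.
        n = self.max_jumps
        if n >= 2 and (hi - lo) < (n - 1) * self.min_interjump_ms:
            raise ConfigError(
                f"jump_window_ms {self.jump_window_ms} too narrow for "
                f"{n} jumps spaced >= {self.min_interjump_ms} ms"
            )

    @property
    def jump_count_choices(self) -> tuple[int, ...]:
        lo = 0 if (self.allow_zero_jumps or self.max_jumps == 0) else 1
        return tuple(range(lo, self.max_jumps + 1))


@dataclass(frozen=True)
class Jump:
    time_ms: float
    from_trail: int
    to_trail: int


@dataclass(frozen=True)
class TrialSpec:
    """One hide-and-seek round: condition, hider trajectory, visibility."""

    condition: str
    initial_hider_trail: int
    jump_schedule: tuple[Jump, ...]
    hider_visible: bool

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.condition == "easy" and self.jump_schedule:
            raise ValueError("easy trials must have an empty jump schedule")
        if self.hider_visible != (self.condition != "hard"):
            raise ValueError("hider is visible iff the condition is easy or medium")
        trail = self.initial_hider_trail
        last_t = -np.inf
        for j in self.jump_schedule:
            if j.from_trail != trail:
                raise ValueError(f"jump {j} does not start on current trail {trail}")
            if abs(j.to_trail - j.from_trail) != 1:
                raise ValueError(f"jump {j} is not between neighboring trails")
            if j.time_ms <= last_t:
                raise ValueError("jump times must be strictly increasing")
            last_t = j.time_ms
            trail = j.to_trail


@dataclass(frozen=True)
class RoundResult:
    press_time_ms: Optional[float]
    action: str  # "up", "down" or "none"
    actor_final_trail: int
    hider_final_trail: int
    points: int
    n_rejected_actions: int


@dataclass(frozen=True)
class Event:
    time_ms: float
    code: int
    condition: str


@dataclass
class EventStream:
    """Time-stamped trigger codes for one or more rounds.

    Times are milliseconds; within a session they are absolute (offset by
    round start). Invariant: non-decreasing times.
    """

    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [e.time_ms for e in self.events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be non-decreasing")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def times_ms(self) -> np.ndarray:
        return np.array([e.time_ms for e in self.events], dtype=float)

    def codes(self) -> np.ndarray:
        return np.array([e.code for e in self.events], dtype=int)

    def select(self, codes: Sequence[int]) -> "EventStream":
        codes = set(codes)
        return EventStream([e for e in self.events if e.code in codes])

    def shifted(self, offset_ms: float) -> "EventStream":
        return EventStream(
            [Event(e.time_ms + offset_ms, e.code, e.condition) for e in self.events]
        )


@dataclass
class SessionResult:
    trials: list[TrialSpec]
    results: list[RoundResult]
    events: EventStream
    success_rates: dict[str, float]
    round_onsets_ms: list[float]


# ---------------------------------------------------------------------------
# Trial generation
# ---------------------------------------------------------------------------

def _neighbor(trail: int, rng: np.random.Generator) -> int:
    """A uniformly chosen neighboring trail (0<->1, 1<->2, never 0<->2)."""
    if trail == TRAIL_MIDDLE:
        return int(rng.choice([TRAIL_UPPER, TRAIL_LOWER]))
    return TRAIL_MIDDLE


def _jump_times(n: int, window: tuple[float, float], min_gap: float,
                rng: np.random.Generator) -> np.ndarray:
    """n jump times uniform over the window subject to pairwise min spacing.

    Exact sampling by the spacing transform: draw n uniforms on the
    shrunk interval, sort, then re-inflate by i*min_gap.
    """
    if n == 0:
        return np.empty(0)
    lo, hi = window
    span = hi - lo - (n - 1) * min_gap
    if span < 0:
        raise ConfigError(
            f"jump window {window} cannot fit {n} jumps spaced >= {min_gap} ms"
        )
    u = np.sort(rng.uniform(0.0, span, size=n))
    return lo + u + min_gap * np.arange(n)


def make_trial(config: GameConfig, condition: str, rng: np.random.Generator) -> TrialSpec:
    """Generate one round: hider start, jump schedule, visibility.

    Easy rounds never jump; medium and hard rounds share the same jump
    statistics (count drawn from ``config.jump_count_choices``, times
    uniform within the jump window with minimum spacing, destinations
    always a neighbor of the current trail), but the hider is invisible in
    hard rounds.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    initial = int(rng.integers(0, config.n_trails))
    if condition == "easy":
        return TrialSpec("easy", initial, (), True)

    choices = config.jump_count_choices
    n_jumps = int(rng.choice(choices)) if choices else 0
    times = _jump_times(
        n_jumps, tuple(map(float, config.jump_window_ms)),
        float(config.min_interjump_ms), rng,
    )
    schedule = []
    trail = initial
    for t in times:
        nxt = _neighbor(trail, rng)
        schedule.append(Jump(float(t), trail, nxt))
        trail = nxt
    return TrialSpec(condition, initial, tuple(schedule), condition != "hard")


def hider_trail_at(trial: TrialSpec, t_ms: float,
                   walk_duration_ms: float = 5000.0) -> int:
    """Hider trail at time ``t_ms`` (piecewise constant, left-closed).

    A jump takes effect exactly at its timestamp.
    """
    if not (0.0 <= t_ms <= walk_duration_ms):
        raise ValueError(f"t={t_ms} ms outside round [0, {walk_duration_ms}]")
    trail = trial.initial_hider_trail
    for j in trial.jump_schedule:
        if j.time_ms <= t_ms:
            trail = j.to_trail
        else:
            break
    return trail


# ---------------------------------------------------------------------------
# Round execution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ActionRequest:
    """A press request from an agent: when and which button."""

    time_ms: float
    action: str  # "up" or "down"

    def __post_init__(self) -> None:
        if self.action not in ("up", "down"):
            raise ValueError(f"action must be 'up' or 'down', got {self.action!r}")


@dataclass(frozen=True)
class Observation:
    """What an agent may see: hider info is withheld on hard rounds."""

    condition: str
    walk_duration_ms: float
    hider_visible: bool
    initial_hider_trail: Optional[int]
    jump_schedule: Optional[tuple[Jump, ...]]

    def trail_at(self, t_ms: float) -> int:
        if not self.hider_visible:
            raise ValueError("hider is not visible in this round")
        trail = self.initial_hider_trail
        for j in self.jump_schedule:
            if j.time_ms <= t_ms:
                trail = j.to_trail
        return trail

    def final_trail(self) -> int:
        return self.trail_at(self.walk_duration_ms)


def observe(trial: TrialSpec, config: GameConfig) -> Observation:
    if trial.hider_visible:
        return Observation(trial.condition, float(config.walk_duration_ms), True,
                           trial.initial_hider_trail, trial.jump_schedule)
    return Observation(trial.condition, float(config.walk_duration_ms), False, None, None)


_ACTION_CODE = {"up": EVENT_CODES["PRESS_UP"], "down": EVENT_CODES["PRESS_DOWN"]}


def run_round(trial: TrialSpec, agent, config: GameConfig,
              rng: np.random.Generator) -> tuple[RoundResult, EventStream]:
    """Play one round: query the agent, arbitrate presses, score.

    The agent is queried once with the observable state and returns a list
    of :class:`ActionRequest`. Requests are processed in time order; the
    first ``max_trajectory_changes`` requests falling inside
    ``[0, walk_duration_ms]`` are accepted (the trail change is treated as
    instantaneous), every other request is rejected and counted.
    """
    walk = float(config.walk_duration_ms)
    requests = sorted(agent.requests(observe(trial, config), config, rng),
                      key=lambda r: r.time_ms)

    accepted: list[ActionRequest] = []
    n_rejected = 0
    actor = TRAIL_MIDDLE
    for req in requests:
        in_time = 0.0 <= req.time_ms <= walk
        target = actor - 1 if req.action == "up" else actor + 1
        feasible = 0 <= target < config.n_trails
        if in_time and feasible and len(accepted) < config.max_trajectory_changes:
            accepted.append(req)
            actor = target
        else:
            n_rejected += 1

    hider_final = hider_trail_at(trial, walk, walk)
    points = int(actor == hider_final)
    if accepted:
        first = accepted[0]
        press_time: Optional[float] = first.time_ms
        action = first.action
    else:
        press_time, action = None, "none"

    cond = trial.condition
    events = [Event(0.0, ONSET_CODE_BY_CONDITION[cond], cond)]
    events += [Event(j.time_ms, EVENT_CODES["JUMP"], cond) for j in trial.jump_schedule]
    events += [Event(r.time_ms, _ACTION_CODE[r.action], cond) for r in accepted]
    events.sort(key=lambda e: e.time_ms)
    events.append(Event(walk, EVENT_CODES["WALK_END"], cond))
    events.append(Event(walk, EVENT_CODES["WIN" if points else "LOSS"], cond))

    result = RoundResult(press_time, action, actor, hider_final, points, n_rejected)
    return result, EventStream(events)


def run_session(config: GameConfig, agent, rng: np.random.Generator,
                conditions: Sequence[str] = CONDITIONS) -> SessionResult:
    """Run a full session: interleaved conditions in randomized order.

    Round ``k`` starts at ``k * (walk_duration_ms + iti_ms)``; event times
    in the returned stream are session-absolute milliseconds.  Success
    rates are reported per condition present in ``conditions``.
    """
    if config.trials_per_condition < 1:
        raise ConfigError("trials_per_condition must be >= 1 for a session")
    order = [c for c in conditions for _ in range(config.trials_per_condition)]
    order = [order[i] for i in rng.permutation(len(order))]

    period = float(config.walk_duration_ms + config.iti_ms)
    trials: list[TrialSpec] = []
    results: list[RoundResult] = []
    all_events: list[Event] = []
    onsets: list[float] = []
    for k, cond in enumerate(order):
        trial = make_trial(config, cond, rng)
        result, ev = run_round(trial, agent, config, rng)
        t0 = k * period
        onsets.append(t0)
        trials.append(trial)
        results.append(result)
        all_events.extend(ev.shifted(t0).events)

    rates = {
        c: float(np.mean([r.points for t, r in zip(trials, results) if t.condition == c]))
        for c in conditions
    }
    return SessionResult(trials, results, EventStream(all_events), rates, onsets)
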