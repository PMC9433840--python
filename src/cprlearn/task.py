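"""Common-pool-resource lake environment.

Three harvesters share a fish stock with a hard capacity. Each trial every
harvester removes fish with a net of size 1, 2 or 3 (the two co-players may
jointly remove 2-6 fish); the surviving stock then grows by a factor of 1.5,
rounded down and capped at capacity. A session ends when the lake is fished
out or after a fixed number of trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "TaskConfig",
    "LakeState",
    "TrialRecord",
    "replenish",
    "allocate_catch",
    "run_session",
    "DEFAULT_CONFIG",
]


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the lake game.

    Defaults are the study design: capacity 16, growth x1.5 floored,
    sustainable total catch 6, sessions of at most 8 trials, 16 sessions
    per subject, net sizes {1,2,3}, 0.25 currency units per fish.
    """

    capacity: int = 16
    growth_factor: float = 1.5
    sustainable_catch: int = 6
    max_trials_per_session: int = 8
    sessions_per_subject: int = 16
    net_sizes: tuple[int, ...] = (1, 2, 3)
    payoff_per_fish: float = 0.25

    def __post_init__(self) -> None:
        if self.capacity <= 0:
            raise ValueError("capacity must be positive")
        if self.growth_factor <= 1:
            raise ValueError("growth_factor must exceed 1")
        ns = self.net_sizes
        if any(b - a != 1 for a, b in zip(ns, ns[1:])) or ns[0] <= 0:
            raise ValueError("net_sizes must be consecutive positive integers")
        # with all players at the middle net size, total catch is sustainable
        if self.sustainable_catch != 3 * ns[len(ns) // 2]:
            raise ValueError("sustainable_catch inconsistent with net_sizes")


DEFAULT_CONFIG = TaskConfig()


@dataclass(frozen=True)
class LakeState:
    stock: int
    trial_index: int = 0


@dataclass(frozen=True)
class TrialRecord:
    """One trial: pre-catch stock, demands, realized payoffs, stock trace.

    ``demands``/``payoffs`` order is (own, other1, other2); in the nonsocial
    framing the latter two are the migration outflow split over two lakes.
    """

    stock_pre: int
    demands: tuple[int, int, int]
    payoffs: tuple[int, int, int]
    stock_post_catch: int
    stock_next: int
    terminal: bool


def replenish(stock_post_catch: int, config: TaskConfig = DEFAULT_CONFIG) -> int:
    """Grow the surviving stock by the growth factor, floored and capped.

    An empty lake stays empty; the result never exceeds capacity.
    """
    if stock_post_catch < 0:
        raise ValueError(f"negative stock: {stock_post_catch}")
    return min(math.floor(config.growth_factor * stock_post_catch), config.capacity)


def allocate_catch(
    stock: int,
    demands: Sequence[int],
    rng: np.random.Generator | None = None,
) -> tuple[tuple[int, ...], int]:
    """Allocate the stock among the demanded catches.

    If the stock covers the total demand everyone receives their demand.
    Under scarcity, demands are granted in a random player order (seeded via
    ``rng``), each player taking ``min(demand, remaining)``; all remaining
    fish are taken, so the lake ends empty.
    """
    demands = tuple(int(d) for d in demands)
    total = sum(demands)
    if stock >= total:
        return demands, stock - total
    payoffs = [0] * len(demands)
    order = np.arange(len(demands))
    if rng is not None:
        order = rng.permutation(len(demands))
    remaining = stock
    for j in order:
        take = min(demands[j], remaining)
        payoffs[j] = take
        remaining -= take
    return tuple(payoffs), remaining


def run_session(
    policy_own: Callable[[list[TrialRecord], LakeState], int],
    others_stream: Iterable[tuple[int, int]],
    config: TaskConfig = DEFAULT_CONFIG,
    seed: int | None = None,
) -> list[TrialRecord]:
    """Play one session from a full lake until depletion or the trial cap.

    ``policy_own`` maps (history, state) to a net size. ``others_stream``
    yields per-trial (other1, other2) catches; it must cover at least
    ``max_trials_per_session`` trials. Catch is applied before replenishment;
    the session terminates when the post-replenishment stock is zero.
    """
    rng = np.random.default_rng(seed)
    records: list[TrialRecord] = []
    state = LakeState(stock=config.capacity, trial_index=0)
    stream = iter(others_stream)
    while state.trial_index < config.max_trials_per_session:
        own = int(policy_own(records, state))
        if own not in config.net_sizes:
            raise ValueError(f"net size {own} not in {config.net_sizes}")
        o1, o2 = next(stream)
        payoffs, post_catch = allocate_catch(state.stock, (own, o1, o2), rng)
        stock_next = replenish(post_catch, config)
        terminal = stock_next == 0 or state.trial_index + 1 == config.max_trials_per_session
        records.append(
            TrialRecord(
                stock_pre=state.stock,
                demands=(own, o1, o2),
                payoffs=payoffs,
                stock_post_catch=post_catch,
                stock_next=stock_next,
                terminal=terminal,
            )
        )
        if stock_next == 0:
            break
        state = LakeState(stock=stock_next, trial_index=state.trial_index + 1)
    return records
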