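"""Single decision trials and seeded batches.

A trial starts the system at the saddle (0, 0) and iterates the
stochastic map while maintaining a signed running sum of each process's
coordinate (the accumulators).  The trial ends at the first step where
either accumulator's magnitude reaches the threshold: the crossing
accumulator is the "winner" and its sign gives the decision —
negative for egocentric, positive for other-centric.  If neither
accumulator crosses within ``max_steps`` the trial is a non-decision.

Accumulators start at 0 and sum the coordinate after each update (the
initial state is not summed).  If both accumulators cross on the same
step, the one with the larger magnitude wins; on an exact tie the fast
process wins.  These conventions are fixed so that deterministic step
counts are stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import SystemState, TwoProcessConfig, _require_finite
from .exceptions import ConfigurationError, InvalidArgumentError

__all__ = [
    "TrialConfig",
    "TrialResult",
    "Trial1DResult",
    "BatchSummary",
    "decide",
    "run_trial_2d",
    "run_trial_1d",
    "run_batch",
    "summarize",
    "results_to_frame",
    "trajectories_to_frame",
]

#: Noise draws are generated in blocks of this many steps to avoid
#: per-step RNG call overhead without pre-allocating max_steps draws.
_CHUNK = 1024

EGOCENTRIC = "egocentric"
OTHER_CENTRIC = "other_centric"
NONE = "none"


@dataclass(frozen=True)
class TrialConfig:
    """Everything needed to run one trial (or a batch of them)."""

    dynamics: TwoProcessConfig
    threshold: float = 30.0
    max_steps: int = 50_000
    init: SystemState = SystemState(0.0, 0.0)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.threshold > 0.0:
            raise ConfigurationError(f"threshold must be > 0, got {self.threshold}")
        if not self.max_steps >= 1:
            raise ConfigurationError(f"max_steps must be >= 1, got {self.max_steps}")
        _require_finite("init.x_fast", self.init[0])
        _require_finite("init.x_slow", self.init[1])
        object.__setattr__(self, "init", SystemState(*map(float, self.init)))


@dataclass(frozen=True)
class TrialResult:
    """One simulated two-process decision.

    ``states`` has shape (steps + 1, 2) and includes the initial state;
    ``accum_fast`` / ``accum_slow`` have length steps + 1 with a leading
    zero, aligned with ``states``.
    """

    states: np.ndarray
    accum_fast: np.ndarray
    accum_slow: np.ndarray
    outcome: str
    winner: str
    steps: int

    @property
    def decided(self) -> bool:
        return self.outcome != NONE


@dataclass(frozen=True)
class Trial1DResult:
    """One simulated single-process decision (single accumulator)."""

    states: np.ndarray
    accum: np.ndarray
    outcome: str
    steps: int

    @property
    def decided(self) -> bool:
        return self.outcome != NONE


@dataclass(frozen=True)
class BatchSummary:
    """Counts and decision-time statistics over a batch of trials.

    ``prop_other``, ``mean_steps`` and ``sd_steps`` are computed over
    decided trials only (NaN if none decided; ``sd_steps`` uses the
    n-1 denominator and is NaN for fewer than two decided trials).
    """

    n_trials: int
    counts: dict[tuple[str, str], int] = field(default_factory=dict)
    prop_other: float = float("nan")
    mean_steps: float = float("nan")
    sd_steps: float = float("nan")
    n_nondecision: int = 0


def decide(
    accum_fast: float, accum_slow: float, threshold: float
) -> tuple[str, str] | None:
    """Stopping predicate: ``(outcome, winner)`` if an accumulator's
    magnitude has reached ``threshold``, else ``None``.

    When both accumulators are past the bound on the same step the one
    with larger magnitude wins; an exact tie goes to the fast process.
    """
    if not threshold > 0.0:
        raise InvalidArgumentError(f"threshold must be > 0, got {threshold}")
    fast_hit = abs(accum_fast) >= threshold
    slow_hit = abs(accum_slow) >= threshold
    if not (fast_hit or slow_hit):
        return None
    if fast_hit and slow_hit:
        winner = "fast" if abs(accum_fast) >= abs(accum_slow) else "slow"
    else:
        winner = "fast" if fast_hit else "slow"
    value = accum_fast if winner == "fast" else accum_slow
    return (EGOCENTRIC if value < 0 else OTHER_CENTRIC, winner)


def run_trial_2d(config: TrialConfig, rng: np.random.Generator) -> TrialResult:
    """Simulate one two-process trial with the given RNG stream."""
    cfg = config.dynamics
    u_p, k_p = cfg.fast.u, cfg.fast.k
    u_s, k_s = cfg.slow.u, cfg.slow.k
    alpha, beta, sigma = cfg.alpha, cfg.beta, cfg.sigma
    threshold, max_steps = config.threshold, config.max_steps

    x_p, x_s = config.init
    states = [(x_p, x_s)]
    acc_p_seq = [0.0]
    acc_s_seq = [0.0]
    acc_p = acc_s = 0.0
    outcome, winner = NONE, NONE
    step = 0
    while step < max_steps:
        n = min(_CHUNK, max_steps - step)
        draws = rng.standard_normal((n, 2))
        for i in range(n):
            x_p, x_s = (
                x_p
                - u_p * (k_p - x_p + x_p**3)
                + alpha * (x_s - x_p)
                + sigma * draws[i, 0],
                x_s
                - u_s * (k_s - x_s + x_s**3)
                + beta * (x_p - x_s)
                + sigma * draws[i, 1],
            )
            acc_p += x_p
            acc_s += x_s
            states.append((x_p, x_s))
            acc_p_seq.append(acc_p)
            acc_s_seq.append(acc_s)
            step += 1
            verdict = decide(acc_p, acc_s, threshold)
            if verdict is not None:
                outcome, winner = verdict
                break
        if outcome != NONE:
            break
    return TrialResult(
        states=np.asarray(states),
        accum_fast=np.asarray(acc_p_seq),
        accum_slow=np.asarray(acc_s_seq),
        outcome=outcome,
        winner=winner,
        steps=step,
    )


def run_trial_1d(
    k: float,
    sigma: float,
    threshold: float = 30.0,
    max_steps: int = 50_000,
    rng: np.random.Generator | None = None,
    init: float = 0.0,
) -> Trial1DResult:
    """Simulate one single-process trial (unit descent rate).

    The single accumulator is the running sum of x; the trial stops
    when its magnitude reaches ``threshold`` and the sign gives the
    outcome.
    """
    if not threshold > 0.0:
        raise ConfigurationError(f"threshold must be > 0, got {threshold}")
    if not max_steps >= 1:
        raise ConfigurationError(f"max_steps must be >= 1, got {max_steps}")
    _require_finite("k", k)
    if rng is None:
        rng = np.random.default_rng()
    x = float(init)
    states = [x]
    acc_seq = [0.0]
    acc = 0.0
    outcome = NONE
    step = 0
    while step < max_steps:
        n = min(_CHUNK, max_steps - step)
        draws = rng.standard_normal(n)
        for i in range(n):
            x = x + (-k + x - x**3) + sigma * draws[i]
            acc += x
            states.append(x)
            acc_seq.append(acc)
            step += 1
            if abs(acc) >= threshold:
                outcome = EGOCENTRIC if acc < 0 else OTHER_CENTRIC
                break
        if outcome != NONE:
            break
    return Trial1DResult(
        states=np.asarray(states),
        accum=np.asarray(acc_seq),
        outcome=outcome,
        steps=step,
    )


def _trial_seed_sequences(
    seed: int | np.random.SeedSequence, n_trials: int
) -> list[np.random.SeedSequence]:
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return root.spawn(n_trials)


def run_batch(
    config: TrialConfig,
    n_trials: int,
    seed: int | np.random.SeedSequence,
) -> tuple[list[TrialResult], BatchSummary]:
    """Run ``n_trials`` independent trials with per-trial RNG substreams.

    Trial i uses a stream spawned deterministically from (seed, i), so
    a batch is reproducible and independent of execution order.
    """
    if n_trials < 1:
        raise InvalidArgumentError(f"n_trials must be >= 1, got {n_trials}")
    results = [
        run_trial_2d(config, np.random.default_rng(ss))
        for ss in _trial_seed_sequences(seed, n_trials)
    ]
    return results, summarize(results)


def summarize(results: list[TrialResult]) -> BatchSummary:
    """Aggregate a list of trial results into a :class:`BatchSummary`."""
    if not results:
        raise InvalidArgumentError("cannot summarize an empty list of results")
    counts: dict[tuple[str, str], int] = {}
    decided_steps = []
    n_other = 0
    n_nondecision = 0
    for r in results:
        key = (r.outcome, r.winner)
        counts[key] = counts.get(key, 0) + 1
        if r.decided:
            decided_steps.append(r.steps)
            if r.outcome == OTHER_CENTRIC:
                n_other += 1
        else:
            n_nondecision += 1
    n_decided = len(decided_steps)
    steps_arr = np.asarray(decided_steps, dtype=float)
    return BatchSummary(
        n_trials=len(results),
        counts=counts,
        prop_other=n_other / n_decided if n_decided else float("nan"),
        mean_steps=float(steps_arr.mean()) if n_decided else float("nan"),
        sd_steps=float(steps_arr.std(ddof=1)) if n_decided > 1 else float("nan"),
        n_nondecision=n_nondecision,
    )


def results_to_frame(results: list[TrialResult]) -> pd.DataFrame:
    """One row per trial: outcome, winner, steps, final accumulators."""
    return pd.DataFrame(
        {
            "trial": np.arange(len(results)),
            "outcome": [r.outcome for r in results],
            "winner": [r.winner for r in results],
            "steps": [r.steps for r in results],
            "final_accum_fast": [r.accum_fast[-1] for r in results],
            "final_accum_slow": [r.accum_slow[-1] for r in results],
        }
    )


def trajectories_to_frame(results: list[TrialResult]) -> pd.DataFrame:
    """Long-format trajectories: (trial, step, x_fast, x_slow, accumulators)."""
    frames = []
    for i, r in enumerate(results):
        n = len(r.accum_fast)
        frames.append(
            pd.DataFrame(
                {
                    "trial": i,
                    "step": np.arange(n),
                    "x_fast": r.states[:, 0],
                    "x_slow": r.states[:, 1],
                    "accum_fast": r.accum_fast,
                    "accum_slow": r.accum_slow,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
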