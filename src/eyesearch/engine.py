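"""Trial engine: composes perception, strategy, and motor on one timeline.

A trial unfolds as a strict sequence of stages (the modeled strategies are
sequential, so no processor overlap is needed):

1. display onset; perception at the central fixation point; perceptual
   encoding (50 ms);
2. onset detection (one 50-ms cycle);
3. strategy start-up delay VDelay (100 ms);
4. repeated nominate (50 ms) / choose (50 ms) cycles. A respond choice
   adds the manual response time (125 ms) and ends the trial; a move-eyes
   choice adds the realized saccade duration, re-runs perception at the
   landing point, and adds a 50-ms post-saccade encoding delay.

The reaction time therefore satisfies, exactly,

    rt = encode + onset + vdelay + 2 * cycle * C
         + total_saccade_ms + 50 * N_em + manual

with C nominate/choose pairs and N_em eye movements; every
:class:`TrialResult` carries the terms so the identity can be audited.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .display import Display, TaskSpec, generate_display, make_task_spec
from .motor import ManualParams, OculomotorParams, execute_saccade, manual_response
from .strategy import Action, StrategyConfig, TrialState, choose_action, nominate
from .vision import AvailabilityParams, CrowdingParams, new_store, perceive


@dataclass
class TimingParams:
    """Stage durations in ms (all architectural constants)."""

    cycle_ms: float = 50.0
    perceptual_encode_ms: float = 50.0
    onset_detect_ms: float = 50.0
    vdelay_ms: float = 100.0
    post_saccade_encode_ms: float = 50.0

    def __post_init__(self) -> None:
        for name in ("cycle_ms", "perceptual_encode_ms", "onset_detect_ms",
                     "vdelay_ms", "post_saccade_encode_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class ModelConfig:
    """Everything needed to simulate one task model."""

    task: TaskSpec
    avail: AvailabilityParams
    crowd: CrowdingParams
    oculo: OculomotorParams = field(default_factory=OculomotorParams)
    manual: ManualParams = field(default_factory=ManualParams)
    strategy: StrategyConfig = field(default_factory=StrategyConfig)
    timing: TimingParams = field(default_factory=TimingParams)

    def __post_init__(self) -> None:
        missing = [p for p in self.task.properties if p not in self.avail.theta]
        if missing:
            raise ValueError(
                f"availability theta missing for task properties {missing}"
            )


@dataclass
class TrialResult:
    response: str
    correct: bool
    rt: float  # ms
    n_eye_movements: int
    n_decision_pairs: int  # nominate/choose pairs executed
    total_saccade_ms: float
    manual_ms: float
    polarity: str
    set_size: int

    @property
    def n_cycles(self) -> int:
        return 2 * self.n_decision_pairs


@dataclass
class ConditionSummary:
    task: str
    polarity: str
    set_size: int
    n_trials: int
    mean_rt_correct: float  # ms; NaN when no trial was correct
    rt_sd: float
    error_rate: float  # misses on positive, false alarms on negative
    mean_eye_movements: float


def run_trial(
    config: ModelConfig,
    set_size: int,
    polarity: str,
    rng: np.random.Generator,
    display: Optional[Display] = None,
) -> TrialResult:
    """Simulate one trial; the display is generated unless provided."""
    if display is None:
        display = generate_display(config.task, set_size, polarity, rng)
    timing = config.timing

    store = new_store(display)
    state = TrialState(eye=display.fixation_point)
    perceive(display, state.eye, config.avail, config.crowd, store, rng)

    t = timing.perceptual_encode_ms + timing.onset_detect_ms + timing.vdelay_ms
    pairs = 0
    saccade_ms = 0.0
    guard = 10 * set_size

    while True:
        noms = nominate(store, config.task)
        action = choose_action(noms, state, display, config.strategy, rng)
        pairs += 1
        t += 2 * timing.cycle_ms
        if action.kind == "respond":
            actual, manual_ms = manual_response(action.response, config.manual, rng)
            t += manual_ms
            correct = actual == ("present" if polarity == "positive" else "absent")
            return TrialResult(
                response=actual,
                correct=correct,
                rt=t,
                n_eye_movements=state.n_eye_movements,
                n_decision_pairs=pairs,
                total_saccade_ms=saccade_ms,
                manual_ms=manual_ms,
                polarity=polarity,
                set_size=set_size,
            )
        target_pos = display.objects[action.object_id].position
        landing, duration, _length = execute_saccade(state.eye, target_pos, config.oculo, rng)
        t += duration
        saccade_ms += duration
        state.eye = landing
        state.n_eye_movements += 1
        if state.n_eye_movements > guard:
            raise RuntimeError(
                f"trial exceeded {guard} eye movements at set size {set_size}; "
                "the strategies terminate, so this indicates a logic error"
            )
        perceive(display, state.eye, config.avail, config.crowd, store, rng)
        t += timing.post_saccade_encode_ms


def run_condition(
    config: ModelConfig,
    set_size: int,
    polarity: str,
    n_trials: int,
    rng: np.random.Generator,
) -> ConditionSummary:
    """Monte-Carlo aggregate over independent trials of one design cell.

    Mean RT and its SD are computed over correct trials only; the error
    rate counts misses on positive and false alarms on negative trials.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rts = np.empty(n_trials)
    correct = np.empty(n_trials, dtype=bool)
    n_em = np.empty(n_trials)
    for k in range(n_trials):
        res = run_trial(config, set_size, polarity, rng)
        rts[k] = res.rt
        correct[k] = res.correct
        n_em[k] = res.n_eye_movements
    n_corr = int(correct.sum())
    return ConditionSummary(
        task=config.task.name,
        polarity=polarity,
        set_size=set_size,
        n_trials=n_trials,
        mean_rt_correct=float(rts[correct].mean()) if n_corr else float("nan"),
        rt_sd=float(rts[correct].std(ddof=0)) if n_corr else float("nan"),
        error_rate=1.0 - n_corr / n_trials,
        mean_eye_movements=float(n_em.mean()),
    )


def run_design(
    config: ModelConfig,
    set_sizes: Sequence[int] = (3, 6, 12, 18),
    polarities: Sequence[str] = ("positive", "negative"),
    n_trials_per_cell: int = 1000,
    seed: int | np.random.SeedSequence = 0,
) -> list[ConditionSummary]:
    """Run the full set-size x polarity cross-product.

    Each cell gets its own RNG substream spawned from ``seed`` in cell
    order, so results are deterministic under a fixed seed and cells are
    individually reproducible.
    """
    base = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    cells = [(ss, pol) for ss in set_sizes for pol in polarities]
    streams = base.spawn(len(cells))
    return [
        run_condition(config, ss, pol, n_trials_per_cell, np.random.default_rng(stream))
        for (ss, pol), stream in zip(cells, streams)
    ]


def summaries_to_frame(summaries: Iterable[ConditionSummary]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "task": s.task,
            "polarity": s.polarity,
            "set_size": s.set_size,
            "n_trials": s.n_trials,
            "mean_rt_ms": s.mean_rt_correct,
            "rt_sd_ms": s.rt_sd,
            "error_rate": s.error_rate,
            "mean_eye_movements": s.mean_eye_movements,
        }
        for s in summaries
    ])


def trials_to_frame(trials: Iterable[TrialResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "trial_id": i,
            "polarity": r.polarity,
            "set_size": r.set_size,
            "response": r.response,
            "correct": r.correct,
            "rt_ms": r.rt,
            "n_eye_movements": r.n_eye_movements,
        }
        for i, r in enumerate(trials)
    ])
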