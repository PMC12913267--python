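"""Task strategies: nomination rules and the fixation/response choice.

Each strategy alternates two 50-ms decision phases until it responds:

* **nomination** (:func:`nominate`) classifies every object in the
  perceptual store as a definite *target* (all target properties match),
  a *possible* target (a relevant property is blank), or neither.
* **choice** (:func:`choose_action`) then either responds or commands a
  saccade to the closest possible target, with optional variations:
  limited fixations (respond absent once ``n_max`` eye movements have been
  made), confirm-positive (fixate an apparent target before responding
  present unless it is already within 1 deg), confirm-both (additionally
  check the most eccentric object once before the first absent response),
  and the fixed-eye variant that never moves the eyes at all.

In the Conjunction task, possible targets carry a priority class --
red with unknown orientation (1), unknown color but vertical (2), both
unknown (3) -- and the closest-object rule applies within the highest
occupied class only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .display import (
    COLOR, ORIENTATION, SHAPE, RED, GREEN, VERTICAL, HORIZONTAL, TWO, FIVE,
    Display, TaskSpec,
)
from .vision import BLANK, PerceptualStore

#: Below this eccentricity a commanded saccade is degenerate geometry.
_EPS_DEG = 1e-9


@dataclass
class StrategyConfig:
    variant: str = "basic"  # "basic" | "fixed_eye"
    limited_fixations: Optional[int] = None  # N_max, >= 1
    confirm_positive: bool = False
    confirm_negative: bool = False
    fixated_threshold: float = 1.0  # deg; "already fixated" criterion

    def __post_init__(self) -> None:
        if self.variant not in ("basic", "fixed_eye"):
            raise ValueError(f"unknown strategy variant {self.variant!r}")
        if self.variant == "fixed_eye" and (
            self.limited_fixations is not None or self.confirm_positive or self.confirm_negative
        ):
            raise ValueError("fixed_eye strategy admits no eye-movement options")
        if self.limited_fixations is not None and self.limited_fixations < 1:
            raise ValueError("limited_fixations (N_max) must be >= 1")
        if self.confirm_negative and not self.confirm_positive:
            raise ValueError("confirm_negative requires confirm_positive (confirm-both)")
        if self.fixated_threshold <= 0:
            raise ValueError("fixated_threshold must be > 0")


@dataclass
class Nomination:
    object_id: int
    kind: str  # "target" | "possible"
    priority_class: int = 1  # 1 = highest


@dataclass
class TrialState:
    """Mutable per-trial bookkeeping the strategy can see."""

    eye: tuple[float, float] = (0.0, 0.0)
    n_eye_movements: int = 0  # the initial fixation is not counted
    negative_check_done: bool = False


@dataclass
class Action:
    kind: str  # "respond" | "move_eyes"
    response: Optional[str] = None  # "present" | "absent"
    object_id: Optional[int] = None

    @classmethod
    def respond(cls, response: str) -> "Action":
        return cls(kind="respond", response=response)

    @classmethod
    def move_eyes(cls, object_id: int) -> "Action":
        return cls(kind="move_eyes", object_id=object_id)


def nominate(store: PerceptualStore, task: TaskSpec) -> list[Nomination]:
    """Classify stored percepts as target / possible-target nominations.

    Objects that definitely mismatch the target (a 5 shape, a green color,
    a horizontal orientation) are not nominated at all.
    """
    noms: list[Nomination] = []
    if task.name == "shape":
        for i, v in enumerate(store.values[SHAPE]):
            if v == TWO:
                noms.append(Nomination(i, "target"))
            elif v is BLANK:
                noms.append(Nomination(i, "possible"))
    elif task.name == "color":
        for i, v in enumerate(store.values[COLOR]):
            if v == RED:
                noms.append(Nomination(i, "target"))
            elif v is BLANK:
                noms.append(Nomination(i, "possible"))
    elif task.name == "conjunction":
        colors = store.values[COLOR]
        orients = store.values[ORIENTATION]
        for i, (c, o) in enumerate(zip(colors, orients)):
            if c == GREEN or o == HORIZONTAL:
                continue
            if c == RED and o == VERTICAL:
                noms.append(Nomination(i, "target"))
            elif c == RED:  # orientation blank
                noms.append(Nomination(i, "possible", priority_class=1))
            elif o == VERTICAL:  # color blank
                noms.append(Nomination(i, "possible", priority_class=2))
            else:  # both blank
                noms.append(Nomination(i, "possible", priority_class=3))
    else:  # pragma: no cover - specs are closed
        raise ValueError(f"unknown task {task.name!r}")
    return noms


def _ecc_from_eye(display: Display, eye: Sequence[float]) -> np.ndarray:
    return np.linalg.norm(display.positions - np.asarray(eye, dtype=float), axis=1)


def _closest(ids: list[int], ecc: np.ndarray, rng: np.random.Generator) -> int:
    """Closest object id; distance ties broken uniformly at random."""
    d = ecc[ids]
    best = np.flatnonzero(d == d.min())
    pick = int(best[0]) if len(best) == 1 else int(rng.choice(best))
    return ids[pick]


def choose_action(
    noms: list[Nomination],
    state: TrialState,
    display: Display,
    config: StrategyConfig,
    rng: np.random.Generator,
) -> Action:
    """One choice phase: respond or command a saccade.

    May set ``state.negative_check_done`` when issuing the confirm-negative
    saccade; the caller updates eye position and movement counts.
    """
    ecc = _ecc_from_eye(display, state.eye)
    limit_reached = (
        config.limited_fixations is not None
        and state.n_eye_movements >= config.limited_fixations
    )

    targets = [n.object_id for n in noms if n.kind == "target"]
    if targets:
        # The limited-fixations guard requires "target not found", so it
        # never preempts a confirmation saccade.
        if config.confirm_positive:
            tid = _closest(targets, ecc, rng)
            if ecc[tid] > config.fixated_threshold:
                return Action.move_eyes(tid)
        return Action.respond("present")

    if not noms:
        if (
            config.confirm_negative
            and not state.negative_check_done
            and not limit_reached
        ):
            far = int(np.argmax(ecc))
            if ecc[far] > config.fixated_threshold:
                state.negative_check_done = True
                return Action.move_eyes(far)
        return Action.respond("absent")

    # Only possible-target nominations remain.
    if config.variant == "fixed_eye":
        return Action.respond("absent")
    if limit_reached:
        return Action.respond("absent")
    top = min(n.priority_class for n in noms if n.kind == "possible")
    candidates = [n.object_id for n in noms if n.kind == "possible" and n.priority_class == top]
    oid = _closest(candidates, ecc, rng)
    if ecc[oid] <= _EPS_DEG:
        # Degenerate geometry: refixating the same point cannot add
        # information, so fall through to the absent response.
        return Action.respond("absent")
    return Action.move_eyes(oid)
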