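"""Stimulus-display generation for the three simple visual-search tasks.

The simulated experiment presents a 22.5° x 22.5° field divided into a 5 x 5
grid of invisible cells. On each trial, ``set_size`` objects are placed in
distinct, randomly chosen cells, at a uniformly random position within the
cell subject to a margin that keeps each object's bounding box at least
0.25° inside the cell boundary. Because cells are disjoint, this guarantees
a minimum edge-to-edge separation of 0.5° between any two objects without
rejection sampling.

Three task types are supported:

* **Shape** -- digital-display digit shapes; distractors are 5s, the target
  is a 2. Bounding box 1.5° x 2.7°; object size (mean of box width and
  height) 2.1°.
* **Color** -- vertical bars, 1° x 3.5° (size 2.25°); distractors green,
  target red.
* **Conjunction** -- red-horizontal and green-vertical distractor bars in
  equal numbers; the target is a red vertical bar.

An object's *location* is the center of its bounding box, with the origin at
the display center and y increasing upward. Eccentricity is the Euclidean
distance in degrees of visual angle from a reference point (by default the
central fixation point).

The module also provides :func:`crowding_census`, a geometry-only diagnostic
that measures how much crowding (neighbors within the Bouma critical
spacing, half the eccentricity of the object in question) the random display
construction produces at each set size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from functools import cached_property
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

# Property names
COLOR = "color"
ORIENTATION = "orientation"
SHAPE = "shape"

# Property values
RED = "red"
GREEN = "green"
VERTICAL = "vertical"
HORIZONTAL = "horizontal"
TWO = "2"
FIVE = "5"

# Field geometry: 22.5 deg square, 5 x 5 grid of equal cells.
FIELD_EXTENT_DEG = 22.5
GRID_SIDE = 5
N_CELLS = GRID_SIDE * GRID_SIDE
CELL_SIZE_DEG = FIELD_EXTENT_DEG / GRID_SIDE
CELL_MARGIN_DEG = 0.25

STANDARD_SET_SIZES = (3, 6, 12, 18)


class ConfigurationError(ValueError):
    """Raised for invalid task names or impossible display requests."""


@dataclass(frozen=True)
class TaskSpec:
    """Static description of one search task.

    Attributes
    ----------
    name:
        ``"shape"``, ``"color"`` or ``"conjunction"``.
    object_size:
        Visual size in degrees: the mean of the bounding-box width and
        height, the quantity entering the availability function.
    properties:
        The task-relevant visual properties; exactly these are set on every
        generated object.
    target:
        Property values defining the target object.
    distractor_templates:
        One property-value map per distractor type.
    """

    name: str
    object_size: float
    properties: tuple[str, ...]
    target: Mapping[str, str]
    distractor_templates: tuple[Mapping[str, str], ...]


_TASK_SPECS = {
    "shape": TaskSpec(
        name="shape",
        object_size=2.1,  # mean of the 1.5 x 2.7 deg bounding box
        properties=(SHAPE,),
        target={SHAPE: TWO},
        distractor_templates=({SHAPE: FIVE},),
    ),
    "color": TaskSpec(
        name="color",
        object_size=2.25,  # mean of the 1.0 x 3.5 deg bar
        properties=(COLOR, ORIENTATION),
        target={COLOR: RED, ORIENTATION: VERTICAL},
        distractor_templates=({COLOR: GREEN, ORIENTATION: VERTICAL},),
    ),
    "conjunction": TaskSpec(
        name="conjunction",
        object_size=2.25,
        properties=(COLOR, ORIENTATION),
        target={COLOR: RED, ORIENTATION: VERTICAL},
        distractor_templates=(
            {COLOR: RED, ORIENTATION: HORIZONTAL},
            {COLOR: GREEN, ORIENTATION: VERTICAL},
        ),
    ),
}


def make_task_spec(task_name: str) -> TaskSpec:
    """Return the fully populated :class:`TaskSpec` for a task name.

    Raises
    ------
    ConfigurationError
        If ``task_name`` is not one of ``shape``, ``color``, ``conjunction``.
    """
    key = task_name.lower()
    if key not in _TASK_SPECS:
        raise ConfigurationError(
            f"unknown task {task_name!r}; expected one of {sorted(_TASK_SPECS)}"
        )
    return _TASK_SPECS[key]


def bounding_box(properties: Mapping[str, str]) -> tuple[float, float]:
    """Bounding-box (width, height) in degrees for an object's properties.

    Digit shapes are 1.5 x 2.7; bars are 1 x 3.5 with the long axis along
    the orientation, so horizontal bars use a 3.5 x 1 box.
    """
    if SHAPE in properties:
        return (1.5, 2.7)
    if properties.get(ORIENTATION) == HORIZONTAL:
        return (3.5, 1.0)
    return (1.0, 3.5)


@dataclass
class DisplayObject:
    """One object on the display: geometry plus physical property values."""

    position: tuple[float, float]
    cell_index: int
    properties: dict[str, str]
    is_target: bool = False


@dataclass
class Display:
    """A complete stimulus display: the ground truth a trial runs against."""

    task: TaskSpec
    set_size: int
    polarity: str  # "positive" | "negative"
    objects: list[DisplayObject] = field(default_factory=list)
    fixation_point: tuple[float, float] = (0.0, 0.0)

    @cached_property
    def positions(self) -> np.ndarray:
        """(n, 2) array of object center positions in degrees."""
        return np.array([o.position for o in self.objects], dtype=float)

    @cached_property
    def distance_matrix(self) -> np.ndarray:
        """(n, n) center-to-center distances, fixed for the trial."""
        p = self.positions
        return np.linalg.norm(p[:, None, :] - p[None, :, :], axis=-1)

    @property
    def target_index(self) -> int | None:
        for i, o in enumerate(self.objects):
            if o.is_target:
                return i
        return None


def eccentricity(point: Sequence[float], reference: Sequence[float] = (0.0, 0.0)) -> float:
    """Euclidean distance in degrees of visual angle between two points."""
    return float(np.hypot(point[0] - reference[0], point[1] - reference[1]))


def _cell_origin(cell_index: int) -> tuple[float, float]:
    row, col = divmod(cell_index, GRID_SIDE)
    half = FIELD_EXTENT_DEG / 2.0
    return (-half + col * CELL_SIZE_DEG, -half + row * CELL_SIZE_DEG)


def _sample_position(cell_index: int, box: tuple[float, float], rng: np.random.Generator) -> tuple[float, float]:
    x0, y0 = _cell_origin(cell_index)
    w, h = box
    lo_x = x0 + CELL_MARGIN_DEG + w / 2.0
    hi_x = x0 + CELL_SIZE_DEG - CELL_MARGIN_DEG - w / 2.0
    lo_y = y0 + CELL_MARGIN_DEG + h / 2.0
    hi_y = y0 + CELL_SIZE_DEG - CELL_MARGIN_DEG - h / 2.0
    if lo_x > hi_x or lo_y > hi_y:
        raise ConfigurationError(
            f"bounding box {box} does not fit in a {CELL_SIZE_DEG} deg cell "
            f"with a {CELL_MARGIN_DEG} deg margin"
        )
    return (float(rng.uniform(lo_x, hi_x)), float(rng.uniform(lo_y, hi_y)))


def _distractor_types(spec: TaskSpec, n: int, rng: np.random.Generator) -> list[int]:
    """Indices into ``spec.distractor_templates`` for ``n`` distractors.

    With two templates the split is half/half; an odd remainder goes to a
    uniformly chosen type.
    """
    k = len(spec.distractor_templates)
    if k == 1:
        return [0] * n
    base, extra = divmod(n, k)
    counts = [base] * k
    for t in rng.choice(k, size=extra, replace=False):
        counts[t] += 1
    types = [t for t, c in enumerate(counts) for _ in range(c)]
    rng.shuffle(types)
    return types


def generate_display(
    spec: TaskSpec,
    set_size: int,
    polarity: str,
    rng: np.random.Generator,
) -> Display:
    """Generate one randomized display.

    ``set_size`` distractors are placed in distinct random cells; on a
    positive trial one randomly chosen distractor is then replaced by the
    target. In the Conjunction task at set size 3 the replacement is
    constrained so that at least one distractor of each type remains.

    Raises
    ------
    ConfigurationError
        If ``set_size`` is outside 1..25 or ``polarity`` is invalid.
    """
    if not 1 <= set_size <= N_CELLS:
        raise ConfigurationError(
            f"set_size must be between 1 and {N_CELLS}, got {set_size}"
        )
    if polarity not in ("positive", "negative"):
        raise ConfigurationError(f"polarity must be positive|negative, got {polarity!r}")

    cells = rng.choice(N_CELLS, size=set_size, replace=False)
    types = _distractor_types(spec, set_size, rng)

    target_slot: int | None = None
    if polarity == "positive":
        candidates = list(range(set_size))
        if spec.name == "conjunction" and set_size == 3:
            # Keep one distractor of each type after the replacement: only a
            # slot whose type still has another instance may be replaced.
            counts = {t: types.count(t) for t in set(types)}
            candidates = [i for i in candidates if counts[types[i]] >= 2]
        target_slot = int(rng.choice(candidates))

    objects = []
    for i in range(set_size):
        if i == target_slot:
            props = dict(spec.target)
            is_target = True
        else:
            props = dict(spec.distractor_templates[types[i]])
            is_target = False
        pos = _sample_position(int(cells[i]), bounding_box(props), rng)
        objects.append(
            DisplayObject(position=pos, cell_index=int(cells[i]), properties=props, is_target=is_target)
        )
    return Display(task=spec, set_size=set_size, polarity=polarity, objects=objects)


# ---------------------------------------------------------------------------
# Crowding census


def _census_initial(display: Display) -> float:
    n = display.set_size
    if n < 2:
        return 0.0
    D = display.distance_matrix
    ecc = np.linalg.norm(display.positions - np.asarray(display.fixation_point), axis=1)
    crowders = (D < 0.5 * ecc[:, None]) & ~np.eye(n, dtype=bool)
    return float(crowders.sum(axis=1).mean())


def _census_pairwise(display: Display) -> float:
    n = display.set_size
    if n < 2:
        return 0.0
    D = display.distance_matrix
    off = ~np.eye(n, dtype=bool)
    total = 0.0
    for k in range(n):
        ecc = D[k]  # eccentricity of every object from the fixated object k
        crowders = (D < 0.5 * ecc[:, None]) & off
        per_object = crowders.sum(axis=1)
        mask = np.arange(n) != k  # census covers every *other* object
        total += float(per_object[mask].mean())
    return total / n


def crowding_census(
    spec: TaskSpec,
    set_sizes: Iterable[int],
    n_displays: int,
    mode: str = "initial_fixation",
    rng: np.random.Generator | None = None,
) -> dict[int, float]:
    """Mean number of crowders per object, by set size.

    A neighbor j crowds object i when their center-to-center distance is
    below the critical spacing of i, half of i's eccentricity (Bouma's
    rule). The relation is directional: the census counts crowders *of*
    each object.

    mode ``"initial_fixation"`` measures eccentricity from the central
    fixation point; ``"pairwise"`` iterates the assumed fixation over every
    display object, measures every other object's eccentricity from that
    object, and averages over fixated objects as well.
    """
    set_sizes = list(set_sizes)
    if not set_sizes:
        raise ConfigurationError("set_sizes must not be empty")
    if n_displays < 1:
        raise ConfigurationError("n_displays must be >= 1")
    if mode not in ("initial_fixation", "pairwise"):
        raise ConfigurationError(f"unknown census mode {mode!r}")
    if rng is None:
        rng = np.random.default_rng()

    count = _census_initial if mode == "initial_fixation" else _census_pairwise
    out: dict[int, float] = {}
    for ss in set_sizes:
        total = 0.0
        for _ in range(n_displays):
            total += count(generate_display(spec, ss, "negative", rng))
        out[ss] = total / n_displays
    return out


# ---------------------------------------------------------------------------
# Serialization

_CSV_COLUMNS = [
    "trial_id", "task", "set_size", "polarity", "object_id",
    "x_deg", "y_deg", "cell", "color", "orientation", "shape", "is_target",
]


def displays_to_frame(displays: Iterable[Display]) -> pd.DataFrame:
    """Flatten displays to one row per object (see ``displays_to_csv``)."""
    rows = []
    for trial_id, d in enumerate(displays):
        for oid, obj in enumerate(d.objects):
            rows.append({
                "trial_id": trial_id,
                "task": d.task.name,
                "set_size": d.set_size,
                "polarity": d.polarity,
                "object_id": oid,
                "x_deg": obj.position[0],
                "y_deg": obj.position[1],
                "cell": obj.cell_index,
                "color": obj.properties.get(COLOR, ""),
                "orientation": obj.properties.get(ORIENTATION, ""),
                "shape": obj.properties.get(SHAPE, ""),
                "is_target": obj.is_target,
            })
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def displays_to_csv(displays: Iterable[Display], path) -> None:
    displays_to_frame(displays).to_csv(path, index=False)


def displays_from_csv(path) -> list[Display]:
    df = pd.read_csv(path, keep_default_na=False)
    displays = []
    for _, group in df.groupby("trial_id", sort=True):
        spec = make_task_spec(str(group["task"].iloc[0]))
        objects = []
        for _, row in group.sort_values("object_id").iterrows():
            props = {
                p: str(row[p]) for p in (COLOR, ORIENTATION, SHAPE)
                if p in spec.properties and str(row[p]) != ""
            }
            objects.append(DisplayObject(
                position=(float(row["x_deg"]), float(row["y_deg"])),
                cell_index=int(row["cell"]),
                properties=props,
                is_target=bool(row["is_target"]),
            ))
        displays.append(Display(
            task=spec,
            set_size=int(group["set_size"].iloc[0]),
            polarity=str(group["polarity"].iloc[0]),
            objects=objects,
        ))
    return displays


def display_to_json(display: Display) -> str:
    doc = {
        "task": display.task.name,
        "set_size": display.set_size,
        "polarity": display.polarity,
        "fixation_point": list(display.fixation_point),
        "objects": [asdict(o) for o in display.objects],
    }
    return json.dumps(doc, indent=2)


def display_from_json(text: str) -> Display:
    doc = json.loads(text)
    spec = make_task_spec(doc["task"])
    objects = [
        DisplayObject(
            position=tuple(o["position"]),
            cell_index=o["cell_index"],
            properties=dict(o["properties"]),
            is_target=o["is_target"],
        )
        for o in doc["objects"]
    ]
    return Display(
        task=spec,
        set_size=doc["set_size"],
        polarity=doc["polarity"],
        objects=objects,
        fixation_point=tuple(doc.get("fixation_point", (0.0, 0.0))),
    )
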