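"""Early-vision front end: availability, crowding, and the perceptual store.

Perception is event-driven: at display onset and after every completed
saccade the pipeline :func:`perceive` runs, in order,

1. :func:`sample_snapshot` -- each task-relevant property of each object is
   detected independently with probability ``P = Phi((s - theta*e) / sigma)``
   where ``s`` is the object size, ``e`` its current eccentricity, ``theta``
   the per-property availability threshold coefficient, and ``sigma`` (0.5)
   the spread of the Gaussian detection function. ``theta*e`` is the 50%
   detection threshold expressed as an object size. Undetected properties
   are blank.
2. :func:`form_crowding_groups` -- objects closer together than the Bouma
   critical spacing (half the eccentricity of the object in question,
   measured from the current eye position) are linked; connected components
   of the (symmetrized) relation form crowding groups.
3. :func:`scramble_snapshot` -- within each multi-object group, each
   property is scrambled between group members (including blank values)
   with per-object probability ``phi``.
4. :func:`update_store` -- the persistent perceptual store keeps the last
   non-blank value seen for each object/property; a *scrambled-in* blank
   erases stored knowledge (an illusory blank), mere unavailability does
   not.

The store, not the raw snapshot, is what the task strategy reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .display import Display

#: Sentinel for an unavailable (blank) property value.
BLANK: None = None


@dataclass
class AvailabilityParams:
    """Per-property availability threshold coefficients theta, plus sigma.

    Small theta = property available far into the periphery; large theta =
    property effectively foveal-only. sigma (degrees) sets the steepness of
    the detection function and stays at its default 0.5 unless explicitly
    overridden.
    """

    theta: dict[str, float]
    sigma: float = 0.5

    def __post_init__(self) -> None:
        for prop, th in self.theta.items():
            if th < 0:
                raise ValueError(f"theta[{prop!r}] must be >= 0, got {th}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")


@dataclass
class CrowdingParams:
    """Per-property crowding (scrambling) probabilities phi in [0, 1]."""

    phi: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for prop, p in self.phi.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"phi[{prop!r}] must be in [0, 1], got {p}")


@dataclass
class Snapshot:
    """Perceived values from one fixation, before store merging.

    ``values[prop][i]`` is object i's perceived value for ``prop`` (or
    :data:`BLANK`); ``scrambled[prop][i]`` marks values that arrived via
    crowding scrambling in this snapshot.
    """

    eye: tuple[float, float]
    values: dict[str, list]
    scrambled: dict[str, np.ndarray]

    @property
    def n_objects(self) -> int:
        return len(next(iter(self.values.values())))


@dataclass
class PerceptualStore:
    """Per-object, per-property last-known values; persists within a trial."""

    values: dict[str, list]

    @property
    def n_objects(self) -> int:
        return len(next(iter(self.values.values())))


def new_store(display: Display) -> PerceptualStore:
    n = display.set_size
    return PerceptualStore(
        values={prop: [BLANK] * n for prop in display.task.properties}
    )


def detection_probability(size, ecc, theta: float, sigma: float = 0.5):
    """Probability that a property of an object is available.

    ``Phi((size - theta*ecc) / sigma)``: strictly increasing in size and,
    for ``theta > 0``, strictly decreasing in eccentricity. ``ecc`` may be
    a scalar or an array.
    """
    size = np.asarray(size, dtype=float)
    if np.any(size <= 0):
        raise ValueError("size must be > 0")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if theta < 0:
        raise ValueError("theta must be >= 0")
    ecc = np.asarray(ecc, dtype=float)
    if np.any(ecc < 0):
        raise ValueError("eccentricity must be >= 0")
    out = ndtr((size - theta * ecc) / sigma)
    return float(out) if out.ndim == 0 else out


def sample_snapshot(
    display: Display,
    eye: Sequence[float],
    avail: AvailabilityParams,
    rng: np.random.Generator,
) -> Snapshot:
    """Independent availability sampling of every object and property."""
    n = display.set_size
    ecc = np.linalg.norm(display.positions - np.asarray(eye, dtype=float), axis=1)
    values: dict[str, list] = {}
    scrambled: dict[str, np.ndarray] = {}
    for prop in display.task.properties:
        p = detection_probability(display.task.object_size, ecc, avail.theta[prop], avail.sigma)
        detected = rng.random(n) < p
        values[prop] = [
            display.objects[i].properties[prop] if detected[i] else BLANK
            for i in range(n)
        ]
        scrambled[prop] = np.zeros(n, dtype=bool)
    return Snapshot(eye=(float(eye[0]), float(eye[1])), values=values, scrambled=scrambled)


def critical_spacing(ecc):
    """Bouma critical spacing: half the eccentricity of the object."""
    return 0.5 * np.asarray(ecc, dtype=float) if np.ndim(ecc) else 0.5 * float(ecc)


def form_crowding_groups(display: Display, eye: Sequence[float]) -> list[list[int]]:
    """Partition display objects into crowding groups for this eye position.

    j crowds i iff dist(i, j) < critical_spacing(ecc_i); the directed
    relation is symmetrized and groups are its connected components.
    Isolated objects form singletons. Every object appears in exactly one
    group.
    """
    n = display.set_size
    if n == 1:
        return [[0]]
    D = display.distance_matrix
    ecc = np.linalg.norm(display.positions - np.asarray(eye, dtype=float), axis=1)
    directed = (D < critical_spacing(ecc)[:, None]) & ~np.eye(n, dtype=bool)
    linked = directed | directed.T

    # Union-find over the linked pairs; displays have <= 25 objects and this
    # runs once per fixation, so a plain loop beats sparse-graph machinery.
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in zip(*np.nonzero(np.triu(linked))):
        ri, rj = find(int(i)), find(int(j))
        if ri != rj:
            parent[rj] = ri

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


def scramble_snapshot(
    snapshot: Snapshot,
    groups: Sequence[Sequence[int]],
    crowd: CrowdingParams,
    rng: np.random.Generator,
) -> Snapshot:
    """Crowding scrambling: pairwise value swaps within each group.

    For each property independently, each object of each multi-member group
    is visited once in random order; with probability ``phi`` its current
    value (blank values included) is exchanged with that of a uniformly
    chosen *other* group member. Both swapped values are flagged as
    scrambled-in. The per-group multiset of values is conserved. A group of
    four objects therefore has scrambling applied up to four times per
    property, once per object.
    """
    values = {p: list(v) for p, v in snapshot.values.items()}
    scrambled = {p: s.copy() for p, s in snapshot.scrambled.items()}
    for prop in values:
        phi = crowd.phi.get(prop, 0.0)
        if phi == 0.0:
            continue  # identity; consumes no randomness
        vals = values[prop]
        flags = scrambled[prop]
        for group in groups:
            m = len(group)
            if m < 2:
                continue
            for gi in rng.permutation(m):
                if rng.random() >= phi:
                    continue
                i = group[gi]
                gj = int(rng.integers(m - 1))
                if gj >= gi:
                    gj += 1  # partner uniform among the *other* members
                j = group[gj]
                vals[i], vals[j] = vals[j], vals[i]
                flags[i] = flags[j] = True
    return Snapshot(eye=snapshot.eye, values=values, scrambled=scrambled)


def update_store(store: PerceptualStore, snapshot: Snapshot) -> PerceptualStore:
    """Merge a snapshot into the persistent store (in place).

    Non-blank values overwrite. A blank that was scrambled in erases the
    stored value (illusory blank); a merely unavailable blank leaves prior
    knowledge intact.
    """
    for prop, snap_vals in snapshot.values.items():
        stored = store.values[prop]
        flags = snapshot.scrambled[prop]
        for i, v in enumerate(snap_vals):
            if v is not BLANK:
                stored[i] = v
            elif flags[i]:
                stored[i] = BLANK
    return store


def _fill_from_store(snapshot: Snapshot, store: PerceptualStore) -> Snapshot:
    """Carry remembered values into the snapshot where nothing is available.

    Crowding scrambles the *perceived representation* of the objects, which
    persistence keeps populated between fixations; a remembered value can
    therefore be scrambled away just like a currently available one. Filled
    values are not flagged, so if they survive scrambling the store merge
    leaves them untouched.
    """
    values = {}
    for prop, vals in snapshot.values.items():
        stored = store.values[prop]
        values[prop] = [
            stored[i] if v is BLANK else v for i, v in enumerate(vals)
        ]
    return Snapshot(eye=snapshot.eye, values=values, scrambled=snapshot.scrambled)


def perceive(
    display: Display,
    eye: Sequence[float],
    avail: AvailabilityParams,
    crowd: CrowdingParams,
    store: PerceptualStore,
    rng: np.random.Generator,
) -> PerceptualStore:
    """One perceptual event: sample, group, scramble, merge into the store.

    Invoked at display onset and after each completed saccade. Scrambling
    operates on the persistent percept (availability sample backed by the
    store), so unresolved blanks are *moved* between crowded objects rather
    than multiplied: an unseen object can trade its blank for a neighbor's
    remembered value, which is how illusory targets, distractors, and
    blanks arise in the store.
    """
    snapshot = sample_snapshot(display, eye, avail, rng)
    if any(crowd.phi.get(p, 0.0) > 0.0 for p in display.task.properties):
        snapshot = _fill_from_store(snapshot, store)
        groups = form_crowding_groups(display, eye)
        snapshot = scramble_snapshot(snapshot, groups, crowd, rng)
    return update_store(store, snapshot)


def snapshot_to_frame(
    snapshot: Snapshot, trial_id: int = 0, fixation_index: int = 0
) -> pd.DataFrame:
    """Audit dump: one row per object and property."""
    rows = []
    for prop, vals in snapshot.values.items():
        for i, v in enumerate(vals):
            rows.append({
                "trial_id": trial_id,
                "fixation_index": fixation_index,
                "object_id": i,
                "property": prop,
                "value": "" if v is BLANK else v,
                "scrambled_in": bool(snapshot.scrambled[prop][i]),
            })
    return pd.DataFrame(
        rows,
        columns=["trial_id", "fixation_index", "object_id", "property", "value", "scrambled_in"],
    )
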