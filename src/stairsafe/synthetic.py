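"""Synthetic step geometries and observation cohorts.

The study's video data are withheld for privacy, and the per-event table
was never published.  This module provides (a) parametric generators that
emulate the cohort's statistical structure — step geometries hitting a
target mean/SD/range, traversal cohorts with rare Bernoulli fall events —
and (b) a deterministic *study fixture*: a reconstruction of the step
table and observation table consistent with every published marginal
(per-stairway means and SDs, per-flight ranges, the 20-event cross-tab
2/2/13/3, and the four published event-step heights 155, 170, 170 and
173 mm).  The fixture is synthetic: any table consistent with those
marginals is equally admissible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .events import ConditionCounts, Observation
from .geometry import (
    DEFAULT_THRESHOLD_MM,
    Flight,
    StepMeasurement,
    classify_flights,
    outlier_steps,
)

CELL_KEYS = ("lc", "ls", "hc", "hs")


# ---------------------------------------------------------------------------
# Parametric geometry generator


@dataclass(frozen=True)
class GeometrySpec:
    """Targets for one flight's step dimensions, mm.

    The generator hits ``riser_range`` (and ``depth_range``) exactly by
    pinning two anchor steps at mean +/- range/2 and reaches the mean to
    within 1 mm.
    """

    stairway: str
    position: str
    n_steps: int
    riser_mean: float
    riser_sd: float
    riser_range: float
    depth_mean: float
    depth_sd: float
    depth_range: float

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        for name in ("riser_sd", "riser_range", "depth_sd", "depth_range"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for dim in ("riser", "depth"):
            rng_, sd = getattr(self, f"{dim}_range"), getattr(self, f"{dim}_sd")
            if rng_ == 0 and sd > 0:
                raise ValueError(
                    f"infeasible spec: {dim}_range 0 with {dim}_sd {sd} > 0"
                )
            if rng_ > 0 and self.n_steps < 2:
                raise ValueError(
                    f"infeasible spec: {dim}_range {rng_} needs >= 2 steps"
                )


def _draw_dimension(
    rng: np.random.Generator, mean: float, sd: float, span: float, n: int
) -> np.ndarray:
    """n values with range exactly ``span`` and mean within 1 mm of target.

    Two anchors sit at mean +/- span/2; the remainder is truncated-normal
    within the anchors, recentred so the overall mean is on target, then
    clipped back inside the anchors (the clip perturbs the mean only in
    pathological specs).
    """
    if span == 0:
        return np.full(n, mean)
    lo, hi = mean - span / 2.0, mean + span / 2.0
    values = np.empty(n)
    values[0], values[1] = lo, hi
    m = n - 2
    if m > 0:
        if sd > 0:
            a, b = (lo - mean) / sd, (hi - mean) / sd
            rest = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=m, random_state=rng)
        else:
            rest = np.full(m, mean)
        rest = rest + (mean * n - lo - hi - rest.sum()) / m
        values[2:] = np.clip(rest, lo, hi)
    # shuffle which physical step carries each value
    return values[rng.permutation(n)]


def generate_geometry(spec: GeometrySpec, seed: int) -> Flight:
    """Generate one flight of steps matching the spec's marginals."""
    rng = np.random.default_rng(seed)
    risers = _draw_dimension(rng, spec.riser_mean, spec.riser_sd, spec.riser_range, spec.n_steps)
    depths = _draw_dimension(rng, spec.depth_mean, spec.depth_sd, spec.depth_range, spec.n_steps)
    steps = tuple(
        StepMeasurement(
            stairway=spec.stairway,
            flight=spec.position,
            step_index=i + 1,
            riser_height_mm=float(risers[i]),
            tread_depth_mm=float(depths[i]),
        )
        for i in range(spec.n_steps)
    )
    return Flight(stairway=spec.stairway, position=spec.position, steps=steps)


# ---------------------------------------------------------------------------
# Parametric cohort generator


@dataclass(frozen=True)
class CohortSpec:
    """Shape of a synthetic traversal cohort.

    ``fall_rates`` gives the per-traversal fall-event probability in each
    variation x condition cell (keys lc/ls/hc/hs).  The default allocation
    spreads traversals evenly over flight x condition slots, matching the
    study's counterbalanced, balanced design.  ``outlier_weight`` is the
    probability that an event's step is drawn from the flight's outlier
    steps (when any exist) rather than uniformly.
    """

    seed: int
    n_observations: int = 11_137
    fall_rates: Mapping[str, float] = field(
        default_factory=lambda: {"lc": 0.0, "ls": 0.0, "hc": 0.0, "hs": 0.0}
    )
    ascent_share: float = 0.5
    over_40_share: float = 0.015
    exclusion_rate: float = 0.0
    outlier_weight: float = 0.7
    allocation: Optional[Mapping[tuple[str, str, str], int]] = None

    def __post_init__(self) -> None:
        if self.n_observations < 0:
            raise ValueError("n_observations must be >= 0")
        for key in CELL_KEYS:
            rate = self.fall_rates.get(key, 0.0)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"fall rate for {key} must be in [0, 1], got {rate}")
        for name in ("ascent_share", "over_40_share", "exclusion_rate", "outlier_weight"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.allocation is not None:
            total = sum(self.allocation.values())
            if total != self.n_observations:
                raise ValueError(
                    f"allocation sums to {total}, expected {self.n_observations}"
                )


_EXCLUSION_CYCLE = ("assistive_device", "did_not_traverse", "unusual_behavior")


def _default_allocation(
    n_observations: int, flights: Sequence[Flight]
) -> dict[tuple[str, str, str], int]:
    """Even split of traversals over flight x condition slots."""
    slots = [
        (f.stairway, f.position, condition)
        for f in flights
        for condition in ("control", "stripe")
    ]
    base, extra = divmod(n_observations, len(slots))
    return {slot: base + (1 if i < extra else 0) for i, slot in enumerate(slots)}


def generate_cohort(
    spec: CohortSpec,
    flights: Sequence[Flight],
    threshold_mm: float = DEFAULT_THRESHOLD_MM,
) -> list[Observation]:
    """Generate a traversal cohort with Bernoulli fall events.

    Each traversal is assigned a flight/condition slot per the allocation;
    its fall probability is the rate of the (variation class, condition)
    cell.  Events are placed preferentially on the flight's outlier steps.
    Fall events are independent across traversals.  Reproducible from the
    seed.
    """
    rng = np.random.default_rng(spec.seed)
    classes = classify_flights(flights, threshold_mm)
    flight_by_key = {f.key: f for f in flights}
    outliers_by_key = {f.key: sorted(outlier_steps(f)) if len(f.steps) >= 2 else []
                       for f in flights}
    allocation = (
        dict(spec.allocation)
        if spec.allocation is not None
        else _default_allocation(spec.n_observations, flights)
    )

    observations: list[Observation] = []
    obs_counter = 0
    for (stairway, position, condition), size in allocation.items():
        key = (stairway, position)
        if key not in flight_by_key:
            raise KeyError(f"allocation references unknown flight {stairway}/{position}")
        cell = ("h" if classes[key] == "high" else "l") + (
            "c" if condition == "control" else "s"
        )
        rate = spec.fall_rates.get(cell, 0.0)
        falls = rng.random(size) < rate
        ascents = rng.random(size) < spec.ascent_share
        over40 = rng.random(size) < spec.over_40_share
        excluded = rng.random(size) < spec.exclusion_rate
        n_steps = len(flight_by_key[key].steps)
        outlier_idx = outliers_by_key[key]
        for i in range(size):
            obs_counter += 1
            step_index: Optional[int] = None
            if falls[i]:
                if outlier_idx and rng.random() < spec.outlier_weight:
                    step_index = int(rng.choice(outlier_idx))
                else:
                    step_index = int(rng.integers(1, n_steps + 1))
            reason = "none"
            if excluded[i]:
                reason = _EXCLUSION_CYCLE[obs_counter % len(_EXCLUSION_CYCLE)]
            observations.append(
                Observation(
                    obs_id=f"obs-{obs_counter:06d}",
                    stairway=stairway,
                    flight=position,
                    condition=condition,
                    direction="ascent" if ascents[i] else "descent",
                    fall_event=bool(falls[i]),
                    step_index=step_index,
                    age_group="over-40" if over40[i] else "18-40",
                    exclusion_reason=reason,
                )
            )
    return observations


def calibrate_rates(
    target_counts: ConditionCounts, cell_sizes: Mapping[str, int]
) -> dict[str, float]:
    """Per-cell Bernoulli rates whose expectation reproduces the targets.

    Inverse of the cohort generator's expectation: rate = target / cell
    size.  Errors if any target exceeds its cell size.
    """
    rates = {}
    targets = dict(zip(CELL_KEYS, target_counts.as_tuple()))
    for key in CELL_KEYS:
        size = cell_sizes[key]
        if size <= 0:
            raise ValueError(f"cell size for {key} must be positive, got {size}")
        if targets[key] > size:
            raise ValueError(
                f"target {targets[key]} exceeds cell size {size} for {key}"
            )
        rates[key] = targets[key] / size
    return rates


# ---------------------------------------------------------------------------
# Deterministic study fixture
#
# Integer step tables reconstructed to match every published marginal:
#   riser means/SDs  East 166 (3), West 171 (3), combined 168 (4)
#   depth means/SDs  East 329 (8), West 327 (8), combined 328 (8)
#   riser ranges     East lower 14, East upper 5, West lower 14, West upper 12
#   depth ranges     East lower 38, East upper 4, West lower 38, West upper 6
# and carrying the four published event steps: 155 mm (East lower, step 1),
# 170 mm (East upper, steps 1 and 12) and 173 mm (West lower, step 11).

_STUDY_RISERS = {
    ("East", "lower"): [155, 169, 166, 166, 167, 167, 166, 166, 167, 166, 166, 167],
    ("East", "upper"): [170, 165, 165, 166, 166, 165, 166, 166, 165, 166, 166, 170],
    ("West", "lower"): [164, 178, 171, 171, 170, 172, 170, 172, 171, 171, 173, 171],
    ("West", "upper"): [165, 171, 171, 170, 171, 171, 171, 170, 171, 170, 171, 177],
}

_STUDY_DEPTHS = {
    ("East", "lower"): [310, 348, 316, 342, 318, 340, 321, 337, 325, 333, 329, 329],
    ("East", "upper"): [327, 329, 329, 329, 329, 329, 329, 329, 329, 329, 329, 331],
    ("West", "lower"): [308, 346, 314, 340, 316, 338, 319, 335, 323, 331, 327, 327],
    ("West", "upper"): [324, 327, 327, 327, 327, 327, 327, 327, 327, 327, 327, 330],
}


def study_flights() -> list[Flight]:
    """The four study flights (East/West x lower/upper), 12 steps each."""
    flights = []
    for (stairway, position), risers in _STUDY_RISERS.items():
        depths = _STUDY_DEPTHS[(stairway, position)]
        steps = tuple(
            StepMeasurement(stairway, position, i + 1, float(r), float(d))
            for i, (r, d) in enumerate(zip(risers, depths))
        )
        flights.append(Flight(stairway=stairway, position=position, steps=steps))
    return flights


# (stairway, position, condition, n_events, direction, step_index or None)
_STUDY_EVENTS = [
    # HC = 13: East lower control 7 (3 on the 155 mm bottom step, descending)
    ("East", "lower", "control", 3, "descent", 1),
    ("East", "lower", "control", 2, "ascent", None),
    ("East", "lower", "control", 2, "descent", None),
    # ... West lower control 6 (1 on the 173 mm second-to-last step, ascending)
    ("West", "lower", "control", 1, "ascent", 11),
    ("West", "lower", "control", 3, "ascent", None),
    ("West", "lower", "control", 2, "descent", None),
    # HS = 3
    ("East", "lower", "stripe", 2, "descent", None),
    ("West", "lower", "stripe", 1, "ascent", None),
    # LC = 2: both on the 170 mm first step of the East upper flight, ascending
    ("East", "upper", "control", 2, "ascent", 1),
    # LS = 2: one on the 170 mm last step of the East upper flight, ascending
    ("East", "upper", "stripe", 1, "ascent", 12),
    ("West", "upper", "stripe", 1, "ascent", None),
]

#: Retained traversals per stairway x condition (total 11,137, balanced).
_STUDY_CELL_SIZES = {
    ("East", "control"): 2785,
    ("East", "stripe"): 2784,
    ("West", "control"): 2784,
    ("West", "stripe"): 2784,
}

#: Rows removed during data cleaning, appended on top of the retained total.
_STUDY_EXCLUSIONS = {
    "assistive_device": 40,
    "did_not_traverse": 35,
    "unusual_behavior": 15,
    "under_18": 10,
}


def study_observations() -> list[Observation]:
    """Deterministic reconstruction of the observation table.

    11,237 rows: 11,137 retained traversals balanced across stairway x
    condition carrying exactly 20 fall events in the published 2/2/13/3
    pattern, plus 100 rows that the inclusion/exclusion filter removes.
    Fully deterministic — no RNG.
    """
    observations: list[Observation] = []
    counter = 0

    def add(stairway, flight, condition, direction, fall, step, age="18-40", reason="none"):
        nonlocal counter
        counter += 1
        observations.append(
            Observation(
                obs_id=f"obs-{counter:06d}",
                stairway=stairway,
                flight=flight,
                condition=condition,
                direction=direction,
                fall_event=fall,
                step_index=step,
                age_group=age,
                exclusion_reason=reason,
            )
        )

    # fall events first
    for stairway, flight, condition, n, direction, step in _STUDY_EVENTS:
        for _ in range(n):
            add(stairway, flight, condition, direction, True, step)
    n_events = counter

    # non-event traversals filling each stairway x condition cell, split
    # as evenly as possible over the lower/upper flights
    events_per_slot: dict[tuple[str, str, str], int] = {}
    for stairway, flight, condition, n, _, _ in _STUDY_EVENTS:
        slot = (stairway, flight, condition)
        events_per_slot[slot] = events_per_slot.get(slot, 0) + n
    for (stairway, condition), cell_size in _STUDY_CELL_SIZES.items():
        lower_size = (cell_size + 1) // 2
        for flight, slot_size in (("lower", lower_size), ("upper", cell_size - lower_size)):
            n_fill = slot_size - events_per_slot.get((stairway, flight, condition), 0)
            for i in range(n_fill):
                add(
                    stairway,
                    flight,
                    condition,
                    "ascent" if i % 2 == 0 else "descent",
                    False,
                    None,
                    age="over-40" if i % 67 == 0 else "18-40",
                )

    # rows the cleaning phase removes
    stairways = ("East", "West")
    flights = ("lower", "upper")
    conditions = ("control", "stripe")
    i = 0
    for reason, n in _STUDY_EXCLUSIONS.items():
        for _ in range(n):
            add(
                stairways[i % 2],
                flights[(i // 2) % 2],
                conditions[(i // 4) % 2],
                "ascent" if i % 2 == 0 else "descent",
                False,
                None,
                age="under-18" if reason == "under_18" else "18-40",
                reason=reason,
            )
            i += 1
    return observations
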