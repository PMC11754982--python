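"""Observation filtering and cross-tabulation of fall-related events.

Each observation is one stair-user traversal, coded for direction, study
condition (control vs high-contrast striping) and whether a fall-related
event occurred — anything from a subtle trip or slip with minimal recovery
through a complete loss of balance.  After applying the study's
inclusion/exclusion rules, fall events are cross-tabulated into four cells:
low/high interstep variation crossed with control/stripe (LC, LS, HC, HS).
The striping intervention was counterbalanced between stairways halfway
through data collection, so condition is a per-observation attribute and is
never inferred from stairway identity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

CONDITIONS = frozenset({"control", "stripe"})
DIRECTIONS = frozenset({"ascent", "descent"})
AGE_GROUPS = frozenset({"18-40", "over-40", "under-18"})
EXCLUSION_REASONS = frozenset(
    {"assistive_device", "did_not_traverse", "unusual_behavior", "under_18", "none"}
)
UNDER_18 = "under-18"

#: Expected header of an observation CSV.
OBSERVATION_COLUMNS = [
    "obs_id",
    "stairway",
    "flight",
    "condition",
    "direction",
    "fall_event",
    "step_index",
    "age_group",
    "exclusion_reason",
]


@dataclass(frozen=True)
class Observation:
    """One stair-user traversal of a flight."""

    obs_id: str
    stairway: str
    flight: str
    condition: str
    direction: str
    fall_event: bool
    step_index: Optional[int] = None
    age_group: str = "18-40"
    exclusion_reason: str = "none"

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.age_group not in AGE_GROUPS:
            raise ValueError(f"unknown age_group {self.age_group!r}")
        if self.exclusion_reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion_reason {self.exclusion_reason!r}")
        if self.step_index is not None and self.step_index < 1:
            raise ValueError(f"step_index must be >= 1, got {self.step_index}")


@dataclass
class FilterTally:
    """Per-category removal counts from the inclusion/exclusion filter."""

    retained: int = 0
    removed: dict = field(default_factory=dict)

    @property
    def total_removed(self) -> int:
        return sum(self.removed.values())

    def as_dict(self) -> dict:
        return {"retained": self.retained, "removed": dict(self.removed)}


@dataclass(frozen=True)
class ConditionCounts:
    """Fall-event counts in the four variation x condition cells.

    lc/ls: low interstep variation under control / stripe;
    hc/hs: high interstep variation under control / stripe.
    """

    lc: int
    ls: int
    hc: int
    hs: int

    def __post_init__(self) -> None:
        for name in ("lc", "ls", "hc", "hs"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise TypeError(f"{name} must be an integer, got {v!r}")
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")

    @property
    def n(self) -> int:
        return self.lc + self.ls + self.hc + self.hs

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.lc, self.ls, self.hc, self.hs)

    def as_dict(self) -> dict:
        return {"lc": self.lc, "ls": self.ls, "hc": self.hc, "hs": self.hs, "n": self.n}


def round_percent(value: float) -> int:
    """Round a percentage to integer, halves away from zero (81.25 -> 81,
    18.75 -> 19 after complementing; 0.5 -> 1)."""
    return int(math.floor(abs(value) + 0.5)) * (1 if value >= 0 else -1)


def filter_observations(
    raw: Sequence[Observation],
) -> tuple[list[Observation], FilterTally]:
    """Apply the study's inclusion/exclusion rules.

    Removes traversals with any recorded exclusion reason (assistive walking
    devices, not actually traversing the stairs, unusual stairway behaviour)
    and observations in the under-18 age group.  Order is preserved; one log
    line per removal category.
    """
    tally = FilterTally()
    kept: list[Observation] = []
    for obs in raw:
        if obs.exclusion_reason != "none":
            tally.removed[obs.exclusion_reason] = (
                tally.removed.get(obs.exclusion_reason, 0) + 1
            )
        elif obs.age_group == UNDER_18:
            tally.removed["under_18"] = tally.removed.get("under_18", 0) + 1
        else:
            kept.append(obs)
    tally.retained = len(kept)
    for reason, count in sorted(tally.removed.items()):
        logger.info("filter: removed %d observation(s): %s", count, reason)
    logger.info("filter: retained %d of %d observations", len(kept), len(raw))
    return kept, tally


def cross_tabulate(
    observations: Iterable[Observation],
    flight_classes: Mapping[tuple[str, str], str],
) -> ConditionCounts:
    """Count fall events in the four variation x condition cells.

    ``flight_classes`` maps (stairway, flight) -> "high"/"low" as produced
    by :func:`stairsafe.geometry.classify_flights`.  Every fall event lands
    in exactly one cell; an event on a flight absent from the mapping is an
    error naming that flight.
    """
    cells = {"lc": 0, "ls": 0, "hc": 0, "hs": 0}
    for obs in observations:
        if not obs.fall_event:
            continue
        key = (obs.stairway, obs.flight)
        if key not in flight_classes:
            raise KeyError(
                f"observation {obs.obs_id}: unknown flight "
                f"{obs.stairway}/{obs.flight}"
            )
        var = flight_classes[key]
        cell = ("h" if var == "high" else "l") + (
            "c" if obs.condition == "control" else "s"
        )
        cells[cell] += 1
    return ConditionCounts(**cells)


def summarize_events(counts: ConditionCounts) -> dict:
    """Proportions report over the four cells.

    Reports the high-variation share (hc+hs)/n and, within the
    high-variation events, the control and stripe shares.  Percentages are
    carried at full precision alongside integer display values.  With no
    events the report is defined but flagged not evaluable.
    """
    report: dict = {"counts": counts.as_dict()}
    if counts.n == 0:
        report["evaluable"] = False
        return report
    report["evaluable"] = True
    high = counts.hc + counts.hs
    low = counts.lc + counts.ls
    report["high_variation_share_pct"] = 100.0 * high / counts.n
    report["low_variation_share_pct"] = 100.0 * low / counts.n
    if high > 0:
        report["control_within_high_pct"] = 100.0 * counts.hc / high
        report["stripe_within_high_pct"] = 100.0 * counts.hs / high
    report["display"] = {
        k.replace("_pct", ""): round_percent(v)
        for k, v in report.items()
        if k.endswith("_pct")
    }
    return report


# ---------------------------------------------------------------------------
# CSV I/O


def _parse_row(row: dict) -> Observation:
    fall_raw = str(row["fall_event"]).strip().lower()
    if fall_raw not in {"true", "false"}:
        raise ValueError(f"fall_event must be true/false, got {row['fall_event']!r}")
    step_raw = row.get("step_index")
    step_index = None
    if step_raw is not None and str(step_raw).strip() not in ("", "nan"):
        step_index = int(float(step_raw))
    return Observation(
        obs_id=str(row["obs_id"]),
        stairway=str(row["stairway"]).strip(),
        flight=str(row["flight"]).strip(),
        condition=str(row["condition"]).strip(),
        direction=str(row["direction"]).strip(),
        fall_event=fall_raw == "true",
        step_index=step_index,
        age_group=str(row["age_group"]).strip(),
        exclusion_reason=str(row["exclusion_reason"]).strip(),
    )


def observations_from_frame(
    frame: pd.DataFrame,
) -> tuple[list[Observation], list[dict]]:
    """Parse an observation table; malformed rows go to a rejects report.

    Returns (observations, rejects) where each reject records the 1-based
    row number and the parse error, rather than being silently dropped.
    """
    missing = [c for c in OBSERVATION_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"observation table missing columns: {missing}")
    observations: list[Observation] = []
    rejects: list[dict] = []
    for i, row in enumerate(frame.to_dict("records"), start=1):
        try:
            observations.append(_parse_row(row))
        except (ValueError, TypeError, KeyError) as exc:
            rejects.append({"row": i, "error": str(exc)})
    if rejects:
        logger.warning("rejected %d malformed observation row(s)", len(rejects))
    return observations, rejects


def read_observations(path) -> tuple[list[Observation], list[dict]]:
    """Read an observation CSV; booleans as true/false, blank step_index
    for non-events."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    return observations_from_frame(frame)


def observations_to_frame(observations: Iterable[Observation]) -> pd.DataFrame:
    rows = [
        {
            "obs_id": o.obs_id,
            "stairway": o.stairway,
            "flight": o.flight,
            "condition": o.condition,
            "direction": o.direction,
            "fall_event": "true" if o.fall_event else "false",
            "step_index": "" if o.step_index is None else str(o.step_index),
            "age_group": o.age_group,
            "exclusion_reason": o.exclusion_reason,
        }
        for o in observations
    ]
    return pd.DataFrame(rows, columns=OBSERVATION_COLUMNS)


def write_observations(observations: Iterable[Observation], path) -> None:
    observations_to_frame(observations).to_csv(path, index=False)
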