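"""Step-level stairway geometry and flight-level interstep variation.

Building codes describe stairway "dimensional uniformity" as the tolerance
between the largest and smallest riser height (or tread depth) within one
flight; here that range is called *interstep variation*.  A flight whose
riser-height range reaches a configurable threshold (default 13 mm, i.e.
approximately 0.5 in) is classified *high* variation, otherwise *low*.
All lengths are millimetres internally; a display helper rounds to the
nearest mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

#: Default riser-range threshold separating high from low interstep
#: variation, in mm.  0.5 in is 12.7 mm; epidemiological precedent uses the
#: rounded 13 mm figure, and the comparison is inclusive (range >= threshold
#: is high).
DEFAULT_THRESHOLD_MM: float = 13.0

MM_PER_INCH: float = 25.4

#: Expected header of a step-geometry CSV.
GEOMETRY_COLUMNS = [
    "stairway",
    "flight",
    "step_index",
    "riser_height_mm",
    "tread_depth_mm",
]

HIGH = "high"
LOW = "low"


def inches_to_mm(inches: float) -> float:
    """Convert a threshold given in inches to mm (25.4 mm/in)."""
    return inches * MM_PER_INCH


def round_mm(value: float) -> int:
    """Round a length to the nearest mm, halves away from zero.

    Matches the reporting convention of the source measurements, which are
    printed as whole millimetres.
    """
    return int(math.floor(abs(value) + 0.5)) * (1 if value >= 0 else -1)


@dataclass(frozen=True)
class StepMeasurement:
    """One physical step: riser height and tread depth in mm.

    ``step_index`` counts from the bottom of the flight to the top,
    starting at 1.
    """

    stairway: str
    flight: str
    step_index: int
    riser_height_mm: float
    tread_depth_mm: float

    def __post_init__(self) -> None:
        if self.step_index < 1:
            raise ValueError(f"step_index must be >= 1, got {self.step_index}")
        if not self.riser_height_mm > 0:
            raise ValueError(
                f"riser_height_mm must be positive, got {self.riser_height_mm}"
            )
        if not self.tread_depth_mm > 0:
            raise ValueError(
                f"tread_depth_mm must be positive, got {self.tread_depth_mm}"
            )


@dataclass(frozen=True)
class Flight:
    """An ordered run of steps between landings on one stairway.

    Steps must carry unique, contiguous indices 1..n.  The derived
    ``riser_range`` / ``depth_range`` are max - min over the flight, and
    ``variation_class`` depends solely on the riser range and the
    threshold.
    """

    stairway: str
    position: str  # "lower" or "upper"
    steps: tuple[StepMeasurement, ...]

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("a flight must contain at least one step")
        indices = sorted(s.step_index for s in self.steps)
        if indices != list(range(1, len(self.steps) + 1)):
            raise ValueError(
                f"step indices must be contiguous from 1; got {indices} "
                f"for flight {self.stairway}/{self.position}"
            )
        # store steps sorted bottom-to-top
        object.__setattr__(
            self, "steps", tuple(sorted(self.steps, key=lambda s: s.step_index))
        )

    @property
    def key(self) -> tuple[str, str]:
        return (self.stairway, self.position)

    @property
    def riser_heights(self) -> np.ndarray:
        return np.array([s.riser_height_mm for s in self.steps], dtype=float)

    @property
    def tread_depths(self) -> np.ndarray:
        return np.array([s.tread_depth_mm for s in self.steps], dtype=float)

    @property
    def riser_range(self) -> float:
        return variation_range(self.riser_heights)

    @property
    def depth_range(self) -> float:
        return variation_range(self.tread_depths)

    def variation_class(self, threshold_mm: float = DEFAULT_THRESHOLD_MM) -> str:
        return classify_flight(self.riser_range, threshold_mm)


@dataclass(frozen=True)
class FlightSummary:
    """Mean and sample SD (n-1 denominator) of a flight's dimensions, mm.

    SD fields are ``None`` for a single-step flight, where the sample SD is
    undefined.
    """

    stairway: str
    position: str
    n_steps: int
    riser_mean: float
    riser_sd: Optional[float]
    riser_range: float
    depth_mean: float
    depth_sd: Optional[float]
    depth_range: float

    def rounded(self) -> dict:
        """Display form: every length rounded to the nearest mm."""
        return {
            "stairway": self.stairway,
            "position": self.position,
            "n_steps": self.n_steps,
            "riser_mean_mm": round_mm(self.riser_mean),
            "riser_sd_mm": None if self.riser_sd is None else round_mm(self.riser_sd),
            "riser_range_mm": round_mm(self.riser_range),
            "depth_mean_mm": round_mm(self.depth_mean),
            "depth_sd_mm": None if self.depth_sd is None else round_mm(self.depth_sd),
            "depth_range_mm": round_mm(self.depth_range),
        }


def variation_range(values: Sequence[float] | np.ndarray) -> float:
    """Interstep variation: max - min of a non-empty list of lengths (mm).

    A single value has zero range.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("variation_range requires at least one value")
    if np.any(arr <= 0):
        raise ValueError("lengths must be strictly positive")
    return float(arr.max() - arr.min())


def classify_flight(
    riser_range: float, threshold_mm: float = DEFAULT_THRESHOLD_MM
) -> str:
    """Classify a flight as ``"high"`` or ``"low"`` interstep variation.

    The comparison is inclusive: a riser range exactly at the threshold is
    high.
    """
    if riser_range < 0:
        raise ValueError(f"riser_range must be >= 0, got {riser_range}")
    if not threshold_mm > 0:
        raise ValueError(f"threshold_mm must be positive, got {threshold_mm}")
    return HIGH if riser_range >= threshold_mm else LOW


def flight_summary(flight: Flight) -> FlightSummary:
    """Mean and sample SD of riser heights and tread depths for one flight."""
    risers = flight.riser_heights
    depths = flight.tread_depths
    n = len(flight.steps)
    return FlightSummary(
        stairway=flight.stairway,
        position=flight.position,
        n_steps=n,
        riser_mean=float(risers.mean()),
        riser_sd=float(risers.std(ddof=1)) if n >= 2 else None,
        riser_range=flight.riser_range,
        depth_mean=float(depths.mean()),
        depth_sd=float(depths.std(ddof=1)) if n >= 2 else None,
        depth_range=flight.depth_range,
    )


def outlier_steps(flight: Flight) -> set[int]:
    """Indices of steps whose riser height deviates more than 1 SD from the
    flight mean (strict inequality).

    Requires at least two steps.  A zero-SD flight (all risers equal) has no
    outliers.
    """
    if len(flight.steps) < 2:
        raise ValueError("outlier detection requires a flight with >= 2 steps")
    risers = flight.riser_heights
    mean = risers.mean()
    sd = risers.std(ddof=1)
    if sd == 0:
        return set()
    return {
        s.step_index
        for s in flight.steps
        if abs(s.riser_height_mm - mean) > sd
    }


def classify_flights(
    flights: Iterable[Flight], threshold_mm: float = DEFAULT_THRESHOLD_MM
) -> dict[tuple[str, str], str]:
    """Map (stairway, flight position) -> variation class for a set of flights."""
    return {f.key: f.variation_class(threshold_mm) for f in flights}


# ---------------------------------------------------------------------------
# CSV I/O


def flights_from_frame(frame: pd.DataFrame) -> list[Flight]:
    missing = [c for c in GEOMETRY_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"geometry table missing columns: {missing}")
    flights = []
    for (stairway, position), group in frame.groupby(
        ["stairway", "flight"], sort=True
    ):
        steps = tuple(
            StepMeasurement(
                stairway=str(stairway),
                flight=str(position),
                step_index=int(row.step_index),
                riser_height_mm=float(row.riser_height_mm),
                tread_depth_mm=float(row.tread_depth_mm),
            )
            for row in group.itertuples()
        )
        flights.append(Flight(stairway=str(stairway), position=str(position), steps=steps))
    return flights


def read_geometry(path) -> list[Flight]:
    """Read a step-geometry CSV (one row per step) into flights."""
    return flights_from_frame(pd.read_csv(path))


def flights_to_frame(flights: Iterable[Flight]) -> pd.DataFrame:
    rows = [
        {
            "stairway": s.stairway,
            "flight": f.position,
            "step_index": s.step_index,
            "riser_height_mm": s.riser_height_mm,
            "tread_depth_mm": s.tread_depth_mm,
        }
        for f in flights
        for s in f.steps
    ]
    return pd.DataFrame(rows, columns=GEOMETRY_COLUMNS)


def write_geometry(flights: Iterable[Flight], path) -> None:
    flights_to_frame(flights).to_csv(path, index=False)
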