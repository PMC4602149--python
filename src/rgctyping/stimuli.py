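"""Visual stimulus protocols for functional typing of retinal ganglion cells.

Four protocols are generated as timed event sequences with exact geometry,
so that the simulator and the response-parameter extractors share one
authoritative stimulus description:

* **marching square** -- a 100 um bright square flashed at 81 pseudo-randomly
  ordered locations on a 9 x 9 grid covering a 900 x 900 um area, five
  repetitions per location.  Used for receptive-field mapping, ON/OFF bias,
  latency and transience.
* **narrow moving bars** -- bright bars (1000 um along the motion axis,
  500 um across it) swept in eight directions at three lateral offsets and
  two speeds.  Used for direction selectivity.
* **width test** -- bright and dark bars of five widths at two speeds in four
  directions.  Used for the preferred-width index.
* **speed test** -- bright and dark bars of two widths at six speeds in four
  directions.  Used for the preferred-speed index.

Coordinates are continuous micrometres with the origin at the lower-left
corner of the projected field.  Directions are in degrees, 0 deg = motion
toward +x, counterclockwise positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FieldGeometry",
    "SquareFlashEvent",
    "MovingBarEvent",
    "StimulusSet",
    "make_marching_square",
    "make_narrow_bars",
    "make_width_test",
    "make_speed_test",
    "bar_crossing_time",
    "bar_traversal_duration",
    "events_to_table",
    "write_event_log",
    "read_event_log",
]

#: grid constants of the marching-square protocol
SQUARE_SIDE_UM = 100.0
GRID_N = 9
GRID_EXTENT_UM = 900.0
N_REPETITIONS = 5

#: default per-protocol kinematics
NARROW_BAR_SPEEDS = (600.0, 1200.0)
NARROW_BAR_OFFSETS = (-250.0, 0.0, 250.0)
NARROW_BAR_WIDTH = 1000.0   # extent along the motion axis
NARROW_BAR_LENGTH = 500.0   # extent orthogonal to the motion axis
WIDTH_TEST_WIDTHS = (75.0, 150.0, 300.0, 600.0, 900.0)
WIDTH_TEST_SPEEDS = (150.0, 900.0)
SPEED_TEST_WIDTHS = (150.0, 600.0)
SPEED_TEST_SPEEDS = (150.0, 300.0, 600.0, 900.0, 1200.0, 1800.0)


@dataclass(frozen=True)
class FieldGeometry:
    """Projected stimulus field (default 1 x 1 mm)."""

    width: float = 1000.0
    height: float = 1000.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("field width and height must be positive")

    @property
    def center(self) -> np.ndarray:
        return np.asarray(self.origin, dtype=float) + [self.width / 2, self.height / 2]

    def extent_along(self, direction_deg: float) -> float:
        """Support extent of the field rectangle along a motion axis."""
        th = np.deg2rad(direction_deg)
        return abs(np.cos(th)) * self.width + abs(np.sin(th)) * self.height

    def contains(self, point: Sequence[float]) -> bool:
        p = np.asarray(point, dtype=float) - np.asarray(self.origin, dtype=float)
        return bool(0 <= p[0] <= self.width and 0 <= p[1] <= self.height)


@dataclass(frozen=True)
class SquareFlashEvent:
    """One flashed-square presentation; the square is visible for `duration`
    seconds and its disappearance (return to background) anchors OFF-response
    windows."""

    center: tuple[float, float]
    onset: float
    side: float = SQUARE_SIDE_UM
    contrast: float = 1.0
    duration: float = 2.0
    repetition: int = 0

    @property
    def offset(self) -> float:
        return self.onset + self.duration

    kind = "square"


@dataclass(frozen=True)
class MovingBarEvent:
    """One moving-bar sweep across the field.

    `bar_width` is the extent along the motion axis, `bar_length` the extent
    orthogonal to it.  The leading edge enters the field at `onset`; the
    trailing edge leaves it at `offset`.  `lateral_offset` displaces the bar
    path orthogonally to the motion vector.
    """

    direction: float
    speed: float
    bar_width: float
    bar_length: float
    onset: float
    lateral_offset: float = 0.0
    contrast: float = 1.0
    field: FieldGeometry = field(default_factory=FieldGeometry)

    def __post_init__(self) -> None:
        if self.speed <= 0 or self.bar_width <= 0 or self.bar_length <= 0:
            raise ValueError("speed, bar_width and bar_length must be positive")

    @property
    def traversal_duration(self) -> float:
        return bar_traversal_duration(self)

    @property
    def offset(self) -> float:
        return self.onset + self.traversal_duration

    kind = "bar"


@dataclass
class StimulusSet:
    """Ordered, non-overlapping event sequence of one protocol run."""

    protocol_name: str
    events: list
    rng_seed: int
    field: FieldGeometry = field(default_factory=FieldGeometry)
    lead_in: float = 5.0
    gap: float = 0.5

    def __len__(self) -> int:
        return len(self.events)

    @property
    def total_duration(self) -> float:
        if not self.events:
            return self.lead_in
        return self.events[-1].offset + self.gap

    def background_intervals(self) -> list[tuple[float, float]]:
        """Stimulus-free intervals (used for baseline-rate estimation)."""
        out = [(0.0, self.lead_in)]
        prev = None
        for ev in self.events:
            if prev is not None and ev.onset > prev:
                out.append((prev, ev.onset))
            prev = ev.offset
        return out


def _sequence_events(events: list, lead_in: float, gap: float, order: np.ndarray,
                     durations: np.ndarray) -> list:
    """Lay permuted events head-to-tail with a fixed background gap."""
    t = lead_in
    out = []
    for idx in order:
        ev = events[idx]
        out.append(replace(ev, onset=t))
        t += durations[idx] + gap
    return out


def make_marching_square(geometry: FieldGeometry | None = None, seed: int = 0, *,
                         duration: float = 2.0, gap: float = 2.0,
                         n_repetitions: int = N_REPETITIONS,
                         contrast: float = 1.0, lead_in: float = 5.0) -> StimulusSet:
    """Marching-square-over-grid protocol: 81 locations x 5 repetitions.

    The 9 x 9 grid of 100 um cells is centred in the field; cell centres sit
    at ``margin + 50 + 100*i``.  Presentation order is a seeded pseudo-random
    permutation of all (location, repetition) pairs.  The inter-event gap
    defaults to 2 s so that the 1.5 s OFF-response window following square
    disappearance falls entirely on background.
    """
    geometry = geometry or FieldGeometry()
    if geometry.width < GRID_EXTENT_UM or geometry.height < GRID_EXTENT_UM:
        raise ValueError(
            f"field {geometry.width} x {geometry.height} um cannot hold the "
            f"{GRID_EXTENT_UM} x {GRID_EXTENT_UM} um marching-square grid"
        )
    ox, oy = geometry.origin
    mx = ox + (geometry.width - GRID_EXTENT_UM) / 2
    my = oy + (geometry.height - GRID_EXTENT_UM) / 2
    centers = [
        (mx + SQUARE_SIDE_UM * (i + 0.5), my + SQUARE_SIDE_UM * (j + 0.5))
        for j in range(GRID_N) for i in range(GRID_N)
    ]
    events = [
        SquareFlashEvent(center=c, onset=0.0, duration=duration,
                         contrast=contrast, repetition=r)
        for r in range(n_repetitions) for c in centers
    ]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(events))
    durations = np.full(len(events), duration)
    return StimulusSet("marching_square",
                       _sequence_events(events, lead_in, gap, order, durations),
                       rng_seed=seed, field=geometry, lead_in=lead_in, gap=gap)


def _bar_events(geometry: FieldGeometry, combos: Iterable[tuple], seed: int,
                lead_in: float, gap: float, protocol: str) -> StimulusSet:
    events = []
    for direction, offset, speed, width, length, contrast in combos:
        events.append(MovingBarEvent(direction=direction, speed=speed,
                                     bar_width=width, bar_length=length,
                                     lateral_offset=offset, contrast=contrast,
                                     onset=0.0, field=geometry))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(events))
    durations = np.array([ev.traversal_duration for ev in events])
    return StimulusSet(protocol, _sequence_events(events, lead_in, gap, order, durations),
                       rng_seed=seed, field=geometry, lead_in=lead_in, gap=gap)


def make_narrow_bars(geometry: FieldGeometry | None = None,
                     speeds: Sequence[float] = NARROW_BAR_SPEEDS,
                     seed: int = 0, *, lead_in: float = 5.0, gap: float = 0.5) -> StimulusSet:
    """Narrow-moving-bars protocol: 8 directions x 3 lateral offsets x speeds.

    Bright bars, 1000 um along the motion axis and 500 um across it; the
    three offsets guarantee that every retinal location is swept in every
    direction, and the bar nearest each receptive-field centre is selected
    post hoc during analysis.
    """
    geometry = geometry or FieldGeometry()
    speeds = tuple(speeds)
    if not speeds:
        raise ValueError("speeds must be non-empty")
    if any(s <= 0 or s > 5000 for s in speeds):
        raise ValueError("speeds must lie in (0, 5000] um/s")
    combos = [
        (d, off, s, NARROW_BAR_WIDTH, NARROW_BAR_LENGTH, 1.0)
        for d in np.arange(8) * 45.0
        for off in NARROW_BAR_OFFSETS
        for s in speeds
    ]
    return _bar_events(geometry, combos, seed, lead_in, gap, "narrow_bars")


def make_width_test(geometry: FieldGeometry | None = None, seed: int = 0, *,
                    lead_in: float = 5.0, gap: float = 0.5) -> StimulusSet:
    """Width test: 5 widths x 2 contrasts x 4 directions x 2 speeds = 80 bars.

    Bars span the full field orthogonally to their motion axis.
    """
    geometry = geometry or FieldGeometry()
    combos = [
        (d, 0.0, s, w, geometry.extent_along(d + 90.0), c)
        for w in WIDTH_TEST_WIDTHS
        for c in (1.0, -1.0)
        for d in np.arange(4) * 90.0
        for s in WIDTH_TEST_SPEEDS
    ]
    return _bar_events(geometry, combos, seed, lead_in, gap, "width_test")


def make_speed_test(geometry: FieldGeometry | None = None, seed: int = 0, *,
                    lead_in: float = 5.0, gap: float = 0.5) -> StimulusSet:
    """Speed test: 2 widths x 2 contrasts x 4 directions x 6 speeds = 96 bars."""
    geometry = geometry or FieldGeometry()
    combos = [
        (d, 0.0, s, w, geometry.extent_along(d + 90.0), c)
        for w in SPEED_TEST_WIDTHS
        for c in (1.0, -1.0)
        for d in np.arange(4) * 90.0
        for s in SPEED_TEST_SPEEDS
    ]
    return _bar_events(geometry, combos, seed, lead_in, gap, "speed_test")


def bar_traversal_duration(event: MovingBarEvent) -> float:
    """Time for the bar to fully cross the field: (extent + width) / speed."""
    return (event.field.extent_along(event.direction) + event.bar_width) / event.speed


def _motion_frame(event: MovingBarEvent) -> tuple[np.ndarray, np.ndarray]:
    th = np.deg2rad(event.direction)
    u = np.array([np.cos(th), np.sin(th)])
    return u, np.array([-u[1], u[0]])


def bar_crossing_time(event: MovingBarEvent, point: Sequence[float]) -> float:
    """Time at which the bar's leading edge reaches `point`.

    Raises ``ValueError("no crossing")`` if the bar path (its lateral span
    around the offset axis) never covers the point.
    """
    p = np.asarray(point, dtype=float)
    if not event.field.contains(p):
        raise ValueError("point outside field")
    u, n = _motion_frame(event)
    rel = p - event.field.center
    lateral = float(rel @ n) - event.lateral_offset
    if abs(lateral) > event.bar_length / 2:
        raise ValueError("no crossing: point is laterally outside the bar path")
    extent = event.field.extent_along(event.direction)
    along = float(rel @ u)  # in [-extent/2, extent/2]
    return event.onset + (along + extent / 2) / event.speed


# ---------------------------------------------------------------------------
# serialization

_LOG_COLUMNS = ["protocol", "event_index", "kind", "center_x", "center_y",
                "direction_deg", "speed", "bar_width", "bar_length", "offset",
                "contrast", "onset_s", "offset_s"]


def events_to_table(stimulus: StimulusSet) -> pd.DataFrame:
    """Flatten a stimulus set to the tab-separated event-log schema."""
    rows = []
    for i, ev in enumerate(stimulus.events):
        if ev.kind == "square":
            rows.append((stimulus.protocol_name, i, "square", ev.center[0],
                         ev.center[1], np.nan, np.nan, ev.side, ev.side, np.nan,
                         ev.contrast, ev.onset, ev.offset))
        else:
            rows.append((stimulus.protocol_name, i, "bar", np.nan, np.nan,
                         ev.direction, ev.speed, ev.bar_width, ev.bar_length,
                         ev.lateral_offset, ev.contrast, ev.onset, ev.offset))
    return pd.DataFrame(rows, columns=_LOG_COLUMNS)


def protocol_config(stimulus: StimulusSet) -> str:
    """YAML configuration block describing one protocol run."""
    return yaml.safe_dump({
        "protocol": stimulus.protocol_name,
        "rng_seed": int(stimulus.rng_seed),
        "n_events": len(stimulus.events),
        "lead_in_s": float(stimulus.lead_in),
        "gap_s": float(stimulus.gap),
        "field": {"width_um": stimulus.field.width,
                  "height_um": stimulus.field.height,
                  "origin_um": list(map(float, stimulus.field.origin))},
    }, sort_keys=False)


def write_event_log(stimuli: Iterable[StimulusSet], path) -> None:
    table = pd.concat([events_to_table(s) for s in stimuli], ignore_index=True)
    table.to_csv(path, sep="\t", index=False)


def read_event_log(path) -> dict[str, StimulusSet]:
    """Reconstruct stimulus sets from a tab-separated event log.

    The rng seed is not recoverable from the log and is recorded as -1.
    """
    if isinstance(path, (str,)) or hasattr(path, "read"):
        table = pd.read_csv(path, sep="\t")
    else:
        table = pd.read_csv(str(path), sep="\t")
    missing = set(_LOG_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"event log missing columns: {sorted(missing)}")
    out: dict[str, StimulusSet] = {}
    geometry = FieldGeometry()
    for proto, sub in table.groupby("protocol", sort=False):
        events = []
        for _, row in sub.sort_values("event_index").iterrows():
            if row["kind"] == "square":
                events.append(SquareFlashEvent(
                    center=(row["center_x"], row["center_y"]),
                    onset=row["onset_s"], side=row["bar_width"],
                    contrast=row["contrast"],
                    duration=row["offset_s"] - row["onset_s"]))
            elif row["kind"] == "bar":
                events.append(MovingBarEvent(
                    direction=row["direction_deg"], speed=row["speed"],
                    bar_width=row["bar_width"], bar_length=row["bar_length"],
                    lateral_offset=row["offset"], contrast=row["contrast"],
                    onset=row["onset_s"], field=geometry))
            else:
                raise ValueError(f"unknown event kind {row['kind']!r} "
                                 f"at event_index {row['event_index']}")
        gap = 2.0 if proto == "marching_square" else 0.5
        out[proto] = StimulusSet(proto, events, rng_seed=-1, field=geometry,
                                 lead_in=min(ev.onset for ev in events), gap=gap)
    return out
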