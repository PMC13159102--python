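"""Track/kymograph analysis: event segmentation, velocities, run distances.

Tracks are tables of (t, x[, y]) sampled at a uniform frame interval
(default 5 s), with x the position along the filament axis measured from
the minus end.  Reported velocities are signed positive toward the minus
end, i.e. the negative of the slope of x versus t.

Segmentation rule
-----------------
A *strong* step moves more than the noise floor within one frame.  A
processive event is a maximal run of at least ``MIN_PROCESSIVE_STEPS``
consecutive strong steps of constant sign.  The remaining stretches are
diffusive when above-floor motion persists for more than 3 frame intervals
(15 s at the default interval) — persistence meaning at least a third of
the steps are strong, which separates genuine diffusion (about half of its
steps exceed the floor) from isolated localization-noise spikes.  Everything
else is static.  Events partition each track with no gaps or overlaps; ties
at changepoints go to the earlier event.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_FRAME_INTERVAL_S = 5.0
DEFAULT_NOISE_FLOOR_UM = 0.1
MIN_PROCESSIVE_STEPS = 3
DIFFUSIVE_MIN_STEPS = 4      # "more than three frames"
DIFFUSIVE_STRONG_FRACTION = 1 / 3

PROCESSIVE = "processive"
DIFFUSIVE = "diffusive"
STATIC = "static"


@dataclass
class Track:
    t: np.ndarray                    # s
    x: np.ndarray                    # µm along the filament axis
    y: np.ndarray | None = None      # µm, optional lateral coordinate
    track_id: int = 0
    filament_length: float | None = None  # µm

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=float)
        if len(self.t) != len(self.x):
            raise ValueError("t and x must have equal length")
        if len(self.t) >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if np.max(np.abs(dt - dt[0])) > 1e-6:
                raise ValueError("frame interval must be uniform")

    @property
    def n_frames(self) -> int:
        return len(self.t)

    @property
    def frame_interval(self) -> float:
        return float(self.t[1] - self.t[0])


@dataclass
class MotilityEvent:
    """One classified segment of a track; covers frames [start, end]."""

    cls: str
    start: int
    end: int
    velocity: float = float("nan")      # µm/s, + toward the minus end
    run_distance: float = float("nan")  # µm
    run_over_length_ratio: float = float("nan")


# ---------------------------------------------------------------------- #
# segmentation


def _strong_runs(steps: np.ndarray, noise_floor: float) -> list[tuple[int, int]]:
    """Maximal runs (as half-open step ranges) of same-sign strong steps."""
    strong = np.abs(steps) > noise_floor
    sign = np.sign(steps)
    runs = []
    i = 0
    n = len(steps)
    while i < n:
        if not strong[i]:
            i += 1
            continue
        j = i + 1
        while j < n and strong[j] and sign[j] == sign[i]:
            j += 1
        runs.append((i, j))
        i = j
    return runs


def segment_events(
    track: Track, noise_floor: float = DEFAULT_NOISE_FLOOR_UM
) -> list[MotilityEvent]:
    """Partition a track into processive / diffusive / static events."""
    if track.n_frames < 4:
        raise ValueError(f"track needs >= 4 frames, got {track.n_frames}")
    steps = np.diff(track.x)
    strong = np.abs(steps) > noise_floor
    proc = [(a, b) for a, b in _strong_runs(steps, noise_floor) if b - a >= MIN_PROCESSIVE_STEPS]

    events: list[MotilityEvent] = []

    def classify_gap(a: int, b: int) -> None:
        """Classify the non-processive step range [a, b)."""
        if b <= a:
            return
        n_strong = int(np.sum(strong[a:b]))
        if (b - a) >= DIFFUSIVE_MIN_STEPS and n_strong / (b - a) >= DIFFUSIVE_STRONG_FRACTION:
            cls = DIFFUSIVE
        else:
            cls = STATIC
        events.append(MotilityEvent(cls=cls, start=a, end=b))

    cursor = 0
    for a, b in proc:
        classify_gap(cursor, a)
        events.append(MotilityEvent(cls=PROCESSIVE, start=a, end=b))
        cursor = b
    classify_gap(cursor, len(steps))

    # convert half-open step ranges to inclusive frame ranges and annotate
    for ev in events:
        ev.end = ev.end  # step range end == inclusive end frame index
        if ev.cls == PROCESSIVE:
            ev.velocity = event_velocity(ev, track)
            ev.run_distance = run_distance(ev, track)
            if track.filament_length is not None:
                ev.run_over_length_ratio = run_ratio(ev, track)
    return events


# ---------------------------------------------------------------------- #
# per-event measurements


def event_velocity(event: MotilityEvent, track: Track) -> float:
    """Least-squares slope of x vs t over the event, signed + toward minus end."""
    if event.cls != PROCESSIVE:
        raise ValueError(f"velocity is defined for processive events, not {event.cls!r}")
    sl = slice(event.start, event.end + 1)
    slope = np.polyfit(track.t[sl], track.x[sl], 1)[0]
    return float(-slope)


def run_distance(event: MotilityEvent, track: Track) -> float:
    """Net distance |x_end - x_start| covered by a processive event, µm."""
    if event.cls != PROCESSIVE:
        raise ValueError(f"run distance is defined for processive events, not {event.cls!r}")
    return float(abs(track.x[event.end] - track.x[event.start]))


def run_ratio(event: MotilityEvent, track: Track) -> float:
    """Run distance over filament length, capped at 1."""
    if track.filament_length is None:
        raise ValueError("track has no filament_length; cannot compute run ratio")
    r = run_distance(event, track) / track.filament_length
    if r > 1.0:
        warnings.warn("run distance exceeds filament length; ratio capped at 1")
        r = 1.0
    return float(r)


def longest_processive_event(
    track: Track, noise_floor: float = DEFAULT_NOISE_FLOOR_UM
) -> MotilityEvent | None:
    """The track's dominant transport event (longest processive; earlier wins
    ties), or None — one count per trajectory, kymograph-style."""
    events = [e for e in segment_events(track, noise_floor) if e.cls == PROCESSIVE]
    if not events:
        return None
    return max(events, key=lambda e: (e.end - e.start, -e.start))


# ---------------------------------------------------------------------- #
# rates and summaries


@dataclass
class EventRateSummary:
    n_events: int
    mt_length: float       # µm
    duration: float        # min
    rate: float            # events / (µm · min)


def event_rate(events, mt_length: float, duration: float) -> EventRateSummary:
    """Events per µm of filament per minute of acquisition.

    ``events`` may be a count or a list of MotilityEvent.
    """
    n = events if isinstance(events, (int, np.integer)) else len(events)
    if mt_length <= 0:
        raise ValueError("mt_length must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    return EventRateSummary(
        n_events=int(n),
        mt_length=mt_length,
        duration=duration,
        rate=n / (mt_length * duration),
    )


def event_rates_by_class(
    events: list[MotilityEvent], mt_length: float, duration: float
) -> dict[str, EventRateSummary]:
    """Processive and diffusive rates reported separately."""
    return {
        cls: event_rate([e for e in events if e.cls == cls], mt_length, duration)
        for cls in (PROCESSIVE, DIFFUSIVE)
    }


def track_summary(track: Track) -> tuple[float, float, float]:
    """(track_length, displacement, mean_velocity).

    Track length is the cumulative distance over consecutive positions
    (2-D when a lateral coordinate is present); displacement the straight-line
    start-to-end distance; mean velocity the track length per unit time.
    """
    if track.n_frames < 2:
        raise ValueError("track needs >= 2 samples")
    if track.y is not None:
        pts = np.column_stack([track.x, track.y])
    else:
        pts = track.x[:, None]
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    track_length = float(np.sum(steps))
    displacement = float(np.linalg.norm(pts[-1] - pts[0]))
    mean_velocity = track_length / float(track.t[-1] - track.t[0])
    return track_length, displacement, mean_velocity


# ---------------------------------------------------------------------- #
# table I/O


def read_tracks(path: str | Path, lengths: str | Path | None = None) -> list[Track]:
    """Read long-format CSV (track_id, t_s, x_um[, y_um]) into Track objects.

    ``lengths`` optionally points to a CSV with (track_id, filament_length_um).
    """
    df = pd.read_csv(path)
    lookup = {}
    if lengths is not None:
        ldf = pd.read_csv(lengths)
        lookup = dict(zip(ldf["track_id"], ldf["filament_length_um"]))
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("t_s")
        tracks.append(
            Track(
                t=grp["t_s"].to_numpy(),
                x=grp["x_um"].to_numpy(),
                y=grp["y_um"].to_numpy() if "y_um" in grp.columns else None,
                track_id=int(tid),
                filament_length=lookup.get(tid),
            )
        )
    return tracks


def analyze_tracks(
    tracks: list[Track], noise_floor: float = DEFAULT_NOISE_FLOOR_UM
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Segment every track; return (events table, per-track summary table)."""
    ev_rows, sum_rows = [], []
    for tr in tracks:
        for ev in segment_events(tr, noise_floor):
            ev_rows.append(
                {
                    "track_id": tr.track_id,
                    "class": ev.cls,
                    "start_frame": ev.start,
                    "end_frame": ev.end,
                    "velocity_um_s": ev.velocity,
                    "run_distance_um": ev.run_distance,
                    "run_over_length_ratio": ev.run_over_length_ratio,
                }
            )
        tl, disp, mv = track_summary(tr)
        sum_rows.append(
            {
                "track_id": tr.track_id,
                "track_length_um": tl,
                "displacement_um": disp,
                "mean_velocity_um_s": mv,
            }
        )
    return pd.DataFrame(ev_rows), pd.DataFrame(sum_rows)
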