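"""Zone geometry and event detection on cleaned pose tracks.

Three detectors drive the pose-based indices:

* **Tray approaches** — a hand's false→true transition into the tray
  zone (a circle around the tray center, boundary inclusive).  Multiple
  same-hand entries closer together than the minimum event interval
  (0.5 s) are implausible at camera frame rates and are collapsed:
  only the first of the run is counted.  In pairwise-food sessions with
  two trays an entry is attributed to the nearest tray center.
* **Food-zone occupancy** — intervals during which the body center's
  x-coordinate exceeds the food zone's left edge, at frame resolution.
* **Bouts** — a hand entering the mouth zone (a circle centered on the
  per-frame mouth keypoint, moving with the animal) counts as a bout
  only if that same hand was inside the tray zone at least once during
  the preceding look-back window (3 s): hand to tray, then hand to
  mouth.  The same minimum-interval rule applies to mouth entries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import ZoneConfig
from .preprocess import CleanTrack
from .pose_io import PoseTrack

__all__ = [
    "EventSeries",
    "OccupancyIntervals",
    "in_circle",
    "detect_entries",
    "tray_approaches",
    "food_zone_occupancy",
    "detect_bouts",
]

HANDS = ("left", "right")
_HAND_PARTS = {"left": "left_hand", "right": "right_hand"}


@dataclass
class EventSeries:
    """Timestamped, hand-labelled events of one kind for one session.

    ``events`` columns: time_s, hand ("left"/"right"), kind
    ("tray_entry"/"bout") and tray_id (0-based; -1 when no tray applies).
    Rows are sorted by time; within each (hand, kind) group successive
    times are separated by at least the de-duplication interval used to
    build the series.
    """

    events: pd.DataFrame
    duration: float
    min_interval: float = 0.5

    def __post_init__(self) -> None:
        ev = self.events.reset_index(drop=True)
        if len(ev):
            ev = ev.sort_values("time_s", kind="stable").reset_index(drop=True)
        self.events = ev
        for (hand, kind), grp in ev.groupby(["hand", "kind"]):
            dt = np.diff(grp["time_s"].to_numpy(float))
            if np.any(dt <= 0):
                raise ValueError(f"non-increasing times within ({hand}, {kind})")
            if np.any(dt < self.min_interval - 1e-9):
                raise ValueError(
                    f"({hand}, {kind}) events closer than min interval "
                    f"{self.min_interval} s"
                )

    def __len__(self) -> int:
        return len(self.events)

    @property
    def times(self) -> np.ndarray:
        return self.events["time_s"].to_numpy(float)

    @classmethod
    def empty(cls, duration: float, min_interval: float = 0.5) -> "EventSeries":
        return cls(
            events=pd.DataFrame(
                {"time_s": [], "hand": [], "kind": [], "tray_id": []}
            ),
            duration=duration,
            min_interval=min_interval,
        )

    @classmethod
    def concat(cls, series: Sequence["EventSeries"]) -> "EventSeries":
        if not series:
            raise ValueError("nothing to concatenate")
        dur = series[0].duration
        mi = min(s.min_interval for s in series)
        frames = [s.events for s in series if len(s.events)]
        ev = (
            pd.concat(frames, ignore_index=True)
            if frames
            else series[0].events
        )
        return cls(events=ev, duration=dur, min_interval=mi)


@dataclass
class OccupancyIntervals:
    """Disjoint, sorted half-open [start, end) intervals, in seconds."""

    intervals: list[tuple[float, float]]
    duration: float

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for start, end in self.intervals:
            if end <= start:
                raise ValueError(f"empty interval [{start}, {end})")
            if start < prev_end:
                raise ValueError("intervals overlap or are unsorted")
            prev_end = end

    @property
    def total(self) -> float:
        """Summed interval length (s)."""
        return float(sum(e - s for s, e in self.intervals))

    def __len__(self) -> int:
        return len(self.intervals)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def in_circle(
    points: np.ndarray, center: tuple[float, float], radius: float
) -> np.ndarray:
    """Boolean mask: Euclidean distance from ``center`` <= ``radius``.

    The boundary is inclusive — a point exactly on the circle has
    entered the zone.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    pts = np.asarray(points, float)
    d2 = (pts[..., 0] - center[0]) ** 2 + (pts[..., 1] - center[1]) ** 2
    return d2 <= radius**2


# ---------------------------------------------------------------------------
# entry detection with minimum-interval de-duplication
# ---------------------------------------------------------------------------


def _entry_frames(inside: np.ndarray) -> np.ndarray:
    """Frames of false→true transitions; frame 0 counts if already inside."""
    inside = np.asarray(inside, bool)
    prev = np.concatenate([[False], inside[:-1]])
    return np.flatnonzero(inside & ~prev)


def _dedup_greedy(times: np.ndarray, min_interval: float) -> np.ndarray:
    """Sequentially keep only the first of runs of events closer than
    ``min_interval``: after a kept event, suppress later events until the
    interval has elapsed; the next surviving event restarts the clock."""
    kept = []
    last = -np.inf
    for t in times:
        if t - last >= min_interval:
            kept.append(t)
            last = t
    return np.asarray(kept, float)


def detect_entries(
    inside: np.ndarray,
    fps: float,
    min_interval: float = 0.5,
    hand: str = "right",
    kind: str = "tray_entry",
    tray_id: int = -1,
    duration: Optional[float] = None,
) -> EventSeries:
    """Turn a per-frame inside/outside mask into de-duplicated entry events.

    An entry is a false→true transition of the mask (a first frame
    already inside counts as an entry at t = 0).  Same-hand entries
    closer together than ``min_interval`` collapse to the first one.
    """
    inside = np.asarray(inside, bool)
    frames = _entry_frames(inside)
    times = _dedup_greedy(frames / fps, min_interval)
    if duration is None:
        duration = len(inside) / fps
    ev = pd.DataFrame(
        {
            "time_s": times,
            "hand": hand,
            "kind": kind,
            "tray_id": tray_id,
        }
    )
    return EventSeries(events=ev, duration=duration, min_interval=min_interval)


# ---------------------------------------------------------------------------
# tray approaches
# ---------------------------------------------------------------------------


def _tray_masks(track: PoseTrack, zone: ZoneConfig, part: str) -> np.ndarray:
    """(n_trays, n_frames) inside masks of one keypoint vs every tray."""
    xy = track.xy(part)
    return np.stack(
        [in_circle(xy, c, zone.tray_radius) for c in zone.tray_centers]
    )


def tray_approaches(clean: CleanTrack, zone: ZoneConfig) -> EventSeries:
    """Detect tray-zone entries of either hand, de-duplicated per hand.

    The minimum-interval constraint applies per hand: left and right
    hands entering within the same 0.5 s yield two events.  With two
    trays (pairwise-food sessions) each entry is attributed to the tray
    nearest the hand at the entry frame.
    """
    for hand, part in _HAND_PARTS.items():
        if part not in clean.body_parts:
            raise ValueError(f"{hand} hand keypoint {part!r} missing from track")
    per_hand = []
    for hand, part in _HAND_PARTS.items():
        masks = _tray_masks(clean, zone, part)
        union = masks.any(axis=0)
        frames = _entry_frames(union)
        times = _dedup_greedy(frames / clean.fps, zone.min_event_interval)
        # attribute each surviving entry to the nearest tray center
        xy = clean.xy(part)
        tray_ids = []
        for t in times:
            f = int(round(t * clean.fps))
            d2 = [
                (xy[f, 0] - c[0]) ** 2 + (xy[f, 1] - c[1]) ** 2
                for c in zone.tray_centers
            ]
            tray_ids.append(int(np.argmin(d2)))
        per_hand.append(
            EventSeries(
                events=pd.DataFrame(
                    {
                        "time_s": times,
                        "hand": hand,
                        "kind": "tray_entry",
                        "tray_id": tray_ids,
                    }
                ),
                duration=clean.duration,
                min_interval=zone.min_event_interval,
            )
        )
    return EventSeries.concat(per_hand)


# ---------------------------------------------------------------------------
# food-zone occupancy
# ---------------------------------------------------------------------------


def food_zone_occupancy(clean: CleanTrack, zone: ZoneConfig) -> OccupancyIntervals:
    """Intervals during which body_center.x > food-zone left edge.

    Bounds are at frame resolution: a run of frames f0..f1 inside maps
    to the half-open interval [f0/fps, (f1+1)/fps).
    """
    if "body_center" not in clean.body_parts:
        raise ValueError("body_center keypoint missing from track")
    x = clean.part("body_center")["x"].to_numpy(float)
    inside = x > zone.food_zone_left_edge_x
    return _mask_to_intervals(inside, clean.fps, clean.duration)


def _mask_to_intervals(
    inside: np.ndarray, fps: float, duration: float
) -> OccupancyIntervals:
    inside = np.asarray(inside, bool)
    padded = np.concatenate([[False], inside, [False]])
    starts = np.flatnonzero(padded[1:] & ~padded[:-1])
    ends = np.flatnonzero(~padded[1:] & padded[:-1])
    ivs = [(s / fps, e / fps) for s, e in zip(starts, ends)]
    return OccupancyIntervals(intervals=ivs, duration=duration)


# ---------------------------------------------------------------------------
# bouts
# ---------------------------------------------------------------------------


def detect_bouts(
    clean: CleanTrack,
    zone: ZoneConfig,
    tray_inside_masks: Optional[dict[str, np.ndarray]] = None,
) -> EventSeries:
    """Detect consummatory bouts: mouth-zone entries with a recent tray visit.

    Per hand, entries into the moving mouth zone are found and
    de-duplicated like tray entries; an entry at time t is a bout iff
    that same hand was inside the tray zone at least once during
    [t − look-back, t] (closed window, evaluated on the per-frame inside
    mask).  ``tray_inside_masks`` may supply precomputed per-hand tray
    masks ({"left": mask, "right": mask}); otherwise they are derived
    from the track and zone config.
    """
    if "mouth" not in clean.body_parts:
        raise ValueError("mouth keypoint missing from track")
    for hand, part in _HAND_PARTS.items():
        if part not in clean.body_parts:
            raise ValueError(f"{hand} hand keypoint {part!r} missing from track")
    mouth = clean.xy("mouth")
    fps = clean.fps
    lookback_frames = int(round(zone.bout_lookback * fps))
    per_hand = []
    for hand, part in _HAND_PARTS.items():
        hand_xy = clean.xy(part)
        d2 = ((hand_xy - mouth) ** 2).sum(axis=1)
        mouth_inside = d2 <= zone.mouth_radius**2
        if tray_inside_masks is not None:
            tray_inside = np.asarray(tray_inside_masks[hand], bool)
        else:
            tray_inside = _tray_masks(clean, zone, part).any(axis=0)
        frames = _entry_frames(mouth_inside)
        times = _dedup_greedy(frames / fps, zone.min_event_interval)
        bout_times = []
        for t in times:
            f = int(round(t * fps))
            lo = max(0, f - lookback_frames)
            if tray_inside[lo : f + 1].any():
                bout_times.append(t)
        per_hand.append(
            EventSeries(
                events=pd.DataFrame(
                    {
                        "time_s": bout_times,
                        "hand": hand,
                        "kind": "bout",
                        "tray_id": -1,
                    }
                ),
                duration=clean.duration,
                min_interval=zone.min_event_interval,
            )
        )
    return EventSeries.concat(per_hand)
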