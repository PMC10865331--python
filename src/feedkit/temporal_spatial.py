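"""Temporal and spatial dynamics of eating behavior.

Temporal side: indices re-computed per 5-min bin over the 20-min
session, a rule-based classifier for the four qualitative bin-profile
shapes (early decline, steady decline, mid-peak with early incline,
late decline), and the temporal event density — events inside the 5-s
window starting at each moment, divided by the window length, i.e. an
instantaneous event rate evaluated on the frame grid.

Spatial side: occupancy heatmaps (proportion of session time a keypoint
spends in each grid cell) and 1-s averaged posture trajectories of the
head-top / mouth / body-center triplet, with an optional trailing-trace
export that keeps the preceding 0.3 s of positions per frame for
animation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence
import warnings

import numpy as np

from .events import EventSeries, OccupancyIntervals
from .pose_io import PoseTrack

__all__ = [
    "BinnedSeries",
    "DensityTrace",
    "OccupancyGrid",
    "PostureTrajectory",
    "bin_index",
    "classify_pattern",
    "temporal_density",
    "occupancy_heatmap",
    "posture_trajectory",
    "PATTERN_CATEGORIES",
]

PATTERN_CATEGORIES = (
    "early_decline",
    "steady_decline",
    "mid_peak_early_incline",
    "late_decline",
    "unclassified",
)


@dataclass
class BinnedSeries:
    """Per-bin value of an index over a session partitioned into bins."""

    bin_edges: np.ndarray  # length n_bins + 1, seconds
    values: np.ndarray  # length n_bins
    kind: str  # "count" | "duration"

    @property
    def n_bins(self) -> int:
        return len(self.values)


@dataclass
class DensityTrace:
    """Forward-window event rate sampled on the frame grid.

    ``density[i]`` is the number of events in [times[i], times[i] +
    window) divided by the effective window length, which is truncated
    at the session end.
    """

    times: np.ndarray
    density: np.ndarray
    window: float
    duration: float
    n_events: int

    def integrate(self) -> float:
        """Recover the event count from the trace.

        The session is partitioned into consecutive window-length pieces
        starting at t = 0; on each piece the trace value at the piece
        start times the effective window length is exactly the number of
        events in that piece, so the piecewise sum equals the total
        count (the final, truncated piece uses its actual length).
        """
        if len(self.times) == 0:
            return 0.0
        dt = self.times[1] - self.times[0] if len(self.times) > 1 else self.duration
        total = 0.0
        t = 0.0
        while t < self.duration - 1e-12:
            i = int(round(t / dt))
            eff = min(self.window, self.duration - self.times[i])
            total += self.density[i] * eff
            t += self.window
        return total


@dataclass
class OccupancyGrid:
    """Proportion of session time a keypoint occupies each spatial cell."""

    grid: np.ndarray  # (ny, nx), row 0 at ymin
    x_edges: np.ndarray
    y_edges: np.ndarray
    in_frame_fraction: float


@dataclass
class PostureTrajectory:
    """Per-second averaged positions of head-top, mouth and body center.

    ``points[part]`` is (n_steps, 2).  ``segments()`` yields the
    head-top–mouth and mouth–body-center connecting segments per step.
    """

    points: dict[str, np.ndarray]
    step: float
    trailing: Optional[dict[str, np.ndarray]] = None  # raw per-frame xy

    @property
    def n_steps(self) -> int:
        return len(next(iter(self.points.values())))

    def segments(self) -> list[tuple[np.ndarray, np.ndarray]]:
        out = []
        for k in range(self.n_steps):
            ht, mo, bc = (
                self.points["head_top"][k],
                self.points["mouth"][k],
                self.points["body_center"][k],
            )
            out.append((ht, mo))
            out.append((mo, bc))
        return out


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------


def bin_index(
    data: EventSeries | OccupancyIntervals,
    bin_width: float = 300.0,
    duration: Optional[float] = None,
) -> BinnedSeries:
    """Re-compute an index per time bin (default 5-min bins of 20 min).

    Event counts are assigned by timestamp; occupancy durations are
    split at bin boundaries so the bin sum always equals the session
    total.  A trailing partial bin is permitted with a warning.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if duration is None:
        duration = data.duration
    n_bins = int(np.ceil(duration / bin_width - 1e-12))
    edges = np.minimum(np.arange(n_bins + 1) * bin_width, duration)
    if abs(n_bins * bin_width - duration) > 1e-9:
        warnings.warn(
            f"duration {duration} s is not a whole number of {bin_width} s bins; "
            "last bin is partial",
            stacklevel=2,
        )
    if isinstance(data, EventSeries):
        counts, _ = np.histogram(data.times, bins=edges) if len(data) else (
            np.zeros(n_bins, int),
            edges,
        )
        # events exactly at the session end belong to the last bin
        return BinnedSeries(bin_edges=edges, values=counts.astype(float), kind="count")
    values = np.zeros(n_bins)
    for start, end in data.intervals:
        for b in range(n_bins):
            lo, hi = edges[b], edges[b + 1]
            overlap = min(end, hi) - max(start, lo)
            if overlap > 0:
                values[b] += overlap
    return BinnedSeries(bin_edges=edges, values=values, kind="duration")


# ---------------------------------------------------------------------------
# pattern classification
# ---------------------------------------------------------------------------


def classify_pattern(bins: Sequence[float]) -> str:
    """Assign one of four qualitative temporal-profile categories.

    Deterministic rules over the four 5-min bin values:

    * ``early_decline`` — bin 1 is the maximum and bin 2 <= half of bin 1
      (sharp drop after a dominant first bin);
    * ``mid_peak_early_incline`` — the maximum sits at bin 2 or bin 3
      and bin 1 is strictly below it (rise then peak in the middle);
    * ``late_decline`` — bins 1–3 all within 20 % of their mean and
      bin 4 below half that mean (flat then a final drop);
    * ``steady_decline`` — monotone non-increasing without the sharp
      early drop.

    Precedence: early > mid-peak > late > steady; anything else,
    including an all-zero profile, is ``unclassified``.
    """
    b = np.asarray(bins, float)
    if b.shape != (4,):
        raise ValueError("pattern classification expects exactly 4 bins")
    if np.any(b < 0):
        raise ValueError("bin values must be non-negative")
    if np.all(b == 0):
        return "unclassified"
    mx = b.max()
    if b[0] == mx and b[1] <= 0.5 * b[0]:
        return "early_decline"
    if (b[1] == mx or b[2] == mx) and b[0] < mx:
        return "mid_peak_early_incline"
    mean123 = b[:3].mean()
    if mean123 > 0 and np.all(np.abs(b[:3] - mean123) <= 0.2 * mean123) and b[
        3
    ] < 0.5 * mean123:
        return "late_decline"
    if np.all(np.diff(b) <= 0):
        return "steady_decline"
    return "unclassified"


# ---------------------------------------------------------------------------
# temporal density
# ---------------------------------------------------------------------------


def temporal_density(
    events: EventSeries,
    window: float = 5.0,
    duration: Optional[float] = None,
    fps: float = 30.0,
) -> DensityTrace:
    """Event rate: events in the forward window / window length, per frame.

    The window starting at t is [t, t + window); windows reaching past
    the session end are truncated and divided by their actual length.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if duration is None:
        duration = events.duration
    n = int(round(duration * fps))
    grid = np.arange(n) / fps
    times = np.sort(events.times)
    # events in [t, t+w) via two searchsorted passes
    eff = np.minimum(window, duration - grid)
    lo = np.searchsorted(times, grid, side="left")
    hi = np.searchsorted(times, grid + window, side="left")
    counts = hi - lo
    density = counts / eff
    return DensityTrace(
        times=grid,
        density=density,
        window=window,
        duration=duration,
        n_events=len(times),
    )


# ---------------------------------------------------------------------------
# occupancy heatmap
# ---------------------------------------------------------------------------


def occupancy_heatmap(
    track: PoseTrack,
    part: str = "body_center",
    grid_shape: tuple[int, int] = (50, 50),
    extent: Optional[tuple[float, float, float, float]] = None,
) -> OccupancyGrid:
    """Proportion of session time a keypoint spends in each spatial cell.

    ``extent`` is (xmin, xmax, ymin, ymax); by default the observed
    bounding box.  In-frame cell values sum to the in-frame fraction
    (1.0 when the keypoint never leaves the extent).
    """
    xy = track.xy(part)
    n = len(xy)
    if extent is None:
        xmin, xmax = xy[:, 0].min(), xy[:, 0].max()
        ymin, ymax = xy[:, 1].min(), xy[:, 1].max()
    else:
        xmin, xmax, ymin, ymax = extent
    if xmax <= xmin or ymax <= ymin:
        raise ValueError("degenerate spatial extent (zero range)")
    ny, nx = grid_shape
    x_edges = np.linspace(xmin, xmax, nx + 1)
    y_edges = np.linspace(ymin, ymax, ny + 1)
    h, _, _ = np.histogram2d(xy[:, 1], xy[:, 0], bins=[y_edges, x_edges])
    grid = h / n
    return OccupancyGrid(
        grid=grid,
        x_edges=x_edges,
        y_edges=y_edges,
        in_frame_fraction=float(grid.sum()),
    )


# ---------------------------------------------------------------------------
# posture trajectory
# ---------------------------------------------------------------------------

_POSTURE_PARTS = ("head_top", "mouth", "body_center")


def posture_trajectory(
    track: PoseTrack,
    window: float = 60.0,
    step: float = 1.0,
    trailing: float = 0.0,
) -> PostureTrajectory:
    """Average head-top / mouth / body-center positions per 1-s step.

    Summarises the first ``window`` seconds (default the first minute)
    as one averaged triplet per step.  ``trailing`` > 0 additionally
    exports, per frame of the window, the raw positions of the previous
    ``trailing`` seconds (0.3 s in the published animations).
    """
    for p in _POSTURE_PARTS:
        if p not in track.body_parts:
            raise ValueError(f"posture trajectory requires keypoint {p!r}")
    if window > track.duration + 1e-9:
        warnings.warn(
            f"summary window {window} s exceeds session ({track.duration} s); truncated",
            stacklevel=2,
        )
        window = track.duration
    n_steps = int(np.floor(window / step + 1e-9))
    fps = track.fps
    frames_per_step = int(round(step * fps))
    points = {}
    for p in _POSTURE_PARTS:
        xy = track.xy(p)
        means = np.empty((n_steps, 2))
        for k in range(n_steps):
            seg = xy[k * frames_per_step : (k + 1) * frames_per_step]
            means[k] = seg.mean(axis=0)
        points[p] = means
    trail = None
    if trailing > 0:
        n_frames = int(round(window * fps))
        trail = {p: track.xy(p)[:n_frames] for p in _POSTURE_PARTS}
    return PostureTrajectory(points=points, step=step, trailing=trail)
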