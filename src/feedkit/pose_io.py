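"""Reading and writing pose coordinate tables and ethogram event logs.

Pose tables follow the standard markerless pose-estimation CSV export
dialect: a three-row header (scorer / body part / coordinate) over
``x``, ``y``, ``likelihood`` triplets per body part, one row per video
frame.  An HDF5 variant of the same table is also supported.  Image
coordinates: origin top-left, y increasing downward, units px; time in
seconds is ``frame_index / fps`` (30 frames/s by default).

Ethogram logs are manual-coding exports: point events (a moment) and
state intervals (a duration), each carrying a behavior code from a
codebook that assigns the behavioral phase (appetitive or
consummatory) and record kind.  State records use the half-open
convention [onset, offset).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "PoseTrack",
    "EthogramLog",
    "Behavior",
    "DEFAULT_CODEBOOK",
    "STANDARD_BODY_PARTS",
    "read_pose_track",
    "write_pose_track",
    "read_ethogram",
    "write_ethogram",
    "repair_frame_index",
]

COORDS = ("x", "y", "likelihood")

#: Keypoints tracked in the study: head, mouth, trunk, both hands/feet, tail.
STANDARD_BODY_PARTS = (
    "head_top",
    "mouth",
    "body_center",
    "left_hand",
    "right_hand",
    "left_foot",
    "right_foot",
    "tail",
)


class FormatError(ValueError):
    """A file does not follow the expected export dialect."""


# ---------------------------------------------------------------------------
# PoseTrack
# ---------------------------------------------------------------------------


@dataclass
class PoseTrack:
    """Frame-indexed keypoint coordinates with per-sample confidence.

    ``data`` has a two-level column index (body part, coordinate) with
    coordinates ``x``, ``y``, ``likelihood`` per part, and a gap-free
    integer frame index starting at 0.
    """

    data: pd.DataFrame
    fps: float = 30.0

    def __post_init__(self) -> None:
        self.validate()

    @property
    def body_parts(self) -> list[str]:
        return list(dict.fromkeys(self.data.columns.get_level_values(0)))

    @property
    def n_frames(self) -> int:
        return len(self.data)

    @property
    def duration(self) -> float:
        """Session length in seconds (frames / fps)."""
        return self.n_frames / self.fps

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps

    def part(self, name: str) -> pd.DataFrame:
        """The (x, y, likelihood) table of one body part."""
        if name not in self.body_parts:
            raise KeyError(f"body part {name!r} not in track ({self.body_parts})")
        return self.data[name]

    def xy(self, name: str) -> np.ndarray:
        """(n_frames, 2) float array of a part's pixel coordinates."""
        p = self.part(name)
        return np.column_stack([p["x"].to_numpy(float), p["y"].to_numpy(float)])

    def validate(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.data.columns.nlevels != 2:
            raise FormatError("pose table needs (body part, coordinate) columns")
        idx = self.data.index.to_numpy()
        if len(idx) and not np.array_equal(idx, np.arange(len(idx))):
            if np.any(np.diff(idx) <= 0):
                raise ValueError("frame_index must be strictly increasing")
            missing = sorted(set(range(int(idx[0]), int(idx[-1]) + 1)) - set(idx))
            raise ValueError(
                f"frame_index has gaps (first missing frames: {missing[:5]}); "
                "use repair_frame_index to reindex explicitly"
            )
        for part in self.body_parts:
            cols = set(self.data[part].columns)
            if not set(COORDS) <= cols:
                raise FormatError(
                    f"body part {part!r} lacks columns {set(COORDS) - cols}"
                )
            lk = self.data[(part, "likelihood")].to_numpy(float)
            bad = np.flatnonzero((lk < 0) | (lk > 1) | ~np.isfinite(lk))
            if bad.size:
                raise ValueError(
                    f"likelihood outside [0, 1] for part {part!r} "
                    f"at frame {int(self.data.index[bad[0]])} (value {lk[bad[0]]})"
                )


def read_pose_track(
    path: str | Path,
    fps: float = 30.0,
    required_parts: Optional[list[str]] = None,
) -> PoseTrack:
    """Read a pose export (CSV with 3-row header, or HDF5) into a PoseTrack.

    Unknown body parts are preserved; ``required_parts`` (default: none)
    are checked present.  Raises :class:`FormatError` for files missing
    the likelihood columns and ``ValueError`` for invariant violations.
    """
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        df = pd.read_hdf(path, key="poses")
        if df.columns.nlevels == 3:  # scorer level present
            df.columns = df.columns.droplevel(0)
    else:
        try:
            df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
        except (pd.errors.ParserError, IndexError) as exc:
            raise FormatError(f"{path}: not a 3-row-header pose CSV: {exc}") from exc
        df.columns = df.columns.droplevel(0)  # drop scorer row
    df = df.astype(float)
    df.index = df.index.astype(int)
    df.index.name = "frame"
    parts = list(dict.fromkeys(df.columns.get_level_values(0)))
    for part in parts:
        if "likelihood" not in df[part].columns:
            raise FormatError(f"{path}: body part {part!r} has no likelihood column")
    if required_parts:
        missing = [p for p in required_parts if p not in parts]
        if missing:
            raise FormatError(f"{path}: declared body parts missing: {missing}")
    return PoseTrack(data=df[parts], fps=fps)


def write_pose_track(
    track: PoseTrack, path: str | Path, scorer: str = "feedkit"
) -> Path:
    """Write a PoseTrack as a pose-export CSV (or HDF5 if suffix is .h5)."""
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        track.data.to_hdf(path, key="poses", mode="w")
        return path
    out = track.data.copy()
    out.columns = pd.MultiIndex.from_tuples(
        [(scorer, part, coord) for part, coord in out.columns],
        names=["scorer", "bodyparts", "coords"],
    )
    out.to_csv(path)
    return path


def repair_frame_index(track_data: pd.DataFrame, fps: float = 30.0) -> PoseTrack:
    """Explicitly reindex an export with dropped rows onto a gap-free grid.

    Missing frames get NaN coordinates and likelihood 0, so downstream
    likelihood filtering treats them as unobserved.
    """
    idx = track_data.index.to_numpy(int)
    full = pd.RangeIndex(int(idx.min()), int(idx.max()) + 1)
    out = track_data.reindex(full)
    for part in dict.fromkeys(out.columns.get_level_values(0)):
        lk = out[(part, "likelihood")]
        out[(part, "likelihood")] = lk.fillna(0.0)
    out.index = out.index - out.index[0]
    out.index.name = "frame"
    return PoseTrack(data=out, fps=fps)


# ---------------------------------------------------------------------------
# EthogramLog
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Behavior:
    """Codebook entry: phase and record kind of one behavior code."""

    phase: str  # "appetitive" | "consummatory"
    kind: str  # "point" | "state"

    def __post_init__(self) -> None:
        if self.phase not in ("appetitive", "consummatory"):
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.kind not in ("point", "state"):
            raise ValueError(f"unknown kind {self.kind!r}")


#: Default codebook mirroring the manual coding scheme: tray/food
#: approaches and food-zone occupancy (appetitive); cheek pushing,
#: chewing and intake (consummatory); food drops (appetitive, pairwise).
DEFAULT_CODEBOOK: dict[str, Behavior] = {
    "approach": Behavior("appetitive", "point"),
    "food_zone": Behavior("appetitive", "state"),
    "drop": Behavior("appetitive", "point"),
    "cheek_push": Behavior("consummatory", "point"),
    "chewing": Behavior("consummatory", "state"),
    "intake": Behavior("consummatory", "point"),
}

_ETHO_COLUMNS = ["code", "kind", "onset_s", "offset_s", "food_target"]


@dataclass
class EthogramLog:
    """Typed manual-coding records for one session.

    ``records`` columns: code, kind, phase, onset_s, offset_s,
    food_target (palatable / unpalatable / none) and an optional
    ``value`` column (e.g. grams for weighed intake).  Point events have
    offset == onset; state intervals are half-open [onset, offset).
    """

    records: pd.DataFrame
    duration: Optional[float] = None
    codebook: Mapping[str, Behavior] = field(
        default_factory=lambda: dict(DEFAULT_CODEBOOK)
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.records
        unknown = sorted(set(df["code"]) - set(self.codebook))
        if unknown:
            rows = df.index[df["code"].isin(unknown)].tolist()
            raise ValueError(
                f"behavior codes {unknown} absent from codebook (rows {rows})"
            )
        on = df["onset_s"].to_numpy(float)
        off = df["offset_s"].to_numpy(float)
        if np.any(on < 0):
            raise ValueError("negative onset in ethogram record")
        bad = np.flatnonzero(off < on)
        if bad.size:
            raise ValueError(
                f"offset < onset in rows {df.index[bad].tolist()}"
            )
        is_state = df["kind"].to_numpy() == "state"
        degen = np.flatnonzero(is_state & (off <= on))
        if degen.size:
            raise ValueError(
                f"state records must have offset > onset (rows {df.index[degen].tolist()})"
            )
        for i, row in df.iterrows():
            expected = self.codebook[row["code"]].kind
            if row["kind"] != expected:
                raise ValueError(
                    f"row {i}: code {row['code']!r} is a {expected} behavior, "
                    f"got kind {row['kind']!r}"
                )
        if self.duration is not None and len(df) and off.max() > self.duration + 1e-9:
            raise ValueError("record extends past declared session duration")

    def select(self, code: str, food_target: Optional[str] = None) -> pd.DataFrame:
        out = self.records[self.records["code"] == code]
        if food_target is not None:
            out = out[out["food_target"] == food_target]
        return out


def read_ethogram(
    path: str | Path,
    codebook: Optional[Mapping[str, Behavior]] = None,
    duration: Optional[float] = None,
) -> EthogramLog:
    """Read an ethogram CSV (code, kind, onset_s, offset_s, food_target).

    Every code must exist in the codebook; intervals are validated.  An
    optional ``value`` column (intake amount) is carried through.
    """
    codebook = dict(codebook) if codebook is not None else dict(DEFAULT_CODEBOOK)
    df = pd.read_csv(path)
    missing = [c for c in _ETHO_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: ethogram CSV missing columns {missing}")
    df["phase"] = [
        codebook[c].phase if c in codebook else "?" for c in df["code"]
    ]
    keep = _ETHO_COLUMNS + ["phase"] + (["value"] if "value" in df.columns else [])
    return EthogramLog(records=df[keep], duration=duration, codebook=codebook)


def write_ethogram(log: EthogramLog, path: str | Path) -> Path:
    path = Path(path)
    cols = _ETHO_COLUMNS + (["value"] if "value" in log.records.columns else [])
    log.records[cols].to_csv(path, index=False)
    return path
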