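"""Likelihood filtering, linear interpolation and unit conversion.

Keypoint predictions with likelihood below the confidence threshold
(default 0.7, strict ``<``) are treated as missing and replaced by
linear interpolation between the nearest flanking confident samples,
independently per body part and per coordinate.  Leading or trailing
low-confidence runs, which have no flanking sample on one side, are
filled by holding the nearest confident value (no extrapolation).

The original likelihood values are preserved on replaced samples so the
provenance of every coordinate remains auditable; a per-sample flag
records whether it was observed, interpolated, or boundary-filled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ZoneConfig
from .pose_io import PoseTrack

__all__ = ["CleanTrack", "filter_interpolate", "to_cm", "OBSERVED", "INTERPOLATED", "BOUNDARY_FILLED"]

OBSERVED = "observed"
INTERPOLATED = "interpolated"
BOUNDARY_FILLED = "boundary-filled"


@dataclass
class CleanTrack(PoseTrack):
    """A PoseTrack after likelihood filtering and interpolation.

    ``flags`` has one column per body part with per-frame provenance in
    {observed, interpolated, boundary-filled}.  Replaced samples keep
    their original (sub-threshold) likelihood.
    """

    flags: pd.DataFrame = None
    threshold: float = 0.7

    def validate(self) -> None:
        # likelihoods of replaced samples keep their original values, so
        # only structural PoseTrack invariants minus the flag semantics
        # are re-checked here
        super().validate()
        if self.flags is not None:
            if list(self.flags.columns) != self.body_parts:
                raise ValueError("flags must have one column per body part")
            if len(self.flags) != self.n_frames:
                raise ValueError("flags length must equal track length")


def _interp_column(values: np.ndarray, ok: np.ndarray) -> np.ndarray:
    """Replace samples where ~ok by linear interpolation over frame index;
    hold the nearest observed value at the boundaries."""
    out = values.astype(float).copy()
    idx = np.arange(len(values))
    obs = np.flatnonzero(ok)
    out[~ok] = np.interp(idx[~ok], obs, values[obs])
    return out


def filter_interpolate(track: PoseTrack, threshold: float = 0.7) -> CleanTrack:
    """Remove sub-threshold samples and fill them by linear interpolation.

    Parameters
    ----------
    track
        Raw pose track.
    threshold
        Confidence cut-off; samples with likelihood strictly below it
        are replaced (``= threshold`` is kept).

    Returns
    -------
    CleanTrack
        Same shape as the input, with provenance flags.  Idempotent:
        running it again on the result is a no-op (the flags recompute
        from the preserved likelihoods, but coordinates do not change).

    Raises
    ------
    ValueError
        If any body part has no sample at or above the threshold.
    """
    data = track.data.copy()
    parts = track.body_parts
    n = track.n_frames
    flag_cols = {}
    for part in parts:
        lk = data[(part, "likelihood")].to_numpy(float)
        ok = lk >= threshold
        if not ok.any():
            raise ValueError(
                f"body part {part!r} has no sample with likelihood >= {threshold}"
            )
        flags = np.where(ok, OBSERVED, INTERPOLATED).astype(object)
        first, last = np.flatnonzero(ok)[[0, -1]]
        flags[:first][~ok[:first]] = BOUNDARY_FILLED
        flags[last + 1 :][~ok[last + 1 :]] = BOUNDARY_FILLED
        for coord in ("x", "y"):
            col = data[(part, coord)].to_numpy(float)
            data[(part, coord)] = _interp_column(col, ok)
        flag_cols[part] = flags
    flags_df = pd.DataFrame(flag_cols, index=data.index, columns=parts)
    return CleanTrack(data=data, fps=track.fps, flags=flags_df, threshold=threshold)


def to_cm(value_px: float | np.ndarray, zone: ZoneConfig) -> float | np.ndarray:
    """Convert a pixel distance to centimetres using the zone calibration."""
    return value_px / zone.px_per_cm
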