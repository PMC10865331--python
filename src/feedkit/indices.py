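"""Behavioral indices of the appetitive and consummatory phases.

Nine indices summarise a session, split by analysis route (M- manual
coding, D- pose-based) and by phase:

========  =========================  ======================================
code      measure                    definition
========  =========================  ======================================
M-AF      approach frequency (n)     count of coded food-approach events
M-AD      appetitive duration (s)    summed coded food-zone occupancy
M-AL      approach latency (s)       onset of the first approach; censored
                                     at 900 s if the food is never touched
M-AC      appetitive composite       AF / AL (a.u.)
M-CF      cheek-push frequency (n)   count of coded cheek-pushing events
M-CD      consummatory duration (s)  summed coded chewing time
D-AF      approach frequency (n)     de-duplicated tray-zone hand entries
D-AD      appetitive duration (s)    time body center is in the food zone
D-CF      bout frequency (n)         mouth-zone entries with recent tray visit
========  =========================  ======================================

Pairwise-food sessions additionally yield per-food M-AF, M-AL, food-drop
counts and latencies (M-AF-d, M-AL-d) and the consummatory amount CA,
plus the approach-per-intake ratio used to check that per-approach
intake does not vary with internal state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import pandas as pd

from .config import LATENCY_CENSOR_BOUND, SessionDesign, TestType
from .events import EventSeries, OccupancyIntervals
from .pose_io import EthogramLog

__all__ = [
    "IndexRow",
    "IndexTable",
    "manual_indices",
    "deep_indices",
    "af_per_intake",
    "MANUAL_INDEX_CODES",
    "DEEP_INDEX_CODES",
]

MANUAL_INDEX_CODES = ("M_AF", "M_AD", "M_AL", "M_AC", "M_CF", "M_CD")
DEEP_INDEX_CODES = ("D_AF", "D_AD", "D_CF")
PAIRWISE_EXTRA_CODES = ("M_AF_d", "M_AL_d", "CA")


@dataclass
class IndexRow:
    """Index values for one (subject, condition, state, food) cell."""

    subject: str
    condition: str
    internal_state: str
    food: str
    values: dict[str, float] = dc_field(default_factory=dict)
    censored: dict[str, bool] = dc_field(default_factory=dict)
    units: dict[str, str] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        for code in ("M_AF", "M_CF", "D_AF", "D_CF", "M_AF_d"):
            v = self.values.get(code)
            if v is not None and not np.isnan(v):
                if v < 0 or v != int(v):
                    raise ValueError(f"{code} must be a non-negative integer, got {v}")
        for code in ("M_AD", "M_CD", "D_AD"):
            v = self.values.get(code)
            if v is not None and not np.isnan(v) and v < 0:
                raise ValueError(f"{code} must be non-negative, got {v}")


class IndexTable:
    """Long-format collection of index rows across sessions.

    ``to_frame()`` yields one row per (subject, condition, state, food,
    index) with columns value / censored / unit — the CSV layout the
    command line emits.
    """

    def __init__(self, rows: Optional[list[IndexRow]] = None) -> None:
        self.rows: list[IndexRow] = list(rows) if rows else []

    def add(self, row: IndexRow) -> None:
        self.rows.append(row)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            for code, value in r.values.items():
                recs.append(
                    {
                        "subject": r.subject,
                        "condition": r.condition,
                        "internal_state": r.internal_state,
                        "food": r.food,
                        "index": code,
                        "value": value,
                        "censored": r.censored.get(code, False),
                        "unit": r.units.get(code, ""),
                    }
                )
        return pd.DataFrame(recs)

    def pivot(self, index_code: str) -> pd.DataFrame:
        """Wide table of one index: rows (subject, condition), columns
        (internal_state, food)."""
        df = self.to_frame()
        df = df[df["index"] == index_code]
        return df.pivot_table(
            index=["subject", "condition"],
            columns=["internal_state", "food"],
            values="value",
            aggfunc="first",
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "IndexTable":
        table = cls()
        keys = ["subject", "condition", "internal_state", "food"]
        for key, grp in df.groupby(keys, sort=False):
            row = IndexRow(*key)
            for _, rec in grp.iterrows():
                row.values[rec["index"]] = rec["value"]
                row.censored[rec["index"]] = bool(rec.get("censored", False))
                if rec.get("unit"):
                    row.units[rec["index"]] = rec["unit"]
            table.add(row)
        return table


def _summed_state_duration(log: EthogramLog, code: str, food: Optional[str]) -> float:
    df = log.select(code, food)
    df = df[df["kind"] == "state"]
    return float((df["offset_s"] - df["onset_s"]).sum())


def _latency(
    approaches: pd.DataFrame, censor_bound: float = LATENCY_CENSOR_BOUND
) -> tuple[float, bool]:
    """Onset of the first approach; (censor bound, True) when absent."""
    if len(approaches) == 0:
        return censor_bound, True
    return float(approaches["onset_s"].min()), False


def manual_indices(log: EthogramLog, design: SessionDesign) -> IndexRow:
    """Compute the manual-route indices from a coded ethogram log.

    One-food sessions yield M-AF, M-AD, M-AL, M-AC, M-CF, M-CD.
    Pairwise sessions yield per-food M-AF, M-AL, M-AF-d, M-AL-d and CA
    as separate rows is the caller's concern; here the per-food values
    are returned keyed ``<code>__<food>`` alongside the totals.

    Latencies are censored at the 900 s bound when the food is never
    approached; a censored latency makes M-AC missing rather than a
    number divided by a censoring artifact.
    """
    row = IndexRow(
        subject=design.subject_id,
        condition=design.condition.value,
        internal_state=design.internal_state.value,
        food=design.food.value,
    )

    if design.test_type is TestType.ONE_FOOD:
        targets = log.records["food_target"].unique()
        per_food = set(targets) - {"none", design.food.value}
        if per_food:
            warnings.warn(
                f"one-food log contains per-food targets {sorted(per_food)}; "
                "they are counted toward the session totals",
                stacklevel=2,
            )
        approaches = log.select("approach")
        m_af = float(len(approaches))
        m_al, censored = _latency(approaches)
        if censored and m_af > 0:
            raise ValueError(
                "inconsistent log: approaches present but no first-approach onset"
            )
        row.values["M_AF"] = m_af
        row.values["M_AD"] = _summed_state_duration(log, "food_zone", None)
        row.values["M_AL"] = m_al
        row.censored["M_AL"] = censored
        row.values["M_AC"] = np.nan if (censored or m_al == 0) else m_af / m_al
        row.censored["M_AC"] = censored
        row.values["M_CF"] = float(len(log.select("cheek_push")))
        row.values["M_CD"] = _summed_state_duration(log, "chewing", None)
        return row

    # pairwise-food session: per-food approach/drop/intake measures
    for food in ("palatable", "unpalatable"):
        approaches = log.select("approach", food)
        drops = log.select("drop", food)
        m_al, al_cens = _latency(approaches)
        m_al_d, ald_cens = _latency(drops)
        row.values[f"M_AF__{food}"] = float(len(approaches))
        row.values[f"M_AL__{food}"] = m_al
        row.censored[f"M_AL__{food}"] = al_cens
        row.values[f"M_AF_d__{food}"] = float(len(drops))
        row.values[f"M_AL_d__{food}"] = m_al_d
        row.censored[f"M_AL_d__{food}"] = ald_cens
        intake = log.select("intake", food)
        if "value" in intake.columns and intake["value"].notna().any():
            row.values[f"CA__{food}"] = float(intake["value"].sum())
            row.units[f"CA__{food}"] = "g"
        else:
            row.values[f"CA__{food}"] = float(len(intake))
            row.units[f"CA__{food}"] = "items"
    return row


def deep_indices(
    tray_events: EventSeries,
    bout_events: EventSeries,
    occupancy: OccupancyIntervals,
    design: SessionDesign,
) -> IndexRow:
    """Aggregate pose-based events into D-AF, D-AD, D-CF.

    All three inputs must describe the same session (equal durations).
    """
    durations = {tray_events.duration, bout_events.duration, occupancy.duration}
    if max(durations) - min(durations) > 1e-6:
        raise ValueError(f"session duration mismatch across inputs: {durations}")
    row = IndexRow(
        subject=design.subject_id,
        condition=design.condition.value,
        internal_state=design.internal_state.value,
        food=design.food.value,
    )
    row.values["D_AF"] = float(len(tray_events))
    row.values["D_AD"] = occupancy.total
    row.values["D_CF"] = float(len(bout_events))
    return row


def af_per_intake(m_af: float, total_intake: float) -> float:
    """Approach frequency divided by total food intake (a.u.).

    Used to check whether the amount taken per approach varies with
    internal state.  Zero intake with nonzero approaches has no defined
    ratio and is reported as missing with a warning.
    """
    if total_intake > 0:
        return m_af / total_intake
    if m_af > 0:
        warnings.warn(
            "zero intake with nonzero approach frequency; ratio undefined",
            stacklevel=2,
        )
        return float("nan")
    return 0.0
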