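"""Synthetic sessions with planted ground truth.

The study's videos are not public, so every pipeline stage is exercised
on generated data that reproduces the *structure* of a session: a
36,000-frame (20 min at 30 frames/s) pose export of eight keypoints,
and the matching manually-coded event log.  The generator plants an
explicit schedule — tray entries per hand, mouth entries lagging a tray
visit (bouts), food-zone occupancy segments, chewing/cheek-push/intake
records — and returns that schedule alongside the files, so detectors
can be held to exact recovery.

Hands rest away from all zones and make smooth eased excursions to the
tray or mouth; during the approach the hand-to-target distance is kept
outside the zone radius by a guard margin several times the positional
noise SD, so the per-frame inside mask transitions exactly at the
planted frame even with jitter.  Pose-estimator failure is emulated by
likelihood dropout: runs of frames whose likelihood falls below the
confidence threshold and whose coordinates are scrambled, which the
filtering/interpolation stage must repair.

Event times are drawn from hard-core (minimum-spacing) renewal
processes so planted counts are unambiguous under the de-duplication
rule.  One seeded generator drives all randomness; the seed fully
determines the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .config import (
    Condition,
    Food,
    InternalState,
    SessionDesign,
    TestType,
    ZoneConfig,
)
from .events import EventSeries, OccupancyIntervals
from .indices import IndexTable, manual_indices, deep_indices
from .pose_io import (
    DEFAULT_CODEBOOK,
    EthogramLog,
    PoseTrack,
    STANDARD_BODY_PARTS,
)

__all__ = [
    "SynthSpec",
    "simulate_pose",
    "simulate_ethogram",
    "simulate_experiment",
    "random_session_spec",
    "default_zone",
    "ExperimentResult",
]

IMG_W, IMG_H = 640.0, 480.0

#: Resting keypoint layout of the synthetic cage (px, image coordinates).
BASE_POSITIONS: dict[str, tuple[float, float]] = {
    "head_top": (240.0, 90.0),
    "mouth": (240.0, 140.0),
    "body_center": (250.0, 260.0),
    "left_hand": (180.0, 330.0),
    "right_hand": (260.0, 330.0),
    "left_foot": (200.0, 420.0),
    "right_foot": (280.0, 420.0),
    "tail": (120.0, 380.0),
}

#: Body-center x when inside the food zone.
BODY_CENTER_INSIDE_X = 460.0
#: Clearance kept between the hand and a zone boundary during approach (px).
GATE_MARGIN = 8.0


def default_zone(pairwise: bool = False) -> ZoneConfig:
    centers = [(500.0, 220.0), (500.0, 380.0)] if pairwise else [(500.0, 300.0)]
    return ZoneConfig(
        tray_centers=centers,
        tray_radius=40.0,
        mouth_radius=30.0,
        food_zone_left_edge_x=380.0,
        cage_extent=(0.0, IMG_W, 0.0, IMG_H),
    )


class SynthSpec(BaseModel):
    """Planted schedule and noise model of one synthetic session.

    Times are seconds; pose-side event times are snapped to the frame
    grid on generation.  Same-hand excursions (tray or mouth) must not
    overlap; a bout lag must be at most the look-back window to plant a
    valid bout, or exceed look-back + dwell to plant an unambiguous
    negative.
    """

    model_config = ConfigDict(arbitrary_types_allowed=True)

    duration: float = Field(default=1200.0, gt=0)
    fps: float = Field(default=30.0, gt=0)
    seed: int = 0
    zone: ZoneConfig = Field(default_factory=default_zone)

    # pose-side schedule
    tray_entry_times: dict[str, list[float]] = Field(
        default_factory=lambda: {"left": [], "right": []}
    )
    bout_lags: list[tuple[str, float, float]] = Field(default_factory=list)
    occupancy_segments: list[tuple[float, float]] = Field(default_factory=list)

    # kinematic / noise parameters
    approach_duration: float = Field(default=0.3, gt=0)
    dwell: float = Field(default=0.3, gt=0)
    noise_sd: float = Field(default=1.0, ge=0)
    dropout_prob: float = Field(default=0.0, ge=0, le=0.5)
    dropout_run_mean: float = Field(default=2.0, ge=1)

    # ethogram-side schedule (one-food); approach times default to the
    # pose-side tray entries, food-zone states to the occupancy segments
    approach_times: Optional[list[float]] = None
    food_zone_segments: Optional[list[tuple[float, float]]] = None
    cheek_push_times: list[float] = Field(default_factory=list)
    chewing_segments: list[tuple[float, float]] = Field(default_factory=list)
    intake_times: list[float] = Field(default_factory=list)
    intake_amounts: Optional[list[float]] = None

    # pairwise-session schedule, keyed palatable/unpalatable
    approaches_by_food: Optional[dict[str, list[float]]] = None
    drops_by_food: Optional[dict[str, list[float]]] = None
    intakes_by_food: Optional[dict[str, list[float]]] = None

    @model_validator(mode="after")
    def _check_schedule(self) -> "SynthSpec":
        margin = self.approach_duration
        windows: dict[str, list[tuple[float, float, str]]] = {
            "left": [],
            "right": [],
        }
        for hand, times in self.tray_entry_times.items():
            if hand not in windows:
                raise ValueError(f"unknown hand {hand!r}")
            for t in times:
                if t - margin < 0 or t + self.dwell + margin > self.duration:
                    raise ValueError(
                        f"planted tray entry at {t} s does not fit in the session"
                    )
                windows[hand].append((t - margin, t + self.dwell + margin, "tray"))
        lookback = self.zone.bout_lookback
        for hand, t_entry, lag in self.bout_lags:
            if t_entry not in self.tray_entry_times.get(hand, []):
                raise ValueError(
                    f"bout references missing {hand} tray entry at {t_entry} s"
                )
            if lag <= 0:
                raise ValueError("bout lag must be positive")
            if lookback < lag <= lookback + self.dwell + 2.0 / self.fps:
                raise ValueError(
                    f"bout lag {lag} s is ambiguous: within dwell reach of the "
                    f"{lookback} s look-back window"
                )
            t_m = t_entry + lag
            if t_m + self.dwell + margin > self.duration:
                raise ValueError(f"planted mouth entry at {t_m} s exceeds session")
            windows[hand].append((t_m - margin, t_m + self.dwell + margin, "mouth"))
        for hand, wins in windows.items():
            wins.sort()
            for (s0, e0, k0), (s1, e1, k1) in zip(wins, wins[1:]):
                if s1 < e0:
                    raise ValueError(
                        f"overlapping {hand}-hand excursions ({k0} ending {e0:.2f} s, "
                        f"{k1} starting {s1:.2f} s)"
                    )
        prev_end = 0.0
        for s, e in sorted(self.occupancy_segments):
            if s < prev_end or e <= s or e > self.duration:
                raise ValueError(f"invalid occupancy segment [{s}, {e})")
            prev_end = e
        for name in ("chewing_segments", "food_zone_segments"):
            segs = getattr(self, name)
            if segs:
                prev = -1.0
                for s, e in sorted(segs):
                    if s < prev or e <= s:
                        raise ValueError(f"overlapping state records in {name}")
                    prev = e
        if self.intake_amounts is not None and len(self.intake_amounts) != len(
            self.intake_times
        ):
            raise ValueError("intake_amounts must match intake_times in length")
        return self

    def valid_bouts(self) -> list[tuple[str, float]]:
        """(hand, mouth-entry time) of bouts whose lag is within look-back."""
        return [
            (hand, t + lag)
            for hand, t, lag in self.bout_lags
            if lag <= self.zone.bout_lookback
        ]


# ---------------------------------------------------------------------------
# pose synthesis
# ---------------------------------------------------------------------------


def _snap(t: float, fps: float) -> int:
    return int(round(t * fps))


def _ease(u: np.ndarray) -> np.ndarray:
    """Cosine ease-in/out on [0, 1]."""
    return 0.5 - 0.5 * np.cos(np.pi * u)


def _dropout_mask(rng: np.random.Generator, n: int, prob: float, run_mean: float) -> np.ndarray:
    """Runs of dropped frames with overall dropped fraction ~= prob."""
    mask = np.zeros(n, bool)
    if prob <= 0:
        return mask
    # per-frame run-start probability giving the target stationary fraction
    q = prob / (run_mean * (1.0 - prob))
    i = 0
    while i < n:
        if rng.random() < q:
            run = rng.geometric(1.0 / run_mean)
            mask[i : i + run] = True
            i += run
        else:
            i += 1
    return mask


def simulate_pose(
    spec: SynthSpec,
) -> tuple[PoseTrack, dict]:
    """Generate a pose export realising the planted schedule.

    Returns the track and its ground truth: de-duplication-proof tray
    entries and bouts (as :class:`EventSeries`) and the food-zone
    occupancy intervals, all snapped to the frame grid.
    """
    rng = np.random.default_rng(spec.seed)
    fps = spec.fps
    n = int(round(spec.duration * fps))
    t_grid = np.arange(n) / fps
    zone = spec.zone

    xy = {
        part: np.tile(np.asarray(BASE_POSITIONS[part]), (n, 1)).astype(float)
        for part in STANDARD_BODY_PARTS
    }
    # slow mouth drift: the mouth zone moves with the animal
    drift = np.column_stack(
        [8.0 * np.sin(2 * np.pi * t_grid / 63.0), 5.0 * np.cos(2 * np.pi * t_grid / 97.0)]
    )
    xy["mouth"] += drift
    xy["head_top"] += drift

    # body center crosses the food-zone edge per planted segments
    inside_frames = np.zeros(n, bool)
    for s, e in spec.occupancy_segments:
        inside_frames[_snap(s, fps) : _snap(e, fps)] = True
    xy["body_center"][inside_frames, 0] = BODY_CENTER_INSIDE_X

    a_frames = max(1, _snap(spec.approach_duration, fps))
    d_frames = max(1, _snap(spec.dwell, fps))

    def _excursion(hand_xy: np.ndarray, k_entry: int, target: np.ndarray, gate: float):
        """Ease the hand from rest toward ``target`` (per-frame positions,
        shape (n, 2) or (2,)), staying ``gate`` px outside until the entry
        frame, dwell on target, then retreat."""
        tgt = np.broadcast_to(np.asarray(target, float), (n, 2))
        rest = hand_xy[k_entry - a_frames - 1].copy()
        for j in range(a_frames):
            f = k_entry - a_frames + j
            vec = rest - tgt[f]
            dist0 = np.hypot(*vec)
            u = _ease(np.array([(j + 1) / a_frames]))[0]
            dist = dist0 + (gate - dist0) * u
            hand_xy[f] = tgt[f] + vec / dist0 * dist
        hand_xy[k_entry : k_entry + d_frames] = tgt[k_entry : k_entry + d_frames]
        for j in range(a_frames):
            f = k_entry + d_frames + j
            if f >= n:
                break
            vec = rest - tgt[f]
            dist0 = np.hypot(*vec)
            u = _ease(np.array([(j + 1) / a_frames]))[0]
            dist = gate + (dist0 - gate) * u
            hand_xy[f] = tgt[f] + vec / dist0 * dist

    truth_rows = []
    for hand, times in spec.tray_entry_times.items():
        part = f"{hand}_hand"
        for t in sorted(times):
            k = _snap(t, fps)
            tray_id = 0
            if len(zone.tray_centers) > 1:
                tray_id = int(rng.integers(len(zone.tray_centers)))
            center = np.asarray(zone.tray_centers[tray_id], float)
            _excursion(xy[part], k, center, zone.tray_radius + GATE_MARGIN)
            truth_rows.append(
                {
                    "time_s": k / fps,
                    "hand": hand,
                    "kind": "tray_entry",
                    "tray_id": tray_id,
                }
            )
    for hand, t_entry, lag in spec.bout_lags:
        part = f"{hand}_hand"
        k = _snap(t_entry + lag, fps)
        _excursion(xy[part], k, xy["mouth"], zone.mouth_radius + GATE_MARGIN)
    for hand, t_m in spec.valid_bouts():
        truth_rows.append(
            {"time_s": _snap(t_m, fps) / fps, "hand": hand, "kind": "bout", "tray_id": -1}
        )

    # positional jitter and likelihoods
    likelihood = {}
    thr = zone.likelihood_threshold
    for part in STANDARD_BODY_PARTS:
        xy[part] += rng.normal(0.0, spec.noise_sd, size=(n, 2))
        lk = rng.uniform(min(thr + 0.05, 1.0), 1.0, size=n)
        drop = _dropout_mask(rng, n, spec.dropout_prob, spec.dropout_run_mean)
        if drop.any():
            lk[drop] = rng.uniform(0.02, max(thr - 0.05, 0.03), size=drop.sum())
            xy[part][drop, 0] = rng.uniform(0, IMG_W, size=drop.sum())
            xy[part][drop, 1] = rng.uniform(0, IMG_H, size=drop.sum())
        likelihood[part] = lk

    cols = pd.MultiIndex.from_product(
        [STANDARD_BODY_PARTS, ("x", "y", "likelihood")]
    )
    data = np.empty((n, len(STANDARD_BODY_PARTS) * 3))
    for i, part in enumerate(STANDARD_BODY_PARTS):
        data[:, 3 * i] = xy[part][:, 0]
        data[:, 3 * i + 1] = xy[part][:, 1]
        data[:, 3 * i + 2] = likelihood[part]
    track = PoseTrack(data=pd.DataFrame(data, columns=cols), fps=fps)

    ev = pd.DataFrame(
        truth_rows, columns=["time_s", "hand", "kind", "tray_id"]
    )
    tray_truth = EventSeries(
        events=ev[ev["kind"] == "tray_entry"],
        duration=spec.duration,
        min_interval=zone.min_event_interval,
    )
    bout_truth = EventSeries(
        events=ev[ev["kind"] == "bout"],
        duration=spec.duration,
        min_interval=zone.min_event_interval,
    )
    occ_truth = OccupancyIntervals(
        intervals=[
            (_snap(s, fps) / fps, _snap(e, fps) / fps)
            for s, e in sorted(spec.occupancy_segments)
        ],
        duration=spec.duration,
    )
    truth = {"tray_entries": tray_truth, "bouts": bout_truth, "occupancy": occ_truth}
    return track, truth


# ---------------------------------------------------------------------------
# ethogram synthesis
# ---------------------------------------------------------------------------


def simulate_ethogram(
    spec: SynthSpec, design: Optional[SessionDesign] = None
) -> tuple[EthogramLog, dict]:
    """Generate a coded event log whose totals are known by construction.

    One-food sessions emit approach points, food-zone states, cheek
    pushes, chewing states and intake points; pairwise sessions emit
    the per-food approach / drop / intake schedule.  Returns the log
    and the planted index totals.
    """
    pairwise = design is not None and design.test_type is TestType.PAIRWISE
    rows: list[dict] = []
    totals: dict[str, float] = {}

    def _row(code, kind, onset, offset, food="none", value=np.nan):
        rows.append(
            {
                "code": code,
                "kind": kind,
                "onset_s": onset,
                "offset_s": offset,
                "food_target": food,
                "value": value,
            }
        )

    if not pairwise:
        approaches = spec.approach_times
        if approaches is None:
            approaches = sorted(
                t for ts in spec.tray_entry_times.values() for t in ts
            )
        fz = (
            spec.food_zone_segments
            if spec.food_zone_segments is not None
            else sorted(spec.occupancy_segments)
        )
        for t in sorted(approaches):
            _row("approach", "point", t, t)
        for s, e in fz:
            _row("food_zone", "state", s, e)
        for t in spec.cheek_push_times:
            _row("cheek_push", "point", t, t)
        for s, e in spec.chewing_segments:
            _row("chewing", "state", s, e)
        amounts = spec.intake_amounts or [np.nan] * len(spec.intake_times)
        for t, a in zip(spec.intake_times, amounts):
            _row("intake", "point", t, t, value=a)
        totals["M_AF"] = float(len(approaches))
        totals["M_AD"] = float(sum(e - s for s, e in fz))
        if approaches:
            totals["M_AL"] = float(min(approaches))
            totals["M_AL_censored"] = False
            totals["M_AC"] = (
                totals["M_AF"] / totals["M_AL"] if totals["M_AL"] > 0 else np.nan
            )
        else:
            totals["M_AL"] = 900.0
            totals["M_AL_censored"] = True
            totals["M_AC"] = np.nan
        totals["M_CF"] = float(len(spec.cheek_push_times))
        totals["M_CD"] = float(sum(e - s for s, e in spec.chewing_segments))
    else:
        for food in ("palatable", "unpalatable"):
            app = sorted((spec.approaches_by_food or {}).get(food, []))
            drops = sorted((spec.drops_by_food or {}).get(food, []))
            intakes = sorted((spec.intakes_by_food or {}).get(food, []))
            for t in app:
                _row("approach", "point", t, t, food=food)
            for t in drops:
                _row("drop", "point", t, t, food=food)
            for t in intakes:
                _row("intake", "point", t, t, food=food)
            totals[f"M_AF__{food}"] = float(len(app))
            totals[f"M_AL__{food}"] = float(min(app)) if app else 900.0
            totals[f"M_AL__{food}_censored"] = not app
            totals[f"M_AF_d__{food}"] = float(len(drops))
            totals[f"CA__{food}"] = float(len(intakes))

    df = pd.DataFrame(
        rows, columns=["code", "kind", "onset_s", "offset_s", "food_target", "value"]
    )
    if df["value"].isna().all():
        df = df.drop(columns=["value"])
    codebook = dict(DEFAULT_CODEBOOK)
    df["phase"] = [codebook[c].phase for c in df["code"]]
    log = EthogramLog(records=df, duration=spec.duration, codebook=codebook)
    return log, totals


# ---------------------------------------------------------------------------
# randomized sessions and full experiments
# ---------------------------------------------------------------------------


def _hardcore_times(
    rng: np.random.Generator,
    duration: float,
    rate: float,
    min_spacing: float,
    t0: float = 1.0,
) -> list[float]:
    """Renewal process with gaps = min_spacing + Exp(1/rate)."""
    out = []
    t = t0 + rng.exponential(1.0 / rate)
    while t < duration - 2.0:
        out.append(t)
        t += min_spacing + rng.exponential(1.0 / rate)
    return out


def _alternating_segments(
    rng: np.random.Generator,
    duration: float,
    gap_mean: float,
    dur_mean: float,
    min_len: float = 0.5,
) -> list[tuple[float, float]]:
    """Disjoint occupancy-style segments: Exp gaps between Exp dwells."""
    segs = []
    t = rng.exponential(gap_mean)
    while t < duration - 2.0:
        d = min_len + rng.exponential(dur_mean)
        end = min(t + d, duration - 1.0)
        if end > t:
            segs.append((t, end))
        t = end + 1.0 + rng.exponential(gap_mean)
    return segs


def random_session_spec(
    seed: int,
    duration: float = 1200.0,
    rate_multiplier: float = 1.0,
    dropout_prob: float = 0.0,
    noise_sd: float = 1.0,
    approach_rate: float = 0.02,
    bout_fraction: float = 0.4,
    occupancy_gap_mean: float = 60.0,
    occupancy_dur_mean: float = 15.0,
    chewing_gap_mean: float = 80.0,
    chewing_dur_mean: float = 10.0,
    cheek_push_rate: float = 0.01,
    intake_rate: float = 0.008,
) -> SynthSpec:
    """Draw a full session schedule at study-like event rates.

    Defaults emulate a 20-min one-food test of a motivated animal:
    ~20 tray approaches (hard-core renewal, 2 s minimum spacing,
    alternating hands so per-hand spacing is twice that), ~40 %
    followed by a mouth entry within the look-back window (a bout), a
    few hundred seconds of food-zone occupancy, and sparser chewing /
    cheek-push / intake records on the consummatory side.
    ``rate_multiplier`` scales event rates and dwell means jointly, the
    knob used to emulate internal-state and palatability effects.
    """
    rng = np.random.default_rng(seed)
    m = rate_multiplier
    approaches = _hardcore_times(rng, duration, approach_rate * m, 2.0)
    hands = ("left", "right")
    tray_by_hand: dict[str, list[float]] = {"left": [], "right": []}
    for i, t in enumerate(approaches):
        tray_by_hand[hands[i % 2]].append(t)
    bout_lags = []
    for hand in hands:
        for t in tray_by_hand[hand]:
            if rng.random() < bout_fraction and t + 3.6 < duration - 2.0:
                lag = rng.uniform(1.0, 2.8)
                bout_lags.append((hand, t, float(lag)))
    occupancy = _alternating_segments(
        rng, duration, occupancy_gap_mean / m, occupancy_dur_mean * m
    )
    chewing = _alternating_segments(
        rng, duration, chewing_gap_mean / m, chewing_dur_mean * m
    )
    cheek = _hardcore_times(rng, duration, cheek_push_rate * m, 1.0)
    intake = _hardcore_times(rng, duration, intake_rate * m, 1.0)
    return SynthSpec(
        duration=duration,
        seed=seed,
        tray_entry_times=tray_by_hand,
        bout_lags=bout_lags,
        occupancy_segments=occupancy,
        cheek_push_times=cheek,
        chewing_segments=chewing,
        intake_times=intake,
        dropout_prob=dropout_prob,
        noise_sd=noise_sd,
    )


@dataclass
class ExperimentResult:
    """A full synthetic experiment and its planted effect directions."""

    manual_table: IndexTable
    deep_table: Optional[IndexTable]
    true_directions: dict[str, int]
    designs: list[SessionDesign] = dc_field(default_factory=list)

    def hunger_differences(
        self, index_code: str, food: str, condition: str, table: str = "manual"
    ) -> np.ndarray:
        """Per-subject hunger − satiety difference of one index."""
        tab = self.manual_table if table == "manual" else self.deep_table
        piv = tab.pivot(index_code)
        sel = piv[piv.index.get_level_values("condition") == condition]
        return (
            sel[("hunger", food)].to_numpy(float)
            - sel[("satiety", food)].to_numpy(float)
        )


_CONDITIONS = (Condition.ARTIFICIAL_1, Condition.ARTIFICIAL_2, Condition.NATURAL)


def simulate_experiment(
    hunger_effect: float = 0.0,
    palatability_effect: float = 0.0,
    n_subjects: int = 3,
    seed: int = 0,
    duration: float = 1200.0,
    include_pose: bool = False,
    conditions: tuple = _CONDITIONS,
) -> ExperimentResult:
    """Simulate the full design: subjects × conditions × states × foods.

    Event rates in each cell are the base rates scaled by
    ``1 + hunger_effect`` in the hunger state and ``1 +
    palatability_effect`` for palatable food, on top of a per-subject
    baseline drawn once per subject.  With both effects zero, hunger
    and satiety cells are exchangeable, so each subject's
    hunger−satiety difference is symmetric around zero.

    With ``include_pose`` the pose route is run too (slower): each cell
    also gets a synthetic track, the event detectors, and a pose-based
    index row.
    """
    if hunger_effect < 0 or palatability_effect < 0:
        raise ValueError("effect sizes must be non-negative")
    rng = np.random.default_rng(seed)
    manual = IndexTable()
    deep = IndexTable() if include_pose else None
    designs = []
    subjects = [chr(ord("A") + i) for i in range(n_subjects)]
    baselines = rng.uniform(0.7, 1.3, size=n_subjects)
    for si, subj in enumerate(subjects):
        for cond in conditions:
            for state in (InternalState.HUNGER, InternalState.SATIETY):
                for food in (Food.PALATABLE, Food.UNPALATABLE):
                    mult = baselines[si]
                    if state is InternalState.HUNGER:
                        mult *= 1.0 + hunger_effect
                    if food is Food.PALATABLE:
                        mult *= 1.0 + palatability_effect
                    cell_seed = int(rng.integers(0, 2**31 - 1))
                    spec = random_session_spec(
                        seed=cell_seed,
                        duration=duration,
                        rate_multiplier=mult,
                    )
                    design = SessionDesign(
                        subject_id=subj,
                        internal_state=state,
                        food=food,
                        condition=cond,
                        test_type=TestType.ONE_FOOD,
                        duration=duration,
                    )
                    designs.append(design)
                    log, _ = simulate_ethogram(spec, design)
                    manual.add(manual_indices(log, design))
                    if include_pose:
                        from .preprocess import filter_interpolate
                        from .events import (
                            tray_approaches,
                            food_zone_occupancy,
                            detect_bouts,
                        )

                        track, _truth = simulate_pose(spec)
                        clean = filter_interpolate(
                            track, spec.zone.likelihood_threshold
                        )
                        tray = tray_approaches(clean, spec.zone)
                        occ = food_zone_occupancy(clean, spec.zone)
                        bouts = detect_bouts(clean, spec.zone)
                        deep.add(deep_indices(tray, bouts, occ, design))
    directions = {
        "hunger": 1 if hunger_effect > 0 else 0,
        "palatability": 1 if palatability_effect > 0 else 0,
    }
    return ExperimentResult(
        manual_table=manual,
        deep_table=deep,
        true_directions=directions,
        designs=designs,
    )
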