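"""Session metadata and zone-calibration configuration.

A session is one videotaped test: one subject, one internal state
(hunger / neutral / satiety), one food stimulus arrangement (a single
palatable or unpalatable food, or a palatable/unpalatable pair), under
one of three replicate conditions (two artificial-food runs and one
natural-food run).  Zone calibration ties the pixel coordinate frame of
the pose export to the physical cage: tray-zone circle(s), the moving
mouth-zone radius, the rectangular food zone (defined by its left-edge
x), and the px-per-cm scale.

Config files are YAML or JSON documents with ``session:`` and
``zones:`` sections.  Calibration fields the file omits fall back to
the published defaults (5.77 px/cm, likelihood threshold 0.7, 0.5 s
minimum event interval, 3 s bout look-back, 5 s density window); every
applied default is logged at INFO level.
"""

from __future__ import annotations

import json
import logging
from enum import Enum
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

logger = logging.getLogger("feedkit")

#: Pixel-to-physical scale of the study's camera geometry (px per cm).
DEFAULT_PX_PER_CM = 5.77
#: Keypoint confidence below which a sample is discarded and interpolated.
DEFAULT_LIKELIHOOD_THRESHOLD = 0.7
#: De-duplication window for same-hand zone entries (s).
DEFAULT_MIN_EVENT_INTERVAL = 0.5
#: How far back a tray visit can precede a mouth entry and still make a bout (s).
DEFAULT_BOUT_LOOKBACK = 3.0
#: Forward window of the temporal event-density trace (s).
DEFAULT_DENSITY_WINDOW = 5.0
#: One-food test length (s).
ONE_FOOD_DURATION = 1200.0
#: Pairwise-food test length (s); also the latency censoring bound.
PAIRWISE_DURATION = 900.0
#: Latency values are censored here when the subject never contacts the food (s).
LATENCY_CENSOR_BOUND = 900.0


class InternalState(str, Enum):
    HUNGER = "hunger"
    NEUTRAL = "neutral"
    SATIETY = "satiety"


class Food(str, Enum):
    PALATABLE = "palatable"
    UNPALATABLE = "unpalatable"
    PAIRWISE = "pairwise"


class Condition(str, Enum):
    ARTIFICIAL_1 = "artificial-1"
    ARTIFICIAL_2 = "artificial-2"
    NATURAL = "natural"


class TestType(str, Enum):
    ONE_FOOD = "one-food"
    PAIRWISE = "pairwise"


class SessionDesign(BaseModel):
    """Identity and design cell of a single behavioral session."""

    subject_id: str
    internal_state: InternalState
    food: Food
    condition: Condition
    test_type: TestType
    duration: Optional[float] = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _apply_duration_default(self) -> "SessionDesign":
        if self.duration is None:
            self.duration = (
                ONE_FOOD_DURATION
                if self.test_type is TestType.ONE_FOOD
                else PAIRWISE_DURATION
            )
            logger.info(
                "session.duration not given; default %.0f s applied for %s test",
                self.duration,
                self.test_type.value,
            )
        if self.test_type is TestType.PAIRWISE and self.food is not Food.PAIRWISE:
            raise ValueError("pairwise test requires food='pairwise'")
        if self.test_type is TestType.ONE_FOOD and self.food is Food.PAIRWISE:
            raise ValueError("one-food test cannot use food='pairwise'")
        return self


class ZoneConfig(BaseModel):
    """Geometric calibration of tray / mouth / food zones, in pixels.

    Image coordinates: origin top-left, y increases downward.  The food
    zone is the half-plane right of ``food_zone_left_edge_x`` (the
    rectangle's other edges coincide with the cage extent on camera).
    """

    tray_centers: list[tuple[float, float]] = Field(min_length=1)
    tray_radius: float = Field(gt=0)
    mouth_radius: float = Field(gt=0)
    food_zone_left_edge_x: float
    px_per_cm: float = Field(default=DEFAULT_PX_PER_CM, gt=0)
    likelihood_threshold: float = Field(
        default=DEFAULT_LIKELIHOOD_THRESHOLD, ge=0.0, le=1.0
    )
    min_event_interval: float = Field(default=DEFAULT_MIN_EVENT_INTERVAL, gt=0)
    bout_lookback: float = Field(default=DEFAULT_BOUT_LOOKBACK, gt=0)
    density_window: float = Field(default=DEFAULT_DENSITY_WINDOW, gt=0)
    # optional cage bounding box for heatmaps: (xmin, xmax, ymin, ymax)
    cage_extent: Optional[tuple[float, float, float, float]] = None

    @field_validator("cage_extent")
    @classmethod
    def _check_extent(cls, v):
        if v is not None:
            xmin, xmax, ymin, ymax = v
            if not (xmax > xmin and ymax > ymin):
                raise ValueError("cage_extent must have xmax > xmin and ymax > ymin")
        return v


_ZONE_DEFAULT_FIELDS = (
    "px_per_cm",
    "likelihood_threshold",
    "min_event_interval",
    "bout_lookback",
    "density_window",
)


def load_config(path: str | Path) -> tuple[SessionDesign, ZoneConfig]:
    """Load a YAML/JSON config with ``session:`` and ``zones:`` sections.

    Returns the validated ``(SessionDesign, ZoneConfig)`` pair.  Defaults
    applied for omitted calibration fields are logged.
    """
    path = Path(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(doc, dict) or "session" not in doc or "zones" not in doc:
        raise ValueError(f"{path}: config must contain 'session' and 'zones' sections")
    design = SessionDesign(**doc["session"])
    zones_raw = doc["zones"]
    zones = ZoneConfig(**zones_raw)
    for name in _ZONE_DEFAULT_FIELDS:
        if name not in zones_raw:
            logger.info(
                "zones.%s not given; default %s applied", name, getattr(zones, name)
            )
    return design, zones
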