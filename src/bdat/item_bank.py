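"""Item bank for the Beat-Drop Alignment Test (BDAT).

The BDAT presents short 4/4 music clips in which bar 4 contains a "beat
drop": all rhythmic cues are removed from beats 2-4 and a single probe
click is placed either exactly on a beat (ON condition) or displaced from
it (OFF condition).  The listener judges whether the probe is on the beat.

This module constructs the combinatorial item bank: the seven probe
displacement levels derived from a perceptual-accuracy scale, the full
cross of tracks x conditions x probe variants x tempi, and the exact
timing of every event on the beat grid.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from enum import Enum
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "Condition",
    "Direction",
    "DisplacementScale",
    "ItemSpec",
    "TimingPlan",
    "ItemBank",
    "DEFAULT_EXCLUSIONS",
    "perceptual_accuracy",
    "displacement_levels",
    "build_item_bank",
    "probe_timing",
    "tempo_variants",
]

# Clip structure shared by every item: six 4/4 bars, with the beat drop
# spanning beats 2-4 of bar 4 and the rhythm re-entering at bar 5 beat 1.
BARS = 6
BEATS_PER_BAR = 4
BEAT_DROP_BAR = 4
BEAT_DROP_BEATS = (2, 4)  # inclusive range of dropped beats within bar 4
DEFAULT_TEMPO_BPM = 125


class Condition(str, Enum):
    ON = "ON"
    OFF = "OFF"


class Direction(str, Enum):
    EARLY = "early"
    LATE = "late"
    NONE = "none"


#: Tracks screened out of the published bank: track 3 showed below-chance
#: accuracy in the ON condition, tracks 12, 27 and 30 in the OFF condition.
DEFAULT_EXCLUSIONS: tuple[tuple[int, Condition], ...] = (
    (3, Condition.ON),
    (12, Condition.OFF),
    (27, Condition.OFF),
    (30, Condition.OFF),
)


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


@dataclass(frozen=True)
class DisplacementScale:
    """Derivation rule for the probe displacement levels.

    Displacements are fractions of the beat period.  Levels are chosen so
    that perceptual accuracy PA(d) = cos(pi*d)**exponent is equally spaced
    between PA(d_min) and PA(d_max), then rounded to whole percent
    (half up) to match the published level set.
    """

    exponent: float = 4.0
    d_min: float = 0.15
    d_max: float = 0.45
    n_levels: int = 7
    round_to_percent: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.d_min < self.d_max < 0.5):
            raise ValueError("require 0 < d_min < d_max < 0.5")
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")


def perceptual_accuracy(d: float, exponent: float = 4.0) -> float:
    """Perceptual accuracy of a probe displaced by ``d`` beat periods.

    PA(d) = cos(pi * d) ** exponent.  For an even positive exponent this
    is strictly decreasing from 1 at d=0 to 0 at d=0.5: displacements near
    the beat are hard to reject, displacements near the half-beat easy.
    """
    d = float(d)
    if not (0.0 <= d <= 0.5):
        raise ValueError(f"displacement {d} outside [0, 0.5]")
    return float(np.cos(np.pi * d) ** exponent)


def displacement_levels(scale: DisplacementScale = DisplacementScale()) -> list[float]:
    """Displacement levels equally spaced on the perceptual-accuracy scale.

    Computes PA at the endpoints, takes ``n_levels`` equally spaced PA
    values (inclusive), inverts PA numerically for each (bisection to
    1e-12), and rounds each displacement to the nearest whole percent
    (half up).  Returned ascending, as fractions of the beat period.

    With the defaults this reproduces the published level set
    [0.15, 0.18, 0.20, 0.23, 0.26, 0.31, 0.45].
    """
    pa = lambda d: perceptual_accuracy(d, scale.exponent)  # noqa: E731
    pa_lo, pa_hi = pa(scale.d_min), pa(scale.d_max)
    if not pa_lo > pa_hi:
        raise RuntimeError("perceptual accuracy not decreasing on interval")
    targets = np.linspace(pa_lo, pa_hi, scale.n_levels)
    levels = []
    for t in targets:
        d = brentq(lambda x: pa(x) - t, scale.d_min - 1e-12, scale.d_max + 1e-12,
                   xtol=1e-12)
        if scale.round_to_percent:
            d = _round_half_up(d * 100.0) / 100.0
        levels.append(float(d))
    levels.sort()
    return levels


def tempo_variants(base_bpm: float = DEFAULT_TEMPO_BPM) -> list[int]:
    """Five tempo variants at -5%, -2.5%, 0, +2.5%, +5% of the base tempo.

    The published variant set for the 125 bpm bank is the verbatim list
    [119, 122, 125, 128, 132]; note its top step (132) departs from plain
    half-up rounding of 131.25, so that list is returned as a constant.
    Other base tempi use the multiplicative rule with half-up rounding,
    computed in exact per-mille arithmetic to avoid float artefacts.
    """
    if base_bpm <= 0:
        raise ValueError("base_bpm must be positive")
    if base_bpm == 125:
        return [119, 122, 125, 128, 132]
    steps = (-50, -25, 0, 25, 50)  # per mille
    out = []
    for s in steps:
        exact = Fraction(base_bpm).limit_denominator(10**6) * (1000 + s) / 1000
        out.append(math.floor(exact + Fraction(1, 2)))
    return out


@dataclass(frozen=True)
class ItemSpec:
    """One test item: a (track, condition, probe placement, tempo) cell."""

    item_id: str
    track_id: int
    condition: Condition
    target_beat: int  # 3 (strong) or 4 (weak)
    direction: Direction
    displacement: float  # fraction of beat period; 0 for ON
    displacement_level: int  # 1..n_levels, or 0 for ON
    tempo_bpm: float = DEFAULT_TEMPO_BPM

    def __post_init__(self) -> None:
        if self.target_beat not in (3, 4):
            raise ValueError("target_beat must be 3 (strong) or 4 (weak)")
        if self.condition is Condition.ON:
            if self.direction is not Direction.NONE or self.displacement != 0:
                raise ValueError("ON items must have direction=none, displacement=0")
        else:
            if self.direction not in (Direction.EARLY, Direction.LATE):
                raise ValueError("OFF items must have direction early or late")
            if not (0 < self.displacement < 0.5):
                raise ValueError("OFF displacement must lie in (0, 0.5)")


@dataclass(frozen=True)
class TimingPlan:
    """Event times (seconds from clip start) for one item's clip."""

    beat_period: float
    bars: int = BARS
    beats_per_bar: int = BEATS_PER_BAR
    beat_drop_bar: int = BEAT_DROP_BAR
    beat_drop_beats: tuple[int, int] = BEAT_DROP_BEATS
    probe_onset: float = 0.0
    probe_duration: float = 0.120
    reentry_time: float = 0.0
    clip_duration: float = 0.0

    def beat_time(self, bar: int, beat: int) -> float:
        """Time of ``beat`` (1-based) in ``bar`` (1-based); clip starts at 0."""
        return ((bar - 1) * self.beats_per_bar + (beat - 1)) * self.beat_period

    @property
    def drop_window(self) -> tuple[float, float]:
        """[start, end) of the beat-drop: bar-4 beat 2 up to re-entry."""
        return (self.beat_time(self.beat_drop_bar, self.beat_drop_beats[0]),
                self.reentry_time)


def probe_timing(item: ItemSpec) -> TimingPlan:
    """Exact probe and grid timing for an item.

    Beat k of bar b (1-based) falls at ((b-1)*4 + (k-1)) * beat_period.
    Early probes precede the target beat by displacement*beat_period,
    late probes follow it; ON probes sit exactly on the beat.
    """
    bp = 60.0 / item.tempo_bpm
    plan = TimingPlan(beat_period=bp)
    target_time = plan.beat_time(BEAT_DROP_BAR, item.target_beat)
    if item.condition is Condition.ON:
        onset = target_time
    elif item.direction is Direction.EARLY:
        onset = target_time - item.displacement * bp
    else:
        onset = target_time + item.displacement * bp
    reentry = plan.beat_time(BEAT_DROP_BAR + 1, 1)
    return TimingPlan(
        beat_period=bp,
        probe_onset=onset,
        reentry_time=reentry,
        clip_duration=BARS * BEATS_PER_BAR * bp,
    )


def _item_id(track: int, cond: Condition, beat: int, direction: Direction,
             level: int, tempo: float) -> str:
    t = f"{tempo:g}"
    if cond is Condition.ON:
        return f"T{track:02d}_ON_B{beat}_t{t}"
    return f"T{track:02d}_OFF_B{beat}_{direction.value}_L{level}_t{t}"


@dataclass
class ItemBank:
    """The full set of items plus the parameters that generated it."""

    items: list[ItemSpec]
    exclusions: list[tuple[int, Condition]] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for it in self.items:
            d = asdict(it)
            d["condition"] = it.condition.value
            d["direction"] = it.direction.value
            rows.append(d)
        return pd.DataFrame(rows, columns=["item_id", "track_id", "condition",
                                           "target_beat", "direction",
                                           "displacement", "displacement_level",
                                           "tempo_bpm"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path) -> None:
        payload = {
            "metadata": self.metadata,
            "exclusions": [[t, c.value] for t, c in self.exclusions],
            "items": self.to_frame().to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, metadata: dict | None = None) -> "ItemBank":
        items = [
            ItemSpec(
                item_id=str(r.item_id),
                track_id=int(r.track_id),
                condition=Condition(r.condition),
                target_beat=int(r.target_beat),
                direction=Direction(r.direction),
                displacement=float(r.displacement),
                displacement_level=int(r.displacement_level),
                tempo_bpm=float(r.tempo_bpm),
            )
            for r in frame.itertuples()
        ]
        return cls(items=items, metadata=metadata or {})

    @classmethod
    def from_csv(cls, path) -> "ItemBank":
        return cls.from_frame(pd.read_csv(path))


def build_item_bank(
    n_tracks: int = 30,
    scale: DisplacementScale = DisplacementScale(),
    tempi: Sequence[float] = (DEFAULT_TEMPO_BPM,),
    exclusions: Iterable[tuple[int, Condition]] = (),
    seed: int = 0,
) -> ItemBank:
    """Full combinatorial item bank.

    Per track and tempo: 2 ON items (probe on beat 3 or 4) and, for each
    displacement level, 4 OFF items (beat 3/4 x early/late).  With the
    default 7-level scale that is 30 items per track per tempo; 30 tracks
    at one tempo give the published 900-item bank, five tempi give 4,500.
    ``exclusions`` removes whole (track, condition) cells, mirroring the
    track screening applied to the published bank.
    """
    if n_tracks < 1:
        raise ValueError("n_tracks must be >= 1")
    tempi = list(tempi)
    if not tempi:
        raise ValueError("tempi must be non-empty")
    if len(set(tempi)) != len(tempi):
        raise ValueError("duplicate tempi in configuration")
    excl = {(int(t), Condition(c)) for t, c in exclusions}
    levels = displacement_levels(scale)

    items: list[ItemSpec] = []
    for tempo in tempi:
        for track in range(1, n_tracks + 1):
            if (track, Condition.ON) not in excl:
                for beat in (3, 4):
                    items.append(ItemSpec(
                        item_id=_item_id(track, Condition.ON, beat,
                                         Direction.NONE, 0, tempo),
                        track_id=track, condition=Condition.ON,
                        target_beat=beat, direction=Direction.NONE,
                        displacement=0.0, displacement_level=0,
                        tempo_bpm=tempo))
            if (track, Condition.OFF) not in excl:
                for beat in (3, 4):
                    for direction in (Direction.EARLY, Direction.LATE):
                        for lvl, d in enumerate(levels, start=1):
                            items.append(ItemSpec(
                                item_id=_item_id(track, Condition.OFF, beat,
                                                 direction, lvl, tempo),
                                track_id=track, condition=Condition.OFF,
                                target_beat=beat, direction=direction,
                                displacement=d, displacement_level=lvl,
                                tempo_bpm=tempo))
    meta = {
        "n_tracks": n_tracks,
        "tempi": tempi,
        "scale": asdict(scale),
        "levels": levels,
        "seed": seed,
    }
    return ItemBank(items=items, exclusions=sorted(excl), metadata=meta)
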