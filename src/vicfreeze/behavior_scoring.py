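"""Behavioral outcome measures on the experiment's bin schedules.

Freezing is consumed as annotated bout intervals (video scoring by a blinded
human is upstream of this package). The witness/demonstrator test session is
scored over 14 minutes in 6 bins: a 2-min baseline ending at the first shock
onset, then one bin per shock trial; since inter-shock gaps are 2 or 3 min,
the post-shock bins form the multiset {2, 2, 2, 3, 3} minutes. Locomotion is
consumed as per-5-min-bin distances, position tracks as (t, x, y) samples
with the window (divider-adjacent) zone being x in [0, 12.5) cm.

All intervals are half-open [start, end) in seconds from session start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SessionSchedule",
    "FreezingBoutSeries",
    "BinSchedule",
    "PositionTrack",
    "build_empathy_bins",
    "percent_freezing",
    "average_shock_period_freezing",
    "pre_exposure_freezing",
    "locomotion_percent_change",
    "window_zone_occupancy",
    "sound_test_bins",
]

SessionType = Literal[
    "pre_exposure_training", "pre_exposure_test", "empathy_test", "sound_test"
]

EMPATHY_GAPS = (120.0, 180.0)  # admissible inter-shock gaps, seconds
EMPATHY_POST_MULTISET = (120.0, 120.0, 120.0, 180.0, 180.0)


@dataclass
class SessionSchedule:
    """Timing of one session: baseline, event (shock/sound) onsets, durations."""

    session_type: SessionType
    baseline_duration: float
    event_onsets: Sequence[float] = ()
    event_duration: float = 5.0
    total_duration: float = 2400.0

    def __post_init__(self) -> None:
        onsets = list(self.event_onsets)
        if onsets != sorted(onsets):
            raise ValueError("event_onsets must be sorted")
        if onsets and onsets[0] < self.baseline_duration:
            raise ValueError("events must start after the baseline")


@dataclass
class FreezingBoutSeries:
    """Sorted, non-overlapping [start, end) freezing intervals for one animal."""

    animal_id: str
    bouts: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for (a, b) in self.bouts:
            if b <= a:
                raise ValueError(f"bout [{a}, {b}) is empty or reversed")
        for (_, b0), (a1, _) in zip(self.bouts, self.bouts[1:]):
            if a1 < b0:
                raise ValueError("bouts must be sorted and non-overlapping")

    @property
    def total_time(self) -> float:
        return sum(b - a for a, b in self.bouts)


@dataclass
class BinSchedule:
    """Labelled, sorted, non-overlapping scoring bins."""

    bins: list[tuple[float, float]]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.bins) != len(self.labels):
            raise ValueError("one label per bin")
        for (_, b0), (a1, _) in zip(self.bins, self.bins[1:]):
            if a1 < b0:
                raise ValueError("bins must be sorted and non-overlapping")

    @property
    def total_duration(self) -> float:
        return sum(b - a for a, b in self.bins)


@dataclass
class PositionTrack:
    """Position samples for one animal; x measured from the divider wall."""

    animal_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    compartment_width: float = 25.0
    zone_split: float = 12.5

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.float64)
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if np.any((self.x < 0) | (self.x > self.compartment_width)):
            raise ValueError("x outside the compartment")


def build_empathy_bins(schedule: SessionSchedule) -> BinSchedule:
    """The 6-bin, 14-minute scoring schedule of the witness/demonstrator test.

    Bin 1 is the 2 minutes before the first shock onset; bins 2-5 run from
    each shock onset to the next; the final bin's length is the gap value
    completing the {3x2 min, 2x3 min} post-shock multiset, so the schedule
    always totals 840 s.
    """
    if schedule.session_type != "empathy_test":
        raise ValueError("schedule is not an empathy_test session")
    onsets = list(schedule.event_onsets)
    if len(onsets) != 5:
        raise ValueError(f"empathy test has 5 shocks, got {len(onsets)}")
    gaps = np.diff(onsets)
    for g in gaps:
        if not any(abs(g - ok) < 1e-9 for ok in EMPATHY_GAPS):
            raise ValueError(f"inter-shock gap {g} s not in {EMPATHY_GAPS}")
    last = sum(EMPATHY_POST_MULTISET) - float(np.sum(gaps))
    if not any(abs(last - ok) < 1e-9 for ok in EMPATHY_GAPS):
        raise ValueError(
            "gaps are not a sub-multiset of three 120-s and two 180-s bins"
        )
    bins = [(onsets[0] - 120.0, onsets[0])]
    for k in range(4):
        bins.append((onsets[k], onsets[k + 1]))
    bins.append((onsets[4], onsets[4] + last))
    labels = ["before_shock"] + [f"post_shock_{k}" for k in range(1, 6)]
    return BinSchedule(bins=bins, labels=labels)


def _overlap(bouts: Sequence[tuple[float, float]], lo: float, hi: float) -> float:
    return sum(max(0.0, min(b, hi) - max(a, lo)) for a, b in bouts)


def percent_freezing(bouts: FreezingBoutSeries, bins: BinSchedule) -> np.ndarray:
    """Percentage of each bin spent freezing (overlap / bin length * 100)."""
    if not bins.bins:
        raise ValueError("empty bin schedule")
    return np.array(
        [100.0 * _overlap(bouts.bouts, lo, hi) / (hi - lo) for lo, hi in bins.bins]
    )


def average_shock_period_freezing(per_bin: Sequence[float]) -> float:
    """Mean freezing over the 5 post-shock bins (baseline bin excluded)."""
    per_bin = np.asarray(per_bin, dtype=np.float64)
    if per_bin.shape != (6,):
        raise ValueError(f"expected a 6-bin vector, got shape {per_bin.shape}")
    return float(np.mean(per_bin[1:]))


def pre_exposure_freezing(bouts: FreezingBoutSeries, schedule: SessionSchedule) -> float:
    """% freezing over the last 3 minutes of the 5-minute pre-exposure test."""
    if schedule.session_type != "pre_exposure_test":
        raise ValueError("schedule is not a pre_exposure_test session")
    if schedule.total_duration < 300.0:
        raise ValueError("pre-exposure test session must last 300 s")
    return 100.0 * _overlap(bouts.bouts, 120.0, 300.0) / 180.0


def locomotion_percent_change(activity: Sequence[float]) -> np.ndarray:
    """% change in locomotion per 5-min bin relative to the first bin.

    Bin 1 is 0 by definition; bin k is 100*(A_k - A_1)/A_1.
    """
    a = np.asarray(activity, dtype=np.float64)
    if a.size < 2:
        raise ValueError("need at least 2 locomotion bins")
    if a[0] == 0:
        raise ValueError("first-bin activity is zero; percent change undefined")
    out = 100.0 * (a - a[0]) / a[0]
    out[0] = 0.0
    return out


def window_zone_occupancy(
    track: PositionTrack, periods: Sequence[tuple[float, float]]
) -> np.ndarray:
    """% of position samples in the window zone (x < 12.5 cm) per period.

    The boundary x == zone_split belongs to the far zone (half-open).
    """
    out = []
    for lo, hi in periods:
        if lo < track.t[0] - 1e-9 or hi > track.t[-1] + 1e-9:
            raise ValueError(f"period [{lo}, {hi}) outside the track span")
        mask = (track.t >= lo) & (track.t < hi)
        n = int(mask.sum())
        if n == 0:
            raise ValueError(f"no samples in period [{lo}, {hi})")
        out.append(100.0 * float(np.sum(track.x[mask] < track.zone_split)) / n)
    return np.array(out)


def sound_test_bins(schedule: SessionSchedule) -> BinSchedule:
    """2-bin playback schedule: 2 min before onset, 12 min during playback."""
    if schedule.session_type != "sound_test":
        raise ValueError("schedule is not a sound_test session")
    if len(schedule.event_onsets) != 1:
        raise ValueError("sound test has exactly one playback onset")
    onset = float(schedule.event_onsets[0])
    if onset < 120.0:
        raise ValueError("playback onset must allow a 2-minute pre-bin")
    return BinSchedule(
        bins=[(onset - 120.0, onset), (onset, onset + 720.0)],
        labels=["before_sound", "during_sound"],
    )


# ---------------------------------------------------------------------------
# CSV adapters (tracker / scoring exports)

def read_bouts_csv(path) -> dict[str, FreezingBoutSeries]:
    """Load bouts.csv (animal_id, start_s, end_s) into per-animal series."""
    df = pd.read_csv(path)
    out = {}
    for animal, grp in df.groupby("animal_id", sort=False):
        grp = grp.sort_values("start_s")
        out[str(animal)] = FreezingBoutSeries(
            animal_id=str(animal),
            bouts=list(zip(grp["start_s"].astype(float), grp["end_s"].astype(float))),
        )
    return out


def read_track_csv(path, **kwargs) -> dict[str, PositionTrack]:
    """Load track.csv (animal_id, t_s, x_cm, y_cm) into per-animal tracks."""
    df = pd.read_csv(path)
    return {
        str(animal): PositionTrack(
            animal_id=str(animal),
            t=grp["t_s"].to_numpy(),
            x=grp["x_cm"].to_numpy(),
            y=grp["y_cm"].to_numpy(),
            **kwargs,
        )
        for animal, grp in df.groupby("animal_id", sort=False)
    }


def read_activity_csv(path) -> dict[str, np.ndarray]:
    """Load activity.csv (animal_id, bin_index, distance_cm) per animal."""
    df = pd.read_csv(path)
    return {
        str(animal): grp.sort_values("bin_index")["distance_cm"].to_numpy(dtype=float)
        for animal, grp in df.groupby("animal_id", sort=False)
    }
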