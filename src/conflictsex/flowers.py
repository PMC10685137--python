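"""Core data model: individual flowers and their phenological intervals.

The flower — not the plant — is the modular unit of analysis throughout this
package.  An andromonoecious individual produces male and/or bisexual flowers;
bisexual flowers are strongly protogynous, presenting receptive pistils for
several days before their anthers open.  Time is discretized to integer day
indices from the start of the season, and all phase membership is expressed
with half-open intervals ``[start, end)`` so that overlap arithmetic is
unambiguous.

Phase overlap between flowers is always evaluated on the census-day grid
(every 3–4 days), matching the resolution at which a field census would
observe flowering states.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

MALE = "male"
BISEXUAL = "bisexual"

Interval = tuple[int, int]  # half-open [start, end), integer days


def interval_length(iv: Optional[Interval]) -> int:
    if iv is None:
        return 0
    return max(0, iv[1] - iv[0])


def interval_contains(iv: Optional[Interval], day: int) -> bool:
    return iv is not None and iv[0] <= day < iv[1]


def days_in_interval(iv: Optional[Interval], census_days: Sequence[int]) -> list[int]:
    """Census days falling inside a half-open interval."""
    if iv is None:
        return []
    return [d for d in census_days if iv[0] <= d < iv[1]]


def intervals_overlap_on_grid(a: Optional[Interval], b: Optional[Interval],
                              census_days: Sequence[int]) -> bool:
    """True if both intervals cover at least one common census day."""
    if a is None or b is None:
        return False
    lo, hi = max(a[0], b[0]), min(a[1], b[1])
    if lo >= hi:
        return False
    return any(lo <= d < hi for d in census_days)


def census_schedule(season_length: float, census_interval: float) -> list[int]:
    """Integer census days at (approximately) regular spacing.

    A fractional interval such as the default 3.5 yields an alternating 3/4
    day visit pattern (0, 4, 7, 11, ...), mimicking a field census carried out
    every three to four days.
    """
    if census_interval <= 0:
        raise ValueError("census_interval must be > 0")
    days, t = [], 0.0
    while round(t) <= season_length:
        days.append(int(round(t)))
        t += census_interval
    return sorted(set(days))


@dataclass
class FlowerRecord:
    """One flower: sex class, allocation, phenology and morphology.

    ``stamen_count_effective`` reflects experimental stamen removal and is
    derived, never stored: the pre-manipulation count is preserved in
    ``stamen_count_initial``.
    """

    flower_id: str
    individual_id: str
    sex_class: str
    pistil_count: int
    stamen_count_initial: int
    opening_day: int
    male_interval: Interval
    female_interval: Optional[Interval] = None
    removal_fraction: float = 0.0
    tepal_length: float = float("nan")   # mm
    stalk_height: float = float("nan")   # cm
    seed_count: int = 0

    def __post_init__(self) -> None:
        if self.sex_class not in (MALE, BISEXUAL):
            raise ValueError(f"unknown sex_class {self.sex_class!r}")
        if self.removal_fraction not in (0.0, 0.5, 1.0):
            raise ValueError("removal_fraction must be one of 0, 0.5, 1.0")
        if self.pistil_count < 0 or self.stamen_count_initial < 0:
            raise ValueError("counts must be non-negative")
        if self.sex_class == MALE:
            if self.pistil_count != 0:
                raise ValueError("male flowers must have pistil_count = 0")
            if self.female_interval is not None and interval_length(self.female_interval) > 0:
                raise ValueError("male flowers must have an empty female interval")
            self.female_interval = None
        else:
            if self.female_interval is None:
                raise ValueError("bisexual flowers require a female interval")
            if self.female_interval[0] != self.opening_day:
                raise ValueError("female phase must start on the opening day")
            if self.male_interval[0] < self.female_interval[0]:
                raise ValueError("protogyny violated: male phase precedes female phase")
        if self.seed_count > self.pistil_count:
            raise ValueError("seed_count cannot exceed pistil_count")

    @property
    def stamen_count_effective(self) -> int:
        return int(round(self.stamen_count_initial * (1.0 - self.removal_fraction)))

    @property
    def duration(self) -> int:
        """Flowering duration: union length of the phase intervals."""
        f, m = self.female_interval, self.male_interval
        if f is None:
            return interval_length(m)
        overlap = max(0, min(f[1], m[1]) - max(f[0], m[0]))
        return interval_length(f) + interval_length(m) - overlap

    def state_on(self, day: int) -> str:
        """Derived flowering state on a given day.

        One of ``pre``, ``female``, ``male``, ``interphase`` (a bisexual
        flower between the end of its female phase and the opening of its
        anthers) or ``finished``.
        """
        if day < self.opening_day:
            return "pre"
        if interval_contains(self.female_interval, day):
            return "female"
        if interval_contains(self.male_interval, day):
            return "male"
        if day >= self.male_interval[1]:
            return "finished"
        return "interphase"

    def copy(self, **changes) -> "FlowerRecord":
        return replace(self, **changes)


def flowers_to_frame(flowers: Iterable[FlowerRecord]) -> pd.DataFrame:
    rows = []
    for f in flowers:
        fi = f.female_interval
        rows.append({
            "flower_id": f.flower_id,
            "individual_id": f.individual_id,
            "sex_class": f.sex_class,
            "pistil_count": f.pistil_count,
            "stamen_count_initial": f.stamen_count_initial,
            "removal_fraction": f.removal_fraction,
            "stamen_count_effective": f.stamen_count_effective,
            "opening_day": f.opening_day,
            "female_start": np.nan if fi is None else fi[0],
            "female_end": np.nan if fi is None else fi[1],
            "male_start": f.male_interval[0],
            "male_end": f.male_interval[1],
            "tepal_length": f.tepal_length,
            "stalk_height": f.stalk_height,
            "seed_count": f.seed_count,
        })
    return pd.DataFrame(rows)


def frame_to_flowers(df: pd.DataFrame) -> list[FlowerRecord]:
    flowers = []
    for _, r in df.iterrows():
        female = None
        if r["sex_class"] == BISEXUAL and not pd.isna(r["female_start"]):
            female = (int(r["female_start"]), int(r["female_end"]))
        flowers.append(FlowerRecord(
            flower_id=str(r["flower_id"]),
            individual_id=str(r["individual_id"]),
            sex_class=str(r["sex_class"]),
            pistil_count=int(r["pistil_count"]),
            stamen_count_initial=int(r["stamen_count_initial"]),
            removal_fraction=float(r["removal_fraction"]),
            opening_day=int(r["opening_day"]),
            female_interval=female,
            male_interval=(int(r["male_start"]), int(r["male_end"])),
            tepal_length=float(r["tepal_length"]),
            stalk_height=float(r["stalk_height"]),
            seed_count=int(r["seed_count"]),
        ))
    return flowers


def census_states(flowers: Sequence[FlowerRecord], census_days: Sequence[int]) -> pd.DataFrame:
    """Long-format census table: one row per flower per census day."""
    rows = [
        {"day": d, "flower_id": f.flower_id, "state": f.state_on(d)}
        for d in census_days for f in flowers
    ]
    return pd.DataFrame(rows)
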