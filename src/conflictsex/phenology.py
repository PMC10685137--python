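"""Season-level phenology: mate availability per census day, the male-onset
delay of protogynous bisexual flowers, and flowering-duration summaries.

The central quantity is *pistil availability per stamen* — the ratio of
receptive pistils to mature stamens in the whole population at each census
day — which measures prospective siring opportunity through time.  It is
computed under three scenarios: (1) stamens as experimentally manipulated
(effective counts), (2) stamens as produced (initial counts), and (3) initial
counts but with unisexual male flowers excluded from the pool of potential
sires.  Comparing scenario 3 with the others shows how much siring
opportunity the early male flowers capture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._lmm import fit_random_intercept
from .errors import EstimationError
from .flowers import BISEXUAL, MALE, FlowerRecord, days_in_interval

log = logging.getLogger(__name__)

SCENARIOS = (1, 2, 3)


def census_counts(flowers: Sequence[FlowerRecord],
                  census_days: Sequence[int],
                  scenario: int) -> pd.DataFrame:
    """Receptive pistils, mature stamens and their ratio per census day.

    A flower whose phase spans k census days is assumed to present an equal
    share of its organs at each of them, i.e. it contributes
    ``pistil_count / k`` (or ``stamen_count / k``) per day — so each flower's
    total contribution over the season equals its organ count exactly.
    Availability is left undefined (NaN) on days with no mature stamens.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {SCENARIOS}")
    days = list(census_days)
    pistils = pd.Series(0.0, index=days)
    stamens = pd.Series(0.0, index=days)
    for f in flowers:
        fdays = days_in_interval(f.female_interval, days)
        if fdays:
            pistils.loc[fdays] += f.pistil_count / len(fdays)
        if scenario == 3 and f.sex_class == MALE:
            continue
        count = f.stamen_count_effective if scenario == 1 else f.stamen_count_initial
        mdays = days_in_interval(f.male_interval, days)
        if mdays and count > 0:
            stamens.loc[mdays] += count / len(mdays)
    avail = pistils / stamens.replace(0.0, np.nan)
    return pd.DataFrame({"day": days,
                         "pistils": pistils.to_numpy(),
                         "stamens": stamens.to_numpy(),
                         "availability": avail.to_numpy(),
                         "scenario": scenario})


@dataclass
class DelayRecord:
    """Male-onset delay of one unmanipulated bisexual flower."""
    flower_id: str
    delay_days: float     # anther-opening day minus flower-opening day
    pistil_count: int
    opening_day: int


def male_onset_delay(flowers: Sequence[FlowerRecord]) -> list[DelayRecord]:
    """Delay records for bisexual flowers whose stamens were not manipulated.

    Male flowers and stamen-removal flowers are skipped (with a log entry for
    male flowers, which should not normally be passed in).
    """
    records = []
    for f in flowers:
        if f.sex_class == MALE:
            log.info("male_onset_delay: skipping male flower %s", f.flower_id)
            continue
        if f.removal_fraction != 0.0:
            continue
        records.append(DelayRecord(
            flower_id=f.flower_id,
            delay_days=f.male_interval[0] - f.opening_day,
            pistil_count=f.pistil_count,
            opening_day=f.opening_day))
    return records


def delay_regression(delay_records: Sequence[DelayRecord],
                     reml: bool = True) -> dict:
    """Mixed-model regression of male-onset delay on pistil number.

    Fits ``delay ~ pistils/100`` with a random intercept per flower-opening
    day (absorbing shared weather effects on phenology), by direct
    optimization of the Gaussian likelihood.  Returns the slope in days per
    100 pistils with its standard error and a Wald t p-value.
    """
    records = list(delay_records)
    if len(records) < 10:
        raise EstimationError("need at least 10 delay records")
    days = {r.opening_day for r in records}
    if len(days) < 3:
        raise EstimationError("need at least 3 distinct opening days")
    x = np.array([r.pistil_count / 100.0 for r in records])
    if np.ptp(x) == 0:
        raise EstimationError("pistil counts are constant; slope is not "
                              "identifiable")
    y = np.array([float(r.delay_days) for r in records])
    groups = np.array([r.opening_day for r in records])
    X = np.column_stack([np.ones_like(x), x])
    fit = fit_random_intercept(y, X, groups, reml=reml)
    p = fit.t_pvalues()
    return {"slope": float(fit.beta[1]), "se": float(fit.se[1]),
            "p": float(p[1]), "intercept": float(fit.beta[0]),
            "sigma2_e": fit.sigma2_e, "sigma2_u": fit.sigma2_u,
            "n": len(records), "n_days": fit.n_groups,
            "boundary": fit.boundary}


def duration_summary(flowers: Sequence[FlowerRecord]) -> dict:
    """Mean flowering duration by sex class with a Welch t-test.

    Duration is the union length of a flower's phase intervals.  If one class
    is absent the means are reported without a test.
    """
    durs = {MALE: [], BISEXUAL: []}
    for f in flowers:
        durs[f.sex_class].append(f.duration)
    out = {
        "mean_male": float(np.mean(durs[MALE])) if durs[MALE] else np.nan,
        "mean_bisexual": float(np.mean(durs[BISEXUAL])) if durs[BISEXUAL] else np.nan,
        "n_male": len(durs[MALE]),
        "n_bisexual": len(durs[BISEXUAL]),
        "t": np.nan, "p": np.nan,
    }
    if len(durs[MALE]) >= 2 and len(durs[BISEXUAL]) >= 2:
        t, p = stats.ttest_ind(durs[MALE], durs[BISEXUAL], equal_var=False)
        out["t"], out["p"] = float(t), float(p)
    return out
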