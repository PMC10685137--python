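"""Per-flower female and male contributions to fitness.

Female contribution: seeds produced, discounted for self-fertilization.
A flower with selfing rate *s* keeps its outcrossed seeds at full value while
its selfed seeds are devalued by the inbreeding depression δ, giving
``W_f = N (1 − s·δ)``.  (The alternative literal reading ``N·s·(1−δ)`` would
assign zero fitness to a fully outcrossing flower and is rejected; see the
methods note.)  δ defaults to 0.93 and can be re-estimated from population
data with the equilibrium estimator of Ritland, which compares the adult
inbreeding coefficient with the population selfing rate.

Male contribution: the sum over seed families of the flower's fractional
siring credits from the paternity stage.

Relative fitness divides each component by its mean over the inclusion set —
bisexual flowers of single-flowered individuals with complete trait
measurements — so each sexual function has mean relative fitness 1 over the
flowers entering the selection analysis.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .flowers import BISEXUAL, FlowerRecord

TRAIT_COLUMNS = ["pistil_count", "stamen_count", "flowering_date",
                 "tepal_length", "stalk_height"]


def ritland_delta(F_adult: float, s_pop: float) -> float:
    """Equilibrium inbreeding-depression estimate from F and the selfing rate.

    At inbreeding equilibrium under partial selfing, δ = 1 − 2F(1−s)/[s(1−F)].
    The estimate is clamped to [0, 1] with a warning if it falls outside.
    """
    if not 0.0 < F_adult < 1.0:
        raise ValueError("F_adult must lie strictly between 0 and 1")
    if not 0.0 < s_pop < 1.0:
        raise ValueError("s_pop must lie strictly between 0 and 1")
    delta = 1.0 - (2.0 * F_adult * (1.0 - s_pop)) / (s_pop * (1.0 - F_adult))
    if delta < 0.0 or delta > 1.0:
        warnings.warn(f"equilibrium estimator gave δ = {delta:.3f}; clamped to [0, 1]")
        delta = min(1.0, max(0.0, delta))
    return float(delta)


def female_contribution(seed_count: float, selfing_rate: float,
                        delta: float) -> float:
    """W_f = seeds × (1 − selfing_rate × δ)."""
    if seed_count < 0:
        raise ValueError("seed_count must be >= 0")
    if not 0.0 <= selfing_rate <= 1.0 or not 0.0 <= delta <= 1.0:
        raise ValueError("selfing_rate and delta must be in [0, 1]")
    return float(seed_count) * (1.0 - selfing_rate * delta)


def male_contribution(siring: pd.Series, flower_id: str) -> float:
    """Total fractional seeds sired by a flower (0 if it sired none)."""
    return float(siring.get(flower_id, 0.0))


def inclusion_set(flowers: Sequence[FlowerRecord]) -> list[FlowerRecord]:
    """Bisexual flowers of single-flowered individuals with all five traits
    measured — the flowers entering relativization and selection analysis."""
    per_ind: dict[str, int] = {}
    for f in flowers:
        per_ind[f.individual_id] = per_ind.get(f.individual_id, 0) + 1
    out = []
    for f in flowers:
        if f.sex_class != BISEXUAL or per_ind[f.individual_id] != 1:
            continue
        if np.isnan(f.tepal_length) or np.isnan(f.stalk_height):
            continue
        out.append(f)
    return out


def fitness_table(flowers: Sequence[FlowerRecord],
                  selfing_rates: pd.Series,
                  siring: pd.Series,
                  delta: float = 0.93) -> pd.DataFrame:
    """Absolute W_female / W_male per flower.

    Flowers without a genotyped seed family get the population mean selfing
    rate for their female discount (a flower with no seeds contributes 0
    regardless).
    """
    mean_s = float(selfing_rates.mean()) if len(selfing_rates) else 0.0
    rows = []
    for f in flowers:
        s = float(selfing_rates.get(f.flower_id, mean_s))
        rows.append({
            "flower_id": f.flower_id,
            "individual_id": f.individual_id,
            "sex_class": f.sex_class,
            "selfing_rate": s if f.sex_class == BISEXUAL else np.nan,
            "W_female": (female_contribution(f.seed_count, s, delta)
                         if f.sex_class == BISEXUAL else 0.0),
            "W_male": male_contribution(siring, f.flower_id),
        })
    return pd.DataFrame(rows)


def relativize(fitness: pd.DataFrame,
               include_ids: Sequence[str]) -> pd.DataFrame:
    """Divide each fitness component by its mean over the inclusion set.

    Means are computed within the inclusion set only; the returned table is
    restricted to it, with relW columns each averaging exactly 1.
    """
    include_ids = list(include_ids)
    if not include_ids:
        raise ValueError("empty inclusion set")
    sub = fitness[fitness["flower_id"].isin(include_ids)].copy()
    if len(sub) != len(include_ids):
        missing = set(include_ids) - set(sub["flower_id"])
        raise ValueError(f"fitness table missing flowers: {sorted(missing)[:5]}")
    for col, rel in (("W_female", "relW_female"), ("W_male", "relW_male")):
        mean = sub[col].mean()
        if mean <= 0:
            raise ValueError(f"mean {col} over the inclusion set is not positive")
        sub[rel] = sub[col] / mean
    return sub.reset_index(drop=True)
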