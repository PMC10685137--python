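"""Synthetic flowering season for an andromonoecious, protogynous plant.

The generator produces a complete season with the statistical structure the
downstream analyses assume: a population of ~150 individuals bearing male and
bisexual flowers, strongly protogynous bisexual flowers whose male-phase onset
is delayed in proportion to their pistil number, experimental stamen removal,
census-day mating with pollen drawn in proportion to available stamens, a
known pedigree, and microsatellite genotypes with a replacement-type
genotyping error.

All stochastic draws flow from a single seeded :class:`numpy.random.Generator`
in a fixed order (flower counts → sex classes → phenology → morphology →
removal → mating → genotypes), so identical configs and seeds give
byte-identical outputs at every stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import _distributions as dist
from .errors import ConfigurationError
from .flowers import BISEXUAL, MALE, FlowerRecord, census_schedule
from .genotypes import ADULT, SEED, GenotypeTable, _META_COLS

log = logging.getLogger(__name__)


def _default_flowers_per_individual() -> dict:
    # 1 + Poisson(0.15): most individuals single-flowered, a minority with 2+
    return {"kind": "poisson", "mean": 0.15, "offset": 1, "integer": True}


def _default_pistil_count() -> dict:
    # one to a few hundred pistils; right-skewed with median ~70
    return {"kind": "lognormal", "mu": 4.25, "sigma": 0.7, "lo": 1, "hi": 300,
            "integer": True}


def _default_stamen_count() -> dict:
    # stamen number is comparatively uniform across flowers
    return {"kind": "normal", "mean": 150, "sd": 25, "lo": 20, "hi": 300,
            "integer": True}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic season.

    Defaults emulate the study population: ~150 mostly single-flowered
    individuals (~135–175 flowers), about a quarter of flowers unisexual male
    and opening ~3 days earlier than bisexual ones, a 5 ± 2.1-day female
    phase, mean flowering durations of 9.6 d (bisexual) and 10.7 d (male),
    a male-onset delay of 0.58 days per 100 pistils, censuses every 3.5 days,
    10 microsatellite loci and a genotyping error rate of 0.018, and stamen
    removal treatments applied to 16% (half the stamens) and 9.6% (all
    stamens, bisexual flowers only) of flowers.
    """

    n_individuals: int = 150
    flowers_per_individual: dict = field(default_factory=_default_flowers_per_individual)
    prop_male_flowers: float = 0.26
    season_length: float = 30.0
    census_interval: float = 3.5
    opening_mean: float = 12.0
    opening_sd: float = 4.5
    male_opening_offset: float = -3.0
    female_phase_mean: float = 5.0
    female_phase_sd: float = 2.1
    bisexual_duration_mean: float = 9.6
    bisexual_duration_sd: float = 1.5
    male_duration_mean: float = 10.7
    male_duration_sd: float = 1.5
    pistil_count: dict = field(default_factory=_default_pistil_count)
    stamen_count: dict = field(default_factory=_default_stamen_count)
    pistil_delay_slope: float = 0.58     # days delayed per 100 pistils
    selfing_weight: float = 1.0          # relative weight of own-individual pollen
    seed_set_prob: float = 0.3           # per receptive pistil per census day
    n_loci: int = 10
    alleles_per_locus: int = 8
    genotyping_error: float = 0.018
    missing_rate: float = 0.02
    removal_50_fraction: float = 0.16
    removal_100_fraction: float = 0.096
    tepal_length_mean: float = 28.0
    tepal_length_sd: float = 4.0
    stalk_height_mean: float = 20.0
    stalk_height_sd: float = 5.0
    stalk_height_male_offset: float = -8.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        fractions = {
            "prop_male_flowers": self.prop_male_flowers,
            "seed_set_prob": self.seed_set_prob,
            "genotyping_error": self.genotyping_error,
            "missing_rate": self.missing_rate,
            "removal_50_fraction": self.removal_50_fraction,
            "removal_100_fraction": self.removal_100_fraction,
        }
        for name, val in fractions.items():
            if not 0.0 <= val <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {val}")
        if self.removal_50_fraction + self.removal_100_fraction > 1.0:
            raise ConfigurationError("removal fractions must sum to <= 1")
        if self.census_interval <= 0:
            raise ConfigurationError("census_interval must be > 0")
        if not self.female_phase_mean < self.bisexual_duration_mean:
            raise ConfigurationError(
                "female_phase_mean must be shorter than bisexual_duration_mean")
        if self.n_individuals <= 0 or self.n_loci <= 0 or self.alleles_per_locus < 2:
            raise ConfigurationError("counts must be positive (>= 2 alleles per locus)")
        if self.selfing_weight < 0:
            raise ConfigurationError("selfing_weight must be non-negative")
        for name in ("flowers_per_individual", "pistil_count", "stamen_count"):
            dist.validate_spec(getattr(self, name), name)
        if dist.spec_mean(self.flowers_per_individual) < 1:
            raise ConfigurationError("flowers_per_individual must have mean >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown simulation keys: {sorted(unknown)}")
        return cls(**d)


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

def simulate_population(config: SimulationConfig,
                        rng: Optional[np.random.Generator] = None
                        ) -> tuple[list[FlowerRecord], list[int]]:
    """Draw flowers and their phenology; returns (flowers, census days).

    Male flowers open earlier on average (``male_opening_offset``) and present
    stamens for their whole duration.  Bisexual flowers open in their female
    phase; anthers open ``female phase + pistil_delay_slope × pistils/100``
    days after flower opening, so the male-onset delay grows with female
    allocation.  The male phase runs until the flower's total duration is
    reached, keeping mean durations at their configured values.
    """
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    census_days = census_schedule(config.season_length, config.census_interval)

    counts = dist.draw(config.flowers_per_individual, rng, config.n_individuals)
    counts = np.maximum(1, np.rint(counts)).astype(int)
    n_flowers = int(counts.sum())
    is_male = rng.random(n_flowers) < config.prop_male_flowers

    open_b = rng.normal(config.opening_mean, config.opening_sd, n_flowers)
    open_m = open_b + config.male_opening_offset
    fem_raw = np.clip(rng.normal(config.female_phase_mean, config.female_phase_sd,
                                 n_flowers), 1.0, None)
    dur_b = rng.normal(config.bisexual_duration_mean, config.bisexual_duration_sd,
                       n_flowers)
    dur_m = rng.normal(config.male_duration_mean, config.male_duration_sd, n_flowers)
    pistils = dist.draw(config.pistil_count, rng, n_flowers).astype(int)
    stamens = dist.draw(config.stamen_count, rng, n_flowers).astype(int)
    tepal = rng.normal(config.tepal_length_mean, config.tepal_length_sd, n_flowers)
    stalk = rng.normal(config.stalk_height_mean, config.stalk_height_sd, n_flowers)

    max_open = config.season_length - config.bisexual_duration_mean
    flowers: list[FlowerRecord] = []
    idx = 0
    for i, n_i in enumerate(counts):
        ind = f"I{i + 1:03d}"
        for _ in range(n_i):
            fid = f"F{idx + 1:03d}"
            if is_male[idx]:
                day = int(np.clip(np.rint(open_m[idx]), 0, max_open))
                dur = max(1, int(np.rint(dur_m[idx])))
                flowers.append(FlowerRecord(
                    flower_id=fid, individual_id=ind, sex_class=MALE,
                    pistil_count=0, stamen_count_initial=int(stamens[idx]),
                    opening_day=day, male_interval=(day, day + dur),
                    tepal_length=float(tepal[idx]),
                    stalk_height=float(stalk[idx] + config.stalk_height_male_offset)))
            else:
                day = int(np.clip(np.rint(open_b[idx]), 0, max_open))
                n_pistils = max(1, int(pistils[idx]))
                fem_len = max(1, int(np.rint(fem_raw[idx])))
                delay = config.pistil_delay_slope * n_pistils / 100.0
                male_start = day + max(1, int(np.rint(fem_raw[idx] + delay)))
                male_len = max(1, int(np.rint(dur_b[idx] - fem_raw[idx])))
                flowers.append(FlowerRecord(
                    flower_id=fid, individual_id=ind, sex_class=BISEXUAL,
                    pistil_count=n_pistils, stamen_count_initial=int(stamens[idx]),
                    opening_day=day, female_interval=(day, day + fem_len),
                    male_interval=(male_start, male_start + male_len),
                    tepal_length=float(tepal[idx]), stalk_height=float(stalk[idx])))
            idx += 1
    return flowers, census_days


def apply_stamen_removal(flowers: Sequence[FlowerRecord],
                         removal_50_fraction: float,
                         removal_100_fraction: float,
                         rng: np.random.Generator) -> list[FlowerRecord]:
    """Assign stamen-removal treatments uniformly at random without replacement.

    Half-removal is applied across flowers of both sexes; full removal is
    restricted to bisexual flowers.  Target counts are the treatment fraction
    times the total flower number, rounded to the nearest integer.
    """
    if removal_50_fraction < 0 or removal_100_fraction < 0:
        raise ConfigurationError("removal fractions must be non-negative")
    if removal_50_fraction + removal_100_fraction > 1.0:
        raise ConfigurationError("removal fractions must sum to <= 1")
    out = [f.copy(removal_fraction=0.0) for f in flowers]
    n = len(out)
    n50 = int(round(removal_50_fraction * n))
    n100 = int(round(removal_100_fraction * n))
    order = rng.permutation(n)
    chosen50 = list(order[:n50])
    bisexual_rest = [i for i in order[n50:] if out[i].sex_class == BISEXUAL]
    if len(bisexual_rest) < n100:
        raise ConfigurationError("not enough untreated bisexual flowers for "
                                 "the 100%-removal treatment")
    for i in chosen50:
        out[i].removal_fraction = 0.5
    for i in bisexual_rest[:n100]:
        out[i].removal_fraction = 1.0
    return out


# ---------------------------------------------------------------------------
# mating
# ---------------------------------------------------------------------------

def simulate_mating(flowers: Sequence[FlowerRecord],
                    census_days: Sequence[int],
                    config: SimulationConfig,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Census-day mating; returns the pedigree and fills in seed counts.

    On each census day, every still-unset receptive pistil sets a seed with
    probability ``seed_set_prob``.  The seed's sire flower is drawn with
    probability proportional to effective stamen number among flowers whose
    male phase covers that day; flowers of the mother's own individual have
    their weights multiplied by ``selfing_weight``.  Days with receptive
    pistils but no available stamens produce no seeds (logged, not an error).
    Seed counts are written back onto the flower records.
    """
    for f in flowers:
        f.seed_count = 0
    remaining = {f.flower_id: f.pistil_count for f in flowers
                 if f.sex_class == BISEXUAL}
    by_id = {f.flower_id: f for f in flowers}
    rows = []
    seed_no = 0
    for day in census_days:
        sires = [f for f in flowers
                 if f.male_interval[0] <= day < f.male_interval[1]
                 and f.stamen_count_effective > 0]
        sire_ids = [f.flower_id for f in sires]
        sire_ind = np.array([f.individual_id for f in sires])
        weights = np.array([float(f.stamen_count_effective) for f in sires])
        for mother in flowers:
            if mother.sex_class != BISEXUAL:
                continue
            if not (mother.female_interval[0] <= day < mother.female_interval[1]):
                continue
            n_avail = remaining[mother.flower_id]
            if n_avail == 0:
                continue
            if not sires:
                log.debug("day %d: %s has receptive pistils but no stamens "
                          "are available", day, mother.flower_id)
                continue
            w = weights * np.where(sire_ind == mother.individual_id,
                                   config.selfing_weight, 1.0)
            total = w.sum()
            if total == 0:
                log.debug("day %d: all candidate pollen for %s has zero weight",
                          day, mother.flower_id)
                continue
            n_new = rng.binomial(n_avail, config.seed_set_prob)
            if n_new == 0:
                continue
            picks = rng.choice(len(sires), size=n_new, p=w / total)
            for k in picks:
                seed_no += 1
                rows.append({"seed_id": f"S{seed_no:05d}",
                             "mother_flower_id": mother.flower_id,
                             "sire_flower_id": sire_ids[k],
                             "day": day})
            remaining[mother.flower_id] -= n_new
            by_id[mother.flower_id].seed_count += n_new
    return pd.DataFrame(rows, columns=["seed_id", "mother_flower_id",
                                       "sire_flower_id", "day"])


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(pedigree: pd.DataFrame,
                       flowers: Sequence[FlowerRecord],
                       n_loci: int,
                       alleles_per_locus: int,
                       genotyping_error: float,
                       rng: np.random.Generator,
                       missing_rate: float = 0.0,
                       frequencies: Optional[dict[str, np.ndarray]] = None
                       ) -> GenotypeTable:
    """Genotype all adults (one multilocus genotype per individual) and the
    seeds in ``pedigree``.

    Adult genotypes are in Hardy–Weinberg proportions at Dirichlet(1) allele
    frequencies.  Seeds inherit one allele from the mother's individual and
    one from the sire's individual, each chosen uniformly.  Each observed
    single-locus genotype is then independently replaced, with probability
    ``genotyping_error``, by a random genotype drawn from the population
    allele frequencies — the same error model the paternity likelihood mixes
    in — and set to missing with probability ``missing_rate``.
    """
    by_id = {f.flower_id: f for f in flowers}
    for col in ("mother_flower_id", "sire_flower_id"):
        unknown = set(pedigree[col]) - set(by_id)
        if unknown:
            raise ValueError(f"pedigree references unknown flowers: {sorted(unknown)[:5]}")

    loci = [f"L{k + 1:02d}" for k in range(n_loci)]
    if frequencies is None:
        freqs = {loc: rng.dirichlet(np.ones(alleles_per_locus)) for loc in loci}
    else:
        freqs = {loc: np.asarray(frequencies[loc], float) for loc in loci}
    individuals = sorted({f.individual_id for f in flowers})
    ind_index = {ind: i for i, ind in enumerate(individuals)}

    # true adult genotypes: (n_ind, n_loci, 2), allele codes 1..A
    adult_gt = np.empty((len(individuals), n_loci, 2), dtype=int)
    for j, loc in enumerate(loci):
        adult_gt[:, j, :] = rng.choice(alleles_per_locus, size=(len(individuals), 2),
                                       p=freqs[loc]) + 1

    seed_ids = pedigree["seed_id"].tolist()
    seed_gt = np.empty((len(seed_ids), n_loci, 2), dtype=int)
    for s, (_, row) in enumerate(pedigree.iterrows()):
        mi = ind_index[by_id[row["mother_flower_id"]].individual_id]
        si = ind_index[by_id[row["sire_flower_id"]].individual_id]
        for j in range(n_loci):
            seed_gt[s, j, 0] = adult_gt[mi, j, rng.integers(2)]
            seed_gt[s, j, 1] = adult_gt[si, j, rng.integers(2)]

    def observe(gt: np.ndarray) -> np.ndarray:
        obs = gt.copy()
        n = obs.shape[0]
        for j, loc in enumerate(loci):
            err = rng.random(n) < genotyping_error
            if err.any():
                repl = rng.choice(alleles_per_locus, size=(int(err.sum()), 2),
                                  p=freqs[loc]) + 1
                obs[err, j, :] = repl
            if missing_rate > 0:
                miss = rng.random(n) < missing_rate
                obs[miss, j, :] = 0
        return obs

    adult_obs = observe(adult_gt)
    seed_obs = observe(seed_gt)

    meta = ([{"sample_id": ind, "role": ADULT, "individual_id": ind,
              "mother_flower_id": ""} for ind in individuals]
            + [{"sample_id": sid, "role": SEED, "individual_id": "",
                "mother_flower_id": mom}
               for sid, mom in zip(seed_ids, pedigree["mother_flower_id"])])
    df = pd.DataFrame(meta)
    allele_cols = {}
    both = np.vstack([adult_obs, seed_obs]) if len(seed_ids) else adult_obs
    for j, loc in enumerate(loci):
        allele_cols[loc + "_1"] = both[:, j, 0]
        allele_cols[loc + "_2"] = both[:, j, 1]
    df = pd.concat([df, pd.DataFrame(allele_cols)], axis=1)
    return GenotypeTable(df[_META_COLS + [c for loc in loci for c in
                                          (loc + "_1", loc + "_2")]],
                         loci, true_frequencies=freqs)


# ---------------------------------------------------------------------------
# whole season
# ---------------------------------------------------------------------------

@dataclass
class SeasonData:
    """Bundle returned by :func:`simulate_season`."""
    config: SimulationConfig
    flowers: list[FlowerRecord]
    census_days: list[int]
    pedigree: pd.DataFrame
    genotypes: GenotypeTable


def simulate_season(config: SimulationConfig,
                    max_seeds_per_family: int = 10) -> SeasonData:
    """Run the full generative model: population → removal → mating →
    genotyping of up to ``max_seeds_per_family`` seeds per seed family."""
    rng = np.random.default_rng(config.rng_seed)
    flowers, census_days = simulate_population(config, rng)
    flowers = apply_stamen_removal(flowers, config.removal_50_fraction,
                                   config.removal_100_fraction, rng)
    pedigree = simulate_mating(flowers, census_days, config, rng)
    sampled = sample_families(pedigree, max_seeds_per_family, rng)
    genotypes = simulate_genotypes(sampled, flowers, config.n_loci,
                                   config.alleles_per_locus,
                                   config.genotyping_error, rng,
                                   config.missing_rate)
    return SeasonData(config, flowers, census_days, pedigree, genotypes)


def sample_families(pedigree: pd.DataFrame, max_seeds_per_family: int,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Subsample up to ``max_seeds_per_family`` seeds per mother flower for
    genotyping, preserving pedigree truth for the sampled seeds."""
    if pedigree.empty:
        return pedigree
    parts = []
    for _, fam in pedigree.groupby("mother_flower_id", sort=True):
        if len(fam) <= max_seeds_per_family:
            parts.append(fam)
        else:
            take = rng.choice(len(fam), size=max_seeds_per_family, replace=False)
            parts.append(fam.iloc[np.sort(take)])
    return pd.concat(parts).sort_index().reset_index(drop=True)
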