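"""Microsatellite paternity assignment and siring-success accounting.

Seeds of known mothers are assigned to candidate sire *flowers* by a
likelihood-ratio (LOD) score summed over loci: the probability of the seed's
multilocus genotype given the mother and the candidate, over its probability
given the mother and a random sire drawn from the population allele
frequencies.  Genotyping error is mixed into the offspring transition
probability as a replacement model — with probability ε the observed
single-locus genotype is an independent Hardy–Weinberg draw — mirroring the
error process of the simulator, so the likelihood is exactly matched to the
generative model.

Assignment confidence uses the Δ statistic (best minus second-best LOD): a
critical value Δ* is calibrated by simulating seeds of known sires from the
candidate pool and choosing the smallest threshold at which the desired
fraction (default 80%) of above-threshold assignments is correct.

The candidate list for each seed family is filtered temporally: only flowers
whose pollen presentation overlapped the focal flower's receptive phase on at
least one census day are possible sires; flowers with all stamens removed are
excluded; flowers of the mother's own individual are retained, so
self-fertilization is detectable.  Siring success is fractional: each family's
total seed count is split among sires in proportion to their share of the
genotyped sample.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import MotherMismatchError
from .flowers import FlowerRecord, intervals_overlap_on_grid
from .genotypes import GenotypeTable

log = logging.getLogger(__name__)

Genotype = tuple[int, int]  # unordered allele pair; (0, 0) = missing


@dataclass
class LocusPanel:
    """Allele frequencies and error model for a set of loci.

    Frequencies are counting estimates over non-missing adult alleles.
    ``error`` is the per-locus genotype replacement rate ε used both in the
    transition probabilities and in Δ* calibration.
    """

    loci: list[str]
    alleles: dict[str, np.ndarray]        # allele codes per locus
    frequencies: dict[str, np.ndarray]    # same order as alleles, sums to 1
    missing_rate: dict[str, float] = field(default_factory=dict)
    error: float = 0.018

    def __post_init__(self) -> None:
        for loc in self.loci:
            f = self.frequencies[loc]
            if np.any(f <= 0) or abs(f.sum() - 1.0) > 1e-9:
                raise ValueError(f"locus {loc}: frequencies must be positive "
                                 "and sum to 1")
        self._lookup = {
            loc: {int(a): float(p)
                  for a, p in zip(self.alleles[loc], self.frequencies[loc])}
            for loc in self.loci}

    def freq(self, locus: str, allele: int) -> float:
        try:
            return self._lookup[locus][int(allele)]
        except KeyError:
            raise KeyError(f"allele {allele} absent from panel at {locus}")


def allele_frequencies(genotypes: GenotypeTable, error: float = 0.018) -> LocusPanel:
    """Counting estimator of allele frequencies over non-missing adult calls.

    Loci at which every adult call is missing are dropped with a warning.
    Alleles that appear only among seeds (possible in small samples, e.g.
    when every adult carrier was miscalled) are added with a half-count
    pseudo-frequency so the likelihood stays defined for every observed seed
    genotype.
    """
    adults = genotypes.adults
    if adults.empty:
        raise ValueError("no adult genotypes to estimate frequencies from")
    seeds = genotypes.seeds
    loci, alleles, freqs, miss = [], {}, {}, {}
    for loc in genotypes.loci:
        a1, a2 = genotypes.alleles_at(loc, adults)
        pooled = np.concatenate([a1, a2])
        observed = pooled[pooled > 0]
        if observed.size == 0:
            warnings.warn(f"locus {loc}: all adult calls missing; dropped")
            continue
        vals, counts = np.unique(observed, return_counts=True)
        counts = counts.astype(float)
        if not seeds.empty:
            s1, s2 = genotypes.alleles_at(loc, seeds)
            seed_alleles = np.unique(np.concatenate([s1, s2]))
            unseen = seed_alleles[(seed_alleles > 0)
                                  & ~np.isin(seed_alleles, vals)]
            if unseen.size:
                log.info("locus %s: %d seed-only allele(s) added with "
                         "pseudo-counts", loc, unseen.size)
                vals = np.concatenate([vals, unseen])
                counts = np.concatenate([counts, np.full(unseen.size, 0.5)])
                order = np.argsort(vals)
                vals, counts = vals[order], counts[order]
        loci.append(loc)
        alleles[loc] = vals
        freqs[loc] = counts / counts.sum()
        miss[loc] = float(np.mean((a1 == 0) | (a2 == 0)))
    return LocusPanel(loci, alleles, freqs, miss, error)


# ---------------------------------------------------------------------------
# transition probabilities and LOD scores
# ---------------------------------------------------------------------------

def _gamete_prob(gt: Genotype, allele: int) -> float:
    # explicit float casts: numpy bool scalars define + as logical OR
    return 0.5 * (float(gt[0] == allele) + float(gt[1] == allele))


def _hw_prob(gt: Genotype, locus: str, panel: LocusPanel) -> float:
    fx, fy = panel.freq(locus, gt[0]), panel.freq(locus, gt[1])
    return fx * fy if gt[0] == gt[1] else 2.0 * fx * fy


def transition_probability(offspring_gt: Optional[Genotype],
                           mother_gt: Optional[Genotype],
                           father_gt: Optional[Genotype],
                           locus: str, panel: LocusPanel) -> float:
    """P(observed offspring genotype | mother, father) at one locus.

    ``father_gt=None`` is the null sire: the paternal allele is drawn from
    the population allele frequencies.  Missing observations (``None`` or a
    0 allele) contribute probability 1.  The error model is mixed in as
    ``(1-ε)·P_mendel + ε·P_HW(offspring)``.
    """
    def missing(gt):
        return gt is None or gt[0] == 0 or gt[1] == 0
    if missing(offspring_gt) or missing(mother_gt):
        return 1.0
    x, y = offspring_gt
    qm = (_gamete_prob(mother_gt, x), _gamete_prob(mother_gt, y))
    if father_gt is None:
        qp = (panel.freq(locus, x), panel.freq(locus, y))
    elif missing(father_gt):
        return transition_probability(offspring_gt, mother_gt, None, locus, panel)
    else:
        qp = (_gamete_prob(father_gt, x), _gamete_prob(father_gt, y))
    p_mendel = qm[0] * qp[0] if x == y else qm[0] * qp[1] + qm[1] * qp[0]
    eps = panel.error
    return (1.0 - eps) * p_mendel + eps * _hw_prob(offspring_gt, locus, panel)


def lod_score(seed_gt: dict[str, Genotype], mother_gt: dict[str, Genotype],
              candidate_gt: dict[str, Genotype], panel: LocusPanel) -> float:
    """Multilocus LOD = Σ_loci ln[P(seed|mother,candidate)/P(seed|mother,null)].

    A candidate genotype missing at a locus contributes 0 to the sum (the
    ratio is 1).  A zero denominator — Mendelian-impossible mother-offspring
    pair, only possible at ε = 0 — raises :class:`MotherMismatchError`.
    """
    total = 0.0
    for loc in panel.loci:
        num = transition_probability(seed_gt.get(loc), mother_gt.get(loc),
                                     candidate_gt.get(loc), loc, panel)
        den = transition_probability(seed_gt.get(loc), mother_gt.get(loc),
                                     None, loc, panel)
        if den == 0.0:
            raise MotherMismatchError(
                f"offspring genotype impossible given mother at {loc}")
        total += -np.inf if num == 0.0 else np.log(num / den)
    return float(total)


@dataclass
class CandidateSet:
    """Candidate sire flowers with genotype arrays laid out per locus for
    vectorized LOD computation."""
    flower_ids: list[str]
    individual_ids: list[str]
    a1: dict[str, np.ndarray]
    a2: dict[str, np.ndarray]

    def __len__(self) -> int:
        return len(self.flower_ids)

    @classmethod
    def build(cls, flowers: Sequence[FlowerRecord], genotypes: GenotypeTable,
              panel: LocusPanel) -> "CandidateSet":
        adults = genotypes.adults.set_index("sample_id")
        a1 = {loc: np.empty(len(flowers), int) for loc in panel.loci}
        a2 = {loc: np.empty(len(flowers), int) for loc in panel.loci}
        for i, f in enumerate(flowers):
            row = adults.loc[f.individual_id]
            for loc in panel.loci:
                a1[loc][i] = int(row[loc + "_1"])
                a2[loc][i] = int(row[loc + "_2"])
        return cls([f.flower_id for f in flowers],
                   [f.individual_id for f in flowers], a1, a2)

    def subset(self, idx: Sequence[int]) -> "CandidateSet":
        idx = list(idx)
        return CandidateSet([self.flower_ids[i] for i in idx],
                            [self.individual_ids[i] for i in idx],
                            {loc: a[idx] for loc, a in self.a1.items()},
                            {loc: a[idx] for loc, a in self.a2.items()})


def lod_scores(seed_gt: dict[str, Genotype], mother_gt: dict[str, Genotype],
               candidates: CandidateSet, panel: LocusPanel) -> np.ndarray:
    """LOD of every candidate against one seed, vectorized over candidates."""
    m = len(candidates)
    total = np.zeros(m)
    eps = panel.error
    for loc in panel.loci:
        off = seed_gt.get(loc)
        mom = mother_gt.get(loc)
        if off is None or mom is None or 0 in off or 0 in mom:
            continue
        x, y = off
        fx, fy = panel.freq(loc, x), panel.freq(loc, y)
        qm_x, qm_y = _gamete_prob(mom, x), _gamete_prob(mom, y)
        phw = fx * fy if x == y else 2.0 * fx * fy
        p_null = qm_x * fx if x == y else qm_x * fy + qm_y * fx
        den = (1.0 - eps) * p_null + eps * phw
        if den == 0.0:
            raise MotherMismatchError(
                f"offspring genotype impossible given mother at {loc}")
        c1, c2 = candidates.a1[loc], candidates.a2[loc]
        qp_x = 0.5 * ((c1 == x).astype(float) + (c2 == x))
        qp_y = 0.5 * ((c1 == y).astype(float) + (c2 == y))
        p_men = qm_x * qp_x if x == y else qm_x * qp_y + qm_y * qp_x
        num = (1.0 - eps) * p_men + eps * phw
        with np.errstate(divide="ignore"):
            contrib = np.log(num / den)
        contrib[(c1 == 0) | (c2 == 0)] = 0.0  # untyped candidate locus skipped
        total += contrib
    return total


# ---------------------------------------------------------------------------
# candidate filtering and the Δ criterion
# ---------------------------------------------------------------------------

def candidate_filter(focal: FlowerRecord, all_flowers: Sequence[FlowerRecord],
                     census_days: Sequence[int]) -> list[FlowerRecord]:
    """Temporally plausible sires for a focal bisexual flower.

    Keeps flowers whose male phase shares at least one census day with the
    focal flower's female phase and which retained at least one stamen.
    Flowers of the focal flower's own individual are retained (selfing is
    possible); the focal flower itself is excluded only through phenology.
    """
    return [f for f in all_flowers
            if f.stamen_count_effective > 0
            and intervals_overlap_on_grid(f.male_interval, focal.female_interval,
                                          census_days)]


def critical_delta(panel: LocusPanel, candidates: CandidateSet,
                   confidence: float, n_sim: int,
                   rng: np.random.Generator) -> float:
    """Calibrate the Δ threshold for the requested assignment confidence.

    Seeds of known sires are simulated from the candidate pool (mothers drawn
    from Hardy–Weinberg proportions at the panel frequencies, offspring
    observed through the ε replacement-error model) and scored against every
    candidate.  Returns the smallest Δ* such that, among simulated seeds with
    Δ ≥ Δ*, the fraction whose best candidate is the true sire reaches
    ``confidence``.  Returns ``inf`` if no threshold achieves it.
    """
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    if n_sim < 1000:
        raise ValueError("n_sim must be at least 1000")
    m = len(candidates)
    if m <= 1:
        warnings.warn("single candidate: Δ* = 0")
        return 0.0
    deltas = np.empty(n_sim)
    correct = np.zeros(n_sim, bool)
    for s in range(n_sim):
        true = int(rng.integers(m))
        mother_gt, seed_gt = {}, {}
        for loc in panel.loci:
            alleles, freqs = panel.alleles[loc], panel.frequencies[loc]
            mom = tuple(int(a) for a in rng.choice(alleles, 2, p=freqs))
            mother_gt[loc] = mom
            sire = (int(candidates.a1[loc][true]), int(candidates.a2[loc][true]))
            if sire[0] == 0 or sire[1] == 0:
                pat = int(rng.choice(alleles, p=freqs))
            else:
                pat = sire[rng.integers(2)]
            child = (mom[rng.integers(2)], pat)
            if rng.random() < panel.error:
                child = tuple(int(a) for a in rng.choice(alleles, 2, p=freqs))
            seed_gt[loc] = child
        lods = lod_scores(seed_gt, mother_gt, candidates, panel)
        order = np.argsort(lods)[::-1]
        best, second = lods[order[0]], lods[order[1]]
        deltas[s] = best - second
        correct[s] = (order[0] == true) and (best - second) > 0
    order = np.argsort(deltas)[::-1]
    suffix_correct = np.cumsum(correct[order])
    counts = np.arange(1, n_sim + 1)
    accuracy = suffix_correct / counts           # accuracy among top-k by Δ
    ok = accuracy >= confidence
    if not ok.any():
        warnings.warn("no Δ threshold reaches the requested confidence")
        return float("inf")
    if ok[-1]:
        return 0.0                               # whole pool already confident
    k = int(np.max(np.nonzero(ok)[0]))           # largest confident prefix
    return float(deltas[order[k]])


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------

@dataclass
class SeedFamily:
    """Sampled, genotyped seeds of one mother flower."""
    mother_flower_id: str
    mother_individual_id: str
    total_seed_count: int
    seed_ids: list[str]
    seed_genotypes: list[dict[str, Genotype]]
    mother_genotype: dict[str, Genotype]


def build_families(genotypes: GenotypeTable, flowers: Sequence[FlowerRecord],
                   min_loci: int = 5) -> list[SeedFamily]:
    """Group genotyped seeds by mother flower, dropping seeds typed at fewer
    than ``min_loci`` loci."""
    by_id = {f.flower_id: f for f in flowers}
    adults = genotypes.adults.set_index("sample_id")
    seeds = genotypes.seeds
    typed = genotypes.n_typed_loci(seeds)
    dropped = int((typed < min_loci).sum())
    if dropped:
        log.info("dropping %d seeds typed at < %d loci", dropped, min_loci)
    seeds = seeds.loc[typed >= min_loci]
    families = []
    for mother_id, fam in seeds.groupby("mother_flower_id", sort=True):
        flower = by_id[mother_id]
        mom_row = adults.loc[flower.individual_id]
        mother_gt = {loc: (int(mom_row[loc + "_1"]), int(mom_row[loc + "_2"]))
                     for loc in genotypes.loci}
        seed_gts = [
            {loc: (int(r[loc + "_1"]), int(r[loc + "_2"]))
             for loc in genotypes.loci}
            for _, r in fam.iterrows()]
        families.append(SeedFamily(
            mother_flower_id=mother_id,
            mother_individual_id=flower.individual_id,
            total_seed_count=flower.seed_count,
            seed_ids=fam["sample_id"].tolist(),
            seed_genotypes=seed_gts,
            mother_genotype=mother_gt))
    return families


def assign_paternity(family: SeedFamily, candidates: CandidateSet,
                     panel: LocusPanel, delta_star: float
                     ) -> tuple[pd.DataFrame, float]:
    """Assign each sampled seed of a family to its most likely sire flower.

    A seed is assigned iff its best LOD is finite, unique (LOD ties leave the
    seed unassigned) and exceeds the second-best by at least Δ*.  The family
    selfing rate is the fraction of *sampled* seeds assigned to a flower of
    the mother's own individual — unassigned seeds stay in the denominator.
    """
    rows = []
    n_self = 0
    for sid, gt in zip(family.seed_ids, family.seed_genotypes):
        if len(candidates) == 0:
            rows.append({"seed_id": sid, "mother_flower_id": family.mother_flower_id,
                         "sire_flower_id": "", "lod": np.nan, "delta": np.nan,
                         "assigned": False, "is_self": pd.NA})
            continue
        lods = lod_scores(gt, family.mother_genotype, candidates, panel)
        order = np.argsort(lods)[::-1]
        best = int(order[0])
        lod_best = float(lods[best])
        delta = float(lod_best - lods[order[1]]) if len(lods) > 1 else lod_best
        tied = len(lods) > 1 and abs(lods[order[1]] - lod_best) <= 1e-9
        assigned = (np.isfinite(lod_best) and not tied
                    and delta >= delta_star and np.isfinite(delta_star))
        is_self: object = pd.NA
        if assigned:
            is_self = candidates.individual_ids[best] == family.mother_individual_id
            n_self += bool(is_self)
        rows.append({"seed_id": sid,
                     "mother_flower_id": family.mother_flower_id,
                     "sire_flower_id": candidates.flower_ids[best] if assigned else "",
                     "lod": lod_best,
                     "delta": max(delta, 0.0) if np.isfinite(delta) else np.inf,
                     "assigned": bool(assigned),
                     "is_self": is_self})
    selfing_rate = n_self / len(family.seed_ids) if family.seed_ids else np.nan
    return pd.DataFrame(rows), float(selfing_rate)


def siring_success(assignments: pd.DataFrame,
                   families: Sequence[SeedFamily]) -> pd.Series:
    """Fractional whole-family seed credit per sire flower.

    For each family, a sire's credit is the family's total seed count times
    the sire's share of the genotyped sample; the unassigned share of the
    sample is credited to no one, so credits never exceed the family size.
    """
    credit: dict[str, float] = {}
    assigned = assignments[assignments["assigned"]]
    for fam in families:
        n_sampled = len(fam.seed_ids)
        if n_sampled == 0:
            warnings.warn(f"family {fam.mother_flower_id} has no sampled seeds")
            continue
        sub = assigned[assigned["mother_flower_id"] == fam.mother_flower_id]
        for sire, n in sub["sire_flower_id"].value_counts().items():
            credit[sire] = credit.get(sire, 0.0) + fam.total_seed_count * n / n_sampled
    return pd.Series(credit, dtype=float).sort_index()


def assignment_rate(n_assigned: int, n_genotyped: int) -> float:
    """Successful assignment rate, in percent."""
    if n_genotyped <= 0:
        raise ValueError("no genotyped seeds")
    return 100.0 * n_assigned / n_genotyped


# ---------------------------------------------------------------------------
# pipeline convenience
# ---------------------------------------------------------------------------

@dataclass
class PaternityResult:
    assignments: pd.DataFrame
    selfing_rates: pd.Series          # per mother flower
    siring: pd.Series                 # per sire flower
    delta_star: float
    n_genotyped: int
    n_assigned: int

    @property
    def rate_percent(self) -> float:
        return assignment_rate(self.n_assigned, self.n_genotyped)


def run_paternity(flowers: Sequence[FlowerRecord], genotypes: GenotypeTable,
                  census_days: Sequence[int], confidence: float = 0.80,
                  error: float = 0.018, min_loci: int = 5,
                  n_sim: int = 1000,
                  rng: Optional[np.random.Generator] = None) -> PaternityResult:
    """Full paternity stage: panel → Δ* calibration → per-family assignment.

    Δ* is calibrated once against the population-wide candidate pool (all
    flowers retaining stamens), then applied to every family with its own
    temporally filtered candidate list.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    panel = allele_frequencies(genotypes, error=error)
    pool_flowers = [f for f in flowers if f.stamen_count_effective > 0]
    pool = CandidateSet.build(pool_flowers, genotypes, panel)
    delta_star = critical_delta(panel, pool, confidence, n_sim, rng)
    log.info("critical Δ* = %.3f (confidence %.0f%%, %d candidates)",
             delta_star, 100 * confidence, len(pool))

    families = build_families(genotypes, flowers, min_loci=min_loci)
    by_id = {f.flower_id: f for f in flowers}
    pool_index = {fid: i for i, fid in enumerate(pool.flower_ids)}
    parts, selfing = [], {}
    for fam in families:
        focal = by_id[fam.mother_flower_id]
        cand_flowers = candidate_filter(focal, pool_flowers, census_days)
        cand = pool.subset([pool_index[f.flower_id] for f in cand_flowers])
        table, s = assign_paternity(fam, cand, panel, delta_star)
        parts.append(table)
        selfing[fam.mother_flower_id] = s
    assignments = (pd.concat(parts, ignore_index=True) if parts else
                   pd.DataFrame(columns=["seed_id", "mother_flower_id",
                                         "sire_flower_id", "lod", "delta",
                                         "assigned", "is_self"]))
    siring = siring_success(assignments, families)
    return PaternityResult(
        assignments=assignments,
        selfing_rates=pd.Series(selfing, dtype=float).sort_index(),
        siring=siring,
        delta_star=delta_star,
        n_genotyped=len(assignments),
        n_assigned=int(assignments["assigned"].sum()) if len(assignments) else 0)
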