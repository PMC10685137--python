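"""Paternity likelihoods, Δ-confidence, assignment and siring credit."""

import math

import numpy as np
import pandas as pd
import pytest

from conflictsex import SimulationConfig, simulate_season
from conflictsex.errors import MotherMismatchError
from conflictsex.genotypes import GenotypeTable
from conflictsex.paternity import (CandidateSet, LocusPanel, SeedFamily,
                                   allele_frequencies, assign_paternity,
                                   assignment_rate, build_families,
                                   candidate_filter, critical_delta,
                                   lod_score, lod_scores, run_paternity,
                                   siring_success, transition_probability)

from conftest import make_bisexual, make_male


def panel_from(freqs: dict, error: float = 0.0) -> LocusPanel:
    loci = list(freqs)
    return LocusPanel(
        loci=loci,
        alleles={loc: np.array(sorted(f)) for loc, f in freqs.items()},
        frequencies={loc: np.array([f[a] for a in sorted(f)])
                     for loc, f in freqs.items()},
        error=error)


def adult_table(genos: dict[str, dict[str, tuple]], loci) -> GenotypeTable:
    rows = []
    for ind, gt in genos.items():
        row = {"sample_id": ind, "role": "adult", "individual_id": ind,
               "mother_flower_id": ""}
        for loc in loci:
            row[loc + "_1"], row[loc + "_2"] = gt[loc]
        rows.append(row)
    return GenotypeTable(pd.DataFrame(rows), list(loci))


class TestAlleleFrequencies:
    def test_counting_estimator(self):
        gt = adult_table({"I1": {"L01": (1, 1)}, "I2": {"L01": (1, 2)},
                          "I3": {"L01": (2, 2)}}, ["L01"])
        panel = allele_frequencies(gt)
        assert panel.freq("L01", 1) == pytest.approx(0.5)

    def test_single_homozygote(self):
        gt = adult_table({"I1": {"L01": (1, 1)}}, ["L01"])
        assert allele_frequencies(gt).freq("L01", 1) == 1.0

    def test_binomial_consistency(self, rng):
        draws = rng.choice([1, 2], p=[0.3, 0.7], size=(10_000, 2))
        gt = adult_table({f"I{i}": {"L01": tuple(d)}
                          for i, d in enumerate(draws)}, ["L01"])
        assert allele_frequencies(gt).freq("L01", 1) == pytest.approx(0.30,
                                                                      abs=0.01)

    def test_all_missing_locus_dropped(self):
        gt = adult_table({"I1": {"L01": (1, 2), "L02": (0, 0)}},
                         ["L01", "L02"])
        with pytest.warns(UserWarning, match="L02"):
            panel = allele_frequencies(gt)
        assert panel.loci == ["L01"]

    def test_invalid_frequencies_rejected(self):
        with pytest.raises(ValueError):
            LocusPanel(["L01"], {"L01": np.array([1, 2])},
                       {"L01": np.array([0.6, 0.5])})


class TestTransitionProbability:
    def test_obligate_heterozygote(self):
        panel = panel_from({"L01": {1: 0.5, 2: 0.5}})
        assert transition_probability((1, 2), (1, 1), (2, 2), "L01",
                                      panel) == 1.0

    def test_exclusion_is_zero_at_no_error(self):
        panel = panel_from({"L01": {1: 0.5, 2: 0.5}})
        assert transition_probability((2, 2), (1, 1), (1, 1), "L01",
                                      panel) == 0.0

    def test_null_father_closed_form(self):
        panel = panel_from({"L01": {1: 0.3, 2: 0.7}})
        # mother AB, null father, offspring AA: 0.5 * freq(A)
        assert transition_probability((1, 1), (1, 2), None, "L01",
                                      panel) == pytest.approx(0.5 * 0.3)

    def test_missing_calls_contribute_one(self):
        panel = panel_from({"L01": {1: 0.5, 2: 0.5}})
        assert transition_probability(None, (1, 1), (1, 1), "L01", panel) == 1.0
        assert transition_probability((0, 0), (1, 1), (1, 1), "L01",
                                      panel) == 1.0

    def test_unknown_allele_raises(self):
        panel = panel_from({"L01": {1: 0.5, 2: 0.5}})
        with pytest.raises(KeyError):
            transition_probability((3, 3), (1, 2), None, "L01", panel)


class TestLodScore:
    def test_closed_form_single_locus(self):
        # mother AA, seed AA, candidate AA, freq(A) = 0.25 -> ln 4
        panel = panel_from({"L01": {1: 0.25, 2: 0.75}})
        lod = lod_score({"L01": (1, 1)}, {"L01": (1, 1)}, {"L01": (1, 1)},
                        panel)
        assert lod == pytest.approx(math.log(4))

    def test_candidate_missing_everywhere_scores_zero(self):
        panel = panel_from({"L01": {1: 0.25, 2: 0.75}})
        lod = lod_score({"L01": (1, 1)}, {"L01": (1, 1)}, {"L01": (0, 0)},
                        panel)
        assert lod == 0.0

    def test_excluded_candidate_scores_minus_infinity(self):
        panel = panel_from({"L01": {1: 0.5, 2: 0.5}})
        lod = lod_score({"L01": (2, 2)}, {"L01": (1, 2)}, {"L01": (1, 1)},
                        panel)
        assert lod == -math.inf

    def test_impossible_mother_raises(self):
        panel = panel_from({"L01": {1: 0.5, 2: 0.5}})
        with pytest.raises(MotherMismatchError):
            lod_score({"L01": (2, 2)}, {"L01": (1, 1)}, {"L01": (2, 2)}, panel)

    def test_additive_over_loci(self):
        freqs = {"L01": {1: 0.25, 2: 0.75}, "L02": {1: 0.4, 2: 0.6}}
        panel_both = panel_from(freqs, error=0.018)
        seed = {"L01": (1, 1), "L02": (1, 2)}
        mom = {"L01": (1, 2), "L02": (2, 2)}
        cand = {"L01": (1, 1), "L02": (1, 2)}
        total = lod_score(seed, mom, cand, panel_both)
        parts = sum(lod_score(seed, mom, cand,
                              panel_from({loc: freqs[loc]}, error=0.018))
                    for loc in freqs)
        assert total == pytest.approx(parts)

    def test_vectorized_scores_match_scalar(self, rng):
        freqs = {f"L{k:02d}": {1: 0.2, 2: 0.3, 3: 0.5} for k in range(1, 4)}
        panel = panel_from(freqs, error=0.018)
        cands = {}
        for i in range(6):
            cands[f"I{i}"] = {loc: tuple(rng.choice([1, 2, 3], 2))
                              for loc in panel.loci}
        table = adult_table(cands, panel.loci)
        flowers = [make_male(fid=f"C{i}", ind=f"I{i}") for i in range(6)]
        cset = CandidateSet.build(flowers, table, panel)
        seed = {loc: tuple(rng.choice([1, 2, 3], 2)) for loc in panel.loci}
        mom = {loc: (int(seed[loc][0]), int(rng.choice([1, 2, 3])))
               for loc in panel.loci}
        vec = lod_scores(seed, mom, cset, panel)
        for i in range(6):
            assert vec[i] == pytest.approx(
                lod_score(seed, mom, cands[f"I{i}"], panel))


class TestCandidateFilter:
    def test_overlap_on_census_grid_required(self):
        focal = make_bisexual(fid="D", ind="ID", opening=12, fem_len=3,
                              male_start=16)
        keep = make_male(fid="A", ind="IA", opening=10, dur=4)    # [10,14)
        days = [0, 4, 7, 11, 12, 14]
        out = candidate_filter(focal, [keep], days)
        assert [f.flower_id for f in out] == ["A"]

    def test_half_open_boundary_excludes(self):
        focal = make_bisexual(fid="D", ind="ID", opening=5, fem_len=4,
                              male_start=9)
        cand = make_male(fid="A", ind="IA", opening=0, dur=5)     # [0,5)
        out = candidate_filter(focal, [cand], list(range(0, 12)))
        assert out == []

    def test_full_removal_excluded_despite_overlap(self):
        focal = make_bisexual(fid="D", ind="ID", opening=0, fem_len=5)
        cand = make_bisexual(fid="A", ind="IA", opening=0, fem_len=1,
                             male_start=1, male_len=6, removal=1.0)
        out = candidate_filter(focal, [cand], [0, 3])
        assert out == []

    def test_own_individual_flowers_retained(self):
        focal = make_bisexual(fid="D", ind="ID", opening=0, fem_len=5)
        geiton = make_male(fid="G", ind="ID", opening=0, dur=5)
        out = candidate_filter(focal, [geiton], [0, 3])
        assert [f.flower_id for f in out] == ["G"]


class TestCriticalDelta:
    def test_single_candidate_warns_and_returns_zero(self, rng):
        panel = panel_from({"L01": {1: 0.5, 2: 0.5}}, error=0.01)
        table = adult_table({"I0": {"L01": (1, 2)}}, ["L01"])
        cset = CandidateSet.build([make_male(fid="C0", ind="I0")], table, panel)
        with pytest.warns(UserWarning):
            assert critical_delta(panel, cset, 0.8, 1000, rng) == 0.0

    def test_private_alleles_need_no_threshold(self, rng):
        # every candidate homozygous for its own allele: fully distinguishable
        n = 4
        freqs = {"L01": {i + 1: 1.0 / n for i in range(n)}}
        panel = panel_from(freqs, error=0.0)
        table = adult_table({f"I{i}": {"L01": (i + 1, i + 1)}
                             for i in range(n)}, ["L01"])
        flowers = [make_male(fid=f"C{i}", ind=f"I{i}") for i in range(n)]
        cset = CandidateSet.build(flowers, table, panel)
        assert critical_delta(panel, cset, 0.8, 1000, rng) == 0.0

    def test_invalid_arguments(self, rng):
        panel = panel_from({"L01": {1: 0.5, 2: 0.5}})
        cset = CandidateSet.build([], adult_table({}, ["L01"]) if False else
                                  adult_table({"I0": {"L01": (1, 1)}},
                                              ["L01"]), panel)
        with pytest.raises(ValueError):
            critical_delta(panel, cset, 1.2, 1000, rng)
        with pytest.raises(ValueError):
            critical_delta(panel, cset, 0.8, 10, rng)

    def test_self_consistent_confidence(self, rng):
        """Δ* calibrated at 80% yields >= 80% correct assignments on an
        independent simulation from the same pool."""
        n_cand, n_loci = 20, 10
        loci = [f"L{k:02d}" for k in range(n_loci)]
        freqs = {loc: {a: 0.2 for a in range(1, 6)} for loc in loci}
        panel = panel_from(freqs, error=0.018)
        genos = {f"I{i}": {loc: tuple(rng.choice(range(1, 6), 2))
                           for loc in loci} for i in range(n_cand)}
        table = adult_table(genos, loci)
        flowers = [make_male(fid=f"C{i}", ind=f"I{i}") for i in range(n_cand)]
        cset = CandidateSet.build(flowers, table, panel)
        dstar = critical_delta(panel, cset, 0.80, 2000, rng)
        # independent simulation
        correct = total = 0
        for _ in range(500):
            true = int(rng.integers(n_cand))
            mom = {loc: tuple(rng.choice(range(1, 6), 2)) for loc in loci}
            seed = {}
            for loc in loci:
                pat = genos[f"I{true}"][loc][rng.integers(2)]
                child = (mom[loc][rng.integers(2)], pat)
                if rng.random() < 0.018:
                    child = tuple(rng.choice(range(1, 6), 2))
                seed[loc] = child
            lods = lod_scores(seed, mom, cset, panel)
            order = np.argsort(lods)[::-1]
            delta = lods[order[0]] - lods[order[1]]
            if delta >= dstar and delta > 0:
                total += 1
                correct += order[0] == true
        assert total > 0
        assert correct / total >= 0.80


def exclusion_oracle(seed, mom, candidates_gts, loci):
    """Exhaustive Mendelian exclusion analysis at zero genotyping error:
    a candidate is compatible iff at every locus some (maternal, paternal)
    gamete pair produces the seed genotype."""
    def compatible(cand):
        for loc in loci:
            x, y = seed[loc]
            ok = False
            for mg in mom[loc]:
                for pg in cand[loc]:
                    if {mg, pg} == {x, y} or (x == y and mg == x and pg == x):
                        ok = True
            if not ok:
                return False
        return True
    return [i for i, c in enumerate(candidates_gts) if compatible(c)]


def run_exclusion_oracle_check(rng, n_reps=40):
    """Shared check: at zero error with few candidates and loci, LOD
    assignment equals exhaustive exclusion analysis whenever exclusion is
    decisive, and never contradicts it otherwise."""
    loci = ["L01", "L02", "L03"]
    for rep in range(n_reps):
        n_cand = int(rng.integers(2, 6))
        freqs = {loc: {1: 0.25, 2: 0.25, 3: 0.25, 4: 0.25} for loc in loci}
        panel = panel_from(freqs, error=0.0)
        genos = {f"I{i}": {loc: tuple(rng.choice(range(1, 5), 2))
                           for loc in loci} for i in range(n_cand)}
        table = adult_table(genos, loci)
        flowers = [make_male(fid=f"C{i}", ind=f"I{i}")
                   for i in range(n_cand)]
        cset = CandidateSet.build(flowers, table, panel)
        mom = {loc: tuple(rng.choice(range(1, 5), 2)) for loc in loci}
        true = int(rng.integers(n_cand))
        seed = {loc: (mom[loc][rng.integers(2)],
                      genos[f"I{true}"][loc][rng.integers(2)])
                for loc in loci}
        fam = SeedFamily(mother_flower_id="D", mother_individual_id="ID",
                         total_seed_count=10, seed_ids=["S0"],
                         seed_genotypes=[seed], mother_genotype=mom)
        result, _ = assign_paternity(fam, cset, panel, delta_star=0.0)
        row = result.iloc[0]
        compat = exclusion_oracle(seed, mom,
                                  [genos[f"I{i}"] for i in range(n_cand)],
                                  loci)
        assert true in compat
        if len(compat) == 1:
            assert row["assigned"]
            assert row["sire_flower_id"] == f"C{compat[0]}"
        if row["assigned"]:
            assert int(row["sire_flower_id"][1:]) in compat


class TestAssignment:
    def _family(self, seeds, mom_gt, mother="D", ind="ID", total=10):
        return SeedFamily(mother_flower_id=mother, mother_individual_id=ind,
                          total_seed_count=total,
                          seed_ids=[f"S{i}" for i in range(len(seeds))],
                          seed_genotypes=seeds, mother_genotype=mom_gt)

    def test_matches_exclusion_oracle_on_small_fixtures(self, rng):
        run_exclusion_oracle_check(rng)

    def test_all_selfed_sample_gives_selfing_rate_one(self):
        panel = panel_from({"L01": {1: 0.5, 2: 0.5}}, error=0.0)
        mom = {"L01": (1, 1)}
        table = adult_table({"ID": {"L01": (1, 1)}, "IX": {"L01": (2, 2)}},
                            ["L01"])
        flowers = [make_male(fid="SELF", ind="ID"),
                   make_male(fid="OTHER", ind="IX")]
        cset = CandidateSet.build(flowers, table, panel)
        seeds = [{"L01": (1, 1)} for _ in range(4)]  # only ID-compatible
        fam = self._family(seeds, mom)
        result, selfing = assign_paternity(fam, cset, panel, delta_star=0.0)
        assert selfing == 1.0
        assert result["is_self"].all()

    def test_zero_selfing_weight_season_has_no_selfed_assignments(self):
        season = simulate_season(SimulationConfig(
            selfing_weight=0.0, genotyping_error=0.0, missing_rate=0.0,
            n_individuals=60, rng_seed=21))
        res = run_paternity(season.flowers, season.genotypes,
                            season.census_days, error=0.0,
                            rng=np.random.default_rng(3))
        assert (res.selfing_rates == 0.0).all()

    def test_tied_lods_leave_seed_unassigned(self):
        panel = panel_from({"L01": {1: 0.5, 2: 0.5}}, error=0.0)
        table = adult_table({"IA": {"L01": (1, 1)}, "IB": {"L01": (1, 1)}},
                            ["L01"])
        flowers = [make_male(fid="A", ind="IA"), make_male(fid="B", ind="IB")]
        cset = CandidateSet.build(flowers, table, panel)
        fam = self._family([{"L01": (1, 1)}], {"L01": (1, 1)})
        result, _ = assign_paternity(fam, cset, panel, delta_star=0.0)
        assert not result.iloc[0]["assigned"]

    def test_no_candidates_leaves_all_unassigned(self):
        panel = panel_from({"L01": {1: 0.5, 2: 0.5}})
        empty = CandidateSet([], [], {"L01": np.array([], int)},
                             {"L01": np.array([], int)})
        fam = self._family([{"L01": (1, 2)}], {"L01": (1, 1)})
        result, selfing = assign_paternity(fam, empty, panel, delta_star=0.0)
        assert not result["assigned"].any()
        assert selfing == 0.0

    def test_low_coverage_seeds_dropped_before_assignment(self, default_season):
        gt = default_season.genotypes
        # blank out all but 4 loci of the first seed
        df = gt.data.copy()
        seed_idx = df.index[df["role"] == "seed"][0]
        sid = df.loc[seed_idx, "sample_id"]
        for loc in gt.loci[4:]:
            df.loc[seed_idx, [loc + "_1", loc + "_2"]] = 0
        gt2 = GenotypeTable(df, gt.loci)
        fams = build_families(gt2, default_season.flowers, min_loci=5)
        all_ids = {s for f in fams for s in f.seed_ids}
        assert sid not in all_ids


class TestSiringSuccess:
    def _fam(self, mother, total, n_sampled):
        return SeedFamily(mother, "I" + mother, total,
                          [f"{mother}s{i}" for i in range(n_sampled)],
                          [{} for _ in range(n_sampled)], {})

    def _assign_df(self, rows):
        return pd.DataFrame(rows, columns=["seed_id", "mother_flower_id",
                                           "sire_flower_id", "lod", "delta",
                                           "assigned", "is_self"])

    def test_fractional_expansion(self):
        fam = self._fam("D", total=50, n_sampled=10)
        rows = [(f"Ds{i}", "D", "A", 1.0, 1.0, True, False) for i in range(4)]
        rows += [(f"Ds{i}", "D", "", np.nan, np.nan, False, pd.NA)
                 for i in range(4, 10)]
        credit = siring_success(self._assign_df(rows), [fam])
        assert credit["A"] == pytest.approx(20.0)

    def test_single_sire_gets_whole_family(self):
        fam = self._fam("D", total=30, n_sampled=5)
        rows = [(f"Ds{i}", "D", "A", 1.0, 1.0, True, False) for i in range(5)]
        credit = siring_success(self._assign_df(rows), [fam])
        assert credit["A"] == pytest.approx(30.0)

    def test_split_credit_conserves_family_size(self):
        fam = self._fam("D", total=30, n_sampled=10)
        rows = [(f"Ds{i}", "D", "A", 1.0, 1.0, True, False) for i in range(5)]
        rows += [(f"Ds{i}", "D", "B", 1.0, 1.0, True, False)
                 for i in range(5, 10)]
        credit = siring_success(self._assign_df(rows), [fam])
        assert credit["A"] == credit["B"] == pytest.approx(15.0)
        assert credit.sum() == pytest.approx(30.0)

    def test_empty_family_warns(self):
        fam = self._fam("D", total=10, n_sampled=0)
        with pytest.warns(UserWarning, match="no sampled seeds"):
            credit = siring_success(self._assign_df([]), [fam])
        assert credit.sum() == 0.0


class TestRates:
    def test_assignment_rate_percent(self):
        assert assignment_rate(3, 4) == pytest.approx(75.0)
        with pytest.raises(ValueError):
            assignment_rate(0, 0)

    def test_unique_sire_recovered_at_zero_error(self):
        """With error-free genotypes, assignments agree with pedigree truth
        whenever the sire individual is genotypically unique."""
        season = simulate_season(SimulationConfig(
            genotyping_error=0.0, missing_rate=0.0, n_individuals=60,
            rng_seed=8))
        res = run_paternity(season.flowers, season.genotypes,
                            season.census_days, error=0.0,
                            rng=np.random.default_rng(5))
        truth = season.pedigree.set_index("seed_id")["sire_flower_id"]
        by_id = {f.flower_id: f.individual_id for f in season.flowers}
        assigned = res.assignments[res.assignments["assigned"]]
        agree = (assigned.set_index("seed_id")["sire_flower_id"].map(by_id)
                 == truth.loc[assigned["seed_id"]].map(by_id))
        assert agree.all()
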