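"""End-to-end orchestration: simulate → phenology → paternity → fitness →
selection → report, with one config, stage logging and a JSON results bundle.

The config file is YAML with up to four sections::

    simulation: { ... SimulationConfig fields ... }
    paternity:  { confidence: 0.80, error: 0.018, min_loci: 5,
                  max_seeds_per_family: 10, n_sim: 1000 }
    fitness:    { delta: 0.93 }
    seed: 1

A run writes ``flowers.csv``, ``censuses.csv``, ``pedigree.csv``,
``genotypes.csv``, ``availability.csv``, ``assignments.csv``, ``selfing.csv``,
``siring.csv``, ``fitness.csv``, ``gradients.csv``, ``report.json``, a
``manifest.json`` (config + seed + file digests) and ``run.log``.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fitness as fitness_mod
from . import io, paternity, phenology, selection
from .errors import ConfigurationError
from .simulate import SimulationConfig, simulate_season

log = logging.getLogger(__name__)

PATERNITY_DEFAULTS = {"confidence": 0.80, "error": 0.018, "min_loci": 5,
                      "max_seeds_per_family": 10, "n_sim": 1000}
FITNESS_DEFAULTS = {"delta": 0.93}


@dataclass
class PipelineConfig:
    simulation: SimulationConfig
    paternity: dict = field(default_factory=lambda: dict(PATERNITY_DEFAULTS))
    fitness: dict = field(default_factory=lambda: dict(FITNESS_DEFAULTS))
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - {"simulation", "paternity", "fitness", "seed"}
        if unknown:
            raise ConfigurationError(f"unknown config sections: {sorted(unknown)}")
        pat = dict(PATERNITY_DEFAULTS)
        pat.update(d.get("paternity", {}))
        fit = dict(FITNESS_DEFAULTS)
        fit.update(d.get("fitness", {}))
        sim = d.get("simulation", {})
        seed = int(d.get("seed", 0))
        sim = dict(sim)
        sim.setdefault("rng_seed", seed)
        return cls(simulation=SimulationConfig.from_dict(sim),
                   paternity=pat, fitness=fit, seed=seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_all(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage and write the results bundle; returns the report dict.

    A stage failure raises with the failing stage named; outputs of completed
    stages are left on disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("conflictsex")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    stage = "simulate"
    try:
        season = simulate_season(config.simulation,
                                 config.paternity["max_seeds_per_family"])
        flowers, census_days = season.flowers, season.census_days
        io.write_flowers(flowers, outdir / "flowers.csv")
        io.write_censuses(flowers, census_days, outdir / "censuses.csv")
        io.write_pedigree(season.pedigree, outdir / "pedigree.csv")
        season.genotypes.write_csv(outdir / "genotypes.csv")
        log.info("simulate: %d flowers, %d seeds in pedigree, %d genotyped",
                 len(flowers), len(season.pedigree), len(season.genotypes.seeds))

        stage = "phenology"
        avail = pd.concat([phenology.census_counts(flowers, census_days, s)
                           for s in phenology.SCENARIOS], ignore_index=True)
        avail.to_csv(outdir / "availability.csv", index=False)
        delays = phenology.male_onset_delay(
            [f for f in flowers if f.sex_class == "bisexual"])
        delay_fit = phenology.delay_regression(delays)
        durations = phenology.duration_summary(flowers)
        log.info("phenology: delay slope %.3f ± %.3f per 100 pistils",
                 delay_fit["slope"], delay_fit["se"])

        stage = "paternity"
        pat_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 1]).generate_state(1)[0])
        pat = paternity.run_paternity(
            flowers, season.genotypes, census_days,
            confidence=config.paternity["confidence"],
            error=config.paternity["error"],
            min_loci=config.paternity["min_loci"],
            n_sim=config.paternity["n_sim"], rng=pat_rng)
        pat.assignments.to_csv(outdir / "assignments.csv", index=False)
        pat.selfing_rates.rename("selfing_rate").to_csv(
            outdir / "selfing.csv", index_label="mother_flower_id")
        pat.siring.rename("seeds_sired").to_csv(
            outdir / "siring.csv", index_label="sire_flower_id")
        log.info("paternity: %d/%d seeds assigned (%.1f%%), Δ* = %.2f",
                 pat.n_assigned, pat.n_genotyped,
                 pat.rate_percent if pat.n_genotyped else float("nan"),
                 pat.delta_star)

        stage = "fitness"
        fit_table = fitness_mod.fitness_table(
            flowers, pat.selfing_rates, pat.siring,
            delta=config.fitness["delta"])
        included = fitness_mod.inclusion_set(flowers)
        include_ids = [f.flower_id for f in included]
        rel = fitness_mod.relativize(fit_table, include_ids)
        rel.to_csv(outdir / "fitness.csv", index=False)
        log.info("fitness: %d flowers in the inclusion set", len(include_ids))

        stage = "selection"
        raw_traits = selection.trait_frame(included)
        traits = selection.standardize(raw_traits)
        sexfit = selection.fit_sex_specific(traits, rel)
        gradients = sexfit.gradient_table()
        regimes = selection.regime_table(gradients, traits)
        combined = selection.fit_combined(
            traits, (rel.set_index("flower_id")["relW_female"]
                     + rel.set_index("flower_id")["relW_male"]))
        combined_regimes = selection.combined_regime_table(combined, traits)
        out_grad = gradients.merge(regimes, on="trait")
        out_grad.to_csv(outdir / "gradients.csv", index=False)
        combined.merge(combined_regimes, on="trait").to_csv(
            outdir / "gradients_combined.csv", index=False)

        stage = "report"
        report = {
            "counts": {
                "flowers": len(flowers),
                "bisexual": sum(f.sex_class == "bisexual" for f in flowers),
                "male": sum(f.sex_class == "male" for f in flowers),
                "seeds_total": int(sum(f.seed_count for f in flowers)),
                "seeds_genotyped": pat.n_genotyped,
                "seeds_assigned": pat.n_assigned,
                "inclusion_set": len(include_ids),
            },
            "paternity": {
                "assignment_rate_percent": (round(pat.rate_percent, 1)
                                            if pat.n_genotyped else None),
                "delta_star": pat.delta_star,
                "mean_selfing_rate": (float(pat.selfing_rates.mean())
                                      if len(pat.selfing_rates) else None),
                "selfing_rates": {k: float(v)
                                  for k, v in pat.selfing_rates.items()},
            },
            "phenology": {
                "delay_regression": delay_fit,
                "durations": durations,
                "availability_summary": {
                    f"scenario_{s}": _availability_summary(avail, s)
                    for s in phenology.SCENARIOS},
            },
            "selection": {
                "gradients": gradients.to_dict(orient="records"),
                "regimes": regimes.to_dict(orient="records"),
                "combined": combined.to_dict(orient="records"),
                "combined_regimes": combined_regimes.to_dict(orient="records"),
                "variance_components": {
                    "sigma2_F": sexfit.sigma2_F, "sigma2_M": sexfit.sigma2_M,
                    "tau2": sexfit.tau2},
            },
        }
        io.write_json(report, outdir / "report.json")

        manifest = {
            "config": {"simulation": config.simulation.to_dict(),
                       "paternity": config.paternity,
                       "fitness": config.fitness, "seed": config.seed},
            "outputs": {p.name: _digest(p) for p in sorted(outdir.iterdir())
                        if p.suffix == ".csv" or p.name == "report.json"},
        }
        io.write_json(manifest, outdir / "manifest.json")
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()


def _availability_summary(avail: pd.DataFrame, scenario: int) -> dict:
    sub = avail[avail["scenario"] == scenario]
    defined = sub.dropna(subset=["availability"])
    if defined.empty:
        return {"peak_day": None, "peak_availability": None, "mean": None}
    peak = defined.loc[defined["availability"].idxmax()]
    return {"peak_day": int(peak["day"]),
            "peak_availability": float(peak["availability"]),
            "mean": float(defined["availability"].mean())}


_STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"), (0.1, "."))


def significance_stars(p: float) -> str:
    for level, mark in _STAR_LEVELS:
        if p < level:
            return mark
    return ""


def make_table1(gradients: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Format a sex-specific gradient table in the published layout:
    one row per trait × term, estimates with SEs and significance stars,
    interaction stars, SAS and SA rounded to ``decimals`` (half-even)."""
    required = {"trait", "term", "est_F", "se_F", "p_F", "est_M", "se_M",
                "p_M", "p_interaction", "SAS", "SA"}
    missing = required - set(gradients.columns)
    if missing:
        raise ValueError(f"gradient table missing columns: {sorted(missing)}")
    traits = gradients["trait"].unique()
    for t in traits:
        terms = set(gradients.loc[gradients["trait"] == t, "term"])
        if terms != {"beta", "gamma"}:
            raise ValueError(f"trait {t!r} missing a beta or gamma row")

    def cell(est, se, p):
        return (f"{round(float(est), decimals):.{decimals}f} "
                f"({round(float(se), decimals):.{decimals}f})"
                f"{significance_stars(p)}")

    rows = []
    for _, r in gradients.iterrows():
        rows.append({
            "trait": r["trait"],
            "term": "beta" if r["term"] == "beta" else "gamma_ii",
            "female function (s.e.)": cell(r["est_F"], r["se_F"], r["p_F"]),
            "male function (s.e.)": cell(r["est_M"], r["se_M"], r["p_M"]),
            "interaction": significance_stars(r["p_interaction"]),
            "SAS": round(float(r["SAS"]), decimals),
            "SA Index": round(float(r["SA"]), decimals),
        })
    return pd.DataFrame(rows)
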