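"""Diploid microsatellite genotype tables (GenAlEx-like CSV dialect).

Storage is a flat table with two integer allele columns per locus
(``L01_1, L01_2, ...``); allele 0 codes a missing call.  Adults carry one
multilocus genotype per *individual* (all flowers of an individual share it);
seed rows record the mother flower so families can be reconstructed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

ADULT = "adult"
SEED = "seed"

_META_COLS = ["sample_id", "role", "individual_id", "mother_flower_id"]


@dataclass
class GenotypeTable:
    """Genotypes for adults (per individual) and sampled seeds.

    ``data`` columns: the four metadata columns followed by two allele
    columns per locus.  ``true_frequencies`` optionally carries the
    generating allele frequencies when the table came from the simulator
    (handy for recovery tests; never used by the estimators).
    """

    data: pd.DataFrame
    loci: list[str]
    true_frequencies: Optional[dict[str, np.ndarray]] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        for c in _META_COLS:
            if c not in self.data.columns:
                raise ValueError(f"genotype table missing column {c!r}")
        for locus in self.loci:
            for suffix in ("_1", "_2"):
                if locus + suffix not in self.data.columns:
                    raise ValueError(f"missing allele column {locus + suffix!r}")

    # -- accessors ---------------------------------------------------------
    @property
    def adults(self) -> pd.DataFrame:
        return self.data[self.data["role"] == ADULT]

    @property
    def seeds(self) -> pd.DataFrame:
        return self.data[self.data["role"] == SEED]

    def alleles_at(self, locus: str, rows: Optional[pd.DataFrame] = None) -> tuple[np.ndarray, np.ndarray]:
        df = self.data if rows is None else rows
        return df[locus + "_1"].to_numpy(int), df[locus + "_2"].to_numpy(int)

    def genotype_of(self, sample_id: str) -> dict[str, tuple[int, int]]:
        row = self.data.loc[self.data["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(f"no sample {sample_id!r}")
        r = row.iloc[0]
        return {loc: (int(r[loc + "_1"]), int(r[loc + "_2"])) for loc in self.loci}

    def n_typed_loci(self, rows: Optional[pd.DataFrame] = None) -> np.ndarray:
        """Number of non-missing loci per sample (a call is missing if either
        allele is 0)."""
        df = self.data if rows is None else rows
        typed = np.zeros(len(df), dtype=int)
        for loc in self.loci:
            a1 = df[loc + "_1"].to_numpy(int)
            a2 = df[loc + "_2"].to_numpy(int)
            typed += ((a1 > 0) & (a2 > 0)).astype(int)
        return typed

    # -- I/O ---------------------------------------------------------------
    def write_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "GenotypeTable":
        df = pd.read_csv(path, dtype={"sample_id": str, "individual_id": str,
                                      "mother_flower_id": str})
        loci = sorted({c[:-2] for c in df.columns if c.endswith("_1")
                       and c[:-2] + "_2" in df.columns})
        for loc in loci:
            df[loc + "_1"] = df[loc + "_1"].fillna(0).astype(int)
            df[loc + "_2"] = df[loc + "_2"].fillna(0).astype(int)
        if "role" not in df.columns:
            # plain two-column-per-locus files without roles: treat as adults
            df["role"] = ADULT
        for c in ("individual_id", "mother_flower_id"):
            if c not in df.columns:
                df[c] = ""
        df["mother_flower_id"] = df["mother_flower_id"].fillna("")
        df["individual_id"] = df["individual_id"].fillna("")
        return cls(df[_META_COLS + [loc + s for loc in loci for s in ("_1", "_2")]],
                   loci)
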