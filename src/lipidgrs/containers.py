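"""In-memory containers: genotype matrix, cohort table, score results.

Both main containers are thin wrappers over pandas DataFrames that enforce
the closed vocabularies and coding rules the analysis relies on, so that
validation happens once at construction instead of inside every operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .traits import ARMS, ETHNICITIES, TRAIT_NAMES, baseline_col, year1_col

MISSING = np.nan  # missing genotype marker on the 0/1/2 count scale


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs allele-count codes.

    calls: float DataFrame, index = individual ids, columns = rsIDs, values
      in {0, 1, 2} with NaN for missing.  Each column counts copies of that
      SNP's *counted allele* (``counted_allele[rsid]``); orientation to risk
      alleles is a separate, explicit step.
    alleles: rsid -> (allele_a, allele_b) labels.
    """

    calls: pd.DataFrame
    alleles: Dict[str, Tuple[str, str]]
    counted_allele: Dict[str, str]

    def __post_init__(self):
        if self.calls.index.duplicated().any():
            raise ValueError("duplicate individual ids in genotype matrix")
        if self.calls.columns.duplicated().any():
            raise ValueError("duplicate rsIDs in genotype matrix")
        vals = self.calls.to_numpy(dtype=float)
        bad = ~(np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0)))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype code {vals[i, j]!r} for individual "
                f"{self.calls.index[i]!r} at {self.calls.columns[j]!r}"
            )
        # allele pairs are unordered; store sorted so round-trips through
        # formats that impose an order (VCF REF/ALT) compare equal
        self.alleles = {
            r: tuple(sorted(pair)) for r, pair in self.alleles.items()
        }
        for rsid in self.calls.columns:
            if rsid not in self.alleles:
                raise ValueError(f"no allele labels for {rsid}")
            if rsid not in self.counted_allele:
                raise ValueError(f"no counted allele declared for {rsid}")
            if self.counted_allele[rsid] not in self.alleles[rsid]:
                raise ValueError(
                    f"{rsid}: counted allele {self.counted_allele[rsid]!r} "
                    f"not among alleles {self.alleles[rsid]}"
                )

    @property
    def ids(self):
        return list(self.calls.index)

    @property
    def rsids(self):
        return list(self.calls.columns)

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    def call_rate(self) -> pd.Series:
        """Fraction of non-missing calls per SNP."""
        return self.calls.notna().mean(axis=0)

    def subset(self, ids=None, rsids=None) -> "GenotypeMatrix":
        calls = self.calls
        if ids is not None:
            calls = calls.loc[list(ids)]
        if rsids is not None:
            calls = calls[list(rsids)]
        keep = set(calls.columns)
        return GenotypeMatrix(
            calls=calls.copy(),
            alleles={r: a for r, a in self.alleles.items() if r in keep},
            counted_allele={
                r: a for r, a in self.counted_allele.items() if r in keep
            },
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.calls.equals(other.calls)
            and self.alleles == other.alleles
            and self.counted_allele == other.counted_allele
        )


_SEXES = ("F", "M")

_META_COLS = {"age", "sex", "ethnicity", "bmi", "arm", "lipid_med"}


@dataclass
class CohortTable:
    """Per-individual covariates, arm assignment, flags, and trait values.

    data: DataFrame indexed by individual id.  Required columns: age, sex
    ("M"/"F"), ethnicity, bmi, arm, lipid_med (bool).  Trait values live in
    ``<trait>_bl`` / ``<trait>_y1`` columns in native units; any subset of
    traits may be present.
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        if df.index.duplicated().any():
            raise ValueError("duplicate individual ids in cohort table")
        missing = _META_COLS - set(df.columns)
        if missing:
            raise ValueError(f"cohort table missing columns {sorted(missing)}")
        bad_eth = set(df["ethnicity"].dropna()) - set(ETHNICITIES)
        if bad_eth:
            raise ValueError(f"unknown ethnicity labels {sorted(bad_eth)}")
        bad_arm = set(df["arm"].dropna()) - set(ARMS)
        if bad_arm:
            raise ValueError(f"unknown arm labels {sorted(bad_arm)}")
        bad_sex = set(df["sex"].dropna()) - set(_SEXES)
        if bad_sex:
            raise ValueError(f"unknown sex labels {sorted(bad_sex)}")
        for col in self.trait_columns():
            vals = df[col].dropna()
            if (vals <= 0).any():
                offender = vals[vals <= 0].index[0]
                raise ValueError(
                    f"non-positive trait value in {col} for id {offender!r}"
                )

    def trait_columns(self):
        cols = []
        for t in TRAIT_NAMES:
            for c in (baseline_col(t), year1_col(t)):
                if c in self.data.columns:
                    cols.append(c)
        return cols

    @property
    def ids(self):
        return list(self.data.index)

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, ids) -> "CohortTable":
        return CohortTable(self.data.loc[list(ids)].copy())

    def equals(self, other: "CohortTable") -> bool:
        return self.data.equals(other.data)


@dataclass
class ScoreResult:
    """Per-individual genetic risk score with labelling and fill record.

    scores: DataFrame indexed by id with columns grs, n_imputed, and (after
    labelling) quartile ("Q1".."Q4") and median_split ("low"/"high").
    fill_values: (rsid, ethnicity) -> integer fill in {0,1,2} used for
    imputation (empty when nothing was missing).
    """

    scores: pd.DataFrame
    fill_values: Dict[Tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self):
        for (rsid, eth), v in self.fill_values.items():
            if v not in (0, 1, 2):
                raise ValueError(
                    f"fill value {v!r} for ({rsid}, {eth}) outside {{0,1,2}}"
                )

    @property
    def grs(self) -> pd.Series:
        return self.scores["grs"]
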