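"""Baseline association stage: trait transforms, single-SNP tests, score
association, quartile summaries, and familywise error control.

Analysis conventions (all of them configurable only where noted):

* every trait is analysed as its natural log except LDL-C, analysed raw;
* single-SNP tests use the measured-genotype approach — the additive test
  codes genotype as a 0/1/2 risk-allele count in a multiple regression,
  and the general test treats genotype as a 3-level factor assessed by a
  2-df extra-sum-of-squares F test against the covariate-only model;
* baseline models adjust for age, sex, self-reported ethnicity and BMI,
  with ethnicity as fixed-effect indicators;
* the multiple-testing threshold is Bonferroni over the full SNP x trait
  grid (for 32 SNPs and 14 traits: 448 tests, 0.05/448 ~ 1e-4);
* a SNP "replicates" for its source trait when the additive p is at most
  0.05 and the risk-allele effect has the expected sign (up for TG and
  LDL-C, down for HDL-C).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._util import pct_diff, round_half_away
from .containers import CohortTable, GenotypeMatrix
from .panel import RiskTable
from .regress import AdjustedMeans, build_design, fit_ols, ls_means, nested_f_test, partial_r
from .traits import LN, RAW, TRAIT_NAMES, baseline_col, trait_scale

#: covariates of every baseline model
BASELINE_COVARIATES = ("age", "sex", "ethnicity", "bmi")

_NUMERIC = ["age", "bmi"]
_FACTORS = ["sex", "ethnicity"]


# ---------------------------------------------------------------------------
# Trait transformation
# ---------------------------------------------------------------------------

def transform_trait(values: pd.Series, trait: str) -> Tuple[pd.Series, str]:
    """Put trait values on their analysis scale.

    Natural log for every trait except LDL-C (returned unchanged with tag
    "raw").  A non-positive value in a log-transformed trait is an error
    naming the individual, since it signals corrupted input rather than a
    legitimate measurement.
    """
    scale = trait_scale(trait)
    if scale == RAW:
        return values.astype(float), RAW
    bad = values.dropna() <= 0
    if bad.any():
        who = bad[bad].index[0]
        raise ValueError(
            f"non-positive value for ln-transformed trait {trait!r} "
            f"(individual {who!r})"
        )
    return np.log(values.astype(float)), LN


# ---------------------------------------------------------------------------
# Results containers
# ---------------------------------------------------------------------------

@dataclass
class AssociationResult:
    """One predictor-trait association on the trait's analysis scale."""

    trait: str
    predictor: str          # rsID or "grs"
    scale: str              # "raw" or "ln"
    beta: float             # per risk allele
    se: float
    t: float
    p_additive: float
    p_general: Optional[float]   # 2-df F p; None when skipped
    general_skipped: bool
    partial_r: float
    n: int
    covariates: Tuple[str, ...] = BASELINE_COVARIATES

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        d["covariates"] = list(self.covariates)
        return d


@dataclass
class QuartileSummary:
    """Adjusted means by score quartile plus the Q4-vs-Q1 percent difference
    (integer magnitude, direction read from the means)."""

    trait: str
    scale: str
    means: AdjustedMeans
    pct_diff_q4_vs_q1: int
    n_per_quartile: Dict[str, int]


@dataclass
class BonferroniResult:
    n_tests: int
    threshold: float              # alpha / m, full precision
    threshold_presentation: float  # rounded to one significant figure
    alpha: float
    significant: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# Model machinery
# ---------------------------------------------------------------------------

def _analysis_frame(
    cohort: CohortTable, trait: str, extra: Optional[pd.Series] = None
) -> Tuple[pd.DataFrame, str]:
    """Complete-case frame with the transformed response in column ``_y``."""
    col = baseline_col(trait)
    if col not in cohort.data.columns:
        raise ValueError(f"cohort has no baseline values for trait {trait!r}")
    df = cohort.data[["age", "sex", "ethnicity", "bmi", col]].copy()
    y, scale = transform_trait(df.pop(col), trait)
    df["_y"] = y
    if extra is not None:
        df["_x"] = extra.reindex(df.index)
    return df.dropna(), scale


def snp_tests(
    genotype: pd.Series, cohort: CohortTable, trait: str
) -> AssociationResult:
    """Additive and general (2-df) tests of one SNP against one trait.

    `genotype` must be risk-allele counts (0/1/2, NaN missing); missing
    calls are dropped here — mean imputation is a score-construction device,
    not part of single-SNP testing.  The general test needs all three
    genotype groups; with fewer it is skipped (flagged) and the additive
    test still runs.  Monomorphic SNPs are an error.
    """
    df, scale = _analysis_frame(cohort, trait, extra=genotype)
    groups = sorted(df["_x"].unique())
    if len(groups) < 2:
        raise ValueError(
            f"monomorphic genotype for {genotype.name!r}: no association test"
        )
    X_cov = build_design(df, numeric=_NUMERIC, factors=_FACTORS)
    X_add = X_cov.copy()
    X_add["genotype"] = df["_x"].to_numpy(dtype=float)
    fit_add = fit_ols(X_add, df["_y"])

    p_general, skipped = None, True
    if len(groups) == 3:
        X_gen = X_cov.copy()
        X_gen["geno[1]"] = (df["_x"] == 1).astype(float)
        X_gen["geno[2]"] = (df["_x"] == 2).astype(float)
        fit_gen = fit_ols(X_gen, df["_y"])
        fit_red = fit_ols(X_cov, df["_y"])
        _, p_general = nested_f_test(fit_gen, fit_red)
        skipped = False

    term = fit_add["genotype"]
    return AssociationResult(
        trait=trait,
        predictor=str(genotype.name),
        scale=scale,
        beta=term["beta"],
        se=term["se"],
        t=term["t"],
        p_additive=term["p"],
        p_general=p_general,
        general_skipped=skipped,
        partial_r=partial_r(fit_add, "genotype"),
        n=len(df),
    )


def grs_association(
    scores: pd.Series, cohort: CohortTable, trait: str
) -> AssociationResult:
    """Association of the risk score, as a quantitative covariate, with one
    baseline trait, adjusted for age, sex, ethnicity and BMI."""
    df, scale = _analysis_frame(cohort, trait, extra=scores)
    if df["_x"].nunique() < 2:
        raise ValueError("risk score is constant; association is undefined")
    X = build_design(df, numeric=_NUMERIC, factors=_FACTORS)
    X["grs"] = df["_x"].to_numpy(dtype=float)
    fit = fit_ols(X, df["_y"])
    term = fit["grs"]
    return AssociationResult(
        trait=trait,
        predictor="grs",
        scale=scale,
        beta=term["beta"],
        se=term["se"],
        t=term["t"],
        p_additive=term["p"],
        p_general=None,
        general_skipped=True,
        partial_r=partial_r(fit, "grs"),
        n=len(df),
    )


def quartile_summary(
    cohort: CohortTable, quartiles: pd.Series, trait: str
) -> QuartileSummary:
    """Covariate-adjusted means per score quartile with the Q4-vs-Q1
    percent difference.

    Means are geometric (ln traits back-transformed) except LDL-C, and are
    adjusted for age, sex, ethnicity and BMI at the sample reference point.
    """
    df, scale = _analysis_frame(cohort, trait)
    df = df.join(quartiles.rename("quartile")).dropna(subset=["quartile"])
    counts = df["quartile"].value_counts().to_dict()
    for q in ("Q1", "Q4"):
        if counts.get(q, 0) == 0:
            raise ValueError(f"empty quartile {q} for trait {trait!r}")
    means = ls_means(
        df,
        response="_y",
        factor="quartile",
        covariates=_NUMERIC,
        other_factors=_FACTORS,
        scale="ln" if scale == LN else "raw",
    )
    return QuartileSummary(
        trait=trait,
        scale=scale,
        means=means,
        pct_diff_q4_vs_q1=pct_diff(means.mean("Q1"), means.mean("Q4")),
        n_per_quartile={q: int(counts.get(q, 0)) for q in ("Q1", "Q2", "Q3", "Q4")},
    )


# ---------------------------------------------------------------------------
# Multiple testing and replication
# ---------------------------------------------------------------------------

def bonferroni(
    p_values: Optional[Sequence[float]] = None,
    n_snps: int = 32,
    n_traits: int = 14,
    alpha: float = 0.05,
) -> BonferroniResult:
    """Bonferroni control over the SNP x trait test grid.

    m = n_snps * n_traits; the per-test threshold is alpha/m, also reported
    rounded to one significant figure as it would be quoted (0.05/448 ->
    1e-4).  When `p_values` is given, flags p <= threshold.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    m = int(n_snps) * int(n_traits)
    if m <= 0:
        raise ValueError("empty test grid")
    threshold = alpha / m
    exp10 = np.floor(np.log10(threshold))
    presentation = float(
        round_half_away(threshold / 10**exp10) * 10**exp10
    )
    flags = None
    if p_values is not None:
        flags = np.asarray(p_values, dtype=float) <= threshold
    return BonferroniResult(
        n_tests=m,
        threshold=threshold,
        threshold_presentation=presentation,
        alpha=alpha,
        significant=flags,
    )


def replication_check(
    results: Dict[Tuple[str, str], AssociationResult],
    risk_table: RiskTable,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Directionally consistent replication of each panel SNP for its
    source trait(s).

    A (SNP, trait) pair replicates when the additive p-value is at most
    `alpha` and the risk-allele beta has the direction that defines the
    risk allele (+ for TG/LDL-C, - for HDL-C).  `results` must hold an
    AssociationResult for every SNP's source traits, keyed by
    (rsid, trait); betas must be on the risk-allele orientation.
    """
    rows = []
    for snp in risk_table:
        for trait, direction in sorted(snp.source_traits.items()):
            res = results.get((snp.rsid, trait))
            if res is None:
                raise ValueError(
                    f"missing association result for {snp.rsid} / {trait}"
                )
            ok = res.p_additive <= alpha and np.sign(res.beta) == direction
            rows.append(
                {
                    "rsid": snp.rsid,
                    "trait": trait,
                    "beta": res.beta,
                    "p_additive": res.p_additive,
                    "expected_direction": direction,
                    "replicated": bool(ok),
                }
            )
    df = pd.DataFrame(rows)
    df.attrs["n_replicated_snps"] = int(
        df.groupby("rsid")["replicated"].any().sum()
    )
    return df


# ---------------------------------------------------------------------------
# Whole-stage drivers
# ---------------------------------------------------------------------------

def single_snp_scan(
    oriented: GenotypeMatrix,
    cohort: CohortTable,
    traits: Sequence[str] = TRAIT_NAMES,
) -> Dict[Tuple[str, str], AssociationResult]:
    """Additive + general tests for every (SNP, trait) pair.  Monomorphic
    SNPs are skipped with a warning entry rather than aborting the scan."""
    out: Dict[Tuple[str, str], AssociationResult] = {}
    for rsid in oriented.rsids:
        col = oriented.calls[rsid]
        for trait in traits:
            try:
                out[(rsid, trait)] = snp_tests(col, cohort, trait)
            except ValueError as err:
                if "monomorphic" not in str(err):
                    raise
    return out


def grs_scan(
    scores: pd.Series,
    cohort: CohortTable,
    traits: Sequence[str] = TRAIT_NAMES,
) -> Dict[str, AssociationResult]:
    return {t: grs_association(scores, cohort, t) for t in traits}
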