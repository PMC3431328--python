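"""Monte-Carlo calibration and recovery suites for the analysis pipeline.

These routines measure, by simulation, the statistical properties the
analysis claims: unbiased recovery of injected per-allele and interaction
effects, nominal type-I error of the additive and product-term Wald tests,
Hardy-Weinberg conformance of the genotype generator, and numerical
agreement of the least-squares engine with the closed-form normal
equations.  They are used both by the test suite and by the reproduction
script, so the numbers reported there are recomputed from scratch on every
run.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .association import snp_tests
from .containers import CohortTable
from .grs import score_cohort
from .interaction import fit_interaction_model
from .io import hwe_scan
from .regress import fit_ols
from .simulate import SimConfig, simulate_study
from .traits import ETHNICITIES

__all__ = [
    "ols_oracle_max_rel_err",
    "recover_injected_effects",
    "type1_error_additive",
    "type1_error_interaction",
    "hwe_flag_rate",
]


# ---------------------------------------------------------------------------
# OLS vs normal equations
# ---------------------------------------------------------------------------

def ols_oracle_max_rel_err(n_instances: int = 1000, seed: int = 0) -> float:
    """Worst relative coefficient error of the QR-based engine against the
    normal-equations solution (X'X)^-1 X'y over random small instances."""
    rng = np.random.Generator(np.random.PCG64(seed))
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(15, 60))
        p = int(rng.integers(2, 6))
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        beta = rng.normal(size=p)
        y = X @ beta + rng.normal(size=n)
        fit = fit_ols(X, y)
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        denom = max(np.max(np.abs(oracle)), 1.0)
        worst = max(worst, float(np.max(np.abs(fit.params - oracle)) / denom))
    return worst


# ---------------------------------------------------------------------------
# Effect recovery
# ---------------------------------------------------------------------------

def recovery_config(n: int = 3000, seed: int = 0) -> SimConfig:
    """Study conditions for the recovery suite: per-allele effects of
    0.026 ln units (TG) and 1.0 mg/dl (LDL-C), and a lifestyle-arm
    score interaction of 0.9 mg/dl per allele on LDL-C."""
    return SimConfig(
        n_individuals=n,
        per_allele_effects={"tg": 0.026, "ldl_c": 1.0},
        grs_by_arm_interactions={"ldl_c": {"lifestyle": 0.9}},
        seed=seed,
    )


def recover_injected_effects(
    n_seeds: int = 200, n: int = 3000, seed: int = 0
) -> pd.DataFrame:
    """Run the full pipeline (simulate, impute, score, fit) across seeds
    and report the mean recovered estimate for each injected effect.

    Rows: ln-trait per-allele slope (truth 0.026), LDL-C per-allele slope
    (truth 1.0 mg/dl), lifestyle interaction (truth 0.9 mg/dl/allele).
    Columns: truth, mean_estimate, mean_bias, sd.
    """
    root = np.random.SeedSequence(seed).generate_state(1)[0] % (2**31)
    rows = {"tg_slope": [], "ldl_slope": [], "lifestyle_interaction": []}
    for k in range(n_seeds):
        cfg = recovery_config(n=n, seed=int((root + k) % (2**31)))
        study = simulate_study(cfg)
        cohort, geno = study.cohort, study.genotypes
        scores = score_cohort(geno, cfg.panel, cohort.data["ethnicity"])
        grs = scores.grs

        from .association import grs_association

        rows["tg_slope"].append(grs_association(grs, cohort, "tg").beta)
        rows["ldl_slope"].append(grs_association(grs, cohort, "ldl_c").beta)
        inter = fit_interaction_model(cohort, grs, "ldl_c")
        rows["lifestyle_interaction"].append(inter.interactions["lifestyle"].beta)

    truth = {"tg_slope": 0.026, "ldl_slope": 1.0, "lifestyle_interaction": 0.9}
    out = []
    for name, vals in rows.items():
        vals = np.asarray(vals)
        out.append(
            {
                "effect": name,
                "truth": truth[name],
                "mean_estimate": float(vals.mean()),
                "mean_bias": float(vals.mean() - truth[name]),
                "sd": float(vals.std(ddof=1)),
                "n_seeds": n_seeds,
            }
        )
    return pd.DataFrame(out).set_index("effect")


# ---------------------------------------------------------------------------
# Type-I error
# ---------------------------------------------------------------------------

def _null_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    eth = rng.choice(list(ETHNICITIES), size=n, p=[0.55, 0.21, 0.17, 0.04, 0.03])
    return pd.DataFrame(
        {
            "age": np.clip(rng.normal(50, 9, n), 25, 85),
            "sex": np.where(rng.random(n) < 0.32, "M", "F"),
            "ethnicity": eth,
            "bmi": np.clip(rng.normal(33.5, 6, n), 20, 60),
            "lipid_med": False,
            "arm": rng.choice(["placebo", "metformin", "lifestyle"], size=n),
        },
        index=[f"N{i}" for i in range(n)],
    )


def type1_error_additive(
    n_sims: int = 5000, n: int = 1000, alpha: float = 0.05, seed: int = 0
) -> float:
    """Rejection rate of the additive measured-genotype test when the SNP
    has no effect (ln-scale trait driven by covariates and noise only)."""
    rng = np.random.Generator(np.random.PCG64(seed))
    base = _null_covariates(n, rng)
    cohort = CohortTable(base.assign(tg_bl=100.0))
    male = (base["sex"] == "M").to_numpy(float)
    age_c = base["age"].to_numpy() - 50.0
    rejections = 0
    for _ in range(n_sims):
        g = pd.Series(rng.binomial(2, 0.3, size=n), index=base.index, name="snp")
        y = np.exp(5.0 + 0.002 * age_c + 0.02 * male + rng.normal(0, 0.4, n))
        cohort.data["tg_bl"] = y
        res = snp_tests(g, cohort, "tg")
        rejections += res.p_additive <= alpha
    return rejections / n_sims


def type1_error_interaction(
    n_sims: int = 5000, n: int = 1500, alpha: float = 0.05, seed: int = 0
) -> Dict[str, float]:
    """Rejection rates of the two score-by-arm product-term Wald tests under
    the null (one-year value = carryover of baseline plus noise, no arm or
    score effects)."""
    rng = np.random.Generator(np.random.PCG64(seed))
    base = _null_covariates(n, rng)
    cohort = CohortTable(base.assign(ldl_c_bl=120.0, ldl_c_y1=120.0))
    rej = {"metformin": 0, "lifestyle": 0}
    for _ in range(n_sims):
        grs = pd.Series(
            rng.binomial(64, 0.5, size=n).astype(float), index=base.index
        )
        y0 = 123.0 + rng.normal(0, 30.0, n)
        y1 = 0.6 * y0 + 0.4 * 123.0 + rng.normal(0, 25.0, n)
        cohort.data["ldl_c_bl"] = np.maximum(y0, 1.0)
        cohort.data["ldl_c_y1"] = np.maximum(y1, 1.0)
        res = fit_interaction_model(cohort, grs, "ldl_c")
        for arm in rej:
            rej[arm] += res.interactions[arm].p <= alpha
    return {arm: k / n_sims for arm, k in rej.items()}


# ---------------------------------------------------------------------------
# Hardy-Weinberg conformance of the generator
# ---------------------------------------------------------------------------

def hwe_flag_rate(
    n_per_ethnicity: int = 10000,
    n_seeds: int = 3,
    threshold: float = 0.001,
    seed: int = 0,
) -> Tuple[float, int]:
    """Fraction of (SNP, ethnicity) cells flagged by the Hardy-Weinberg
    chi-square scan on freshly simulated genotypes.  Returns (rate, cells).
    """
    from .simulate import simulate_genotypes, draw_covariates

    flagged = 0
    cells = 0
    for k in range(n_seeds):
        cfg = SimConfig(
            n_individuals=n_per_ethnicity * len(ETHNICITIES),
            ethnicity_proportions=tuple([1 / len(ETHNICITIES)] * len(ETHNICITIES)),
            missing_rate=0.0,
            seed=seed + k,
        )
        geno = simulate_genotypes(cfg)
        eth = draw_covariates(cfg)["ethnicity"]
        scan = hwe_scan(geno, eth, threshold=threshold)
        flagged += int(scan["flagged"].sum())
        cells += len(scan)
    return flagged / cells, cells
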