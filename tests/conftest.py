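import numpy as np
import pandas as pd
import pytest

from lipidgrs import (
    CohortTable,
    GenotypeMatrix,
    PanelSNP,
    RiskTable,
    SimConfig,
    simulate_study,
)


@pytest.fixture(scope="session")
def study():
    """A mid-sized simulated study shared by read-only tests."""
    return simulate_study(SimConfig(n_individuals=600, seed=42))


@pytest.fixture(scope="session")
def study_nomiss():
    """Same conditions but without missing calls (identity checks)."""
    return simulate_study(SimConfig(n_individuals=400, missing_rate=0.0, seed=7))


@pytest.fixture()
def tiny_panel():
    """A 3-SNP panel with mixed risk-allele orientations."""
    return RiskTable(
        [
            PanelSNP("rs1", "A", "G", "A", {"tg": +1}),
            PanelSNP("rs2", "C", "T", "T", {"hdl_c": -1}),
            PanelSNP("rs3", "G", "T", "G", {"ldl_c": +1, "tg": +1}),
        ]
    )


def make_genotypes(calls, panel, counted="risk"):
    """GenotypeMatrix from a dict {rsid: list}, counted on each SNP's risk
    allele (or its other allele with counted='other')."""
    n = len(next(iter(calls.values())))
    ids = [f"S{i}" for i in range(n)]
    df = pd.DataFrame(
        {r: pd.array(v, dtype=float) for r, v in calls.items()}, index=ids
    )
    alleles = {s.rsid: (s.allele_a, s.allele_b) for s in panel}
    counted_map = {
        s.rsid: (s.risk_allele if counted == "risk" else s.other_allele)
        for s in panel
    }
    return GenotypeMatrix(calls=df, alleles=alleles, counted_allele=counted_map)


def make_cohort(n, trait_values=None, seed=0, ethnicity=None, arm=None):
    """Minimal valid cohort with optional fixed trait columns."""
    rng = np.random.default_rng(seed)
    ids = [f"S{i}" for i in range(n)]
    df = pd.DataFrame(
        {
            "age": rng.normal(50, 9, n),
            "sex": np.where(rng.random(n) < 0.32, "M", "F"),
            "ethnicity": ethnicity if ethnicity is not None else "white",
            "bmi": rng.normal(33.5, 6, n),
            "arm": arm
            if arm is not None
            else rng.choice(["placebo", "metformin", "lifestyle"], n),
            "lipid_med": False,
        },
        index=ids,
    )
    for col, vals in (trait_values or {}).items():
        df[col] = vals
    return CohortTable(df)
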