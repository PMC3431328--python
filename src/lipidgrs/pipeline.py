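"""Pipeline orchestration: exclusions -> QC -> score -> associations ->
interactions, with a manifest and report tables.

The stages compose the library modules in the order a full analysis runs
them; everything is deterministic given the run configuration (and its
seed, when simulating).  Outputs are TSV tables mirroring the standard
report layouts (score-quartile association table, gene-by-treatment table,
per-SNP scan), JSON twins of each, an exclusion/QC manifest, and the
score file.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Tuple

import pandas as pd
import yaml

from . import __version__
from .association import (
    AssociationResult,
    bonferroni,
    grs_scan,
    quartile_summary,
    replication_check,
    single_snp_scan,
)
from .containers import CohortTable, GenotypeMatrix, ScoreResult
from .grs import orient_matrix, score_cohort
from .interaction import InteractionResult, analyze_interactions, median_split_summary
from .io import (
    apply_exclusions,
    hwe_scan,
    read_genotypes,
    read_phenotypes,
    read_risk_table,
)
from .panel import RiskTable
from .simulate import SimConfig, simulate_study
from .traits import TRAIT_NAMES

#: traits shown in the trajectory (median-split) summary
FIGURE_TRAITS = ("ldl_c", "small_ldl_p")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of `simulate` (a SimConfig) or the three input paths must
    be provided.
    """

    simulate: Optional[SimConfig] = None
    genotypes_path: Optional[str] = None
    genotypes_format: str = "vcf"
    phenotypes_path: Optional[str] = None
    risk_table_path: Optional[str] = None

    min_call_rate: float = 0.94
    hwe_threshold: float = 0.001
    alpha: float = 0.05
    include_bmi_y1: bool = False
    subgroup_ethnicity: Optional[str] = None  # sensitivity rerun filter
    traits: Tuple[str, ...] = TRAIT_NAMES
    run_snp_scan: bool = True

    out_dir: Optional[str] = None
    seed: int = 0

    def __post_init__(self):
        has_paths = any(
            p is not None
            for p in (self.genotypes_path, self.phenotypes_path, self.risk_table_path)
        )
        if (self.simulate is None) == (not has_paths):
            raise ValueError(
                "exactly one of simulate-config or input paths must be given"
            )
        if has_paths and not all(
            p is not None
            for p in (self.genotypes_path, self.phenotypes_path, self.risk_table_path)
        ):
            raise ValueError(
                "genotypes_path, phenotypes_path and risk_table_path are all "
                "required when not simulating"
            )
        if not (0 < self.min_call_rate <= 1):
            raise ValueError("min_call_rate must lie in (0, 1]")
        if not (0 < self.hwe_threshold < 1):
            raise ValueError("hwe_threshold must lie in (0, 1)")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        unknown = set(self.traits) - set(TRAIT_NAMES)
        if unknown:
            raise ValueError(f"unknown trait(s) {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        if sim is not None:
            sim = SimConfig(**sim)
        if "traits" in raw:
            raw["traits"] = tuple(raw["traits"])
        return cls(simulate=sim, **raw)


@dataclass
class ReportBundle:
    """Everything one pipeline run produced, in memory."""

    cohort: CohortTable
    genotypes: GenotypeMatrix
    risk_table: RiskTable
    scores: ScoreResult
    exclusion_report: dict
    hwe: pd.DataFrame
    grs_results: Dict[str, AssociationResult]
    quartile_summaries: dict
    snp_results: Dict[Tuple[str, str], AssociationResult]
    replication: Optional[pd.DataFrame]
    bonferroni: object
    interactions: Dict[str, InteractionResult]
    figure_cells: Dict[str, pd.DataFrame]
    manifest: dict


def _load_inputs(config: RunConfig):
    if config.simulate is not None:
        study = simulate_study(config.simulate)
        return study.cohort, study.genotypes, config.simulate.panel
    risk = read_risk_table(config.risk_table_path)
    geno = read_genotypes(
        config.genotypes_path, fmt=config.genotypes_format, risk_table=risk
    )
    cohort = read_phenotypes(config.phenotypes_path)
    return cohort, geno, risk


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run every stage and optionally write the report bundle to disk."""
    cohort, geno, risk = _load_inputs(config)
    n_input = len(cohort)

    cohort, geno, excl = apply_exclusions(
        cohort, geno, min_call_rate=config.min_call_rate
    )
    if config.subgroup_ethnicity is not None:
        keep = cohort.data.index[
            cohort.data["ethnicity"] == config.subgroup_ethnicity
        ]
        if len(keep) == 0:
            raise ValueError(
                f"no individuals in subgroup {config.subgroup_ethnicity!r}"
            )
        cohort = cohort.subset(keep)
        geno = geno.subset(ids=keep)
        excl["subgroup_ethnicity"] = config.subgroup_ethnicity
        excl["n_after_subgroup"] = len(cohort)

    # QC is run on the analysis cohort (post-exclusion)
    hwe = hwe_scan(geno, cohort.data["ethnicity"], threshold=config.hwe_threshold)

    scores = score_cohort(geno, risk, cohort.data["ethnicity"])
    grs_results = grs_scan(scores.grs, cohort, traits=config.traits)
    quartiles = {
        t: quartile_summary(cohort, scores.scores["quartile"], t)
        for t in config.traits
    }

    snp_results: Dict[Tuple[str, str], AssociationResult] = {}
    replication = None
    if config.run_snp_scan:
        oriented = orient_matrix(geno, risk)
        snp_results = single_snp_scan(oriented, cohort, traits=config.traits)
        # replication needs every SNP's source traits analysed; with a
        # restricted trait set (or monomorphic SNPs dropped) skip the check
        source_needed = {
            (s.rsid, t)
            for s in risk
            if s.rsid in set(geno.rsids)
            for t in s.source_traits
        }
        if source_needed <= set(snp_results):
            present = [s for s in risk if s.rsid in set(geno.rsids)]
            replication = replication_check(
                snp_results, RiskTable(list(present)), alpha=config.alpha
            )
    bonf = bonferroni(
        p_values=[r.p_additive for r in snp_results.values()] or None,
        n_snps=len(geno.rsids),
        n_traits=len(config.traits),
        alpha=config.alpha,
    )

    interactions = {}
    figure_cells = {}
    has_y1 = any(c.endswith("_y1") for c in cohort.data.columns)
    if has_y1:
        interactions = {
            t: analyze_interactions(
                cohort, scores.grs, t, include_bmi=config.include_bmi_y1
            )
            for t in config.traits
        }
        for t in FIGURE_TRAITS:
            if t in config.traits:
                figure_cells[t] = median_split_summary(
                    cohort, scores.scores["median_split"], t
                )

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "n_input": n_input,
        "exclusions": excl,
        "n_analysis": len(cohort),
        "n_snps": len(geno.rsids),
        "hwe_threshold": config.hwe_threshold,
        "n_hwe_flagged": int(hwe["flagged"].sum()) if len(hwe) else 0,
        "min_call_rate": config.min_call_rate,
        "alpha": config.alpha,
        "bonferroni_tests": bonf.n_tests,
        "bonferroni_threshold": bonf.threshold,
        "traits": list(config.traits),
        "covariates_baseline": ["age", "sex", "ethnicity", "bmi"],
        "covariates_year1": ["baseline", "age", "sex", "ethnicity"]
        + (["bmi"] if config.include_bmi_y1 else []),
        "simulated": config.simulate is not None,
    }

    bundle = ReportBundle(
        cohort=cohort,
        genotypes=geno,
        risk_table=risk,
        scores=scores,
        exclusion_report=excl,
        hwe=hwe,
        grs_results=grs_results,
        quartile_summaries=quartiles,
        snp_results=snp_results,
        replication=replication,
        bonferroni=bonf,
        interactions=interactions,
        figure_cells=figure_cells,
        manifest=manifest,
    )
    if config.out_dir is not None:
        write_tables(bundle, config.out_dir)
    return bundle


# ---------------------------------------------------------------------------
# Report writing
# ---------------------------------------------------------------------------

def _grs_table(bundle: ReportBundle) -> pd.DataFrame:
    rows = []
    for trait, res in bundle.grs_results.items():
        qs = bundle.quartile_summaries[trait]
        row = {"trait": trait, "scale": res.scale}
        for q in ("Q1", "Q2", "Q3", "Q4"):
            if q in qs.means.table.index:
                row[f"{q}_mean"] = qs.means.table.loc[q, "mean"]
                row[f"{q}_ci_low"] = qs.means.table.loc[q, "ci_low"]
                row[f"{q}_ci_high"] = qs.means.table.loc[q, "ci_high"]
        row.update(
            pct_diff_q4_vs_q1=qs.pct_diff_q4_vs_q1,
            partial_r=res.partial_r,
            beta_per_allele=res.beta,
            se=res.se,
            p=res.p_additive,
            n=res.n,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def _interaction_table(bundle: ReportBundle) -> pd.DataFrame:
    rows = []
    for trait, res in bundle.interactions.items():
        row = {"trait": trait, "scale": res.scale, "n": res.n}
        for arm, eff in res.arm_effects.items():
            row[f"beta_{arm}"] = eff.beta
            row[f"se_{arm}"] = eff.se
            row[f"p_{arm}"] = eff.p
            row[f"n_{arm}"] = eff.n
        row["p_grs_x_metformin"] = res.interactions["metformin"].p
        row["p_grs_x_lifestyle"] = res.interactions["lifestyle"].p
        rows.append(row)
    return pd.DataFrame(rows)


def _snp_table(bundle: ReportBundle) -> pd.DataFrame:
    rows = []
    for (rsid, trait), res in bundle.snp_results.items():
        rows.append(
            {
                "rsid": rsid,
                "trait": trait,
                "scale": res.scale,
                "beta_per_risk_allele": res.beta,
                "se": res.se,
                "p_additive": res.p_additive,
                "p_general_2df": res.p_general,
                "general_skipped": res.general_skipped,
                "n": res.n,
            }
        )
    return pd.DataFrame(rows)


def write_tables(bundle: ReportBundle, out_dir) -> Dict[str, str]:
    """Write TSV report tables, JSON twins, scores, manifest.  Returns
    {relative filename: sha256} recorded in the manifest on disk."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    checksums: Dict[str, str] = {}

    def _write(name: str, text: str):
        path = out / name
        path.write_text(text)
        checksums[name] = hashlib.sha256(text.encode()).hexdigest()

    def _df_pair(stem: str, df: pd.DataFrame):
        _write(f"{stem}.tsv", df.to_csv(sep="\t", index=False))
        _write(f"{stem}.json", df.to_json(orient="records", indent=2))

    _df_pair("grs_baseline_associations", _grs_table(bundle))
    if bundle.snp_results:
        _df_pair("snp_associations", _snp_table(bundle))
    if bundle.replication is not None:
        _df_pair("replication", bundle.replication)
    if bundle.interactions:
        _df_pair("grs_treatment_interactions", _interaction_table(bundle))
    for trait, cells in bundle.figure_cells.items():
        _df_pair(f"median_split_cells_{trait}", cells)
    _df_pair("hwe_scan", bundle.hwe)

    scores_csv = bundle.scores.scores.to_csv(index_label="id")
    _write("scores.csv", scores_csv)
    fills = {
        f"{rsid}|{eth}": v for (rsid, eth), v in bundle.scores.fill_values.items()
    }
    _write("imputation_fills.json", json.dumps(fills, indent=2, sort_keys=True))
    _write(
        "exclusion_report.json",
        json.dumps(bundle.exclusion_report, indent=2, sort_keys=True),
    )

    manifest = dict(bundle.manifest)
    manifest["files"] = checksums
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return checksums
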