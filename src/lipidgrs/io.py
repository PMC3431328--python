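"""Reading, writing, and QC of genotypes, phenotypes, and risk tables.

Formats
-------
* VCF 4.2 (GT only, one pseudo-contig): read via cyvcf2, written as plain
  text.  Diploid biallelic sites only; calls are counted on the ALT allele
  at load and re-counted onto the declared counted allele downstream.
* TSV genotype matrix: header row of rsIDs, first column ``id``, codes
  0/1/2/NA.  Allele labels travel in ``#allele`` comment lines so the
  format round-trips; a risk table can supply them for foreign files.
* CSV phenotype table with documented headers (see `read_phenotypes`).

QC operations implement the standard trial-cohort exclusions (baseline
lipid-medication users, per-SNP call-rate floor) and a per-stratum
Hardy-Weinberg goodness-of-fit test used to flag, never drop, SNPs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .containers import CohortTable, GenotypeMatrix
from .panel import RiskTable, read_risk_table  # re-exported
from .traits import TRAIT_NAMES, baseline_col, year1_col

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_risk_table",
    "apply_exclusions",
    "hwe_test",
    "hwe_exact_test",
    "hwe_scan",
    "HWEResult",
]


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def write_genotypes(geno: GenotypeMatrix, path, fmt: str = "vcf") -> None:
    path = Path(path)
    if fmt == "vcf":
        _write_vcf(geno, path)
    elif fmt == "tsv":
        _write_tsv(geno, path)
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")


def read_genotypes(
    path, fmt: str = "vcf", risk_table: Optional[RiskTable] = None
) -> GenotypeMatrix:
    """Read genotype calls into a GenotypeMatrix.

    VCF: GT "0/0"->0, "0/1"->1, "1/1"->2 counted on ALT; "./." missing.
    TSV: codes validated; allele labels taken from ``#allele`` comment
    lines or, failing that, from `risk_table` (counted allele = risk
    allele).  Multiallelic sites, non-diploid calls, and duplicate rsIDs
    are errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "tsv":
        return _read_tsv(path, risk_table)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _write_vcf(geno: GenotypeMatrix, path: Path) -> None:
    ids = geno.ids
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=chrP,length=100000000>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(str(i) for i in ids),
    ]
    code_to_gt = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    for pos, rsid in enumerate(geno.rsids, start=1):
        a, b = geno.alleles[rsid]
        counted = geno.counted_allele[rsid]
        # ALT carries the counted allele so VCF round-trips without a flip
        ref, alt = (b, a) if counted == a else (a, b)
        col = geno.calls[rsid].to_numpy(dtype=float)
        gts = [
            "./." if np.isnan(c) else code_to_gt[c] for c in col
        ]
        lines.append(
            f"chrP\t{pos}\t{rsid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts)
        )
    path.write_text("\n".join(lines) + "\n")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    cols: Dict[str, np.ndarray] = {}
    alleles: Dict[str, Tuple[str, str]] = {}
    counted: Dict[str, str] = {}
    for variant in vcf:
        rsid = variant.ID
        if rsid is None:
            raise ValueError(f"{path}: variant at POS {variant.POS} has no ID")
        if rsid in cols:
            raise ValueError(f"{path}: duplicate rsID {rsid}")
        if len(variant.ALT) != 1:
            raise ValueError(
                f"{path}: {rsid} is not biallelic (ALT={variant.ALT})"
            )
        calls = np.full(len(sample_ids), np.nan)
        for i, gt in enumerate(variant.genotypes):
            al = [a for a in gt[:-1]]  # last element is the phased flag
            if len(al) != 2:
                raise ValueError(f"{path}: {rsid} sample {sample_ids[i]} "
                                 f"has ploidy {len(al)}")
            if al[0] < 0 or al[1] < 0:  # missing
                continue
            if max(al) > 1:
                raise ValueError(
                    f"{path}: {rsid} sample {sample_ids[i]} has multiallelic "
                    f"genotype {al[0]}/{al[1]}"
                )
            calls[i] = float(al[0] + al[1])
        cols[rsid] = calls
        alleles[rsid] = (variant.REF, variant.ALT[0])
        counted[rsid] = variant.ALT[0]
    calls_df = pd.DataFrame(cols, index=sample_ids)
    return GenotypeMatrix(calls=calls_df, alleles=alleles, counted_allele=counted)


def _write_tsv(geno: GenotypeMatrix, path: Path) -> None:
    lines = []
    for rsid in geno.rsids:
        a, b = geno.alleles[rsid]
        lines.append(f"#allele\t{rsid}\t{a}\t{b}\t{geno.counted_allele[rsid]}")
    lines.append("id\t" + "\t".join(geno.rsids))
    for ind, row in geno.calls.iterrows():
        codes = [
            "NA" if np.isnan(v) else str(int(v)) for v in row.to_numpy(dtype=float)
        ]
        lines.append(f"{ind}\t" + "\t".join(codes))
    path.write_text("\n".join(lines) + "\n")


def _read_tsv(path: Path, risk_table: Optional[RiskTable]) -> GenotypeMatrix:
    alleles: Dict[str, Tuple[str, str]] = {}
    counted: Dict[str, str] = {}
    header = None
    rows = []
    ids = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("#allele\t"):
            _, rsid, a, b, c = line.split("\t")
            alleles[rsid] = (a, b)
            counted[rsid] = c
            continue
        fields = line.rstrip("\n").split("\t")
        if header is None:
            if fields[0] != "id":
                raise ValueError(f"{path}:{lineno}: first column must be 'id'")
            header = fields[1:]
            if len(set(header)) != len(header):
                raise ValueError(f"{path}: duplicate rsIDs in header")
            continue
        ids.append(fields[0])
        row = []
        for rsid, tok in zip(header, fields[1:]):
            if tok in ("NA", "", "."):
                row.append(np.nan)
            elif tok in ("0", "1", "2"):
                row.append(float(tok))
            else:
                raise ValueError(
                    f"{path}:{lineno}: unknown genotype token {tok!r} for {rsid}"
                )
        rows.append(row)
    if header is None:
        raise ValueError(f"{path}: no header row")
    for rsid in header:
        if rsid not in alleles:
            if risk_table is None or rsid not in risk_table:
                raise ValueError(
                    f"{path}: no allele labels for {rsid}; add #allele lines "
                    "or pass a risk table"
                )
            snp = risk_table[rsid]
            alleles[rsid] = (snp.allele_a, snp.allele_b)
            counted[rsid] = snp.risk_allele
    calls = pd.DataFrame(rows, index=ids, columns=header)
    return GenotypeMatrix(calls=calls, alleles=alleles, counted_allele=counted)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

_PHENO_META = ["age", "sex", "ethnicity", "bmi", "arm", "lipid_med"]


def write_phenotypes(cohort: CohortTable, path) -> None:
    df = cohort.data.copy()
    df["lipid_med"] = df["lipid_med"].astype(int)
    df.to_csv(path, index_label="id")


def read_phenotypes(path) -> CohortTable:
    """Read a phenotype CSV.

    Required headers: id, age, sex (M/F), ethnicity, bmi, arm, lipid_med
    (0/1).  Trait columns are named ``<trait>_bl`` / ``<trait>_y1`` (e.g.
    ``tg_bl``) in native units; unknown columns are an error so typos do not
    silently drop a trait.
    """
    df = pd.read_csv(path, index_col="id")
    missing = [c for c in _PHENO_META if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table {path}: missing columns {missing}")
    allowed = set(_PHENO_META) | {
        c for t in TRAIT_NAMES for c in (baseline_col(t), year1_col(t))
    }
    unknown = [c for c in df.columns if c not in allowed]
    if unknown:
        raise ValueError(f"phenotype table {path}: unknown columns {unknown}")
    df["lipid_med"] = df["lipid_med"].astype(bool)
    df.index = df.index.astype(str)
    return CohortTable(df)


# ---------------------------------------------------------------------------
# Exclusions
# ---------------------------------------------------------------------------

def apply_exclusions(
    cohort: CohortTable,
    geno: GenotypeMatrix,
    min_call_rate: float = 0.94,
) -> Tuple[CohortTable, GenotypeMatrix, dict]:
    """Apply the standard analysis exclusions.

    Drops (1) individuals flagged as taking lipid-lowering medication at
    baseline, (2) individuals present in only one of the two tables, and
    (3) SNPs whose call rate among retained individuals falls below
    `min_call_rate` (default 0.94).  Returns the filtered tables plus a
    report dict counting each exclusion reason.  The operation is
    idempotent.
    """
    cohort_ids = set(cohort.ids)
    geno_ids = set(geno.ids)
    med_flagged = set(cohort.data.index[cohort.data["lipid_med"]])
    shared = cohort_ids & geno_ids
    keep_ids = [i for i in cohort.ids if i in shared and i not in med_flagged]
    if not keep_ids:
        raise ValueError("no individuals remain after exclusions")

    geno_kept = geno.subset(ids=[i for i in geno.ids if i in set(keep_ids)])
    call_rate = geno_kept.call_rate()
    low = call_rate[call_rate < min_call_rate]
    keep_snps = [r for r in geno_kept.rsids if r not in set(low.index)]

    report = {
        "n_cohort_input": len(cohort),
        "n_genotyped_input": len(geno.ids),
        "n_medication_excluded": len(med_flagged & shared),
        "n_cohort_without_genotypes": len(cohort_ids - geno_ids),
        "n_genotypes_without_phenotypes": len(geno_ids - cohort_ids),
        "n_retained": len(keep_ids),
        "min_call_rate": min_call_rate,
        "snps_dropped_call_rate": {
            r: float(call_rate[r]) for r in low.index
        },
        "n_snps_retained": len(keep_snps),
    }
    return (
        cohort.subset(keep_ids),
        geno_kept.subset(rsids=keep_snps),
        report,
    )


def write_exclusion_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Hardy-Weinberg equilibrium
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HWEResult:
    chi2: float
    p: float
    monomorphic: bool


def hwe_test(n_aa: int, n_ab: int, n_bb: int) -> HWEResult:
    """1-df chi-square goodness-of-fit test against Hardy-Weinberg
    proportions at the sample allele frequency.

    (n_aa, n_ab, n_bb) are genotype counts homozygous-A / heterozygous /
    homozygous-B; allele labelling is immaterial.  A monomorphic sample
    returns p=1 with the monomorphic flag (there is nothing to test).
    """
    counts = np.array([n_aa, n_ab, n_bb], dtype=float)
    if (counts < 0).any():
        raise ValueError("negative genotype count")
    n = counts.sum()
    if n == 0:
        raise ValueError("no genotypes")
    p_a = (2 * n_aa + n_ab) / (2 * n)
    if p_a in (0.0, 1.0):
        return HWEResult(chi2=0.0, p=1.0, monomorphic=True)
    expected = n * np.array([p_a**2, 2 * p_a * (1 - p_a), (1 - p_a) ** 2])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return HWEResult(chi2=chi2, p=float(stats.chi2.sf(chi2, df=1)), monomorphic=False)


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> HWEResult:
    """Exact Hardy-Weinberg test (sum of genotype-configuration
    probabilities no greater than the observed one, conditional on allele
    counts).  Preferable to the chi-square at low minor-allele counts."""
    counts = np.array([n_aa, n_ab, n_bb], dtype=int)
    if (counts < 0).any():
        raise ValueError("negative genotype count")
    n = int(counts.sum())
    if n == 0:
        raise ValueError("no genotypes")
    n_a = 2 * n_aa + n_ab  # copies of allele A
    n_b = 2 * n - n_a
    if n_a == 0 or n_b == 0:
        return HWEResult(chi2=0.0, p=1.0, monomorphic=True)
    rare = min(n_a, n_b)
    # heterozygote count shares the parity of the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)

    def logprob(h):
        # P(h hets | n, rare allele count) conditional on allele counts
        n_rare_hom = (rare - h) // 2
        n_common_hom = n - n_rare_hom - h
        return (
            h * np.log(2)
            + gammaln(n + 1)
            - gammaln(n_rare_hom + 1)
            - gammaln(h + 1)
            - gammaln(n_common_hom + 1)
            + gammaln(rare + 1)
            + gammaln(2 * n - rare + 1)
            - gammaln(2 * n + 1)
        )

    lp = np.array([logprob(int(h)) for h in hets])
    probs = np.exp(lp - lp.max())
    probs /= probs.sum()
    obs = probs[hets == n_ab]
    if obs.size == 0:
        raise ValueError("heterozygote count inconsistent with allele counts")
    p = float(probs[probs <= obs[0] * (1 + 1e-12)].sum())
    return HWEResult(chi2=np.nan, p=min(p, 1.0), monomorphic=False)


def hwe_scan(
    geno: GenotypeMatrix,
    ethnicity: pd.Series,
    threshold: float = 0.001,
    method: str = "chi2",
) -> pd.DataFrame:
    """Hardy-Weinberg test per (SNP, ethnicity) stratum.

    Returns a tidy DataFrame with columns rsid, ethnicity, n, chi2, p,
    monomorphic, flagged.  SNPs are flagged below `threshold` (default
    0.001) but never dropped automatically.
    """
    test = {"chi2": hwe_test, "exact": hwe_exact_test}[method]
    ethnicity = ethnicity.loc[geno.calls.index]
    rows = []
    for eth, idx in ethnicity.groupby(ethnicity).groups.items():
        sub = geno.calls.loc[idx]
        for rsid in geno.rsids:
            col = sub[rsid].dropna().to_numpy()
            if col.size == 0:
                continue
            res = test(
                int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
            )
            rows.append(
                {
                    "rsid": rsid,
                    "ethnicity": eth,
                    "n": int(col.size),
                    "chi2": res.chi2,
                    "p": res.p,
                    "monomorphic": res.monomorphic,
                    "flagged": (not res.monomorphic) and res.p < threshold,
                }
            )
    return pd.DataFrame(rows)
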