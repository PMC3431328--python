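"""Risk-allele panel: the SNP table the genetic risk score is built from.

A panel row names a SNP, its two alleles, which allele is the *risk* allele,
and the lipid trait(s) the SNP was associated with in the source GWAS
meta-analysis, with the direction of that association.  The risk allele is,
by definition, the allele associated with higher triglycerides or LDL-C
and/or lower HDL-C; the stored directions must be consistent with that
definition, and loading a table that violates it is an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np
import pandas as pd

from .traits import ETHNICITIES, SOURCE_TRAITS

_VALID_BASES = set("ACGT")

#: direction the risk allele must push each source trait
RISK_DIRECTION = {"tg": +1, "ldl_c": +1, "hdl_c": -1}


@dataclass(frozen=True)
class PanelSNP:
    rsid: str
    allele_a: str
    allele_b: str
    risk_allele: str
    #: mapping source trait -> direction (+1/-1) of the risk allele's effect
    source_traits: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for al in (self.allele_a, self.allele_b):
            if al not in _VALID_BASES:
                raise ValueError(f"{self.rsid}: allele {al!r} is not a single base")
        if self.allele_a == self.allele_b:
            raise ValueError(f"{self.rsid}: alleles must differ")
        if self.risk_allele not in (self.allele_a, self.allele_b):
            raise ValueError(
                f"{self.rsid}: risk allele {self.risk_allele!r} not among "
                f"alleles {{{self.allele_a},{self.allele_b}}}"
            )
        if not self.source_traits:
            raise ValueError(f"{self.rsid}: at least one source trait required")
        for trait, direction in self.source_traits.items():
            if trait not in SOURCE_TRAITS:
                raise ValueError(f"{self.rsid}: unknown source trait {trait!r}")
            if direction != RISK_DIRECTION[trait]:
                raise ValueError(
                    f"{self.rsid}: direction {direction:+d} for {trait} is "
                    "inconsistent with the risk-allele definition "
                    "(risk allele raises TG/LDL-C and lowers HDL-C)"
                )

    @property
    def other_allele(self) -> str:
        return self.allele_b if self.risk_allele == self.allele_a else self.allele_a


@dataclass
class RiskTable:
    """Ordered collection of panel SNPs with unique rsIDs."""

    snps: List[PanelSNP]

    def __post_init__(self):
        ids = [s.rsid for s in self.snps]
        if len(set(ids)) != len(ids):
            dups = sorted({r for r in ids if ids.count(r) > 1})
            raise ValueError(f"duplicate rsIDs in risk table: {dups}")
        self._by_id = {s.rsid: s for s in self.snps}

    def __len__(self) -> int:
        return len(self.snps)

    def __iter__(self):
        return iter(self.snps)

    def __getitem__(self, rsid: str) -> PanelSNP:
        return self._by_id[rsid]

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._by_id

    @property
    def rsids(self) -> List[str]:
        return [s.rsid for s in self.snps]

    def flipped(self) -> "RiskTable":
        """Panel with every SNP's risk-allele designation swapped.

        Used for the complement-symmetry property of the score (a full flip
        maps a score g to 2*n_snps - g); the flipped table intentionally
        bypasses direction validation since it no longer encodes risk.
        """
        out = []
        for s in self.snps:
            obj = object.__new__(PanelSNP)
            object.__setattr__(obj, "rsid", s.rsid)
            object.__setattr__(obj, "allele_a", s.allele_a)
            object.__setattr__(obj, "allele_b", s.allele_b)
            object.__setattr__(obj, "risk_allele", s.other_allele)
            object.__setattr__(obj, "source_traits", dict(s.source_traits))
            out.append(obj)
        return RiskTable(out)

    # ---------------------------------------------------------------- I/O

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.snps:
            traits = sorted(s.source_traits)
            rows.append(
                {
                    "rsid": s.rsid,
                    "allele_a": s.allele_a,
                    "allele_b": s.allele_b,
                    "risk_allele": s.risk_allele,
                    "source_traits": ";".join(traits),
                    "directions": ";".join(
                        f"{s.source_traits[t]:+d}" for t in traits
                    ),
                }
            )
        return pd.DataFrame(rows)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


REQUIRED_COLUMNS = (
    "rsid",
    "allele_a",
    "allele_b",
    "risk_allele",
    "source_traits",
    "directions",
)


def read_risk_table(path) -> RiskTable:
    """Read a risk-allele table from CSV.

    Columns: rsid, allele_a, allele_b, risk_allele, source_traits
    (';'-separated trait names among ldl_c/hdl_c/tg), directions
    (';'-separated signed integers aligned with source_traits).
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"risk table {path}: missing columns {missing}")
    snps = []
    for _, row in df.iterrows():
        traits = str(row["source_traits"]).split(";")
        dirs = [int(d) for d in str(row["directions"]).split(";")]
        if len(traits) != len(dirs):
            raise ValueError(
                f"{row['rsid']}: source_traits and directions lengths differ"
            )
        snps.append(
            PanelSNP(
                rsid=row["rsid"],
                allele_a=row["allele_a"],
                allele_b=row["allele_b"],
                risk_allele=row["risk_allele"],
                source_traits=dict(zip(traits, dirs)),
            )
        )
    return RiskTable(snps)


# --------------------------------------------------------------------------
# Bundled default panel (synthetic)
# --------------------------------------------------------------------------

#: Source-trait composition of the default 32-SNP panel: 11 LDL-C SNPs,
#: 10 HDL-C-only, 7 TG-only, and 4 associated with both HDL-C and TG.
_PANEL_COMPOSITION = (
    [("ldl_c",)] * 11 + [("hdl_c",)] * 10 + [("tg",)] * 7 + [("hdl_c", "tg")] * 4
)

_PANEL_SEED = 20120830  # fixed: the default panel is a constant, not a sample


def default_panel() -> RiskTable:
    """The bundled 32-SNP lipid panel.

    This is a *synthetic* stand-in panel: rsID labels, allele pairs and the
    risk-allele choices are generated deterministically, while the
    source-trait composition (11 LDL-C, 10 HDL-C, 7 TG, 4 HDL-C+TG) matches
    the GWAS meta-analysis panels this kind of score is built from.  Supply
    your own risk table CSV to score real genotypes.
    """
    rng = np.random.Generator(np.random.PCG64(_PANEL_SEED))
    bases = np.array(list("ACGT"))
    snps = []
    for i, traits in enumerate(_PANEL_COMPOSITION, start=1):
        a, b = rng.choice(4, size=2, replace=False)
        risk = rng.integers(2)
        alleles = (str(bases[a]), str(bases[b]))
        snps.append(
            PanelSNP(
                rsid=f"rs90{i:04d}",
                allele_a=alleles[0],
                allele_b=alleles[1],
                risk_allele=alleles[risk],
                source_traits={t: RISK_DIRECTION[t] for t in traits},
            )
        )
    return RiskTable(snps)


def default_allele_freqs(panel: RiskTable | None = None) -> pd.DataFrame:
    """Default per-SNP, per-ethnicity risk-allele frequencies.

    Frequencies are drawn once (fixed internal seed) from a mid-range base
    frequency per SNP with moderate ethnic divergence on the logit scale,
    emulating common variants whose frequencies differ across self-reported
    ethnic groups without being fixed or absent anywhere.
    Rows: rsIDs; columns: ethnicities; values in [0.05, 0.95].
    """
    panel = panel if panel is not None else default_panel()
    rng = np.random.Generator(np.random.PCG64(_PANEL_SEED + 1))
    base = rng.uniform(0.15, 0.85, size=len(panel))
    logit = np.log(base / (1 - base))
    shifts = rng.normal(0.0, 0.35, size=(len(panel), len(ETHNICITIES)))
    freqs = 1.0 / (1.0 + np.exp(-(logit[:, None] + shifts)))
    freqs = np.clip(freqs, 0.05, 0.95)
    return pd.DataFrame(freqs, index=panel.rsids, columns=list(ETHNICITIES))
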