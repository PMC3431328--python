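"""Registry of the 14 lipid / NMR-lipoprotein traits handled by the pipeline.

Four standard lipid panel traits (total cholesterol, LDL-C, HDL-C,
triglycerides) plus ten NMR lipoprotein subfraction measures (particle
concentrations and average particle diameters of the VLDL/LDL/HDL classes).
All traits are analysed on the natural-log scale except LDL-C, which is
analysed in raw mg/dl — right-skew in lipid concentrations motivates the
log transform, while calculated LDL-C is close enough to symmetric to model
directly.

The ``typical_median`` / ``typical_iqr`` entries describe a middle-aged,
overweight, prediabetic trial population and seed the synthetic-cohort
generator's intercepts and noise levels; they are not estimates of anything
in the analysis itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

RAW = "raw"
LN = "ln"


@dataclass(frozen=True)
class Trait:
    name: str               # internal identifier
    label: str              # human-readable, used in reports
    unit: str
    scale: str              # "ln" (analysed as natural log) or "raw"
    typical_median: float
    typical_iqr: Tuple[float, float]

    @property
    def noise_sd(self) -> float:
        """Default residual SD on the analysis scale, from the typical IQR.

        For a normal variate the IQR spans 1.349 SD; ln-scale traits use the
        IQR of the logs, raw-scale traits the raw IQR.
        """
        lo, hi = self.typical_iqr
        if self.scale == LN:
            return float(np.log(hi / lo) / 1.349)
        return float((hi - lo) / 1.349)

    @property
    def intercept(self) -> float:
        """Generator intercept on the analysis scale (value at reference
        covariates)."""
        m = self.typical_median
        return float(np.log(m)) if self.scale == LN else float(m)


TRAITS = {
    t.name: t
    for t in [
        Trait("chol", "Total cholesterol", "mg/dl", LN, 201.0, (178.0, 227.0)),
        Trait("ldl_c", "LDL-C", "mg/dl", RAW, 123.0, (102.0, 147.0)),
        Trait("hdl_c", "HDL-C", "mg/dl", LN, 43.0, (37.0, 50.0)),
        Trait("tg", "Triglycerides", "mg/dl", LN, 146.0, (102.5, 205.5)),
        Trait("large_hdl_p", "Large HDL particles", "umol/L", LN, 3.3, (2.1, 5.5)),
        Trait("small_hdl_p", "Small HDL particles", "umol/L", LN, 19.0, (16.1, 22.2)),
        Trait("total_hdl_p", "Total HDL particles", "umol/L", LN, 34.1, (30.4, 38.5)),
        Trait("hdl_size", "HDL size", "nm", LN, 8.8, (8.6, 9.1)),
        Trait("ldl_size", "LDL size", "nm", LN, 0.263, (0.237, 0.289)),
        Trait("total_ldl_p", "Total LDL particles", "nmol/L", LN, 1369.0, (1140.0, 1629.0)),
        Trait("small_ldl_p", "Small LDL particles", "nmol/L", LN, 788.0, (517.0, 1059.0)),
        Trait("total_vldl_p", "Total VLDL particles", "nmol/L", LN, 63.3, (43.9, 88.1)),
        Trait("large_vldl_p", "Large VLDL particles", "nmol/L", LN, 5.4, (2.8, 10.8)),
        Trait("vldl_size", "VLDL size", "nm", LN, 52.2, (47.0, 58.9)),
    ]
}

TRAIT_NAMES = tuple(TRAITS)

#: The three source lipid traits a panel SNP can carry risk for.
SOURCE_TRAITS = ("ldl_c", "hdl_c", "tg")

ETHNICITIES = ("white", "african_american", "hispanic", "asian", "american_indian")
ETHNICITY_PROPORTIONS = (0.55, 0.21, 0.17, 0.04, 0.03)

ARMS = ("placebo", "metformin", "lifestyle")


def trait_scale(name: str) -> str:
    try:
        return TRAITS[name].scale
    except KeyError:
        raise KeyError(f"unknown trait {name!r}") from None


def baseline_col(name: str) -> str:
    return f"{name}_bl"


def year1_col(name: str) -> str:
    return f"{name}_y1"
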