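"""Small shared helpers: rounding, seeding, percent differences."""

from __future__ import annotations

import numpy as np

# Stage names, in spawn order, for deriving per-stage random streams from the
# root seed.  The order is part of the package contract: changing it would
# change every simulated dataset.
STAGES = (
    "genotypes",
    "missing",
    "covariates",
    "traits",
    "medflag",
    "arms",
    "followup",
)


def round_half_away(x):
    """Round to nearest integer, ties going away from zero.

    ``np.round`` rounds half to even, which would send a group mean of
    exactly 1.5 to 2 but 0.5 to 0; the imputation fill rule documented for
    this package always rounds .5 upward (for the non-negative genotype
    scale, away from zero).
    """
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from one root seed.

    Uses ``SeedSequence.spawn`` so stages can be re-run independently
    without consuming each other's streams.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown simulation stage {stage!r}")
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return np.random.Generator(np.random.PCG64(children[STAGES.index(stage)]))


def pct_diff(ref: float, other: float) -> int:
    """Percent difference of `other` vs `ref`, as rounded integer magnitude.

    This is the convention used when summarising extreme-quartile adjusted
    means: the magnitude of 100*(Q4-Q1)/Q1, rounded half away from zero, with
    the direction left to be read off the means themselves.
    """
    if ref == 0:
        raise ZeroDivisionError("reference mean is zero")
    return int(round_half_away(abs(100.0 * (other - ref) / ref)))
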