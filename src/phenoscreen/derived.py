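"""Closed-form derived quantities used throughout the drought screen.

These are the unit-level transforms applied before any modeling: the
percent stress-response index of a trait, photosystem-II quantum yield
from chlorophyll fluorescence, volumetric-water-content scaling,
protein-normalized peroxisome fluorescence, and baseline-relative fold
change for time-course trajectories.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import (
    InvalidFluorescenceError,
    InvalidProteinError,
    UndefinedBaselineError,
)
from .io import ENVIRONMENTS, NON_STRESSED, STRESSED, PhenotypeTable


def stress_index(mean_non_stressed: float, mean_stressed: float) -> float:
    """Percent change of a trait mean under stress relative to the control.

    index = (mean_stressed - mean_non_stressed) / mean_non_stressed * 100

    A negative index means the trait declined under stress; +148.49 for
    peroxisome abundance means a 2.5-fold increase of the population mean.
    """
    if mean_non_stressed == 0:
        raise UndefinedBaselineError(
            "stress index undefined: non-stressed mean is zero"
        )
    return (mean_stressed - mean_non_stressed) / mean_non_stressed * 100.0


def yii(f_ground: float, f_max: float) -> float:
    """Photosystem-II quantum yield (Fv/Fm form) from fluorescence levels.

    yii = (f_max - f_ground) / f_max, bounded in [0, 1].
    """
    if f_max <= 0:
        raise InvalidFluorescenceError(f"maximal fluorescence must be > 0, got {f_max}")
    if f_ground < 0 or f_ground > f_max:
        raise InvalidFluorescenceError(
            f"ground fluorescence {f_ground} outside [0, f_max={f_max}]"
        )
    return (f_max - f_ground) / f_max


def vwc_percent(raw: float) -> float:
    """Volumetric water content m^3/m^3 expressed as a percentage."""
    return raw * 100.0


def normalized_fluorescence(raw_signal: float, protein_mg: float) -> float:
    """Fluorescence signal re-expressed per 1 mg of extracted protein."""
    if protein_mg <= 0:
        raise InvalidProteinError(f"protein amount must be > 0 mg, got {protein_mg}")
    return raw_signal / protein_mg


def fold_change(value: float, baseline: float) -> float:
    """Ratio of a value to its non-stressed baseline (baseline > 0)."""
    if baseline <= 0:
        raise UndefinedBaselineError(f"fold-change baseline must be > 0, got {baseline}")
    return value / baseline


def trait_summary(table: PhenotypeTable) -> pd.DataFrame:
    """Per-trait mean +/- SD per environment, n, and stress-response index.

    One row per trait with columns ``mean_non_stressed, sd_non_stressed,
    n_non_stressed, mean_stressed, sd_stressed, n_stressed, index``; the
    index is computed from the two environment means at full precision
    (round for presentation only).
    """
    rows = []
    for trait in table.traits:
        row: dict = {"trait": trait}
        means = {}
        for env in ENVIRONMENTS:
            vals = table.trait_values(trait, env)["value"].to_numpy(dtype=float)
            suffix = env
            row[f"mean_{suffix}"] = vals.mean() if vals.size else np.nan
            row[f"sd_{suffix}"] = vals.std(ddof=1) if vals.size > 1 else np.nan
            row[f"n_{suffix}"] = int(vals.size)
            means[env] = row[f"mean_{suffix}"]
        if (
            np.isfinite(means.get(NON_STRESSED, np.nan))
            and np.isfinite(means.get(STRESSED, np.nan))
            and means[NON_STRESSED] != 0
        ):
            row["index"] = stress_index(means[NON_STRESSED], means[STRESSED])
        else:
            row["index"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("trait")


def genotype_stress_index(table: PhenotypeTable, trait: str) -> pd.Series:
    """Stress-response index computed per genotype instead of population-wide."""
    sub = table.trait_values(trait)
    means = sub.groupby(["genotype", "environment"], observed=True)["value"].mean()
    wide = means.unstack("environment")
    idx = (wide[STRESSED] - wide[NON_STRESSED]) / wide[NON_STRESSED] * 100.0
    idx.name = "index"
    return idx
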