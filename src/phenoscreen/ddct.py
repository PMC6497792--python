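"""Relative gene expression by the comparative-Ct (2^-ddCt) method.

Target Ct values are normalized to a housekeeping gene (dCt), technical
replicates averaged on the Ct scale, biological replicates averaged on
the dCt scale, and each treated cell expressed relative to its
genotype-matched untreated calibrator at the same day:

    fold = 2 ** -( dCt_treated - dCt_calibrator )

Amplification efficiency is fixed at 2 per cycle (the classical
assumption of the comparative-Ct method).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import CalibratorError, NormalizationError
from .io import NON_STRESSED


def delta_ct(ct_target: float, ct_housekeeping: float) -> float:
    """Ct of the target gene minus Ct of the housekeeping gene."""
    return ct_target - ct_housekeeping


def fold_change_ddct(dct_treated: float, dct_calibrator: float) -> float:
    """2^-ddCt fold change of a treated sample vs its calibrator."""
    return float(2.0 ** -(dct_treated - dct_calibrator))


def expression_matrix(
    qpcr: pd.DataFrame,
    housekeeping: str = "actin",
    calibrator_treatment: str = NON_STRESSED,
) -> pd.DataFrame:
    """Per-cell 2^-ddCt fold changes from a long qPCR Ct table.

    Returns a tidy frame with one row per (genotype, treatment, day,
    gene) and columns ``fold_change, n_bio, n_tech``.  Calibrator cells
    (the untreated sample of the same genotype and day) come out exactly
    1 by construction.
    """
    genes = sorted(g for g in qpcr["gene"].unique() if g != housekeeping)
    if not genes:
        raise NormalizationError("no target genes besides the housekeeping gene")
    if housekeeping not in set(qpcr["gene"]):
        raise NormalizationError(f"housekeeping gene {housekeeping!r} not in table")

    # Technical replicates averaged on the Ct scale.
    tech = (
        qpcr.groupby(
            ["genotype", "treatment", "day", "gene", "biological_rep"], observed=True
        )["ct"]
        .agg(["mean", "size"])
        .rename(columns={"mean": "ct", "size": "n_tech"})
        .reset_index()
    )
    hk = tech[tech["gene"] == housekeeping].rename(columns={"ct": "ct_hk"})
    target = tech[tech["gene"] != housekeeping]
    merged = target.merge(
        hk[["genotype", "treatment", "day", "biological_rep", "ct_hk"]],
        on=["genotype", "treatment", "day", "biological_rep"],
        how="left",
    )
    if merged["ct_hk"].isna().any():
        bad = merged.loc[merged["ct_hk"].isna()].iloc[0]
        raise NormalizationError(
            f"missing housekeeping Ct for genotype={bad['genotype']!r}, "
            f"treatment={bad['treatment']!r}, day={bad['day']}, "
            f"biological_rep={bad['biological_rep']}"
        )
    merged["dct"] = merged["ct"] - merged["ct_hk"]

    # Biological replicates averaged on the dCt scale.
    cells = (
        merged.groupby(["genotype", "treatment", "day", "gene"], observed=True)
        .agg(dct=("dct", "mean"), n_bio=("dct", "size"), n_tech=("n_tech", "max"))
        .reset_index()
    )
    cal = cells[cells["treatment"] == calibrator_treatment][
        ["genotype", "day", "gene", "dct"]
    ].rename(columns={"dct": "dct_cal"})
    out = cells.merge(cal, on=["genotype", "day", "gene"], how="left")
    if out["dct_cal"].isna().any():
        bad = out.loc[out["dct_cal"].isna()].iloc[0]
        raise CalibratorError(
            f"missing {calibrator_treatment!r} calibrator for "
            f"genotype={bad['genotype']!r}, day={bad['day']}, gene={bad['gene']!r}"
        )
    out["fold_change"] = 2.0 ** -(out["dct"] - out["dct_cal"])
    out["n_bio"] = out["n_bio"].astype(int)
    out["n_tech"] = out["n_tech"].astype(int)
    return out[
        ["genotype", "treatment", "day", "gene", "fold_change", "n_bio", "n_tech"]
    ].sort_values(["day", "genotype", "treatment", "gene"]).reset_index(drop=True)


def fold_change_heatmap(folds: pd.DataFrame, day: int) -> pd.DataFrame:
    """Pivot one day's fold changes to a (genotype x treatment) by gene matrix."""
    sub = folds[folds["day"] == day]
    mat = sub.pivot_table(
        index=["genotype", "treatment"], columns="gene", values="fold_change"
    )
    assert (mat.to_numpy() > 0).all(), "fold changes must be positive"
    return mat
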