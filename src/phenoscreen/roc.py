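"""Per-trait ROC curves and AUC for stressed-vs-control discrimination.

The positive class is the stressed group.  AUC is the midrank
Mann-Whitney statistic: the probability that a stressed observation
scores higher (after orientation) than a control one, with ties given
half credit.  Orientation "auto" flips a trait whose values decrease
under stress so that AUC >= 0.5 reflects separation regardless of the
direction of the response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import EmptyGroupError, ParameterError, UnknownTraitError
from .io import NON_STRESSED, STRESSED, PhenotypeTable
from .structure import observation_matrix, pca

ORIENTATIONS = ("stressed_high", "stressed_low", "auto")


@dataclass
class RocCurve:
    thresholds: np.ndarray  # decision thresholds, oriented scores, descending
    tpr: np.ndarray  # sensitivity at each threshold
    fpr: np.ndarray  # 1 - specificity at each threshold
    auc: float
    orientation: str  # resolved orientation actually applied


def _oriented(
    control: np.ndarray, stressed: np.ndarray, orientation: str
) -> tuple[np.ndarray, np.ndarray, str]:
    if orientation not in ORIENTATIONS:
        raise ParameterError(f"unknown orientation {orientation!r}")
    control = np.asarray(control, dtype=float)
    stressed = np.asarray(stressed, dtype=float)
    if control.size == 0 or stressed.size == 0:
        raise EmptyGroupError("both control and stressed groups must be non-empty")
    if orientation == "auto":
        orientation = (
            "stressed_high" if stressed.mean() >= control.mean() else "stressed_low"
        )
    if orientation == "stressed_low":
        control, stressed = -control, -stressed
    return control, stressed, orientation


def auc(control, stressed, orientation: str = "auto") -> float:
    """Midrank Mann-Whitney AUC for discriminating stressed from control.

    AUC = [#(stressed > control pairs) + 0.5 * #ties] / (n_s * n_c),
    computed via ranks in O(n log n).
    """
    control, stressed, _ = _oriented(control, stressed, orientation)
    n_c, n_s = control.size, stressed.size
    ranks = rankdata(np.concatenate([control, stressed]))
    rank_sum_s = ranks[n_c:].sum()
    return float((rank_sum_s - n_s * (n_s + 1) / 2.0) / (n_s * n_c))


def roc_curve(control, stressed, orientation: str = "auto") -> RocCurve:
    """Stepwise ROC curve over the unique observed thresholds.

    The curve starts at (0, 0) and ends at (1, 1); its trapezoidal area
    equals the midrank AUC (ties produce diagonal segments whose
    trapezoids contribute exactly the half-credit).
    """
    c, s, resolved = _oriented(control, stressed, orientation)
    scores = np.concatenate([c, s])
    labels = np.concatenate([np.zeros(c.size), np.ones(s.size)])
    thresholds = np.unique(scores)[::-1]
    tpr = [0.0]
    fpr = [0.0]
    for t in thresholds:
        positive = scores >= t
        tpr.append(float((labels[positive] == 1).sum()) / s.size)
        fpr.append(float((labels[positive] == 0).sum()) / c.size)
    tpr_arr = np.array(tpr)
    fpr_arr = np.array(fpr)
    area = float(np.trapezoid(tpr_arr, fpr_arr))
    return RocCurve(
        thresholds=thresholds,
        tpr=tpr_arr,
        fpr=fpr_arr,
        auc=area,
        orientation=resolved,
    )


def _groups(table: PhenotypeTable, trait: str) -> tuple[np.ndarray, np.ndarray]:
    control = table.trait_values(trait, NON_STRESSED)["value"].to_numpy(dtype=float)
    stressed = table.trait_values(trait, STRESSED)["value"].to_numpy(dtype=float)
    if control.size == 0 and stressed.size == 0:
        raise UnknownTraitError(f"trait {trait!r} has no observations")
    return control, stressed


def trait_auc(table: PhenotypeTable, trait: str, orientation: str = "auto") -> float:
    """Replicate-level AUC for one trait of a phenotype table."""
    control, stressed = _groups(table, trait)
    return auc(control, stressed, orientation)


def auc_table(table: PhenotypeTable, orientation: str = "auto") -> pd.DataFrame:
    """Per-trait AUC summary (trait, auc, orientation, n_control, n_stressed)."""
    rows = []
    for trait in table.traits:
        control, stressed = _groups(table, trait)
        c, s, resolved = _oriented(control, stressed, orientation)
        rows.append(
            {
                "trait": trait,
                "auc": auc(control, stressed, orientation),
                "orientation": resolved,
                "n_control": control.size,
                "n_stressed": stressed.size,
            }
        )
    return pd.DataFrame(rows).set_index("trait")


def category_auc(
    table: PhenotypeTable, traits: list, method: str = "pc1"
) -> float:
    """Category-level AUC over a group of member traits.

    method "pc1" (default): AUC of the first principal-component score of
    the member traits, computed on z-scored replicate-level observations.
    method "mean": arithmetic mean of the member traits' AUCs.
    """
    if not traits:
        raise ParameterError("category needs at least one trait")
    missing = [t for t in traits if t not in set(table.traits)]
    if missing:
        raise UnknownTraitError(f"traits absent from table: {missing}")
    if method == "mean":
        return float(np.mean([trait_auc(table, t) for t in traits]))
    if method != "pc1":
        raise ParameterError(f"unknown category method {method!r}")
    if len(traits) == 1:
        return trait_auc(table, traits[0])
    wide = observation_matrix(table, level="replicates")[traits]
    result = pca(wide, standardize=True)
    scores = result.scores["PC1"]
    env = scores.index.get_level_values("environment")
    control = scores[env == NON_STRESSED].to_numpy()
    stressed = scores[env == STRESSED].to_numpy()
    return auc(control, stressed, orientation="auto")


def category_auc_table(
    table: PhenotypeTable, categories: dict, method: str = "pc1"
) -> pd.DataFrame:
    """AUC per named category (mapping category -> list of member traits)."""
    rows = [
        {
            "category": name,
            "auc": category_auc(table, members, method=method),
            "n_traits": len(members),
            "method": method,
        }
        for name, members in categories.items()
    ]
    return pd.DataFrame(rows).set_index("category")
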