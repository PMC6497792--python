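"""Composite trait prioritization and redundancy pruning.

Each trait receives a robustness score in [0, 1] combining four
evidences that a trait is worth keeping in a reduced drought-phenotyping
panel: heritability under stress, ROC sensitivity (AUC), strength of its
correlation with a reference yield trait, and a positive gain of
heritability under stress.  Each criterion is min-max normalized over
the trait set and the score is their convex combination.  A greedy pass
in descending score then drops traits that are redundant (|r| at or
above a threshold) with an already-retained trait, mirroring the
practice of keeping one representative per correlated yield cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CoverageError, ParameterError, WeightError
from .structure import CorrelationMatrix

DEFAULT_WEIGHTS = (0.3, 0.3, 0.2, 0.2)
CRITERIA = ("H_s", "auc", "abs_r_yield", "H_gain")


@dataclass
class TraitScoreCard:
    trait: str
    index_magnitude: float  # |stress index|, percent
    H_ns: float  # heritability non-stressed, percent
    H_s: float  # heritability stressed, percent
    H_delta: float  # H_s - H_ns, percent
    auc: float
    r_yield: float  # signed Pearson r with the reference trait
    robustness: float = np.nan
    selected: bool = False


@dataclass
class ReductionResult:
    ranked: list  # TraitScoreCards in descending robustness
    selected: list  # retained trait names, in rank order
    dropped_for_redundancy: dict = field(default_factory=dict)  # trait -> proxy

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for card in self.ranked:
            rows.append(
                {
                    "trait": card.trait,
                    "robustness": card.robustness,
                    "H_ns": card.H_ns,
                    "H_s": card.H_s,
                    "H_delta": card.H_delta,
                    "auc": card.auc,
                    "r_yield": card.r_yield,
                    "index_magnitude": card.index_magnitude,
                    "selected": card.selected,
                    "redundant_with": self.dropped_for_redundancy.get(card.trait, ""),
                }
            )
        return pd.DataFrame(rows).set_index("trait")


def _minmax(values: np.ndarray, bounds: tuple | None) -> np.ndarray:
    if bounds is not None:
        lo, hi = bounds
    else:
        lo, hi = float(np.min(values)), float(np.max(values))
    if hi <= lo:
        return np.zeros_like(values, dtype=float)
    return np.clip((values - lo) / (hi - lo), 0.0, 1.0)


def score_traits(
    heritability: pd.DataFrame,
    aucs: dict | pd.Series,
    indices: dict | pd.Series,
    correlations: CorrelationMatrix,
    reference_trait: str,
    weights: tuple = DEFAULT_WEIGHTS,
    bounds: dict | None = None,
) -> list:
    """Build ranked scorecards for the trait set.

    ``heritability`` is the per-environment table from
    :func:`phenoscreen.anova.heritability_table` (columns trait, scope,
    H_percent).  ``bounds`` optionally fixes the min-max range per
    criterion (keys from ``("H_s", "auc", "abs_r_yield", "H_gain")``),
    which makes scores independent of which other traits are present.

    robustness = w1*norm(H_s) + w2*norm(auc) + w3*norm(|r_yield|)
               + w4*norm(max(H_delta, 0));  ties broken by trait name.
    """
    weights = tuple(float(w) for w in weights)
    if len(weights) != 4 or any(w < 0 for w in weights):
        raise WeightError("four non-negative weights required")
    if abs(sum(weights) - 1.0) > 1e-9:
        raise WeightError(f"weights must sum to 1, got {sum(weights)}")

    aucs = pd.Series(aucs)
    indices = pd.Series(indices)
    h_wide = heritability.pivot_table(
        index="trait", columns="scope", values="H_percent"
    )
    for col in ("non_stressed", "stressed"):
        if col not in h_wide.columns:
            raise CoverageError(
                f"heritability table lacks scope {col!r}; run with scope='per-env'"
            )
    traits = sorted(h_wide.index)
    for name, available in [
        ("auc", set(aucs.index)),
        ("stress index", set(indices.index)),
        ("correlation", set(correlations.traits)),
    ]:
        lacking = [t for t in traits if t not in available]
        if lacking:
            raise CoverageError(f"{name} input missing traits: {lacking}")
    if reference_trait not in set(correlations.traits):
        raise CoverageError(f"reference trait {reference_trait!r} not in correlations")

    h_ns = h_wide.loc[traits, "non_stressed"].to_numpy(dtype=float)
    h_s = h_wide.loc[traits, "stressed"].to_numpy(dtype=float)
    auc_v = aucs.loc[traits].to_numpy(dtype=float)
    r_yield = np.array(
        [
            1.0 if t == reference_trait else correlations.r.loc[t, reference_trait]
            for t in traits
        ],
        dtype=float,
    )
    h_gain = np.maximum(h_s - h_ns, 0.0)

    bounds = bounds or {}
    norms = {
        "H_s": _minmax(h_s, bounds.get("H_s")),
        "auc": _minmax(auc_v, bounds.get("auc")),
        "abs_r_yield": _minmax(np.abs(r_yield), bounds.get("abs_r_yield")),
        "H_gain": _minmax(h_gain, bounds.get("H_gain")),
    }
    robustness = sum(w * norms[c] for w, c in zip(weights, CRITERIA))

    cards = [
        TraitScoreCard(
            trait=t,
            index_magnitude=abs(float(indices.loc[t])),
            H_ns=float(h_ns[i]),
            H_s=float(h_s[i]),
            H_delta=float(h_s[i] - h_ns[i]),
            auc=float(auc_v[i]),
            r_yield=float(r_yield[i]),
            robustness=float(robustness[i]),
        )
        for i, t in enumerate(traits)
    ]
    cards.sort(key=lambda c: (-c.robustness, c.trait))
    return cards


def reduce_traits(
    scorecards: list,
    correlations: CorrelationMatrix,
    redundancy_threshold: float = 0.8,
    k_max: int | None = None,
) -> ReductionResult:
    """Greedy redundancy pruning of ranked scorecards.

    Traits are visited in descending robustness; a trait is kept unless
    its |r| with an already-kept trait reaches the threshold, in which
    case the kept trait is recorded as its proxy.  Selection stops once
    ``k_max`` traits are retained.
    """
    if not 0.0 < redundancy_threshold <= 1.0:
        raise ParameterError(
            f"redundancy threshold must be in (0, 1], got {redundancy_threshold}"
        )
    kept: list = []
    dropped: dict = {}
    for card in scorecards:
        card.selected = False
        proxy = None
        for kept_card in kept:
            r = correlations.r.loc[card.trait, kept_card.trait]
            if np.isfinite(r) and abs(r) >= redundancy_threshold:
                proxy = kept_card.trait
                break
        if proxy is not None:
            dropped[card.trait] = proxy
        elif k_max is None or len(kept) < k_max:
            card.selected = True
            kept.append(card)
    return ReductionResult(
        ranked=list(scorecards),
        selected=[c.trait for c in kept],
        dropped_for_redundancy=dropped,
    )
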