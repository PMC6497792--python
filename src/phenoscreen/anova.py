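"""Balanced ANOVA, variance components and broad-sense heritability.

The analysis follows the manual route used in plant breeding: a balanced
one- or two-way fixed-effects ANOVA per trait, expected-mean-squares
(method-of-moments) variance components with negative estimates truncated
to zero, and broad-sense heritability on a genotype-mean basis

    H = sigma2_g / (sigma2_g + sigma2_ge / s + sigma2_e / (s * r))

for the combined two-environment analysis, and

    H = sigma2_g / (sigma2_g + sigma2_e / r)

within a single environment, both reported as percentages.  Here s is the
number of environments and r the number of replicates per environment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DesignMismatchError,
    InsufficientReplicationError,
    UnbalancedDesignError,
    UnknownTraitError,
)
from .io import ENVIRONMENTS, PhenotypeTable, normalize_environment

SOURCE_GENOTYPE = "genotype"
SOURCE_ENVIRONMENT = "environment"
SOURCE_INTERACTION = "genotype:environment"
SOURCE_RESIDUAL = "residual"


@dataclass(frozen=True)
class VarianceComponents:
    """Method-of-moments variance components from a balanced ANOVA.

    ``sigma2_ge`` is ``None`` for a one-way (single-environment) analysis.
    ``truncated`` lists components whose raw moment estimate was negative
    and was clamped to zero.
    """

    sigma2_g: float
    sigma2_ge: float | None
    sigma2_e: float
    s: int
    r: int
    truncated: tuple = field(default_factory=tuple)


@dataclass(frozen=True)
class HeritabilityResult:
    trait: str
    scope: str  # "combined", "non_stressed" or "stressed"
    H: float  # percent, in [0, 100]
    components: VarianceComponents
    anova: pd.DataFrame


def _balanced_trait_array(
    table: PhenotypeTable, trait: str, environment: str | None = None
) -> tuple[np.ndarray, list, list]:
    """Extract a (g, s, r) value array for one trait, enforcing balance.

    Missing-data policy: if cells are unequal the trait is analyzed on the
    largest balanced subset (r reduced to the minimum cell count, keeping
    the lowest replicate numbers) with a warning; below two replicates the
    design is unusable.
    """
    sub = table.trait_values(trait, environment)
    if len(sub) == 0:
        raise UnknownTraitError(f"trait {trait!r} has no observations")
    genotypes = sorted(sub["genotype"].unique())
    envs = sorted(sub["environment"].unique())
    counts = sub.groupby(["genotype", "environment"], observed=True).size()
    full = len(genotypes) * len(envs)
    if len(counts) < full:
        have = set(counts.index)
        missing = [
            (g, e) for g in genotypes for e in envs if (g, e) not in have
        ]
        raise UnbalancedDesignError(
            f"trait {trait!r}: empty genotype x environment cells {missing[:5]}"
        )
    r = int(counts.min())
    if r < 2:
        raise InsufficientReplicationError(
            f"trait {trait!r}: at least 2 replicates per cell required, got {r}"
        )
    if counts.nunique() > 1:
        warnings.warn(
            f"trait {trait!r}: unequal cell counts; analyzing the largest "
            f"balanced subset with r={r}",
            stacklevel=3,
        )
    sub = sub.sort_values(["genotype", "environment", "replicate"])
    sub = sub.groupby(["genotype", "environment"], observed=True).head(r)
    arr = (
        sub.set_index(["genotype", "environment"])["value"]
        .groupby(level=[0, 1], observed=True)
        .apply(lambda v: v.to_numpy(dtype=float))
    )
    data = np.stack([np.stack([arr[g, e] for e in envs]) for g in genotypes])
    return data, genotypes, envs


def _anova_frame(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows).set_index("source")
    df["mean_sq"] = df["sum_sq"] / df["df"]
    ms_res = df.loc[SOURCE_RESIDUAL, "mean_sq"]
    df_res = df.loc[SOURCE_RESIDUAL, "df"]
    f = df["mean_sq"] / ms_res if ms_res > 0 else np.full(len(df), np.nan)
    p = stats.f.sf(f, df["df"], df_res)
    df["F"] = f
    df["p_value"] = p
    df.loc[SOURCE_RESIDUAL, ["F", "p_value"]] = np.nan
    return df[["sum_sq", "df", "mean_sq", "F", "p_value"]]


def two_way_anova(table: PhenotypeTable, trait: str) -> pd.DataFrame:
    """Balanced two-way genotype x environment ANOVA for one trait.

    Returns a statsmodels-style table indexed by source (genotype,
    environment, genotype:environment, residual) with columns
    ``sum_sq, df, mean_sq, F, p_value``; every F is tested against the
    residual mean square.
    """
    data, genotypes, envs = _balanced_trait_array(table, trait)
    g, s, r = data.shape
    if s < 2:
        raise UnbalancedDesignError(
            "two-way ANOVA needs at least 2 environments; use one_way_anova"
        )
    grand = data.mean()
    g_means = data.mean(axis=(1, 2))
    e_means = data.mean(axis=(0, 2))
    cell_means = data.mean(axis=2)

    ss_g = s * r * float(((g_means - grand) ** 2).sum())
    ss_e = g * r * float(((e_means - grand) ** 2).sum())
    inter = cell_means - g_means[:, None] - e_means[None, :] + grand
    ss_ge = r * float((inter**2).sum())
    ss_res = float(((data - cell_means[:, :, None]) ** 2).sum())

    rows = [
        {"source": SOURCE_GENOTYPE, "sum_sq": ss_g, "df": g - 1},
        {"source": SOURCE_ENVIRONMENT, "sum_sq": ss_e, "df": s - 1},
        {"source": SOURCE_INTERACTION, "sum_sq": ss_ge, "df": (g - 1) * (s - 1)},
        {"source": SOURCE_RESIDUAL, "sum_sq": ss_res, "df": g * s * (r - 1)},
    ]
    return _anova_frame(rows)


def one_way_anova(
    table: PhenotypeTable, trait: str, environment: str
) -> pd.DataFrame:
    """Balanced one-way genotype ANOVA within a single environment."""
    environment = normalize_environment(environment)
    data, genotypes, envs = _balanced_trait_array(table, trait, environment)
    g, _, r = data.shape
    data = data[:, 0, :]
    grand = data.mean()
    g_means = data.mean(axis=1)
    ss_g = r * float(((g_means - grand) ** 2).sum())
    ss_res = float(((data - g_means[:, None]) ** 2).sum())
    rows = [
        {"source": SOURCE_GENOTYPE, "sum_sq": ss_g, "df": g - 1},
        {"source": SOURCE_RESIDUAL, "sum_sq": ss_res, "df": g * (r - 1)},
    ]
    return _anova_frame(rows)


def variance_components(anova: pd.DataFrame, s: int, r: int) -> VarianceComponents:
    """Expected-mean-squares variance components from a balanced ANOVA table.

    Two-way:  sigma2_e = MS_res;  sigma2_ge = (MS_GxE - MS_res) / r;
              sigma2_g = (MS_G - MS_GxE) / (s * r).
    One-way:  sigma2_e = MS_res;  sigma2_g = (MS_G - MS_res) / r.

    Negative moment estimates are truncated to zero and recorded.
    """
    df_g = int(anova.loc[SOURCE_GENOTYPE, "df"])
    g = df_g + 1
    df_res = int(anova.loc[SOURCE_RESIDUAL, "df"])
    two_way = SOURCE_INTERACTION in anova.index
    expected_res = g * s * (r - 1) if two_way else g * (r - 1)
    if df_res != expected_res:
        raise DesignMismatchError(
            f"residual df {df_res} inconsistent with g={g}, s={s}, r={r} "
            f"(expected {expected_res})"
        )
    ms_res = float(anova.loc[SOURCE_RESIDUAL, "mean_sq"])
    ms_g = float(anova.loc[SOURCE_GENOTYPE, "mean_sq"])
    truncated = []
    if two_way:
        if int(anova.loc[SOURCE_ENVIRONMENT, "df"]) != s - 1:
            raise DesignMismatchError(
                f"environment df {anova.loc[SOURCE_ENVIRONMENT, 'df']} "
                f"inconsistent with s={s}"
            )
        ms_ge = float(anova.loc[SOURCE_INTERACTION, "mean_sq"])
        sigma2_ge = (ms_ge - ms_res) / r
        sigma2_g = (ms_g - ms_ge) / (s * r)
        if sigma2_ge < 0:
            sigma2_ge = 0.0
            truncated.append("sigma2_ge")
    else:
        sigma2_ge = None
        sigma2_g = (ms_g - ms_res) / r
    if sigma2_g < 0:
        sigma2_g = 0.0
        truncated.append("sigma2_g")
    return VarianceComponents(
        sigma2_g=sigma2_g,
        sigma2_ge=sigma2_ge,
        sigma2_e=ms_res,
        s=s,
        r=r,
        truncated=tuple(truncated),
    )


def heritability(
    components: VarianceComponents,
    trait: str = "",
    scope: str = "combined",
    anova: pd.DataFrame | None = None,
) -> HeritabilityResult:
    """Broad-sense heritability (percent) on a genotype-mean basis."""
    c = components
    if c.sigma2_ge is not None:
        denom = c.sigma2_g + c.sigma2_ge / c.s + c.sigma2_e / (c.s * c.r)
    else:
        denom = c.sigma2_g + c.sigma2_e / c.r
    if denom == 0:
        warnings.warn(
            f"trait {trait!r}: all variance components are zero; H set to 0",
            stacklevel=2,
        )
        h = 0.0
    else:
        h = 100.0 * c.sigma2_g / denom
    return HeritabilityResult(
        trait=trait, scope=scope, H=h, components=c, anova=anova
    )


def trait_heritability(
    table: PhenotypeTable, trait: str, scope: str = "combined"
) -> HeritabilityResult:
    """ANOVA -> components -> H for one trait at the requested scope."""
    if scope == "combined":
        anova = two_way_anova(table, trait)
        design = design_summary_of_trait(table, trait)
        comp = variance_components(anova, s=design[0], r=design[1])
    else:
        env = normalize_environment(scope)
        anova = one_way_anova(table, trait, env)
        r = int(anova.loc[SOURCE_RESIDUAL, "df"]) // int(anova.loc[SOURCE_GENOTYPE, "df"] + 1) + 1
        comp = variance_components(anova, s=1, r=r)
        scope = env
    return heritability(comp, trait=trait, scope=scope, anova=anova)


def design_summary_of_trait(table: PhenotypeTable, trait: str) -> tuple[int, int]:
    """(s, r) actually used for one trait after the missing-data policy."""
    data, _, envs = _balanced_trait_array(table, trait)
    return data.shape[1], data.shape[2]


def heritability_table(
    table: PhenotypeTable, scope: str = "combined"
) -> pd.DataFrame:
    """Per-trait heritability summary.

    scope "combined" gives one row per trait from the two-way analysis;
    scope "per-env" gives one row per trait and environment from one-way
    analyses, the route used to compare H under control vs stress.
    """
    rows = []
    scopes = list(ENVIRONMENTS) if scope == "per-env" else [scope]
    for trait in table.traits:
        for sc in scopes:
            res = trait_heritability(table, trait, scope=sc)
            c = res.components
            rows.append(
                {
                    "trait": trait,
                    "scope": res.scope,
                    "sigma2_g": c.sigma2_g,
                    "sigma2_gs": c.sigma2_ge if c.sigma2_ge is not None else np.nan,
                    "sigma2_e": c.sigma2_e,
                    "s": c.s,
                    "r": c.r,
                    "H_percent": res.H,
                    "truncated": ";".join(c.truncated),
                }
            )
    return pd.DataFrame(rows)
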