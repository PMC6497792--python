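"""Trait correlation structure and principal component analysis.

The observation unit for correlations defaults to genotype x environment
cell means (32 rows for the 16-genotype, two-environment design);
replicate-level rows are available via ``level="replicates"``.  PCA runs
on z-scored traits by default because the trait panel mixes centimetres,
percentages, counts and fluorescence units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .io import PhenotypeTable


@dataclass
class CorrelationMatrix:
    """Pairwise-complete Pearson correlations with significance.

    ``r`` holds signed coefficients; ``p`` two-sided p-values from the
    t transform with n-2 degrees of freedom; ``n`` the pairwise sample
    sizes.  Undefined entries (constant trait, < min_n pairs) are NaN.
    """

    traits: list
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame

    def r_squared(self) -> pd.DataFrame:
        """Companion r^2 matrix (the signed r remains the primary output)."""
        return self.r**2

    def to_long(self) -> pd.DataFrame:
        """Tidy long form: trait_a, trait_b, r, r_squared, p, n (upper triangle)."""
        rows = []
        for i, a in enumerate(self.traits):
            for b in self.traits[i + 1 :]:
                rows.append(
                    {
                        "trait_a": a,
                        "trait_b": b,
                        "r": self.r.loc[a, b],
                        "r_squared": self.r.loc[a, b] ** 2,
                        "p": self.p.loc[a, b],
                        "n": self.n.loc[a, b],
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class PcaResult:
    """Classical PCA of the trait matrix.

    ``loadings`` is traits x components with orthonormal columns;
    ``scores`` is observations x components; ``variance_explained`` is in
    percent and sums to 100 over all components.  Sign convention: the
    largest-magnitude loading of each component is positive.
    """

    loadings: pd.DataFrame
    scores: pd.DataFrame
    variance_explained: np.ndarray
    standardized: bool
    trait_means: pd.Series
    trait_scales: pd.Series
    imputed: list


def observation_matrix(table: PhenotypeTable, level: str = "means") -> pd.DataFrame:
    """Wide observations x traits matrix from a long phenotype table.

    level "means": genotype x environment cell means (one row per cell);
    level "replicates": one row per genotype x environment x replicate.
    """
    df = table.data.dropna(subset=["value"])
    if level == "means":
        wide = (
            df.groupby(["genotype", "environment", "trait"], observed=True)["value"]
            .mean()
            .unstack("trait")
        )
    elif level == "replicates":
        wide = df.pivot_table(
            index=["genotype", "environment", "replicate"],
            columns="trait",
            values="value",
            aggfunc="mean",
        )
    else:
        raise ParameterError(f"unknown observation level {level!r}")
    return wide.sort_index()


def correlation_matrix(matrix: pd.DataFrame, min_n: int = 3) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlation over the trait columns.

    p-values use t = r * sqrt((n-2)/(1-r^2)) against Student's t with
    n-2 df; |r| = 1 maps to p = 0.  Pairs with fewer than ``min_n``
    complete observations, or involving a constant trait, are NaN.
    """
    traits = list(matrix.columns)
    k = len(traits)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    values = matrix.to_numpy(dtype=float)
    for i in range(k):
        r[i, i] = 1.0
        p[i, i] = 0.0
        n[i, i] = int(np.isfinite(values[:, i]).sum())
        for j in range(i + 1, k):
            mask = np.isfinite(values[:, i]) & np.isfinite(values[:, j])
            nn = int(mask.sum())
            n[i, j] = n[j, i] = nn
            if nn < max(min_n, 3):
                continue
            x = values[mask, i]
            y = values[mask, j]
            sx = x.std(ddof=0)
            sy = y.std(ddof=0)
            if sx == 0 or sy == 0:
                continue  # constant trait: correlation undefined, left NaN
            rij = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
            rij = float(np.clip(rij, -1.0, 1.0))
            if abs(rij) == 1.0:
                pij = 0.0
            else:
                t = rij * np.sqrt((nn - 2) / (1.0 - rij**2))
                pij = 2.0 * float(stats.t.sf(abs(t), nn - 2))
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    return CorrelationMatrix(
        traits=traits,
        r=pd.DataFrame(r, index=traits, columns=traits),
        p=pd.DataFrame(p, index=traits, columns=traits),
        n=pd.DataFrame(n, index=traits, columns=traits),
    )


def pca(matrix: pd.DataFrame, standardize: bool = True) -> PcaResult:
    """Classical PCA via eigendecomposition of the covariance matrix.

    Missing entries are imputed by the trait (column) mean and recorded.
    With ``standardize`` (the default) traits are z-scored first, i.e. the
    decomposition is of the correlation matrix.  All components are kept,
    so scores @ loadings.T reconstructs the centered/scaled data exactly.
    """
    if matrix.shape[0] < 2:
        raise ParameterError("PCA needs at least 2 observations")
    if matrix.shape[1] < 2:
        raise ParameterError("PCA needs at least 2 traits")
    X = matrix.to_numpy(dtype=float).copy()
    imputed = []
    col_means = np.nanmean(X, axis=0)
    for j in range(X.shape[1]):
        miss = ~np.isfinite(X[:, j])
        if miss.any():
            X[miss, j] = col_means[j]
            imputed.extend(
                (matrix.index[i], matrix.columns[j]) for i in np.where(miss)[0]
            )
    means = X.mean(axis=0)
    Xc = X - means
    if standardize:
        scales = Xc.std(axis=0, ddof=1)
        scales[scales == 0] = 1.0  # constant trait contributes zero variance
        Xc = Xc / scales
    else:
        scales = np.ones(X.shape[1])

    cov = np.cov(Xc, rowvar=False, ddof=1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # Deterministic sign: largest-|loading| entry of each component positive.
    for j in range(eigvec.shape[1]):
        pivot = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[pivot, j] < 0:
            eigvec[:, j] = -eigvec[:, j]

    total = eigval.sum()
    var_exp = 100.0 * eigval / total if total > 0 else np.zeros_like(eigval)
    comps = [f"PC{i + 1}" for i in range(eigvec.shape[1])]
    loadings = pd.DataFrame(eigvec, index=matrix.columns, columns=comps)
    scores = pd.DataFrame(Xc @ eigvec, index=matrix.index, columns=comps)
    return PcaResult(
        loadings=loadings,
        scores=scores,
        variance_explained=var_exp,
        standardized=standardize,
        trait_means=pd.Series(means, index=matrix.columns),
        trait_scales=pd.Series(scales, index=matrix.columns),
        imputed=imputed,
    )
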