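"""Orthogonal environmental gradients via correlation-matrix PCA.

Soil covariates are strongly collinear (moisture with conductivity, pH,
organic C and N; elevation with distance to coast), so models use a small
set of PCA axes of the z-scored covariate table instead of the raw
variables.  Axes are retained up to a target fraction of total variance
(default two thirds).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GradientSet", "standardize", "pca_gradients", "select_axes"]


@dataclass
class GradientSet:
    """PCA axes of standardized covariates: scores, loadings, eigenvalues."""

    scores: pd.DataFrame        # site x axis
    loadings: pd.DataFrame      # variable x axis
    eigenvalues: np.ndarray
    proportion_variance: np.ndarray
    selected: np.ndarray        # boolean mask, leading prefix
    variable_groups: dict[str, str] = field(default_factory=dict)

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    def selected_scores(self) -> pd.DataFrame:
        return self.scores.loc[:, self.selected]


def standardize(table: pd.DataFrame, impute: bool = True) -> pd.DataFrame:
    """z-score each numeric column (mean 0, sample SD 1).

    Missing values are mean-imputed within column (count reported via a
    warning); constant columns are dropped with a warning naming them.
    """
    if len(table) < 2:
        raise ValueError("standardization requires at least two rows")
    df = table.astype(float).copy()
    n_missing = int(df.isna().sum().sum())
    if n_missing:
        if not impute:
            raise ValueError(f"{n_missing} missing values; enable imputation or clean input")
        warnings.warn(f"mean-imputed {n_missing} missing values before PCA")
        df = df.fillna(df.mean())
    sd = df.std(ddof=1)
    constant = sd.index[(sd == 0) | sd.isna()]
    if len(constant) == len(df.columns):
        raise ValueError("all columns are constant; nothing to standardize")
    if len(constant):
        warnings.warn(f"dropped constant columns: {', '.join(map(str, constant))}")
        df = df.drop(columns=constant)
        sd = sd.drop(constant)
    return (df - df.mean()) / sd


def pca_gradients(z: pd.DataFrame,
                  variable_groups: dict[str, str] | None = None) -> GradientSet:
    """PCA of a standardized matrix (equivalently, of the correlation matrix).

    Axes are ordered by decreasing eigenvalue.  Sign convention: on each
    axis the largest-magnitude loading is made positive.
    """
    if z.isna().any().any():
        raise ValueError("missing values present; run standardize() with imputation first")
    x = z.to_numpy(dtype=float)
    n = x.shape[0]
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    eig = s ** 2 / (n - 1)
    loadings = vt.T  # columns are eigenvectors of the correlation matrix
    # fix signs so the dominant loading on each axis is positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = x @ loadings
    prop = eig / eig.sum()
    axes = [f"PC{i + 1}" for i in range(len(eig))]
    return GradientSet(
        scores=pd.DataFrame(scores, index=z.index, columns=axes),
        loadings=pd.DataFrame(loadings, index=z.columns, columns=axes),
        eigenvalues=eig,
        proportion_variance=prop,
        selected=np.ones(len(eig), dtype=bool),
        variable_groups=dict(variable_groups or {}),
    )


def select_axes(g: GradientSet, target_fraction: float = 2 / 3) -> GradientSet:
    """Keep the smallest leading prefix of axes reaching *target_fraction*."""
    if not (0 < target_fraction <= 1):
        raise ValueError(f"target_fraction must be in (0, 1], got {target_fraction}")
    cum = np.cumsum(g.proportion_variance)
    k = int(np.searchsorted(cum, target_fraction - 1e-12) + 1)
    k = min(k, len(cum))
    mask = np.zeros(len(cum), dtype=bool)
    mask[:k] = True
    return GradientSet(
        scores=g.scores, loadings=g.loadings, eigenvalues=g.eigenvalues,
        proportion_variance=g.proportion_variance, selected=mask,
        variable_groups=g.variable_groups,
    )
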