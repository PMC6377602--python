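"""Hellinger transformation, redundancy analysis and variance partitioning.

RDA is multivariate linear regression of a (column-centred) response
matrix on a predictor matrix followed by a PCA of the fitted values.
Applied to Hellinger-transformed abundances it gives a Euclidean
ordination appropriate for species count data.  Variance partitioning
decomposes the adjusted R-squared of three predictor sets (abiotic,
biotic, spatial) into unique and shared fractions by inclusion-exclusion.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .community import CommunityMatrix

__all__ = [
    "RdaResult",
    "VariancePartition",
    "hellinger",
    "rda",
    "adjusted_r2",
    "variance_partition",
    "residual_correlations",
]


@dataclass
class RdaResult:
    """Redundancy-analysis fit of a multivariate response."""

    r2: float
    adj_r2: float
    canonical_eigenvalues: np.ndarray
    fitted: np.ndarray      # site x species (centred scale)
    residuals: np.ndarray   # fitted + residuals = centred response exactly
    permutation_p: float = np.nan
    species: list[str] = field(default_factory=list)

    def residual_frame(self) -> pd.DataFrame:
        cols = self.species or [f"sp{i}" for i in range(self.residuals.shape[1])]
        return pd.DataFrame(self.residuals, columns=cols)


@dataclass
class VariancePartition:
    """Unique/shared adjusted-R2 fractions for three predictor sets.

    Negative shared fractions (possible with adjusted R2) are reported
    as-is and flagged, never truncated.
    """

    unique: dict[str, float]          # a, b, c
    shared_pairwise: dict[str, float]  # "abiotic+biotic", ...
    shared_triple: float
    residual: float
    total_explained: float
    marginal: dict[str, float] = field(default_factory=dict)
    has_negative_fraction: bool = False

    def fractions(self) -> dict[str, float]:
        out = dict(self.unique)
        out.update(self.shared_pairwise)
        out["triple"] = self.shared_triple
        out["residual"] = self.residual
        return out

    def to_dict(self) -> dict:
        return {
            "unique": self.unique,
            "shared_pairwise": self.shared_pairwise,
            "shared_triple": self.shared_triple,
            "residual": self.residual,
            "total_explained": self.total_explained,
            "marginal_adj_r2": self.marginal,
            "has_negative_fraction": self.has_negative_fraction,
        }


def hellinger(cm: CommunityMatrix | np.ndarray) -> np.ndarray:
    """Hellinger transform: sqrt of row-relative abundances.

    Each nonzero row of the result has unit Euclidean norm; all-zero rows
    stay zero (with a warning).
    """
    y = cm.values if isinstance(cm, CommunityMatrix) else np.asarray(cm, dtype=float)
    if (y < 0).any():
        raise ValueError("Hellinger transform requires non-negative abundances")
    rs = y.sum(axis=1)
    zero = rs == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero rows map to zero rows")
    rs = np.where(zero, 1.0, rs)
    return np.sqrt(y / rs[:, None])


def rda(y: np.ndarray, x: np.ndarray, n_perm: int = 0,
        rng_seed: int | None = None,
        species: list[str] | None = None) -> RdaResult:
    """RDA: least squares of column-centred *y* on *x*, PCA of fitted values.

    r2 is SS(fitted)/SS(centred y).  With n_perm > 0 an overall
    permutation test (random row permutations of x) is run.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if y.ndim == 1:
        y = y[:, None]
    if y.shape[0] != x.shape[0]:
        raise ValueError("response and predictors must have aligned rows")
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(x)), x]))
    if rank < x.shape[1] + 1:
        raise ValueError("predictor matrix is rank deficient (aliased columns)")

    yc = y - y.mean(axis=0)
    xc = x - x.mean(axis=0)
    beta, *_ = np.linalg.lstsq(xc, yc, rcond=None)
    fitted = xc @ beta
    resid = yc - fitted
    ss_tot = float((yc ** 2).sum())
    ss_fit = float((fitted ** 2).sum())
    r2 = ss_fit / ss_tot if ss_tot > 0 else 0.0
    n, m = y.shape[0], x.shape[1]
    adj = adjusted_r2(r2, n, m) if n > m + 1 else np.nan
    sv = np.linalg.svd(fitted, compute_uv=False)
    eig = sv ** 2 / (n - 1)
    eig = eig[eig > 1e-12 * max(1.0, eig.max(initial=0.0))]

    p = np.nan
    if n_perm > 0:
        rng = np.random.default_rng(rng_seed)
        count = 0
        for _ in range(n_perm):
            xp = xc[rng.permutation(n)]
            bp, *_ = np.linalg.lstsq(xp, yc, rcond=None)
            if float(((xp @ bp) ** 2).sum()) >= ss_fit:
                count += 1
        p = (count + 1) / (n_perm + 1)

    return RdaResult(r2=r2, adj_r2=adj, canonical_eigenvalues=eig,
                     fitted=fitted, residuals=resid, permutation_p=p,
                     species=list(species or []))


def adjusted_r2(r2: float, n: int, m: int) -> float:
    """Ezekiel adjustment: 1 - (1 - r2)(n - 1)/(n - m - 1)."""
    if n <= m + 1:
        raise ValueError(f"need n > m + 1 (got n={n}, m={m})")
    return 1 - (1 - r2) * (n - 1) / (n - m - 1)


def _adj(y: np.ndarray, xs: list[np.ndarray]) -> float:
    blocks = [x for x in xs if x is not None and x.shape[1] > 0]
    if not blocks:
        return 0.0
    x = np.hstack(blocks)
    res = rda(y, x)
    return float(res.adj_r2)


def variance_partition(
    y: np.ndarray,
    x_abiotic: np.ndarray | None,
    x_biotic: np.ndarray | None,
    x_spatial: np.ndarray | None,
) -> VariancePartition:
    """Three-set variance partitioning on adjusted R2 by inclusion-exclusion.

    Fractions: unique a, b, c for abiotic/biotic/spatial; three pairwise
    shared; one triple shared; residual = 1 - adjR2(all).  The eight
    fractions sum to 1 by construction.
    """
    names = ("abiotic", "biotic", "spatial")
    sets = []
    for nm, xx in zip(names, (x_abiotic, x_biotic, x_spatial)):
        if xx is None or np.size(xx) == 0 or np.asarray(xx).shape[-1] == 0:
            warnings.warn(f"predictor set {nm!r} is empty; its fractions are 0")
            sets.append(None)
        else:
            xx = np.asarray(xx, dtype=float)
            sets.append(xx if xx.ndim == 2 else xx[:, None])
    a, b, c = sets

    r = {}
    for combo in itertools.chain.from_iterable(
            itertools.combinations(range(3), k) for k in (1, 2, 3)):
        r[combo] = _adj(y, [sets[i] for i in combo])

    r_abc = r[(0, 1, 2)]
    # unique fractions: [a] = R(abc) - R(bc), etc.
    unique = {
        "abiotic": r_abc - r[(1, 2)],
        "biotic": r_abc - r[(0, 2)],
        "spatial": r_abc - r[(0, 1)],
    }
    f_a = unique["abiotic"]
    f_b = unique["biotic"]
    f_c = unique["spatial"]
    # pairwise shared (net of the third set) and the triple overlap
    f_d = r_abc - r[(2,)] - f_a - f_b          # abiotic & biotic, not spatial
    f_e = r_abc - r[(0,)] - f_b - f_c          # biotic & spatial, not abiotic
    f_f = r_abc - r[(1,)] - f_a - f_c          # abiotic & spatial, not biotic
    f_g = r_abc - (f_a + f_b + f_c + f_d + f_e + f_f)  # triple
    pair = {
        "abiotic+biotic": f_d,
        "biotic+spatial": f_e,
        "abiotic+spatial": f_f,
    }
    residual = 1 - r_abc
    neg = any(v < 0 for v in [f_d, f_e, f_f, f_g])
    return VariancePartition(
        unique=unique, shared_pairwise=pair, shared_triple=f_g,
        residual=residual, total_explained=r_abc,
        marginal={nm: r[(i,)] for i, nm in enumerate(names)},
        has_negative_fraction=neg,
    )


def residual_correlations(res: RdaResult | pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations between species' RDA residuals, with t-test p.

    Returns one row per unordered pair with columns pair_a, pair_b, r, p.
    Zero-variance residual columns yield NaN for affected pairs.
    """
    frame = res.residual_frame() if isinstance(res, RdaResult) else res
    if len(frame) < 3:
        raise ValueError("residual correlations require at least three sites")
    rows = []
    cols = list(frame.columns)
    for a, b in itertools.combinations(cols, 2):
        xa, xb = frame[a].to_numpy(), frame[b].to_numpy()
        if np.std(xa) == 0 or np.std(xb) == 0:
            rows.append((a, b, np.nan, np.nan))
            continue
        r, p = stats.pearsonr(xa, xb)
        rows.append((a, b, float(r), float(p)))
    return pd.DataFrame(rows, columns=["pair_a", "pair_b", "r", "p"])
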