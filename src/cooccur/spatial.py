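"""Spatial structure: Moran's I correlograms, the spherical correlation
function, PCNM/db-MEM eigenvectors and AIC forward selection.

PCNM (principal coordinates of neighbour matrices, also called db-MEM)
builds orthogonal spatial descriptors at all scales from a truncated
inter-site distance matrix: distances beyond the longest edge of the
minimum spanning tree t are set to 4t, the truncated matrix is
double-centred as in PCoA, and eigenvectors with positive eigenvalues
serve as spatial predictors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "Correlogram",
    "SphericalModel",
    "SpatialEigenvectors",
    "pairwise_distances",
    "morans_i",
    "spherical_corr",
    "build_pcnm",
    "forward_select_aic",
]


@dataclass
class Correlogram:
    """Moran's I per distance class with permutation p-values."""

    class_edges: np.ndarray   # (n_bins + 1,), metres, increasing
    morans_i: np.ndarray      # (n_bins,)
    p_values: np.ndarray      # (n_bins,), two-sided permutation p
    n_pairs: np.ndarray       # (n_bins,)

    def to_dict(self) -> dict:
        return {
            "class_edges": self.class_edges.tolist(),
            "morans_i": [None if np.isnan(v) else float(v) for v in self.morans_i],
            "p_values": [None if np.isnan(v) else float(v) for v in self.p_values],
            "n_pairs": self.n_pairs.tolist(),
        }


@dataclass
class SphericalModel:
    """Spherical spatial correlation: range (m), nugget proportion, sill."""

    range: float
    nugget: float = 0.0
    sill: float = 1.0

    def __post_init__(self) -> None:
        if self.range <= 0:
            raise ValueError("range must be > 0")
        if not (0 <= self.nugget < 1):
            raise ValueError("nugget proportion must be in [0, 1)")


@dataclass
class SpatialEigenvectors:
    """PCNM eigenvectors: site x vector scores, orthonormal, positive eigenvalues."""

    truncation: float
    eigenvalues: np.ndarray
    vectors: np.ndarray               # (n_sites, n_vectors)
    selected: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    selection_path: list = field(default_factory=list)  # [(vector index, AIC)]

    @property
    def n_vectors(self) -> int:
        return self.vectors.shape[1]

    def selected_vectors(self) -> np.ndarray:
        return self.vectors[:, self.selected]


def pairwise_distances(coords: np.ndarray) -> np.ndarray:
    """Symmetric Euclidean distance matrix for planar metre coordinates."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be an (n, 2) array")
    bad = ~np.isfinite(coords).all(axis=1)
    if bad.any():
        raise ValueError(f"non-finite coordinates at rows {list(np.flatnonzero(bad))}")
    if coords.shape[0] == 1:
        return np.zeros((1, 1))
    return squareform(pdist(coords))


def _equal_count_edges(d: np.ndarray, n_classes: int) -> np.ndarray:
    """Distance-class edges with roughly equal pair counts (quantile bins)."""
    pairs = d[np.triu_indices_from(d, k=1)]
    qs = np.linspace(0, 1, n_classes + 1)
    edges = np.quantile(pairs, qs)
    edges[0] = 0.0
    edges[-1] = edges[-1] * (1 + 1e-9)
    return np.unique(edges)


def _moran_stat(z: np.ndarray, w: np.ndarray) -> float:
    n = z.size
    s0 = w.sum()
    return float(n / s0 * (z @ w @ z) / (z @ z))


def morans_i(
    values: np.ndarray,
    coords: np.ndarray,
    class_edges: np.ndarray | None = None,
    n_classes: int = 10,
    n_perm: int = 199,
    rng_seed: int | None = None,
) -> Correlogram:
    """Moran's I correlogram with binary distance-class weights.

    Within each class the weight is 1 for site pairs whose distance falls
    in [low, high) and 0 otherwise.  Significance is assessed by
    permuting site labels (two-sided).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("Moran's I requires at least three sites")
    if np.ptp(values) == 0:
        raise ValueError("variable is constant: Moran's I undefined")
    d = pairwise_distances(coords)
    if class_edges is None:
        class_edges = _equal_count_edges(d, n_classes)
    class_edges = np.asarray(class_edges, dtype=float)
    if np.any(np.diff(class_edges) <= 0):
        raise ValueError("class edges must be strictly increasing")

    z = values - values.mean()
    rng = np.random.default_rng(rng_seed)
    n_bins = len(class_edges) - 1
    eye = np.eye(d.shape[0], dtype=bool)

    iobs = np.full(n_bins, np.nan)
    pvals = np.full(n_bins, np.nan)
    npairs = np.zeros(n_bins, dtype=int)
    perms = np.array([rng.permutation(z) for _ in range(n_perm)])
    for b in range(n_bins):
        w = ((d >= class_edges[b]) & (d < class_edges[b + 1]) & ~eye).astype(float)
        npairs[b] = int(w.sum() // 2)
        if w.sum() == 0:
            continue
        iobs[b] = _moran_stat(z, w)
        ip = np.array([_moran_stat(p, w) for p in perms])
        pvals[b] = (np.sum(np.abs(ip) >= abs(iobs[b])) + 1) / (n_perm + 1)
    return Correlogram(class_edges=class_edges, morans_i=iobs,
                       p_values=pvals, n_pairs=npairs)


def spherical_corr(d, model: SphericalModel):
    """Spherical correlation at distance d: continuous, zero beyond the range.

    corr(d) = (1 - nugget) * (1 - 1.5 h + 0.5 h^3) with h = d / range for
    d < range, and 0 for d >= range; corr(0) = 1 exactly.
    """
    d = np.asarray(d, dtype=float)
    h = np.clip(d / model.range, 0.0, 1.0)
    c = (1 - model.nugget) * (1 - 1.5 * h + 0.5 * h ** 3)
    c = np.where(d >= model.range, 0.0, c)
    c = np.where(d == 0, 1.0, c)
    if c.ndim == 0:
        return float(c)
    return c


def spherical_corr_matrix(d: np.ndarray, model: SphericalModel) -> np.ndarray:
    """Correlation matrix over a distance matrix (unit diagonal)."""
    r = spherical_corr(d, model)
    np.fill_diagonal(r, 1.0)
    return r


def build_pcnm(coords: np.ndarray, tol: float = 1e-10) -> SpatialEigenvectors:
    """PCNM / db-MEM eigenvectors from planar coordinates.

    Truncation t is the longest edge of the minimum spanning tree of the
    distance matrix; larger distances are replaced by 4t before
    double-centring.  Eigenvectors with positive eigenvalues are kept,
    centred and scaled to unit norm.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 4:
        raise ValueError("PCNM requires at least four sites")
    d = pairwise_distances(coords)
    dup = (d + np.eye(len(d)) == 0)
    if dup.any():
        warnings.warn("coincident sites present; PCNM built on jittered distances")
        d = d + 1e-8 * (dup & ~np.eye(len(d), dtype=bool))

    mst = minimum_spanning_tree(d)
    t = float(mst.data.max())
    dt = np.where(d > t, 4 * t, d)
    np.fill_diagonal(dt, 0.0)

    # Gower double-centring of -0.5 * D^2 (classical PCoA)
    a = -0.5 * dt ** 2
    n = len(a)
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    eigval, eigvec = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    keep = eigval > tol * max(1.0, eigval.max())
    eigval, eigvec = eigval[keep], eigvec[:, keep]
    eigvec = eigvec - eigvec.mean(axis=0)
    eigvec = eigvec / np.linalg.norm(eigvec, axis=0)
    return SpatialEigenvectors(truncation=t, eigenvalues=eigval, vectors=eigvec)


def _multivariate_aic(response: np.ndarray, x: np.ndarray, k: int) -> float:
    """Multivariate AIC: n log(RSS_total/n) + 2(k+1) summed over response columns.

    RSS_total pools residual sums of squares over the response columns;
    the parameter penalty is likewise paid once per response column, so
    with m responses the effective penalty is 2 m (k + 1).  The stronger
    penalty is what keeps greedy selection over a large eigenvector pool
    parsimonious (near-zero selections on pure-noise responses).
    """
    n, m = response.shape
    if x.shape[1]:
        beta, *_ = np.linalg.lstsq(x, response, rcond=None)
        resid = response - x @ beta
    else:
        resid = response
    rss = float((resid ** 2).sum())
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2 * m * (k + 1)


def forward_select_aic(response: np.ndarray, sev: SpatialEigenvectors) -> SpatialEigenvectors:
    """Greedy forward selection of PCNM vectors by multivariate AIC.

    At each step the candidate most reducing the AIC of the multi-response
    linear fit (intercept included) is added; selection stops when no
    candidate lowers AIC.  Ties break to the lower vector index.
    """
    y = np.asarray(response, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if y.shape[0] != sev.vectors.shape[0]:
        raise ValueError("response rows must align with eigenvector rows")
    y = y - y.mean(axis=0)
    ones = np.ones((y.shape[0], 1))

    selected: list[int] = []
    path: list[tuple[int, float]] = []
    current = _multivariate_aic(y, ones, 0)
    remaining = list(range(sev.n_vectors))
    while remaining:
        best_aic, best_idx = None, None
        for idx in remaining:
            x = np.hstack([ones, sev.vectors[:, selected + [idx]]])
            aic = _multivariate_aic(y, x, len(selected) + 1)
            if best_aic is None or aic < best_aic - 1e-12:
                best_aic, best_idx = aic, idx
        if best_aic is None or best_aic >= current:
            break
        selected.append(best_idx)
        remaining.remove(best_idx)
        path.append((best_idx, best_aic))
        current = best_aic
    return SpatialEigenvectors(
        truncation=sev.truncation, eigenvalues=sev.eigenvalues,
        vectors=sev.vectors, selected=np.asarray(selected, dtype=int),
        selection_path=path,
    )
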