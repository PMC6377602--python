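"""C-score null models: SIM9 fixed-fixed randomization and effect sizes.

The C-score averages, over all unordered species pairs, the number of
"checkerboard units" (r_i - S)(r_j - S), where r_i and r_j are the two
species' occupancy counts and S the number of sites they share.  Species
that co-occur less often than their occupancies allow produce a high
value.  Its null distribution comes from the SIM9 (fixed-fixed)
randomization: a Markov chain whose elementary move picks a random 2x2
submatrix and, when it is a checkerboard, flips it to the opposite
configuration, preserving every row and column total.  With uniform
submatrix proposals this chain's stationary distribution is uniform over
all matrices with the observed marginals.

Effect sizes are standardized: (observed - null mean) / null SD.
Pairwise segregation/aggregation calls combine per-pair tail tests with
confidence limits built from the pooled distribution of all pairs'
null-standardized scores (an empirical-Bayes style pooling in the spirit
of the Pairs program).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from numba import njit

from .community import PresenceMatrix

__all__ = [
    "NullDistribution",
    "PairResult",
    "checkerboard_units",
    "c_score",
    "sim9_swap",
    "null_distribution",
    "pairwise_tests",
]

#: default burn-in, elementary swap attempts
DEFAULT_BURN_IN = 30_000


@dataclass
class NullDistribution:
    """Observed statistic, its SIM9 null replicates and derived quantities."""

    observed: float
    replicates: np.ndarray
    null_mean: float
    null_sd: float
    ses: float  # (observed - null_mean) / null_sd; NaN when null_sd == 0
    ci_low: float  # empirical 2.5 percentile of replicates
    ci_high: float  # empirical 97.5 percentile
    p_upper: float
    p_lower: float
    n_iter: int
    burn_in: int
    thin: int
    seed: int | None

    def to_dict(self, include_replicates: bool = False) -> dict:
        d = {
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "ses": None if np.isnan(self.ses) else self.ses,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_upper": self.p_upper,
            "p_lower": self.p_lower,
            "n_iter": self.n_iter,
            "burn_in": self.burn_in,
            "thin": self.thin,
            "seed": self.seed,
        }
        if include_replicates:
            d["replicates"] = self.replicates.tolist()
        return d


@dataclass
class PairResult:
    """Per-pair checkerboard-unit test result."""

    pair: tuple[str, str]
    observed_cu: float
    null: NullDistribution
    ses: float
    classification: str  # "segregated" | "aggregated" | "random"
    adjusted_significance: bool = False
    p_value: float = field(default=np.nan)

    def to_dict(self) -> dict:
        return {
            "pair": list(self.pair),
            "observed_cu": self.observed_cu,
            "ses": None if np.isnan(self.ses) else self.ses,
            "classification": self.classification,
            "p_value": None if np.isnan(self.p_value) else self.p_value,
            "adjusted_significance": bool(self.adjusted_significance),
            "null": self.null.to_dict(),
        }


def checkerboard_units(pm: PresenceMatrix, i: str, j: str) -> int:
    """Checkerboard units (r_i - S)(r_j - S) for one species pair."""
    if i == j:
        raise ValueError("checkerboard units require two distinct species")
    occ = pm.occupancy
    for name in (i, j):
        if name not in occ.columns:
            raise KeyError(f"unknown species {name!r}")
    a = occ[i].to_numpy()
    b = occ[j].to_numpy()
    ri = int(a.sum())
    rj = int(b.sum())
    s = int((a & b).sum())
    return (ri - s) * (rj - s)


def _cu_matrix(occ: np.ndarray) -> np.ndarray:
    """Checkerboard units for all unordered pairs of a 0/1 array, flattened."""
    r = occ.sum(axis=0)
    shared = occ.T.astype(np.int64) @ occ.astype(np.int64)
    k = occ.shape[1]
    out = []
    for i, j in itertools.combinations(range(k), 2):
        out.append((r[i] - shared[i, j]) * (r[j] - shared[i, j]))
    return np.asarray(out, dtype=np.int64)


def c_score(pm: PresenceMatrix) -> float:
    """Mean checkerboard units over all unordered species pairs."""
    occ = pm.values
    if occ.shape[1] < 2:
        raise ValueError("C-score requires at least two species")
    return float(_cu_matrix(occ).mean())


@njit(cache=True)
def _run_swaps(occ, r1, r2, c1, c2):  # pragma: no cover - compiled
    """Apply a sequence of elementary SIM9 swap attempts in place."""
    for t in range(r1.shape[0]):
        a, b, c, d = r1[t], r2[t], c1[t], c2[t]
        x = occ[a, c]
        if x == occ[b, d] and x != occ[a, d] and occ[a, d] == occ[b, c]:
            # 2x2 checkerboard: flip to the other configuration
            occ[a, c] = 1 - x
            occ[b, d] = 1 - x
            occ[a, d] = x
            occ[b, c] = x


def _draw_submatrices(rng: np.random.Generator, n: int, n_rows: int, n_cols: int):
    """Pre-draw n random 2x2 submatrices (distinct rows, distinct cols)."""
    r1 = rng.integers(0, n_rows, size=n)
    r2 = (r1 + rng.integers(1, n_rows, size=n)) % n_rows
    c1 = rng.integers(0, n_cols, size=n)
    c2 = (c1 + rng.integers(1, n_cols, size=n)) % n_cols
    return r1, r2, c1, c2


def _swap_chain(occ: np.ndarray, n_attempts: int, rng: np.random.Generator,
                chunk: int = 1_000_000) -> None:
    """Advance the SIM9 chain by n_attempts elementary moves, in place."""
    n_rows, n_cols = occ.shape
    done = 0
    while done < n_attempts:
        m = min(chunk, n_attempts - done)
        r1, r2, c1, c2 = _draw_submatrices(rng, m, n_rows, n_cols)
        _run_swaps(occ, r1, r2, c1, c2)
        done += m


def sim9_swap(pm: PresenceMatrix, n_swaps: int, rng_seed: int | None = None) -> PresenceMatrix:
    """Apply *n_swaps* elementary SIM9 swap attempts to a presence matrix.

    Row and column sums are preserved exactly; attempts that do not hit a
    checkerboard 2x2 submatrix are no-ops that still count.
    """
    if n_swaps < 0:
        raise ValueError("n_swaps must be >= 0")
    occ = pm.values.copy()
    if n_swaps and min(occ.shape) >= 2:
        rng = np.random.default_rng(rng_seed)
        _swap_chain(occ, n_swaps, rng)
    out = pm.occupancy.copy()
    out.iloc[:, :] = occ
    return PresenceMatrix(out, filtered=pm.filtered)


def _tail_stats(observed: float, reps: np.ndarray):
    n = reps.size
    mean = float(reps.mean())
    sd = float(reps.std(ddof=1)) if n > 1 else 0.0
    ses = (observed - mean) / sd if sd > 0 else float("nan")
    lo, hi = np.percentile(reps, [2.5, 97.5])
    # ties count toward the extreme tail (conservative)
    p_up = (np.sum(reps >= observed) + 1) / (n + 1)
    p_lo = (np.sum(reps <= observed) + 1) / (n + 1)
    return mean, sd, ses, float(lo), float(hi), float(p_up), float(p_lo)


def _harvest_chain(
    occ: np.ndarray,
    n_iter: int,
    burn_in: int,
    thin: int,
    rng: np.random.Generator,
    collect: Callable[[np.ndarray], np.ndarray],
) -> np.ndarray:
    """Run one SIM9 chain, applying *collect* to every thinned state."""
    work = occ.copy()
    _swap_chain(work, burn_in, rng)
    first = np.atleast_1d(np.asarray(collect(work), dtype=float))
    out = np.empty((n_iter,) + first.shape, dtype=float)
    out[0] = first
    for it in range(1, n_iter):
        _swap_chain(work, thin, rng)
        out[it] = np.atleast_1d(np.asarray(collect(work), dtype=float))
    return out


def null_distribution(
    pm: PresenceMatrix,
    statistic: Callable[[PresenceMatrix], float] | None = None,
    n_iter: int = 5000,
    burn_in: int = DEFAULT_BURN_IN,
    thin: int | None = None,
    rng_seed: int | None = None,
) -> NullDistribution:
    """SIM9 null distribution of *statistic* (default: the C-score).

    A single swap chain is run; after *burn_in* elementary attempts one
    replicate is recorded every *thin* attempts (default: one per matrix
    cell).  Fully reproducible from *rng_seed*.
    """
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2")
    occ = pm.values
    if thin is None:
        thin = occ.size
    stat = statistic if statistic is not None else c_score

    def wrap(arr: np.ndarray) -> float:
        view = PresenceMatrix(
            pm.occupancy.copy().astype(np.int8), filtered=pm.filtered
        )
        view.occupancy.iloc[:, :] = arr
        return float(stat(view))

    # fast path: the default C-score works on the raw array directly
    if statistic is None:
        collect = lambda arr: _cu_matrix(arr).mean()
        observed = c_score(pm)
    else:
        collect = wrap
        observed = float(stat(pm))

    rng = np.random.default_rng(rng_seed)
    if min(occ.shape) < 2:
        warnings.warn("matrix has no swappable 2x2 submatrices; null is degenerate")
        reps = np.full(n_iter, observed)
    else:
        reps = _harvest_chain(occ, n_iter, burn_in, thin, rng, collect).ravel()
        if np.allclose(reps, reps[0]) and np.isclose(reps[0], observed):
            warnings.warn("swap chain never moved: degenerate marginals")

    mean, sd, ses, lo, hi, p_up, p_lo = _tail_stats(observed, reps)
    return NullDistribution(
        observed=observed, replicates=reps, null_mean=mean, null_sd=sd,
        ses=ses, ci_low=lo, ci_high=hi, p_upper=p_up, p_lower=p_lo,
        n_iter=n_iter, burn_in=burn_in, thin=thin, seed=rng_seed,
    )


def _bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out


def pairwise_tests(
    pm: PresenceMatrix,
    n_iter: int = 5000,
    alpha: float = 0.05,
    rng_seed: int | None = None,
    burn_in: int = DEFAULT_BURN_IN,
    thin: int | None = None,
) -> list[PairResult]:
    """Per-pair checkerboard-unit tests with empirical-Bayes pooled limits.

    All pairs' null replicates are harvested from the same SIM9 chain.
    A pair is called non-random only when (a) its standardized observed
    score falls outside confidence limits built from the pooled
    distribution of every pair's null-standardized scores and (b) its own
    tail p-value is at most *alpha*.  Segregated pairs have positive SES,
    aggregated pairs negative SES.
    """
    if not (0 < alpha <= 0.5):
        raise ValueError(f"alpha must be in (0, 0.5], got {alpha}")
    occ = pm.values
    if occ.shape[1] < 2:
        raise ValueError("pairwise tests require at least two species")
    if thin is None:
        thin = occ.size

    names = pm.species
    pairs = list(itertools.combinations(range(len(names)), 2))
    observed_cu = _cu_matrix(occ).astype(float)

    rng = np.random.default_rng(rng_seed)
    reps = _harvest_chain(occ, n_iter, burn_in, thin, rng, _cu_matrix)
    # reps: (n_iter, n_pairs)

    # per-pair standardization of the null replicates
    means = reps.mean(axis=0)
    sds = reps.std(axis=0, ddof=1)
    safe = np.where(sds > 0, sds, np.nan)
    z_null = (reps - means) / safe  # (n_iter, n_pairs)
    z_obs = (observed_cu - means) / safe

    pooled = z_null[:, np.isfinite(safe)].ravel()
    if pooled.size:
        lim_lo, lim_hi = np.percentile(pooled, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    else:  # all pairs degenerate
        lim_lo, lim_hi = -np.inf, np.inf

    results: list[PairResult] = []
    p_two = []
    for k, (i, j) in enumerate(pairs):
        mean, sd, ses, lo, hi, p_up, p_lo = _tail_stats(observed_cu[k], reps[:, k])
        p_two.append(min(1.0, 2 * min(p_up, p_lo)))
        nd = NullDistribution(
            observed=observed_cu[k], replicates=reps[:, k], null_mean=mean,
            null_sd=sd, ses=ses, ci_low=lo, ci_high=hi, p_upper=p_up,
            p_lower=p_lo, n_iter=n_iter, burn_in=burn_in, thin=thin,
            seed=rng_seed,
        )
        if np.isnan(ses):
            cls = "random"
        elif z_obs[k] > lim_hi and p_up <= alpha:
            cls = "segregated"
        elif z_obs[k] < lim_lo and p_lo <= alpha:
            cls = "aggregated"
        else:
            cls = "random"
        results.append(PairResult(
            pair=(names[i], names[j]), observed_cu=float(observed_cu[k]),
            null=nd, ses=ses, classification=cls, p_value=p_two[-1],
        ))

    adj = _bh_adjust(p_two)
    for res, pa in zip(results, adj):
        res.adjusted_significance = bool(pa <= alpha)
    return results
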