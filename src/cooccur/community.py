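"""Site tables, abundance matrices and presence/absence views.

The in-memory containers are thin wrappers around pandas objects: a
:class:`SiteTable` holds one row per sampling point (coordinates plus the
abiotic and biotic covariates measured there), a :class:`CommunityMatrix`
holds site x species abundances (individuals per kg dry soil), and a
:class:`PresenceMatrix` is its binary occupancy view.  The descriptive
co-occurrence counts used throughout the analysis (per-species occupancy,
pairwise co-occurrence, richness histogram) live in
:class:`CooccurrenceSummary`.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SiteTable",
    "CommunityMatrix",
    "PresenceMatrix",
    "CooccurrenceSummary",
    "load_site_table",
    "load_community_matrix",
    "save_community_matrix",
    "to_presence",
    "filter_occupied_sites",
    "cooccurrence_counts",
]

#: column names a site table must provide
MANDATORY_SITE_COLUMNS = ("site_id", "x", "y")

#: reporting order for the three focal nematode species
DEFAULT_SPECIES_ORDER = ("Scottnema", "Eudorylaimus", "Plectus")


class SchemaError(ValueError):
    """A tabular input violates the expected schema."""


@dataclass
class SiteTable:
    """One row per sampling point: coordinates and environmental covariates.

    Coordinates are planar-projected metres; geographic input must be
    projected before loading.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        for col in MANDATORY_SITE_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"site table is missing mandatory column {col!r}")
        dup = df["site_id"][df["site_id"].duplicated()]
        if len(dup):
            raise SchemaError(
                "duplicated site_id values: " + ", ".join(map(str, dup.unique()))
            )
        xy = df[["x", "y"]].to_numpy(dtype=float)
        bad = ~np.isfinite(xy).all(axis=1)
        if bad.any():
            raise SchemaError(
                f"non-finite coordinates at row indices {list(np.flatnonzero(bad))}"
            )

    @property
    def site_ids(self) -> list[str]:
        return self.data["site_id"].astype(str).tolist()

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of projected x/y in metres."""
        return self.data[["x", "y"]].to_numpy(dtype=float)

    def numeric_columns(self, exclude: tuple[str, ...] = ("x", "y")) -> pd.DataFrame:
        """Numeric covariates indexed by site_id, excluding coordinates."""
        df = self.data.set_index("site_id")
        num = df.select_dtypes(include=[np.number])
        return num.drop(columns=[c for c in exclude if c in num.columns])

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class CommunityMatrix:
    """Site x species abundances, individuals per kg dry soil."""

    abundance: pd.DataFrame  # index = site ids, columns = species

    def __post_init__(self) -> None:
        vals = self.abundance.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError("abundance matrix contains non-finite entries")
        if (vals < 0).any():
            raise ValueError("abundance matrix contains negative entries")

    @property
    def sites(self) -> list[str]:
        return [str(s) for s in self.abundance.index]

    @property
    def species(self) -> list[str]:
        return [str(s) for s in self.abundance.columns]

    @property
    def values(self) -> np.ndarray:
        return self.abundance.to_numpy(dtype=float)


@dataclass
class PresenceMatrix:
    """Binary site x species occupancy.

    ``filtered`` records whether zero-richness sites have been dropped.
    """

    occupancy: pd.DataFrame  # index = site ids, columns = species, values in {0, 1}
    filtered: bool = False

    def __post_init__(self) -> None:
        vals = self.occupancy.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("occupancy entries must be 0 or 1")
        self.occupancy = self.occupancy.astype(np.int8)

    @property
    def sites(self) -> list[str]:
        return [str(s) for s in self.occupancy.index]

    @property
    def species(self) -> list[str]:
        return [str(s) for s in self.occupancy.columns]

    @property
    def values(self) -> np.ndarray:
        return self.occupancy.to_numpy(dtype=np.int8)

    def occupancy_counts(self) -> pd.Series:
        return self.occupancy.sum(axis=0)

    def richness(self) -> pd.Series:
        return self.occupancy.sum(axis=1)


@dataclass
class CooccurrenceSummary:
    """Descriptive co-occurrence counts for a presence matrix."""

    n_sites: int
    species_occupancy: dict[str, int]
    pair_cooccurrence: dict[tuple[str, str], int]
    richness_histogram: dict[int, int] = field(default_factory=dict)

    @property
    def n_sites_two_plus(self) -> int:
        return sum(v for k, v in self.richness_histogram.items() if k >= 2)

    @property
    def n_sites_all(self) -> int:
        k = len(self.species_occupancy)
        return self.richness_histogram.get(k, 0)

    def to_dict(self) -> dict:
        return {
            "n_sites": self.n_sites,
            "species_occupancy": dict(self.species_occupancy),
            "pair_cooccurrence": {
                f"{a}|{b}": v for (a, b), v in self.pair_cooccurrence.items()
            },
            "richness_histogram": {str(k): v for k, v in self.richness_histogram.items()},
            "n_sites_two_plus": self.n_sites_two_plus,
            "n_sites_all": self.n_sites_all,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def load_site_table(path) -> SiteTable:
    """Read a site table from CSV (header row, '.' decimal point).

    Rows with missing coordinates are rejected with their row indices
    reported; missing mandatory columns raise :class:`SchemaError`.
    """
    df = pd.read_csv(path)
    for col in MANDATORY_SITE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"site table {path} is missing mandatory column {col!r}")
    missing = df[["x", "y"]].isna().any(axis=1)
    if missing.any():
        raise SchemaError(
            f"rows with missing coordinates: {list(df.index[missing])}"
        )
    return SiteTable(df)


def save_site_table(table: SiteTable, path) -> None:
    table.data.to_csv(path, index=False)


def load_community_matrix(path) -> CommunityMatrix:
    """Read a site x species abundance matrix from CSV (first column = site id)."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    return CommunityMatrix(df)


def save_community_matrix(cm: CommunityMatrix, path) -> None:
    """Write abundances to CSV with 17 significant digits (round-trip exact)."""
    cm.abundance.to_csv(path, float_format="%.17g")


def to_presence(cm: CommunityMatrix, threshold: float = 0.0) -> PresenceMatrix:
    """Binary occupancy view: present iff abundance strictly exceeds *threshold*."""
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    occ = (cm.abundance > threshold).astype(np.int8)
    return PresenceMatrix(occ, filtered=False)


def filter_occupied_sites(pm: PresenceMatrix) -> PresenceMatrix:
    """Drop sites where no species occurs; site order is preserved."""
    keep = pm.occupancy.sum(axis=1) > 0
    return PresenceMatrix(pm.occupancy.loc[keep], filtered=True)


def cooccurrence_counts(pm: PresenceMatrix) -> CooccurrenceSummary:
    """Per-species occupancy, pairwise co-occurrence and richness histogram."""
    occ = pm.occupancy
    counts = occ.sum(axis=0)
    pairs: dict[tuple[str, str], int] = {}
    for a, b in itertools.combinations(occ.columns, 2):
        pairs[(str(a), str(b))] = int((occ[a] & occ[b]).sum())
    richness = occ.sum(axis=1)
    hist = {
        k: int((richness == k).sum()) for k in range(occ.shape[1] + 1)
    }
    if not pm.filtered and hist.get(0, 0) > 0:
        warnings.warn(
            "presence matrix contains zero-richness sites; "
            "call filter_occupied_sites() first for occupied-site summaries",
            stacklevel=2,
        )
    return CooccurrenceSummary(
        n_sites=int(occ.shape[0]),
        species_occupancy={str(s): int(counts[s]) for s in occ.columns},
        pair_cooccurrence=pairs,
        richness_histogram=hist,
    )
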