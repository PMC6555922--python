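"""Core containers: genotype matrix, locus metadata, population map, sites.

Genotypes are diploid biallelic allele dosages (count of alternate alleles,
0/1/2) stored in an individuals x loci int8 matrix.  Missing calls use the
sentinel :data:`MISSING` (-1), which is outside the valid dosage range.
Locus metadata (RAD tag id, scaffold, 1-based position, alleles) lives in a
pandas DataFrame indexed by locus id, one row per locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: sentinel for a missing diploid genotype call; outside {0, 1, 2}
MISSING: int = -1

LOCUS_COLUMNS = ["tag_id", "scaffold", "position", "ref", "alt", "n_alleles"]


def make_locus_table(
    locus_ids: Sequence[str],
    tag_ids: Sequence | None = None,
    scaffolds: Sequence | None = None,
    positions: Sequence | None = None,
    ref: Sequence | None = None,
    alt: Sequence | None = None,
    n_alleles: Sequence | None = None,
) -> pd.DataFrame:
    """Assemble a locus metadata table (index: locus_id).

    Positions are 1-based inclusive, the convention of every on-disk format
    this package reads or writes; half-open window arithmetic converts at
    the boundary (see :mod:`ctenopop.windows`).
    """
    n = len(locus_ids)

    def _col(x, default):
        return list(x) if x is not None else [default] * n

    tab = pd.DataFrame(
        {
            "tag_id": _col(tag_ids, ""),
            "scaffold": _col(scaffolds, ""),
            "position": _col(positions, 0),
            "ref": _col(ref, "A"),
            "alt": _col(alt, "T"),
            "n_alleles": _col(n_alleles, 2),
        },
        index=pd.Index(locus_ids, name="locus_id"),
    )
    if tab.index.has_duplicates:
        dupes = tab.index[tab.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate locus ids: {dupes[:5]}")
    return tab


@dataclass
class GenotypeMatrix:
    """Individuals x loci diploid allele-dosage matrix with metadata.

    Attributes
    ----------
    individuals : list of str
        Ordered, unique individual ids (rows).
    loci : pandas.DataFrame
        Locus metadata indexed by unique locus id (columns), in column
        order.  Columns: tag_id, scaffold, position, ref, alt, n_alleles.
    dosage : ndarray of int8, shape (n_individuals, n_loci)
        Count of alternate alleles, 0/1/2, or :data:`MISSING`.
    """

    individuals: list
    loci: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.individuals = list(self.individuals)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.individuals), len(self.loci)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.loci)} loci"
            )
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("duplicate individual ids")
        if self.loci.index.has_duplicates:
            raise ValueError("duplicate locus ids")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage entries must be in {0,1,2} or MISSING")

    # -- basic geometry -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> np.ndarray:
        return self.loci.index.to_numpy()

    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    # -- subsetting (pure projections; genotypes are never altered) -----
    def take_loci(self, which) -> "GenotypeMatrix":
        """Subset columns.  `which` may be a boolean mask over columns,
        integer positions, or locus ids."""
        idx = self._locus_indexer(which)
        return GenotypeMatrix(self.individuals, self.loci.iloc[idx], self.dosage[:, idx])

    def take_individuals(self, which) -> "GenotypeMatrix":
        if isinstance(which, np.ndarray) and which.dtype == bool:
            idx = np.flatnonzero(which)
        else:
            lookup = {ind: i for i, ind in enumerate(self.individuals)}
            which = list(which)
            if which and isinstance(which[0], (str, np.str_)):
                idx = np.array([lookup[w] for w in which], dtype=int)
            else:
                idx = np.asarray(which, dtype=int)
        return GenotypeMatrix(
            [self.individuals[i] for i in idx], self.loci, self.dosage[idx, :]
        )

    def _locus_indexer(self, which) -> np.ndarray:
        arr = np.asarray(which)
        if arr.dtype == bool:
            if arr.shape != (self.n_loci,):
                raise ValueError("boolean locus mask of wrong length")
            return np.flatnonzero(arr)
        if arr.dtype.kind in "US":
            pos = self.loci.index.get_indexer(arr)
            if (pos < 0).any():
                raise KeyError("unknown locus ids in selection")
            return pos
        return arr.astype(int)

    # -- frequencies ----------------------------------------------------
    def allele_counts(self, rows: np.ndarray | None = None):
        """(alt allele count, called allele count) per locus over `rows`
        (default: all individuals).  Missing genotypes contribute nothing."""
        d = self.dosage if rows is None else self.dosage[rows]
        called = d != MISSING
        alt = np.where(called, d, 0).sum(axis=0).astype(float)
        tot = 2.0 * called.sum(axis=0)
        return alt, tot

    def alt_freq(self, rows: np.ndarray | None = None) -> np.ndarray:
        """Pooled alternate-allele frequency per locus; NaN where no calls."""
        alt, tot = self.allele_counts(rows)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, alt / tot, np.nan)

    def minor_allele_freq(self, rows: np.ndarray | None = None) -> np.ndarray:
        p = self.alt_freq(rows)
        return np.minimum(p, 1.0 - p)


@dataclass
class PopulationMap:
    """individual -> population, population -> river-system group, native flag."""

    population_of: "pd.Series"  # index: individual id
    group_of: "pd.Series"  # index: population label
    native: "pd.Series"  # index: population label, bool

    def __post_init__(self):
        self.population_of = pd.Series(self.population_of)
        self.group_of = pd.Series(self.group_of)
        self.native = pd.Series(self.native).astype(bool)
        if self.population_of.index.has_duplicates:
            raise ValueError("duplicate individual ids in population map")
        missing = set(self.population_of.unique()) - set(self.group_of.index)
        if missing:
            raise ValueError(f"populations without a group: {sorted(missing)}")

    @property
    def populations(self) -> list:
        """Population labels in first-appearance order."""
        return list(dict.fromkeys(self.population_of))

    def individuals_of(self, population: str) -> list:
        return list(self.population_of.index[self.population_of == population])

    def row_indices(self, g: GenotypeMatrix) -> dict:
        """population -> integer row indices into `g`.

        Raises if any individual of `g` is absent from the map.
        """
        absent = [i for i in g.individuals if i not in self.population_of.index]
        if absent:
            raise KeyError(f"individuals missing from population map: {absent[:10]}")
        pops = self.population_of.reindex(g.individuals).to_numpy()
        out: dict = {}
        for p in self.populations:
            rows = np.flatnonzero(pops == p)
            if rows.size:
                out[p] = rows
        for p, rows in out.items():
            if rows.size == 0:
                raise ValueError(f"population {p} has no individuals")
        return out

    def subset(self, populations: Iterable[str]) -> "PopulationMap":
        keep = list(populations)
        mask = self.population_of.isin(keep)
        return PopulationMap(
            self.population_of[mask],
            self.group_of.loc[keep],
            self.native.loc[keep],
        )


@dataclass
class SiteTable:
    """Per-population sampling-site covariates.

    DataFrame indexed by population with columns latitude (deg), longitude
    (deg) and temp_c (annual mean air temperature, degrees Celsius).
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = pd.DataFrame(self.table)
        need = {"latitude", "longitude"}
        if not need.issubset(t.columns):
            raise ValueError(f"site table needs columns {sorted(need)}")
        if ((t["latitude"] < -90) | (t["latitude"] > 90)).any():
            raise ValueError("latitude outside [-90, 90]")
        if ((t["longitude"] < -180) | (t["longitude"] > 180)).any():
            raise ValueError("longitude outside [-180, 180]")
        self.table = t

    @property
    def populations(self) -> list:
        return list(self.table.index)

    def covariate(self, name: str, populations: Sequence[str]) -> np.ndarray:
        if name not in self.table.columns:
            raise KeyError(f"site table has no covariate {name!r}")
        vals = self.table[name].reindex(list(populations))
        if vals.isna().any():
            missing = list(vals.index[vals.isna()])
            raise ValueError(
                f"covariate {name!r} missing for populations {missing}; "
                "a selection-scan stage requires it"
            )
        return vals.to_numpy(dtype=float)


@dataclass
class RunConfig:
    """Seeds, filter thresholds and output plumbing shared across stages."""

    seed: int = 0
    call_rate_min: float = 0.7
    hwe_alpha: float = 0.01
    maf_min: float = 0.05
    missing_max: float = 0.05
    ld_r2_max: float = 0.05
    outdir: str = "results"
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("call_rate_min", "hwe_alpha", "maf_min", "missing_max", "ld_r2_max"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
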