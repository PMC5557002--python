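"""Species locality data: deduplication, pseudo-occurrence augmentation, splits.

Niche models need a minimum number of localities per species; rare taxa are
brought up to that minimum by adding "pseudo-occurrences" displaced 1 km from
true localities, following fixed per-count rules:

* 5-9 true localities: pseudo points 1 km east of randomly chosen true points
  until the minimum is reached;
* 2-4 true localities: pseudo points 1 km east/west/north/south, cycling over
  the true points in input order until the minimum is reached;
* a single true locality: pseudo points at 1 km and 2 km in each cardinal
  direction plus one extra point 3 km east (9 pseudo points, 10 total).

Kilometres are converted to degrees on a spherical earth of radius 6371.0 km,
so 1 degree of latitude is 111.195 km and 1 degree of longitude is
111.195 * cos(lat) km.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "OccurrenceRecord",
    "OccurrenceSet",
    "deduplicate",
    "augment_pseudo",
    "train_test_split",
    "read_occurrences",
    "write_occurrences",
    "KM_PER_DEGREE",
]

EARTH_RADIUS_KM = 6371.0
KM_PER_DEGREE = EARTH_RADIUS_KM * np.pi / 180.0  # 111.195 km


@dataclass(frozen=True)
class OccurrenceRecord:
    species: str
    lon: float
    lat: float
    provenance: Literal["true", "pseudo"] = "true"
    source: str = ""

    def __post_init__(self):
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude out of range: {self.lon}")
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude out of range: {self.lat}")


class OccurrenceSet:
    """Collection of occurrence records with per-species true/pseudo counts."""

    def __init__(self, records: Iterable[OccurrenceRecord]):
        self.records: list[OccurrenceRecord] = list(records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def species(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.species, None)
        return list(seen)

    def for_species(self, species: str) -> list[OccurrenceRecord]:
        return [r for r in self.records if r.species == species]

    def counts(self) -> pd.DataFrame:
        """Per-species n_true / n_pseudo / n_total table."""
        rows = []
        for sp in self.species:
            recs = self.for_species(sp)
            n_true = sum(r.provenance == "true" for r in recs)
            rows.append({"species": sp, "n_true": n_true,
                         "n_pseudo": len(recs) - n_true, "n_total": len(recs)})
        return pd.DataFrame(rows, columns=["species", "n_true", "n_pseudo", "n_total"])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.species, r.lon, r.lat, r.provenance, r.source) for r in self.records],
            columns=["species", "lon", "lat", "provenance", "source"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "OccurrenceSet":
        recs = []
        for row in df.itertuples(index=False):
            prov = getattr(row, "provenance", "true")
            src = getattr(row, "source", "")
            recs.append(OccurrenceRecord(str(row.species), float(row.lon), float(row.lat),
                                         prov if isinstance(prov, str) else "true",
                                         src if isinstance(src, str) else ""))
        return cls(recs)


def read_occurrences(path: str | Path) -> OccurrenceSet:
    return OccurrenceSet.from_frame(pd.read_csv(path))


def write_occurrences(occ: OccurrenceSet, path: str | Path) -> None:
    occ.to_frame().to_csv(path, index=False)


def deduplicate(records: Iterable[OccurrenceRecord]) -> tuple[OccurrenceSet, list[OccurrenceRecord]]:
    """Collapse exact (species, lon, lat) duplicates, keeping first occurrence.

    Returns the deduplicated set and the list of removed records (the log).
    Identical coordinates in different species are both retained.
    """
    seen: set[tuple[str, float, float]] = set()
    kept, removed = [], []
    for r in records:
        key = (r.species, r.lon, r.lat)
        if key in seen:
            removed.append(r)
        else:
            seen.add(key)
            kept.append(r)
    return OccurrenceSet(kept), removed


def _offset(lon: float, lat: float, km_east: float = 0.0, km_north: float = 0.0) -> tuple[float, float]:
    """Displace a point by kilometres east/north on the spherical earth."""
    dlat = km_north / KM_PER_DEGREE
    dlon = km_east / (KM_PER_DEGREE * np.cos(np.radians(lat)))
    return lon + dlon, lat + dlat


def _pseudo(rec: OccurrenceRecord, km_east: float = 0.0, km_north: float = 0.0) -> OccurrenceRecord:
    lon, lat = _offset(rec.lon, rec.lat, km_east, km_north)
    return OccurrenceRecord(rec.species, lon, lat, "pseudo", f"pseudo:{rec.lon},{rec.lat}")


_CARDINAL = (("E", 1, 0), ("W", -1, 0), ("N", 0, 1), ("S", 0, -1))


def augment_pseudo(occ: OccurrenceSet, min_n: int = 10, seed: int = 0) -> OccurrenceSet:
    """Add pseudo-occurrences to bring every species up to ``min_n`` localities.

    Species already at or above ``min_n`` true localities are unchanged
    (the operation is idempotent for them).  See the module docstring for
    the per-count rules.  Raises on a species with zero records.
    """
    rng = np.random.default_rng(seed)
    out: list[OccurrenceRecord] = []
    for sp in occ.species:
        recs = [r for r in occ.for_species(sp) if r.provenance == "true"]
        if not recs:
            raise ValueError(f"species {sp!r} has no true records")
        out.extend(recs)
        k = len(recs)
        if k >= min_n:
            continue
        if k == 1:
            base = recs[0]
            for km in (1.0, 2.0):
                for _, de, dn in _CARDINAL:
                    out.append(_pseudo(base, km * de, km * dn))
            out.append(_pseudo(base, 3.0, 0.0))
        elif k <= 4:
            # cycle true points in input order; each contributes E, W, N, S
            # in that fixed order; stop as soon as the minimum is reached
            total = k
            ptr = 0
            while total < min_n:
                base = recs[ptr % k]
                _, de, dn = _CARDINAL[(ptr // k) % 4]
                out.append(_pseudo(base, float(de), float(dn)))
                ptr += 1
                total += 1
        else:  # 5-9 true localities: 1 km east of randomly selected true points
            total = k
            pool = list(range(k))
            rng.shuffle(pool)
            ptr = 0
            while total < min_n:
                if ptr >= len(pool):  # exhausted without replacement; continue with replacement
                    pool.extend(rng.integers(0, k, size=min_n).tolist())
                base = recs[pool[ptr]]
                out.append(_pseudo(base, 1.0, 0.0))
                ptr += 1
                total += 1
    return OccurrenceSet(out)


def train_test_split(
    occ: OccurrenceSet, train_frac: float = 0.75, seed: int = 0
) -> tuple[OccurrenceSet, OccurrenceSet]:
    """Random per-species split into training and testing sets.

    Per species the training size is ``round(train_frac * n)`` (nearest
    integer, ties to even) and the rest is the test set.  Deterministic under
    a seed.  Species with fewer than 4 localities are refused by name.
    """
    rng = np.random.default_rng(seed)
    train, test = [], []
    for sp in occ.species:
        recs = occ.for_species(sp)
        n = len(recs)
        if n < 4 and train_frac < 1.0:
            raise ValueError(f"species {sp!r} has only {n} localities; need >= 4 to split")
        n_train = int(round(train_frac * n))
        idx = rng.permutation(n)
        chosen = set(idx[:n_train].tolist())
        for i, r in enumerate(recs):
            (train if i in chosen else test).append(r)
    return OccurrenceSet(train), OccurrenceSet(test)
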