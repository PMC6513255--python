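"""Occurrence-record ingestion, validation, deduplication and breeding
classification.

A record is a georeferenced eagle observation (WGS84 decimal degrees) with
one of four breeding-evidence codes.  Evidence of breeding is any of:
fledgling (greyish-white) plumage, an adult with brown breast coloration
from nest contact, or any individual recorded at a nest.  A record with
code ``none`` is a non-breeding observation.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .environment import RasterGrid

BREEDING_CODES = ("fledgling_plumage", "brown_breast", "at_nest")
EVIDENCE_CODES = BREEDING_CODES + ("none",)

CSV_HEADER = ["id", "longitude", "latitude", "source", "breeding_evidence", "date"]


class FormatError(ValueError):
    """Raised when an occurrence CSV does not match the expected schema."""


@dataclass(frozen=True)
class OccurrenceRecord:
    id: str
    longitude: float
    latitude: float
    source: str = ""
    breeding_evidence: str = "none"
    date: Optional[str] = None  # ISO date or None

    def __post_init__(self):
        if self.breeding_evidence not in EVIDENCE_CODES:
            raise ValueError(f"unknown breeding_evidence {self.breeding_evidence!r}")

    @property
    def is_breeding(self) -> bool:
        return self.breeding_evidence != "none"


@dataclass
class OccurrenceSet:
    """Ordered record collection plus an ingestion/filter provenance log."""

    records: list[OccurrenceRecord] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(CSV_HEADER)
            for r in self.records:
                w.writerow(
                    [r.id, repr(r.longitude), repr(r.latitude), r.source,
                     r.breeding_evidence, r.date or ""]
                )

    def write_provenance(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.provenance, indent=1))


def read_occurrences_csv(path: str | Path) -> OccurrenceSet:
    """Read an occurrence CSV, dropping (and counting) malformed rows.

    Rows with unparseable coordinates or coordinates outside the valid
    lon/lat ranges are dropped; drop counts land in ``provenance``.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            warnings.warn(f"empty occurrence file: {path}")
            return OccurrenceSet([], {"file": str(path), "n_rows": 0})
        missing = {"id", "longitude", "latitude", "breeding_evidence"} - set(reader.fieldnames)
        if missing:
            raise FormatError(f"missing required columns {sorted(missing)} in {path}")
        records: list[OccurrenceRecord] = []
        n_bad_coord, n_bad_evidence, n_rows = 0, 0, 0
        for row in reader:
            n_rows += 1
            try:
                lon = float(row["longitude"])
                lat = float(row["latitude"])
            except (TypeError, ValueError):
                n_bad_coord += 1
                continue
            if not (-180.0 <= lon <= 180.0 and -90.0 <= lat <= 90.0):
                n_bad_coord += 1
                continue
            ev = (row.get("breeding_evidence") or "none").strip()
            if ev not in EVIDENCE_CODES:
                n_bad_evidence += 1
                continue
            records.append(
                OccurrenceRecord(
                    id=row["id"],
                    longitude=lon,
                    latitude=lat,
                    source=row.get("source", "") or "",
                    breeding_evidence=ev,
                    date=(row.get("date") or None),
                )
            )
    prov = {
        "file": str(path),
        "n_rows": n_rows,
        "n_kept": len(records),
        "n_dropped_bad_coordinates": n_bad_coord,
        "n_dropped_bad_evidence": n_bad_evidence,
    }
    return OccurrenceSet(records, prov)


def classify_breeding(occ: OccurrenceSet) -> tuple[OccurrenceSet, OccurrenceSet]:
    """Partition into (breeding, non-breeding) by the evidence codes.

    A record is breeding iff any of the three evidence criteria holds,
    i.e. its code is not ``none``.  The partition is exhaustive and
    disjoint and preserves input order.
    """
    br = [r for r in occ.records if r.is_breeding]
    nb = [r for r in occ.records if not r.is_breeding]
    base = dict(occ.provenance)
    return (
        OccurrenceSet(br, {**base, "subset": "breeding", "n": len(br)}),
        OccurrenceSet(nb, {**base, "subset": "nonbreeding", "n": len(nb)}),
    )


def _dedup_sort_key(r: OccurrenceRecord):
    # earliest date wins; undated records sort after dated; then lowest id
    return (r.date is None, r.date or "", r.id)


def dedup_pseudoreplicates(occ: OccurrenceSet, grid: RasterGrid) -> OccurrenceSet:
    """Collapse pseudo-replicates to one record per (cell, breeding-status).

    The same nest or individual photographed by several observers produces
    clustered records; at analysis resolution these collapse onto one grid
    cell.  Within a cell at most one breeding and one non-breeding record
    survive — the earliest-dated (undated last), then lexicographically
    smallest id.  Records outside the grid extent are kept untouched.
    """
    best: dict[tuple[int, int, bool], OccurrenceRecord] = {}
    outside: list[OccurrenceRecord] = []
    order: list[tuple] = []  # preserve first-seen ordering of keys
    for r in occ.records:
        row, col = grid.cell_index(r.longitude, r.latitude)
        row, col = int(row), int(col)
        if row < 0:
            outside.append(r)
            continue
        key = (row, col, r.is_breeding)
        if key not in best:
            best[key] = r
            order.append(key)
        elif _dedup_sort_key(r) < _dedup_sort_key(best[key]):
            best[key] = r
    kept = [best[k] for k in order] + outside
    n_dropped = len(occ.records) - len(kept)
    prov = {**occ.provenance, "n_pseudoreplicates_dropped": n_dropped}
    return OccurrenceSet(kept, prov)


def filter_study_area(occ: OccurrenceSet, max_lat: float = 40.0) -> OccurrenceSet:
    """Drop records north of the study boundary (latitude > max_lat).

    The boundary is inclusive: a record at exactly ``max_lat`` is kept.
    """
    kept = [r for r in occ.records if r.latitude <= max_lat]
    prov = {**occ.provenance, "n_dropped_north_of_boundary": len(occ.records) - len(kept)}
    return OccurrenceSet(kept, prov)


def load_reference_occurrences() -> OccurrenceSet:
    """Load the packaged synthetic stand-in occurrence fixture.

    A 322-record CSV mirroring the published bookkeeping of the compiled
    Harpy Eagle record set (148 breeding / 174 non-breeding, source
    counts as reported); coordinates are synthetic.
    """
    from importlib.resources import files

    path = files("harpyrange.data") / "synthetic_reference_occurrences.csv"
    return read_occurrences_csv(str(path))
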