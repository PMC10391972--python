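"""Feather-isotope tables: records, CSV I/O, outlier filtering and grouping.

A feather record carries the measurements taken from one winter-grown
feather (δ²H on the VSMOW scale, δ¹³C on VPDB, δ¹⁵N on AIR, all in ‰) plus
the bird's species, sampling site, population group, sex and wing chord.
Feathers grown on the breeding grounds (e.g. replaced after loss) show very
depleted δ²H; records below a −120‰ cutoff are treated as outliers and
removed before assignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "FeatherRecord",
    "SPECIES_CODES",
    "DEFAULT_COLUMNS",
    "read_feather_table",
    "write_feather_table",
    "records_to_frame",
    "filter_outliers",
    "group_populations",
    "OUTLIER_D2H_THRESHOLD",
]

#: Four-letter species codes used throughout: Bank, Barn and Cliff Swallow.
SPECIES_CODES = ("BANS", "BARS", "CLSW")

#: Strictly-below-this δ²H_f (‰) marks a feather as breeding-ground grown.
OUTLIER_D2H_THRESHOLD = -120.0

#: Default CSV column names for each record field.
DEFAULT_COLUMNS: dict[str, str] = {
    "id": "id",
    "species": "species",
    "site": "site",
    "population": "population",
    "sex": "sex",
    "d2h_f": "d2h_f",
    "d13c_f": "d13c_f",
    "d15n_f": "d15n_f",
    "wing_mm": "wing_mm",
    "year": "year",
}

_MANDATORY = ("id", "species", "site", "population", "sex", "d2h_f", "d13c_f")
_ISOTOPES = ("d2h_f", "d13c_f", "d15n_f")


@dataclass(frozen=True)
class FeatherRecord:
    """One individual's feather isotope and morphometric measurements."""

    id: str
    species: str
    site: str
    population: str
    sex: str  # M, F or U
    d2h_f: float        # ‰ VSMOW
    d13c_f: float       # ‰ VPDB
    d15n_f: float | None = None  # ‰ AIR
    wing_mm: float | None = None
    year: int | None = None

    def __post_init__(self) -> None:
        for name in _ISOTOPES:
            v = getattr(self, name)
            if v is not None and not math.isfinite(v):
                raise ValueError(f"{name} must be finite for record {self.id!r}")
        if self.wing_mm is not None and not self.wing_mm > 0:
            raise ValueError(f"wing_mm must be > 0 for record {self.id!r}")
        if self.sex not in ("M", "F", "U"):
            raise ValueError(f"sex must be M/F/U, got {self.sex!r} for record {self.id!r}")


def _opt_float(value: object) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def read_feather_table(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
) -> list[FeatherRecord]:
    """Read a feather table from CSV.

    Parameters
    ----------
    path
        CSV file with a header row.
    columns
        Optional mapping from record field names (``id``, ``species``,
        ``site``, ``population``, ``sex``, ``d2h_f``, ``d13c_f``,
        ``d15n_f``, ``wing_mm``, ``year``) to the CSV column names that hold
        them; unspecified fields use :data:`DEFAULT_COLUMNS`.

    Raises
    ------
    ValueError
        If a mandatory column is missing (the message names it), if an
        isotope value is non-numeric (the message lists the offending rows),
        or if ids are not unique.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for fld in _MANDATORY:
        if colmap[fld] not in df.columns:
            raise ValueError(
                f"feather table {path} is missing mandatory column "
                f"{colmap[fld]!r} (field {fld!r})"
            )
    records: list[FeatherRecord] = []
    bad_rows: list[tuple[int, str, str]] = []
    for i, row in df.iterrows():
        numeric: dict[str, float | None] = {}
        for fld in _ISOTOPES + ("wing_mm",):
            col = colmap[fld]
            raw = row[col].strip() if col in df.columns else ""
            if raw == "":
                numeric[fld] = None
                continue
            try:
                numeric[fld] = float(raw)
            except ValueError:
                bad_rows.append((int(i) + 2, fld, raw))  # +2: header + 1-based
                numeric[fld] = None
        if bad_rows:
            continue
        year_col = colmap["year"]
        year_raw = row[year_col].strip() if year_col in df.columns else ""
        records.append(
            FeatherRecord(
                id=row[colmap["id"]],
                species=row[colmap["species"]],
                site=row[colmap["site"]],
                population=row[colmap["population"]],
                sex=row[colmap["sex"]] or "U",
                d2h_f=numeric["d2h_f"],
                d13c_f=numeric["d13c_f"],
                d15n_f=numeric["d15n_f"],
                wing_mm=numeric["wing_mm"],
                year=int(year_raw) if year_raw else None,
            )
        )
    if bad_rows:
        listing = "; ".join(f"row {r}: {f}={v!r}" for r, f, v in bad_rows)
        raise ValueError(f"non-numeric values in feather table {path}: {listing}")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if ids.count(x) > 1})
        raise ValueError(f"duplicate ids in feather table {path}: {dupes}")
    return records


def records_to_frame(records: Sequence[FeatherRecord]) -> pd.DataFrame:
    """Return the records as a DataFrame (absent values become NaN)."""
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "species": [r.species for r in records],
            "site": [r.site for r in records],
            "population": [r.population for r in records],
            "sex": [r.sex for r in records],
            "d2h_f": [r.d2h_f for r in records],
            "d13c_f": [r.d13c_f for r in records],
            "d15n_f": [r.d15n_f for r in records],
            "wing_mm": [r.wing_mm for r in records],
            "year": [r.year for r in records],
        }
    )


def write_feather_table(
    records: Sequence[FeatherRecord],
    path: str | Path,
    columns: Mapping[str, str] | None = None,
) -> None:
    """Write records as CSV; absent optional values become empty fields."""
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    df = records_to_frame(records)
    df = df.rename(columns=colmap)
    df.to_csv(path, index=False, float_format="%.10g")


def filter_outliers(
    records: Iterable[FeatherRecord],
    threshold: float = OUTLIER_D2H_THRESHOLD,
) -> tuple[list[FeatherRecord], list[FeatherRecord]]:
    """Partition records into (kept, removed) on the δ²H_f outlier rule.

    A record is removed iff ``d2h_f`` is *strictly* below ``threshold``
    (default −120‰); a value exactly at the threshold is kept.  Order is
    preserved in both lists.
    """
    kept: list[FeatherRecord] = []
    removed: list[FeatherRecord] = []
    for rec in records:
        (removed if rec.d2h_f < threshold else kept).append(rec)
    return kept, removed


def group_populations(
    records: Iterable[FeatherRecord],
    site_to_population: Mapping[str, str],
) -> list[FeatherRecord]:
    """Overwrite each record's population label from a site→population map.

    Every site occurring in the records must be mapped; unmapped sites raise
    a ``ValueError`` listing them.
    """
    records = list(records)
    missing = sorted({r.site for r in records} - set(site_to_population))
    if missing:
        raise ValueError(f"sites missing from population map: {missing}")
    return [replace(r, population=site_to_population[r.site]) for r in records]
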