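"""Ingest of FAOSTAT-dialect area-harvested tables.

Reads the bulk-download CSV dialect (columns Area, Item, Element, Year,
Unit, Value by default; the mapping is configurable), keeps only
"Area harvested" rows, harmonizes crop-group labels and filters to a
configured set of recognized countries.  Zero or missing areas are treated
as absences and dropped before any diversity calculation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .exceptions import ConfigurationError, EmptyInputError

__all__ = [
    "DEFAULT_COLUMNS",
    "AREA_HARVESTED",
    "IngestReport",
    "HarmonizationReport",
    "read_production_table",
    "harmonize_crop_groups",
    "filter_countries",
]

#: FAOSTAT bulk-download column names -> normalized field
DEFAULT_COLUMNS = {
    "country": "Area",
    "item": "Item",
    "element": "Element",
    "year": "Year",
    "value": "Value",
}

AREA_HARVESTED = "Area harvested"

#: labels merged into a single group (areas summed per country-year)
MERGE_INTO = {"Cottonlint": "Seedcotton", "Cottonseed": "Seedcotton"}
#: straight renames
RENAME = {"Palmkernels": "Oilpalmfruit"}
#: groups excluded outright: not tied to a crop species, non-plant, or a
#: by-product
REMOVE = {"Fruitpomenes", "Fruitstonenes", "Grainmixed", "Mushroomsandtruffles", "Coir"}


@dataclass
class IngestReport:
    n_rows: int = 0
    n_kept: int = 0
    n_element_filtered: int = 0
    skip_reasons: dict = field(default_factory=dict)

    @property
    def n_skipped(self) -> int:
        return sum(self.skip_reasons.values())

    def _skip(self, reason: str, count: int):
        if count:
            self.skip_reasons[reason] = self.skip_reasons.get(reason, 0) + int(count)


@dataclass
class HarmonizationReport:
    merged_rows: int = 0
    renamed_rows: int = 0
    removed_rows: int = 0


def read_production_table(
    path,
    dialect_config: dict | None = None,
    element: str = AREA_HARVESTED,
    year_range: tuple[int, int] = (1961, 2017),
    country_aliases: dict | None = None,
) -> tuple[pd.DataFrame, IngestReport]:
    """Read a FAOSTAT-dialect CSV into normalized long-format records.

    Returns ``(records, report)`` where records has columns
    ``country, year, crop_group, area_ha`` and the report counts rows
    skipped per reason.  Raises :class:`ConfigurationError` for a missing
    mapped column and :class:`EmptyInputError` when nothing survives.
    """
    cols = dict(DEFAULT_COLUMNS)
    if dialect_config:
        cols.update(dialect_config)
    raw = pd.read_csv(path, dtype=str)
    missing = [v for v in cols.values() if v not in raw.columns]
    if missing:
        raise ConfigurationError(
            f"required columns {missing} not found in {path} "
            f"(available: {list(raw.columns)})"
        )
    report = IngestReport(n_rows=len(raw))

    kept = raw[raw[cols["element"]] == element]
    report.n_element_filtered = len(raw) - len(kept)

    value = pd.to_numeric(kept[cols["value"]], errors="coerce")
    year = pd.to_numeric(kept[cols["year"]], errors="coerce")

    bad_value = value.isna()
    report._skip("missing_or_malformed_value", bad_value.sum())
    negative = value < 0
    report._skip("negative_value", (negative & ~bad_value).sum())
    zero = value == 0
    report._skip("zero_area_absence", (zero & ~bad_value).sum())
    bad_year = year.isna() | (year < year_range[0]) | (year > year_range[1])
    report._skip(
        "year_out_of_range",
        (bad_year & ~(bad_value | negative | zero)).sum(),
    )

    ok = ~(bad_value | negative | zero | bad_year)
    records = pd.DataFrame(
        {
            "country": kept.loc[ok, cols["country"]].astype(str),
            "year": year[ok].astype(int),
            "crop_group": kept.loc[ok, cols["item"]].astype(str),
            "area_ha": value[ok].astype(float),
        }
    ).reset_index(drop=True)
    if country_aliases:
        records["country"] = records["country"].map(
            lambda c: country_aliases.get(c, c)
        )
    report.n_kept = len(records)
    if records.empty:
        raise EmptyInputError(f"no usable '{element}' records in {path}")
    return records, report


def harmonize_crop_groups(
    records: pd.DataFrame,
) -> tuple[pd.DataFrame, HarmonizationReport]:
    """Apply the crop-group merge/rename/removal rules.

    Cotton lint and cotton seed rows become "Seedcotton" with areas summed
    per country-year; palm kernels are renamed to the oil-palm fruit group;
    the five excluded labels are dropped.  All other labels pass through.
    Output is unique on (country, year, crop_group).
    """
    report = HarmonizationReport()
    out = records.copy()
    report.removed_rows = int(out["crop_group"].isin(REMOVE).sum())
    out = out[~out["crop_group"].isin(REMOVE)]
    merged_mask = out["crop_group"].isin(MERGE_INTO)
    report.merged_rows = int(merged_mask.sum())
    renamed_mask = out["crop_group"].isin(RENAME)
    report.renamed_rows = int(renamed_mask.sum())
    out["crop_group"] = out["crop_group"].map(lambda g: MERGE_INTO.get(g, RENAME.get(g, g)))
    out = (
        out.groupby(["country", "year", "crop_group"], as_index=False)["area_ha"]
        .sum()
        .sort_values(["country", "year", "crop_group"])
        .reset_index(drop=True)
    )
    return out, report


def filter_countries(
    records: pd.DataFrame, valid_countries
) -> tuple[pd.DataFrame, list[str]]:
    """Drop records from countries outside the configured recognized set.

    Returns the filtered records and the sorted list of retained countries.
    """
    valid = set(valid_countries)
    if not valid:
        raise ConfigurationError("valid_countries must not be empty")
    out = records[records["country"].isin(valid)].reset_index(drop=True)
    retained = sorted(out["country"].unique().tolist())
    return out, retained
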