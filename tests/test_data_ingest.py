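import pandas as pd
import pytest

from cropdiv.data_ingest import (
    filter_countries,
    harmonize_crop_groups,
    read_production_table,
)
from cropdiv.exceptions import ConfigurationError, EmptyInputError


def _write_csv(tmp_path, rows, name="prod.csv"):
    path = tmp_path / name
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


class TestReadProductionTable:
    def test_element_filter(self, tmp_path):
        path = _write_csv(
            tmp_path,
            [
                {"Area": "A", "Item": "Wheat", "Element": "Area harvested", "Year": 2000, "Unit": "ha", "Value": 10},
                {"Area": "A", "Item": "Wheat", "Element": "Production", "Year": 2000, "Unit": "t", "Value": 99},
                {"Area": "B", "Item": "Maize", "Element": "Area harvested", "Year": 2001, "Unit": "ha", "Value": 5},
            ],
        )
        records, report = read_production_table(path)
        assert len(records) == 2
        assert report.n_element_filtered == 1

    def test_missing_value_skipped(self, tmp_path):
        path = _write_csv(
            tmp_path,
            [
                {"Area": "A", "Item": "Wheat", "Element": "Area harvested", "Year": 2000, "Unit": "ha", "Value": 10},
                {"Area": "A", "Item": "Maize", "Element": "Area harvested", "Year": 2000, "Unit": "ha", "Value": ""},
            ],
        )
        records, report = read_production_table(path)
        assert len(records) == 1
        assert report.skip_reasons["missing_or_malformed_value"] == 1

    def test_fixture_round_trip_count(self, faostat_csv):
        records, report = read_production_table(faostat_csv, year_range=(1961, 2017))
        assert len(records) == 300  # 5 countries x 10 years x 6 crops
        assert report.n_kept == 300

    def test_missing_column_config_error(self, tmp_path):
        path = _write_csv(tmp_path, [{"Area": "A", "Item": "Wheat", "Year": 2000, "Value": 1}])
        with pytest.raises(ConfigurationError):
            read_production_table(path)

    def test_empty_result_error(self, tmp_path):
        path = _write_csv(
            tmp_path,
            [{"Area": "A", "Item": "Wheat", "Element": "Production", "Year": 2000, "Unit": "t", "Value": 1}],
        )
        with pytest.raises(EmptyInputError):
            read_production_table(path)

    def test_zero_area_treated_as_absence(self, tmp_path):
        path = _write_csv(
            tmp_path,
            [
                {"Area": "A", "Item": "Wheat", "Element": "Area harvested", "Year": 2000, "Unit": "ha", "Value": 0},
                {"Area": "A", "Item": "Maize", "Element": "Area harvested", "Year": 2000, "Unit": "ha", "Value": 2},
            ],
        )
        records, report = read_production_table(path)
        assert len(records) == 1
        assert report.skip_reasons["zero_area_absence"] == 1

    def test_country_alias_applied(self, tmp_path):
        path = _write_csv(
            tmp_path,
            [{"Area": "Ivory Coast", "Item": "Wheat", "Element": "Area harvested", "Year": 2000, "Unit": "ha", "Value": 3}],
        )
        records, _ = read_production_table(path, country_aliases={"Ivory Coast": "Côte d'Ivoire"})
        assert records["country"].iloc[0] == "Côte d'Ivoire"


def _rec(country, year, crop, area):
    return {"country": country, "year": year, "crop_group": crop, "area_ha": area}


class TestHarmonize:
    def test_cotton_merge_sums_areas(self):
        records = pd.DataFrame(
            [_rec("A", 2000, "Cottonlint", 10.0), _rec("A", 2000, "Cottonseed", 5.0)]
        )
        out, report = harmonize_crop_groups(records)
        assert len(out) == 1
        assert out.iloc[0]["crop_group"] == "Seedcotton"
        assert out.iloc[0]["area_ha"] == 15.0
        assert report.merged_rows == 2

    def test_palmkernels_renamed(self):
        records = pd.DataFrame([_rec("A", 2000, "Palmkernels", 7.0)])
        out, report = harmonize_crop_groups(records)
        assert out.iloc[0]["crop_group"] == "Oilpalmfruit"
        assert out.iloc[0]["area_ha"] == 7.0
        assert report.renamed_rows == 1

    def test_excluded_labels_removed(self):
        records = pd.DataFrame([_rec("A", 2000, "Coir", 3.0), _rec("A", 2000, "Wheat", 9.0)])
        out, report = harmonize_crop_groups(records)
        assert list(out["crop_group"]) == ["Wheat"]
        assert report.removed_rows == 1

    def test_all_five_removals(self):
        labels = ["Fruitpomenes", "Fruitstonenes", "Grainmixed", "Mushroomsandtruffles", "Coir"]
        records = pd.DataFrame([_rec("A", 2000, lab, 1.0) for lab in labels])
        out, report = harmonize_crop_groups(records)
        assert out.empty and report.removed_rows == 5

    def test_area_conserved_except_removals(self, fixture_records):
        extra = pd.DataFrame(
            [
                _rec("C1", 2000, "Cottonlint", 4.0),
                _rec("C1", 2000, "Cottonseed", 6.0),
                _rec("C1", 2000, "Coir", 100.0),
            ]
        )
        records = pd.concat([fixture_records, extra], ignore_index=True)
        out, _ = harmonize_crop_groups(records)
        removed_area = 100.0
        assert out["area_ha"].sum() == pytest.approx(
            records["area_ha"].sum() - removed_area
        )

    def test_idempotent_on_clean_data(self, fixture_records):
        once, _ = harmonize_crop_groups(fixture_records)
        twice, _ = harmonize_crop_groups(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_unique_keys_after_harmonization(self, fixture_records):
        out, _ = harmonize_crop_groups(fixture_records)
        assert not out.duplicated(["country", "year", "crop_group"]).any()


class TestFilterCountries:
    def test_dissolved_country_dropped(self):
        records = pd.DataFrame(
            [_rec("Yugoslavia", 1980, "Wheat", 1.0), _rec("France", 1980, "Wheat", 2.0)]
        )
        out, retained = filter_countries(records, ["France"])
        assert retained == ["France"]
        assert "Yugoslavia" not in set(out["country"])

    def test_identity_when_all_valid(self, fixture_records):
        valid = sorted(fixture_records["country"].unique())
        out, retained = filter_countries(fixture_records, valid)
        assert retained == valid
        assert len(out) == len(fixture_records)

    def test_two_of_five_invalid(self, fixture_records):
        out, retained = filter_countries(fixture_records, ["C1", "C3", "C5"])
        assert len(retained) == 3

    def test_empty_valid_set_config_error(self, fixture_records):
        with pytest.raises(ConfigurationError):
            filter_countries(fixture_records, [])
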