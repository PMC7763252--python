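"""Panel I/O, interpolation and direction-aware normalization."""

import numpy as np
import pandas as pd
import pytest

from ecowarn import IndicatorPanel, interpolate_missing, normalize_panel, read_panel, write_panel
from ecowarn.errors import (
    DegenerateIndicatorError,
    DuplicateObservationError,
    EndpointMissingError,
    MissingIndicatorError,
    PanelParseError,
)


def _panel_from_rows(rows, codes):
    frame = pd.DataFrame(rows, columns=["region", "year", *codes])
    return IndicatorPanel(frame.set_index(["region", "year"]))


class TestReadWrite:
    @pytest.mark.parametrize("fmt", ["wide", "long"])
    def test_round_trip_is_bit_exact(self, mini_panel, mini_registry, tmp_path, fmt):
        path = tmp_path / f"panel_{fmt}.csv"
        write_panel(mini_panel, path, fmt=fmt)
        back = read_panel(path, mini_registry)
        pd.testing.assert_frame_equal(back.data, mini_panel.data)

    def test_dimension_count_one_region(self, mini_registry, tmp_path):
        rows = [("r1", y, 1.0 + y % 3, 2.0, 3.0 + y % 2) for y in range(2011, 2019)]
        panel = _panel_from_rows(rows, mini_registry.codes)
        assert panel.n_observations == 8
        assert len(panel.indicators) == 3

    def test_unparseable_cell_names_coordinates(self, mini_registry, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "region,year,pos_a,pos_b,neg_a\nr1,2011,1.0,n/a,3.0\n", encoding="utf-8"
        )
        with pytest.raises(PanelParseError) as err:
            read_panel(path, mini_registry)
        assert err.value.region == "r1"
        assert err.value.year == 2011
        assert err.value.indicator == "pos_b"

    def test_registry_indicator_absent_from_file(self, mini_registry, tmp_path):
        path = tmp_path / "short.csv"
        path.write_text("region,year,pos_a,pos_b\nr1,2011,1.0,2.0\n", encoding="utf-8")
        with pytest.raises(MissingIndicatorError) as err:
            read_panel(path, mini_registry)
        assert "neg_a" in err.value.codes

    def test_duplicate_region_year_rows_rejected(self, mini_registry):
        rows = [("r1", 2011, 1, 2, 3), ("r1", 2011, 4, 5, 6)]
        with pytest.raises(DuplicateObservationError):
            _panel_from_rows(rows, mini_registry.codes)

    def test_gap_in_year_run_rejected(self, mini_registry):
        rows = [("r1", 2011, 1, 2, 3), ("r1", 2013, 4, 5, 6)]
        with pytest.raises(ValueError, match="contiguous"):
            _panel_from_rows(rows, mini_registry.codes)


class TestInterpolation:
    def test_interior_gap_filled_linearly(self, mini_registry):
        rows = [("r1", 2011, 2.0, 1.0, 1.0), ("r1", 2012, np.nan, 2.0, 2.0), ("r1", 2013, 4.0, 3.0, 3.0)]
        filled = interpolate_missing(_panel_from_rows(rows, mini_registry.codes))
        assert filled.data.loc[("r1", 2012), "pos_a"] == pytest.approx(3.0)
        # observed cells untouched
        assert filled.data.loc[("r1", 2011), "pos_a"] == 2.0

    def test_complete_panel_returned_unchanged(self, mini_panel):
        filled = interpolate_missing(mini_panel)
        pd.testing.assert_frame_equal(filled.data, mini_panel.data)

    @pytest.mark.parametrize("gap_year", [2011, 2013])
    def test_missing_endpoint_refused(self, mini_registry, gap_year):
        rows = [("r1", y, 1.0 * y, 3.0, 4.0) for y in (2011, 2012, 2013)]
        panel = _panel_from_rows(rows, mini_registry.codes)
        panel.data.loc[("r1", gap_year), "pos_a"] = np.nan
        with pytest.raises(EndpointMissingError):
            interpolate_missing(IndicatorPanel(panel.data))


class TestNormalization:
    def test_extremes_and_midpoint(self, mini_registry):
        rows = [("r1", 2011, 0.0, 5.0, 0.0), ("r1", 2012, 2.0, 6.0, 2.0), ("r1", 2013, 4.0, 7.0, 4.0)]
        norm = normalize_panel(_panel_from_rows(rows, mini_registry.codes), mini_registry)
        col = norm.data["pos_a"]
        assert col.tolist() == [0.0, 0.5, 1.0]  # positive: max -> 1, midpoint -> 0.5
        neg = norm.data["neg_a"]
        assert neg.tolist() == [1.0, 0.5, 0.0]  # negative: max -> 0

    def test_monotone_in_direction(self, mini_panel, mini_registry):
        norm = normalize_panel(mini_panel, mini_registry)
        raw = mini_panel.data
        for code in mini_registry.codes:
            order = np.argsort(raw[code].to_numpy())
            normed = norm.data[code].to_numpy()[order]
            if mini_registry.direction(code) == "positive":
                assert (np.diff(normed) >= -1e-12).all()
            else:
                assert (np.diff(normed) <= 1e-12).all()

    def test_all_values_in_unit_interval(self, mini_panel, mini_registry):
        norm = normalize_panel(mini_panel, mini_registry)
        vals = norm.data.to_numpy()
        assert vals.min() >= 0.0 and vals.max() <= 1.0

    def test_constant_indicator_rejected_by_default(self, mini_registry):
        rows = [("r1", 2011, 1.0, 5.0, 1.0), ("r1", 2012, 2.0, 5.0, 2.0)]
        with pytest.raises(DegenerateIndicatorError) as err:
            normalize_panel(_panel_from_rows(rows, mini_registry.codes), mini_registry)
        assert err.value.code == "pos_b"

    def test_constant_indicator_midpoint_policy(self, mini_registry):
        rows = [("r1", 2011, 1.0, 5.0, 1.0), ("r1", 2012, 2.0, 5.0, 2.0)]
        panel = _panel_from_rows(rows, mini_registry.codes)
        norm = normalize_panel(panel, mini_registry, constant_policy="midpoint")
        assert (norm.data["pos_b"] == 0.5).all()

    def test_per_year_pooling_normalizes_within_years(self, mini_registry):
        rows = [
            ("r1", 2011, 1.0, 1.0, 1.0), ("r1", 2012, 10.0, 1.0, 1.0),
            ("r2", 2011, 3.0, 2.0, 2.0), ("r2", 2012, 30.0, 2.0, 2.0),
        ]
        panel = _panel_from_rows(rows, mini_registry.codes)
        norm = normalize_panel(panel, mini_registry, pooling="per-year")
        # within each year the min maps to 0 and the max to 1
        assert norm.data.loc[("r1", 2011), "pos_a"] == 0.0
        assert norm.data.loc[("r2", 2011), "pos_a"] == 1.0
        assert norm.data.loc[("r1", 2012), "pos_a"] == 0.0
        assert norm.data.loc[("r2", 2012), "pos_a"] == 1.0
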