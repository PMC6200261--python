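"""Annual-series data model, CSV round trip and preprocessing."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from codcast.errors import (
    AlignmentError,
    BaselineError,
    CodcastError,
    SeriesFormatError,
)
from codcast.series import (
    AnnualSeries,
    align,
    detrend_linear,
    harvest_rate,
    highpass,
    lowpass,
    read_series,
    to_anomalies,
    write_series,
)

from conftest import make_series


class TestIO:
    def test_round_trip_preserves_values_exactly(self, tmp_path, rng):
        values = rng.normal(size=60)
        values[[0, 7, 33]] = np.nan
        s = make_series(values, name="TSB")
        path = tmp_path / "tsb.csv"
        write_series(s, path)
        back = read_series(path, name="TSB")
        assert back.equals(s)

    def test_non_consecutive_years_densified_with_missing(self, tmp_path):
        path = tmp_path / "gap.csv"
        path.write_text("year,value\n1950,1.0\n1952,3.0\n")
        s = read_series(path)
        assert list(s.years) == [1950, 1951, 1952]
        assert np.isnan(s.values[1])
        assert s.values[0] == 1.0 and s.values[2] == 3.0

    def test_duplicate_year_error_names_the_year(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("year,value\n1959,1.0\n1960,2.0\n1960,3.0\n")
        with pytest.raises(SeriesFormatError, match="1960"):
            read_series(path)

    def test_unparseable_row_error_names_the_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("year,value\n1950,1.0\n1951,oops\n")
        with pytest.raises(SeriesFormatError, match="3"):
            read_series(path)

    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=40))
    def test_round_trip_property(self, tmp_path_factory, values):
        s = make_series(values)
        path = tmp_path_factory.mktemp("io") / "s.csv"
        write_series(s, path)
        assert read_series(path, name="s").equals(s)


class TestInvariants:
    def test_years_must_be_consecutive(self):
        with pytest.raises(SeriesFormatError):
            AnnualSeries("x", np.array([1950, 1952]), np.array([1.0, 2.0]))

    def test_needs_two_observed_values(self):
        with pytest.raises(SeriesFormatError):
            AnnualSeries("x", np.arange(1950, 1953),
                         np.array([1.0, np.nan, np.nan]))


class TestAnomalies:
    def test_constant_series_gives_zero_anomalies(self):
        s = make_series(np.full(40, 3.7))
        a = to_anomalies(s, 1950, 1989)
        assert np.allclose(a.values, 0.0, atol=1e-12)

    def test_values_outside_window_offset_by_baseline_mean(self):
        values = np.concatenate([np.full(30, 2.0), np.full(10, 3.0)])
        s = make_series(values)  # 1950-1989, baseline below covers 1950-1979
        a = to_anomalies(s, 1950, 1979)
        assert np.allclose(a.values[:30], 0.0)
        assert np.allclose(a.values[30:], 1.0)

    def test_full_span_baseline_centers_exactly(self, rng):
        s = make_series(rng.normal(size=63))
        a = to_anomalies(s, 1950, 2012)
        assert abs(np.nanmean(a.values)) < 1e-12

    def test_insufficient_baseline_overlap_raises(self, rng):
        s = make_series(rng.normal(size=40))
        with pytest.raises(BaselineError):
            to_anomalies(s, 2030, 2050)


class TestDetrend:
    def test_exact_line_removed_to_zero(self):
        years = np.arange(1950, 2000)
        s = AnnualSeries("lin", years, 2.0 + 0.3 * years)
        assert np.allclose(detrend_linear(s).values, 0.0, atol=1e-10)

    def test_idempotent(self, rng):
        s = make_series(rng.normal(size=50) + 0.1 * np.arange(50))
        once = detrend_linear(s)
        twice = detrend_linear(once)
        assert np.allclose(once.values, twice.values, atol=1e-10)

    def test_refit_slope_is_zero(self, rng):
        # AR(1)-ish series plus trend: residual of detrend has zero OLS slope
        v = np.cumsum(rng.normal(size=80)) * 0.3 + 0.2 * np.arange(80)
        d = detrend_linear(make_series(v))
        slope = np.polyfit(d.years - d.years.mean(), d.values, 1)[0]
        assert abs(slope) < 1e-10

    def test_commutes_with_anomalies(self, rng):
        s = make_series(rng.normal(size=63) + 0.05 * np.arange(63))
        ab = detrend_linear(to_anomalies(s, 1950, 2012))
        ba = to_anomalies(detrend_linear(s), 1950, 2012)
        assert np.allclose(ab.values, ba.values, atol=1e-10)


class TestHighpass:
    def test_constant_series_has_zero_highpass(self):
        s = make_series(np.full(30, 5.0))
        assert np.allclose(highpass(s, 5).values, 0.0, atol=1e-12)

    def test_complementarity_is_exact(self, rng):
        s = make_series(rng.normal(size=60))
        hp = highpass(s, 5)
        lp = lowpass(s, 5)
        assert np.allclose(hp.values + lp.values, s.values, atol=1e-12)

    def test_two_year_oscillation_passes_highpass(self):
        # a width-5 boxcar averages 5 alternating +-1 values to +-1/5, so
        # the interior high-pass amplitude is exactly 1 - 1/5 = 0.8 and the
        # retained variance fraction is 0.8^2 = 0.64
        t = np.arange(60)
        s = make_series((-1.0) ** t)  # period-2 oscillation
        hp = highpass(s, 5)
        interior = hp.values[2:-2]
        assert np.allclose(np.abs(interior), 0.8, atol=1e-12)
        assert np.var(hp.values) >= 0.6 * np.var(s.values)

    def test_cutoff_below_two_rejected(self, rng):
        with pytest.raises(CodcastError):
            highpass(make_series(rng.normal(size=30)), 1)


class TestHarvestRate:
    def test_proportional_catch_gives_constant_rate(self, rng):
        tsb = make_series(rng.uniform(1000, 3000, size=40), name="TSB")
        catch = tsb.with_values(0.3 * tsb.values, name="catch")
        hr = harvest_rate(catch, tsb)
        assert np.allclose(hr.values, 0.3)

    def test_output_restricted_to_year_intersection(self, rng):
        tsb = make_series(rng.uniform(1000, 3000, size=40), name="TSB")
        catch = make_series(rng.uniform(100, 300, size=10),
                            start_year=1960, name="catch")
        hr = harvest_rate(catch, tsb)
        assert hr.start_year == 1960 and hr.end_year == 1969

    def test_toy_arithmetic(self):
        tsb = make_series([2000.0] * 10, name="TSB")
        catch = make_series([700.0] * 10, name="catch")
        assert np.allclose(harvest_rate(catch, tsb).values, 0.35)

    def test_nonpositive_tsb_rejected(self):
        tsb = make_series([2000.0, 0.0, 2000.0, 1000.0], name="TSB")
        catch = make_series([1.0] * 4, name="catch")
        with pytest.raises(CodcastError):
            harvest_rate(catch, tsb)


class TestAlign:
    def test_row_count_by_enumeration(self, rng):
        y = make_series(rng.normal(size=63), name="y")          # 1950-2012
        x = make_series(rng.normal(size=63), name="x")
        design = align(y, [(x, 7)])
        # y_i needs x_{i-7}: first usable year is 1957
        assert design.years[0] == 1957 and design.years[-1] == 2012
        assert design.n_rows == 56

    def test_lead_zero_identical_series(self, rng):
        y = make_series(rng.normal(size=30), name="y")
        design = align(y, [(y, 0)])
        assert np.array_equal(design.X[:, 0], design.y)

    def test_missing_predictor_year_drops_the_lagged_row(self, rng):
        vals = rng.normal(size=63)
        vals[20] = np.nan  # 1970 missing
        x = make_series(vals, name="x")
        y = make_series(rng.normal(size=63), name="y")
        design = align(y, [(x, 7)])
        assert 1977 not in design.years
        assert design.n_rows == 55

    def test_predictor_order_only_permutes_columns(self, rng):
        y = make_series(rng.normal(size=50), name="y")
        a = make_series(rng.normal(size=50), name="a")
        b = make_series(rng.normal(size=50), name="b")
        d1 = align(y, [(a, 3), (b, 5)])
        d2 = align(y, [(b, 5), (a, 3)])
        assert np.array_equal(d1.years, d2.years)
        assert np.allclose(d1.X[:, 0], d2.X[:, 1])
        assert np.allclose(d1.X[:, 1], d2.X[:, 0])

    def test_empty_intersection_reports_coverage(self, rng):
        y = make_series(rng.normal(size=10), start_year=1950, name="y")
        x = make_series(rng.normal(size=10), start_year=2000, name="x")
        with pytest.raises(AlignmentError, match="x"):
            align(y, [(x, 3)])

    def test_lagging_never_relabels_years(self, dataset):
        # calendar safety: design years are predictand years, and each
        # column equals the source series read at (year - lead)
        design = align(dataset["TSB"], [(dataset["FSC"], 4)])
        fsc = dataset["FSC"]
        expected = fsc.values_at(design.years - 4)
        assert np.allclose(design.X[:, 0], expected)
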