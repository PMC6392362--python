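"""Covariate engineering: diurnal interpolation, stress hours,
smoothing, land-cover year mapping, standardization and decomposition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from occdyn.covariates import (
    DiurnalTiming,
    assign_landcover_years,
    build_covariate_table,
    decompose,
    hourly_series,
    interpolate_hourly,
    moving_average,
    standardize,
    stress_hours,
)


def _constant_hourly(value, start="2000-06-01", years=1):
    end = pd.Timestamp(start) + pd.DateOffset(years=years)
    idx = pd.date_range(start, end - pd.Timedelta(hours=1), freq="h")
    return pd.Series(value, index=idx)


class TestInterpolateHourly:
    def test_constant_day(self):
        out = interpolate_hourly(20.0, 20.0, 20.0)
        assert np.allclose(out, 20.0)

    def test_peak_attains_tmax(self):
        timing = DiurnalTiming(sunrise=6, peak=15, sunset=20)
        out = interpolate_hourly(10.0, 25.0, 12.0, timing)
        assert out[15] == pytest.approx(25.0)

    def test_sunrise_attains_tmin(self):
        out = interpolate_hourly(10.0, 25.0, 12.0, DiurnalTiming(sunrise=6))
        assert out[6] == pytest.approx(10.0)

    def test_monotone_sunrise_to_peak(self):
        # dense sampling of the defining daytime segment
        from occdyn.covariates import _diurnal_curve
        timing = DiurnalTiming()
        hours = np.linspace(timing.sunrise, timing.peak, 500)
        vals = _diurnal_curve(hours, 8.0, 30.0, 10.0, timing)
        assert np.all(np.diff(vals) >= -1e-12)

    def test_night_decays_toward_next_min(self):
        timing = DiurnalTiming()
        out = interpolate_hourly(10.0, 25.0, 5.0, timing)
        night = out[int(timing.sunset) + 1:]
        assert np.all(np.diff(night) < 0)

    def test_inverted_temperatures_error(self):
        with pytest.raises(ValueError):
            interpolate_hourly(25.0, 10.0, 12.0)

    def test_bad_timing(self):
        with pytest.raises(ValueError):
            DiurnalTiming(sunrise=16, peak=15)


class TestStressHours:
    def test_constant_20_no_stress(self):
        out = stress_hours(_constant_hourly(20.0))
        assert out.loc[2001, "heat_hours"] == 0
        assert out.loc[2001, "cold_hours"] == 0

    def test_constant_10_all_cold(self):
        out = stress_hours(_constant_hourly(10.0, start="2001-06-01"))
        # cycle 2001/02 contains no Feb 29 -> 8760 hours
        assert out.loc[2002, "cold_hours"] == 8760
        assert out.loc[2002, "heat_hours"] == 0

    def test_constant_40_all_heat(self):
        out = stress_hours(_constant_hourly(40.0, start="2001-06-01"))
        assert out.loc[2002, "heat_hours"] == 8760
        assert out.loc[2002, "cold_hours"] == 0

    def test_partial_year_errors(self):
        s = _constant_hourly(20.0)
        with pytest.raises(ValueError, match="cycle"):
            stress_hours(s.iloc[:-100])

    def test_thresholds_are_strict(self):
        s = _constant_hourly(18.0)
        out = stress_hours(s)
        assert out.loc[2001, "cold_hours"] == 0  # exactly 18 is not below 18
        s38 = _constant_hourly(38.0)
        assert stress_hours(s38).loc[2001, "heat_hours"] == 0

    def test_monotone_in_temperature(self, rng):
        base = pd.Series(
            rng.uniform(0, 45, 8760),
            index=pd.date_range("2001-06-01", periods=8760, freq="h"),
        )
        lo = stress_hours(base)
        hi = stress_hours(base + 2.0)
        assert hi.loc[2002, "heat_hours"] >= lo.loc[2002, "heat_hours"]
        assert hi.loc[2002, "cold_hours"] <= lo.loc[2002, "cold_hours"]


class TestMovingAverage:
    def test_constant(self):
        s = pd.Series(3.0, index=range(1982, 2013))
        out = moving_average(s, 15)
        assert np.allclose(out, 3.0)

    def test_arithmetic_mean(self):
        s = pd.Series(range(1, 16), index=range(1998, 2013))
        assert moving_average(s, 15).iloc[0] == pytest.approx(8.0)

    def test_linear_trend_preserved_with_lag(self):
        years = np.arange(1982, 2013)
        slope, intercept = 0.7, -3.0
        s = pd.Series(slope * years + intercept, index=years)
        out = moving_average(s, 15)
        # trailing mean of a line: same slope, evaluated 7 years back
        expected = slope * (out.index.to_numpy() - 7.0) + intercept
        assert np.allclose(out.to_numpy(), expected)

    def test_window_labeling(self):
        # cycles 1981/82..2011/12 labeled 1982..2012 -> outputs 1996..2012;
        # the modeled years 1997-2012 are the last 16
        s = pd.Series(1.0, index=range(1982, 2013))
        out = moving_average(s, 15)
        assert out.index[0] == 1996
        assert out.index[-1] == 2012

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            moving_average(pd.Series(range(10)), 15)

    def test_commutes_with_constant_shift(self, rng):
        s = pd.Series(rng.normal(size=30))
        a = moving_average(s + 5.0, 15)
        b = moving_average(s, 15) + 5.0
        assert np.allclose(a, b)


class TestLandcoverYears:
    def test_printed_mapping(self):
        out = assign_landcover_years(0.4, 0.3, 0.2)
        assert (out.loc[1997:2001] == 0.4).all()
        assert (out.loc[2002:2006] == 0.3).all()
        assert (out.loc[2007:2012] == 0.2).all()

    def test_2002_takes_2006_value(self):
        out = assign_landcover_years(0.4, 0.3, 0.2)
        assert out.loc[2002] == 0.3

    def test_equal_inputs_constant(self):
        out = assign_landcover_years(0.5, 0.5, 0.5)
        assert (out == 0.5).all()

    def test_out_of_range_fraction(self):
        with pytest.raises(ValueError):
            assign_landcover_years(1.2, 0.3, 0.2)

    def test_unmapped_year(self):
        with pytest.raises(ValueError):
            assign_landcover_years(0.4, 0.3, 0.2, years=[1990])


class TestStandardize:
    def test_population_sd_convention(self):
        z, scaler = standardize([0.0, 2.0])
        assert np.allclose(z, [-1.0, 1.0])
        assert scaler.mean == 1.0 and scaler.sd == 1.0

    def test_output_moments(self, rng):
        z, _ = standardize(rng.normal(3, 2, size=500))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std() == pytest.approx(1.0, abs=1e-12)

    def test_idempotent_with_stored_scaler(self, rng):
        x = rng.normal(size=100)
        z, scaler = standardize(x)
        z2, _ = standardize(z, scaler=None)
        # standardized stack re-standardized is unchanged
        assert np.allclose(z, z2, atol=1e-12)

    def test_scaler_reuse_roundtrip(self, rng):
        x = rng.normal(size=50)
        z, scaler = standardize(x)
        assert np.allclose(scaler.invert(z), x)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            standardize([1.0, 1.0, 1.0])


class TestDecompose:
    def _table(self, values):
        rows = []
        for rid, series in values.items():
            for year, v in enumerate(series, start=1997):
                rows.append({"route_id": rid, "year": year, "x": v})
        return pd.DataFrame(rows)

    def test_constant_route_all_zero_deviations(self):
        t = decompose(self._table({"a": [2.0, 2.0, 2.0]}), "x")
        assert np.allclose(t["x_dev"], 0.0)

    def test_two_point_example(self):
        t = decompose(self._table({"a": [1.0, 3.0]}), "x")
        assert np.allclose(t["x_mean"], 2.0)
        assert np.allclose(t["x_dev"], [-1.0, 1.0])

    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=8))
    @settings(max_examples=100, deadline=None)
    def test_reconstruction_identity(self, series):
        t = decompose(self._table({"a": series}), "x")
        assert np.allclose(t["x_mean"] + t["x_dev"], t["x"], atol=1e-9)
        assert abs(t["x_dev"].mean()) < 1e-10


class TestDecomposeStandardizeOrder:
    def test_orders_differ_only_by_affine_maps(self, rng):
        """standardize-then-decompose vs decompose-then-standardize-each-
        component: the resulting mean/deviation series are affine images
        of each other (exact linear relation, r^2 = 1)."""
        rows = []
        for r in range(12):
            base = rng.normal()
            for y in range(1997, 2005):
                rows.append({"route_id": f"r{r}", "year": y,
                             "x": base + rng.normal(scale=0.3)})
        table = pd.DataFrame(rows)

        # order A: standardize the stack, then decompose
        za, _ = standardize(table["x"].to_numpy())
        ta = table.assign(z=za)
        ta = decompose(ta, "z")

        # order B: decompose raw, then standardize each component
        tb = decompose(table.copy(), "x")
        mb, _ = standardize(tb["x_mean"].to_numpy())
        db_sd = tb["x_dev"].to_numpy().std()
        db = tb["x_dev"].to_numpy() / db_sd

        # affine relation: corrcoef magnitude 1 within float tolerance
        assert abs(np.corrcoef(ta["z_mean"], mb)[0, 1]) == pytest.approx(1.0, abs=1e-10)
        assert abs(np.corrcoef(ta["z_dev"], db)[0, 1]) == pytest.approx(1.0, abs=1e-10)


class TestBuildCovariateTable:
    def _landcover(self):
        return pd.DataFrame(
            [
                {"route_id": "a", "frac_2001": 0.5, "frac_2006": 0.4, "frac_2011": 0.3},
                {"route_id": "b", "frac_2001": 0.2, "frac_2006": 0.2, "frac_2011": 0.25},
            ]
        )

    def _stress(self):
        rows = []
        for rid, base in (("a", 5000.0), ("b", 5400.0)):
            for y in range(1997, 2013):
                rows.append(
                    {"route_id": rid, "year": y, "heat_hours": 1.0 + 0.1 * (y - 1997),
                     "cold_hours": base - 10.0 * (y - 1997)}
                )
        return pd.DataFrame(rows)

    def test_shapes_and_columns(self):
        table = build_covariate_table(self._landcover(), stress=self._stress())
        assert len(table) == 32
        for col in ("habitat_mean", "habitat_dev", "heat_mean", "heat_dev",
                    "cold_mean", "cold_dev"):
            assert col in table.columns

    def test_standardized_stack_moments(self):
        table = build_covariate_table(self._landcover(), stress=self._stress())
        z = table["habitat_z"]
        assert z.mean() == pytest.approx(0.0, abs=1e-10)
        assert z.std(ddof=0) == pytest.approx(1.0, abs=1e-10)

    def test_per_route_deviation_mean_zero(self):
        table = build_covariate_table(self._landcover(), stress=self._stress())
        dev_means = table.groupby("route_id")["cold_dev"].mean()
        assert np.allclose(dev_means, 0.0, atol=1e-10)

    def test_missing_climate_year_errors(self):
        stress = self._stress()
        stress = stress[stress["year"] != 2005]
        with pytest.raises(ValueError, match="2005"):
            build_covariate_table(self._landcover(), stress=stress)

    def test_daily_temps_route(self):
        # two routes, constant temperatures: cold route accumulates cold hours
        dates = pd.date_range("1995-06-01", "2012-05-31", freq="D")
        frames = []
        for rid, t in (("a", 40.0), ("b", 10.0)):
            frames.append(pd.DataFrame({
                "route_id": rid, "date": dates, "tmin_c": t, "tmax_c": t,
            }))
        daily = pd.concat(frames, ignore_index=True)
        lc = self._landcover()
        # moving-average window of 2 keeps the short series usable
        table = build_covariate_table(lc, daily_temps=daily, window=2,
                                      years=range(1998, 2013))
        a = table[table.route_id == "a"]
        b = table[table.route_id == "b"]
        assert (a["cold_hours"] == 0).all()
        assert (b["cold_hours"] >= 8760).all()
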