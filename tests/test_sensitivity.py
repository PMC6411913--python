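import numpy as np
import pytest

from beelong import (
    CensusSeries,
    ColonyParams,
    LongevitySeries,
    MISCOUNT_CASE_SPECS,
    MiscountSpec,
    ValidationError,
    apply_miscount,
    compute_longevity_series,
    load_miscount_reference,
    reference_longevity_series,
    relative_errors,
    sensitivity_report,
)


class TestApplyMiscount:
    def test_multiplies_only_target_inside_window(self):
        census = CensusSeries([0.0, 10.0, 20.0], [1000.0] * 3, [500.0] * 3)
        spec = MiscountSpec("adult", 1.2, 5.0, 15.0)
        out = apply_miscount(census, spec)
        assert np.allclose(out.adult_counts, [1000.0, 1200.0, 1000.0])
        assert np.allclose(out.brood_counts, census.brood_counts)
        # original untouched
        assert np.allclose(census.adult_counts, 1000.0)

    def test_window_endpoints_inclusive(self):
        census = CensusSeries([0.0, 10.0, 20.0], [100.0] * 3, [50.0] * 3)
        spec = MiscountSpec("brood", 0.8, 0.0, 20.0)
        out = apply_miscount(census, spec)
        assert np.allclose(out.brood_counts, 40.0)

    def test_factor_one_is_identity(self):
        census = CensusSeries([0.0, 10.0], [100.0, 200.0], [50.0, 60.0])
        out = apply_miscount(census, MiscountSpec("adult", 1.0, 0.0, 10.0))
        assert np.array_equal(out.adult_counts, census.adult_counts)
        assert np.array_equal(out.brood_counts, census.brood_counts)

    def test_empty_window_warns_and_returns_identity(self):
        census = CensusSeries([0.0, 10.0], [100.0, 200.0], [50.0, 60.0])
        with pytest.warns(UserWarning, match="no census date"):
            out = apply_miscount(census, MiscountSpec("adult", 1.2, 3.0, 4.0))
        assert np.array_equal(out.adult_counts, census.adult_counts)

    def test_calendar_date_window(self):
        census = CensusSeries(
            ["2013-08-13", "2013-08-24", "2013-10-04"],
            [100.0, 100.0, 100.0],
            [50.0, 50.0, 50.0],
        )
        spec = MiscountSpec("adult", 1.2, "2013-08-24", "2013-09-27")
        out = apply_miscount(census, spec)
        assert np.allclose(out.adult_counts, [100.0, 120.0, 100.0])

    def test_round_flag(self):
        census = CensusSeries([0.0], [101.0], [50.0])
        out = apply_miscount(census, MiscountSpec("adult", 1.15, 0.0, 0.0),
                             round_counts=True)
        assert out.adult_counts[0] == 116.0


class TestRelativeErrors:
    def test_reference_miscount_row_values(self):
        """The windowed-miscount reference rows yield the documented
        +0.715 / -0.233 extremes at the largest-error census date."""
        orig = reference_longevity_series("L_original")
        up = reference_longevity_series("L_adult_plus20")
        down = reference_longevity_series("L_adult_minus20")
        import datetime as dt

        idx = list(orig.dates).index(dt.date(2013, 9, 27))
        rel_up = relative_errors(orig, up)
        rel_down = relative_errors(orig, down)
        assert rel_up[idx] == pytest.approx(0.715, abs=5e-4)
        assert rel_down[idx] == pytest.approx(-0.233, abs=5e-4)

    def test_identical_series_all_zero(self):
        s = LongevitySeries([0.0, 10.0], [20.0, 30.0])
        assert np.allclose(relative_errors(s, s), 0.0)

    def test_zero_original_is_nan(self):
        a = LongevitySeries([0.0, 10.0], [0.0, 10.0])
        b = LongevitySeries([0.0, 10.0], [5.0, 20.0])
        rel = relative_errors(a, b)
        assert np.isnan(rel[0]) and rel[1] == 1.0

    def test_misaligned_series_rejected(self):
        a = LongevitySeries([0.0, 10.0], [1.0, 2.0])
        b = LongevitySeries([0.0, 11.0], [1.0, 2.0])
        with pytest.raises(ValidationError, match="aligned"):
            relative_errors(a, b)


class TestSensitivityReport:
    def test_empty_spec_list(self, params, steady_census):
        rep = sensitivity_report(steady_census, [], params)
        assert rep.cases == ()
        assert np.allclose(rep.original.longevity, 20.0)

    def test_adult_miscount_is_local(self, params, seasonal_census):
        """Adult-count errors change L only at census dates inside the window."""
        census, _ = seasonal_census
        spec = MiscountSpec("adult", 1.2, 11.0, 45.0)
        rep = sensitivity_report(census, [spec], params)
        rel = rep.cases[0].rel_errors
        times = census.times()
        outside = (times < 11.0) | (times > 45.0)
        inside = ~outside
        assert np.allclose(rel[outside], 0.0, atol=1e-12)
        assert np.all(np.abs(rel[inside]) > 1e-6)

    def test_brood_miscount_persists_after_window(self, params, seasonal_census):
        """Brood-count errors keep distorting L after the window closes."""
        census, _ = seasonal_census
        spec = MiscountSpec("brood", 1.2, 11.0, 45.0)
        rep = sensitivity_report(census, [spec], params)
        rel = rep.cases[0].rel_errors
        post = census.times() > 45.0
        assert np.any(np.abs(rel[post]) > 1e-6)

    def test_sign_structure(self, params, steady_census):
        """Adult overestimation and brood underestimation lengthen L;
        the reverse shortens it."""
        window = (0.0, 50.0)
        rep = sensitivity_report(
            steady_census,
            [
                MiscountSpec("adult", 1.2, *window),
                MiscountSpec("adult", 0.8, *window),
                MiscountSpec("brood", 0.8, *window),
            ],
            params,
        )
        adult_up, adult_down, brood_down = rep.cases
        assert np.all(adult_up.rel_errors > 0)
        assert np.all(adult_down.rel_errors < 0)
        # brood underestimation only acts once the lowered rates feed
        # intervals the longevity walk traverses; it never shortens L
        assert np.all(brood_down.rel_errors >= 0)
        assert np.any(brood_down.rel_errors > 0)

    def test_failing_case_marked_not_fatal(self, params):
        # inflating only the first brood count implies more residual capped
        # brood 5 days later than was observed -> negative rate -> unsolvable
        census = CensusSeries([0.0, 5.0], [100.0, 100.0], [5000.0, 3000.0])
        specs = [
            MiscountSpec("brood", 2.0, 0.0, 0.0),   # inflate only the first count
            MiscountSpec("adult", 1.1, 0.0, 5.0),   # harmless
        ]
        rep = sensitivity_report(census, specs, params)
        assert rep.cases[0].failed
        assert rep.cases[0].series is None
        assert not rep.cases[1].failed

    def test_extremes_reported_signed(self, params, seasonal_census):
        census, _ = seasonal_census
        rep = sensitivity_report(
            census, [MiscountSpec("adult", 1.2, 11.0, 45.0)], params
        )
        case = rep.cases[0]
        rel = case.rel_errors[np.isfinite(case.rel_errors)]
        assert case.max_positive == pytest.approx(rel.max())
        assert case.max_negative == pytest.approx(min(rel.min(), 0.0))

    def test_to_frame_layout(self, params, steady_census):
        rep = sensitivity_report(
            steady_census, [MiscountSpec("adult", 1.2, 0.0, 50.0)], params
        )
        frame = rep.to_frame()
        assert list(frame.columns) == [
            "date",
            "elapsed_day",
            "L_original",
            "L_adult_+20pct",
            "rel_err_pct_adult_+20pct",
        ]
        assert len(frame) == steady_census.n
        assert frame["rel_err_pct_adult_+20pct"].iloc[0] == pytest.approx(20.0)


class TestReferenceExperiment:
    def test_case_specs_cover_four_quadrants(self):
        targets = [(s.target, s.factor) for s in MISCOUNT_CASE_SPECS]
        assert targets == [
            ("adult", 1.2),
            ("adult", 0.8),
            ("brood", 1.2),
            ("brood", 0.8),
        ]

    def test_reference_extremes(self):
        """Recomputing relative errors from the published longevity columns
        reproduces the reported extreme errors: about +72%, -23%, -19%, +80%."""
        orig = reference_longevity_series("L_original")
        expected = {
            "L_adult_plus20": 72.0,
            "L_adult_minus20": -23.0,
            "L_brood_plus20": -19.0,
            "L_brood_minus20": 80.0,
        }
        for column, printed in expected.items():
            rel = relative_errors(orig, reference_longevity_series(column))
            rel = rel[np.isfinite(rel)]
            extreme = rel.max() if printed > 0 else rel.min()
            assert extreme * 100 == pytest.approx(printed, abs=1.0)

    def test_reference_table_shape(self):
        frame = load_miscount_reference()
        assert len(frame) == 15
        assert frame["elapsed_day"].iloc[-1] == 199
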