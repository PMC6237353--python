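"""Internal-standard quantification, calibration fits and detection limits."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from metlab import targeted_quant as tq
from metlab.errors import AmbiguousInversionError, FitError, ValidationError

CAL_LEVELS = np.geomspace(3.463e-4, 161.2, 11)  # 11-level, ~6-decade design


def oracle_is_conc(area, area_is, conc_is, dilution):
    """Spreadsheet-style re-statement of the IS ratio rule."""
    return (area / area_is) * conc_is * dilution


class TestQuantifyIS:
    @pytest.mark.parametrize(
        "area,area_is,conc_is,dil,expected",
        [(1.0, 1.0, 0.5, 1.0, 0.5), (2.0, 1.0, 0.5, 10.0, 10.0)],
    )
    def test_hand_computed_cases(self, area, area_is, conc_is, dil, expected):
        assert tq.quantify_is(area, area_is, conc_is, dil) == pytest.approx(expected)

    def test_matches_independent_oracle_on_random_tuples(self, rng):
        vals = rng.uniform(0.01, 1e6, size=(10_000, 4))
        for area, area_is, conc_is, dil in vals:
            got = tq.quantify_is(area, area_is, conc_is, dil)
            assert got == pytest.approx(oracle_is_conc(area, area_is, conc_is, dil), rel=1e-12)

    def test_zero_is_area_names_the_offender(self):
        with pytest.raises(ZeroDivisionError, match="ala.*s1"):
            tq.quantify_is(1.0, 0.0, 0.5, 1.0, analyte="ala", sample_id="s1")

    def test_negative_input_rejected(self):
        with pytest.raises(ValidationError):
            tq.quantify_is(-1.0, 1.0, 0.5, 1.0)

    @given(
        area=st.floats(1e-3, 1e6),
        area_is=st.floats(1e-3, 1e6),
        conc_is=st.floats(1e-3, 1e3),
        dil=st.floats(1e-3, 1e3),
        c=st.floats(1e-3, 1e3),
    )
    def test_homogeneity(self, area, area_is, conc_is, dil, c):
        """Scaling both areas is neutral; scaling dilution scales conc."""
        base = tq.quantify_is(area, area_is, conc_is, dil)
        assert tq.quantify_is(c * area, c * area_is, conc_is, dil) == pytest.approx(
            base, rel=1e-9
        )
        assert tq.quantify_is(area, area_is, conc_is, c * dil) == pytest.approx(
            c * base, rel=1e-9
        )


class TestFitCalibration:
    @pytest.mark.parametrize("weighting", ["inv_x_squared", "log_log", "none"])
    def test_noiseless_line_recovered_exactly(self, weighting):
        pts = [(c, 3.0 * c) for c in CAL_LEVELS]
        m = tq.fit_calibration(pts, "linear", weighting)
        if weighting == "log_log":
            # line through origin in log space: slope 1, intercept log10(3)
            assert m.coefficients[1] == pytest.approx(1.0, rel=1e-9)
            assert 10 ** m.coefficients[0] == pytest.approx(3.0, rel=1e-9)
        else:
            assert m.coefficients[0] == pytest.approx(0.0, abs=1e-9)
            assert m.coefficients[1] == pytest.approx(3.0, rel=1e-12)
        assert m.r == pytest.approx(1.0, abs=1e-12)

    def test_unweighted_linear_equals_closed_form_ols(self, rng):
        conc = CAL_LEVELS
        resp = 5.0 * conc + 2.0 + rng.normal(0, 0.5, size=conc.size)
        m = tq.fit_calibration(list(zip(conc, resp)), "linear", "none")
        x = np.column_stack([np.ones_like(conc), conc])
        beta = np.linalg.solve(x.T @ x, x.T @ resp)
        assert m.coefficients == pytest.approx(tuple(beta), rel=1e-10)

    def test_minimum_point_counts(self):
        pts = [(float(i), float(i)) for i in range(1, 5)]
        with pytest.raises(FitError):
            tq.fit_calibration(pts, "linear", "none")
        with pytest.raises(FitError):
            tq.fit_calibration(pts + [(5.0, 5.0)], "quadratic", "none")

    def test_nonpositive_conc_rejected_under_weighting(self):
        pts = [(0.0, 1.0)] + [(float(i), float(i)) for i in range(1, 6)]
        with pytest.raises(ValidationError):
            tq.fit_calibration(pts, "linear", "inv_x_squared")

    def test_inverse_variance_weighting_cuts_low_end_bias(self, rng):
        """With noise proportional to conc, 1/x^2 beats OLS at the low end.

        Monte-Carlo: relative error of the back-calculated lowest
        standard, 1000 simulated curves.
        """
        conc = CAL_LEVELS
        truth_slope = 4.0
        low = conc[0]
        err_w, err_u = [], []
        for _ in range(1000):
            resp = truth_slope * conc * (1 + rng.normal(0, 0.05, conc.size))
            mw = tq.fit_calibration(list(zip(conc, resp)), "linear", "inv_x_squared")
            mu = tq.fit_calibration(list(zip(conc, resp)), "linear", "none")
            target = truth_slope * low
            err_w.append(abs(tq.invert_calibration(target, mw).conc - low) / low)
            err_u.append(abs(tq.invert_calibration(target, mu).conc - low) / low)
        assert np.mean(err_w) < np.mean(err_u)


class TestInvertCalibration:
    @pytest.mark.parametrize(
        "kind,weighting",
        [
            ("linear", "inv_x_squared"),
            ("linear", "log_log"),
            ("linear", "none"),
            ("quadratic", "log_log"),
            ("quadratic", "none"),
            ("quadratic", "inv_x_squared"),
        ],
    )
    def test_fit_invert_roundtrip_noiseless(self, kind, weighting):
        """Forward response at known conc inverts back exactly."""
        pts = [(c, 2.0 * c + 0.05 * c**1.5) for c in CAL_LEVELS]
        m = tq.fit_calibration(pts, kind, weighting)
        for conc in [CAL_LEVELS[1], 1.0, CAL_LEVELS[-2]]:
            resp = float(m.predict(conc))
            inv = tq.invert_calibration(resp, m)
            assert inv.conc == pytest.approx(conc, rel=1e-9)

    def test_dilution_multiplies_result(self):
        pts = [(c, 3.0 * c) for c in CAL_LEVELS]
        m = tq.fit_calibration(pts, "linear", "inv_x_squared")
        inv = tq.invert_calibration(float(m.predict(1.0)), m, dilution_factor=5.0)
        assert inv.conc == pytest.approx(5.0, rel=1e-9)

    def test_quadratic_root_matches_numpy_roots_oracle(self):
        pts = [(c, 1.0 + 2.0 * c + 0.3 * c**2) for c in np.linspace(0.5, 10, 8)]
        m = tq.fit_calibration(pts, "quadratic", "none")
        resp = float(m.predict(4.0))
        b0, b1, b2 = m.coefficients
        roots = np.roots([b2, b1, b0 - resp])
        in_range = [r.real for r in roots if abs(r.imag) < 1e-12 and 0.5 <= r.real <= 10]
        assert len(in_range) == 1
        assert tq.invert_calibration(resp, m).conc == pytest.approx(in_range[0], rel=1e-9)

    def test_response_below_curve_reports_zero_below_lod(self):
        pts = [(c, 10.0 + 3.0 * c) for c in CAL_LEVELS]
        m = tq.fit_calibration(pts, "linear", "none")
        inv = tq.invert_calibration(5.0, m)  # below the intercept
        assert inv.conc == 0.0
        assert inv.below_range and inv.below_lod

    def test_two_in_range_roots_raise_instead_of_guessing(self):
        # downward parabola peaking inside the range: two crossings
        conc = np.linspace(1.0, 9.0, 9)
        pts = [(c, -((c - 5.0) ** 2) + 30.0) for c in conc]
        m = tq.fit_calibration(pts, "quadratic", "none")
        with pytest.raises(AmbiguousInversionError):
            tq.invert_calibration(20.0, m)


class TestDetectionLimits:
    @pytest.mark.parametrize(
        "blanks,expected",
        [([0.2, 0.2], 2.0), ([0.0], 0.0), ([0.1, 0.3], 2.0)],
    )
    def test_ten_times_mean_blank(self, blanks, expected):
        lod, loq = tq.blank_lod(blanks)
        assert lod == pytest.approx(expected)
        assert loq == lod

    def test_empty_blanks_rejected(self):
        with pytest.raises(ValidationError):
            tq.blank_lod([])

    def test_sn_lod_is_conc_at_sn3(self):
        # lowest standard 0.01 µM at S/N 12 -> LOD 0.0025 µM
        assert tq.sn_lod(0.01, 12.0) == pytest.approx(0.0025)


def test_quantify_run_pipeline(demo_panel, nist_style_sheet):
    """Whole-matrix IS quantification honours per-sample dilution."""
    import pandas as pd

    from metlab.tables_io import AreaMatrix

    ids = nist_style_sheet.sample_ids
    frame = pd.DataFrame(
        {
            "alanine": 2.0,
            "met_13C_d3": 1.0,
        },
        index=pd.Index(ids, name="sample_id"),
        dtype=float,
    )
    conc, results = tq.quantify_run(AreaMatrix(frame), demo_panel, nist_style_sheet)
    # 2/1 * 0.19 µM IS * dilution 5 = 1.9
    assert np.allclose(conc["alanine"], 1.9)
    assert all(not r.below_lod for r in results)
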