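"""Calibration fitting/inversion, ladder MW estimation, degradation degree."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gelquant.errors import DomainError, FitError, InputError
from gelquant.peakproc import Peak
from gelquant.quant import (
    MolecularWeightLadder,
    QuadraticCalibration,
    degradation_degree,
    estimate_mw,
    fit_calibration,
    fit_ladder,
    invert_calibration,
    predict_content,
)

# Serial-dilution calibration data: loaded mass (µg) vs measured peak area.
DILUTION_POINTS = [(1288.0, 2.0), (934.0, 1.0), (763.0, 0.5), (525.0, 0.25), (348.0, 0.125)]

WEIGHTINGS = ["none", "inverse_Q", "inverse_Q2"]


def normal_equations_oracle(S, Q, weighting):
    """Independent through-origin quadratic fit via explicit normal equations.

    Solves the 2x2 system for min sum w*(Q - a S^2 - b S)^2 directly; written
    separately from the lstsq path used by the estimator.
    """
    S = np.asarray(S, float)
    Q = np.asarray(Q, float)
    w = {"none": np.ones_like(Q), "inverse_Q": 1 / Q, "inverse_Q2": 1 / Q**2}[weighting]
    A = np.array(
        [
            [np.sum(w * S**4), np.sum(w * S**3)],
            [np.sum(w * S**3), np.sum(w * S**2)],
        ]
    )
    rhs = np.array([np.sum(w * S**2 * Q), np.sum(w * S * Q)])
    return np.linalg.solve(A, rhs)


class TestQuadraticCalibration:
    @pytest.mark.parametrize("weighting", WEIGHTINGS)
    def test_exact_quadratic_recovered(self, weighting):
        a, b = 2e-6, 3e-4
        S = np.array([200.0, 500.0, 900.0, 1300.0])
        model = QuadraticCalibration(weighting=weighting).fit(S, a * S**2 + b * S)
        assert model.a_ == pytest.approx(a, rel=1e-9)
        assert model.b_ == pytest.approx(b, rel=1e-9)
        assert model.relative_deviation_pct_ == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("weighting", WEIGHTINGS)
    def test_dilution_series_fit_is_finite_and_through_origin(self, weighting):
        model = fit_calibration(DILUTION_POINTS, weighting=weighting)
        assert np.isfinite([model.a_, model.b_]).all()
        assert model.predict(0.0) == 0.0
        assert model.relative_deviation_pct_ >= 0.0

    @pytest.mark.parametrize("weighting", WEIGHTINGS)
    def test_agrees_with_normal_equations_oracle(self, weighting):
        S = [p[0] for p in DILUTION_POINTS]
        Q = [p[1] for p in DILUTION_POINTS]
        model = QuadraticCalibration(weighting=weighting).fit(S, Q)
        a, b = normal_equations_oracle(S, Q, weighting)
        assert model.a_ == pytest.approx(a, rel=1e-8)
        assert model.b_ == pytest.approx(b, rel=1e-8)

    def test_published_curve_reproduces_loaded_mass(self):
        """Forward evaluation of a published quadratic calibration at the top
        dilution lane's area recovers that lane's loaded mass at 2 s.f."""
        model = QuadraticCalibration.from_coefficients(0.1e-5, 2.6e-4)
        q = predict_content(model, 1288.0)
        assert q == pytest.approx(1.9938, abs=1e-4)
        assert float(f"{q:.2g}") == 2.0

    def test_prediction_strictly_increasing(self):
        model = QuadraticCalibration.from_coefficients(1e-6, 2e-4)
        s = np.linspace(0, 5000, 200)
        assert (np.diff(model.predict(s)) > 0).all()

    def test_negative_area_rejected(self):
        model = QuadraticCalibration.from_coefficients(1e-6, 2e-4)
        with pytest.raises(DomainError):
            model.predict(-1.0)

    def test_too_few_or_degenerate_points_rejected(self):
        with pytest.raises(FitError):
            fit_calibration([(100.0, 1.0), (200.0, 2.0)])
        with pytest.raises(FitError):
            fit_calibration([(100.0, 1.0), (100.0, 2.0), (100.0, 3.0)])

    def test_scale_invariance_unweighted(self):
        """S -> cS recovers a/c^2, b/c with unit weights."""
        a, b, c = 1.5e-6, 4e-4, 7.0
        rng = np.random.default_rng(1)
        S = rng.uniform(100, 2000, 6)
        Q = a * S**2 + b * S + rng.normal(0, 1e-3, 6)
        m1 = QuadraticCalibration(weighting="none").fit(S, Q)
        m2 = QuadraticCalibration(weighting="none").fit(c * S, Q)
        assert m2.a_ == pytest.approx(m1.a_ / c**2, rel=1e-9)
        assert m2.b_ == pytest.approx(m1.b_ / c, rel=1e-9)

    def test_relative_deviation_zero_iff_exact(self):
        S = np.array([300.0, 700.0, 1100.0, 1500.0])
        exact = 2e-6 * S**2 + 3e-4 * S
        m = QuadraticCalibration().fit(S, exact)
        assert m.relative_deviation_pct_ == pytest.approx(0.0, abs=1e-9)
        m2 = QuadraticCalibration().fit(S, exact * [1.0, 1.1, 1.0, 0.95])
        assert m2.relative_deviation_pct_ > 0.1

    def test_sklearn_param_interface(self):
        m = QuadraticCalibration(weighting="inverse_Q")
        assert m.get_params()["weighting"] == "inverse_Q"
        m.set_params(weighting="none", deviation="max")
        S = np.array([200.0, 600.0, 1000.0])
        m.fit(S, 1e-6 * S**2 + 1e-4 * S)
        assert hasattr(m, "a_") and hasattr(m, "relative_deviation_pct_")


class TestInversion:
    def test_zero_mass_maps_to_zero_area(self):
        model = QuadraticCalibration.from_coefficients(1e-6, 2.6e-4)
        assert invert_calibration(model, 0.0) == 0.0

    @pytest.mark.parametrize("S", [10.0, 1e3, 1e5])
    def test_roundtrip(self, S):
        model = QuadraticCalibration.from_coefficients(0.1e-5, 2.6e-4)
        assert invert_calibration(model, model.predict(S)) == pytest.approx(S, rel=1e-9)

    def test_linear_case(self):
        model = QuadraticCalibration.from_coefficients(0.0, 2.6e-4)
        assert invert_calibration(model, 0.26) == pytest.approx(1000.0, rel=1e-12)

    def test_invalid_domains_rejected(self):
        with pytest.raises(DomainError):
            invert_calibration(QuadraticCalibration.from_coefficients(1e-6, 1e-4), -0.5)
        with pytest.raises(DomainError):
            invert_calibration(QuadraticCalibration.from_coefficients(0.0, 0.0), 1.0)


def _exact_law_anchors(n=7, front_row=550):
    """Marker apexes placed exactly on a log-linear mobility law."""
    rf = np.linspace(0.1, 0.95, n)
    logmw = np.linspace(2.06, 1.16, n)  # 116 kDa .. 14.4 kDa, collinear in rf
    return rf * front_row, 10.0**logmw, front_row


class TestMolecularWeightLadder:
    def test_exact_loglinear_law_fit_has_zero_residuals(self):
        apex, mws, front = _exact_law_anchors()
        lad = MolecularWeightLadder(mode="loglinear").fit(apex, mws, front)
        for a, m in zip(apex, mws):
            assert lad.predict(a / front) == pytest.approx(m, rel=1e-9)

    def test_piecewise_reproduces_every_anchor_exactly(self):
        apex, mws, front = _exact_law_anchors()
        lad = MolecularWeightLadder(mode="piecewise").fit(apex, mws, front)
        for a, m in zip(apex, mws):
            mw, ext = lad.predict_with_flags(a / front)
            assert mw == pytest.approx(m, rel=1e-12)
            assert not ext

    def test_midpoint_is_geometric_mean_of_neighbors(self):
        apex = np.array([100.0, 200.0])
        mws = np.array([80.0, 20.0])
        lad = MolecularWeightLadder(mode="piecewise").fit(apex, mws, 500)
        assert lad.predict(150.0 / 500) == pytest.approx(np.sqrt(80 * 20), rel=1e-12)

    def test_removing_interior_anchor_only_changes_between_neighbors(self):
        apex, mws, front = _exact_law_anchors()
        # perturb one anchor off the global law so its removal matters
        mws = mws * np.array([1, 1, 1, 1.15, 1, 1, 1])
        order = np.argsort(apex)
        apex, mws = apex[order], mws[order]
        full = MolecularWeightLadder(mode="piecewise").fit(apex, mws, front)
        keep = [i for i in range(len(apex)) if i != 3]
        reduced = MolecularWeightLadder(mode="piecewise").fit(apex[keep], mws[keep], front)
        grid = np.linspace(apex[0], apex[-1], 300) / front
        m_full, _ = full.predict_with_flags(grid)
        m_red, _ = reduced.predict_with_flags(grid)
        inside = (grid > apex[2] / front) & (grid < apex[4] / front)
        np.testing.assert_allclose(m_full[~inside], m_red[~inside], rtol=1e-12)
        assert np.abs(m_full[inside] / m_red[inside] - 1).max() > 1e-3

    @pytest.mark.parametrize("mode", ["piecewise", "loglinear"])
    def test_strictly_decreasing_in_rf(self, mode):
        apex, mws, front = _exact_law_anchors()
        lad = MolecularWeightLadder(mode=mode).fit(apex, mws, front)
        grid = np.linspace(apex[0], apex[-1], 200) / front
        m, _ = lad.predict_with_flags(grid)
        assert (np.diff(m) < 0).all()

    def test_extrapolation_flagged(self):
        apex, mws, front = _exact_law_anchors()
        lad = MolecularWeightLadder(mode="piecewise").fit(apex, mws, front)
        _, ext = lad.predict_with_flags(0.99)
        assert ext

    def test_invalid_inputs_rejected(self):
        with pytest.raises(InputError):  # masses not decreasing with migration
            MolecularWeightLadder().fit([100, 200], [20.0, 80.0], 500)
        with pytest.raises(InputError):  # front not beyond all apexes
            MolecularWeightLadder().fit([100, 400], [80.0, 20.0], 300)
        with pytest.raises(InputError):  # count mismatch
            MolecularWeightLadder().fit([100, 200, 300], [80.0, 20.0], 500)
        lad = MolecularWeightLadder().fit([100, 200], [80.0, 20.0], 500)
        with pytest.raises(DomainError):
            lad.predict(1.5)

    def test_fit_ladder_wrapper_accepts_peaks(self):
        peaks = [Peak(3, a, a - 2, a + 3, 10.0, 5.0) for a in (100, 250, 400)]
        lad = fit_ladder(peaks, [90.0, 40.0, 15.0], front_row=500)
        mw, ext = estimate_mw(lad, 250, 500)
        assert mw == pytest.approx(40.0, rel=1e-12)
        assert not ext
        with pytest.raises(DomainError):
            estimate_mw(lad, 600, 500)

    def test_unknown_band_mw_recovered_from_synthetic_gel(self, calibration_gel):
        """Pipeline end to end: unknown band planted by the generator's
        mobility law is read back within 2% via the marker ladder."""
        from conftest import lanes_config
        from gelquant.cli import RunConfig, run_quantify

        spec = calibration_gel["spec"]
        masses = {
            b.lane_id: b.mass_ug for b in spec.bands if b.kind == "native"
        }
        cfg = RunConfig(
            image=str(calibration_gel["path"]),
            lanes=lanes_config(spec),
            calibration_masses={k: masses[k] for k in range(1, 6)},
            marker_masses=list(synthgel_marker(spec)),
            front_row=spec.front_row,
        )
        cfg.validate()
        rep = run_quantify(cfg, write=False)
        q = rep["quantification"]
        sample = q[(q.role == "sample")].sort_values("area", ascending=False).iloc[0]
        assert sample.estimated_mw_kDa == pytest.approx(66.0, rel=0.02)


def synthgel_marker(spec):
    return sorted(
        (b.mw for b in spec.bands if b.kind == "marker"), reverse=True
    )


class TestDegradationDegree:
    def test_no_loss_gives_zero(self):
        assert degradation_degree(1000.0, 1000.0).alpha_pct == 0.0

    def test_total_loss_gives_hundred(self):
        assert degradation_degree(1000.0, 0.0).alpha_pct == 100.0

    def test_worked_ratio(self):
        assert degradation_degree(1288.0, 103.04).alpha_pct == pytest.approx(92.0, abs=1e-9)

    def test_apparent_gain_warns_and_goes_negative(self):
        with pytest.warns(UserWarning):
            res = degradation_degree(100.0, 110.0)
        assert res.alpha_pct == pytest.approx(-10.0)

    def test_invalid_areas_rejected(self):
        with pytest.raises(DomainError):
            degradation_degree(0.0, 10.0)
        with pytest.raises(DomainError):
            degradation_degree(10.0, -1.0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        S0=st.floats(1e-3, 1e6),
        St=st.floats(0, 1e6),
        c=st.floats(1e-3, 1e3),
    )
    def test_unit_free_and_antitone(self, S0, St, c):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = degradation_degree(S0, St).alpha_pct
            a_scaled = degradation_degree(c * S0, c * St).alpha_pct
            assert a_scaled == pytest.approx(a, rel=1e-9, abs=1e-9)
            if St * 1.1 <= 1e6:
                assert degradation_degree(S0, St * 1.1 + 1e-6).alpha_pct < a
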