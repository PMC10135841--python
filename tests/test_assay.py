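"""Assay calculation chain: curves, rates, units, recovery statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from c1flux import (
    AssayTrace,
    SyntheticTraceSpec,
    fit_standard_curve,
    initial_rate,
    make_standard_curve_points,
    make_trace,
    phb_content,
    protein_from_od,
    specific_activity,
)


class TestStandardCurve:
    def test_exact_line(self):
        curve = fit_standard_curve([0, 0.1, 0.2], [0.0, 0.062, 0.124])
        assert curve.slope == pytest.approx(0.62, abs=1e-12)
        assert curve.intercept == pytest.approx(0.0, abs=1e-12)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_nonlinear_points_warn(self):
        with pytest.warns(UserWarning, match="below"):
            curve = fit_standard_curve([0, 0.1, 0.2], [0.0, 0.124, 0.062])
        assert curve.r_squared < 0.98

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_standard_curve([0.1, 0.1, 0.1], [1, 2, 3])
        with pytest.raises(ValueError, match="at least 3"):
            fit_standard_curve([0, 1], [0, 1])

    def test_noisy_slope_recovered_within_three_se(self):
        """sigma = 0.002 AU noise on a known 0.62 AU/mM line."""
        conc, ab = make_standard_curve_points(seed=11, slope=0.62, noise_sd=0.002)
        curve = fit_standard_curve(conc, ab)
        # standard error of an OLS slope with known noise sd
        se = 0.002 / np.sqrt(((conc - conc.mean()) ** 2).sum())
        assert abs(curve.slope - 0.62) < 3 * se


class TestInitialRate:
    CURVE = None

    @pytest.fixture(autouse=True)
    def _curve(self):
        type(self).CURVE = fit_standard_curve([0, 0.1, 0.2], [0.0, 0.062, 0.124])

    def test_exact_division(self):
        t = np.arange(6.0)
        trace = AssayTrace(tuple(t), tuple(0.05 + 0.0062 * t))
        assert initial_rate(trace, self.CURVE) == pytest.approx(0.01, abs=1e-12)

    def test_flat_trace_is_zero(self):
        trace = AssayTrace((0, 1, 2, 3), (0.05, 0.05, 0.05, 0.05))
        assert initial_rate(trace, self.CURVE) == pytest.approx(0.0, abs=1e-12)

    def test_window_validation_and_time_ordering(self):
        trace = AssayTrace((0, 1, 2), (0.0, 0.1, 0.2))
        with pytest.raises(ValueError, match="window"):
            initial_rate(trace, self.CURVE, window=1)
        with pytest.raises(ValueError, match="increasing"):
            AssayTrace((0, 2, 1), (0.0, 0.1, 0.2))

    def test_saturating_trace_falls_back_to_linear_prefix(self):
        """Steady state after 5 min: the adaptive window must not average the
        plateau into the initial slope."""
        t = np.arange(10.0)
        conc_like = np.minimum(0.0062 * t, 0.0062 * 5)
        trace = AssayTrace(tuple(t), tuple(0.05 + conc_like))
        rate = initial_rate(trace, self.CURVE)
        assert rate == pytest.approx(0.01, rel=1e-6)

    def test_blank_subtraction_shifts_not_slope(self):
        t = np.arange(6.0)
        trace = AssayTrace(tuple(t), tuple(0.30 + 0.0062 * t))
        assert initial_rate(trace, self.CURVE, blank=0.25) == pytest.approx(
            initial_rate(trace, self.CURVE), abs=1e-12
        )

    def test_round_trip_identity_zero_noise(self):
        """Generator -> rate estimator is the identity on noise-free traces."""
        for rate in (0.0, 0.004, 0.01, 0.05):
            trace, truth = make_trace(
                SyntheticTraceSpec(seed=1, true_rate=rate, curve_slope=0.62, noise_sd=0.0)
            )
            assert initial_rate(trace, self.CURVE) == pytest.approx(truth, abs=1e-9)

    @pytest.mark.parametrize("noise_sd", [0.001, 0.005])
    def test_rate_recovery_bias_under_noise(self, noise_sd):
        """Over 200 seeded traces, mean recovered rate is within 2% of truth
        and +-2 SE empirical coverage is near 95%."""
        true_rate = 0.01
        estimates = []
        covered = 0
        t = np.arange(10.0)
        x = t[:5] - t[:5].mean()
        # SE of the 5-point initial-rate slope given the AU noise level
        se = (noise_sd / 0.62) / np.sqrt((x**2).sum())
        for seed in range(200):
            trace, _ = make_trace(
                SyntheticTraceSpec(seed=seed, true_rate=true_rate,
                                   curve_slope=0.62, noise_sd=noise_sd)
            )
            est = initial_rate(trace, self.CURVE, window=5)
            estimates.append(est)
            covered += abs(est - true_rate) <= 2 * se
        bias = abs(np.mean(estimates) - true_rate) / true_rate
        assert bias <= 0.02
        assert 0.90 <= covered / 200 <= 1.0


class TestUnitsAndContent:
    def test_specific_activity_under_both_unit_conventions(self):
        paper = specific_activity(0.01, 0.2)
        assert paper.total_units == pytest.approx(0.01)
        assert paper.specific_activity == pytest.approx(50.0)
        conventional = specific_activity(0.01, 0.2, units="umol", reaction_volume_l=200e-6)
        assert conventional.total_units == pytest.approx(0.002)  # umol/min
        assert conventional.specific_activity == pytest.approx(10.0)
        assert specific_activity(0.0, 0.2).specific_activity == 0.0
        with pytest.raises(ValueError, match="protein"):
            specific_activity(0.01, 0.0)
        with pytest.raises(ValueError, match="units"):
            specific_activity(0.01, 0.2, units="kat")

    @settings(deadline=None, max_examples=40)
    @given(
        rate=st.floats(min_value=1e-6, max_value=1.0),
        protein=st.floats(min_value=1e-3, max_value=10.0),
        k=st.floats(min_value=0.1, max_value=10.0),
    )
    def test_specific_activity_linearity(self, rate, protein, k):
        base = specific_activity(rate, protein).specific_activity
        assert specific_activity(k * rate, protein).specific_activity == pytest.approx(
            k * base, rel=1e-9
        )
        assert specific_activity(rate, k * protein).specific_activity == pytest.approx(
            base / k, rel=1e-9
        )

    def test_protein_from_od_rule(self):
        assert protein_from_od(1.0, 1.0) == pytest.approx(125.0)
        assert protein_from_od(0.0, 1.0) == 0.0
        assert protein_from_od(2.0, 0.05) == pytest.approx(12.5)
        with pytest.raises(ValueError):
            protein_from_od(-1, 1)
        with pytest.raises(ValueError):
            protein_from_od(1, 0)

    def test_phb_content_formula_and_validation(self):
        assert phb_content(0.619, 10.0) == pytest.approx(6.19)
        assert phb_content(0.0, 10.0) == 0.0
        assert phb_content(5.0, 5.0) == pytest.approx(100.0)
        with pytest.raises(ValueError, match="inconsistent"):
            phb_content(11.0, 10.0)
        with pytest.raises(ValueError):
            phb_content(1.0, 0.0)
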