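"""Unit tests for 4PL concentration-response fitting and IC50 calls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vsdassay.dose_response import (
    DoseResponseModel,
    fit_crc,
    four_param_logistic,
    ic50_from_antagonist_run,
    minmax_normalize,
)

CONCS = np.logspace(-8.5, -4, 8)


class TestFourParamLogistic:
    def test_midpoint_identity(self):
        # f(ec50) is exactly the asymptote midpoint
        assert four_param_logistic(1e-6, 1.0, 5.0, 1e-6, 1.7) == (1.0 + 5.0) / 2

    def test_zero_concentration_gives_bottom(self):
        assert four_param_logistic(0.0, 1.0, 5.0, 1e-6, 2.0) == 1.0


class TestCRCFit:
    def test_noiseless_parameter_recovery(self):
        true = dict(bottom=1.0, top=5.0, ec50=1e-6, hill=1.0)
        y = four_param_logistic(CONCS, **true)
        fit = DoseResponseModel(CONCS, y).fit()
        assert fit.ec50 == pytest.approx(true["ec50"], rel=1e-6)
        assert fit.hill == pytest.approx(true["hill"], rel=1e-6)
        assert fit.top == pytest.approx(true["top"], rel=1e-6)
        assert fit.bottom == pytest.approx(true["bottom"], rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.direction == "ascending"
        assert not fit.censored

    @given(
        log_ec50=st.floats(-7.5, -5.0),
        hill=st.floats(0.5, 3.0),
        top=st.floats(2.0, 10.0),
    )
    @settings(max_examples=25, deadline=None)
    def test_recovery_across_parameter_space(self, log_ec50, hill, top):
        y = four_param_logistic(CONCS, 1.0, top, 10.0**log_ec50, hill)
        fit = DoseResponseModel(CONCS, y).fit()
        assert fit.ec50 == pytest.approx(10.0**log_ec50, rel=1e-4)
        assert fit.hill == pytest.approx(hill, rel=1e-4)

    def test_flat_curve_outcome_for_constant_response(self):
        fit = DoseResponseModel(CONCS, np.ones_like(CONCS)).fit()
        assert fit.flat
        assert fit.ec50 is None
        assert "flat" in fit.summary()

    def test_descending_resistance_mode(self):
        # Rd/Rc falls with agonist concentration: the "inverse sigmoid"
        y = four_param_logistic(CONCS, 1.0, 0.2, 1e-6, 1.0)
        fit = DoseResponseModel(CONCS, y).fit()
        assert fit.direction == "descending"
        assert fit.ec50 == pytest.approx(1e-6, rel=1e-5)

    def test_concentration_unit_rescaling(self):
        y = four_param_logistic(CONCS, 1.0, 5.0, 1e-6, 1.4)
        fit_m = DoseResponseModel(CONCS, y).fit()
        fit_um = DoseResponseModel(CONCS * 1e6, y).fit()
        assert fit_um.ec50 == pytest.approx(fit_m.ec50 * 1e6, rel=1e-6)
        assert fit_um.hill == pytest.approx(fit_m.hill, rel=1e-6)
        assert fit_um.r_squared == pytest.approx(fit_m.r_squared, abs=1e-9)

    def test_out_of_range_ec50_censored(self):
        y = four_param_logistic(CONCS, 1.0, 5.0, 1e-10, 1.0)
        y += np.linspace(0, 0.3, len(y))  # keep a fittable window
        fit = DoseResponseModel(CONCS, y, min_range=0.05).fit()
        assert fit.censored

    def test_needs_four_distinct_concentrations(self):
        with pytest.raises(ValueError, match="4 distinct"):
            DoseResponseModel([1e-7, 1e-6, 1e-5], [1, 2, 3]).fit()

    def test_bottom_fixed_mode(self):
        y = four_param_logistic(CONCS, 1.0, 5.0, 1e-6, 1.0)
        fit = DoseResponseModel(CONCS, y, bottom_fixed=1.0).fit()
        assert fit.bottom == pytest.approx(1.0, abs=1e-9)
        assert fit.ec50 == pytest.approx(1e-6, rel=1e-5)

    def test_weighted_fit_downweights_noisy_point(self):
        y = four_param_logistic(CONCS, 1.0, 5.0, 1e-6, 1.0)
        y_bad = y.copy()
        y_bad[3] += 1.0
        se = np.full_like(y, 0.05)
        se[3] = 5.0
        fit_w = DoseResponseModel(CONCS, y_bad, se=se).fit()
        fit_u = DoseResponseModel(CONCS, y_bad, se=se, weighted=False).fit()
        assert abs(fit_w.ec50 - 1e-6) < abs(fit_u.ec50 - 1e-6)

    def test_fit_crc_accepts_tuples(self):
        y = four_param_logistic(CONCS, 1.0, 5.0, 1e-6, 1.0)
        fit = fit_crc(list(zip(CONCS, y)))
        assert fit.ec50 == pytest.approx(1e-6, rel=1e-5)


class TestMinMaxNormalize:
    def test_arithmetic(self):
        assert np.allclose(minmax_normalize([1, 3, 5]), [0, 0.5, 1])

    def test_idempotent_on_normalized(self):
        v = np.array([0.0, 0.25, 1.0])
        assert np.allclose(minmax_normalize(v), v)

    @given(a=st.floats(0.1, 10), b=st.floats(-5, 5))
    @settings(max_examples=30, deadline=None)
    def test_affine_invariance(self, a, b):
        v = np.array([0.2, 0.9, 1.4, 3.0])
        assert np.allclose(minmax_normalize(a * v + b), minmax_normalize(v))

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            minmax_normalize([2.0, 2.0])


class TestAntagonistIC50:
    ANTAG_CONCS = np.logspace(-9, -4, 8)

    def _responses(self, ic50, agonist_response=5.0):
        block = 1.0 / (1.0 + self.ANTAG_CONCS / ic50)
        return 1.0 + (agonist_response - 1.0) * block

    def test_ic50_recovery(self):
        fit = ic50_from_antagonist_run(
            self.ANTAG_CONCS, self._responses(1e-6), agonist_alone_response=5.0
        )
        assert fit.direction == "descending"
        assert fit.ic50 == pytest.approx(1e-6, rel=0.05)

    def test_zero_potency_inactive_call(self):
        resp = np.full_like(self.ANTAG_CONCS, 5.0)
        resp[-1] = 4.5  # < 50 % of the window
        fit = ic50_from_antagonist_run(
            self.ANTAG_CONCS, resp, agonist_alone_response=5.0
        )
        assert fit.inactive
        assert fit.ic50 is None

    def test_infinite_potency_flagged_out_of_range(self):
        # true IC50 well below the lowest tested concentration
        resp = self._responses(3e-10)
        fit = ic50_from_antagonist_run(
            self.ANTAG_CONCS, resp, agonist_alone_response=5.0, min_range=0.05
        )
        assert fit.censored
        assert fit.ic50 < self.ANTAG_CONCS.min()

    def test_missing_anchor_rejected(self):
        with pytest.raises(ValueError, match="anchor"):
            ic50_from_antagonist_run(
                self.ANTAG_CONCS, self._responses(1e-6), agonist_alone_response=None
            )
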