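import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from painlaw import (
    DomainError,
    FitError,
    PowerLawParams,
    TimeSeriesRecord,
    evaluate,
    fit_prefactor_fixed_exponent,
    fit_two_param,
    geometric_from_nrs,
    half_reduction_time,
    halving_ratio,
    nrs_from_geometric,
    step_ratio_from_endpoints,
)
from conftest import powerlaw_record


class TestEvaluate:
    def test_value_at_zero_is_prefactor(self):
        assert evaluate(PowerLawParams(6, 0.3, 1), 0) == pytest.approx(6.0)

    def test_unit_case(self):
        assert evaluate(PowerLawParams(1, 1, 1), 1) == pytest.approx(0.5)

    def test_direct_exponentiation_oracle(self):
        assert evaluate(PowerLawParams(8, 0.3, 1), 12) == pytest.approx(8 * 13 ** (-0.3), rel=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(DomainError):
            evaluate(PowerLawParams(5, 0.3, 1), -1)

    def test_strictly_decreasing_and_convex(self):
        t = np.linspace(0, 40, 201)
        f = evaluate(PowerLawParams(7, 0.5, 1), t)
        assert np.all(np.diff(f) < 0)
        assert np.all(np.diff(f, 2) > 0)

    def test_invalid_params_rejected(self):
        with pytest.raises(DomainError):
            PowerLawParams(-1, 0.3, 1)
        with pytest.raises(DomainError):
            PowerLawParams(1, 0.3, 0)


class TestFitTwoParam:
    def test_noise_free_recovery(self):
        rec = powerlaw_record("r", 5.0, 0.4)
        fit = fit_two_param(rec)
        assert fit.exponent == pytest.approx(0.4, abs=1e-9)
        assert fit.prefactor == pytest.approx(5.0, abs=1e-9)

    def test_flat_record(self):
        rec = TimeSeriesRecord("r", (0, 1, 6, 12), (3, 3, 3, 3))
        fit = fit_two_param(rec)
        assert fit.exponent == pytest.approx(0.0, abs=1e-12)
        assert fit.prefactor == pytest.approx(3.0, rel=1e-12)

    def test_noisy_recovery_within_tolerance(self, rng):
        true = PowerLawParams(5.0, 0.35, 1.0)
        grid = (0.0, 1.0, 6.0, 12.0)
        vals = evaluate(true, np.array(grid)) * np.exp(rng.normal(0, 0.05, len(grid)))
        rec = TimeSeriesRecord("r", grid, tuple(vals), scale="geometric")
        assert fit_two_param(rec).exponent == pytest.approx(0.35, abs=0.1)

    def test_too_few_marks(self, exact_record):
        with pytest.raises(FitError):
            fit_two_param(exact_record, marks=[0.0])

    def test_marks_subset(self):
        rec = powerlaw_record("r", 5.0, 0.4)
        fit = fit_two_param(rec, marks=[0.0, 6.0])
        assert fit.exponent == pytest.approx(0.4, abs=1e-9)

    @given(
        prefactor=st.floats(2.0, 9.0),
        exponent=st.floats(-1.0, 1.0),  # keeps all values above the log floor
    )
    def test_fit_inverts_evaluate(self, prefactor, exponent):
        rec = powerlaw_record("r", prefactor, exponent)
        fit = fit_two_param(rec)
        assert math.isclose(fit.exponent, exponent, abs_tol=1e-9)
        assert math.isclose(fit.prefactor, prefactor, rel_tol=1e-9)


class TestFixedExponentPrefactor:
    def test_exact_power_law_prefactor(self):
        rec = powerlaw_record("r", 5.0, 0.4)
        assert fit_prefactor_fixed_exponent(rec, 0.4) == pytest.approx(5.0, rel=1e-12)

    def test_hand_computed_mean(self):
        rec = TimeSeriesRecord("r", (0, 1), (4.0, 4.0))
        expected = (4 * 1.0 + 4 * 2**0.3) / 2  # per-mark prefactors A_k
        assert fit_prefactor_fixed_exponent(rec, 0.3) == pytest.approx(expected, rel=1e-12)

    def test_single_mark(self):
        rec = TimeSeriesRecord("r", (0, 1), (4.0, 3.0))
        assert fit_prefactor_fixed_exponent(rec, 0.3, marks=[0.0]) == pytest.approx(4.0)

    def test_empty_marks(self, exact_record):
        with pytest.raises(FitError):
            fit_prefactor_fixed_exponent(exact_record, 0.3, marks=[])


class TestHalvingRatio:
    def test_case_study_value(self):
        # P = 1.7 -> M = 1.5 to 2 significant figures
        assert round(halving_ratio(1.7), 1) == 1.5

    def test_unit_exponent(self):
        assert halving_ratio(1.0) == pytest.approx(2.0)

    def test_small_exponent(self):
        assert halving_ratio(0.4) == pytest.approx(2**2.5, rel=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(DomainError):
            halving_ratio(0.0)
        with pytest.raises(DomainError):
            halving_ratio(-0.3)


class TestHalfReductionTime:
    def test_day_30_case(self):
        assert round(half_reduction_time(30, 1.7)) == 45

    def test_month_24_case(self):
        assert round(half_reduction_time(24, 1.7)) == 36

    def test_small_exponent_long_horizon(self):
        t_half = half_reduction_time(12, 0.4)
        assert t_half == pytest.approx(12 * 2**2.5, rel=1e-12)  # 67.88 months
        additional_years = (t_half - 12) / 12
        assert round(additional_years) == 5

    def test_nonpositive_time_rejected(self):
        with pytest.raises(DomainError):
            half_reduction_time(0, 1.7)

    @given(u=st.floats(0.1, 100.0), exponent=st.floats(0.1, 3.0))
    def test_exact_halving_identity_in_shifted_time(self, u, exponent):
        # pure power law in u = t0 + t: F(u*M) = F(u)/2
        m = halving_ratio(exponent)
        f = lambda x: x ** (-exponent)
        assert math.isclose(f(u * m), f(u) / 2, rel_tol=1e-9)


class TestGeometricScale:
    def test_level_8(self):
        assert geometric_from_nrs(8) == pytest.approx(256.0)

    def test_level_0_is_unity(self):
        assert geometric_from_nrs(0) == pytest.approx(1.0)

    def test_round_trip(self):
        assert nrs_from_geometric(geometric_from_nrs(5.5)) == pytest.approx(5.5, rel=1e-12)

    def test_bad_ratio(self):
        with pytest.raises(DomainError):
            geometric_from_nrs(3, step_ratio=0)

    @given(n=st.floats(0.01, 10.0), ratio=st.floats(1.1, 5.0))
    def test_mutual_inverses(self, n, ratio):
        assert math.isclose(nrs_from_geometric(geometric_from_nrs(n, ratio), ratio), n, rel_tol=1e-9)


class TestStepRatio:
    def test_six_steps_of_two(self):
        assert step_ratio_from_endpoints(64, 6) == pytest.approx(2.0)

    def test_unit_ratio(self):
        assert step_ratio_from_endpoints(1, 6) == pytest.approx(1.0)

    def test_case_study_endpoints(self):
        # proxy 70 at NRS 8 vs proxy ~1.09 at NRS 2: 6 scale steps, ratio near 2
        assert step_ratio_from_endpoints(70 / 1.09, 6) == pytest.approx(2.0, abs=0.01)

    def test_zero_steps_rejected(self):
        with pytest.raises(DomainError):
            step_ratio_from_endpoints(64, 0)
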