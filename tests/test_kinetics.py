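"""Undersaturation, rate extraction and power-law fitting."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from comdiss.errors import FitError, SupersaturationError, ValidationError
from comdiss.kinetics import (
    DissolutionRun,
    RatePoint,
    TitrationTrace,
    fit_rate_law,
    percent_inhibition,
    rate_from_titration,
    relative_undersaturation,
)

H0 = 1.994e-4


class TestRelativeUndersaturation:
    @pytest.mark.parametrize(
        "h, expected",
        [
            (1.994e-4, 0.0),        # saturated
            (0.0, 1.0),             # pure solvent
            (1.433e-4, 0.2814),     # published row, printed 28e-2
            (1.791e-4, 0.1018),     # published row, printed 10e-2
        ],
    )
    def test_reference_values(self, h, expected):
        assert relative_undersaturation(h, H0) == pytest.approx(expected, abs=1e-4)

    def test_supersaturation_rejected(self):
        with pytest.raises(SupersaturationError):
            relative_undersaturation(2.1e-4, H0)

    @given(
        h=st.floats(min_value=0.0, max_value=1.0, exclude_max=True),
        c=st.floats(min_value=1e-6, max_value=1e6),
    )
    def test_scale_invariance(self, h, c):
        """σ is unchanged when both ion products are scaled together."""
        assert relative_undersaturation(h * c, 1.0 * c) == pytest.approx(
            relative_undersaturation(h, 1.0), rel=1e-9, abs=1e-12
        )

    @given(
        h1=st.floats(min_value=0.0, max_value=0.99),
        h2=st.floats(min_value=0.0, max_value=0.99),
    )
    def test_strictly_decreasing_in_ion_product(self, h1, h2):
        if h1 == h2:
            return
        lo, hi = sorted((h1, h2))
        assert relative_undersaturation(hi, 1.0) < relative_undersaturation(lo, 1.0)


class TestRateFromTitration:
    def test_hand_computed_linear_trace(self):
        """0.01 M titrant at 0.0113 cm³/min over 10 mg × 3.73 m²/g."""
        t = np.arange(0.0, 31.0)
        trace = TitrationTrace(
            times=t, titrant_volume=0.0113 * t, titrant_conc=0.01,
            seed_mass=10.0, specific_surface_area=3.73,
        )
        assert rate_from_titration(trace) == pytest.approx(3.0295e-6, rel=1e-3)

    def test_constant_volume_means_zero_rate(self):
        trace = TitrationTrace(
            times=[0, 1, 2, 3], titrant_volume=[0.5, 0.5, 0.5, 0.5],
            titrant_conc=0.01, seed_mass=10.0,
        )
        assert rate_from_titration(trace) == pytest.approx(0.0, abs=1e-18)

    def test_doubling_seed_mass_halves_rate(self):
        t = np.arange(0.0, 11.0)
        kwargs = dict(times=t, titrant_volume=0.02 * t, titrant_conc=0.01)
        r10 = rate_from_titration(TitrationTrace(**kwargs, seed_mass=10.0))
        r20 = rate_from_titration(TitrationTrace(**kwargs, seed_mass=20.0))
        assert r20 == pytest.approx(r10 / 2.0, rel=1e-12)

    def test_non_monotone_volume_rejected(self):
        with pytest.raises(ValidationError):
            TitrationTrace(
                times=[0, 1, 2], titrant_volume=[0.0, 0.5, 0.2],
                titrant_conc=0.01, seed_mass=10.0,
            )

    def test_too_few_points_rejected(self):
        trace = TitrationTrace(
            times=[0.0], titrant_volume=[0.0], titrant_conc=0.01, seed_mass=10.0
        )
        with pytest.raises(ValidationError):
            rate_from_titration(trace)

    def test_burn_in_trims_initial_transient(self):
        t = np.arange(0.0, 21.0)
        v = 0.01 * t
        v[:5] += np.linspace(0.05, 0.0, 5)  # decaying transient
        trace = TitrationTrace(times=t, titrant_volume=np.maximum.accumulate(v),
                               titrant_conc=0.01, seed_mass=10.0)
        full = rate_from_titration(trace)
        trimmed = rate_from_titration(trace, burn_in_fraction=0.3)
        true = 0.01 * 0.01 * 1e-3 / (10e-3 * 3.73)
        assert abs(trimmed - true) < abs(full - true)


def _power_law_run(k, n, sigmas, rpm=None):
    points = [
        RatePoint(sigma=s, rate=k * s ** n,
                  stirring=300.0 if rpm is None else rpm[i])
        for i, s in enumerate(sigmas)
    ]
    return DissolutionRun(points=points, label="synthetic")


class TestFitRateLaw:
    def test_exact_power_law_recovery(self):
        run = _power_law_run(1e-4, 2.0, [0.1, 0.15, 0.2, 0.25, 0.3])
        fit = fit_rate_law(run)
        assert fit.n == pytest.approx(2.0, rel=1e-10)
        assert fit.k == pytest.approx(1e-4, rel=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    @given(
        n=st.floats(min_value=0.5, max_value=4.0),
        logk=st.floats(min_value=-7.0, max_value=-2.0),
    )
    def test_exact_recovery_across_parameter_space(self, n, logk):
        run = _power_law_run(10.0 ** logk, n, [0.05, 0.1, 0.18, 0.25, 0.3])
        fit = fit_rate_law(run)
        assert fit.n == pytest.approx(n, rel=1e-8, abs=1e-10)
        assert fit.k == pytest.approx(10.0 ** logk, rel=1e-8)

    def test_control_series_order_and_constant(self, dissolution_runs):
        """Free OLS on the reference control series: n ≈ 1.69 → order 2."""
        control, _ = dissolution_runs
        fit = fit_rate_law(control)
        assert fit.n == pytest.approx(1.689, abs=0.005)
        assert fit.n_rounded == 2
        assert fit.k > 0

    def test_additive_series_order(self, dissolution_runs):
        _, additive = dissolution_runs
        fit = fit_rate_law(additive)
        assert fit.n == pytest.approx(1.753, abs=0.005)
        assert fit.n_rounded == 2

    def test_stirring_speed_is_ignored(self):
        """Transport-independent kinetics: permuting rpm leaves the fit."""
        sig = [0.1, 0.15, 0.2, 0.25, 0.3]
        base = _power_law_run(1e-4, 1.7, sig)
        permuted = _power_law_run(1e-4, 1.7, sig, rpm=[500, 100, 300, 200, 400])
        f1, f2 = fit_rate_law(base), fit_rate_law(permuted)
        assert (f1.n, f1.k) == (f2.n, f2.k)

    def test_too_few_points_rejected(self):
        run = _power_law_run(1e-4, 2.0, [0.1, 0.2])
        with pytest.raises(ValidationError):
            fit_rate_law(run)

    def test_degenerate_design_rejected(self):
        run = DissolutionRun(
            points=[RatePoint(sigma=0.2, rate=r) for r in (1e-6, 2e-6, 3e-6)]
        )
        with pytest.raises(FitError):
            fit_rate_law(run)


class TestPercentInhibition:
    @pytest.mark.parametrize(
        "r0, ri, expected",
        [
            (3.027e-6, 3.027e-6, 0.0),
            (3.027e-6, 2.466e-6, 18.53),   # published "at least 18.519%"
            (3.027e-6, 2.712e-6, 10.41),   # published 10.417
        ],
    )
    def test_reference_values(self, r0, ri, expected):
        assert percent_inhibition(r0, ri) == pytest.approx(expected, abs=0.02)

    def test_promotion_flagged_not_errored(self):
        with pytest.warns(UserWarning):
            value = percent_inhibition(1e-6, 1.2e-6)
        assert value < 0

    @given(
        ri=st.floats(min_value=1e-9, max_value=1e-6),
        rj=st.floats(min_value=1e-9, max_value=1e-6),
    )
    def test_monotone_decreasing_in_inhibited_rate(self, ri, rj):
        if ri == rj:
            return
        lo, hi = sorted((ri, rj))
        assert percent_inhibition(1e-6, hi) < percent_inhibition(1e-6, lo)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValidationError):
            percent_inhibition(0.0, 1e-6)
        with pytest.raises(ValidationError):
            percent_inhibition(1e-6, 0.0)


class TestRatePointValidation:
    def test_sigma_bounds(self):
        with pytest.raises(ValidationError):
            RatePoint(sigma=1.0, rate=1e-6)
        with pytest.raises(ValidationError):
            RatePoint(sigma=-0.1, rate=1e-6)

    def test_positive_rate_and_seed(self):
        with pytest.raises(ValidationError):
            RatePoint(sigma=0.2, rate=0.0)
        with pytest.raises(ValidationError):
            RatePoint(sigma=0.2, rate=1e-6, seed_mass=0.0)
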