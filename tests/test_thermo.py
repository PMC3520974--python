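"""Binding equilibrium, titration fits, calorimetry and correlations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

from colinshift import (
    TitrationSeries,
    correlate,
    dG_to_kd,
    fit_delta_cp,
    fit_kd,
    fraction_bound,
    generate_titration,
    growth_threshold_analysis,
    kd_to_dG,
    ligand_for_saturation,
)

SCHEDULE = [0, 10, 25, 50, 75, 100, 150, 200, 400, 800]


def bisection_fraction(kd, P, L):
    """Independent oracle: solve the mass balance for free protein by bisection."""
    if L == 0:
        return 0.0

    def residual(pl):
        return (P - pl) * (L - pl) - kd * pl

    return optimize.bisect(residual, 0.0, min(P, L), xtol=1e-12) / P


class TestFractionBound:
    def test_zero_ligand_gives_zero(self):
        assert fraction_bound(10.0, 100.0, 0.0) == 0.0

    def test_stoichiometric_limit(self):
        assert fraction_bound(1e-12, 100.0, 150.0) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("kd,P,L", [(10.0, 100.0, 200.0),
                                        (250.0, 70.0, 50.0),
                                        (1.0, 100.0, 100.0)])
    def test_quadratic_matches_bisection_oracle(self, kd, P, L):
        assert fraction_bound(kd, P, L) == pytest.approx(
            bisection_fraction(kd, P, L), abs=1e-10
        )

    @settings(max_examples=100, derandomize=True)
    @given(
        kd=st.floats(0.1, 1000.0),
        P=st.floats(1.0, 500.0),
        L1=st.floats(0.0, 2000.0),
        dL=st.floats(0.0, 500.0),
    )
    def test_monotone_in_ligand_and_kd(self, kd, P, L1, dL):
        f1 = fraction_bound(kd, P, L1)
        assert fraction_bound(kd, P, L1 + dL) >= f1 - 1e-12
        assert fraction_bound(kd * 2, P, L1) <= f1 + 1e-12


class TestLigandForSaturation:
    def test_definitional_bound(self):
        for kd in (0.5, 10.0, 200.0):
            L = ligand_for_saturation(kd, 100.0, 0.99)
            assert fraction_bound(kd, 100.0, L) >= 0.99 - 1e-12

    def test_matches_bisection_inversion(self):
        kd, P, target = 10.0, 100.0, 0.5
        L = ligand_for_saturation(kd, P, target)
        L_oracle = optimize.bisect(
            lambda x: fraction_bound(kd, P, x) - target, 1e-9, 1e7, xtol=1e-9
        )
        assert L == pytest.approx(L_oracle, abs=1e-6)

    def test_tight_binding_limit(self):
        assert ligand_for_saturation(0.0, 100.0, 0.99) == pytest.approx(99.0)

    def test_target_one_raises(self):
        with pytest.raises(ValueError):
            ligand_for_saturation(10.0, 100.0, 1.0)


class TestFitKd:
    @pytest.mark.parametrize("kd", [1.0, 25.0, 100.0, 500.0])
    def test_noiseless_recovery_within_0_1_percent(self, kd):
        series = generate_titration(kd, 100.0, 0.30, SCHEDULE)
        fit = fit_kd(series)
        assert abs(fit.kd - kd) / kd < 1e-3
        assert abs(fit.shift_max - 0.30) / 0.30 < 1e-3

    def test_flat_response_flagged_degenerate(self):
        series = TitrationSeries(100.0, [(L, 8.0) for L in SCHEDULE])
        with pytest.warns(UserWarning, match="degenerate"):
            fit = fit_kd(series)
        assert fit.degenerate

    def test_noisy_interval_covers_truth_usually(self):
        hits = 0
        for rep in range(40):
            series = generate_titration(25.0, 100.0, 0.30, SCHEDULE,
                                        noise_sigma=0.0051, seed=rep)
            fit = fit_kd(series)
            hits += abs(fit.kd - 25.0) <= fit.kd_ci95
        assert hits >= 32  # ~90% nominal coverage

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            TitrationSeries(100.0, [(0, 8.0), (50, 8.1), (100, 8.2)])

    def test_summary_mentions_kd(self):
        fit = fit_kd(generate_titration(25.0, 100.0, 0.30, SCHEDULE))
        assert "Kd" in fit.summary()


class TestFreeEnergy:
    def test_molar_kd_is_zero(self):
        assert kd_to_dG(1e6) == pytest.approx(0.0)

    def test_micromolar_at_30C(self):
        assert kd_to_dG(1.0, 303.15) == pytest.approx(-8.32, abs=0.01)

    def test_tenfold_kd_step(self):
        step = kd_to_dG(10.0) - kd_to_dG(100.0)
        assert step == pytest.approx(-0.0019872 * 303.15 * math.log(10),
                                     abs=1e-9)
        assert step == pytest.approx(-1.387, abs=0.01)

    @settings(max_examples=50, derandomize=True)
    @given(kd=st.floats(1e-3, 1e6))
    def test_round_trip(self, kd):
        assert dG_to_kd(kd_to_dG(kd)) == pytest.approx(kd, rel=1e-10)


class TestDeltaCp:
    def test_exact_line(self):
        points = [(T, -5.0 - 0.36 * (T - 293.15)) for T in
                  (293.15, 298.15, 303.15, 308.15)]
        slope, se = fit_delta_cp(points)
        assert slope == pytest.approx(-0.36)
        assert se == pytest.approx(0.0, abs=1e-8)

    def test_constant_enthalpy_zero_slope(self):
        slope, _ = fit_delta_cp([(T, -7.0) for T in (293.0, 298.0, 303.0)])
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_planted_slope_calibrated_against_its_se(self):
        # with 4 temperatures the slope error is t-distributed with 2 dof,
        # so the calibrated 95% factor is t(0.975, 2) = 4.303, not 2
        from scipy import stats

        rng = np.random.default_rng(4)
        temps = (293.15, 298.15, 303.15, 308.15)
        tcrit = stats.t.ppf(0.975, 2)
        hits = 0
        for _ in range(200):
            points = [(T, -5.0 - 0.36 * (T - 293.15) + rng.normal(0, 0.3))
                      for T in temps]
            slope, se = fit_delta_cp(points)
            hits += abs(slope + 0.36) <= tcrit * se
        assert hits >= 0.90 * 200  # nominal ~95%

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError):
            fit_delta_cp([(293.0, -5.0), (298.0, -6.0)])


class TestCorrelate:
    def test_perfect_linear(self):
        x = {f"c{i}": float(i) for i in range(6)}
        y = {k: -1.5 * v + 4 for k, v in x.items()}
        c = correlate(x, y)
        assert c.r_squared == pytest.approx(1.0)
        assert c.slope == pytest.approx(-1.5)

    def test_null_r2_distribution(self):
        # under independence R^2 ~ Beta(1/2, (n-2)/2); check the mean 1/(n-1)
        rng = np.random.default_rng(5)
        n = 10
        r2s = []
        for _ in range(400):
            x = {f"c{i}": float(v) for i, v in enumerate(rng.normal(size=n))}
            y = {f"c{i}": float(v) for i, v in enumerate(rng.normal(size=n))}
            r2s.append(correlate(x, y).r_squared)
        assert np.mean(r2s) == pytest.approx(1 / (n - 1), abs=0.03)

    def test_intersection_only(self):
        x = {"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0}
        y = {"b": 2.0, "c": 4.0, "d": 6.0, "e": 9.0}
        assert correlate(x, y).n == 3


class TestGrowthThreshold:
    def test_separated_midpoint(self):
        ccsp = {"a": 60.0, "b": 84.0, "c": 93.0, "d": 99.0}
        growth = {"a": 0, "b": 0, "c": 8, "d": 8}
        res = growth_threshold_analysis(ccsp, growth)
        assert res.threshold == pytest.approx((84 + 93) / 2)
        assert res.separable and not res.exceptions

    def test_planted_violator_listed(self):
        ccsp = {"a": 60.0, "b": 95.0, "c": 93.0, "d": 99.0}
        growth = {"a": 0, "b": 0, "c": 8, "d": 8}
        res = growth_threshold_analysis(ccsp, growth)
        assert res.exceptions == ["b"]
        assert res.threshold == pytest.approx((60 + 93) / 2)

    def test_all_growers_no_threshold(self):
        ccsp = {c: 90.0 + i for i, c in enumerate("abcd")}
        growth = {c: 8 for c in "abcd"}
        res = growth_threshold_analysis(ccsp, growth)
        assert res.threshold is None and not res.separable
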