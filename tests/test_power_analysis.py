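"""Asymptotic variance, Wald power, required sites and Monte-Carlo calibration."""

import math
from dataclasses import replace

import numpy as np
import pytest

from occudesign import (
    PowerSpec,
    asymptotic_var_factor,
    empirical_power,
    power_curves,
    required_sites,
    wald_power,
)
from occudesign.study_io import ValidationError

BASE = dict(psi1=0.49, p=0.61, n_occasions=20, alpha=0.1)


class TestVarianceFactor:
    def test_perfect_detection_reduces_to_binomial(self):
        v = asymptotic_var_factor(0.3, 1 - 1e-12, 5)
        assert v == pytest.approx(0.3 * 0.7, rel=1e-9)

    def test_direct_arithmetic_example(self):
        # psi(1-psi) floor plus the imperfect-detection penalty
        v = asymptotic_var_factor(0.49, 0.61, 3)
        p_star = 1 - 0.39**3
        denom = p_star - 3 * 0.61 * 0.39**2
        expected = 0.49 * (0.51 + (1 - p_star) / denom)
        assert v == pytest.approx(expected, rel=1e-12)
        assert v == pytest.approx(0.2938, abs=2e-4)

    def test_never_below_binomial_floor(self):
        for psi in (0.1, 0.5, 0.9):
            for p in (0.2, 0.5, 0.9):
                for K in (2, 4, 8):
                    assert asymptotic_var_factor(psi, p, K) >= psi * (1 - psi)

    def test_single_visit_rejected(self):
        with pytest.raises(ValidationError, match="K"):
            asymptotic_var_factor(0.5, 0.5, 1)

    def test_matches_simulated_variance(self):
        # simulation cross-check of the closed form at a large design
        from occudesign import DesignScenario, simulate_mle_distribution

        summ = simulate_mle_distribution(
            DesignScenario(psi=0.49, p=0.61, n_sites=1000, n_occasions=5), 600, seed=4
        )
        asym_sd = math.sqrt(asymptotic_var_factor(0.49, 0.61, 5) / 1000)
        assert summ.stats.loc["psi", "sd"] == pytest.approx(asym_sd, rel=0.10)


class TestWaldPower:
    def test_zero_effect_recovers_alpha(self):
        spec = PowerSpec(effect=0.0, n_sites=143, **BASE)
        assert wald_power(spec) == pytest.approx(0.1, abs=1e-12)

    def test_monotone_in_sites_and_effect(self):
        powers_s = [
            wald_power(PowerSpec(effect=0.2, n_sites=S, **BASE))
            for S in (50, 100, 200, 400)
        ]
        assert all(a < b for a, b in zip(powers_s, powers_s[1:]))
        powers_e = [
            wald_power(PowerSpec(effect=e, n_sites=143, **BASE))
            for e in (0.05, 0.15, 0.3, 0.5)
        ]
        assert all(a < b for a, b in zip(powers_e, powers_e[1:]))

    def test_higher_initial_occupancy_more_power(self):
        lo = wald_power(PowerSpec(psi1=0.3, effect=0.3, p=0.61, n_occasions=20,
                                  n_sites=143, alpha=0.1))
        hi = wald_power(PowerSpec(psi1=0.6, effect=0.3, p=0.61, n_occasions=20,
                                  n_sites=143, alpha=0.1))
        assert hi > lo

    def test_absolute_convention(self):
        spec = PowerSpec(psi1=0.7, effect=0.3, p=0.61, n_occasions=20,
                         n_sites=143, alpha=0.1, effect_convention="absolute")
        assert spec.psi2 == pytest.approx(0.4)

    def test_invalid_psi2_rejected(self):
        with pytest.raises(ValidationError, match="convention"):
            PowerSpec(psi1=0.2, effect=0.3, p=0.61, n_occasions=20,
                      effect_convention="absolute")


class TestRequiredSites:
    def test_minimality(self):
        for eff, target in ((0.3, 0.8), (0.2, 0.9), (0.15, 0.8)):
            spec = PowerSpec(effect=eff, target_power=target, **BASE)
            S = required_sites(spec)
            assert wald_power(replace(spec, n_sites=S)) >= target
            assert wald_power(replace(spec, n_sites=S - 1)) < target

    def test_perfect_detection_closed_form_is_tiny(self):
        spec = PowerSpec(psi1=0.5, effect=0.4, p=1 - 1e-9, n_occasions=2,
                         alpha=0.05, target_power=0.8, effect_convention="absolute")
        S = required_sites(spec)
        assert S <= 20
        # brute-force scan agrees on minimality
        brute = next(
            n for n in range(2, 100)
            if wald_power(replace(spec, n_sites=n)) >= 0.8
        )
        assert S == brute

    def test_doubling_effect_quarters_sites(self):
        s_small = required_sites(PowerSpec(effect=0.1, target_power=0.8, **BASE))
        s_big = required_sites(PowerSpec(effect=0.2, target_power=0.8, **BASE))
        assert s_small / s_big == pytest.approx(4.0, rel=0.1)

    def test_zero_effect_rejected(self):
        with pytest.raises(ValidationError):
            required_sites(PowerSpec(effect=0.0, target_power=0.8, **BASE))


class TestEmpiricalPower:
    def test_agrees_with_analytic(self):
        spec = PowerSpec(effect=0.3, n_sites=143, **BASE)
        res = empirical_power(spec, n_iter=600, seed=12)
        se = math.sqrt(res.analytic_power * (1 - res.analytic_power) / 600)
        assert abs(res.empirical_power - res.analytic_power) < 3 * se

    def test_type_one_error_calibrated(self):
        spec = PowerSpec(effect=0.0, n_sites=143, **BASE)
        res = empirical_power(spec, n_iter=600, seed=12)
        se = math.sqrt(0.1 * 0.9 / 600)
        assert abs(res.empirical_power - 0.1) < 3 * se

    def test_reproducible(self):
        spec = PowerSpec(effect=0.3, n_sites=60, **BASE)
        a = empirical_power(spec, n_iter=500, seed=3)
        b = empirical_power(spec, n_iter=500, seed=3)
        assert a.empirical_power == b.empirical_power


class TestPowerCurves:
    def test_grid_shape(self):
        tab = power_curves(0.49, [0.3, 0.2, 0.15], [0.61], [20], [50, 143, 300, 565])
        assert len(tab) == 12
        assert (tab["power"] > 0).all() and (tab["power"] < 1).all()

    def test_power_plateaus_in_detectability(self):
        tab = power_curves(0.49, [0.3], list(np.arange(0.5, 0.96, 0.05)), [6], [143])
        assert tab["power"].max() - tab["power"].min() < 0.02

    def test_power_plateaus_in_occasions(self):
        g4 = wald_power(PowerSpec(psi1=0.49, effect=0.3, p=0.61, n_occasions=4,
                                  n_sites=143, alpha=0.1))
        g8 = wald_power(PowerSpec(psi1=0.49, effect=0.3, p=0.61, n_occasions=8,
                                  n_sites=143, alpha=0.1))
        assert abs(g8 - g4) < 0.02
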