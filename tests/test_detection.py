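import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import brute_force_integrated_lik
from scrkit.data import CaptureHistory, OccasionCalendar, StateSpace, TrapArray
from scrkit.detection import (
    ModelSpec,
    ScrParams,
    detection_prob,
    integrated_loglik,
    per_individual_loglik,
)


def _space(centers, spacing=1.0):
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    return StateSpace(
        pixel_centers=centers,
        pixel_area=spacing**2,
        extent=(-10, 10, -10, 10),
        spacing=spacing,
    )


class TestDetectionProb:
    def test_at_distance_zero(self):
        assert detection_prob(0.0, lam0=0.05, sigma=1.0) == pytest.approx(
            1 - math.exp(-0.05)
        )

    def test_at_unit_distance(self):
        # p = 1 - exp(-0.05 * e^{-1/2})
        assert detection_prob(1.0, lam0=0.05, sigma=1.0, theta=1.0) == pytest.approx(
            1 - math.exp(-0.05 * math.exp(-0.5)), abs=1e-10
        )
        assert detection_prob(1.0, 0.05, 1.0, 1.0) == pytest.approx(0.02988, abs=5e-5)

    def test_vanishes_at_large_distance(self):
        assert detection_prob(1e4, lam0=0.5, sigma=1.0) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"d": -1.0, "lam0": 0.1, "sigma": 1.0},
            {"d": 1.0, "lam0": 0.0, "sigma": 1.0},
            {"d": 1.0, "lam0": 0.1, "sigma": -1.0},
            {"d": 1.0, "lam0": 0.1, "sigma": 1.0, "theta": 1.5},
        ],
    )
    def test_domain_errors(self, kwargs):
        with pytest.raises(ValueError):
            detection_prob(**kwargs)

    def test_theta_endpoints_match_named_kernels(self):
        d, lam0, sigma = 1.7, 0.3, 1.3
        gauss = 1 - math.exp(-lam0 * math.exp(-0.5 * (d / sigma) ** 2))
        expo = 1 - math.exp(-lam0 * math.exp(-0.5 * (d / sigma)))
        assert detection_prob(d, lam0, sigma, theta=1.0) == pytest.approx(gauss)
        assert detection_prob(d, lam0, sigma, theta=0.5) == pytest.approx(expo)

    @given(
        d1=st.floats(0, 20),
        gap=st.floats(0.01, 10),
        lam0=st.floats(0.001, 4.9),
        sigma=st.floats(0.05, 10),
        theta=st.floats(0.5, 1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_decreasing_in_distance(self, d1, gap, lam0, sigma, theta):
        near = detection_prob(d1, lam0, sigma, theta)
        far = detection_prob(d1 + gap, lam0, sigma, theta)
        assert near >= far
        if near > 0:  # strict unless the hazard underflows to zero
            assert near > far or far == 0

    @given(
        d=st.floats(0, 10),
        lam0=st.floats(0.001, 2.0),
        sigma=st.floats(0.1, 5.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_lam0_and_sigma(self, d, lam0, sigma):
        assert detection_prob(d, lam0 * 1.5, sigma) >= detection_prob(d, lam0, sigma)
        assert detection_prob(d, lam0, sigma * 1.5) >= detection_prob(d, lam0, sigma)

    def test_bounded_by_lam0_ceiling(self):
        p = detection_prob(np.linspace(0, 5, 50), lam0=0.7, sigma=1.0)
        assert (p > 0).all() and (p <= 1 - math.exp(-0.7) + 1e-12).all()


class TestScrParams:
    def test_sigma_male_defaults_to_female(self):
        p = ScrParams(lam0_female=0.1, sigma_female=2.0)
        assert p.sigma_male == 2.0

    def test_sex_specific_hazard(self):
        p = ScrParams(lam0_female=0.05, beta_sex=-1.61, sigma_female=1.0)
        assert p.lam0("M") == pytest.approx(0.05 * math.exp(-1.61))
        assert p.lam0("F") == 0.05

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"lam0_female": -0.1, "sigma_female": 1.0},
            {"lam0_female": 0.1, "sigma_female": 0.0},
            {"lam0_female": 0.1, "sigma_female": 1.0, "theta": 0.4},
            {"lam0_female": 0.1, "sigma_female": 1.0, "psi": 1.5},
        ],
    )
    def test_invalid_params(self, kwargs):
        with pytest.raises(ValueError):
            ScrParams(**kwargs)


class TestModelSpec:
    @pytest.mark.parametrize(
        "name,on_lam0,on_sigma",
        [
            ("distance", False, False),
            ("sex", True, False),
            ("sigma-sex", False, True),
            ("sex+sigma-sex", True, True),
        ],
    )
    def test_from_name(self, name, on_lam0, on_sigma):
        spec = ModelSpec.from_name(name, M=10)
        assert (spec.sex_on_lam0, spec.sex_on_sigma) == (on_lam0, on_sigma)
        assert spec.name == name

    def test_constrain_ties_parameters(self):
        spec = ModelSpec.from_name("distance", M=10, theta_fixed=1.0)
        p = spec.constrain(
            ScrParams(0.1, 1.0, beta_sex=2.0, sigma_male=3.0, theta=0.6)
        )
        assert p.beta_sex == 0.0 and p.sigma_male == p.sigma_female
        assert p.theta == 1.0


class TestPerIndividualLoglik:
    def test_single_bernoulli_term(self, square_traps):
        traps = TrapArray(("A",), np.array([[0.0, 0.0]]))
        y = np.array([[1]])
        params = ScrParams(lam0_female=0.05, sigma_female=1.0)
        ll = per_individual_loglik(y, np.array([0.0, 0.0]), "F", params, traps)
        assert ll == pytest.approx(math.log(1 - math.exp(-0.05)))

    def test_all_zero_small_lam0_limit(self, square_traps):
        y = np.zeros((4, 3), dtype=int)
        params = ScrParams(lam0_female=1e-12, sigma_female=1.0)
        ll = per_individual_loglik(y, np.array([0.5, 0.5]), "F", params, square_traps)
        assert ll == pytest.approx(0.0, abs=1e-8)

    def test_reflection_symmetry(self, square_traps):
        y = np.array([[1, 0], [0, 0], [0, 1], [1, 1]])
        params = ScrParams(lam0_female=0.2, sigma_female=0.8, theta=0.7)
        s = np.array([0.3, -0.4])
        mirrored = TrapArray(
            square_traps.trap_id, square_traps.coords * np.array([-1.0, 1.0])
        )
        ll1 = per_individual_loglik(y, s, "F", params, square_traps)
        ll2 = per_individual_loglik(y, s * np.array([-1.0, 1.0]), "F", params, mirrored)
        assert ll1 == pytest.approx(ll2, rel=1e-12)

    def test_operation_mask_removes_terms(self):
        traps_on = TrapArray(("A",), np.array([[0.0, 0.0]]))
        traps_half = TrapArray(
            ("A",), np.array([[0.0, 0.0]]), operation=np.array([[1, 0]])
        )
        y = np.array([[1, 0]])
        params = ScrParams(lam0_female=0.3, sigma_female=1.0)
        full = per_individual_loglik(y, np.zeros(2), "F", params, traps_on)
        masked = per_individual_loglik(y, np.zeros(2), "F", params, traps_half)
        # masking the second occasion drops its log(1-p) term
        assert masked == pytest.approx(math.log(1 - math.exp(-0.3)))
        assert masked > full


def _history(y, sexes, traps, n_days):
    return CaptureHistory(
        y=y,
        individual_id=tuple(f"i{k}" for k in range(y.shape[0])),
        sex=np.array(sexes),
        calendar=OccasionCalendar.daily(n_days),
        traps=traps,
    )


class TestIntegratedLoglik:
    def test_single_config_hand_enumeration(self):
        traps = TrapArray(("A",), np.array([[0.0, 0.0]]))
        history = _history(np.ones((1, 1, 1), dtype=int), ["F"], traps, 1)
        space = _space([[0.0, 0.0]])
        params = ScrParams(lam0_female=0.05, sigma_female=1.0, psi=1.0)
        spec = ModelSpec.from_name("distance", M=1)
        ll = integrated_loglik(params, history, space, spec)
        assert ll == pytest.approx(math.log(1 - math.exp(-0.05)))

    def test_two_symmetric_pixels_equal_single_pixel(self):
        traps = TrapArray(("A",), np.array([[0.0, 0.0]]))
        y = np.ones((1, 1, 1), dtype=int)
        history = _history(y, ["F"], traps, 1)
        params = ScrParams(lam0_female=0.3, sigma_female=1.0, psi=0.7)
        spec = ModelSpec.from_name("distance", M=1)
        ll_two = integrated_loglik(
            params, history, _space([[1.0, 0.0], [-1.0, 0.0]]), spec
        )
        ll_one = integrated_loglik(params, history, _space([[1.0, 0.0]]), spec)
        assert ll_two == pytest.approx(ll_one, rel=1e-12)

    def test_small_lam0_all_zero_limit(self):
        traps = TrapArray(("A", "B"), np.array([[0.0, 0.0], [1.0, 0.0]]))
        history = _history(np.zeros((0, 2, 2), dtype=int), [], traps, 2)
        space = _space([[0.0, 0.0], [1.0, 1.0]])
        params = ScrParams(lam0_female=1e-13, sigma_female=1.0, psi=0.5)
        ll = integrated_loglik(params, history, space, ModelSpec.from_name("distance", M=2))
        assert ll == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("n_pixels", [1, 2, 3])
    @pytest.mark.parametrize("n_traps", [1, 2])
    @pytest.mark.parametrize("n_occ", [1, 2])
    @pytest.mark.parametrize("model", ["distance", "sex", "sex+sigma-sex"])
    def test_matches_brute_force_enumeration(self, n_pixels, n_traps, n_occ, model):
        rng = np.random.default_rng(n_pixels * 100 + n_traps * 10 + n_occ)
        pixels = rng.uniform(-1, 1, (n_pixels, 2))
        trap_coords = rng.uniform(-1, 1, (n_traps, 2))
        traps = TrapArray(tuple(f"T{j}" for j in range(n_traps)), trap_coords)
        y = np.zeros((1, n_traps, n_occ), dtype=int)
        y[0, 0, 0] = 1
        if n_traps > 1 and n_occ > 1:
            y[0, 1, 1] = 1
        history = _history(y, ["M"], traps, n_occ)
        params = ScrParams(
            lam0_female=0.4, beta_sex=-0.9, sigma_female=0.8,
            sigma_male=1.4, theta=0.75, psi=0.6, psi_sex=0.35,
        )
        spec = ModelSpec.from_name(model, M=2, theta_fixed=0.75)
        expected = brute_force_integrated_lik(
            spec.constrain(params), [y[0]], ["M"], 2, pixels, trap_coords
        )
        got = integrated_loglik(params, history, _space(pixels), spec)
        assert got == pytest.approx(math.log(expected), abs=1e-10)

    def test_unknown_sex_observed_individual(self):
        rng = np.random.default_rng(5)
        pixels = rng.uniform(-1, 1, (3, 2))
        trap_coords = rng.uniform(-1, 1, (2, 2))
        traps = TrapArray(("T0", "T1"), trap_coords)
        y = np.zeros((1, 2, 2), dtype=int)
        y[0, 1, 0] = 1
        history = _history(y, ["U"], traps, 2)
        params = ScrParams(
            lam0_female=0.5, beta_sex=-1.0, sigma_female=1.0,
            sigma_male=0.6, psi=0.5, psi_sex=0.4, theta=1.0,
        )
        spec = ModelSpec.from_name("sex+sigma-sex", M=2)
        expected = brute_force_integrated_lik(
            spec.constrain(params), [y[0]], ["U"], 2, pixels, trap_coords
        )
        got = integrated_loglik(params, history, _space(pixels), spec)
        assert got == pytest.approx(math.log(expected), abs=1e-10)

    def test_invariant_to_augmented_slot_count_scaling(self):
        # augmented slots are exchangeable: M->M+1 multiplies the likelihood
        # by the (constant) per-slot zero-history mass
        traps = TrapArray(("A",), np.array([[0.0, 0.0]]))
        y = np.ones((1, 1, 1), dtype=int)
        history = _history(y, ["F"], traps, 1)
        space = _space([[0.0, 0.0], [2.0, 0.0]])
        params = ScrParams(lam0_female=0.3, sigma_female=1.0, psi=0.6)
        spec2 = ModelSpec.from_name("distance", M=2)
        spec3 = ModelSpec.from_name("distance", M=3)
        ll2 = integrated_loglik(params, history, space, spec2)
        ll3 = integrated_loglik(params, history, space, spec3)
        per_slot = ll3 - ll2
        spec4 = ModelSpec.from_name("distance", M=4)
        ll4 = integrated_loglik(params, history, space, spec4)
        assert ll4 - ll3 == pytest.approx(per_slot, rel=1e-12)

    def test_m_below_observed_errors(self, tiny_history):
        params = ScrParams(lam0_female=0.1, sigma_female=1.0)
        with pytest.raises(ValueError, match="M"):
            integrated_loglik(
                params, tiny_history, _space([[0.0, 0.0]] * 4),
                ModelSpec.from_name("distance", M=1),
            )
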