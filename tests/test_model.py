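"""The steady-state system: construction routes, symmetry, recovery."""

import numpy as np
import pytest
import sympy as sp

from ptmgeo.fixtures import THETA_FIXTURES
from ptmgeo.model import (
    ConservedTotals,
    InconsistencyError,
    InvalidParameterError,
    NondimensionalParameters,
    SamplingBox,
    build_system,
    build_system_via_psi,
    recover_concentrations,
    system_coefficient_grids,
)
from ptmgeo.solver import ClassifierThresholds, solve_system


def _random_params(rng, mode="weak"):
    theta = 10.0 ** rng.uniform(-1, 1, 8)
    if mode == "strong":
        theta[4] = theta[5] = 0.0
    return NondimensionalParameters.from_theta(theta, mode=mode)


class TestConstruction:
    def test_origin_is_always_a_root(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            system = build_system(
                _random_params(rng),
                ConservedTotals(10 ** rng.uniform(0, 2), 10 ** rng.uniform(0, 2),
                                10 ** rng.uniform(-0.5, 0.5)),
            )
            assert system.phi1(0.0, 0.0) == 0.0
            assert system.phi2(0.0, 0.0) == 0.0

    def test_degrees_match_the_quartic_structure(self):
        rng = np.random.default_rng(1)
        system = build_system(_random_params(rng), ConservedTotals.equal_enzymes(5.0))
        assert (system.phi1.u_degree, system.phi1.v_degree) == (4, 3)
        assert (system.phi2.u_degree, system.phi2.v_degree) == (3, 4)

    def test_value_at_unit_point_equal_enzymes(self):
        """With zeta = 1, Phi1(1,1) = -sigma (alpha eps0 + eps1 + beta eps2)
        and Phi2(1,1) = -lam (alpha phi0 + phi1 + beta phi2)."""
        rng = np.random.default_rng(2)
        for _ in range(10):
            p = _random_params(rng)
            sigma, lam = 10 ** rng.uniform(0, 2), 10 ** rng.uniform(0, 2)
            system = build_system(p, ConservedTotals(sigma, lam, 1.0))
            assert np.isclose(
                system.phi1(1.0, 1.0),
                -sigma * (p.alpha * p.eps0 + p.eps1 + p.beta * p.eps2),
                rtol=1e-12,
            )
            assert np.isclose(
                system.phi2(1.0, 1.0),
                -lam * (p.alpha * p.phi0 + p.phi1 + p.beta * p.phi2),
                rtol=1e-12,
            )

    def test_all_ones_gives_minus_three(self):
        p = NondimensionalParameters.from_theta([1.0] * 8)
        t = ConservedTotals(1.0, 1.0, 1.0)
        for builder in (build_system, build_system_via_psi):
            assert np.isclose(builder(p, t).phi1(1.0, 1.0), -3.0)

    def test_strong_mode_zeroes_the_rebinding_coefficients(self):
        rng = np.random.default_rng(3)
        p = _random_params(rng, mode="strong")
        system = build_system(p, ConservedTotals.equal_enzymes(7.0))
        c1, c2 = system.phi1.coeffs, system.phi2.coeffs
        # all terms carrying eps2 or phi0 vanish exactly
        assert c1[4, 0] == 0 and c1[0, 3] == 0 and c1[1, 3] == 0
        assert c2[3, 0] == 0 and c2[3, 1] == 0 and c2[0, 4] == 0
        assert (system.phi1.u_degree, system.phi1.v_degree) == (3, 2)
        assert (system.phi2.u_degree, system.phi2.v_degree) == (2, 3)


class TestRouteEquivalence:
    def test_expanded_and_factorised_routes_agree(self):
        """1000 random draws: the psi-factorised assembly reproduces the
        expanded coefficient grids to machine precision, for general totals."""
        rng = np.random.default_rng(4)
        for _ in range(1000):
            p = _random_params(rng)
            totals = ConservedTotals(
                10 ** rng.uniform(0, 2.7), 10 ** rng.uniform(0, 2.7),
                10 ** rng.uniform(-0.5, 0.5),
            )
            a = build_system(p, totals)
            b = build_system_via_psi(p, totals)
            scale = max(np.abs(a.phi1.coeffs).max(), np.abs(a.phi2.coeffs).max())
            assert np.allclose(a.phi1.coeffs, b.phi1.coeffs, atol=1e-10 * scale)
            assert np.allclose(a.phi2.coeffs, b.phi2.coeffs, atol=1e-10 * scale)

    def test_symbolic_expansion_matches_numeric_grids(self):
        """Exact rational expansion of the factorised form reproduces every
        one of the 24 expanded coefficients (guards transcription errors)."""
        vals = {
            "a": sp.Rational(7, 3), "b": sp.Rational(1, 5),
            "e0": sp.Rational(2, 7), "e1": sp.Rational(3, 2),
            "e2": sp.Rational(5, 4), "p0": sp.Rational(1, 9),
            "p1": sp.Rational(8, 3), "p2": sp.Rational(4, 7),
            "sg": sp.Rational(11, 2), "lm": sp.Rational(7, 2),
            "z": sp.Rational(3, 4),
        }
        a, b, e0, e1, e2, p0, p1, p2, sg, lm, z = (
            vals[k] for k in ("a", "b", "e0", "e1", "e2", "p0", "p1", "p2",
                              "sg", "lm", "z"))
        u, v = sp.symbols("u v")
        psi1 = (a / z) * v / u + 1 + b * z * u / v
        psi2 = e0 * (a / z) * v / u + e1 + e2 * b * z * u / v
        psi3 = p0 * (a / z) * v / u + p1 + p2 * b * z * u / v
        P = psi1 + u * psi2 + v * psi3
        phi1 = sp.expand(z * u * v * ((1 - u) * P - sg * u * psi2))
        phi2 = sp.expand(z * u * v * ((1 - v) * P - lm * v * psi3))
        theta = np.array([float(x) for x in (a, b, e0, e1, e2, p0, p1, p2)])
        c1, c2 = system_coefficient_grids(theta, float(sg), float(lm), float(z))
        for expr, grid in ((phi1, c1), (phi2, c2)):
            poly = sp.Poly(expr, u, v)
            exact = np.zeros((5, 5))
            for (i, j), coeff in zip(poly.monoms(), poly.coeffs()):
                exact[i, j] = float(coeff)
            assert np.allclose(grid, exact, rtol=1e-13, atol=1e-15)


class TestValidation:
    @pytest.mark.parametrize("bad", [
        dict(alpha=0.0), dict(beta=-1.0), dict(eps1=0.0), dict(phi2=0.0),
        dict(eps2=-0.1), dict(phi0=-0.1),
    ])
    def test_invalid_parameters_raise(self, bad):
        good = dict(alpha=1, beta=1, eps0=1, eps1=1, eps2=1, phi0=1,
                    phi1=1, phi2=1)
        good.update(bad)
        with pytest.raises(InvalidParameterError):
            NondimensionalParameters(**good)

    def test_strong_mode_requires_exact_zeros(self):
        with pytest.raises(InvalidParameterError):
            NondimensionalParameters(1, 1, 1, 1, 1e-12, 0, 1, 1, mode="strong")

    def test_totals_must_be_positive(self):
        with pytest.raises(InvalidParameterError):
            ConservedTotals(0.0, 1.0, 1.0)

    def test_box_log_volume(self):
        assert SamplingBox(1, 8).log_volume == 256.0
        assert SamplingBox(2, 6).log_volume == 4096.0


class TestConcentrationRecovery:
    def test_conservation_and_bounds(self, theta1_system_sigma10):
        system = theta1_system_sigma10
        sol = solve_system(system)
        pos = [p for p in sol.solutions
               if p.is_positive_real(ClassifierThresholds())]
        assert pos
        for p in pos:
            conc = recover_concentrations(
                p.u.real, p.v.real, system.params, system.totals
            )
            assert conc.conservation_residual < 1e-8
            assert 0 < conc.u <= 1 and 0 < conc.v <= 1
            assert min(conc.s0, conc.s1, conc.s2) > 0

    def test_modform_ratio_identities(self, theta1_system_sigma10):
        system = theta1_system_sigma10
        sol = solve_system(system)
        p = next(s for s in sol.solutions
                 if s.is_positive_real(ClassifierThresholds()))
        conc = recover_concentrations(p.u.real, p.v.real, system.params,
                                      system.totals)
        al, be, z = system.params.alpha, system.params.beta, system.totals.zeta
        assert np.isclose(conc.s0 / conc.s1, al / z * conc.v / conc.u, rtol=1e-10)
        assert np.isclose(conc.s2 / conc.s1, be * z * conc.u / conc.v, rtol=1e-10)

    def test_non_solution_is_rejected(self, theta1_system_sigma10):
        system = theta1_system_sigma10
        with pytest.raises(InconsistencyError):
            recover_concentrations(0.5, 0.5, system.params, system.totals)


def test_enzyme_swap_symmetry():
    """With zeta = 1 and lam = sigma, swapping the two enzymes (which also
    reverses the modform order) maps theta ->
    (beta, alpha, phi2, phi1, phi0, eps2, eps1, eps0) and (u, v) -> (v, u);
    in fact Phi1(theta; u, v) = Phi2(theta'; v, u) identically, so the
    solution sets must correspond coordinate-swapped."""
    rng = np.random.default_rng(6)
    for _ in range(5):
        theta = 10.0 ** rng.uniform(-1, 1, 8)
        a, b, e0, e1, e2, p0, p1, p2 = theta
        swapped = np.array([b, a, p2, p1, p0, e2, e1, e0])
        sigma = float(10 ** rng.uniform(0.5, 1.5))
        totals = ConservedTotals.equal_enzymes(sigma)
        s1 = solve_system(build_system(
            NondimensionalParameters.from_theta(theta), totals))
        s2 = solve_system(build_system(
            NondimensionalParameters.from_theta(swapped), totals))
        assert s1.n_positive_real == s2.n_positive_real
        uv1 = sorted((round(p.u.real, 6), round(p.v.real, 6))
                     for p in s1.solutions if abs(p.u.imag) < 1e-12)
        uv2 = sorted((round(p.v.real, 6), round(p.u.real, 6))
                     for p in s2.solutions if abs(p.u.imag) < 1e-12)
        np.testing.assert_allclose(np.array(uv1), np.array(uv2),
                                   rtol=1e-4, atol=1e-8)
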