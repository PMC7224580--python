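"""Exhaustive solution of the steady-state system at one parameter point.

The two steady-state polynomials form a square system of total degree 4, so
Bezout's theorem allows 16 projective complex solutions.  For generic
parameter points the solutions split into: the origin u = v = 0 with local
intersection multiplicity 6; seven (weak irreversibility) or five (strong)
finite nonzero solutions; and the remainder projectively at infinity.  Of the
finite nonzero solutions, either one or three are positive real -- the
monostable / bistable dichotomy that the whole parameter-geography analysis
rests on.

The solver eliminates one variable with a Sylvester resultant whose
determinant is evaluated at roots of unity and interpolated by FFT, finds the
roots of the deflated (origin-free) univariate factor from the companion
matrix, back-substitutes, and polishes every candidate with Newton's method
on the full 2x2 system.  Solutions are then classified coordinate-wise by
magnitude thresholds and the point is labelled monostable, bistable, or
nongeneric.  Points that fail any genericity check are automatically
re-solved with a sheared projection and, if necessary, in 50-digit arithmetic
(exact rational resultant + multiprecision root finding); only then is the
point flagged NONGENERIC -- it is never silently dropped.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import mpmath
import numpy as np
import sympy as sp

from .model import (
    BivariatePolynomial,
    SteadyStateSystem,
)

__all__ = [
    "ClassifierThresholds",
    "CoordinateClass",
    "Stationarity",
    "SolutionPoint",
    "SolutionSet",
    "DegenerateSystemError",
    "classify_coordinate",
    "solve_system",
    "origin_multiplicity",
    "certify_newton",
]

#: generic origin multiplicity (both modes)
GENERIC_ORIGIN_MULTIPLICITY = 6
#: generic number of finite nonzero solutions by mode
GENERIC_FINITE_COUNT = {"weak": 7, "strong": 5}
#: generic degree of the deflated resultant = multiplicity + finite count
GENERIC_RESULTANT_DEGREE = {"weak": 13, "strong": 11}

_DEDUP_RTOL = 1e-8
#: solutions with |u| + |v| below this are origin-cluster artifacts: the
#: multiplicity-6 origin (whose tangent cone both curves share) lets Newton
#: stall at tiny nonzero coordinates with tiny residuals.  Genuine finite
#: solutions scale like 1/sigma and stay above ~2e-4 even at sigma = 5000.
_ORIGIN_CLUSTER_RADIUS = 3e-5


class DegenerateSystemError(RuntimeError):
    """The elimination produced an identically zero resultant."""


@dataclass(frozen=True)
class ClassifierThresholds:
    """Magnitude thresholds for classifying solution coordinates.

    ``t_zmin`` and ``t_zmax`` separate exact zeros from numerically ambiguous
    near-zeros, ``t_inf`` separates finite coordinates from ones escaping to
    projective infinity, and ``newton_tol`` is the relative residual demanded
    of refined solutions.
    """

    t_zmin: float = 1e-25
    t_zmax: float = 1e-10
    t_inf: float = 1e8
    newton_tol: float = 1e-12

    def __post_init__(self) -> None:
        if not (0 < self.t_zmin <= self.t_zmax < 1 < self.t_inf):
            raise ValueError("need 0 < t_zmin <= t_zmax < 1 < t_inf")


class CoordinateClass(enum.Enum):
    SMALL = "small"
    AMBIGUOUS = "ambiguous"
    INFINITE = "infinite"
    NONZERO_REAL = "nonzero_real"
    NONZERO_NONREAL = "nonzero_nonreal"


class Stationarity(enum.Enum):
    MONOSTABLE = "monostable"
    BISTABLE = "bistable"
    NONGENERIC = "nongeneric"


def classify_coordinate(
    x: complex, thresholds: ClassifierThresholds | None = None
) -> CoordinateClass:
    """Classify one solution coordinate x = a + ib by magnitude.

    The cases are evaluated in a fixed order: small, ambiguous, infinite,
    nonzero real, and otherwise nonzero non-real.
    """
    t = thresholds or ClassifierThresholds()
    a, b = abs(x.real), abs(x.imag)
    if a < t.t_zmax and b < t.t_zmax:
        return CoordinateClass.SMALL
    if t.t_zmin < b < t.t_zmax:
        return CoordinateClass.AMBIGUOUS
    if a > t.t_inf or b > t.t_inf:
        return CoordinateClass.INFINITE
    if t.t_zmax < a < t.t_inf and b < t.t_zmin:
        return CoordinateClass.NONZERO_REAL
    return CoordinateClass.NONZERO_NONREAL


@dataclass(frozen=True)
class SolutionPoint:
    """One refined finite solution of the system."""

    u: complex
    v: complex
    residual: float
    u_class: CoordinateClass
    v_class: CoordinateClass
    certified: bool = False

    def is_positive_real(self, thresholds: ClassifierThresholds) -> bool:
        return (
            self.u_class is CoordinateClass.NONZERO_REAL
            and self.v_class is CoordinateClass.NONZERO_REAL
            and self.u.real > thresholds.t_zmax
            and self.v.real > thresholds.t_zmax
        )


@dataclass(frozen=True)
class SolutionSet:
    """All finite solutions at one parameter point, with stationarity label."""

    solutions: tuple[SolutionPoint, ...]
    origin_multiplicity: int
    n_finite_nonzero: int
    n_positive_real: int
    stationarity: Stationarity
    escalations: int = 0  # number of precision escalations used


# ---------------------------------------------------------------------------
# elimination machinery


def _v_degrees(c1: np.ndarray, c2: np.ndarray) -> tuple[int, int]:
    dv1 = max(j for j in range(5) if np.any(c1[:, j]))
    dv2 = max(j for j in range(5) if np.any(c2[:, j]))
    return dv1, dv2


def _resultant_coeffs(c1: np.ndarray, c2: np.ndarray, n_nodes: int = 33) -> np.ndarray:
    """Coefficients of Res_v(Phi1, Phi2) as a polynomial in u.

    The Sylvester determinant is evaluated at the ``n_nodes``-th roots of
    unity and the coefficients recovered by FFT; this is exact (up to
    rounding) whenever the resultant degree is below ``n_nodes``.
    """
    dv1, dv2 = _v_degrees(c1, c2)
    n = dv1 + dv2
    nodes = np.exp(2j * np.pi * np.arange(n_nodes) / n_nodes)
    powers = nodes[:, None] ** np.arange(5)[None, :]  # (M, 5)
    f1 = powers @ c1  # (M, 5): f1[k, j] = sum_i c1[i, j] node_k^i
    f2 = powers @ c2
    S = np.zeros((n_nodes, n, n), dtype=complex)
    for r in range(dv2):
        S[:, r, r : r + dv1 + 1] = f1[:, : dv1 + 1][:, ::-1]
    for r in range(dv1):
        S[:, dv2 + r, r : r + dv2 + 1] = f2[:, : dv2 + 1][:, ::-1]
    dets = np.linalg.det(S)
    coeffs = np.fft.fft(dets) / n_nodes  # coeffs[k] multiplies u^k
    if np.abs(coeffs).max() == 0.0:
        raise DegenerateSystemError("identically zero resultant")
    return coeffs


def _shear_grid(c: np.ndarray, g: complex) -> np.ndarray:
    """Coefficient grid after the substitution u -> u + g*v (total degree kept)."""
    from math import comb

    out = np.zeros((5, 5), dtype=complex)
    for i in range(5):
        for j in range(5):
            if c[i, j] == 0:
                continue
            # u^i -> sum_k C(i,k) u^(i-k) (g v)^k
            for k in range(i + 1):
                out[i - k, j + k] += c[i, j] * comb(i, k) * g**k
    return out


def _eval_grid(c: np.ndarray, u: complex, v: complex) -> complex:
    up = u ** np.arange(5)
    vp = v ** np.arange(5)
    return up @ c @ vp


def _jacobian(c1, c2, u, v):
    iu = np.arange(1, 5)
    up = u ** np.arange(5)
    vp = v ** np.arange(5)
    dup = iu * u ** (iu - 1)
    dvp = iu * v ** (iu - 1)
    j11 = dup @ c1[1:, :] @ vp
    j12 = up @ c1[:, 1:] @ dvp
    j21 = dup @ c2[1:, :] @ vp
    j22 = up @ c2[:, 1:] @ dvp
    return j11, j12, j21, j22


def _newton_polish(c1, c2, u, v, iters: int = 40):
    for _ in range(iters):
        f1 = _eval_grid(c1, u, v)
        f2 = _eval_grid(c2, u, v)
        j11, j12, j21, j22 = _jacobian(c1, c2, u, v)
        det = j11 * j22 - j12 * j21
        if det == 0:
            break
        du = (f1 * j22 - f2 * j12) / det
        dv = (f2 * j11 - f1 * j21) / det
        u, v = u - du, v - dv
        if abs(du) + abs(dv) < 1e-15 * (abs(u) + abs(v) + 1.0):
            break
    return u, v


def _residual(c1, c2, u, v) -> float:
    return float(max(abs(_eval_grid(c1, u, v)), abs(_eval_grid(c2, u, v))))


def _try_realify(c1, c2, u, v):
    """Sharpen a near-real solution in real arithmetic.

    A true real solution, refined in complex arithmetic, retains a rounding-
    level imaginary part.  Re-running Newton from the real part in real
    arithmetic converges to the exact real solution (imaginary part
    identically zero) whenever one is present; the result is accepted only if
    it stays within deduplication distance of the complex iterate.
    """
    if abs(u.imag) > 1e-8 * (1 + abs(u)) or abs(v.imag) > 1e-8 * (1 + abs(v)):
        return u, v
    ur, vr = _newton_polish(c1.real, c2.real, u.real, v.real, iters=20)
    if abs(ur - u) < 1e-6 * (1 + abs(u)) and abs(vr - v) < 1e-6 * (1 + abs(v)):
        return complex(ur), complex(vr)
    return u, v


def _valuation_and_degree(coeffs: np.ndarray, rtol: float) -> tuple[int, int]:
    mag = np.abs(coeffs)
    nz = np.nonzero(mag > rtol * mag.max())[0]
    return int(nz.min()), int(nz.max())


def _balanced_roots(reduced: np.ndarray) -> np.ndarray:
    """Roots of the deflated factor after geometric coefficient balancing."""
    if len(reduced) <= 1:
        return np.array([])
    R = len(reduced) - 1
    lo_c, hi_c = abs(reduced[0]), abs(reduced[-1])
    s_bal = (lo_c / hi_c) ** (1.0 / R) if lo_c > 0 and hi_c > 0 else 1.0
    balanced = reduced * s_bal ** np.arange(R + 1)
    return np.roots(balanced[::-1]) * s_bal


def _structural_deflation(coeffs: np.ndarray, D: int):
    """Deflate the origin's multiplicity-6 factor structurally.

    The coefficient c6 may sit far below the top coefficients at large sigma
    without any degeneracy, so it must not be thresholded away; only the
    surrounding structure (valuation >= 6, degree D, nothing above) is
    verified.  Returns (mult0, degree, reduced) with measured values when
    the structure check fails.
    """
    mag = np.abs(coeffs)
    cmax = mag.max()
    m0 = GENERIC_ORIGIN_MULTIPLICITY
    structure_ok = (
        mag[:m0].max(initial=0.0) < 1e-10 * cmax
        and mag[D + 1 :].max(initial=0.0) < 1e-10 * cmax
        and mag[D] > 3e-13 * cmax
    )
    if structure_ok:
        return m0, D, coeffs[m0 : D + 1]
    mult0, degree = _valuation_and_degree(coeffs, 1e-10)
    return mult0, degree, coeffs[mult0 : degree + 1]


def scaled_candidate_roots(
    c1: np.ndarray, c2: np.ndarray, scale: float, D: int, n_nodes: int = 33
) -> np.ndarray:
    """Candidate nonzero u-roots from an elimination at rescaled variables.

    Substituting (u, v) -> (scale*u, scale*v) re-centres the solution
    cluster of magnitude ~scale at order one.  The rescaled resultant then
    resolves that cluster only: coefficients representing clusters at other
    scales sit at the determinant rounding floor and are truncated away
    before root extraction.  Candidates must be Newton-verified downstream.
    """
    scl = scale ** np.arange(5)
    g1 = c1 * scl[:, None] * scl[None, :]
    g2 = c2 * scl[:, None] * scl[None, :]
    m = max(np.abs(g1).max(), np.abs(g2).max())
    if m == 0:
        return np.array([])
    coeffs = _resultant_coeffs(g1 / m, g2 / m, n_nodes)
    mag = np.abs(coeffs)
    cmax = mag.max()
    m0 = GENERIC_ORIGIN_MULTIPLICITY
    if cmax == 0 or mag[:m0].max(initial=0.0) > 1e-10 * cmax:
        return np.array([])
    above = np.nonzero(mag > 1e-12 * cmax)[0]
    above = above[(above >= m0) & (above <= D)]
    if above.size == 0 or above.max() <= above.min():
        return np.array([])
    reduced = coeffs[above.min() : above.max() + 1]
    return _balanced_roots(reduced) * scale


def _solve_double(
    c1: np.ndarray,
    c2: np.ndarray,
    thresholds: ClassifierThresholds,
    shear: complex = 0.0,
    n_nodes: int = 33,
    extra_scales: tuple[float, ...] = (),
):
    """One double-precision solve pass; returns (mult0, degree, solutions).

    ``extra_scales`` pools candidate roots from further eliminations with
    the variables rescaled, resolving solution clusters whose scale differs
    too much from one to survive determinant rounding on the unit circle.
    """
    if shear != 0.0:
        s1, s2 = _shear_grid(c1, shear), _shear_grid(c2, shear)
    else:
        s1, s2 = c1.astype(complex), c2.astype(complex)
    dv1, dv2 = _v_degrees(c1, c2)
    D = GENERIC_ORIGIN_MULTIPLICITY + dv1 + dv2  # 13 weak, 11 strong
    coeffs = _resultant_coeffs(s1, s2, n_nodes)
    mult0, degree, reduced = _structural_deflation(coeffs, D)
    uroots = _balanced_roots(reduced)
    if extra_scales and shear == 0.0:
        pools = [uroots]
        for sc in extra_scales:
            pools.append(scaled_candidate_roots(s1, s2, sc, D, n_nodes))
        uroots = np.concatenate(pools)

    dv1, dv2 = _v_degrees(c1, c2)
    sols = []
    for ur in uroots:
        up = ur ** np.arange(5)
        cands = []
        for c, dv in ((s1, None), (s2, None)):
            f = up @ c
            dv = max(j for j in range(5) if abs(f[j]) > 0) if np.any(f) else 0
            if dv >= 1:
                cands.extend(np.roots(f[: dv + 1][::-1]))
        best = None
        for vc in cands:
            u2, v2 = _newton_polish(s1, s2, ur, vc)
            if abs(u2 - ur) > 1e-4 * (1 + abs(ur)):
                continue  # Newton wandered off this u-root
            if (
                abs(u2) + abs(v2) < _ORIGIN_CLUSTER_RADIUS
                and abs(u2 - ur) > 0.25 * abs(ur)
            ):
                continue  # wandered into the origin cluster: an artifact
            r = max(abs(_eval_grid(s1, u2, v2)), abs(_eval_grid(s2, u2, v2)))
            if best is None or r < best[2]:
                best = (u2, v2, r)
        if best is None:
            continue
        u2, v2, _ = best
        # undo the shear: grid substitution was u -> u + g v
        uu, vv = u2 + shear * v2, v2
        uu, vv = _newton_polish(c1.astype(complex), c2.astype(complex), uu, vv)
        uu, vv = _try_realify(c1, c2, uu, vv)
        sols.append((uu, vv, _residual(c1, c2, uu, vv)))
    return mult0, degree, sols


def _solve_exact(c1: np.ndarray, c2: np.ndarray, dps: int = 50):
    """Exact-rational resultant + multiprecision roots (the last rung).

    Double-precision coefficient grids are rationalised exactly, the
    resultant computed over Q, and its deflated factor solved with mpmath at
    ``dps`` digits.  Solutions are polished with multiprecision Newton so
    that true real solutions carry imaginary parts far below t_zmin.
    """
    u, v = sp.symbols("u v")

    def to_expr(c):
        return sp.Add(
            *(
                sp.Rational(*float(c[i, j]).as_integer_ratio()) * u**i * v**j
                for i in range(5)
                for j in range(5)
                if c[i, j] != 0.0
            )
        )

    P1, P2 = to_expr(c1), to_expr(c2)
    R = sp.resultant(sp.Poly(P1, v), sp.Poly(P2, v))
    Rp = sp.Poly(R, u)
    if Rp.is_zero:
        raise DegenerateSystemError("identically zero exact resultant")
    monoms = [m[0] for m in Rp.monoms()]
    mult0, degree = min(monoms), max(monoms)
    all_c = Rp.all_coeffs()[::-1]  # index k -> coeff of u^k
    with mpmath.workdps(dps):
        red = [mpmath.mpf(sp.Float(all_c[k], dps)) for k in range(mult0, degree + 1)]
        try:
            uroots = mpmath.polyroots(red, maxsteps=200, extraprec=80, asc=True)
        except TypeError:  # older mpmath without the asc keyword
            uroots = mpmath.polyroots(red[::-1], maxsteps=200, extraprec=80)
        f1v = sp.Poly(P1, v).all_coeffs()  # highest first, coeffs in u
        f2v = sp.Poly(P2, v).all_coeffs()
        p1num = sp.lambdify((u, v), P1, "mpmath")
        p2num = sp.lambdify((u, v), P2, "mpmath")
        j1u = sp.lambdify((u, v), sp.diff(P1, u), "mpmath")
        j1v = sp.lambdify((u, v), sp.diff(P1, v), "mpmath")
        j2u = sp.lambdify((u, v), sp.diff(P2, u), "mpmath")
        j2v = sp.lambdify((u, v), sp.diff(P2, v), "mpmath")

        def mp_newton(uu, vv, iters=60):
            for _ in range(iters):
                f1 = p1num(uu, vv)
                f2 = p2num(uu, vv)
                a, b = j1u(uu, vv), j1v(uu, vv)
                c, d = j2u(uu, vv), j2v(uu, vv)
                det = a * d - b * c
                if det == 0:
                    break
                du = (f1 * d - f2 * b) / det
                dv = (f2 * a - f1 * c) / det
                uu, vv = uu - du, vv - dv
                if abs(du) + abs(dv) < mpmath.mpf(10) ** (-dps + 5):
                    break
            return uu, vv

        sols = []
        for ur in uroots:
            cands = []
            for fv in (f1v, f2v):
                cf = [sp.lambdify(u, c, "mpmath")(ur) for c in fv]
                while cf and abs(cf[0]) < mpmath.mpf(10) ** (-dps):
                    cf = cf[1:]
                if len(cf) > 1:
                    try:
                        cands.extend(
                            mpmath.polyroots(cf[::-1], maxsteps=200,
                                             extraprec=80, asc=True)
                        )
                    except TypeError:
                        try:
                            cands.extend(
                                mpmath.polyroots(cf, maxsteps=200, extraprec=80)
                            )
                        except mpmath.libmp.libhyper.NoConvergence:
                            pass
                    except mpmath.libmp.libhyper.NoConvergence:
                        pass
            best = None
            for vc in cands:
                uu, vv = mp_newton(mpmath.mpc(ur), mpmath.mpc(vc))
                if abs(uu - ur) > mpmath.mpf("1e-6") * (1 + abs(ur)):
                    continue
                r = max(abs(p1num(uu, vv)), abs(p2num(uu, vv)))
                if best is None or r < best[2]:
                    best = (uu, vv, r)
            if best is None:
                continue
            uu, vv, _r = best
            # collapse rounding-level imaginary parts before leaving mp
            if abs(uu.imag) < mpmath.mpf(10) ** (-dps + 12) and abs(
                vv.imag
            ) < mpmath.mpf(10) ** (-dps + 12):
                uu, vv = mpmath.mpc(uu.real), mpmath.mpc(vv.real)
            sols.append(
                (complex(uu), complex(vv), _residual(c1, c2, complex(uu), complex(vv)))
            )
    return mult0, degree, sols


def _dedup(sols):
    """Merge numerically identical solutions; report whether any merged."""
    kept: list[tuple[complex, complex, float]] = []
    merged = False
    for u, v, r in sorted(sols, key=lambda s: s[2]):
        scale = 1.0 + abs(u) + abs(v)
        if any(
            abs(u - u0) + abs(v - v0) < _DEDUP_RTOL * scale for u0, v0, _ in kept
        ):
            merged = True
            continue
        kept.append((u, v, r))
    return kept, merged


def _classify_solutions(raw, system: SteadyStateSystem, t: ClassifierThresholds):
    """Build SolutionPoints for finite solutions; count positives/ambiguity."""
    scale = system.coefficient_scale()
    points = []
    n_pos = 0
    questionable = False
    for u, v, r in raw:
        cu = classify_coordinate(u, t)
        cv = classify_coordinate(v, t)
        if cu is CoordinateClass.INFINITE or cv is CoordinateClass.INFINITE:
            continue
        if cu is CoordinateClass.SMALL and cv is CoordinateClass.SMALL:
            questionable = True  # a nonzero solution collapsed onto the origin
            continue
        if CoordinateClass.AMBIGUOUS in (cu, cv) or CoordinateClass.SMALL in (cu, cv):
            questionable = True
        # residual bound relative to the size of the evaluated terms: far
        # from the unit box the polynomial terms themselves grow like
        # (|u| + |v|)^4 and absolute residuals scale with them
        if r > 1e-10 * scale * max(1.0, abs(u) + abs(v)) ** 4:
            questionable = True
        pt = SolutionPoint(u, v, r, cu, cv)
        if pt.is_positive_real(t):
            n_pos += 1
        points.append(pt)
    return points, n_pos, questionable


def solve_system(
    system: SteadyStateSystem,
    thresholds: ClassifierThresholds | None = None,
    eliminate: str = "v",
    certify: bool = False,
) -> SolutionSet:
    """Find, refine, classify and count all finite solutions of the system.

    Parameters
    ----------
    system : SteadyStateSystem
    thresholds : ClassifierThresholds, optional
    eliminate : {"v", "u"}
        Which variable the Sylvester resultant eliminates.  The two orders
        are algebraically equivalent and serve as mutual cross-checks.
    certify : bool
        Additionally run the Newton-contraction certificate on every finite
        nonzero solution.
    """
    t = thresholds or ClassifierThresholds()
    c1 = system.phi1.coeffs
    c2 = system.phi2.coeffs
    if eliminate == "u":
        c1, c2 = c1.T.copy(), c2.T.copy()
    elif eliminate != "v":
        raise ValueError("eliminate must be 'u' or 'v'")

    mode = system.mode
    expect_finite = GENERIC_FINITE_COUNT[mode]
    expect_degree = GENERIC_RESULTANT_DEGREE[mode]

    # normalise the coefficient scale; roots are unchanged
    s = max(np.abs(c1).max(), np.abs(c2).max())
    c1n, c2n = c1 / s, c2 / s

    big = max(system.totals.sigma, system.totals.lam, 2.0)
    # (solver pass, pooled): pooled passes combine candidates from several
    # eliminations, so duplicate candidates are expected and not a
    # degeneracy signal there
    attempts = [
        (lambda: _solve_double(c1n, c2n, t), False),
        (lambda: _solve_double(c1n, c2n, t, extra_scales=(1.0 / big, big)), True),
        (lambda: _solve_double(c1n, c2n, t, shear=0.2718 + 0.3141j), False),
        (lambda: _solve_exact(c1n, c2n, dps=50), False),
    ]
    escalations = 0
    result = None
    tight = t
    for k, (attempt, pooled) in enumerate(attempts):
        try:
            mult0, degree, raw = attempt()
        except (DegenerateSystemError, np.linalg.LinAlgError):
            escalations += 1
            continue
        raw, merged = _dedup(raw)
        if k == len(attempts) - 1:
            # after the 50-digit pass a tighter ambiguity threshold applies
            tight = ClassifierThresholds(t.t_zmin, min(t.t_zmax, 1e-11), t.t_inf, t.newton_tol)
        points, n_pos, questionable = _classify_solutions(raw, system, tight)
        generic = (
            mult0 == GENERIC_ORIGIN_MULTIPLICITY
            and degree == expect_degree
            and len(points) == expect_finite
            and (pooled or not merged)
            and not questionable
            and n_pos in (1, 3)
        )
        result = (mult0, points, n_pos)
        if generic:
            break
        escalations += 1

    if result is None:
        raise DegenerateSystemError("all solver attempts failed")
    mult0, points, n_pos = result
    if eliminate == "u":
        points = [
            SolutionPoint(p.v, p.u, p.residual, p.v_class, p.u_class, p.certified)
            for p in points
        ]
    generic = (
        mult0 == GENERIC_ORIGIN_MULTIPLICITY
        and len(points) == expect_finite
        and n_pos in (1, 3)
        and escalations < len(attempts)
    )
    if not generic:
        stat = Stationarity.NONGENERIC
    elif n_pos == 1:
        stat = Stationarity.MONOSTABLE
    else:
        stat = Stationarity.BISTABLE
    if certify:
        points = [
            SolutionPoint(
                p.u, p.v, p.residual, p.u_class, p.v_class,
                certify_newton((p.u, p.v), system),
            )
            for p in points
        ]
    return SolutionSet(
        solutions=tuple(points),
        origin_multiplicity=int(mult0),
        n_finite_nonzero=len(points),
        n_positive_real=int(n_pos),
        stationarity=stat,
        escalations=escalations,
    )


def origin_multiplicity(
    system: SteadyStateSystem, thresholds: ClassifierThresholds | None = None
) -> int:
    """Local intersection multiplicity of the solution u = v = 0.

    Computed as the multiplicity of the u = 0 root of the v-eliminating
    resultant, after checking that no other finite solution has u within
    ``t_zmax`` of zero; if one does, the projection is made generic with a
    random shear before reading off the valuation.
    """
    t = thresholds or ClassifierThresholds()
    sol = solve_system(system, t)
    clear = all(abs(p.u) > t.t_zmax for p in sol.solutions)
    c1 = system.phi1.coeffs.astype(complex)
    c2 = system.phi2.coeffs.astype(complex)
    s = max(np.abs(c1).max(), np.abs(c2).max())
    if not clear:
        g = 0.6180 + 0.7862j
        c1, c2 = _shear_grid(c1 / s, g), _shear_grid(c2 / s, g)
    else:
        c1, c2 = c1 / s, c2 / s
    coeffs = _resultant_coeffs(c1, c2)
    mult0, _ = _valuation_and_degree(coeffs, 1e-10)
    return int(mult0)


def certify_newton(
    solution: tuple[complex, complex] | SolutionPoint,
    system: SteadyStateSystem,
    n_steps: int = 3,
) -> bool:
    """Newton-contraction certificate for a refined solution.

    Returns True iff the Jacobian at the solution is non-singular and
    successive Newton steps contract at least quadratically over ``n_steps``
    iterations (allowing a floor at rounding level).  Singular solutions --
    notably the multiplicity-6 origin -- are never certified.
    """
    if isinstance(solution, SolutionPoint):
        u, v = solution.u, solution.v
    else:
        u, v = solution
    c1 = system.phi1.coeffs
    c2 = system.phi2.coeffs
    scale = system.coefficient_scale()
    j11, j12, j21, j22 = _jacobian(c1, c2, u, v)
    det = j11 * j22 - j12 * j21
    jnorm = max(abs(j11), abs(j12), abs(j21), abs(j22))
    if jnorm == 0 or abs(det) < 1e-12 * jnorm**2:
        return False  # singular Jacobian: Newton certification does not apply
    norms = []
    uu, vv = u, v
    for _ in range(n_steps):
        f1 = _eval_grid(c1, uu, vv)
        f2 = _eval_grid(c2, uu, vv)
        j11, j12, j21, j22 = _jacobian(c1, c2, uu, vv)
        det = j11 * j22 - j12 * j21
        if det == 0:
            return False
        du = (f1 * j22 - f2 * j12) / det
        dv = (f2 * j11 - f1 * j21) / det
        norms.append(float(np.hypot(abs(du), abs(dv))))
        uu, vv = uu - du, vv - dv
    floor = 64 * np.finfo(float).eps * (1 + abs(u) + abs(v))
    contraction_C = 1e6  # generous bound tied to local conditioning
    for a, b in zip(norms, norms[1:]):
        if b > max(contraction_C * a * a, floor):
            return False
    if _residual(c1, c2, uu, vv) > 1e-8 * scale:
        return False
    return norms[0] < 1e-5 * (1 + abs(u) + abs(v))
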