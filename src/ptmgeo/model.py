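"""Non-dimensional parameters and the steady-state polynomial system.

A substrate S carries two modification sites that are modified in a fixed
order by a forward enzyme E and demodified in the reverse order by a reverse
enzyme F, each enzyme acting distributively through an arbitrary mechanism of
intermediate complexes.  At steady state the whole network collapses to two
polynomial equations in the normalised free-enzyme concentrations

    u = [E]/E_tot,   v = [F]/F_tot,

namely ``Phi1(u, v) = 0`` and ``Phi2(u, v) = 0``, each of total degree 4.
The eight non-dimensional parameters are

    alpha, beta          -- ratios of total generalised catalytic efficiencies,
    eps0, eps1, eps2     -- binding parameters of E (rtgMMC x E_tot),
    phi0, phi1, phi2     -- binding parameters of F (rtgMMC x F_tot),

and the conserved totals enter through sigma = S_tot/E_tot,
lam = S_tot/F_tot and zeta = E_tot/F_tot.  "Weak irreversibility" allows the
product of each demodification-side reaction to rebind its producing enzyme
(eps2, phi0 > 0); "strong irreversibility" (Michaelis-Menten-like) forces
eps2 = phi0 = 0 exactly, leaving six free parameters.

Two independent construction routes for the system are provided:
:func:`build_system` writes out the expanded degree-4 coefficient grids
term by term, while :func:`build_system_via_psi` assembles the same
polynomials from the factorised form

    Phi1 = zeta*u*v*((1 - u)*(psi1 + u*psi2 + v*psi3) - sigma*u*psi2)
    Phi2 = zeta*u*v*((1 - v)*(psi1 + u*psi2 + v*psi3) - lam*v*psi3)

with the rational functions psi_k spanned by {v/u, 1, u/v}.  Agreement of
the two routes is a strong guard against transcription errors in the 24
expanded coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "InvalidParameterError",
    "InconsistencyError",
    "NondimensionalParameters",
    "ConservedTotals",
    "SamplingBox",
    "BivariatePolynomial",
    "SteadyStateSystem",
    "PsiExpressions",
    "SteadyStateConcentrations",
    "build_system",
    "build_system_via_psi",
    "recover_concentrations",
]

Mode = Literal["weak", "strong"]

#: theta-order of the eight non-dimensional parameters.
THETA_ORDER = ("alpha", "beta", "eps0", "eps1", "eps2", "phi0", "phi1", "phi2")
#: eta-order of the six strong-irreversibility parameters.
ETA_ORDER = ("alpha", "beta", "eps0", "eps1", "phi1", "phi2")


class InvalidParameterError(ValueError):
    """A parameter violates its positivity/mode constraint."""


class InconsistencyError(ValueError):
    """A quantity fails a consistency check (e.g. (u, v) is not a solution)."""


@dataclass(frozen=True)
class NondimensionalParameters:
    """One parameter point theta of the two-site PTM system.

    ``mode='strong'`` requires ``eps2 == phi0 == 0`` exactly (no product
    rebinding on the reactions consuming the singly-modified form); all other
    parameters are strictly positive in both modes.
    """

    alpha: float
    beta: float
    eps0: float
    eps1: float
    eps2: float
    phi0: float
    phi1: float
    phi2: float
    mode: Mode = "weak"

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "eps0", "eps1", "phi1", "phi2"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be strictly positive")
        if self.eps2 < 0 or self.phi0 < 0:
            raise InvalidParameterError("eps2 and phi0 must be non-negative")
        if self.mode == "strong" and (self.eps2 != 0.0 or self.phi0 != 0.0):
            raise InvalidParameterError("strong irreversibility forces eps2 = phi0 = 0")
        if self.mode not in ("weak", "strong"):
            raise InvalidParameterError(f"unknown mode {self.mode!r}")

    @classmethod
    def from_theta(cls, theta, mode: Mode = "weak") -> "NondimensionalParameters":
        """Build from a point in theta-order (length 8) or eta-order (length 6)."""
        theta = tuple(float(x) for x in theta)
        if len(theta) == 8:
            return cls(*theta, mode=mode)
        if len(theta) == 6:
            a, b, e0, e1, p1, p2 = theta
            return cls(a, b, e0, e1, 0.0, 0.0, p1, p2, mode="strong")
        raise InvalidParameterError("expected 8 (weak) or 6 (strong) coordinates")

    def to_theta(self) -> np.ndarray:
        """Coordinates in theta-order (always length 8)."""
        return np.array([getattr(self, n) for n in THETA_ORDER])

    def to_eta(self) -> np.ndarray:
        """Strong-mode coordinates in eta-order (length 6)."""
        if self.mode != "strong":
            raise InvalidParameterError("eta-order is defined for strong mode only")
        return np.array([getattr(self, n) for n in ETA_ORDER])


@dataclass(frozen=True)
class ConservedTotals:
    """Non-dimensionalised conserved totals.

    sigma = S_tot/E_tot, lam = S_tot/F_tot, zeta = E_tot/F_tot.  The default
    study configuration sets the two enzyme totals equal, so zeta = 1 and
    lam = sigma; lam is nevertheless stored independently.
    """

    sigma: float
    lam: float
    zeta: float = 1.0

    def __post_init__(self) -> None:
        if not (self.sigma > 0 and self.lam > 0 and self.zeta > 0):
            raise InvalidParameterError("sigma, lam, zeta must be strictly positive")

    @classmethod
    def equal_enzymes(cls, sigma: float) -> "ConservedTotals":
        """E_tot = F_tot: zeta = 1 and lam = sigma."""
        return cls(sigma=float(sigma), lam=float(sigma), zeta=1.0)


@dataclass(frozen=True)
class SamplingBox:
    """The box H_p = [0.1^p, 10^p]^dim, described in log10 coordinates."""

    exponent_p: int = 1
    dimension: int = 8

    def __post_init__(self) -> None:
        if self.exponent_p < 1 or int(self.exponent_p) != self.exponent_p:
            raise InvalidParameterError("exponent_p must be a positive integer")
        if self.dimension not in (6, 8):
            raise InvalidParameterError("dimension must be 8 (weak) or 6 (strong)")

    @property
    def mode(self) -> Mode:
        return "weak" if self.dimension == 8 else "strong"

    @property
    def log_bounds(self) -> tuple[float, float]:
        return (-float(self.exponent_p), float(self.exponent_p))

    @property
    def log_volume(self) -> float:
        """(2p)^dimension, the log10-measure volume of the box."""
        return float((2.0 * self.exponent_p) ** self.dimension)


@dataclass(frozen=True)
class BivariatePolynomial:
    """Real bivariate polynomial stored as a (5, 5) grid c[i, j] on u^i v^j."""

    coeffs: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.coeffs, dtype=float)
        if c.shape != (5, 5):
            raise InvalidParameterError("coefficient grid must be 5x5")
        object.__setattr__(self, "coeffs", c)

    def __call__(self, u, v):
        return np.polynomial.polynomial.polyval2d(u, v, self.coeffs)

    @property
    def u_degree(self) -> int:
        nz = np.nonzero(self.coeffs)[0]
        return int(nz.max()) if nz.size else 0

    @property
    def v_degree(self) -> int:
        nz = np.nonzero(self.coeffs)[1]
        return int(nz.max()) if nz.size else 0

    def partial_u(self) -> "BivariatePolynomial":
        d = np.zeros((5, 5))
        d[:4, :] = self.coeffs[1:, :] * np.arange(1, 5)[:, None]
        return BivariatePolynomial(d)

    def partial_v(self) -> "BivariatePolynomial":
        d = np.zeros((5, 5))
        d[:, :4] = self.coeffs[:, 1:] * np.arange(1, 5)[None, :]
        return BivariatePolynomial(d)


@dataclass(frozen=True)
class PsiExpressions:
    """The rational functions psi_k(u, v) = a_k v/u + b_k + c_k u/v.

    Row k of ``table`` holds (a_k, b_k, c_k) for psi_{k+1} over the monomial
    basis (v/u, 1, u/v).  Note the expanded degree-4 system is authoritative
    for the zeta-dependence: the coefficients used here are
    psi1 = (alpha/zeta, 1, beta*zeta), psi2 = (eps0*alpha/zeta, eps1,
    eps2*beta*zeta), psi3 = (phi0*alpha/zeta, phi1, phi2*beta*zeta), which
    reproduce the expanded system exactly for every zeta and coincide with
    the zeta = 1 configuration used throughout the study.
    """

    table: np.ndarray  # (3, 3)

    @classmethod
    def from_parameters(
        cls, params: NondimensionalParameters, totals: ConservedTotals
    ) -> "PsiExpressions":
        a, b, z = params.alpha, params.beta, totals.zeta
        weights = np.array(
            [
                [1.0, 1.0, 1.0],
                [params.eps0, params.eps1, params.eps2],
                [params.phi0, params.phi1, params.phi2],
            ]
        )
        return cls(weights * np.array([a / z, 1.0, b * z]))

    def __call__(self, k: int, u, v):
        """Evaluate psi_k (k = 1, 2, 3) at (u, v)."""
        a, b, c = self.table[k - 1]
        return a * v / u + b + c * u / v


@dataclass(frozen=True)
class SteadyStateSystem:
    """The pair (Phi1, Phi2) at fixed parameters and totals."""

    phi1: BivariatePolynomial
    phi2: BivariatePolynomial
    params: NondimensionalParameters
    totals: ConservedTotals

    def __post_init__(self) -> None:
        if self.phi1.coeffs[0, 0] != 0.0 or self.phi2.coeffs[0, 0] != 0.0:
            raise InconsistencyError("the origin must be a root of both polynomials")

    @property
    def mode(self) -> Mode:
        return self.params.mode

    def residual(self, u, v) -> float:
        """max |Phi_k(u, v)| over k = 1, 2."""
        return float(max(abs(self.phi1(u, v)), abs(self.phi2(u, v))))

    def coefficient_scale(self) -> float:
        return float(
            max(np.abs(self.phi1.coeffs).max(), np.abs(self.phi2.coeffs).max())
        )


def system_coefficient_grids(
    theta: np.ndarray, sigma: float, lam: float, zeta: float
) -> tuple[np.ndarray, np.ndarray]:
    """Expanded coefficient grids of (Phi1, Phi2) for points ``theta``.

    ``theta`` has shape (..., 8) in theta-order; the returned grids have
    shape (..., 5, 5) with entry [i, j] multiplying u^i v^j.  This is the
    vectorised workhorse behind :func:`build_system`.
    """
    theta = np.asarray(theta, dtype=float)
    a, b = theta[..., 0], theta[..., 1]
    e0, e1, e2 = theta[..., 2], theta[..., 3], theta[..., 4]
    p0, p1, p2 = theta[..., 5], theta[..., 6], theta[..., 7]
    z = zeta
    bz2 = b * z * z
    c1 = np.zeros(theta.shape[:-1] + (5, 5))
    c2 = np.zeros_like(c1)

    # shared quadratic part: alpha v^2 + zeta u v + beta zeta^2 u^2
    for c in (c1, c2):
        c[..., 0, 2] = a
        c[..., 1, 1] = z
        c[..., 2, 0] = bz2

    c1[..., 1, 2] = a * e0 - a * e0 * sigma - a + p1 * z
    c1[..., 2, 1] = e1 * z - e1 * z * sigma - z + b * p2 * z * z
    c1[..., 3, 0] = bz2 * e2 - bz2 * e2 * sigma - bz2
    c1[..., 0, 3] = a * p0
    c1[..., 2, 2] = -(a * e0 + p1 * z)
    c1[..., 3, 1] = -(e1 * z + b * p2 * z * z)
    c1[..., 4, 0] = -bz2 * e2
    c1[..., 1, 3] = -a * p0

    c2[..., 0, 3] = a * p0 - a * p0 * lam - a
    c2[..., 1, 2] = p1 * z - p1 * z * lam - z + a * e0
    c2[..., 2, 1] = bz2 * p2 - bz2 * p2 * lam - bz2 + e1 * z
    c2[..., 3, 0] = bz2 * e2
    c2[..., 1, 3] = -(a * e0 + p1 * z)
    c2[..., 2, 2] = -(e1 * z + b * p2 * z * z)
    c2[..., 3, 1] = -bz2 * e2
    c2[..., 0, 4] = -a * p0
    return c1, c2


def build_system(
    params: NondimensionalParameters, totals: ConservedTotals
) -> SteadyStateSystem:
    """Assemble (Phi1, Phi2) from the expanded degree-4 coefficient grids."""
    c1, c2 = system_coefficient_grids(
        params.to_theta(), totals.sigma, totals.lam, totals.zeta
    )
    return SteadyStateSystem(
        BivariatePolynomial(c1), BivariatePolynomial(c2), params, totals
    )


def _shift(grid: np.ndarray, di: int, dj: int) -> np.ndarray:
    """Multiply a coefficient grid by u^di v^dj (grids stay within 5x5)."""
    out = np.zeros_like(grid)
    out[di:, dj:] = grid[: grid.shape[0] - di, : grid.shape[1] - dj]
    return out


def build_system_via_psi(
    params: NondimensionalParameters, totals: ConservedTotals
) -> SteadyStateSystem:
    """Assemble (Phi1, Phi2) from the psi-factorised form.

    Each psi_k spans {v/u, 1, u/v}, so u*v*psi_k is a genuine polynomial:
    a_k v^2 + b_k u v + c_k u^2.  Everything else is polynomial arithmetic on
    coefficient grids, giving an independent route to the same system.
    """
    psi = PsiExpressions.from_parameters(params, totals)
    z, sigma, lam = totals.zeta, totals.sigma, totals.lam

    uv_psi = []  # grid of u*v*psi_k
    for k in range(3):
        a, b, c = psi.table[k]
        g = np.zeros((5, 5))
        g[0, 2], g[1, 1], g[2, 0] = a, b, c
        uv_psi.append(g)

    # u*v*(psi1 + u psi2 + v psi3)
    uvP = uv_psi[0] + _shift(uv_psi[1], 1, 0) + _shift(uv_psi[2], 0, 1)
    c1 = z * ((uvP - _shift(uvP, 1, 0)) - sigma * _shift(uv_psi[1], 1, 0))
    c2 = z * ((uvP - _shift(uvP, 0, 1)) - lam * _shift(uv_psi[2], 0, 1))
    return SteadyStateSystem(
        BivariatePolynomial(c1), BivariatePolynomial(c2), params, totals
    )


@dataclass(frozen=True)
class SteadyStateConcentrations:
    """Full steady state recovered from a positive real solution (u, v).

    Modform concentrations s0, s1, s2 and the two summed enzyme-substrate
    complex pools are all expressed in units of S_tot, so substrate
    conservation reads s0 + s1 + s2 + complex_e + complex_f = 1.
    """

    u: float
    v: float
    s0: float
    s1: float
    s2: float
    complex_e: float
    complex_f: float

    @property
    def conservation_residual(self) -> float:
        return abs(self.s0 + self.s1 + self.s2 + self.complex_e + self.complex_f - 1.0)


def recover_concentrations(
    u: float,
    v: float,
    params: NondimensionalParameters,
    totals: ConservedTotals,
    tol: float = 1e-8,
) -> SteadyStateConcentrations:
    """Recover all steady-state concentrations from a positive real solution.

    The substrate conservation law gives s1 = 1/(psi1 + u psi2 + v psi3); the
    flux-balance ratios give s0 = (alpha/zeta)(v/u) s1 and
    s2 = beta zeta (u/v) s1; the complex pools are u s1 psi2 and v s1 psi3.

    Raises
    ------
    InconsistencyError
        If (u, v) does not solve the steady-state system to within ``tol``
        relative to the coefficient scale.
    """
    if not (u > 0 and v > 0):
        raise InvalidParameterError("u and v must be strictly positive")
    system = build_system(params, totals)
    if system.residual(u, v) > tol * system.coefficient_scale():
        raise InconsistencyError(
            f"(u, v) = ({u}, {v}) is not a steady-state solution within tolerance"
        )
    psi = PsiExpressions.from_parameters(params, totals)
    psi1, psi2, psi3 = (psi(k, u, v) for k in (1, 2, 3))
    s1 = 1.0 / (psi1 + u * psi2 + v * psi3)
    s0 = (params.alpha / totals.zeta) * (v / u) * s1
    s2 = params.beta * totals.zeta * (u / v) * s1
    return SteadyStateConcentrations(
        u=float(u),
        v=float(v),
        s0=float(s0),
        s1=float(s1),
        s2=float(s2),
        complex_e=float(u * s1 * psi2),
        complex_f=float(v * s1 * psi3),
    )
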