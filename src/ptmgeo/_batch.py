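"""Vectorised stationarity labelling of many parameter points at once.

This mirrors the per-point solver in :mod:`ptmgeo.solver` -- Sylvester
elimination, FFT interpolation of the resultant, companion-matrix roots,
back-substitution and Newton polish -- but runs every stage as batched numpy
linear algebra over chunks of parameter points.

At large sigma the seven finite solutions split into a cluster of size
~1/sigma (the physically saturated branch) and a cluster of size ~sigma, and
no single determinant evaluation scale resolves both in double precision:
coefficients of the resultant spanning more than ~14 orders of magnitude
drop below the rounding floor of the determinant.  Points the fast pass
cannot certify are therefore re-solved in a second vectorised pass with the
variables rescaled by 1/sigma (re-centring the small cluster at order one)
and the root candidates of both passes pooled; only the remaining stragglers
go through the per-point escalation ladder of
:func:`ptmgeo.solver.solve_system`.  No questionable point is ever decided
by the fast path alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import solver as _solver
from .model import (
    ConservedTotals,
    NondimensionalParameters,
    build_system,
    system_coefficient_grids,
)
from .solver import ClassifierThresholds, Stationarity

__all__ = ["BatchLabels", "label_points", "expand_eta", "bistability_indicator"]

_N_NODES = 17  # > generic resultant degree (13 weak, 11 strong)
_CHUNK = 4096
_RES_RTOL = 1e-10

#: integer codes used in labelled tables
STAT_CODE = {
    Stationarity.MONOSTABLE: 0,
    Stationarity.BISTABLE: 1,
    Stationarity.NONGENERIC: 2,
}


@dataclass
class BatchLabels:
    """Per-point labelling outcome for one (sigma, lam, zeta) configuration."""

    stationarity: np.ndarray  # int8 codes: 0 mono, 1 bi, 2 nongeneric
    n_positive: np.ndarray  # int8
    n_finite: np.ndarray  # int8
    n_fallback: int  # points decided by the per-point ladder

    @property
    def bistable(self) -> np.ndarray:
        return self.stationarity == STAT_CODE[Stationarity.BISTABLE]

    @property
    def nongeneric(self) -> np.ndarray:
        return self.stationarity == STAT_CODE[Stationarity.NONGENERIC]


def expand_eta(eta: np.ndarray) -> np.ndarray:
    """Map (N, 6) strong-mode eta points to (N, 8) theta points (eps2=phi0=0)."""
    eta = np.asarray(eta, dtype=float)
    theta = np.zeros(eta.shape[:-1] + (8,))
    theta[..., [0, 1, 2, 3, 6, 7]] = eta
    return theta


# ---------------------------------------------------------------------------
# batched pipeline stages


def _companion_roots(coeffs: np.ndarray) -> np.ndarray:
    """Roots of monic-normalisable polynomials coeffs[..., k] x^k, batched."""
    deg = coeffs.shape[-1] - 1
    b = coeffs[..., :-1] / coeffs[..., -1:]
    comp = np.zeros(coeffs.shape[:-1] + (deg, deg), dtype=complex)
    idx = np.arange(deg - 1)
    comp[..., idx + 1, idx] = 1.0
    comp[..., :, deg - 1] = -b
    return np.linalg.eigvals(comp)


def _eval_many(c: np.ndarray, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Evaluate grids c (C,5,5) at u, v of shape (C, ...) -> (C, ...)."""
    U = u[..., None] ** np.arange(5)
    V = v[..., None] ** np.arange(5)
    return np.einsum("cij,c...i,c...j->c...", c, U, V)


def _normalise(c1: np.ndarray, c2: np.ndarray):
    C = c1.shape[0]
    scale = np.maximum(
        np.abs(c1).reshape(C, -1).max(1), np.abs(c2).reshape(C, -1).max(1)
    )
    scale = np.where(scale == 0, 1.0, scale)
    return c1 / scale[:, None, None], c2 / scale[:, None, None]


def _resultant_batch(c1: np.ndarray, c2: np.ndarray, dv1: int, dv2: int):
    """FFT-interpolated Sylvester resultant coefficients, (C, _N_NODES)."""
    C = c1.shape[0]
    n = dv1 + dv2
    nodes = np.exp(2j * np.pi * np.arange(_N_NODES) / _N_NODES)
    P = nodes[:, None] ** np.arange(5)[None, :]
    F1 = np.einsum("cij,ki->ckj", c1, P)
    F2 = np.einsum("cij,ki->ckj", c2, P)
    F1r = np.ascontiguousarray(F1[:, :, : dv1 + 1][:, :, ::-1])
    F2r = np.ascontiguousarray(F2[:, :, : dv2 + 1][:, :, ::-1])
    S = np.zeros((C, _N_NODES, n, n), dtype=complex)
    for r in range(dv2):
        S[:, :, r, r : r + dv1 + 1] = F1r
    for r in range(dv1):
        S[:, :, dv2 + r, r : r + dv2 + 1] = F2r
    dets = np.linalg.det(S.reshape(-1, n, n)).reshape(C, _N_NODES)
    return np.fft.fft(dets, axis=1) / _N_NODES


def _deflated_uroots(coeffs: np.ndarray, m0: int, D: int):
    """Structurally deflate the origin factor and return balanced roots.

    Returns (uroots (C, D-m0), bad mask (C,)).  ``bad`` marks points whose
    resultant violates the generic structure (origin valuation >= m0, degree
    D, nothing above).
    """
    C = coeffs.shape[0]
    R = D - m0
    cmax = np.abs(coeffs).max(axis=1)
    cmax = np.where(cmax == 0, 1.0, cmax)
    low = np.abs(coeffs[:, :m0]).max(axis=1)
    trail = (
        np.abs(coeffs[:, D + 1 :]).max(axis=1)
        if D + 1 < coeffs.shape[1]
        else np.zeros(C)
    )
    lead = np.abs(coeffs[:, D])
    bad = (low > 1e-10 * cmax) | (trail > 1e-10 * cmax) | (lead < 3e-13 * cmax)

    reduced = coeffs[:, m0 : D + 1]
    lo_c = np.abs(reduced[:, 0])
    hi_c = np.abs(reduced[:, -1])
    s_bal = np.where(
        (lo_c > 0) & (hi_c > 0),
        (lo_c / np.where(hi_c == 0, 1.0, hi_c)) ** (1.0 / R),
        1.0,
    )
    balanced = reduced * s_bal[:, None] ** np.arange(R + 1)
    uroots = np.zeros((C, R), dtype=complex)
    ok = ~bad
    if ok.any():
        uroots[ok] = _companion_roots(balanced[ok]) * s_bal[ok, None]
    return uroots, bad


def _best_v(c1, c2, u, dv1, dv2):
    """For each u-root, the v-candidate (from either polynomial) with the
    smallest scaled residual."""
    C, R = u.shape
    U5 = u[..., None] ** np.arange(5)
    cands = []
    for c, dv in ((c1, dv1), (c2, dv2)):
        fv = np.einsum("cij,cri->crj", c, U5)[..., : dv + 1]
        # only a rounding-level leading coefficient is degenerate; a merely
        # small one yields dv-1 accurate roots plus one huge spurious root
        # that residual selection discards
        bad = np.abs(fv[..., -1]) < 1e-14 * np.abs(fv).max(axis=-1)
        bad |= ~np.isfinite(fv).all(axis=-1)
        fv = np.where(bad[..., None], 0.0, fv)
        fv[..., -1] = np.where(bad, 1.0, fv[..., -1])
        roots = _companion_roots(fv.reshape(-1, dv + 1)).reshape(C, R, dv)
        roots[bad] = np.inf  # placeholder roots must never win selection
        cands.append(roots)
    vcand = np.concatenate(cands, axis=-1)
    ub = np.broadcast_to(u[..., None], vcand.shape)
    with np.errstate(all="ignore"):
        rsel = np.maximum(
            np.abs(_eval_many(c1, ub, vcand)), np.abs(_eval_many(c2, ub, vcand))
        )
        rsel /= np.maximum(1.0, np.abs(ub) + np.abs(vcand)) ** 4
        rsel = np.where(np.isfinite(rsel), rsel, np.inf)
    return np.take_along_axis(vcand, rsel.argmin(axis=-1)[..., None], axis=-1)[..., 0]


def _newton_batch(c1, c2, u, v, iters: int):
    d1u = c1[:, 1:, :] * np.arange(1, 5)[None, :, None]
    d1v = c1[:, :, 1:] * np.arange(1, 5)[None, None, :]
    d2u = c2[:, 1:, :] * np.arange(1, 5)[None, :, None]
    d2v = c2[:, :, 1:] * np.arange(1, 5)[None, None, :]
    for _ in range(iters):
        U = u[..., None] ** np.arange(5)
        V = v[..., None] ** np.arange(5)
        f1 = np.einsum("cij,cri,crj->cr", c1, U, V)
        f2 = np.einsum("cij,cri,crj->cr", c2, U, V)
        j11 = np.einsum("cij,cri,crj->cr", d1u, U[..., :4], V)
        j12 = np.einsum("cij,cri,crj->cr", d1v, U, V[..., :4])
        j21 = np.einsum("cij,cri,crj->cr", d2u, U[..., :4], V)
        j22 = np.einsum("cij,cri,crj->cr", d2v, U, V[..., :4])
        det = j11 * j22 - j12 * j21
        det = np.where(det == 0, 1.0, det)
        du = (f1 * j22 - f2 * j12) / det
        dv = (f2 * j11 - f1 * j21) / det
        u = u - du
        v = v - dv
    return u, v


def _polish_and_realify(c1, c2, u, v, iters: int = 10):
    """Complex Newton polish followed by real-arithmetic sharpening.

    True real solutions keep a rounding-level imaginary part after complex
    refinement; re-running Newton from the real part in real arithmetic
    collapses it to exactly zero whenever a real solution is indeed there.
    """
    with np.errstate(all="ignore"):
        u, v = _newton_batch(c1, c2, u, v, iters)
        near = (np.abs(u.imag) < 1e-8 * (1 + np.abs(u))) & (
            np.abs(v.imag) < 1e-8 * (1 + np.abs(v))
        )
        ur, vr = _newton_batch(
            c1, c2, u.real.astype(float), v.real.astype(float), 5
        )
        ok = (
            near
            & (np.abs(ur - u) < 1e-6 * (1 + np.abs(u)))
            & (np.abs(vr - v) < 1e-6 * (1 + np.abs(v)))
        )
        u = np.where(ok, ur.astype(complex), u)
        v = np.where(ok, vr.astype(complex), v)
        res = np.maximum(
            np.abs(_eval_many(c1, u, v)), np.abs(_eval_many(c2, u, v))
        )
    return u, v, res


def _finalise(u, v, res, R_expect, t: ClassifierThresholds):
    """Vectorised genericity checks and stationarity for (C, R) solutions.

    Returns (stat, n_pos, n_finite, suspicious) where ``suspicious`` marks
    points needing a more careful pass.
    """
    finite = (np.abs(u) <= t.t_inf) & (np.abs(v) <= t.t_inf)
    finite &= np.isfinite(u.real) & np.isfinite(v.real)
    suspicious = ~finite.all(axis=1)
    term_scale = np.maximum(1.0, np.abs(u) + np.abs(v)) ** 4
    suspicious |= (np.where(finite, res, 0.0) > _RES_RTOL * term_scale).any(axis=1)
    smallish = (
        np.abs(u) + np.abs(v) < _solver._ORIGIN_CLUSTER_RADIUS
    ) | (np.abs(u) < t.t_zmax) | (np.abs(v) < t.t_zmax)
    ambiguous = (
        (np.abs(u.imag) > t.t_zmin) & (np.abs(u.imag) < t.t_zmax)
    ) | ((np.abs(v.imag) > t.t_zmin) & (np.abs(v.imag) < t.t_zmax))
    suspicious |= (finite & (smallish | ambiguous)).any(axis=1)

    dist = np.abs(u[:, :, None] - u[:, None, :]) + np.abs(
        v[:, :, None] - v[:, None, :]
    )
    sc = 1.0 + np.abs(u) + np.abs(v)
    np.einsum("crr->cr", dist)[...] = np.inf
    with np.errstate(all="ignore"):
        suspicious |= np.nanmin(dist, axis=(1, 2)) < 1e-8 * np.nanmax(sc, axis=1)

    pos = (
        finite
        & (np.abs(u.imag) < t.t_zmin)
        & (np.abs(v.imag) < t.t_zmin)
        & (u.real > t.t_zmax)
        & (v.real > t.t_zmax)
    )
    n_pos = pos.sum(axis=1).astype(np.int8)
    n_fin = finite.sum(axis=1).astype(np.int8)
    suspicious |= n_fin != R_expect
    suspicious |= ~np.isin(n_pos, (1, 3))
    stat = np.where(n_pos == 3, 1, 0).astype(np.int8)
    return stat, n_pos, n_fin, suspicious


def _rescue_rescaled(c1, c2, urootsA, su, dv1, dv2, m0, D, t):
    """Second vectorised pass with variables rescaled by ``su``.

    Root candidates from the rescaled resultant are pooled with those of the
    first pass, every candidate is polished against the original system, and
    the per-point solution list is rebuilt by residual filtering and
    deduplication.  Returns per-point (n_finite, n_pos, ok).
    """
    C = c1.shape[0]
    R = D - m0
    # each rescaled elimination resolves only the solution cluster at its
    # own scale: coefficients representing the other clusters sit at the
    # determinant rounding floor by construction and are truncated away.
    pools = [urootsA]
    for scale in (su, 1.0 / su):
        scl = scale ** np.arange(5)
        c1s, c2s = _normalise(
            c1 * scl[None, :, None] * scl[None, None, :],
            c2 * scl[None, :, None] * scl[None, None, :],
        )
        coeffs = _resultant_batch(c1s, c2s, dv1, dv2)
        urootsB = np.full((C, R), 1e75, dtype=complex)
        cmax = np.abs(coeffs).max(axis=1)
        cmax = np.where(cmax == 0, 1.0, cmax)
        for c in range(C):
            mag = np.abs(coeffs[c])
            if mag[:m0].max(initial=0.0) > 1e-10 * cmax[c]:
                continue
            above = np.nonzero(mag > 1e-12 * cmax[c])[0]
            above = above[(above >= m0) & (above <= D)]
            if above.size == 0 or above.max() <= above.min():
                continue
            red = coeffs[c, above.min() : above.max() + 1]
            roots = _solver._balanced_roots(red) * scale
            urootsB[c, : len(roots)] = roots
        pools.append(urootsB)
    allu = np.concatenate(pools, axis=1)  # (C, 3R)
    allu = np.where(np.isfinite(allu), allu, 1e75)
    v = _best_v(c1, c2, allu, dv1, dv2)
    u, v, res = _polish_and_realify(c1, c2, allu, v, iters=15)

    n_fin = np.zeros(C, dtype=np.int8)
    n_pos = np.zeros(C, dtype=np.int8)
    ok = np.zeros(C, dtype=bool)
    for c in range(C):
        sols = []
        for k in range(u.shape[1]):
            uu, vv, rr = u[c, k], v[c, k], res[c, k]
            if not (np.isfinite(uu.real) and np.isfinite(vv.real)):
                continue
            if abs(uu) > t.t_inf or abs(vv) > t.t_inf:
                continue
            if (
                abs(uu) + abs(vv) < _solver._ORIGIN_CLUSTER_RADIUS
                and abs(uu - allu[c, k]) > 0.25 * abs(allu[c, k])
            ):
                continue  # wandered into the origin cluster: an artifact
            ts = max(1.0, abs(uu) + abs(vv)) ** 4
            if rr > _RES_RTOL * ts:
                continue
            sols.append((complex(uu), complex(vv), float(rr)))
        ded, _merged = _solver._dedup(sols)
        npv = 0
        quest = False
        for uu, vv, rr in ded:
            for x in (uu, vv):
                if t.t_zmin < abs(x.imag) < t.t_zmax:
                    quest = True
            if abs(uu) < t.t_zmax or abs(vv) < t.t_zmax:
                quest = True
            if (
                abs(uu.imag) < t.t_zmin
                and abs(vv.imag) < t.t_zmin
                and uu.real > t.t_zmax
                and vv.real > t.t_zmax
            ):
                npv += 1
        n_fin[c] = len(ded)
        n_pos[c] = npv
        ok[c] = len(ded) == R and npv in (1, 3) and not quest
    return n_fin, n_pos, ok


def _label_chunk(
    theta: np.ndarray,
    sigma: float,
    lam: float,
    zeta: float,
    mode: str,
    t: ClassifierThresholds,
):
    c1r, c2r = system_coefficient_grids(theta, sigma, lam, zeta)
    c1, c2 = _normalise(c1r, c2r)
    dv1, dv2 = (3, 4) if mode == "weak" else (2, 3)
    R = _solver.GENERIC_FINITE_COUNT[mode]
    D = _solver.GENERIC_RESULTANT_DEGREE[mode]
    m0 = _solver.GENERIC_ORIGIN_MULTIPLICITY

    coeffs = _resultant_batch(c1, c2, dv1, dv2)
    uroots, bad = _deflated_uroots(coeffs, m0, D)
    v = _best_v(c1, c2, uroots, dv1, dv2)
    u, v, res = _polish_and_realify(c1, c2, uroots, v)
    stat, n_pos, n_fin, suspicious = _finalise(u, v, res, R, t)
    fallback = bad | suspicious

    # stage B: pooled-candidate rescue with 1/sigma-rescaled variables
    idx = np.nonzero(fallback)[0]
    if idx.size:
        su = 1.0 / max(sigma, lam, 2.0)
        nf, npv, ok = _rescue_rescaled(
            c1[idx], c2[idx], u[idx], su, dv1, dv2, m0, D, t
        )
        resolved = idx[ok]
        stat[resolved] = (npv[ok] == 3).astype(np.int8)
        n_pos[resolved] = npv[ok]
        n_fin[resolved] = nf[ok]
        fallback[resolved] = False
    return stat, n_pos, n_fin, fallback


def label_points(
    points: np.ndarray,
    sigma: float,
    lam: float | None = None,
    zeta: float = 1.0,
    mode: str = "weak",
    thresholds: ClassifierThresholds | None = None,
    max_retries: int = 2,
) -> BatchLabels:
    """Label parameter points monostable / bistable / nongeneric.

    Parameters
    ----------
    points : ndarray
        Linear-scale parameter coordinates, shape (N, 8) in theta-order for
        weak irreversibility or (N, 6) in eta-order for strong.
    sigma, lam, zeta : float
        Conserved totals; ``lam`` defaults to ``sigma`` (equal enzyme totals).
    max_retries : int
        Ignored escalations cap forwarded to the per-point ladder.
    """
    t = thresholds or ClassifierThresholds()
    lam = sigma if lam is None else lam
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2:
        raise ValueError("points must be 2-D")
    if mode == "strong" and pts.shape[1] == 6:
        theta = expand_eta(pts)
    elif pts.shape[1] == 8:
        theta = pts
    else:
        raise ValueError("expected 8 (weak) or 6 (strong) columns")

    N = theta.shape[0]
    stat = np.empty(N, dtype=np.int8)
    n_pos = np.empty(N, dtype=np.int8)
    n_fin = np.empty(N, dtype=np.int8)
    fb_total = 0
    for lo in range(0, N, _CHUNK):
        hi = min(lo + _CHUNK, N)
        s, p, f, fb = _label_chunk(theta[lo:hi], sigma, lam, zeta, mode, t)
        for i in np.nonzero(fb)[0]:
            params = NondimensionalParameters.from_theta(theta[lo + i], mode=mode)
            totals = ConservedTotals(sigma=sigma, lam=lam, zeta=zeta)
            sol = _solver.solve_system(build_system(params, totals), t)
            s[i] = STAT_CODE[sol.stationarity]
            p[i] = sol.n_positive_real
            f[i] = sol.n_finite_nonzero
        fb_total += int(fb.sum())
        stat[lo:hi], n_pos[lo:hi], n_fin[lo:hi] = s, p, f
    return BatchLabels(stat, n_pos, n_fin, fb_total)


def bistability_indicator(
    sigma: float,
    mode: str = "weak",
    zeta: float = 1.0,
    lam: float | None = None,
    thresholds: ClassifierThresholds | None = None,
):
    """Return a callable mapping log10 parameter points -> bistability mask.

    Nongeneric points evaluate as not-bistable (they are rare and excluded
    from estimator numerators elsewhere; an indicator must return a boolean).
    """

    def indicator(log_points: np.ndarray) -> np.ndarray:
        log_points = np.atleast_2d(np.asarray(log_points, dtype=float))
        labels = label_points(
            10.0**log_points, sigma, lam=lam, zeta=zeta, mode=mode,
            thresholds=thresholds,
        )
        return labels.bistable

    return indicator
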