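"""ILR sampling, stationarity labelling, volume estimation and VEGAS.

The bistable region M_sigma of the box H_p = [0.1^p, 10^p]^d is explored by
Monte Carlo.  Independent Logarithmic Random (ILR) sampling draws each
log10-coordinate independently and uniformly from [-p, p]; the normalised
log-volume V_sigma of the bistable region is then estimated by the bistable
fraction of the sample, with central-limit-theorem confidence intervals.

VEGAS adaptive importance sampling enriches a bistable sample: each axis of
the box is divided into M bins whose lengths are iteratively adapted so that
bins covering a denser part of the projected bistable set become shorter (and
thus more frequently sampled), with a smoothing factor K guarding against
empty bins.  The stratified assignment of new points to bins uses one shared
uniform draw per axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._batch import BatchLabels, STAT_CODE, label_points
from .model import SamplingBox
from .solver import ClassifierThresholds, Stationarity

__all__ = [
    "MAIN15",
    "VEGAS12",
    "CONNECT14",
    "FINE6",
    "STRONG_EXTRA",
    "LabelledSample",
    "VolumeEstimate",
    "VegasGrid",
    "make_rng",
    "ilr_sample",
    "label_sample",
    "estimate_volume",
    "vegas_step",
    "vegas_run",
]

#: the 15 substrate-to-enzyme ratios of the main volume scan
MAIN15 = (1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 5.0, 7.0, 10.0, 15.0, 20.0, 50.0,
          100.0, 200.0, 500.0)
#: subset used for VEGAS enrichment (sigma >= 2.5)
VEGAS12 = tuple(s for s in MAIN15 if s >= 2.5)
#: subset used for connectivity analysis (sigma >= 1.5)
CONNECT14 = tuple(s for s in MAIN15 if s >= 1.5)
#: fine grid just above sigma = 1 for the threshold search
FINE6 = (1.0078125, 1.015625, 1.03125, 1.0625, 1.125, 1.25)
#: extra large-sigma values examined under strong irreversibility
STRONG_EXTRA = (1000.0, 2000.0, 5000.0)


def make_rng(seed: int) -> np.random.Generator:
    """The package-wide RNG: counter-based Philox keyed by an explicit seed."""
    return np.random.Generator(np.random.Philox(int(seed)))


def ilr_sample(n: int, box: SamplingBox, seed: int) -> np.ndarray:
    """Draw n points of the box by Independent Logarithmic Random sampling.

    Returns an (n, dim) array of log10 coordinates, each independently
    uniform on [-p, p].  Identical seeds give identical tables.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    lo, hi = box.log_bounds
    return make_rng(seed).uniform(lo, hi, size=(int(n), box.dimension))


@dataclass
class LabelledSample:
    """An ILR (or enriched) sample with per-sigma stationarity labels.

    ``labels[sigma]`` is an int8 array over points: 0 monostable, 1 bistable,
    2 nongeneric.  Nongeneric points are excluded from both numerator and
    denominator of volume estimates and tallied in ``nongeneric_tally``.
    """

    box: SamplingBox
    seed: int
    points: np.ndarray  # (n, dim) log10 coordinates
    labels: dict[float, np.ndarray] = field(default_factory=dict)
    nongeneric_tally: dict[float, int] = field(default_factory=dict)
    zeta: float = 1.0

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def bistable_mask(self, sigma: float) -> np.ndarray:
        return self.labels[sigma] == STAT_CODE[Stationarity.BISTABLE]

    def bistable_points(self, sigma: float) -> np.ndarray:
        return self.points[self.bistable_mask(sigma)]


def label_sample(
    points: np.ndarray,
    sigma_grid,
    box: SamplingBox | None = None,
    seed: int = 0,
    mode: str | None = None,
    zeta: float = 1.0,
    lam_rule: str = "equal_sigma",
    thresholds: ClassifierThresholds | None = None,
) -> LabelledSample:
    """Label every point at every sigma of the grid (zeta = 1, lam = sigma).

    ``points`` are log10 coordinates (n, 8) or (n, 6).  The default totals
    follow the equal-enzyme convention; ``lam_rule='equal_sigma'`` sets
    lam = sigma at every grid value.
    """
    points = np.asarray(points, dtype=float)
    if box is None:
        p = max(1, int(np.ceil(np.abs(points).max() - 1e-9))) if points.size else 1
        box = SamplingBox(exponent_p=p, dimension=points.shape[1])
    if mode is None:
        mode = box.mode
    sample = LabelledSample(box=box, seed=seed, points=points, zeta=zeta)
    linear = 10.0**points
    for sigma in sigma_grid:
        lam = float(sigma) if lam_rule == "equal_sigma" else None
        lab: BatchLabels = label_points(
            linear, float(sigma), lam=lam, zeta=zeta, mode=mode,
            thresholds=thresholds,
        )
        sample.labels[float(sigma)] = lab.stationarity
        sample.nongeneric_tally[float(sigma)] = int(lab.nongeneric.sum())
    return sample


@dataclass(frozen=True)
class VolumeEstimate:
    """Bistable-fraction estimate with a CLT confidence interval."""

    v_hat: float
    n: int
    ci_low: float
    ci_high: float
    sigma: float
    box: SamplingBox
    confidence: float = 0.95
    n_bistable: int = 0
    n_nongeneric: int = 0
    degenerate: bool = False  # zero bistable points: rule-of-three upper bound

    @property
    def percent(self) -> float:
        return 100.0 * self.v_hat


def estimate_volume(
    sample: LabelledSample, sigma: float, confidence: float = 0.95
) -> VolumeEstimate:
    """Estimate the normalised bistable volume at one sigma.

    v_hat is the bistable fraction of the generic points; the confidence
    interval is v_hat +/- z * delta_hat / sqrt(n) with delta_hat the sample
    standard deviation of the indicator.  With zero bistable points the
    upper bound falls back to the rule of three (3/n).
    """
    sigma = float(sigma)
    labels = sample.labels[sigma]
    generic = labels != STAT_CODE[Stationarity.NONGENERIC]
    n = int(generic.sum())
    if n < 2:
        raise ValueError("need at least 2 generic labelled points")
    k = int((labels[generic] == STAT_CODE[Stationarity.BISTABLE]).sum())
    v_hat = k / n
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    if k == 0:
        return VolumeEstimate(
            v_hat=0.0, n=n, ci_low=0.0, ci_high=3.0 / n, sigma=sigma,
            box=sample.box, confidence=confidence, n_bistable=0,
            n_nongeneric=int((~generic).sum()),
            degenerate=True,
        )
    delta_hat = math.sqrt(n / (n - 1) * v_hat * (1.0 - v_hat))
    half = z * delta_hat / math.sqrt(n)
    return VolumeEstimate(
        v_hat=v_hat, n=n, ci_low=max(0.0, v_hat - half),
        ci_high=min(1.0, v_hat + half), sigma=sigma, box=sample.box,
        confidence=confidence, n_bistable=k,
        n_nongeneric=int((~generic).sum()),
    )


@dataclass
class VegasGrid:
    """Per-axis adaptive bin edges over [-1, 1] in log10 coordinates."""

    edges: np.ndarray  # (dim, M+1), strictly increasing from -1 to 1
    smoothing_k: int = 1000
    iteration: int = 0

    @classmethod
    def uniform(cls, dim: int = 8, n_bins: int = 50, smoothing_k: int = 1000):
        edges = np.tile(np.linspace(-1.0, 1.0, n_bins + 1), (dim, 1))
        return cls(edges=edges, smoothing_k=smoothing_k)

    @property
    def n_bins(self) -> int:
        return self.edges.shape[1] - 1

    @property
    def dim(self) -> int:
        return self.edges.shape[0]

    def bin_lengths(self) -> np.ndarray:
        return np.diff(self.edges, axis=1)


def vegas_step(
    bistable_points: np.ndarray,
    grid: VegasGrid,
    n_new: int,
    seed: int,
) -> tuple[np.ndarray, VegasGrid]:
    """One VEGAS iteration: adapt the bins, then draw a stratified sample.

    Per axis: histogram the projection of the current bistable set over the
    current bins; smooth the frequencies f <- ceil(K f / #set) + 1 so that
    no bin is empty; resize bins to lengths proportional to the smoothed
    frequencies; then assign the n_new coordinates to bins by the stratified
    rule i = min{i : i/M >= (r + n)/N} with a single uniform r per axis, and
    draw each coordinate uniformly within its bin.

    Returns (new log10 points (n_new, dim), updated grid).
    """
    pts = np.asarray(bistable_points, dtype=float)
    if pts.size == 0:
        raise ValueError(
            "empty bistable set: bootstrap with ILR sampling before VEGAS"
        )
    if np.abs(pts).max() > 1.0 + 1e-12:
        raise ValueError("VEGAS is defined on the unit box [-1, 1]^dim only")
    rng = make_rng(seed)
    M = grid.n_bins
    dim = grid.dim
    K = grid.smoothing_k
    n_set = pts.shape[0]
    new_edges = np.empty_like(grid.edges)
    out = np.empty((int(n_new), dim))
    for j in range(dim):
        freq, _ = np.histogram(pts[:, j], bins=grid.edges[j])
        freq = np.ceil(K * freq / n_set).astype(np.int64) + 1
        # equal-content resize: each new bin receives 1/M of the smoothed
        # mass, so bins shrink where the projected bistable density is high
        # and the stratified draws concentrate there
        cum = np.concatenate([[0.0], np.cumsum(freq.astype(float))])
        targets = cum[-1] * np.arange(1, M) / M
        inner = np.interp(targets, cum, grid.edges[j])
        new_edges[j] = np.concatenate([[-1.0], inner, [1.0]])
        # stratified bin assignment: one shared uniform r per axis gives a
        # near-equal allocation of the N draws over the M bins; the
        # allocation is then assigned to points in an independent random
        # order per axis, so that a point's bin ranks on different axes are
        # uncorrelated (taking the same point order on every axis would
        # confine the sample to the diagonal of the bin grid)
        r = rng.uniform()
        n_idx = np.arange(1, int(n_new) + 1)
        bins = np.ceil(M * (r + n_idx) / n_new).astype(np.int64)
        bins = np.clip(bins, 1, M) - 1
        bins = bins[rng.permutation(int(n_new))]
        lo = new_edges[j, bins]
        hi = new_edges[j, bins + 1]
        out[:, j] = rng.uniform(lo, hi)
    new_grid = VegasGrid(
        edges=new_edges, smoothing_k=K, iteration=grid.iteration + 1
    )
    return out, new_grid


@dataclass
class VegasResult:
    """Outcome of a VEGAS enrichment run."""

    bistable_points: np.ndarray  # union of initial and newfound, log10
    grid: VegasGrid
    n_sampled: int
    n_new_bistable: int
    enrichment: float  # bistable fraction of VEGAS draws / ILR fraction

    @property
    def n_bistable(self) -> int:
        return self.bistable_points.shape[0]


def vegas_run(
    initial_bistable: np.ndarray,
    n_iterations: int,
    n_per_iteration: int,
    sigma: float,
    seed: int,
    mode: str = "weak",
    ilr_fraction: float | None = None,
    thresholds: ClassifierThresholds | None = None,
) -> VegasResult:
    """Run T VEGAS iterations at fixed sigma, accumulating bistable points.

    Each iteration draws ``n_per_iteration`` points from the adapted grid,
    labels them, and adds the bistable subset to the accumulated set.  The
    enrichment factor compares the bistable fraction of the VEGAS draws with
    the ILR fraction (``ilr_fraction``; if omitted it is approximated by the
    initial set's share of a nominal 10^5-point ILR sample and the
    enrichment is reported relative to that).
    """
    current = np.asarray(initial_bistable, dtype=float)
    if current.size == 0:
        raise ValueError(
            "empty bistable set: bootstrap with ILR sampling before VEGAS"
        )
    dim = current.shape[1]
    grid = VegasGrid.uniform(dim=dim)
    n_sampled = 0
    n_new_bi = 0
    for it in range(int(n_iterations)):
        new_pts, grid = vegas_step(current, grid, n_per_iteration, seed + 7919 * it)
        lab = label_points(
            10.0**new_pts, float(sigma), mode=mode, thresholds=thresholds
        )
        bi = new_pts[lab.bistable]
        n_sampled += new_pts.shape[0]
        n_new_bi += bi.shape[0]
        current = np.vstack([current, bi])
    vegas_fraction = n_new_bi / n_sampled if n_sampled else 0.0
    if ilr_fraction is None or ilr_fraction <= 0:
        enrichment = math.inf if vegas_fraction > 0 else 0.0
    else:
        enrichment = vegas_fraction / ilr_fraction
    return VegasResult(
        bistable_points=current,
        grid=grid,
        n_sampled=n_sampled,
        n_new_bistable=n_new_bi,
        enrichment=enrichment,
    )
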