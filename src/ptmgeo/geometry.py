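"""Shape analysis of the bistable region: connectivity and visibility.

Connectedness of the bistable point cloud is assessed with the
fixed-radius connectivity graph G_Delta: vertices are bistable points (log10
coordinates) and edges join points within Euclidean distance Delta.  Only a
spanning forest is built -- its trees are in bijection with the connected
components of the full graph -- using breadth-first search with an exact
KD-tree fixed-radius query.  A closed-form Delta is available from the
requirement that a random sample point has a neighbour within Delta with
probability ~0.99, using the volume of the d-ball.

Near-convexity is quantified by the K-fold visibility ratio: the fraction
of random pairs of bistable points whose log-space connecting segment is
bistable at all K equally spaced interior points.  It converges to the true
visibility ratio from above as K grows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .model import SamplingBox
from .sampling import make_rng

__all__ = [
    "ConnectivityConfig",
    "ConnectivityGraph",
    "ComponentSummary",
    "VisibilityEstimate",
    "choose_delta",
    "effective_sample_size",
    "build_spanning_forest",
    "summarize_components",
    "refine_components",
    "estimate_visibility",
]


@dataclass(frozen=True)
class ConnectivityConfig:
    """Parameters of the connectivity-graph analysis.

    delta is the adjacency radius in log10 coordinates; coverage is the
    probability used by :func:`choose_delta`; ann_epsilon the approximate
    nearest-neighbour slack of the refinement step; segment_step the
    sub-interval length of segment filling as a fraction of delta.
    """

    delta: float = 0.15
    coverage: float = 0.99
    ann_epsilon: float = 0.001
    segment_step: float = 0.98

    def __post_init__(self) -> None:
        if not self.delta > 0:
            raise ValueError("delta must be positive")
        if not 0 < self.coverage < 1:
            raise ValueError("coverage must be in (0, 1)")


def _ball_volume_coeff(dim: int) -> float:
    """Volume of the unit d-ball: pi^(d/2) / Gamma(d/2 + 1)."""
    return math.pi ** (dim / 2.0) / math.gamma(dim / 2.0 + 1.0)


def choose_delta(
    effective_n: float,
    box: SamplingBox | float = 256.0,
    coverage: float = 0.99,
    dim: int = 8,
) -> float:
    """Closed-form adjacency radius for an ILR sample of given size.

    Delta is chosen so that a sample point has at least one neighbour
    within Delta with the given probability:

        Delta = [ V_H * (1 - (1-coverage)^(1/(N-1))) / c_d ]^(1/d),

    with V_H the box log-volume and c_d the unit d-ball volume
    (pi^4/24 for d = 8).  ``box`` may be a SamplingBox or the log-volume.
    """
    if effective_n < 2:
        raise ValueError("effective sample size must be at least 2")
    if isinstance(box, SamplingBox):
        v_h = box.log_volume
        dim = box.dimension
    else:
        v_h = float(box)
    miss = 1.0 - coverage
    frac = -math.expm1(math.log(miss) / (effective_n - 1.0))  # 1 - miss^(1/(N-1))
    return (v_h * frac / _ball_volume_coeff(dim)) ** (1.0 / dim)


def effective_sample_size(
    n_bistable_augmented: int, n_bistable_initial: int, n_initial: int
) -> float:
    """ILR-equivalent size of an enriched sample.

    The augmented sample is treated as if it came from an ILR sample whose
    size scaled proportionally with the growth of the bistable count:
    N' = (augmented bistable / initial bistable) * initial sample size.
    """
    if n_bistable_initial <= 0:
        raise ValueError("initial bistable count must be positive")
    if n_bistable_augmented <= 0 or n_initial <= 0:
        raise ValueError("counts must be positive")
    return n_bistable_augmented / n_bistable_initial * n_initial


@dataclass
class ConnectivityGraph:
    """Spanning forest over bistable points with component labels."""

    points: np.ndarray  # (n, dim) log10 coordinates
    edges: np.ndarray  # (m, 2) vertex indices, acyclic
    component: np.ndarray  # (n,) component label per vertex
    delta: float

    @property
    def n_vertices(self) -> int:
        return self.points.shape[0]

    @property
    def n_components(self) -> int:
        return int(self.component.max()) + 1 if self.component.size else 0

    def component_sizes(self) -> np.ndarray:
        return np.bincount(self.component) if self.component.size else np.array([], int)

    def largest_component_label(self) -> int:
        return int(np.argmax(self.component_sizes()))


def build_spanning_forest(points: np.ndarray, delta: float) -> ConnectivityGraph:
    """Spanning forest of the Delta-adjacency graph by breadth-first search.

    Neighbour queries use an exact KD-tree fixed-radius search, so the
    component partition equals that of the full Delta-graph; the particular
    forest edges depend on traversal order and are not unique.
    """
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    component = np.full(n, -1, dtype=np.int64)
    edges: list[tuple[int, int]] = []
    if n == 0:
        return ConnectivityGraph(pts, np.empty((0, 2), int), component, delta)
    tree = cKDTree(pts)
    label = 0
    from collections import deque

    visited = np.zeros(n, dtype=bool)
    for start in range(n):
        if visited[start]:
            continue
        queue = deque([start])
        visited[start] = True
        while queue:
            j = queue.popleft()
            component[j] = label
            for k in tree.query_ball_point(pts[j], delta):
                if not visited[k]:
                    visited[k] = True
                    edges.append((j, k))
                    queue.append(k)
        label += 1
    edge_arr = np.array(edges, dtype=np.int64) if edges else np.empty((0, 2), int)
    return ConnectivityGraph(pts, edge_arr, component, delta)


@dataclass(frozen=True)
class ComponentSummary:
    """Component statistics of a connectivity graph."""

    n_points: int
    n_components: int
    largest: int
    second_largest: int
    n_singletons: int

    @property
    def largest_share(self) -> float:
        """Largest-component share of the vertices, in percent."""
        return 100.0 * self.largest / self.n_points if self.n_points else 0.0


def summarize_components(graph: ConnectivityGraph) -> ComponentSummary:
    sizes = np.sort(graph.component_sizes())[::-1]
    if sizes.size == 0:
        return ComponentSummary(0, 0, 0, 0, 0)
    return ComponentSummary(
        n_points=graph.n_vertices,
        n_components=int(sizes.size),
        largest=int(sizes[0]),
        second_largest=int(sizes[1]) if sizes.size > 1 else 0,
        n_singletons=int((sizes == 1).sum()),
    )


def _refinement_k(iteration: int, second_largest: int) -> int:
    """The K-update rule for the number of nearest neighbours per iteration."""
    j = iteration
    if second_largest > 10:
        return j + 1
    if second_largest > 3:
        return 3 * (j + 1)
    return 10 * (j + 1)


@dataclass
class RefinementResult:
    graph: ConnectivityGraph
    new_points: np.ndarray
    iterations: int
    shares: list[float]  # largest-component share per iteration (percent)


def refine_components(
    graph: ConnectivityGraph,
    indicator,
    config: ConnectivityConfig | None = None,
    seed: int = 0,
    max_iterations: int = 8,
) -> RefinementResult:
    """Try to connect non-largest components to the largest one.

    For every non-largest component a random vertex is chosen; its K
    approximate nearest neighbours in the largest component are found
    (KD-tree query with the configured epsilon slack); each connecting
    segment is subdivided into sub-intervals of length segment_step * delta
    and the interior endpoints tested with ``indicator`` (a callable mapping
    log10 points to a boolean bistability mask).  Newfound bistable points
    are added, the forest rebuilt, and the process iterated -- with K grown
    by the update rule -- until the largest-component share stabilises or a
    single component remains.
    """
    cfg = config or ConnectivityConfig(delta=graph.delta)
    rng = make_rng(seed)
    new_points = np.empty((0, graph.points.shape[1]))
    shares = [summarize_components(graph).largest_share]
    it = 0
    while it < max_iterations and graph.n_components > 1:
        summary = summarize_components(graph)
        k_nn = _refinement_k(it, summary.second_largest)
        big = graph.largest_component_label()
        big_pts = graph.points[graph.component == big]
        tree = cKDTree(big_pts)
        segment_pts = []
        for comp in range(graph.n_components):
            if comp == big:
                continue
            members = np.nonzero(graph.component == comp)[0]
            theta = graph.points[members[rng.integers(members.size)]]
            k_eff = min(k_nn, big_pts.shape[0])
            _, idx = tree.query(theta, k=k_eff, eps=cfg.ann_epsilon)
            idx = np.atleast_1d(idx)
            for nb in big_pts[idx]:
                d = np.linalg.norm(nb - theta)
                if d == 0:
                    continue
                step = cfg.segment_step * cfg.delta
                n_sub = max(int(math.ceil(d / step)), 1)
                # interior endpoints of the sub-intervals
                for s in range(1, n_sub):
                    segment_pts.append(theta + (s * step / d) * (nb - theta))
        if not segment_pts:
            break
        cand = np.array(segment_pts)
        mask = np.asarray(indicator(cand), dtype=bool)
        found = cand[mask]
        if found.size:
            new_points = np.vstack([new_points, found])
        merged = np.vstack([graph.points, found]) if found.size else graph.points
        graph = build_spanning_forest(merged, cfg.delta)
        it += 1
        share = summarize_components(graph).largest_share
        shares.append(share)
        if found.size == 0 or (
            len(shares) >= 2 and abs(shares[-1] - shares[-2]) < 1e-9
        ):
            break
    return RefinementResult(
        graph=graph, new_points=new_points, iterations=it, shares=shares
    )


@dataclass(frozen=True)
class VisibilityEstimate:
    """K-fold visibility ratio with a finite-population confidence interval."""

    ratio: float
    k_subdivisions: int
    n_pairs: int
    population: int  # size of the pair population (#bistable)^2
    ci_low: float
    ci_high: float
    confidence: float = 0.95


def estimate_visibility(
    bistable_points: np.ndarray,
    indicator,
    n_pairs: int,
    k_subdivisions: int = 10,
    seed: int = 0,
    confidence: float = 0.95,
) -> VisibilityEstimate:
    """Estimate the K-fold visibility ratio from random pairs.

    Draws ``n_pairs`` pairs of distinct bistable points without replacement
    from the pair population, tests bistability at the K equally spaced
    interior points t = j/(K+1) of each log-space segment, and reports the
    fraction of pairs with all interior points bistable.  The confidence
    interval carries the finite-population correction sqrt(1 - M/N) with
    N the pair-population size (#bistable)^2; the correction is negligible
    when M << N.
    """
    pts = np.asarray(bistable_points, dtype=float)
    n = pts.shape[0]
    if n < 2:
        raise ValueError("need at least 2 bistable points")
    population = n * n
    if n_pairs > n * (n - 1) // 2:
        raise ValueError("more pairs requested than distinct pairs available")
    rng = make_rng(seed)
    chosen: set[tuple[int, int]] = set()
    while len(chosen) < n_pairs:
        i, j = rng.integers(n), rng.integers(n)
        if i == j:
            continue
        chosen.add((min(i, j), max(i, j)))
    pairs = np.array(sorted(chosen))
    K = int(k_subdivisions)
    t = (np.arange(1, K + 1) / (K + 1.0))[None, :, None]  # (1, K, 1)
    a = pts[pairs[:, 0]][:, None, :]
    b = pts[pairs[:, 1]][:, None, :]
    interior = a + t * (b - a)  # (M, K, dim)
    mask = np.asarray(
        indicator(interior.reshape(-1, pts.shape[1])), dtype=bool
    ).reshape(n_pairs, K)
    ok = mask.all(axis=1)
    ratio = float(ok.mean())
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    if n_pairs > 1:
        delta_hat = ok.std(ddof=1)
    else:
        delta_hat = 0.0
    fpc = math.sqrt(max(0.0, 1.0 - n_pairs / population))
    half = z * delta_hat / math.sqrt(n_pairs) * fpc
    return VisibilityEstimate(
        ratio=ratio,
        k_subdivisions=K,
        n_pairs=int(n_pairs),
        population=population,
        ci_low=max(0.0, ratio - half),
        ci_high=min(1.0, ratio + half),
        confidence=confidence,
    )
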