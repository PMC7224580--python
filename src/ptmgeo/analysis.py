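"""Cross-sigma analyses: bistability threshold, blinking, rebinding tradeoff.

Blinking: a parameter point that is bistable at some sigma but monostable at
a larger sigma on the same grid.  Blinking shows that the bistable region
does not grow monotonically with substrate, even though its estimated
volume does; blinking points are expected to live near the region's
boundary, i.e. outside the largest connected component of the
sigma-specific connectivity graph.

Rebinding tradeoff: under weak irreversibility, bistability is empirically
confined to eps2 * phi0 < K(sigma) -- high product rebinding on both
enzymes abrogates bistability.  K_hat is estimated as the sample maximum of
theta5 * theta6 over bistable points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._batch import STAT_CODE, label_points
from .model import SamplingBox
from .sampling import LabelledSample, ilr_sample, label_sample
from .solver import Stationarity

__all__ = [
    "threshold_scan",
    "blinking_summary",
    "BlinkingSummary",
    "tradeoff_bound",
    "TradeoffBound",
]

_BI = STAT_CODE[Stationarity.BISTABLE]
_MONO = STAT_CODE[Stationarity.MONOSTABLE]
_NG = STAT_CODE[Stationarity.NONGENERIC]


@dataclass(frozen=True)
class ThresholdScan:
    """Per-sigma bistable counts on a common ILR sample."""

    counts: pd.DataFrame  # columns: sigma, n_bistable, n_nongeneric
    n_points: int
    smallest_bistable_sigma: float | None  # least sigma with a bistable hit


def threshold_scan(
    box: SamplingBox,
    n: int,
    sigma_values,
    seed: int,
    mode: str | None = None,
) -> ThresholdScan:
    """Count bistable points per sigma on one common ILR sample.

    Reports the least sigma (of the sorted input values) at which at least
    one bistable point is found -- evidence about the bistability threshold
    sigma*.
    """
    sigma_values = sorted(float(s) for s in sigma_values)
    points = ilr_sample(n, box, seed)
    sample = label_sample(points, sigma_values, box=box, seed=seed, mode=mode)
    rows = []
    smallest = None
    for s in sigma_values:
        k = int(sample.bistable_mask(s).sum())
        rows.append(
            {"sigma": s, "n_bistable": k,
             "n_nongeneric": sample.nongeneric_tally[s]}
        )
        if k > 0 and smallest is None:
            smallest = s
    return ThresholdScan(
        counts=pd.DataFrame(rows), n_points=n, smallest_bistable_sigma=smallest
    )


@dataclass(frozen=True)
class BlinkingSummary:
    """Per-sigma blinking statistics.

    Per sigma: the bistable count, the number of blinking points (BP,
    bistable here but monostable at some larger grid sigma), the number of
    those outside the sigma-specific largest component (BPSC), the number
    never entering the largest component at any larger sigma where they are
    bistable (BPNL), and the number monostable at the largest grid sigma
    ("asymptotically monostable", BPAM).
    """

    table: pd.DataFrame  # columns: sigma, n_bistable, bp, bpsc, bpnl, bpam
    blinking_indices: dict[float, np.ndarray] = field(default_factory=dict)
    n_disqualified: int = 0  # points with a nongeneric entry in their profile


def blinking_summary(
    sample: LabelledSample,
    largest_component_members: dict[float, np.ndarray] | None = None,
) -> BlinkingSummary:
    """Detect blinking points on a common sample labelled across a grid.

    ``sample`` must carry labels for every grid sigma.
    ``largest_component_members`` optionally maps sigma to the array of
    point indices (into the sample) belonging to the largest connected
    component of the sigma-specific connectivity graph; when given, the
    BPSC/BPNL columns are filled, otherwise they are NaN.

    Points with a nongeneric label anywhere in their profile are
    disqualified from the statistics (and counted).
    """
    sigmas = sorted(sample.labels.keys())
    if not sigmas:
        raise ValueError("sample carries no labels")
    lab = np.stack([sample.labels[s] for s in sigmas])  # (S, n)
    disq = (lab == _NG).any(axis=0)
    sigma_max = sigmas[-1]
    rows = []
    blink_idx: dict[float, np.ndarray] = {}
    for si, s in enumerate(sigmas):
        bi_here = (lab[si] == _BI) & ~disq
        later = lab[si + 1 :]
        blinking = bi_here & (later == _MONO).any(axis=0) if later.size else (
            np.zeros_like(bi_here)
        )
        idx = np.nonzero(blinking)[0]
        blink_idx[s] = idx
        row = {
            "sigma": s,
            "n_bistable": int(bi_here.sum()),
            "bp": int(idx.size),
            "bpsc": np.nan,
            "bpnl": np.nan,
            "bpam": int((blinking & (lab[-1] == _MONO)).sum()),
        }
        if largest_component_members is not None:
            members = largest_component_members.get(s)
            in_large = np.zeros(lab.shape[1], dtype=bool)
            if members is not None and len(members):
                in_large[np.asarray(members, int)] = True
            row["bpsc"] = int((blinking & ~in_large).sum())
            # never in the largest component at any larger sigma
            never = blinking.copy()
            for sj in range(si + 1, len(sigmas)):
                mem_j = largest_component_members.get(sigmas[sj])
                if mem_j is None or not len(mem_j):
                    continue
                in_large_j = np.zeros(lab.shape[1], dtype=bool)
                in_large_j[np.asarray(mem_j, int)] = True
                never &= ~in_large_j
            row["bpnl"] = int(never.sum())
        rows.append(row)
    return BlinkingSummary(
        table=pd.DataFrame(rows),
        blinking_indices=blink_idx,
        n_disqualified=int(disq.sum()),
    )


@dataclass(frozen=True)
class TradeoffBound:
    """Empirical rebinding-bistability bound at one sigma."""

    sigma: float
    k_hat: float  # max of eps2 * phi0 over bistable points
    n_bistable: int
    products: np.ndarray  # eps2 * phi0 over bistable points (linear scale)

    def count_above(self, c: float) -> int:
        """Number of bistable points with eps2 * phi0 > c."""
        return int((self.products > c).sum())


def tradeoff_bound(sample: LabelledSample, sigma: float) -> TradeoffBound:
    """K_hat(sigma) = max over bistable points of theta5 * theta6.

    Defined for weak irreversibility only: under strong irreversibility the
    product eps2 * phi0 is identically zero.
    """
    if sample.box.mode != "weak":
        raise ValueError(
            "the rebinding tradeoff is defined for weak irreversibility only"
        )
    sigma = float(sigma)
    bi = sample.bistable_points(sigma)
    prods = 10.0 ** bi[:, 4] * 10.0 ** bi[:, 5] if bi.size else np.array([])
    k_hat = float(prods.max()) if prods.size else 0.0
    return TradeoffBound(
        sigma=sigma, k_hat=k_hat, n_bistable=int(bi.shape[0]), products=prods
    )
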