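"""Reference parameter points with known stationarity behaviour.

Four 8-parameter points (theta-order: alpha, beta, eps0, eps1, eps2, phi0,
phi1, phi2) illustrate, at zeta = 1 and lam = sigma, the four qualitative
behaviours across sigma in {3, 4, 5, 7, 10}:

* point 1 -- monostable at all five sigma values;
* point 2 -- becomes bistable between sigma = 4 and 5 and stays bistable;
* point 3 -- bistable only at sigma = 5 (reverts to monostability);
* point 4 -- bistable at sigma = 4, monostable at 5 and 7, bistable again
  at 10 (a "blinking" trajectory).
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from .model import ConservedTotals, NondimensionalParameters, build_system
from .solver import ClassifierThresholds, Stationarity, solve_system

__all__ = [
    "THETA_FIXTURES",
    "FIXTURE_SIGMAS",
    "EXPECTED_STATIONARITY",
    "fixture_parameters",
    "fixture_table_path",
    "stationarity_matrix",
]

THETA_FIXTURES: dict[int, tuple[float, ...]] = {
    1: (7.239380624, 0.1047069812, 0.1045129736, 1.114909161,
        2.017259480, 0.1057288524, 2.544613812, 0.1021803160),
    2: (4.684802750, 0.5200773771, 1.589343505, 0.1804775460,
        0.1270218587, 0.1129848293, 0.1816907000, 5.708851611),
    3: (6.865206499, 0.2105440222, 0.2524064999, 0.1025041753,
        0.1178107732, 0.1017610135, 0.4495453146, 5.796119139),
    4: (4.885859541, 0.4985163876, 0.7212641184, 2.119877596,
        0.1655484166, 0.1246565927, 0.7180476375, 8.912153306),
}

FIXTURE_SIGMAS: tuple[float, ...] = (3.0, 4.0, 5.0, 7.0, 10.0)

_M = Stationarity.MONOSTABLE
_B = Stationarity.BISTABLE
#: expected stationarity of each fixture point at each sigma of FIXTURE_SIGMAS
EXPECTED_STATIONARITY: dict[int, tuple[Stationarity, ...]] = {
    1: (_M, _M, _M, _M, _M),
    2: (_M, _M, _B, _B, _B),
    3: (_M, _M, _B, _M, _M),
    4: (_M, _B, _M, _M, _B),
}


def fixture_parameters(k: int) -> NondimensionalParameters:
    return NondimensionalParameters.from_theta(THETA_FIXTURES[k])


def fixture_table_path():
    """Path to the shipped tab-delimited fixture table."""
    return resources.files("ptmgeo") / "data" / "theta_fixtures.tsv"


def stationarity_matrix(
    thresholds: ClassifierThresholds | None = None,
) -> dict[int, tuple[Stationarity, ...]]:
    """Solve all four fixtures across FIXTURE_SIGMAS and return the labels."""
    out: dict[int, tuple[Stationarity, ...]] = {}
    for k in sorted(THETA_FIXTURES):
        params = fixture_parameters(k)
        row = []
        for sigma in FIXTURE_SIGMAS:
            system = build_system(params, ConservedTotals.equal_enzymes(sigma))
            row.append(solve_system(system, thresholds).stationarity)
        out[k] = tuple(row)
    return out


def load_fixture_table() -> np.ndarray:
    """The four fixture points as a (4, 8) array, read from the data file."""
    import pandas as pd

    with resources.as_file(fixture_table_path()) as path:
        df = pd.read_csv(path, sep="\t")
    return df[[f"theta{i}" for i in range(1, 9)]].to_numpy()
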