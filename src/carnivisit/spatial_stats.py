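"""Global spatial autocorrelation of per-cell counts (Moran's I).

Weights are binary queen contiguity on the 0.01-degree lattice (edge- or
corner-adjacent cells are neighbours), row-standardized. The test uses
the randomisation-assumption variance and a one-sided (greater)
alternative, reported as the familiar standard deviate
(I - E[I]) / sqrt(Var[I]).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
from scipy import stats

from .landscape import GridCell


class DegenerateWeightsError(ValueError):
    """Every unit is an isolate; no contiguity structure exists."""


@dataclass
class SpatialWeights:
    matrix: np.ndarray          # row-standardized, n x n
    binary: np.ndarray          # symmetric 0/1 adjacency
    isolates: List[int]         # indices with no neighbours
    spec: str = "queen contiguity, row-standardized"


def build_queen_weights(cells: Sequence[GridCell]) -> SpatialWeights:
    """Queen-contiguity weights for lattice cells, row-standardized.

    Cells are neighbours iff their (col, row) lattice indices differ by at
    most 1 in each axis. Isolates are allowed but flagged.
    """
    n = len(cells)
    if n < 2:
        raise ValueError("need at least two cells")
    idx = np.array([(c.col_index, c.row_index) for c in cells])
    binary = np.zeros((n, n))
    for a in range(n):
        d = np.abs(idx - idx[a]).max(axis=1)
        nb = (d == 1)
        binary[a, nb] = 1.0
    rowsum = binary.sum(axis=1)
    isolates = [int(i) for i in np.flatnonzero(rowsum == 0)]
    if len(isolates) == n:
        raise DegenerateWeightsError("all cells are isolates")
    w = binary / np.where(rowsum[:, None] > 0, rowsum[:, None], 1.0)
    return SpatialWeights(matrix=w, binary=binary, isolates=isolates)


@dataclass
class MoranResult:
    I: float
    expected_I: float
    variance_I: float
    standard_deviate: float
    p_one_sided: float
    n: int
    weight_spec: str


def moran_test(values: Sequence[float], weights: SpatialWeights) -> MoranResult:
    """Moran's I with randomisation variance and one-sided (greater) p.

    I = (n / S0) * (z' W z) / (z' z) with z the mean-centred values. The
    variance follows the Cliff & Ord randomisation formula, which involves
    the sample kurtosis b2 = n * sum(z^4) / (sum(z^2))^2.
    """
    x = np.asarray(values, dtype=float)
    w = weights.matrix
    n = x.size
    if n != w.shape[0]:
        raise ValueError("values length does not match weights")
    z = x - x.mean()
    z2 = float(np.sum(z ** 2))
    if z2 == 0:
        raise ValueError("values are constant; Moran's I undefined")
    s0 = float(w.sum())
    I = (n / s0) * float(z @ w @ z) / z2

    e_i = -1.0 / (n - 1)
    s1 = 0.5 * float(np.sum((w + w.T) ** 2))
    s2 = float(np.sum((w.sum(axis=1) + w.sum(axis=0)) ** 2))
    b2 = n * float(np.sum(z ** 4)) / z2 ** 2
    num = (n * ((n * n - 3 * n + 3) * s1 - n * s2 + 3 * s0 * s0)
           - b2 * ((n * n - n) * s1 - 2 * n * s2 + 6 * s0 * s0))
    den = (n - 1) * (n - 2) * (n - 3) * s0 * s0
    var_i = num / den - e_i ** 2
    # extreme kurtosis at tiny n can push the randomisation variance
    # non-positive numerically; the deviate is then undefined
    sd = (I - e_i) / np.sqrt(var_i) if var_i > 0 else float("nan")
    p = float(stats.norm.sf(sd))
    return MoranResult(I=float(I), expected_I=e_i, variance_I=float(var_i),
                       standard_deviate=float(sd), p_one_sided=p, n=n,
                       weight_spec=weights.spec)
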