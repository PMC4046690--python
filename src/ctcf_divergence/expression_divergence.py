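"""Expression divergence between the two genes of a pair.

Two complementary dissimilarities across the tissue panel:

* ``ExpD_1-r`` = 1 - Pearson correlation of the two signal vectors — the
  dissimilarity in expression *profile* (shape across tissues), in [0, 2];
* ``ExpD_Euc`` = Euclidean distance of the two signal vectors — the summed
  difference in expression *level*.

The two deliberately dissociate: scaling one vector leaves ExpD_1-r at 0 but
moves ExpD_Euc.  By default the raw deposited signals are used; a log2(x+1)
transform is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .genome_io import ExpressionMatrix

__all__ = ["ExpressionDivergence", "expd_1r", "expd_euc", "pair_divergence",
           "ConstantVectorError"]

TRANSFORMS = ("identity", "log2p1")


class ConstantVectorError(ValueError):
    """Pearson correlation is undefined for a constant signal vector."""


@dataclass(frozen=True)
class ExpressionDivergence:
    expd_1r: float  # NaN when either vector is constant
    expd_euc: float
    n_tissues: int


def expd_1r(x: np.ndarray, y: np.ndarray) -> float:
    """1 - Pearson correlation of the two expression-signal vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("expd_1r needs two equal-length vectors of >=3 tissues")
    xd = x - x.mean()
    yd = y - y.mean()
    denom = math.sqrt((xd @ xd) * (yd @ yd))
    if denom == 0:
        raise ConstantVectorError("constant expression vector")
    return 1.0 - float(xd @ yd) / denom


def expd_euc(x: np.ndarray, y: np.ndarray) -> float:
    """Euclidean distance of the two expression-signal vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("expd_euc needs two equal-length vectors")
    return float(np.sqrt(((x - y) ** 2).sum()))


def pair_divergence(left_id: str, right_id: str, matrix: ExpressionMatrix,
                    transform: str = "identity") -> ExpressionDivergence:
    """Both divergence scores for one pair, after the chosen signal transform.

    A constant vector (Pearson undefined) yields ``expd_1r = NaN`` so the pair
    is dropped listwise from profile-divergence analyses only.
    """
    if transform not in TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}")
    for gid in (left_id, right_id):
        if gid not in matrix:
            raise KeyError(f"gene {gid} missing from expression matrix")
    x = matrix.vector(left_id)
    y = matrix.vector(right_id)
    if transform == "log2p1":
        x = np.log2(x + 1.0)
        y = np.log2(y + 1.0)
    try:
        profile = expd_1r(x, y)
    except ConstantVectorError:
        profile = math.nan
    return ExpressionDivergence(profile, expd_euc(x, y), len(x))
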