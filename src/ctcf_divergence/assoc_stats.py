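"""Rank correlation and partial rank correlation.

Spearman's rho is the Pearson correlation of average (fractional) ranks; its
two-sided p-value comes from t = rho * sqrt((n-2) / (1-rho^2)) on n-2 degrees
of freedom.  The partial Spearman rho_p between x and y given k controls
rank-transforms every variable, regresses the ranks of x and of y on the
control ranks (with intercept), and is the Pearson correlation of the two
residual vectors; its p-value uses t = rho_p * sqrt((n-2-k) / (1-rho_p^2)) on
n-2-k degrees of freedom.  With zero controls the partial estimator reduces
exactly to plain Spearman.

``run_table`` drives a whole correlation table: every requested x/y
combination, controlling for the remaining x variables, optionally within
strata (relation or orientation), with listwise deletion per analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["AssocResult", "spearman", "partial_spearman", "run_table",
           "permutation_envelope"]


@dataclass(frozen=True)
class AssocResult:
    x_name: str
    y_name: str
    controls: tuple[str, ...]
    rho: float
    rho_partial: float
    p_rho: float
    p_partial: float
    n: int
    stratum: str = "all"
    flag: str = ""


def _rank(v: np.ndarray) -> np.ndarray:
    return sps.rankdata(v, method="average")


def _check(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.ndim != 1:
        raise ValueError(f"{name} must be 1-D")
    if not np.isfinite(v).all():
        raise ValueError(f"{name} contains non-finite values")
    if np.all(v == v[0]):
        raise ValueError(f"{name} is constant; rank correlation undefined")
    return v


def _t_pvalue(rho: float, df: int) -> float:
    if df <= 0:
        return math.nan
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt(df / (1.0 - rho * rho))
    return float(2.0 * sps.t.sf(abs(t), df))


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """(rho, two-sided p) for Spearman's rank correlation."""
    x = _check(np.asarray(x, dtype=float), "x")
    y = _check(np.asarray(y, dtype=float), "y")
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("spearman needs two equal-length vectors, n >= 3")
    rx, ry = _rank(x), _rank(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    return rho, _t_pvalue(rho, len(x) - 2)


def partial_spearman(x: Sequence[float], y: Sequence[float],
                     controls: Sequence[Sequence[float]] = (),
                     control_names: Sequence[str] | None = None,
                     ) -> tuple[float, float]:
    """(rho_p, two-sided p) for partial Spearman given the control vectors."""
    x = _check(np.asarray(x, dtype=float), "x")
    y = _check(np.asarray(y, dtype=float), "y")
    k = len(controls)
    if k == 0:
        return spearman(x, y)
    n = len(x)
    if len(y) != n or any(len(c) != n for c in controls):
        raise ValueError("all vectors must share one length")
    if n < k + 3:
        raise ValueError(f"partial correlation needs n >= k+3 (n={n}, k={k})")
    names = list(control_names) if control_names else [f"c{i}" for i in range(k)]
    rx, ry = _rank(x), _rank(y)
    z = np.column_stack([np.ones(n)] +
                        [_rank(_check(np.asarray(c, dtype=float), names[i]))
                         for i, c in enumerate(controls)])
    if np.linalg.matrix_rank(z) < z.shape[1]:
        raise ValueError(f"singular control matrix (collinear controls: {names})")
    beta_x, *_ = np.linalg.lstsq(z, rx, rcond=None)
    beta_y, *_ = np.linalg.lstsq(z, ry, rcond=None)
    ex = rx - z @ beta_x
    ey = ry - z @ beta_y
    denom = math.sqrt(float(ex @ ex) * float(ey @ ey))
    if denom == 0:
        raise ValueError("residuals constant after controlling; rho_p undefined")
    rho_p = float(ex @ ey) / denom
    return rho_p, _t_pvalue(rho_p, n - 2 - k)


def permutation_envelope(x: Sequence[float], y: Sequence[float],
                         controls: Sequence[Sequence[float]],
                         n_perm: int = 200, q: float = 0.95,
                         rng: np.random.Generator | None = None) -> float:
    """q-quantile of |rho_p| under permutations of y (null envelope).

    Permuting y breaks its association with x and the controls jointly, which
    is the appropriate reference for 'no association of y with anything'.
    Vectorised over permutations via the shared residual-maker of the fixed
    design.
    """
    rng = rng if rng is not None else np.random.default_rng()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    rx = _rank(x)
    ry = _rank(y)
    z = np.column_stack([np.ones(n)] + [_rank(np.asarray(c, float)) for c in controls])
    # residual maker for the fixed design
    q_mat, _ = np.linalg.qr(z)
    def resid(m: np.ndarray) -> np.ndarray:
        return m - q_mat @ (q_mat.T @ m)
    ex = resid(rx)
    ex /= np.linalg.norm(ex)
    perms = np.stack([rng.permutation(ry) for _ in range(n_perm)], axis=1)
    ey = resid(perms)
    ey /= np.linalg.norm(ey, axis=0, keepdims=True)
    rhos = np.abs(ex @ ey)
    return float(np.quantile(rhos, q))


def run_table(features: pd.DataFrame, y_vars: Sequence[str],
              x_vars: Sequence[str], stratify_by: str | None = None,
              min_n: int = 10) -> pd.DataFrame:
    """One correlation table: every (stratum, x, y) cell.

    Each x is paired with each y; rho_p controls for the other x variables.
    Rows with any missing value among {x, y, controls} are dropped listwise
    per analysis.  Strata with fewer than ``min_n`` complete rows are flagged
    ``insufficient_n`` (statistics NaN).
    """
    if stratify_by is None:
        strata = [("all", features)]
    else:
        strata = [(str(value), group)
                  for value, group in features.groupby(stratify_by, sort=True)]
    results: list[AssocResult] = []
    for stratum, group in strata:
        for y_name in y_vars:
            for x_name in x_vars:
                controls = [c for c in x_vars if c != x_name]
                cols = [x_name, y_name, *controls]
                sub = group[cols].dropna()
                n = len(sub)
                if n < max(min_n, len(controls) + 3):
                    results.append(AssocResult(
                        x_name, y_name, tuple(controls),
                        math.nan, math.nan, math.nan, math.nan, n,
                        stratum, "insufficient_n"))
                    continue
                rho, p_rho = spearman(sub[x_name], sub[y_name])
                rho_p, p_p = partial_spearman(
                    sub[x_name], sub[y_name],
                    [sub[c] for c in controls], control_names=controls)
                results.append(AssocResult(
                    x_name, y_name, tuple(controls),
                    rho, rho_p, p_rho, p_p, n, stratum))
    return pd.DataFrame([{
        "stratum": r.stratum, "x": r.x_name, "y": r.y_name,
        "controls": ",".join(r.controls), "n": r.n,
        "rho": r.rho, "p_rho": r.p_rho,
        "rho_partial": r.rho_partial, "p_partial": r.p_partial,
        "flag": r.flag,
    } for r in results])
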