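"""Indicator weighting: AHP eigenvector weights, entropy weights, fusion.

Three weight families are produced:

* subjective weights from a pairwise-comparison (judgment) matrix via the
  principal eigenvector, with Saaty's consistency ratio test (CR < 0.1);
* objective entropy weights, where an indicator's weight is proportional to
  one minus the Shannon entropy of its value distribution over grid cells;
* a combined weight, the normalized geometric mean of the two
  (minimum-relative-information-entropy fusion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .index import standardize
from .layers import IndicatorStack

__all__ = [
    "JudgmentMatrix",
    "WeightSet",
    "ConsistencyReport",
    "ahp_weights",
    "entropy_weights",
    "entropy_weights_from_matrix",
    "combine_weights",
    "read_weight_csv",
    "write_weight_csv",
    "read_judgment_csv",
    "SAATY_RI",
]

#: Saaty's random consistency index RI(n), n = 1..15.
SAATY_RI = {
    1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24, 7: 1.32, 8: 1.41,
    9: 1.45, 10: 1.49, 11: 1.51, 12: 1.48, 13: 1.56, 14: 1.57, 15: 1.59,
}

_SUM_TOL = 1e-9
_RECIP_TOL = 1e-9


@dataclass
class JudgmentMatrix:
    """A positive reciprocal pairwise-comparison matrix."""

    entries: np.ndarray
    codes: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.entries, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("judgment matrix must be square")
        n = a.shape[0]
        if not 2 <= n <= 15:
            raise ValueError(f"judgment matrix order must be in 2..15, got {n}")
        if np.any(a <= 0):
            raise ValueError("judgment matrix entries must be positive")
        if not np.allclose(np.diag(a), 1.0, atol=_RECIP_TOL):
            raise ValueError("judgment matrix diagonal must be 1")
        if not np.allclose(a * a.T, 1.0, atol=1e-6):
            raise ValueError("judgment matrix is not reciprocal (a_ij != 1/a_ji)")
        self.entries = a
        if self.codes is not None and len(self.codes) != n:
            raise ValueError("codes length must equal matrix order")

    @property
    def n(self) -> int:
        return self.entries.shape[0]


@dataclass
class ConsistencyReport:
    lambda_max: float
    CI: float
    CR: float
    passes: bool
    n: int


@dataclass
class WeightSet:
    """A normalized, nonnegative weight per indicator code."""

    kind: str  # {"ahp", "eem", "combined"}
    weights: dict[str, float]
    epoch: str | None = None
    note: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        vals = np.array(list(self.weights.values()), dtype=float)
        if np.any(vals < -_SUM_TOL):
            raise ValueError(f"negative weight in {self.kind} set")
        total = float(vals.sum())
        if abs(total - 1.0) > _SUM_TOL:
            raise ValueError(
                f"{self.kind} weights sum to {total!r}, expected 1 within {_SUM_TOL}"
            )

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(self.weights)

    def as_array(self, codes=None) -> np.ndarray:
        codes = self.codes if codes is None else codes
        return np.array([self.weights[c] for c in codes], dtype=float)

    def __getitem__(self, code: str) -> float:
        return self.weights[code]


def _normalize(v: np.ndarray) -> np.ndarray:
    return v / v.sum()


def ahp_weights(
    m: JudgmentMatrix, tol: float = 1e-12, max_iter: int = 10_000
) -> tuple[WeightSet, ConsistencyReport]:
    """Principal-eigenvector weights and consistency report for ``m``.

    The eigenvector is found by power iteration to ``tol`` relative change;
    CI = (lambda_max - n)/(n - 1) and CR = CI/RI(n) with Saaty's RI table.
    """
    a = m.entries
    n = m.n
    if n not in SAATY_RI:
        raise ValueError(f"no random index RI for n={n}")
    v = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        nv = a @ v
        nv = _normalize(nv)
        if np.max(np.abs(nv - v)) < tol * np.max(np.abs(nv)):
            v = nv
            break
        v = nv
    av = a @ v
    lambda_max = float(np.mean(av / v))
    ci = (lambda_max - n) / (n - 1)
    ri = SAATY_RI[n]
    cr = 0.0 if ri == 0 else ci / ri
    # clamp tiny negative round-off on perfectly consistent matrices
    if abs(ci) < 1e-12:
        ci, cr = 0.0, 0.0
    codes = m.codes or tuple(f"C{i+1}" for i in range(n))
    ws = WeightSet(kind="ahp", weights=dict(zip(codes, _normalize(v))))
    report = ConsistencyReport(
        lambda_max=lambda_max, CI=ci, CR=cr, passes=cr < 0.1, n=n
    )
    return ws, report


def entropy_weights_from_matrix(
    s: np.ndarray, codes, epoch: str | None = None
) -> WeightSet:
    """Entropy weights from a (cells × indicators) matrix of nonnegative values.

    For indicator j over n valid cells: P_ij = s_ij / Σ_i s_ij,
    E_j = -(1/ln n) Σ_i P_ij ln P_ij (terms with P_ij = 0 contribute 0),
    w_j = (1 - E_j) / Σ_j (1 - E_j).
    """
    s = np.asarray(s, dtype=float)
    if s.ndim != 2:
        raise ValueError("expected a 2-D (cells x indicators) matrix")
    n, m_ind = s.shape
    if n < 2:
        raise ValueError("entropy weights need at least 2 valid cells")
    if len(codes) != m_ind:
        raise ValueError("codes length must match matrix width")
    if np.any(s < 0):
        raise ValueError("entropy input must be nonnegative (standardize first)")

    col_sums = s.sum(axis=0)
    for j, c in enumerate(codes):
        if col_sums[j] == 0:
            raise ValueError(
                f"indicator {c!r} is zero everywhere; entropy weight undefined"
            )
    p = s / col_sums
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    e = -plogp.sum(axis=0) / math.log(n)
    # snap round-off at the entropy endpoints so uniform columns weigh exactly 0
    e = np.clip(e, 0.0, 1.0)
    e[e > 1.0 - 1e-12] = 1.0
    d = 1.0 - e
    denom = d.sum()
    if denom <= 0:
        const = [c for c, ej in zip(codes, e) if ej >= 1.0]
        raise ValueError(
            "all indicators are maximally entropic (constant over cells): "
            f"{const}; entropy weights undefined"
        )
    return WeightSet(kind="eem", weights=dict(zip(codes, d / denom)), epoch=epoch)


def entropy_weights(stack: IndicatorStack) -> WeightSet:
    """Entropy weights for a stack, using polarity-standardized valid cells.

    Each layer is first standardized to [0, 1] with its polarity (so "larger
    is better" holds for every column), then cells valid in all layers feed
    the entropy computation.
    """
    valid = stack.common_valid()
    n = int(valid.sum())
    if n < 2:
        raise ValueError("stack has fewer than 2 jointly valid cells")
    cols = []
    for lyr in stack:
        std = standardize(lyr)
        cols.append(std.values[valid])
    s = np.column_stack(cols)
    ws = entropy_weights_from_matrix(s, stack.codes, epoch=stack.epoch)
    ws.note = "per-epoch polarity-standardized values over the joint valid mask"
    return ws


def combine_weights(ahp: WeightSet, eem: WeightSet) -> WeightSet:
    """Normalized geometric mean: W_j = sqrt(W_ahp * W_eem) / Σ sqrt(...)."""
    if set(ahp.codes) != set(eem.codes):
        raise ValueError(
            f"code mismatch between weight sets: {sorted(set(ahp.codes) ^ set(eem.codes))}"
        )
    codes = ahp.codes
    g = np.sqrt(ahp.as_array(codes) * eem.as_array(codes))
    total = g.sum()
    if total == 0:
        raise ValueError("all geometric-mean weights are zero")
    return WeightSet(
        kind="combined", weights=dict(zip(codes, g / total)), epoch=eem.epoch
    )


def write_weight_csv(path, ahp: WeightSet, eem: WeightSet, combined: WeightSet) -> None:
    codes = combined.codes
    df = pd.DataFrame(
        {
            "code": codes,
            "w_ahp": ahp.as_array(codes),
            "w_eem": eem.as_array(codes),
            "w_combined": combined.as_array(codes),
        }
    )
    df.to_csv(path, index=False)


def read_weight_csv(path, kind: str = "combined", epoch=None, renormalize: bool = True) -> WeightSet:
    """Read one weight column (``w_ahp``/``w_eem``/``w_combined``) from CSV.

    Printed tables are often rounded so their columns miss 1 by ~1e-4;
    ``renormalize`` rescales to an exact unit sum.
    """
    df = pd.read_csv(path)
    col = {"ahp": "w_ahp", "eem": "w_eem", "combined": "w_combined"}[kind]
    w = df[col].to_numpy(dtype=float)
    if renormalize:
        w = w / w.sum()
    return WeightSet(kind=kind, weights=dict(zip(df["code"], w)), epoch=epoch)


def read_judgment_csv(path) -> JudgmentMatrix:
    """Read a square judgment matrix; header row/index column carry codes."""
    df = pd.read_csv(path, index_col=0)
    return JudgmentMatrix(entries=df.to_numpy(dtype=float), codes=tuple(df.columns))
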