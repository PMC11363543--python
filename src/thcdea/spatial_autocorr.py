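"""Rook-contiguity weights, global Moran's I, and Moran-scatter clustering.

Global Moran's I over n areal units with weights w_ij is

    I = n / S0 * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2,

with S0 the sum of all weights; under spatial randomness E[I] = -1/(n-1).
Inference uses the classic Cliff–Ord moments — either the normality
assumption or the randomization (permutation-moment) assumption — with a
two-sided normal p-value, plus an optional exact Monte-Carlo permutation
p-value.  The Moran scatter classifies each unit by the sign of its
demeaned value and of the row-standardized spatial lag of demeaned values:
HH and LL quadrants mark positive spatial association (agglomeration),
LH and HL mark negative association.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel_io import load_adjacency

__all__ = [
    "WeightMatrix",
    "MoranResult",
    "QuadrantAssignment",
    "build_weights",
    "rook29_weights",
    "global_moran",
    "moran_quadrants",
    "cluster_table",
]


@dataclass(frozen=True)
class WeightMatrix:
    """Symmetric binary contiguity with its row-standardized companion."""

    labels: tuple[str, ...]
    binary: np.ndarray
    row_standardized: np.ndarray

    @property
    def n(self) -> int:
        return len(self.labels)

    def view(self, standardization: str) -> np.ndarray:
        if standardization == "binary":
            return self.binary
        if standardization == "row":
            return self.row_standardized
        raise ValueError(f"standardization must be 'binary' or 'row', got {standardization!r}")


@dataclass(frozen=True)
class MoranResult:
    statistic: float
    expectation: float
    z_value: float
    p_value: float
    standardization: str
    null: str


@dataclass(frozen=True)
class QuadrantAssignment:
    labels: tuple[str, ...]
    quadrant: tuple[str, ...]  # per-unit tag in {HH, LH, LL, HL}
    share_agglomeration: float  # (|HH| + |LL|) / n


def build_weights(adjacency: list[tuple[str, str]], labels: list[str]) -> WeightMatrix:
    """Symmetric binary weight matrix from an undirected edge list.

    Every edge endpoint must appear in ``labels``; isolated units are
    rejected because a zero row cannot be row-standardized.
    """
    idx = {lab: i for i, lab in enumerate(labels)}
    if len(idx) != len(labels):
        raise ValueError("duplicate labels")
    n = len(labels)
    W = np.zeros((n, n))
    for a, b in adjacency:
        if a not in idx or b not in idx:
            unknown = a if a not in idx else b
            raise ValueError(f"unknown unit {unknown!r} in adjacency list")
        if a == b:
            raise ValueError(f"self-loop {a!r}")
        W[idx[a], idx[b]] = 1.0
        W[idx[b], idx[a]] = 1.0
    deg = W.sum(axis=1)
    if (deg == 0).any():
        iso = [labels[i] for i in np.flatnonzero(deg == 0)]
        raise ValueError(f"isolated units with no neighbors: {iso}")
    return WeightMatrix(
        labels=tuple(labels),
        binary=W,
        row_standardized=W / deg[:, None],
    )


def rook29_weights() -> WeightMatrix:
    """The packaged 29-province rook contiguity matrix (Hainan–Guangdong linked)."""
    from .panel_io import PROVINCES_29

    return build_weights(load_adjacency(), list(PROVINCES_29))


def _moran_statistic(z: np.ndarray, W: np.ndarray) -> float:
    n = z.size
    S0 = W.sum()
    return float(n / S0 * (z @ W @ z) / (z @ z))


def global_moran(
    values: np.ndarray,
    W: WeightMatrix,
    standardization: str = "row",
    null: str = "randomization",
    permutations: int = 0,
    seed: int | None = None,
) -> MoranResult:
    """Moran's I with analytic z/p under the chosen null.

    ``null='randomization'`` uses the permutation-moment variance (which
    involves the sample kurtosis); ``'normality'`` assumes an iid Gaussian
    field.  If ``permutations > 0`` the p-value is replaced by the
    Monte-Carlo permutation p (two-sided, pseudo-p convention).
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("Moran's I needs at least 3 units")
    if n != W.n:
        raise ValueError("value vector length mismatches weight matrix")
    z = x - x.mean()
    ss = float(z @ z)
    if ss == 0:
        raise ValueError("degenerate variance: constant value vector")
    Wm = W.view(standardization)
    I = _moran_statistic(z, Wm)

    S0 = Wm.sum()
    S1 = 0.5 * ((Wm + Wm.T) ** 2).sum()
    S2 = ((Wm.sum(axis=1) + Wm.sum(axis=0)) ** 2).sum()
    EI = -1.0 / (n - 1)
    if null == "normality":
        varI = (n * n * S1 - n * S2 + 3 * S0 * S0) / ((n * n - 1) * S0 * S0) - EI ** 2
    elif null == "randomization":
        b2 = n * (z ** 4).sum() / ss ** 2
        varI = (
            n * ((n * n - 3 * n + 3) * S1 - n * S2 + 3 * S0 * S0)
            - b2 * ((n * n - n) * S1 - 2 * n * S2 + 6 * S0 * S0)
        ) / ((n - 1) * (n - 2) * (n - 3) * S0 * S0) - EI ** 2
    else:
        raise ValueError(f"null must be 'normality' or 'randomization', got {null!r}")
    from scipy.stats import norm

    zval = (I - EI) / np.sqrt(varI)
    pval = 2 * norm.sf(abs(zval))
    if permutations > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(permutations):
            zp = rng.permutation(z)
            if abs(_moran_statistic(zp, Wm) - EI) >= abs(I - EI):
                count += 1
        pval = (count + 1) / (permutations + 1)
    return MoranResult(
        statistic=I,
        expectation=EI,
        z_value=float(zval),
        p_value=float(pval),
        standardization=standardization,
        null=null,
    )


def moran_quadrants(values: np.ndarray, W: WeightMatrix) -> QuadrantAssignment:
    """Moran-scatter quadrant of each unit (row-standardized lag).

    Zero deviations or zero lags are classified on the positive side; at
    3-decimal data exact zeros do not occur in practice.
    """
    x = np.asarray(values, dtype=float)
    if x.size != W.n:
        raise ValueError("value vector length mismatches weight matrix")
    d = x - x.mean()
    if (d == 0).all():
        raise ValueError("degenerate variance: constant value vector")
    lag = W.row_standardized @ d
    tags = []
    for di, li in zip(d, lag):
        hi, hl = di >= 0, li >= 0
        tags.append("HH" if hi and hl else "HL" if hi else "LH" if hl else "LL")
    n_agg = sum(t in ("HH", "LL") for t in tags)
    return QuadrantAssignment(
        labels=W.labels,
        quadrant=tuple(tags),
        share_agglomeration=n_agg / W.n,
    )


def cluster_table(assignments: dict[int, QuadrantAssignment]) -> pd.DataFrame:
    """Per-year membership lists per quadrant (published cluster-table layout)."""
    labels = None
    rows = []
    for year in sorted(assignments):
        qa = assignments[year]
        if labels is None:
            labels = qa.labels
        elif qa.labels != labels:
            raise ValueError("assignments do not share a label set")
        row: dict[str, object] = {"year": year}
        for quad in ("HH", "LL", "LH", "HL"):
            members = [lab for lab, q in zip(qa.labels, qa.quadrant) if q == quad]
            row[quad] = ", ".join(members)
            row[f"n_{quad}"] = len(members)
        row["share_agglomeration"] = qa.share_agglomeration
        rows.append(row)
    return pd.DataFrame(rows).set_index("year")
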