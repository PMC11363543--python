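"""Global-frontier Malmquist productivity index with EC × TC decomposition.

Productivity change of a DMU between adjacent periods is measured against a
single pooled reference technology S^g — the union of every period's
observations — which makes the index transitive (circular) across periods:

    MI(t, t+1) = E^g(x_{t+1}, y_{t+1}) / E^g(x_t, y_t)

where E^g is the (plain, non-super) SBM efficiency against the pooled set.
The index decomposes exactly into catch-up and frontier-shift terms,

    MI = EC × TC,   EC = E^{t+1}(x_{t+1}, y_{t+1}) / E^t(x_t, y_t),

with E^t the efficiency against period t's own frontier; TC is defined as
the ratio MI / EC, which makes the identity hold to machine precision.
Plain SBM is used throughout because every evaluated point is a member of
its reference set, so all scores are feasible and lie in (0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dea_sbm import DeaProblem, sbm_score, super_sbm_score
from .panel_io import PanelDataset

__all__ = [
    "MalmquistResult",
    "MalmquistSummary",
    "efficiency_vs_reference",
    "malmquist_chain",
    "summarize_malmquist",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MalmquistResult:
    unit_id: str
    period_pair: tuple[int, int]
    mi: float
    ec: float
    tc: float


@dataclass
class MalmquistSummary:
    per_unit_mean: pd.DataFrame  # index=unit, columns=[MI, EC, TC]
    national_mean: tuple[float, float, float]

    def to_frame(self) -> pd.DataFrame:
        df = self.per_unit_mean.copy()
        df.loc["Mean"] = list(self.national_mean)
        return df


def efficiency_vs_reference(
    point_inputs: np.ndarray,
    point_outputs: np.ndarray,
    ref_inputs: np.ndarray,
    ref_outputs: np.ndarray,
    rts: str = "variable",
) -> float:
    """SBM efficiency of one observation against an arbitrary reference set.

    ``ref_inputs`` is m × r and ``ref_outputs`` s × r (r reference
    observations).  The evaluated point enters only through the objective
    and right-hand side; when it lies inside the reference technology the
    plain SBM score (<= 1) is returned.  A point outside the hull makes the
    plain program infeasible, in which case the super-efficiency program
    against the same reference is returned (score >= 1).
    """
    x0 = np.atleast_1d(np.asarray(point_inputs, dtype=float))
    y0 = np.atleast_1d(np.asarray(point_outputs, dtype=float))
    Xr = np.atleast_2d(np.asarray(ref_inputs, dtype=float))
    Yr = np.atleast_2d(np.asarray(ref_outputs, dtype=float))
    # Append the point as the evaluated column; exclude-self handled per branch.
    X = np.column_stack([Xr, x0])
    Y = np.column_stack([Yr, y0])
    j0 = X.shape[1] - 1

    # Plain SBM but with the evaluated point NOT part of the envelopment
    # is exactly the super program; with it included it is plain SBM.  For
    # reference sets containing the point (the global/contemporaneous case)
    # both coincide when the point is inefficient.  Use plain SBM against
    # reference-plus-point only if the point duplicates a reference column;
    # otherwise evaluate against the reference alone.
    lam_feasible = _plain_sbm_against(x0, y0, Xr, Yr, rts)
    if lam_feasible is not None:
        return lam_feasible
    sup = super_sbm_score(DeaProblem(X, Y, evaluated_index=j0, returns_to_scale=rts))
    if not sup.feasible:
        raise RuntimeError("reference-set efficiency: both SBM and super-SBM infeasible")
    return sup.score


def _plain_sbm_against(x0, y0, Xr, Yr, rts) -> float | None:
    """Plain SBM of (x0, y0) with envelopment over Xr/Yr only; None if infeasible."""
    from scipy.optimize import linprog

    m, r = Xr.shape
    s = Yr.shape[0]
    nv = 1 + r + m + s  # t, Lam, S-, S+
    c = np.zeros(nv)
    c[0] = 1.0
    c[1 + r:1 + r + m] = -1.0 / (m * x0)
    rows, rhs = [], []
    row = np.zeros(nv)
    row[0] = 1.0
    row[1 + r + m:] = 1.0 / (s * y0)
    rows.append(row)
    rhs.append(1.0)
    for i in range(m):
        row = np.zeros(nv)
        row[0] = x0[i]
        row[1:1 + r] = -Xr[i]
        row[1 + r + i] = -1.0
        rows.append(row)
        rhs.append(0.0)
    for k in range(s):
        row = np.zeros(nv)
        row[0] = y0[k]
        row[1:1 + r] = -Yr[k]
        row[1 + r + m + k] = 1.0
        rows.append(row)
        rhs.append(0.0)
    if rts == "variable":
        row = np.zeros(nv)
        row[0] = -1.0
        row[1:1 + r] = 1.0
        rows.append(row)
        rhs.append(0.0)
    res = linprog(c, A_eq=np.array(rows), b_eq=np.array(rhs),
                  bounds=(0, None), method="highs")
    if res.status == 2:
        return None
    if not res.success:
        raise RuntimeError(f"SBM LP failed: {res.message}")
    return float(res.fun)


def malmquist_chain(panel: PanelDataset, rts: str = "variable") -> list[MalmquistResult]:
    """Per-unit MI/EC/TC for every adjacent period pair.

    E^g scores use the pooled all-period reference set; EC uses each
    period's own frontier.  Units whose sub-scores fail are excluded with a
    warning rather than imputed.
    """
    if panel.n_periods < 2:
        raise ValueError("Malmquist index needs at least two periods")
    n, T = panel.n_units, panel.n_periods
    # pooled reference: m × (n·T)
    Xg = np.concatenate([panel.inputs[:, :, t].T for t in range(T)], axis=1)
    Yg = np.concatenate([panel.outputs[:, :, t].T for t in range(T)], axis=1)

    e_global = np.empty((n, T))
    e_contemp = np.empty((n, T))
    failed_units: set[int] = set()
    for t in range(T):
        Xt = panel.inputs[:, :, t].T
        Yt = panel.outputs[:, :, t].T
        for u in range(n):
            try:
                e_global[u, t] = efficiency_vs_reference(
                    Xt[:, u], Yt[:, u], Xg, Yg, rts=rts)
                e_contemp[u, t] = efficiency_vs_reference(
                    Xt[:, u], Yt[:, u], Xt, Yt, rts=rts)
            except RuntimeError as exc:
                logger.warning(
                    "Malmquist sub-score failed for unit %s, period %s: %s",
                    panel.unit_ids[u], panel.period_ids[t], exc)
                failed_units.add(u)
                e_global[u, t] = e_contemp[u, t] = np.nan

    results: list[MalmquistResult] = []
    for u in range(n):
        if u in failed_units:
            logger.warning("unit %s excluded from Malmquist chain", panel.unit_ids[u])
            continue
        for t in range(T - 1):
            mi = e_global[u, t + 1] / e_global[u, t]
            ec = e_contemp[u, t + 1] / e_contemp[u, t]
            results.append(MalmquistResult(
                unit_id=panel.unit_ids[u],
                period_pair=(panel.period_ids[t], panel.period_ids[t + 1]),
                mi=float(mi),
                ec=float(ec),
                tc=float(mi / ec),
            ))
    return results


def summarize_malmquist(results: list[MalmquistResult]) -> MalmquistSummary:
    """Geometric mean per unit over period pairs; arithmetic mean across units.

    Geometric averaging over time preserves the MI = EC × TC identity at the
    per-unit level; the cross-unit national mean is arithmetic, matching the
    published summary convention.
    """
    if not results:
        raise ValueError("no Malmquist results to summarize")
    df = pd.DataFrame(
        [(r.unit_id, r.mi, r.ec, r.tc) for r in results],
        columns=["unit", "MI", "EC", "TC"],
    )
    if (df[["MI", "EC", "TC"]] <= 0).any().any():
        raise ValueError("nonpositive index entries; geometric mean undefined")
    per_unit = np.exp(
        np.log(df.set_index("unit")[["MI", "EC", "TC"]])
        .groupby(level=0, sort=False)
        .mean()
    )
    national = tuple(float(v) for v in per_unit.mean(axis=0))
    return MalmquistSummary(per_unit_mean=per_unit, national_mean=national)  # type: ignore[arg-type]
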