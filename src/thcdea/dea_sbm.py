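"""Slacks-based-measure (SBM) DEA and its super-efficiency extension.

The SBM score of a decision-making unit (DMU) simultaneously penalizes
input excesses and output shortfalls:

    rho = min  (1 - (1/m) sum_i s_i^- / x_i0) / (1 + (1/s) sum_k s_k^+ / y_k0)
    s.t. x_0 = X lam + s^-,  y_0 = Y lam - s^+,  sum lam = 1 (VRS),
         lam, s^-, s^+ >= 0.

Efficient DMUs all score 1 under plain SBM, so ranking among them uses the
super-efficiency variant, which removes the evaluated DMU from the
reference set and finds the least-costly projection (x_bar, y_bar) with
x_bar >= x_0 and y_bar <= y_0 dominated by the remaining units:

    rho_super = min ((1/m) sum x_bar_i / x_i0) / ((1/s) sum y_bar_k / y_k0).

Both fractional programs are solved exactly after the Charnes–Cooper
transformation (multiply every variable by a scale t > 0 chosen so the
denominator equals one), which turns them into ordinary LPs handled by
scipy's HiGHS solver.  The two-stage driver reproduces the published score
pattern: inefficient units keep their SBM score below one, efficient units
are re-scored above one by the super model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .panel_io import PanelDataset

__all__ = [
    "DeaProblem",
    "DeaSolution",
    "EfficiencyTable",
    "sbm_score",
    "super_sbm_score",
    "two_stage_score",
    "score_panel",
]

#: Score-side tolerance classifying a DMU as SBM-efficient.
EFFICIENT_TOL = 1e-6


@dataclass(frozen=True)
class DeaProblem:
    """One evaluation instance: data matrices plus the evaluated column.

    ``input_matrix`` is m × n and ``output_matrix`` s × n (variables in
    rows, DMUs in columns); all entries must be strictly positive.
    """

    input_matrix: np.ndarray
    output_matrix: np.ndarray
    evaluated_index: int
    returns_to_scale: str = "variable"

    def __post_init__(self):
        X = np.atleast_2d(np.asarray(self.input_matrix, dtype=float))
        Y = np.atleast_2d(np.asarray(self.output_matrix, dtype=float))
        object.__setattr__(self, "input_matrix", X)
        object.__setattr__(self, "output_matrix", Y)
        if X.shape[1] != Y.shape[1]:
            raise ValueError("input and output matrices disagree on number of DMUs")
        if (X <= 0).any() or (Y <= 0).any():
            raise ValueError("SBM requires strictly positive inputs and outputs")
        if not 0 <= self.evaluated_index < X.shape[1]:
            raise IndexError("evaluated_index out of range")
        if self.returns_to_scale not in {"variable", "constant"}:
            raise ValueError("returns_to_scale must be 'variable' or 'constant'")


@dataclass
class DeaSolution:
    """Optimal score with its certificate (reference weights and slacks)."""

    score: float
    lambdas: np.ndarray
    input_target: np.ndarray
    output_target: np.ndarray
    input_slacks: np.ndarray
    output_slacks: np.ndarray
    feasible: bool
    stage: str  # "sbm" | "super_sbm"


@dataclass
class EfficiencyTable:
    """Panel of two-stage scores shaped like the published score table."""

    unit_ids: list[str]
    period_ids: list[int]
    scores: np.ndarray  # (n, T)
    stage: np.ndarray  # (n, T) object array of tags
    certificates: list[list[DeaSolution]]

    def to_frame(self, with_means: bool = True):
        import pandas as pd

        df = pd.DataFrame(self.scores, index=self.unit_ids, columns=self.period_ids)
        if with_means:
            df["Mean"] = df.mean(axis=1)
            df.loc["Mean"] = df.mean(axis=0)
        return df


def _solve_lp(c, A_eq, b_eq, A_ub=None, b_ub=None):
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=(0, None), method="highs")
    return res


def sbm_score(problem: DeaProblem) -> DeaSolution:
    """Non-oriented (V|C)RS SBM efficiency of the evaluated DMU.

    The evaluated DMU belongs to its own reference set, so the LP is always
    feasible and the optimal score lies in (0, 1].
    """
    X, Y = problem.input_matrix, problem.output_matrix
    m, n = X.shape
    s = Y.shape[0]
    j0 = problem.evaluated_index
    x0, y0 = X[:, j0], Y[:, j0]

    # Charnes–Cooper variables: [t, Lam (n), S- (m), S+ (s)], all scaled by t.
    nv = 1 + n + m + s
    c = np.zeros(nv)
    c[0] = 1.0
    c[1 + n:1 + n + m] = -1.0 / (m * x0)

    rows = []
    rhs = []
    # denominator normalization: t + (1/s) sum S+_k / y_k0 = 1
    r = np.zeros(nv)
    r[0] = 1.0
    r[1 + n + m:] = 1.0 / (s * y0)
    rows.append(r)
    rhs.append(1.0)
    # x_i0 t - X Lam - S-_i = 0
    for i in range(m):
        r = np.zeros(nv)
        r[0] = x0[i]
        r[1:1 + n] = -X[i]
        r[1 + n + i] = -1.0
        rows.append(r)
        rhs.append(0.0)
    # y_k0 t - Y Lam + S+_k = 0
    for k in range(s):
        r = np.zeros(nv)
        r[0] = y0[k]
        r[1:1 + n] = -Y[k]
        r[1 + n + m + k] = 1.0
        rows.append(r)
        rhs.append(0.0)
    if problem.returns_to_scale == "variable":
        r = np.zeros(nv)
        r[0] = -1.0
        r[1:1 + n] = 1.0
        rows.append(r)
        rhs.append(0.0)

    res = _solve_lp(c, np.array(rows), np.array(rhs))
    if not res.success:
        raise RuntimeError(f"SBM LP failed: {res.message} (status {res.status})")
    t = res.x[0]
    if t <= 0:
        raise RuntimeError("SBM LP returned a nonpositive Charnes–Cooper scale")
    lam = res.x[1:1 + n] / t
    s_minus = res.x[1 + n:1 + n + m] / t
    s_plus = res.x[1 + n + m:] / t
    return DeaSolution(
        score=float(res.fun),
        lambdas=lam,
        input_target=x0 - s_minus,
        output_target=y0 + s_plus,
        input_slacks=s_minus,
        output_slacks=s_plus,
        feasible=True,
        stage="sbm",
    )


def super_sbm_score(problem: DeaProblem) -> DeaSolution:
    """Super-efficiency SBM: the evaluated DMU is excluded from the frontier.

    Finds the projection (x_bar >= x_0, 0 <= y_bar <= y_0) enveloped by the
    remaining DMUs that minimizes the mean input expansion over the mean
    output contraction; the optimum is >= 1 whenever the LP is feasible.
    Infeasibility (possible under variable returns) yields
    ``feasible=False`` with a NaN score.
    """
    X, Y = problem.input_matrix, problem.output_matrix
    m, n = X.shape
    s = Y.shape[0]
    j0 = problem.evaluated_index
    if n < 2:
        raise ValueError("super-efficiency needs at least one reference DMU")
    x0, y0 = X[:, j0], Y[:, j0]
    ref = [j for j in range(n) if j != j0]
    Xr, Yr = X[:, ref], Y[:, ref]
    nr = len(ref)

    # variables: [t, Lam (nr), Xbar (m), Ybar (s)] (scaled by t)
    nv = 1 + nr + m + s
    c = np.zeros(nv)
    c[1 + nr:1 + nr + m] = 1.0 / (m * x0)

    A_eq, b_eq = [], []
    r = np.zeros(nv)  # (1/s) sum Ybar_k / y_k0 = 1
    r[1 + nr + m:] = 1.0 / (s * y0)
    A_eq.append(r)
    b_eq.append(1.0)
    if problem.returns_to_scale == "variable":
        r = np.zeros(nv)  # sum Lam = t
        r[0] = -1.0
        r[1:1 + nr] = 1.0
        A_eq.append(r)
        b_eq.append(0.0)

    A_ub, b_ub = [], []
    for i in range(m):  # Xr Lam - Xbar_i <= 0
        r = np.zeros(nv)
        r[1:1 + nr] = Xr[i]
        r[1 + nr + i] = -1.0
        A_ub.append(r)
        b_ub.append(0.0)
    for k in range(s):  # Ybar_k - Yr Lam <= 0
        r = np.zeros(nv)
        r[1:1 + nr] = -Yr[k]
        r[1 + nr + m + k] = 1.0
        A_ub.append(r)
        b_ub.append(0.0)
    for i in range(m):  # t x_i0 - Xbar_i <= 0
        r = np.zeros(nv)
        r[0] = x0[i]
        r[1 + nr + i] = -1.0
        A_ub.append(r)
        b_ub.append(0.0)
    for k in range(s):  # Ybar_k - t y_k0 <= 0
        r = np.zeros(nv)
        r[0] = -y0[k]
        r[1 + nr + m + k] = 1.0
        A_ub.append(r)
        b_ub.append(0.0)

    res = _solve_lp(c, np.array(A_eq), np.array(b_eq), np.array(A_ub), np.array(b_ub))
    if res.status == 2:  # infeasible
        return DeaSolution(
            score=float("nan"),
            lambdas=np.zeros(n),
            input_target=np.full(m, np.nan),
            output_target=np.full(s, np.nan),
            input_slacks=np.full(m, np.nan),
            output_slacks=np.full(s, np.nan),
            feasible=False,
            stage="super_sbm",
        )
    if not res.success:
        raise RuntimeError(f"super-SBM LP failed: {res.message} (status {res.status})")
    t = res.x[0]
    if t <= 0:
        raise RuntimeError("super-SBM LP returned a nonpositive Charnes–Cooper scale")
    lam = np.zeros(n)
    lam[ref] = res.x[1:1 + nr] / t
    xbar = res.x[1 + nr:1 + nr + m] / t
    ybar = res.x[1 + nr + m:] / t
    return DeaSolution(
        score=float(res.fun),
        lambdas=lam,
        input_target=xbar,
        output_target=ybar,
        input_slacks=xbar - x0,
        output_slacks=y0 - ybar,
        feasible=True,
        stage="super_sbm",
    )


def two_stage_score(problem: DeaProblem, tol: float = EFFICIENT_TOL) -> DeaSolution:
    """SBM first; SBM-efficient DMUs are re-scored with super-efficiency.

    Mirrors the published scoring convention: values below one are plain
    SBM inefficiencies, values at or above one come from the super model.
    An infeasible super LP is reported as feasible=False with score 1.
    """
    base = sbm_score(problem)
    if base.score < 1.0 - tol:
        return base
    sup = super_sbm_score(problem)
    if not sup.feasible:
        sup.score = 1.0
    return sup


def score_panel(panel: PanelDataset, tol: float = EFFICIENT_TOL) -> EfficiencyTable:
    """Two-stage score of every unit in every period, each year its own frontier."""
    n, T = panel.n_units, panel.n_periods
    scores = np.empty((n, T))
    stage = np.empty((n, T), dtype=object)
    certs: list[list[DeaSolution]] = [[None] * T for _ in range(n)]  # type: ignore[list-item]
    for ti in range(T):
        X = panel.inputs[:, :, ti].T  # m × n
        Y = panel.outputs[:, :, ti].T
        for ui in range(n):
            try:
                sol = two_stage_score(
                    DeaProblem(X, Y, evaluated_index=ui), tol=tol
                )
            except Exception as exc:
                raise RuntimeError(
                    f"DEA failed for unit {panel.unit_ids[ui]!r}, "
                    f"year {panel.period_ids[ti]}: {exc}"
                ) from exc
            scores[ui, ti] = sol.score
            stage[ui, ti] = sol.stage if sol.feasible else "infeasible"
            certs[ui][ti] = sol
    return EfficiencyTable(
        unit_ids=list(panel.unit_ids),
        period_ids=list(panel.period_ids),
        scores=scores,
        stage=stage,
        certificates=certs,
    )
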