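"""Independent brute-force oracles used to cross-check the LP solvers.

The SBM oracle evaluates the slacks-based objective in closed form on a
dense grid over the lambda simplex and refines locally; it shares no code
with the Charnes–Cooper LP path it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def _simplex_grid(n: int, resolution: int) -> np.ndarray:
    """All lattice points of the (n-1)-simplex at spacing 1/resolution."""
    pts = [
        np.array(c, dtype=float) / resolution
        for c in itertools.product(range(resolution + 1), repeat=n - 1)
        if sum(c) <= resolution
    ]
    grid = np.empty((len(pts), n))
    for i, p in enumerate(pts):
        grid[i, :-1] = p
        grid[i, -1] = 1.0 - p.sum()
    return grid


def sbm_objective(lam: np.ndarray, X, Y, x0, y0) -> np.ndarray:
    """Closed-form SBM objective for given lambda rows; NaN where infeasible.

    ``X`` and ``Y`` are unit-major, (n, m) and (n, s).  Feasibility requires
    nonnegative slacks s- = x0 - lam X and s+ = lam Y - y0; the objective is
    (1 - mean(s-/x0)) / (1 + mean(s+/y0)).
    """
    lam = np.atleast_2d(lam)
    s_minus = x0[None, :] - lam @ X  # (N, m)
    s_plus = lam @ Y - y0[None, :]  # (N, s)
    feas = (s_minus >= -1e-12).all(axis=1) & (s_plus >= -1e-12).all(axis=1)
    num = 1.0 - (np.clip(s_minus, 0, None) / x0).mean(axis=1)
    den = 1.0 + (np.clip(s_plus, 0, None) / y0).mean(axis=1)
    obj = num / den
    obj[~feas] = np.nan
    return obj


def sbm_grid_oracle(
    input_matrix: np.ndarray,
    output_matrix: np.ndarray,
    evaluated_index: int,
    resolution: int = 50,
    refine_stages: int = 4,
    shrink: float = 0.2,
) -> float:
    """Grid-search SBM score under VRS (sum lambda = 1, self included).

    A full simplex sweep at ``resolution`` is followed by ``refine_stages``
    local sweeps, each mapping the grid into a shrinking neighborhood of
    the incumbent (the SBM objective is a ratio of affine functions, hence
    quasiconvex over the feasible region, so local refinement converges to
    the global minimum).
    """
    X = np.atleast_2d(np.asarray(input_matrix, float)).T  # (n, m)
    Y = np.atleast_2d(np.asarray(output_matrix, float)).T
    n = X.shape[0]
    x0, y0 = X[evaluated_index], Y[evaluated_index]

    grid = _simplex_grid(n, resolution)
    obj = sbm_objective(grid, X, Y, x0, y0)
    if np.isnan(obj).all():
        raise RuntimeError("grid oracle: no feasible lambda (should not happen "
                           "when the evaluated unit is in the reference set)")
    best_idx = np.nanargmin(obj)
    best_lam, best_val = grid[best_idx], obj[best_idx]

    local = _simplex_grid(n, resolution)
    w = shrink
    for _ in range(refine_stages):
        cand = (1.0 - w) * best_lam[None, :] + w * local
        cobj = sbm_objective(cand, X, Y, x0, y0)
        if not np.isnan(cobj).all():
            i = np.nanargmin(cobj)
            if cobj[i] < best_val:
                best_val, best_lam = cobj[i], cand[i]
        w *= shrink
    return float(best_val)
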