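"""Synthetic panels with the statistical structure the analysis assumes.

Two generators make every pipeline stage testable without external data.

The DEA generator places each unit on a concave variable-returns-to-scale
technology — a single latent activity level ``a`` drives proportional
outputs ``y_r = d_r a`` and an input requirement ``x_i = c_i a^gamma`` with
``gamma > 1`` (convex input requirement, hence a strictly concave
production frontier) — and then inflates the inputs by exp(u) with u drawn
half-normal.  With zero inefficiency every unit lies on the frontier by
construction; the drawn u are returned as ground truth for recovery
checks.  A negative ``drift`` shifts the frontier outward over time
(technical progress), positive drift shifts it inward.

The spatial Durbin generator draws covariates emulating the published
descriptive moments of the thirteen province-level factors (GDP per
capita, population density, percentage shares, ...) and builds the
response through the reduced form

    y_t = (I - rho W)^{-1} (X_t beta + W X_t theta + mu + gamma_t 1 + eps_t)

so that the true (rho, beta, theta, sigma) are known to recovery tests.
Defaults mirror the published study conditions: the 29-province rook
contiguity matrix, T = 10 periods, rho = -0.155 and the published SDM
coefficient vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel_io import PanelDataset
from .spatial_autocorr import WeightMatrix, rook29_weights

__all__ = [
    "DeaGenConfig",
    "SdmGenConfig",
    "generate_dea_panel",
    "generate_covariates",
    "generate_sdm_panel",
    "TABLE2_MOMENTS",
    "DEFAULT_SDM_BETA",
    "DEFAULT_SDM_THETA",
]

#: Published descriptive moments of the 13 covariates: (mean, sd, lower,
#: upper, family).  X3 (% urban population) is clipped to [0, 100] and given
#: a plausible spread; its printed maximum is a data defect.
TABLE2_MOMENTS: dict[str, tuple[float, float, float, float, str]] = {
    "X1": (0.67, 0.19, 0.25, 1.20, "normal"),
    "X2": (309.44, 264.59, 2.56, 1209.15, "lognormal"),
    "X3": (74.51, 13.0, 0.0, 100.0, "normal"),
    "X4": (39.30, 6.83, 24.98, 57.79, "normal"),
    "X5": (5.99, 6.32, 1.01, 41.18, "lognormal"),
    "X6": (54919.96, 22568.86, 5896.00, 137039.00, "lognormal"),
    "X7": (3.24, 0.56, 1.80, 4.60, "normal"),
    "X8": (102.67, 2.43, 99.30, 115.40, "normal"),
    "X9": (23800.33, 7804.61, 9746.80, 57540.50, "lognormal"),
    "X10": (8.20, 2.07, 2.63, 13.57, "normal"),
    "X11": (1057.44, 489.26, 391.37, 3944.54, "lognormal"),
    "X12": (61846.29, 58028.25, 825.00, 574265.90, "lognormal"),
    "X13": (10.81, 2.75, 4.98, 18.80, "normal"),
}

#: Published SDM coefficients used as the default data-generating truth.
DEFAULT_SDM_BETA = np.array([
    0.4398813, -0.0019767, 0.0000184, 0.0045304, -0.0036032, 0.0000026,
    -0.0439717, 0.0010251, 0.0000179, 0.0098407, -0.0003305, -0.0000003,
    0.0156813,
])
DEFAULT_SDM_THETA = np.array([
    -0.0263782, 0.0041332, -0.0000498, 0.0012280, 0.0089168, 0.0000025,
    -0.2262410, 0.0055915, -0.0000489, 0.0557525, 0.0000410, 0.0000001,
    0.0251309,
])


@dataclass(frozen=True)
class DeaGenConfig:
    """Study-condition defaults: 29 units, 10 periods, 5 inputs, 4 outputs."""

    n_units: int = 29
    n_periods: int = 10
    n_inputs: int = 5
    n_outputs: int = 4
    frontier_curvature: float = 1.4  # gamma > 1 gives variable returns
    inefficiency_scale: float = 0.3  # half-normal sigma of input inflation
    drift: float = 0.0  # per-period log shift of the input requirement
    seed: int = 0


@dataclass
class SdmGenConfig:
    """Spatial Durbin DGP; defaults follow the published study conditions."""

    rho: float = -0.155
    beta: np.ndarray = field(default_factory=lambda: DEFAULT_SDM_BETA.copy())
    theta: np.ndarray | None = field(default_factory=lambda: DEFAULT_SDM_THETA.copy())
    sigma: float = 0.07
    effects: str = "both"  # none | individual | time | both
    W: WeightMatrix | None = None
    n_periods: int = 10
    seed: int = 0


def generate_dea_panel(config: DeaGenConfig) -> tuple[PanelDataset, np.ndarray]:
    """Draw a DEA panel plus the true per-cell inefficiency exponents.

    Returns ``(panel, u)`` where ``u`` has shape (n_units, n_periods);
    inputs were inflated by ``exp(u)`` relative to the frontier, so larger
    u means a less efficient unit.
    """
    rng = np.random.default_rng(config.seed)
    n, T = config.n_units, config.n_periods
    m, s = config.n_inputs, config.n_outputs
    gamma = config.frontier_curvature
    if gamma <= 0:
        raise ValueError("frontier_curvature must be positive")

    # fixed technology directions shared by all units (keeps every
    # zero-inefficiency unit on the frontier)
    c = rng.uniform(0.5, 2.0, size=m)
    d = rng.uniform(0.5, 2.0, size=s)

    a = rng.uniform(0.5, 3.0, size=(n, T))  # latent activity level
    u = np.abs(rng.normal(0.0, 1.0, size=(n, T))) * config.inefficiency_scale
    shift = np.exp(config.drift * np.arange(T))  # frontier movement

    inputs = np.empty((n, m, T))
    outputs = np.empty((n, s, T))
    for t in range(T):
        base = a[:, t] ** gamma * shift[t]
        inputs[:, :, t] = np.outer(base * np.exp(u[:, t]), c)
        outputs[:, :, t] = np.outer(a[:, t], d)
    from .panel_io import PROVINCES_29

    labels = (list(PROVINCES_29) if n == len(PROVINCES_29)
              else [f"U{i + 1:02d}" for i in range(n)])
    panel = PanelDataset(
        unit_ids=labels,
        period_ids=list(range(2012, 2012 + T)),
        inputs=inputs,
        outputs=outputs,
    )
    return panel, u


def generate_covariates(
    n_units: int = 29,
    n_periods: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Thirteen independent covariate series matching the published moments.

    Positive skewed series (population density, GDP per capita, incomes,
    traffic) are lognormal; bounded shares are normal draws clipped to
    their observed ranges.  Shape (n_units, n_periods, 13).
    """
    rng = np.random.default_rng(seed)
    out = np.empty((n_units, n_periods, len(TABLE2_MOMENTS)))
    for j, (_, (mean, sd, lo, hi, family)) in enumerate(TABLE2_MOMENTS.items()):
        if family == "lognormal":
            s2 = np.log(1.0 + (sd / mean) ** 2)
            mu = np.log(mean) - s2 / 2.0
            draw = rng.lognormal(mu, np.sqrt(s2), size=(n_units, n_periods))
        else:
            draw = rng.normal(mean, sd, size=(n_units, n_periods))
        out[:, :, j] = np.clip(draw, lo, hi)
    return out


def generate_sdm_panel(
    config: SdmGenConfig,
) -> tuple[np.ndarray, np.ndarray, WeightMatrix]:
    """Response and regressors from the spatial Durbin reduced form.

    Returns ``(y, X, W)`` with y of shape (n, T) and X (n, T, k).  The
    spatial multiplier (I - rho W)^{-1} is applied per period, so Moran
    autocorrelation, fixed effects and the true coefficient vector are all
    controlled by the config.
    """
    W = config.W if config.W is not None else rook29_weights()
    Wm = W.row_standardized
    n = W.n
    T = config.n_periods
    ev = np.linalg.eigvals(Wm).real
    lo = 1.0 / ev.min()
    if not lo < config.rho < 1.0:
        raise ValueError(f"rho={config.rho} outside admissible interval ({lo:.4f}, 1)")
    beta = np.asarray(config.beta, dtype=float)
    k = beta.size
    theta = (np.zeros(k) if config.theta is None
             else np.asarray(config.theta, dtype=float))
    if theta.size != k:
        raise ValueError("beta and theta lengths differ")
    if config.sigma <= 0:
        raise ValueError("sigma must be positive")

    rng = np.random.default_rng(config.seed)
    X = generate_covariates(n, T, seed=int(rng.integers(2 ** 31)))[:, :, :k]
    mu = (rng.normal(0.0, 0.1, size=n)
          if config.effects in ("individual", "both") else np.zeros(n))
    gam = (rng.normal(0.0, 0.1, size=T)
           if config.effects in ("time", "both") else np.zeros(T))
    eps = rng.normal(0.0, config.sigma, size=(n, T))

    A_inv = np.linalg.inv(np.eye(n) - config.rho * Wm)
    y = np.empty((n, T))
    for t in range(T):
        xb = X[:, t, :] @ beta + Wm @ (X[:, t, :] @ theta)
        y[:, t] = A_inv @ (xb + mu + gam[t] + eps[:, t])
    return y, X, W
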