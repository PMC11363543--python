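"""End-to-end orchestration: scores → Malmquist → Moran → model selection → effects.

One call runs the full efficiency-and-spatial analysis and emits the six
table artifacts (efficiency panel, Malmquist decomposition, global Moran
per year, cluster table, regression coefficients, effect decomposition)
plus a machine-readable model-selection report and a log.  Model selection
follows the standard spatial-econometric decision chain: LM and robust LM
tests admit spatial lag / error structure, LR and Wald degradation tests
check whether the Durbin model collapses to SAR or SEM, the Hausman test
chooses fixed vs random effects, and LR tests pick the fixed-effect
structure.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dea_sbm, global_malmquist, panel_io, spatial_autocorr, spatial_panel
from .spatial_panel import SpecTestResult
from .synthetic_data import DeaGenConfig, SdmGenConfig, generate_dea_panel, generate_sdm_panel

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "decision_report"]

_REQUIRED_TESTS = (
    "lm_lag", "lm_error", "robust_lm_lag", "robust_lm_error",
    "lr_sar", "lr_sem", "wald_sar", "wald_sem",
    "hausman", "lr_individual", "lr_time",
)


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    ``scores`` selects where efficiency scores come from: ``"dea"``
    computes them from the panel, ``"fixture"`` uses the packaged published
    score table (skipping the DEA and Malmquist stages).  ``panel`` is a
    long-format CSV path or ``None`` for a synthetic panel.
    """

    output_dir: str | Path = "thcdea_output"
    seed: int = 0
    scores: str = "dea"  # dea | fixture
    panel: str | Path | None = None
    schema: panel_io.PanelSchema | None = None
    weights: str | Path = "fixture"
    moran_standardization: str = "row"
    alpha: float = 0.05
    effect_draws: int = 1000
    dea_config: DeaGenConfig | None = None
    sdm_config: SdmGenConfig | None = None
    run_regression: bool = True
    extra: dict = field(default_factory=dict)


def _load_weights(config: PipelineConfig, labels: list[str]) -> spatial_autocorr.WeightMatrix:
    if config.weights == "fixture":
        if list(labels) == list(panel_io.PROVINCES_29):
            return spatial_autocorr.rook29_weights()
        raise ValueError("fixture weights require the 29-province unit set")
    edges = panel_io.load_adjacency(config.weights)
    return spatial_autocorr.build_weights(edges, labels)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the artifact manifest.

    Artifacts are CSV tables in ``config.output_dir``, each with a header
    comment carrying the seed.  Any stage failure removes partial artifacts
    and re-raises with the stage name.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "artifacts": {}}
    written: list[Path] = []

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out / f"{name}.csv"
        with open(path, "w") as fh:
            fh.write(f"# seed={config.seed}\n")
            df.to_csv(fh)
        manifest["artifacts"][name] = str(path)
        written.append(path)

    stage = "setup"
    try:
        # ------------------------------------------------------------ scores
        stage = "scores"
        if config.scores == "fixture":
            scores_df = panel_io.load_fixture("table1_efficiency").values
            unit_ids = list(scores_df.index)
            period_ids = list(scores_df.columns)
            panel = None
            logger.info("using packaged score fixture; DEA stage skipped")
        else:
            if config.panel is not None:
                if config.schema is None:
                    raise ValueError("a schema is required to load a panel CSV")
                panel = panel_io.load_panel(config.panel, config.schema)
            else:
                dea_cfg = config.dea_config or DeaGenConfig(seed=config.seed)
                panel, _ = generate_dea_panel(dea_cfg)
                logger.info("generated synthetic DEA panel (seed=%d)", dea_cfg.seed)
            table = dea_sbm.score_panel(panel)
            scores_df = pd.DataFrame(
                table.scores, index=table.unit_ids, columns=table.period_ids)
            unit_ids = table.unit_ids
            period_ids = table.period_ids
            n_inf = int((table.stage == "infeasible").sum())
            if n_inf:
                logger.warning("%d super-efficiency cells were infeasible", n_inf)
        with_means = scores_df.copy()
        with_means["Mean"] = with_means.mean(axis=1)
        with_means.loc["Mean"] = with_means.mean(axis=0)
        emit("table1_efficiency", with_means.round(3))

        # --------------------------------------------------------- malmquist
        if panel is not None and panel.n_periods >= 2:
            stage = "malmquist"
            chain = global_malmquist.malmquist_chain(panel)
            summary = global_malmquist.summarize_malmquist(chain)
            emit("table3_malmquist", summary.to_frame().round(3))

        # ------------------------------------------------- moran and cluster
        stage = "moran"
        W = _load_weights(config, unit_ids)
        moran_rows = []
        assignments = {}
        for year in period_ids:
            res = spatial_autocorr.global_moran(
                scores_df[year].to_numpy(), W,
                standardization=config.moran_standardization)
            moran_rows.append(
                {"year": year, "I": res.statistic, "Z": res.z_value, "p": res.p_value})
            assignments[year] = spatial_autocorr.moran_quadrants(
                scores_df[year].to_numpy(), W)
        emit("table4_moran", pd.DataFrame(moran_rows).set_index("year").round(3))
        emit("table5_cluster", spatial_autocorr.cluster_table(assignments))

        # -------------------------------------------------------- regression
        if config.run_regression:
            stage = "regression"
            sdm_cfg = config.sdm_config or SdmGenConfig(seed=config.seed, W=W)
            y, X, W = generate_sdm_panel(sdm_cfg)
            report = _selection_and_fits(y, X, W, config, manifest, emit)
            report_path = out / "decision_report.json"
            report_path.write_text(json.dumps(report, indent=2))
            manifest["artifacts"]["decision_report"] = str(report_path)
            written.append(report_path)

        manifest_path = out / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2))
        return manifest
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _selection_and_fits(y, X, W, config: PipelineConfig, manifest, emit) -> dict:
    names = [f"X{j + 1}" for j in range(X.shape[2])]
    mk = dict(response=y, regressors=X, W=W, regressor_names=names)
    lm = spatial_panel.lm_tests(y, X, W, effects="both")
    sdm = spatial_panel.fit_spatial_panel(
        spatial_panel.SpatialPanelSpec(model="sdm", effects="both", **mk))
    sar = spatial_panel.fit_spatial_panel(
        spatial_panel.SpatialPanelSpec(model="sar", effects="both", **mk))
    sem = spatial_panel.fit_spatial_panel(
        spatial_panel.SpatialPanelSpec(model="sem", effects="both", **mk))
    sdm_re = spatial_panel.fit_spatial_panel_re(
        spatial_panel.SpatialPanelSpec(model="sdm", effects="both", **mk))
    battery = spatial_panel.lr_wald_hausman(sdm, sar, sem, sdm_re)

    # effect-structure LR tests need likelihoods on a common transformation
    naive = {
        eff: spatial_panel.fit_spatial_panel(
            spatial_panel.SpatialPanelSpec(model="sdm", effects=eff, **mk),
            transform=False)
        for eff in ("both", "individual", "time")
    }
    n, T = y.shape
    lr_ind = spatial_panel.lr_test(naive["both"], naive["time"],
                                   df=n - 1, name="lr_individual")
    lr_time = spatial_panel.lr_test(naive["both"], naive["individual"],
                                    df=T - 1, name="lr_time")

    all_tests = list(lm) + list(battery) + [lr_ind, lr_time]
    report = decision_report(all_tests, alpha=config.alpha)

    # regression table (published layout: coefficients, W*X rows, rho, sigma2, R2)
    rows = {}
    for fit, col in ((sdm, "SDM"), (sar, "SAR"), (sem, "SEM")):
        se = np.sqrt(np.diag(fit.vcov))
        from scipy import stats as st

        col_vals = {}
        for i, nm in enumerate(fit.param_names[:fit.n_slopes]):
            z = fit.slopes[i] / se[i]
            col_vals[nm] = fit.slopes[i]
            col_vals[f"{nm}_p"] = 2 * st.norm.sf(abs(z))
        col_vals["rho/lambda"] = fit.rho_or_lambda
        col_vals["sigma2"] = fit.sigma2
        col_vals["R2"] = fit.r2
        rows[col] = col_vals
    emit("table8_regression", pd.DataFrame(rows))

    effects = spatial_panel.decompose_effects(
        sdm, W, draws=config.effect_draws, seed=config.seed + 20240816)
    emit("table9_effects", effects.to_frame())
    return report


def decision_report(tests: list[SpecTestResult], alpha: float = 0.05) -> dict:
    """Traverse the model-selection flowchart over a complete test battery.

    Requires the four LM tests, the four degradation tests, the Hausman
    test and the two effect-structure LR tests; raises listing whatever is
    missing.  Returns the selected model with the chain of decisions, each
    backed by its statistic and p-value.
    """
    by_name = {t.name: t for t in tests}
    missing = [n for n in _REQUIRED_TESTS if n not in by_name]
    if missing:
        raise ValueError(f"incomplete test battery; missing: {missing}")

    def sig(name: str) -> bool:
        return by_name[name].p_value < alpha

    chain = []

    def decide(step: str, outcome: str, basis: list[str]) -> None:
        chain.append({
            "step": step,
            "outcome": outcome,
            "tests": {n: {"statistic": by_name[n].statistic,
                          "df": by_name[n].df,
                          "p_value": by_name[n].p_value} for n in basis},
        })

    lag_sig = sig("lm_lag") or sig("robust_lm_lag")
    err_sig = sig("lm_error") or sig("robust_lm_error")
    decide("lm_admission",
           f"spatial lag {'admitted' if lag_sig else 'rejected'}; "
           f"spatial error {'admitted' if err_sig else 'rejected'}",
           ["lm_lag", "robust_lm_lag", "lm_error", "robust_lm_error"])

    if not lag_sig and not err_sig:
        selected = "non-spatial OLS panel"
        decide("model", selected, [])
        return {"selected_model": selected, "alpha": alpha, "chain": chain}

    sar_holds = not (sig("lr_sar") and sig("wald_sar"))  # theta = 0 plausible
    sem_holds = not (sig("lr_sem") and sig("wald_sem"))  # common factor plausible
    if sar_holds and lag_sig:
        model = "SAR"
    elif sem_holds and err_sig:
        model = "SEM"
    else:
        model = "SDM"
    decide("degradation",
           f"SDM {'degrades' if model != 'SDM' else 'does not degrade'}; model {model}",
           ["lr_sar", "wald_sar", "lr_sem", "wald_sem"])

    fe = sig("hausman")
    decide("hausman", "fixed effects" if fe else "random effects", ["hausman"])

    ind = sig("lr_individual")
    tim = sig("lr_time")
    if ind and tim:
        eff = "time and individual dual fixed effects"
    elif ind:
        eff = "individual fixed effects"
    elif tim:
        eff = "time fixed effects"
    else:
        eff = "no fixed effects"
    decide("effect_structure", eff, ["lr_individual", "lr_time"])

    effects_phrase = eff if fe else "random effects"
    selected = f"{model} with {effects_phrase}"
    decide("model", selected, [])
    return {"selected_model": selected, "alpha": alpha, "chain": chain}
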