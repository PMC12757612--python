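"""End-to-end analysis pipeline.

Runs, in order: the VIF multicollinearity screen, the plain logistic (BLR)
baseline with its Wald table, the AIC grid search and full cosine-series
fit with simultaneous LRT and Wald tables, the significant-predictor refit,
and the side-by-side model comparison.  Each stage's results are collected
in a report bundle and written as JSON (canonical) plus TSV tables for
human inspection; failures propagate with the stage name while earlier
stages' results are preserved on disk.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import metrics
from .estimation import FitResult, fit_intercept_only, fit_newton
from .inference import lrt_simultaneous, significant_predictors, wald_partial, wald_table
from .io import RunConfig, read_dataset, write_json, write_tsv
from .model_core import ConvergenceOptions, Dataset, OscillationOrders
from .selection import aic, grid_search, refit_significant, vif

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _fit_summary(fit: FitResult) -> dict:
    return {
        "model_kind": fit.model_kind,
        "orders": list(fit.design.orders.K),
        "labels": list(fit.param_labels),
        "theta_hat": fit.theta_hat.flatten().tolist(),
        "loglik": fit.loglik,
        "aic": aic(fit) if fit.converged else None,
        "n_iter": fit.n_iter,
        "converged": fit.converged,
        "trace": list(fit.trace),
    }


def run_pipeline(path, config: RunConfig | None = None,
                 data: Dataset | None = None) -> dict:
    """Run the full analysis on a CSV file (or a pre-built Dataset).

    Returns the report bundle (a plain dict) and writes
    ``report.json``, per-stage TSV tables and ``run.log`` under
    ``config.output_dir``.
    """
    config = config or RunConfig()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    options = ConvergenceOptions()
    bundle: dict = {"config": config.to_dict(), "stages": []}
    log_lines: list[str] = []

    def _log(msg: str) -> None:
        log_lines.append(msg)

    def _finish() -> None:
        write_json(bundle, out / "report.json")
        (out / "run.log").write_text("\n".join(log_lines) + "\n")

    def _stage(name: str):
        bundle["stages"].append(name)
        _log(f"stage: {name}")

    try:
        _stage("read")
        if data is None:
            data = read_dataset(path, config)
        bundle["data"] = {"n": data.n, "p": data.p, "names": list(data.names),
                          "positives": int(data.y.sum())}
        _log(f"n={data.n} p={data.p} positives={int(data.y.sum())} seed={config.seed}")

        _stage("vif")
        if data.p >= 2:
            scores = vif(data.X, data.names)
            bundle["vif"] = {k: float(v) for k, v in scores.items()}
            write_tsv(scores.to_frame(), out / "vif.tsv")
        else:
            bundle["vif"] = None
            _log("vif skipped: single predictor")

        _stage("blr")
        blr_fit = fit_newton(data, OscillationOrders((0,) * data.p), options)
        blr_wald = wald_partial(blr_fit, config.alpha)
        bundle["blr"] = {
            "fit": _fit_summary(blr_fit),
            "wald": wald_table(blr_wald).to_dict(orient="records"),
        }
        write_tsv(wald_table(blr_wald).set_index("Parameters"), out / "blr_wald.tsv")
        _log(f"blr: loglik={blr_fit.loglik:.4f} iter={blr_fit.n_iter}")

        _stage("selection")
        sel = grid_search(data, Kmax=config.Kmax, options=options,
                          mode=config.search_mode,
                          rescale_cosine=config.rescale_cosine)
        sel_df = pd.DataFrame(
            [{"combination": "-".join(map(str, e.orders.K)),
              "AIC": e.aic, "converged": e.converged} for e in sel.grid]
        )
        bundle["selection"] = {
            "best_orders": list(sel.best_orders.K),
            "best_aic": sel.best.aic,
            "n_evaluated": len(sel.grid),
            "mode": sel.mode,
        }
        write_tsv(sel_df.set_index("combination"), out / "selection.tsv")
        _log(f"selection: best K={sel.best_orders.K} AIC={sel.best.aic:.4f}")

        _stage("fsnblr")
        full_fit = fit_newton(data, sel.best_orders, options,
                              rescale_cosine=config.rescale_cosine)
        null_fit = fit_intercept_only(data, options)
        lrt = lrt_simultaneous(full_fit, null_fit, config.alpha)
        full_wald = wald_partial(full_fit, config.alpha)
        bundle["fsnblr"] = {
            "fit": _fit_summary(full_fit),
            "lrt": {"G2": lrt.G2, "df": lrt.df, "p_value": lrt.p_value,
                    "critical_value": lrt.critical_value, "reject": lrt.reject},
            "wald": wald_table(full_wald).to_dict(orient="records"),
        }
        write_tsv(wald_table(full_wald).set_index("Parameters"),
                  out / "fsnblr_wald.tsv")
        _log(f"fsnblr: loglik={full_fit.loglik:.4f} G2={lrt.G2:.4f} df={lrt.df}")

        _stage("refit")
        kept = sorted(significant_predictors(full_wald, config.alpha),
                      key=data.names.index)
        reduced_fit = refit_significant(data, full_fit, alpha=config.alpha,
                                        Kmax=config.Kmax, options=options,
                                        rescale_cosine=config.rescale_cosine)
        bundle["refit"] = {
            "kept_predictors": kept,
            "fit": _fit_summary(reduced_fit),
        }
        if reduced_fit.m > 1:
            write_tsv(wald_table(wald_partial(reduced_fit, config.alpha))
                      .set_index("Parameters"), out / "refit_wald.tsv")
        _log(f"refit: kept={kept} K={reduced_fit.design.orders.K}")

        _stage("compare")
        entries = []
        for name, fit in (("BLR", blr_fit), ("FSNBLR", full_fit),
                          ("FSNBLR_significant", reduced_fit)):
            rep = metrics.report_for_fit(fit, config.cutoff,
                                         config.sensitivity_class)
            entries.append((name, fit, rep))
        comparison = metrics.compare_models(entries)
        bundle["comparison"] = comparison.reset_index().to_dict(orient="records")
        write_tsv(comparison, out / "comparison.tsv")
        _log("compare: done")
    except Exception as exc:  # preserve partial results, then re-raise
        stage = bundle["stages"][-1] if bundle["stages"] else "init"
        bundle["error"] = {"stage": stage, "message": str(exc)}
        _finish()
        raise PipelineError(stage, exc) from exc

    _finish()
    return bundle
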