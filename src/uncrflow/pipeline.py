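"""End-to-end pipeline: decompose → associate → lagscan, with config."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

import uncrflow
from uncrflow import io as uio
from uncrflow.epochs import enumerate_epochs, epoch_regression_profile, profile_frame
from uncrflow.features import (
    MIN_SAMPLES,
    TUKEY_C,
    ParticipantExcluded,
    build_series,
    fit_robust_trend,
    summarize_participant,
)
from uncrflow.models import fit_inflammation_model, stratified_prediction
from uncrflow.plotting import plot_epoch_profile, plot_participant, plot_stratified

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved settings for a full analysis run.

    Every decomposition/model default is overridable here and echoed in
    the run log so reports are self-describing.
    """

    urine_csv: str = ""
    outcome_csv: str = ""
    output_dir: str = "uncrflow_out"
    # IRLS / decomposition
    tuning_constant: float = TUKEY_C
    irls_tol: float = 1e-8
    irls_max_iter: int = 50
    min_samples: int = MIN_SAMPLES
    # epoch scheme
    span_weeks: int = 130
    window_weeks: int = 52
    step_weeks: int = 1
    # model options
    covariates: tuple[str, ...] = ()
    include_interaction: bool = True
    outcome_field: str = "cord_atrophy"
    stratify: str = "median"
    make_plots: bool = True
    # simulation only
    seed: int | None = None

    @classmethod
    def from_mapping(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "covariates" in raw and isinstance(raw["covariates"], str):
            raw = dict(raw)
            raw["covariates"] = tuple(
                c.strip() for c in raw["covariates"].split(",") if c.strip()
            )
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute decompose → associate → lagscan and write the report bundle.

    Returns a dict with the in-memory results; files are written under
    ``config.output_dir``.  Hard errors abort with a stage-labelled
    message; soft exclusions (participants without data in an epoch,
    under-populated epochs) are logged and the run completes.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    _configure_run_log(out / "run.log", config)

    # --- decompose ---------------------------------------------------
    try:
        samples = uio.read_urine_csv(config.urine_csv)
        series_list = build_series(samples)
        summaries = []
        for s in series_list:
            try:
                summaries.append(
                    summarize_participant(
                        s,
                        min_samples=config.min_samples,
                        tuning_constant=config.tuning_constant,
                        tol=config.irls_tol,
                        max_iter=config.irls_max_iter,
                    )
                )
            except ParticipantExcluded as exc:
                logger.warning("decompose: %s", exc)
        uio.write_summary_csv(out / "summaries.csv", summaries)
        if config.make_plots:
            for s in series_list[:5]:  # diagnostic sample, not the whole cohort
                fit = fit_robust_trend(s, tuning_constant=config.tuning_constant,
                                       tol=config.irls_tol, max_iter=config.irls_max_iter,
                                       min_samples=config.min_samples)
                plot_participant(s, fit, out / f"series_{s.participant_id}.png")
    except (OSError, ValueError) as exc:
        raise RuntimeError(f"decompose stage failed: {exc}") from exc

    # --- associate ---------------------------------------------------
    try:
        outcomes = uio.read_outcome_csv(config.outcome_csv)
        have = {s.participant_id for s in summaries}
        outcomes_matched = [o for o in outcomes if o.participant_id in have]
        fit = fit_inflammation_model(
            summaries,
            outcomes_matched,
            outcome_field=config.outcome_field,
            covariates=config.covariates,
        )
        table = fit.summary_frame()
        table.to_csv(out / "model_table.csv")
        (out / "model_table.txt").write_text(_format_model(fit))
        curves = stratified_prediction(fit, summaries, split=config.stratify)
        for name, df in curves.items():
            df.to_csv(out / f"stratified_{name}.csv", index=False)
        if config.make_plots and curves:
            plot_stratified(curves, out / "stratified.png")
    except (OSError, ValueError) as exc:
        raise RuntimeError(f"associate stage failed: {exc}") from exc

    # --- lagscan -----------------------------------------------------
    try:
        exit_dates = {
            str(r.participant_id): uio._parse_date(r.exit_date, 0, config.outcome_csv)
            for r in pd.read_csv(config.outcome_csv).itertuples(index=False)
        }
        exit_days = uio.exit_days_from_dates(samples, outcomes_matched, exit_dates)
        windows = enumerate_epochs(config.span_weeks, config.window_weeks, config.step_weeks)
        matched_series = [s for s in series_list if s.participant_id in {o.participant_id for o in outcomes_matched}]
        profile = epoch_regression_profile(
            matched_series,
            outcomes_matched,
            windows,
            exit_days,
            outcome_field=config.outcome_field,
            include_interaction=config.include_interaction,
            min_samples=config.min_samples,
        )
        pframe = profile_frame(profile)
        pframe.to_csv(out / "epoch_profile.csv", index=False)
        if config.make_plots:
            plot_epoch_profile(profile, out / "epoch_profile.png")
    except (OSError, ValueError) as exc:
        raise RuntimeError(f"lagscan stage failed: {exc}") from exc

    logger.info("pipeline complete; outputs in %s", out)
    return {"summaries": summaries, "model": fit, "stratified": curves, "profile": profile}


def _format_model(fit) -> str:
    lines = [
        f"outcome: {fit.outcome}   n = {fit.n}",
        f"R^2 = {fit.r2:.4f}   F({fit.df_model}, {fit.df_resid}) = {fit.f_stat:.3f}"
        f"   p = {fit.f_pvalue:.4f}",
        "",
        f"{'term':<14}{'B':>12}{'SE':>12}{'std beta':>10}{'t':>9}{'p':>9}"
        f"{'CI low':>12}{'CI high':>12}{'f2':>8}",
    ]
    for t in fit.terms.values():
        lines.append(
            f"{t.name:<14}{t.coef:>12.4g}{t.se:>12.4g}{t.std_beta:>10.3f}"
            f"{t.t:>9.3f}{t.p:>9.4f}{t.ci_low:>12.4g}{t.ci_high:>12.4g}{t.f2:>8.3f}"
        )
    return "\n".join(lines) + "\n"


def _configure_run_log(path: Path, config: PipelineConfig) -> None:
    handler = logging.FileHandler(path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("uncrflow")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    logger.info("uncrflow %s", uncrflow.__version__)
    for f in dataclasses.fields(config):
        logger.info("config %s = %r", f.name, getattr(config, f.name))
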