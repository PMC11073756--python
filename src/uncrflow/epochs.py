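"""Rolling one-year-epoch lag analysis.

To localize the delay between systemic inflammation and cord atrophy,
the two inflammation exposures are re-computed within one-year windows
("epochs") shifted one week at a time, each anchored to the
participant's own study exit.  With the default scheme — a 130-week
span, 52-week windows, one-week steps — there are 79 epochs: the first
spans the year beginning 2.5 years before exit and the last ends on the
day of exit.  For each epoch the interaction model is refitted across
the cohort (participants without enough data in that window are dropped
from that iteration only) and the per-predictor standardized β with its
Wald 95% CI and p-value forms the lag profile.

Window arithmetic uses one year = 52 weeks = 364 days, which is what
makes a 130-week span with weekly steps yield exactly 79 windows;
annualization of the response inside an epoch still uses 365.25
days/year.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from uncrflow.features import (
    MIN_SAMPLES,
    InflammationSummary,
    ParticipantExcluded,
    UNCRSeries,
    summarize_participant,
)
from uncrflow.models import ParticipantOutcome, fit_inflammation_model

logger = logging.getLogger(__name__)

WEEK = 7

DEFAULT_SPAN_WEEKS = 130
DEFAULT_WINDOW_WEEKS = 52
DEFAULT_STEP_WEEKS = 1


@dataclass(frozen=True)
class EpochWindow:
    """One rolling window, in day offsets relative to study exit (≤ 0)."""

    index: int  # 1-based
    start_day: int
    end_day: int

    @property
    def end_weeks_before_exit(self) -> int:
        return -self.end_day // WEEK


@dataclass
class EpochTermResult:
    std_beta: float
    ci_low: float
    ci_high: float
    p: float
    significant: bool


@dataclass
class EpochResult:
    """Per-epoch regression results for the lag profile."""

    window: EpochWindow
    n_included: int
    excluded_ids: list[str]
    fitted: bool
    terms: dict[str, EpochTermResult] = field(default_factory=dict)
    r2: float = float("nan")
    f_pvalue: float = float("nan")


def enumerate_epochs(
    span_weeks: int = DEFAULT_SPAN_WEEKS,
    window_weeks: int = DEFAULT_WINDOW_WEEKS,
    step_weeks: int = DEFAULT_STEP_WEEKS,
) -> list[EpochWindow]:
    """Enumerate rolling windows covering ``span_weeks`` before exit.

    Window k (1-based) spans days ``[-7·(span − (k−1)·step),
    -7·(span − window − (k−1)·step)]``; the count is
    ``floor((span − window)/step) + 1``.  The default scheme gives 79
    one-year epochs over a 2.5-year (130-week) span.
    """
    if window_weeks < 1 or step_weeks < 1:
        raise ValueError("window_weeks and step_weeks must be at least 1")
    if span_weeks < window_weeks:
        raise ValueError("window cannot be longer than the scanned span")
    count = (span_weeks - window_weeks) // step_weeks + 1
    windows = []
    for k in range(1, count + 1):
        start = -WEEK * (span_weeks - (k - 1) * step_weeks)
        end = -WEEK * (span_weeks - window_weeks - (k - 1) * step_weeks)
        windows.append(EpochWindow(index=k, start_day=start, end_day=end))
    return windows


def epoch_features(
    series: UNCRSeries,
    exit_day: float,
    window: EpochWindow,
    *,
    min_samples: int = MIN_SAMPLES,
) -> InflammationSummary:
    """Exposures within one epoch of one participant's series.

    The exit-anchored window is translated into the participant's own
    day offsets via ``exit_day`` (the offset of study exit in series
    coordinates).  Propagates :class:`ParticipantExcluded` when fewer
    than ``min_samples`` samples fall inside the window.
    """
    return summarize_participant(
        series,
        window=(exit_day + window.start_day, exit_day + window.end_day),
        min_samples=min_samples,
    )


def epoch_summaries(
    series_list: Sequence[UNCRSeries],
    windows: Sequence[EpochWindow],
    exit_days: Mapping[str, float] | None = None,
    *,
    min_samples: int = MIN_SAMPLES,
) -> list[tuple[EpochWindow, list[InflammationSummary], list[str]]]:
    """Per-window exposures for a whole cohort.

    Returns one ``(window, summaries, excluded_ids)`` triple per window.
    Useful on its own when many outcome models are to be fitted against
    the same epoch features (the features depend only on the series).
    """
    if exit_days is None:
        exit_days = {s.participant_id: float(s.days[-1]) for s in series_list}
    out = []
    for w in windows:
        summaries: list[InflammationSummary] = []
        excluded: list[str] = []
        for s in series_list:
            try:
                summaries.append(
                    epoch_features(s, exit_days[s.participant_id], w, min_samples=min_samples)
                )
            except ParticipantExcluded:
                excluded.append(s.participant_id)
        out.append((w, summaries, excluded))
    return out


def epoch_regression_profile(
    series_list: Sequence[UNCRSeries],
    outcomes: Sequence[ParticipantOutcome],
    windows: Sequence[EpochWindow] | None = None,
    exit_days: Mapping[str, float] | None = None,
    *,
    outcome_field: str = "cord_atrophy",
    include_interaction: bool = True,
    min_participants: int = 10,
    min_samples: int = MIN_SAMPLES,
    alpha: float = 0.05,
    precomputed: Sequence[tuple[EpochWindow, list[InflammationSummary], list[str]]] | None = None,
) -> list[EpochResult]:
    """Fit the inflammation model within every epoch.

    ``exit_days`` maps participant id to the study-exit offset in that
    participant's series coordinates; when omitted, the last sample day
    is used.  Epochs with fewer than ``min_participants`` included
    participants are flagged (``fitted=False``) rather than fitted; if
    no epoch can be fitted a hard error is raised.

    An epoch is marked significant for a predictor when the two-tailed p
    of its standardized β is below ``alpha``.  ``precomputed`` (from
    :func:`epoch_summaries`) skips re-deriving the epoch features, e.g.
    when refitting many outcome draws against the same series.
    """
    windows = list(windows) if windows is not None else enumerate_epochs()
    out_by_id = {o.participant_id: o for o in outcomes}
    if set(s.participant_id for s in series_list) != set(out_by_id):
        raise ValueError("series and outcomes must cover the same participants")
    if precomputed is None:
        precomputed = epoch_summaries(series_list, windows, exit_days, min_samples=min_samples)

    results: list[EpochResult] = []
    for w, summaries, excluded in precomputed:
        n_inc = len(summaries)
        res = EpochResult(window=w, n_included=n_inc, excluded_ids=excluded, fitted=False)
        if n_inc >= min_participants:
            included_out = [out_by_id[s.participant_id] for s in summaries]
            try:
                fit = _fit_epoch(
                    summaries, included_out, outcome_field, include_interaction, min_participants
                )
            except ValueError as exc:  # e.g. zero-variance predictor in a quiet epoch
                logger.warning("epoch %d not fitted: %s", w.index, exc)
            else:
                res.fitted = True
                res.r2 = fit.r2
                res.f_pvalue = fit.f_pvalue
                for name in fit.terms:
                    if name == "const":
                        continue
                    t = fit.terms[name]
                    sd_ratio = fit.predictor_sd[name] / fit.outcome_sd
                    res.terms[name] = EpochTermResult(
                        std_beta=t.std_beta,
                        ci_low=t.ci_low * sd_ratio,
                        ci_high=t.ci_high * sd_ratio,
                        p=t.p,
                        significant=t.p < alpha,
                    )
        else:
            logger.warning(
                "epoch %d: %d included participants < %d; flagged", w.index, n_inc, min_participants
            )
        results.append(res)
    if not any(r.fitted for r in results):
        raise ValueError("no epoch had enough included participants to fit")
    return results


def _fit_epoch(summaries, outcomes, outcome_field, include_interaction, min_participants):
    if include_interaction:
        return fit_inflammation_model(
            summaries, outcomes, outcome_field, min_participants=min_participants
        )
    # main-effects-only variant: refit via the same machinery on a design
    # where the product term is suppressed by zeroing one factor is not
    # possible, so fall back to a direct two-predictor OLS
    import statsmodels.api as sm

    y = np.array([getattr(o, outcome_field) for o in outcomes], dtype=float)
    X = np.column_stack(
        [[s.background for s in summaries], [s.response for s in summaries]]
    ).astype(float)
    res = sm.OLS(y, sm.add_constant(X)).fit()
    from uncrflow.models import ModelFit, TermStats

    sd_y = float(np.std(y, ddof=1))
    terms = {}
    conf = res.conf_int()
    for j, name in enumerate(["const", "background", "response"]):
        sd_x = float(np.std(X[:, j - 1], ddof=1)) if j else np.nan
        terms[name] = TermStats(
            name=name,
            coef=float(res.params[j]),
            se=float(res.bse[j]),
            std_beta=float(res.params[j] * sd_x / sd_y) if j else np.nan,
            t=float(res.tvalues[j]),
            p=float(res.pvalues[j]),
            ci_low=float(conf[j, 0]),
            ci_high=float(conf[j, 1]),
            f2=np.nan,
        )
    return ModelFit(
        terms=terms,
        r2=float(res.rsquared),
        f_stat=float(res.fvalue),
        df_model=int(res.df_model),
        df_resid=int(res.df_resid),
        f_pvalue=float(res.f_pvalue),
        n=len(y),
        outcome=outcome_field,
        outcome_sd=sd_y,
        predictor_sd={
            "background": float(np.std(X[:, 0], ddof=1)),
            "response": float(np.std(X[:, 1], ddof=1)),
        },
        predictor_mean={
            "background": float(np.mean(X[:, 0])),
            "response": float(np.mean(X[:, 1])),
        },
        _sm_result=res,
        _design_columns=("background", "response"),
    )


def profile_frame(results: Sequence[EpochResult]) -> pd.DataFrame:
    """Flatten a lag profile into a table (one row per epoch)."""
    rows = []
    for r in results:
        row = {
            "epoch": r.window.index,
            "start_day": r.window.start_day,
            "end_day": r.window.end_day,
            "end_weeks_before_exit": r.window.end_weeks_before_exit,
            "n_included": r.n_included,
            "n_excluded": len(r.excluded_ids),
            "fitted": r.fitted,
            "r2": r.r2,
            "f_pvalue": r.f_pvalue,
        }
        for name, t in r.terms.items():
            row[f"{name}_beta"] = t.std_beta
            row[f"{name}_ci_low"] = t.ci_low
            row[f"{name}_ci_high"] = t.ci_high
            row[f"{name}_p"] = t.p
            row[f"{name}_significant"] = t.significant
        rows.append(row)
    return pd.DataFrame(rows)
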