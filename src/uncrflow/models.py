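"""Progression tests and inflammation–atrophy interaction regression.

Atrophy outcomes are stored as signed annualized percentage change
(negative = volume loss).  The primary model is ordinary least squares
of annualized cord (or brain) atrophy on background inflammation, the
inflammatory response and their raw (uncentered) product, optionally
with age and sex as confounding covariates.  For every term the fit
reports the unstandardized coefficient with SE, t and 95% CI, the
standardized β (obtained by z-scoring outcome and each predictor,
including the product term as its own variable), and Cohen's f²
computed by refitting without that term.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from uncrflow.features import InflammationSummary

logger = logging.getLogger(__name__)

PREDICTORS = ("background", "response", "interaction")


@dataclass(frozen=True)
class ParticipantOutcome:
    """Annualized atrophy outcomes plus covariates for one participant."""

    participant_id: str
    cord_atrophy: float  # % change per year, negative = shrinkage
    brain_atrophy: float  # % change per year
    age: float  # years
    sex: int  # 1 = female, 0 = male
    followup_years: float

    def __post_init__(self) -> None:
        # NaN marks follow-up as not-yet-derived (filled in from dates at join time)
        if not (self.followup_years > 0 or np.isnan(self.followup_years)):
            raise ValueError(f"{self.participant_id}: followup_years must be positive")
        if not self.age > 0:
            raise ValueError(f"{self.participant_id}: age must be positive")
        if self.sex not in (0, 1):
            raise ValueError(f"{self.participant_id}: sex must be coded 0 (male) or 1 (female)")


@dataclass
class TermStats:
    """Per-term regression statistics."""

    name: str
    coef: float  # unstandardized B
    se: float
    std_beta: float
    t: float
    p: float  # two-tailed
    ci_low: float
    ci_high: float
    f2: float  # Cohen's f² from dropping the term


@dataclass
class ModelFit:
    """A fitted interaction model with the reporting conventions used here."""

    terms: dict[str, TermStats]
    r2: float
    f_stat: float
    df_model: int
    df_resid: int
    f_pvalue: float
    n: int
    outcome: str
    outcome_sd: float
    predictor_sd: dict[str, float]
    predictor_mean: dict[str, float]
    _sm_result: object = field(repr=False, default=None)
    _design_columns: tuple[str, ...] = ()

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {
                "term": t.name,
                "B": t.coef,
                "SE": t.se,
                "std_beta": t.std_beta,
                "t": t.t,
                "p": t.p,
                "ci_low": t.ci_low,
                "ci_high": t.ci_high,
                "f2": t.f2,
            }
            for t in self.terms.values()
        ]
        return pd.DataFrame(rows).set_index("term")


def annualized_percent_change(v_start: float, v_end: float, years: float) -> float:
    """Percent change from baseline per year of follow-up."""
    if not v_start > 0:
        raise ValueError("baseline value must be positive")
    if not years > 0:
        raise ValueError("follow-up duration must be positive")
    return 100.0 * (v_end - v_start) / v_start / years


def one_sample_progression_test(values: Sequence[float]):
    """One-sample t test of annualized change against zero.

    Returns ``(t, df, p, mean, (ci_low, ci_high))``.  A constant zero
    vector returns ``t=0, p=1`` by convention; a nonzero constant has an
    undefined statistic and raises.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("at least two observations are required")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    n = len(x)
    df = n - 1
    if sd == 0:
        if mean == 0:
            return 0.0, df, 1.0, 0.0, (0.0, 0.0)
        raise ValueError("degenerate variance: all values identical and nonzero")
    se = sd / np.sqrt(n)
    t = mean / se
    p = float(2 * scipy.stats.t.sf(abs(t), df))
    tcrit = scipy.stats.t.ppf(0.975, df)
    return float(t), df, p, mean, (mean - tcrit * se, mean + tcrit * se)


def paired_progression_test(
    baseline: Sequence[float], endpoint: Sequence[float], parametric: bool
):
    """Paired baseline-vs-endpoint test with the matching effect size.

    Parametric: paired t on ``endpoint − baseline`` with Cohen's D =
    mean(diff)/sd(diff).  Non-parametric: Wilcoxon signed-rank with the
    normal approximation (mid-ranks for ties, zero differences dropped)
    and effect size Z/√n where n counts non-zero pairs.  Returns
    ``(statistic, p, effect_size)``.
    """
    b = np.asarray(baseline, dtype=float)
    e = np.asarray(endpoint, dtype=float)
    if b.shape != e.shape:
        raise ValueError("baseline and endpoint must have equal length")
    ok = ~(np.isnan(b) | np.isnan(e))
    b, e = b[ok], e[ok]
    if len(b) < 2:
        raise ValueError("at least two non-missing pairs are required")
    diff = e - b
    if parametric:
        sd = float(np.std(diff, ddof=1))
        if sd == 0:
            raise ValueError("degenerate variance: all paired differences identical")
        res = scipy.stats.ttest_rel(e, b)
        d = float(np.mean(diff)) / sd
        return float(res.statistic), float(res.pvalue), d
    nonzero = diff[diff != 0]
    if len(nonzero) == 0:
        raise ValueError("all paired differences are zero; signed-rank statistic undefined")
    res = scipy.stats.wilcoxon(nonzero, zero_method="wilcox", correction=False, method="approx")
    z = float(res.zstatistic)
    return z, float(res.pvalue), z / np.sqrt(len(nonzero))


def cohens_f2(r2_full: float, r2_reduced: float) -> float:
    """Cohen's f²: ``(R²_full − R²_reduced) / (1 − R²_full)``."""
    if r2_full >= 1:
        raise ValueError("r2_full must be below 1")
    if r2_reduced < 0 or r2_full < 0:
        raise ValueError("R² values must be non-negative")
    if r2_reduced > r2_full:
        raise ValueError("r2_reduced cannot exceed r2_full")
    return (r2_full - r2_reduced) / (1.0 - r2_full)


def _build_design(
    summaries: Sequence[InflammationSummary],
    outcomes: Sequence[ParticipantOutcome],
    outcome_field: str,
    covariates: Iterable[str],
) -> pd.DataFrame:
    covariates = tuple(covariates)
    bad = set(covariates) - {"age", "sex"}
    if bad:
        raise ValueError(f"unsupported covariates: {sorted(bad)} (allowed: age, sex)")
    s_ids = {s.participant_id for s in summaries}
    o_ids = {o.participant_id for o in outcomes}
    unmatched = sorted(s_ids ^ o_ids)
    if unmatched:
        raise ValueError(f"participants present on only one side of the join: {unmatched}")
    out_by_id = {o.participant_id: o for o in outcomes}
    rows = []
    for s in summaries:
        o = out_by_id[s.participant_id]
        row = {
            "participant_id": s.participant_id,
            "y": getattr(o, outcome_field),
            "background": s.background,
            "response": s.response,
            "interaction": s.background * s.response,
        }
        for c in covariates:
            row[c] = getattr(o, c)
        rows.append(row)
    return pd.DataFrame(rows).set_index("participant_id")


def fit_inflammation_model(
    summaries: Sequence[InflammationSummary],
    outcomes: Sequence[ParticipantOutcome],
    outcome_field: str = "cord_atrophy",
    covariates: Iterable[str] = (),
    *,
    min_participants: int = 10,
) -> ModelFit:
    """OLS of an atrophy outcome on background, response and their product.

    The interaction enters as the raw (uncentered) product of the two
    exposures, treated as its own variable when standardizing — which is
    why standardized βs may legitimately exceed 1 in magnitude.  Per-term
    Cohen's f² compares the full model's R² with the R² of the model
    refitted without that term.
    """
    df = _build_design(summaries, outcomes, outcome_field, covariates)
    n = len(df)
    if n < min_participants:
        raise ValueError(f"only {n} matched participants; need at least {min_participants}")
    x_cols = [c for c in df.columns if c != "y"]
    for c in x_cols:
        if np.std(df[c].to_numpy()) == 0:
            raise ValueError(f"predictor {c!r} has zero variance")
    X = df[x_cols].to_numpy(dtype=float)
    y = df["y"].to_numpy(dtype=float)
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        # identify offending columns by near-perfect multiple correlation
        offenders = []
        for j, name in enumerate(x_cols):
            others = np.delete(X, j, axis=1)
            resid = X[:, j] - sm.add_constant(others) @ np.linalg.lstsq(
                sm.add_constant(others), X[:, j], rcond=None
            )[0]
            if np.allclose(resid, 0, atol=1e-8 * max(1.0, np.abs(X[:, j]).max())):
                offenders.append(name)
        raise ValueError(f"rank-deficient design; collinear terms: {offenders or x_cols}")

    res = sm.OLS(y, Xc).fit()
    r2_full = float(res.rsquared)
    sd_y = float(np.std(y, ddof=1))
    conf = res.conf_int(alpha=0.05)

    terms: dict[str, TermStats] = {}
    names = ["const"] + x_cols
    for j, name in enumerate(names):
        if name == "const":
            f2 = np.nan
            std_beta = np.nan
        else:
            xj = X[:, j - 1]
            std_beta = float(res.params[j] * np.std(xj, ddof=1) / sd_y)
            reduced = np.delete(Xc, j, axis=1)
            beta_r, *_ = np.linalg.lstsq(reduced, y, rcond=None)
            resid_r = y - reduced @ beta_r
            ss_tot = float(np.sum((y - y.mean()) ** 2))
            r2_reduced = 1.0 - float(np.sum(resid_r**2)) / ss_tot
            if r2_full >= 1.0 - 1e-12:
                # perfect fit: f² diverges for any term that carries signal
                f2 = np.inf if r2_reduced < r2_full else 0.0
            else:
                f2 = cohens_f2(r2_full, min(r2_reduced, r2_full))
        terms[name] = TermStats(
            name=name,
            coef=float(res.params[j]),
            se=float(res.bse[j]),
            std_beta=std_beta,
            t=float(res.tvalues[j]),
            p=float(res.pvalues[j]),
            ci_low=float(conf[j, 0]),
            ci_high=float(conf[j, 1]),
            f2=float(f2) if f2 == f2 else np.nan,
        )

    return ModelFit(
        terms=terms,
        r2=r2_full,
        f_stat=float(res.fvalue),
        df_model=int(res.df_model),
        df_resid=int(res.df_resid),
        f_pvalue=float(res.f_pvalue),
        n=n,
        outcome=outcome_field,
        outcome_sd=sd_y,
        predictor_sd={c: float(np.std(df[c].to_numpy(), ddof=1)) for c in x_cols},
        predictor_mean={c: float(np.mean(df[c].to_numpy())) for c in x_cols},
        _sm_result=res,
        _design_columns=tuple(x_cols),
    )


def _tertile_bounds(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Lower/upper tertile membership by rank: the lowest floor(n/3)
    values and the highest ceil(n/3) values (so n=49 gives 16 and 17)."""
    n = len(values)
    order = np.argsort(values, kind="stable")
    n_low = n // 3
    n_high = -(-n // 3)  # ceil
    low = np.zeros(n, dtype=bool)
    high = np.zeros(n, dtype=bool)
    low[order[:n_low]] = True
    high[order[n - n_high:]] = True
    return low, high


def stratified_prediction(
    fit: ModelFit,
    summaries: Sequence[InflammationSummary],
    split: str = "median",
    *,
    n_points: int = 50,
) -> dict[str, pd.DataFrame]:
    """Predicted atrophy vs response for background strata, with 95% CI.

    Visualizes the moderation: for each stratum of background
    inflammation (``median`` halves or lower/upper ``tertile``), the
    fitted surface is evaluated over the stratum's observed response
    range at the stratum's mean background.  Strata with fewer than 3
    participants are skipped with a warning.
    """
    if "interaction" not in fit.terms:
        raise ValueError("stratified prediction requires a fitted interaction term")
    if split not in ("median", "tertile"):
        raise ValueError("split must be 'median' or 'tertile'")
    bg = np.array([s.background for s in summaries])
    resp = np.array([s.response for s in summaries])
    if split == "median":
        med = float(np.median(bg))
        if np.any(bg == med):
            logger.info("background values equal to the median assigned to the lower stratum")
        strata = {"below_median": bg <= med, "above_median": bg > med}
    else:
        low, high = _tertile_bounds(bg)
        strata = {"lower_tertile": low, "upper_tertile": high}

    covariate_cols = [c for c in fit._design_columns if c not in PREDICTORS]
    out: dict[str, pd.DataFrame] = {}
    for name, mask in strata.items():
        if mask.sum() < 3:
            logger.warning("stratum %s has %d participants; skipped", name, int(mask.sum()))
            continue
        bg_mean = float(np.mean(bg[mask]))
        r_grid = np.linspace(resp[mask].min(), resp[mask].max(), n_points)
        cols = {"background": np.full(n_points, bg_mean), "response": r_grid,
                "interaction": bg_mean * r_grid}
        for c in covariate_cols:
            cols[c] = np.full(n_points, fit.predictor_mean[c])
        Xg = np.column_stack([np.ones(n_points)] + [cols[c] for c in fit._design_columns])
        pred = fit._sm_result.get_prediction(Xg)
        frame = pred.summary_frame(alpha=0.05)
        out[name] = pd.DataFrame(
            {
                "response": r_grid,
                "predicted": frame["mean"].to_numpy(),
                "ci_low": frame["mean_ci_lower"].to_numpy(),
                "ci_high": frame["mean_ci_upper"].to_numpy(),
                "background": bg_mean,
                "n": int(mask.sum()),
            }
        )
    return out
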