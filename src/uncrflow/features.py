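"""UNCR time-series decomposition into background inflammation and response.

The urinary neopterin-to-creatinine ratio (UNCR, µmol neopterin per mol
creatinine) profile of a participant is modelled as a slowly drifting
background level with superimposed short-term peaks.  The two exposures
derived here are:

* **background inflammation** — the value of a robust (IRLS, Tukey
  bisquare) straight-line trend at the temporal midpoint of the
  observation span.  Robust weighting keeps inflammatory peaks from
  pulling the trend upward.
* **inflammatory response** — the annualized trapezoidal area under the
  curve of percent heights above the fitted trend (%·days per year).
  Points at or below the trend contribute height 0, so the response is
  non-negative and driven entirely by supra-trend excursions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Tukey bisquare tuning constant giving 95% efficiency at the normal model.
TUKEY_C = 4.685

#: Scale factor turning a median absolute deviation into a normal-consistent
#: scale estimate (1/Phi^-1(0.75)).
MAD_NORMALIZE = 0.6744897501960817

#: Minimum number of samples for any trend fit: two coefficients plus two
#: residual degrees of freedom.
MIN_SAMPLES = 4

DAYS_PER_YEAR = 365.25


class ParticipantExcluded(Exception):
    """Soft signal: a participant lacks enough data in the requested window.

    Callers performing per-window scans catch this and drop the
    participant from that iteration only; it is deliberately distinct
    from hard validation errors.
    """


@dataclass(frozen=True)
class UrineSample:
    """One raw urine measurement.

    Neopterin is in nmol/L and creatinine in mmol/L so that their ratio
    is natively µmol neopterin per mol creatinine.
    """

    participant_id: str
    collection_date: date
    neopterin: float
    creatinine: float

    def __post_init__(self) -> None:
        if self.collection_date is None:
            raise ValueError(f"sample for {self.participant_id!r} has no date")
        if not self.neopterin > 0 or not self.creatinine > 0:
            raise ValueError(
                f"sample for {self.participant_id!r} on {self.collection_date}: "
                f"neopterin ({self.neopterin}) and creatinine ({self.creatinine}) "
                "must both be positive"
            )


@dataclass
class UNCRSeries:
    """A participant's dated UNCR values, the unit of decomposition.

    ``days`` are integer offsets from the first sample (``days[0] == 0``),
    strictly increasing; ``values`` are UNCR in µmol/mol, all positive.
    """

    participant_id: str
    days: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.days.shape != self.values.shape or self.days.ndim != 1:
            raise ValueError("days and values must be 1-d arrays of equal length")
        if len(self.days) and self.days[0] != 0:
            raise ValueError("day offsets must start at 0 (offsets from first sample)")
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("days must be strictly increasing")
        if np.any(self.values <= 0):
            raise ValueError("all UNCR values must be strictly positive")

    def __len__(self) -> int:
        return len(self.days)

    def restrict(self, start_day: float, end_day: float) -> "UNCRSeries":
        """Sub-series with ``start_day <= day <= end_day``, re-anchored to 0.

        Raises :class:`ParticipantExcluded` if fewer than two samples fall
        in the window (no series can be formed).
        """
        mask = (self.days >= start_day) & (self.days <= end_day)
        if mask.sum() < 2:
            raise ParticipantExcluded(
                f"{self.participant_id}: {int(mask.sum())} sample(s) in "
                f"[{start_day}, {end_day}]"
            )
        days = self.days[mask]
        return UNCRSeries(self.participant_id, days - days[0], self.values[mask])


@dataclass
class TrendFit:
    """Robust straight-line trend of UNCR on study day."""

    slope: float  # µmol/mol per day
    intercept: float  # µmol/mol at day 0
    midpoint_value: float  # fitted value at the temporal midpoint
    final_weights: np.ndarray  # per-point bisquare weights in [0, 1]
    n_iter: int
    converged: bool

    def predict(self, days: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(days, dtype=float)


@dataclass
class InflammationSummary:
    """The two derived exposures for one participant over one window."""

    participant_id: str
    background: float  # µmol/mol
    response: float  # %·days per year
    window_start_day: float
    window_end_day: float
    n_samples: int


def compute_uncr(sample: UrineSample) -> float:
    """Neopterin-to-creatinine ratio in µmol/mol.

    nmol/L divided by mmol/L is dimensionally µmol per mol, so no unit
    factor is applied.
    """
    # positivity enforced by UrineSample, but guard for raw inputs
    if not sample.neopterin > 0 or not sample.creatinine > 0:
        raise ValueError(
            f"sample for {sample.participant_id!r} on {sample.collection_date}: "
            "non-positive concentration"
        )
    return sample.neopterin / sample.creatinine


def build_series(samples: Sequence[UrineSample]) -> list[UNCRSeries]:
    """Group raw samples by participant into UNCR series.

    Samples are sorted by date; duplicate same-day samples are averaged
    (the sampling protocol is one sample per week, so duplicates are
    protocol deviations) with a warning.
    """
    by_pid: dict[str, list[UrineSample]] = {}
    for s in samples:
        by_pid.setdefault(s.participant_id, []).append(s)
    out = []
    for pid, group in by_pid.items():
        group.sort(key=lambda s: s.collection_date)
        dates: list[date] = []
        values: list[float] = []
        for s in group:
            v = compute_uncr(s)
            if dates and s.collection_date == dates[-1]:
                logger.warning(
                    "participant %s: duplicate sample on %s averaged", pid, s.collection_date
                )
                values[-1] = (values[-1] + v) / 2.0
            else:
                dates.append(s.collection_date)
                values.append(v)
        days = np.array([(d - dates[0]).days for d in dates], dtype=float)
        out.append(UNCRSeries(pid, days, np.array(values)))
    return out


def _bisquare_weights(resid: np.ndarray, scale: float, c: float) -> np.ndarray:
    u = resid / (c * scale)
    w = np.zeros_like(u)
    inside = np.abs(u) < 1.0
    w[inside] = (1.0 - u[inside] ** 2) ** 2
    return w


def fit_robust_trend(
    series: UNCRSeries,
    *,
    tuning_constant: float = TUKEY_C,
    tol: float = 1e-8,
    max_iter: int = 50,
    min_samples: int = MIN_SAMPLES,
) -> TrendFit:
    """Fit a straight line to UNCR values by iteratively reweighted least squares.

    Residuals are scaled by the normalized median absolute deviation and
    weighted with the Tukey bisquare function (tuning constant
    ``tuning_constant`` times the robust scale), so inflammatory peaks
    receive weight near zero and the line tracks the background level.
    Iteration stops when the relative coefficient change falls below
    ``tol`` or after ``max_iter`` rounds (then ``converged=False``; no
    exception).

    The reported ``midpoint_value`` is the fitted value at the temporal
    midpoint ``(days[0] + days[-1]) / 2`` of the observation span — the
    single-number background summary.
    """
    days, values = series.days, series.values
    if len(days) < min_samples:
        raise ParticipantExcluded(
            f"{series.participant_id}: {len(days)} samples < min_samples={min_samples}"
        )
    if np.ptp(days) == 0:
        raise ValueError("degenerate design: all samples share one day value")

    X = np.column_stack([np.ones_like(days), days])
    beta, *_ = np.linalg.lstsq(X, values, rcond=None)
    w = np.ones_like(values)
    converged = False
    n_iter = 0
    # scale below floating-point noise relative to the data means the line
    # interpolates the majority of points exactly
    eps_scale = 1e-12 * max(1.0, float(np.median(np.abs(values))))
    for n_iter in range(1, max_iter + 1):
        resid = values - X @ beta
        scale = np.median(np.abs(resid)) / MAD_NORMALIZE
        if scale <= eps_scale:
            # (near-)exact fit: unit weight on interpolated points, zero on
            # gross outliers; reweighting on numerical noise is meaningless
            w = (np.abs(resid) <= 6.0 * max(scale, eps_scale)).astype(float)
            converged = True
            break
        w = _bisquare_weights(resid, scale, tuning_constant)
        if w.sum() == 0:  # pathological: keep previous estimate
            break
        sw = np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(X * sw[:, None], values * sw, rcond=None)
        delta = np.max(
            np.abs(beta_new - beta) / np.maximum(np.abs(beta), np.abs(beta_new) + 1e-300)
        )
        beta = beta_new
        if delta < tol:
            converged = True
            break

    intercept, slope = float(beta[0]), float(beta[1])
    mid_day = (days[0] + days[-1]) / 2.0
    return TrendFit(
        slope=slope,
        intercept=intercept,
        midpoint_value=intercept + slope * mid_day,
        final_weights=w,
        n_iter=n_iter,
        converged=converged,
    )


def peak_height_series(series: UNCRSeries, fit: TrendFit) -> np.ndarray:
    """Percent height of each sample above the fitted trend.

    ``height_i = 100 * (value_i - predicted_i) / predicted_i`` where the
    value exceeds the prediction, else 0: only supra-trend excursions
    count as inflammatory response, and sub-trend points serve as zero
    nodes that bound each peak's integral.
    """
    predicted = fit.predict(series.days)
    if np.any(predicted <= 0):
        raise ValueError(
            f"{series.participant_id}: trend prediction non-positive at some sample "
            "days; inspect the trend fit before computing peak heights"
        )
    heights = 100.0 * (series.values - predicted) / predicted
    # relative excesses at floating-point noise level (≪ any biological
    # signal) are treated as exactly on the line, so noiseless series
    # report a response of exactly zero
    heights[heights < 1e-9] = 0.0
    return np.where(heights > 0, heights, 0.0)


def inflammatory_response_auc(
    days: np.ndarray, heights: np.ndarray, *, annualize: bool = True
) -> float:
    """Trapezoidal area under the percent-height curve, optionally per year.

    Integration uses the actual (possibly gapped) day offsets.  When
    ``annualize`` is set the area is scaled by ``365.25 / span`` so
    cohorts with unequal follow-up are comparable.
    """
    days = np.asarray(days, dtype=float)
    heights = np.asarray(heights, dtype=float)
    if len(days) < 2:
        raise ValueError("at least two points are required for a trapezoidal area")
    if np.any(np.diff(days) <= 0):
        raise ValueError("days must be strictly increasing")
    if np.any(heights < 0):
        raise ValueError("heights must be non-negative")
    auc = float(np.trapezoid(heights, days))
    if annualize:
        auc *= DAYS_PER_YEAR / (days[-1] - days[0])
    return auc


def summarize_participant(
    series: UNCRSeries,
    window: tuple[float, float] | None = None,
    *,
    min_samples: int = MIN_SAMPLES,
    tuning_constant: float = TUKEY_C,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> InflammationSummary:
    """Background and annualized response for one participant.

    When ``window=(start_day, end_day)`` is given the series is first
    restricted to samples with ``start_day <= day <= end_day`` (used by
    the rolling-epoch analysis).  If fewer than ``min_samples`` samples
    remain, :class:`ParticipantExcluded` is raised so scans can drop the
    participant from that iteration rather than abort.
    """
    if window is not None:
        start, end = window
        restricted = series.restrict(start, end)
    else:
        start, end = series.days[0], series.days[-1]
        restricted = series
    if len(restricted) < min_samples:
        raise ParticipantExcluded(
            f"{series.participant_id}: {len(restricted)} samples in window "
            f"[{start}, {end}] < min_samples={min_samples}"
        )
    fit = fit_robust_trend(
        restricted,
        tuning_constant=tuning_constant,
        tol=tol,
        max_iter=max_iter,
        min_samples=min_samples,
    )
    heights = peak_height_series(restricted, fit)
    response = inflammatory_response_auc(restricted.days, heights, annualize=True)
    return InflammationSummary(
        participant_id=series.participant_id,
        background=fit.midpoint_value,
        response=response,
        window_start_day=float(start),
        window_end_day=float(end),
        n_samples=len(restricted),
    )
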