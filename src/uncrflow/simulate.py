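"""Synthetic longitudinal UNCR cohorts with known ground truth.

The generator emulates the structure the analysis assumes: each
participant contributes a weekly first-morning UNCR series composed of

* a background level with slow linear drift,
* episodic short-term peaks (homogeneous onsets, exponentially
  distributed multiplicative amplitudes, one-week linear rise then
  exponential decay), and
* multiplicative lognormal noise with unit median,

with each scheduled sample independently missing with a configurable
probability.  Atrophy outcomes are produced by a linear model in the
participant's *true* background and *true* annualized response (and
their product), so parameter-recovery and coverage experiments have an
exact ground truth, returned as a :class:`SimulationTruth` record.

A lagged variant feeds the outcome model exposures computed only from
the series truncated a fixed number of weeks before study exit, giving
the rolling-epoch scan a known causal delay to detect.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
import numpy as np

from uncrflow.features import DAYS_PER_YEAR, UNCRSeries
from uncrflow.models import ParticipantOutcome

WEEK = 7


@dataclass(frozen=True)
class SeriesParams:
    """Generating parameters for one participant's UNCR series.

    Amplitudes are multiplicative: ``peak_amplitude_mean = 1.0`` means
    peaks average +100% of the local background at their maximum.
    ``noise_cv`` is the coefficient of variation of the lognormal
    multiplicative noise (unit median).
    """

    background_level: float = 195.8  # µmol/mol
    drift_slope: float = 0.0  # µmol/mol per year
    peak_rate: float = 2.0  # expected peak onsets per year
    peak_amplitude_mean: float = 1.0  # fraction of background at peak maximum
    peak_decay_halflife: float = 7.0  # days
    noise_cv: float = 0.15
    missing_prob: float = 0.12
    followup_days: int = 949  # ~2.6 years

    def __post_init__(self) -> None:
        if not self.background_level > 0:
            raise ValueError("background_level must be positive")
        if self.peak_rate < 0:
            raise ValueError("peak_rate must be non-negative")
        if not 0 <= self.missing_prob < 1:
            raise ValueError("missing_prob must be in [0, 1)")
        if self.followup_days < 365:
            raise ValueError("followup_days must be at least 365")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.peak_amplitude_mean < 0:
            raise ValueError("peak_amplitude_mean must be non-negative")
        if not self.peak_decay_halflife > 0:
            raise ValueError("peak_decay_halflife must be positive")
        trend_end = self.background_level + self.drift_slope * self.followup_days / DAYS_PER_YEAR
        if trend_end <= 0:
            raise ValueError("drift drives the background non-positive within follow-up")


@dataclass(frozen=True)
class OutcomeParams:
    """Linear outcome model: atrophy (%/year) from true exposures.

    ``outcome = intercept + coef_background*BG + coef_response*RESP +
    coef_interaction*BG*RESP + Normal(0, noise_sd)``.  Defaults are the
    unstandardized coefficients of the cervical-cord model; the residual
    SD is a generator tuning default chosen so the model explains a
    realistically small share of outcome variance at n≈50.
    """

    intercept: float = 5.815
    coef_background: float = -4.525e-2
    coef_response: float = -1.55e-3
    coef_interaction: float = 8.91e-6
    noise_sd: float = 0.9  # %/year

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def expected(self, background: float, response: float) -> float:
        return (
            self.intercept
            + self.coef_background * background
            + self.coef_response * response
            + self.coef_interaction * background * response
        )


#: Brain-atrophy analogue of the outcome model (secondary outcome); the
#: weak coefficients make brain atrophy essentially noise-dominated.
BRAIN_OUTCOME = OutcomeParams(
    intercept=0.145,
    coef_background=-1.77e-3,
    coef_response=-7.18e-5,
    coef_interaction=1.91e-7,
    noise_sd=0.45,
)


@dataclass(frozen=True)
class CohortDistribution:
    """Population distributions from which per-participant params are drawn.

    Background levels are lognormal around ``background_median`` with
    geometric SD ``background_gsd``; drift slopes are Normal(0,
    ``drift_sd``); follow-up durations are uniform on
    ``followup_years_range``.  Peak-process, noise and missingness
    settings are shared by all participants.
    """

    background_median: float = 195.8  # µmol/mol
    background_gsd: float = 1.35  # geometric SD (unitless, > 1)
    drift_sd: float = 8.0  # µmol/mol per year
    peak_rate: float = 2.0
    peak_amplitude_mean: float = 1.0
    peak_decay_halflife: float = 7.0
    noise_cv: float = 0.15
    missing_prob: float = 0.12
    followup_years_range: tuple[float, float] = (1.3, 3.2)
    age_mean: float = 53.4
    age_sd: float = 8.0
    female_prob: float = 0.58

    def draw_series_params(self, rng: np.random.Generator) -> SeriesParams:
        background = float(self.background_median * rng.lognormal(0.0, np.log(self.background_gsd)))
        followup_years = float(rng.uniform(*self.followup_years_range))
        followup_days = int(round(followup_years * DAYS_PER_YEAR))
        # keep drift from driving the trend negative over follow-up
        drift = float(rng.normal(0.0, self.drift_sd))
        max_drop = -0.8 * background / (followup_days / DAYS_PER_YEAR)
        drift = max(drift, max_drop)
        return SeriesParams(
            background_level=background,
            drift_slope=drift,
            peak_rate=self.peak_rate,
            peak_amplitude_mean=self.peak_amplitude_mean,
            peak_decay_halflife=self.peak_decay_halflife,
            noise_cv=self.noise_cv,
            missing_prob=self.missing_prob,
            followup_days=followup_days,
        )


@dataclass
class ParticipantTruth:
    """Generating values for one synthetic participant."""

    participant_id: str
    background_true: float
    response_true: float
    expected_outcome: float
    peak_times: list[float]
    peak_amplitudes: list[float]
    followup_days: int
    exit_day: float  # exit offset in the emitted series' day coordinates
    first_day_offset: float  # scheduled day of the first retained sample
    truncation_day: float | None = None  # series day at which exposures were cut (lagged)


@dataclass
class SimulationTruth:
    """Ground truth for a generated cohort; regenerating with the same
    seed reproduces it exactly."""

    seed: int
    lag_weeks: int
    participants: list[ParticipantTruth] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimulationTruth":
        raw = json.loads(text)
        parts = [ParticipantTruth(**p) for p in raw.pop("participants")]
        return cls(participants=parts, **raw)


def _peak_component(t: np.ndarray, times: np.ndarray, amps: np.ndarray, halflife: float) -> np.ndarray:
    """Sum of peak shapes at times ``t``: linear 1-week rise to the
    amplitude, then exponential decay with the given half-life."""
    if len(times) == 0:
        return np.zeros_like(t, dtype=float)
    dt = t[:, None] - times[None, :]
    shape = np.zeros_like(dt)
    rising = (dt >= 0) & (dt < WEEK)
    shape[rising] = dt[rising] / WEEK
    decaying = dt >= WEEK
    shape[decaying] = np.exp(-np.log(2.0) * (dt[decaying] - WEEK) / halflife)
    return shape @ amps


def _true_exposures(
    params: SeriesParams,
    times: np.ndarray,
    amps: np.ndarray,
    end_day: float,
) -> tuple[float, float]:
    """Noise-free background and annualized response over [0, end_day].

    Background is the true trend's value at the span midpoint.  The
    response is the annualized trapezoid of the true percent-height
    curve evaluated on the full weekly grid (no missingness), i.e. what
    the estimator would recover from complete, noise-free data.
    """
    grid = np.arange(0.0, end_day + 1e-9, WEEK)
    background = params.background_level + params.drift_slope * (grid[-1] / 2.0) / DAYS_PER_YEAR
    inside = times < grid[-1]
    heights = 100.0 * _peak_component(grid, times[inside], amps[inside], params.peak_decay_halflife)
    auc = float(np.trapezoid(heights, grid))
    response = auc * DAYS_PER_YEAR / (grid[-1] - grid[0])
    return float(background), response


def _simulate_series(
    params: SeriesParams, rng: np.random.Generator, participant_id: str = "P0"
) -> tuple[UNCRSeries, np.ndarray, np.ndarray, float]:
    """Draw one series; returns (series, peak_times, peak_amps, first_day_offset)."""
    grid = np.arange(0.0, params.followup_days + 1e-9, WEEK)
    span_years = params.followup_days / DAYS_PER_YEAR
    n_peaks = rng.poisson(params.peak_rate * span_years)
    times = np.sort(rng.uniform(0.0, params.followup_days, size=n_peaks))
    amps = (
        rng.exponential(params.peak_amplitude_mean, size=n_peaks)
        if params.peak_amplitude_mean > 0
        else np.zeros(n_peaks)
    )
    trend = params.background_level + params.drift_slope * grid / DAYS_PER_YEAR
    peaks = _peak_component(grid, times, amps, params.peak_decay_halflife)
    if params.noise_cv > 0:
        sigma = np.sqrt(np.log1p(params.noise_cv**2))
        noise = rng.lognormal(0.0, sigma, size=grid.shape)
    else:
        noise = np.ones_like(grid)
    values = trend * (1.0 + peaks) * noise
    keep = rng.uniform(size=grid.shape) >= params.missing_prob
    if keep.sum() < 2:
        raise RuntimeError("missingness left fewer than two samples; raise followup or lower missing_prob")
    days = grid[keep]
    first = days[0]
    series = UNCRSeries(participant_id, days - first, values[keep])
    return series, times, amps, float(first)


def generate_uncr_series(params: SeriesParams, seed: int) -> UNCRSeries:
    """Generate one participant's weekly UNCR series.

    Values are ``(background + drift·t/365.25) · (1 + Σ peaks) · noise``
    on the weekly grid ``0, 7, …, ≤ followup_days``, with each sample
    independently dropped with ``missing_prob``; day offsets are
    re-anchored to the first retained sample.  Identical ``(params,
    seed)`` give identical output.
    """
    rng = np.random.default_rng(seed)
    series, *_ = _simulate_series(params, rng)
    return series


def generate_lagged_cohort(
    n: int,
    distribution: CohortDistribution | None = None,
    outcome_params: OutcomeParams | None = None,
    lag_weeks: int = 0,
    seed: int = 0,
    *,
    brain_outcome_params: OutcomeParams = BRAIN_OUTCOME,
) -> tuple[list[UNCRSeries], list[ParticipantOutcome], SimulationTruth]:
    """Cohort whose outcomes depend only on inflammation up to a cutoff.

    Identical to :func:`generate_cohort` except that the background and
    response entering the outcome model are computed from the series
    truncated at ``exit − lag_weeks·7`` days, so downstream epoch scans
    have a known lag to localize.  ``lag_weeks=0`` reduces exactly to
    the unlagged generator.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if lag_weeks < 0:
        raise ValueError("lag_weeks must be non-negative")
    distribution = distribution or CohortDistribution()
    outcome_params = outcome_params or OutcomeParams()
    rng = np.random.default_rng(seed)
    width = len(str(max(n - 1, 1)))

    series_list: list[UNCRSeries] = []
    outcomes: list[ParticipantOutcome] = []
    truth = SimulationTruth(seed=seed, lag_weeks=lag_weeks)
    for i in range(n):
        pid = f"SIM{i:0{width}d}"
        params = distribution.draw_series_params(rng)
        if lag_weeks * WEEK >= params.followup_days:
            raise ValueError(
                f"lag of {lag_weeks} weeks is not shorter than participant "
                f"{pid}'s follow-up of {params.followup_days} days"
            )
        series, times, amps, first = _simulate_series(params, rng, pid)
        cutoff = params.followup_days - lag_weeks * WEEK
        bg, resp = _true_exposures(params, times, amps, cutoff)
        expected = outcome_params.expected(bg, resp)
        cord = expected + (rng.normal(0.0, outcome_params.noise_sd) if outcome_params.noise_sd else 0.0)
        brain = brain_outcome_params.expected(bg, resp) + (
            rng.normal(0.0, brain_outcome_params.noise_sd) if brain_outcome_params.noise_sd else 0.0
        )
        age = float(np.clip(rng.normal(distribution.age_mean, distribution.age_sd), 18.0, 70.0))
        sex = int(rng.uniform() < distribution.female_prob)
        followup_years = params.followup_days / DAYS_PER_YEAR
        series_list.append(series)
        outcomes.append(
            ParticipantOutcome(
                participant_id=pid,
                cord_atrophy=float(cord),
                brain_atrophy=float(brain),
                age=age,
                sex=sex,
                followup_years=followup_years,
            )
        )
        truth.participants.append(
            ParticipantTruth(
                participant_id=pid,
                background_true=bg,
                response_true=resp,
                expected_outcome=expected,
                peak_times=[float(t) for t in times],
                peak_amplitudes=[float(a) for a in amps],
                followup_days=params.followup_days,
                exit_day=params.followup_days - first,
                first_day_offset=first,
                truncation_day=(cutoff - first) if lag_weeks else None,
            )
        )
    return series_list, outcomes, truth


def generate_cohort(
    n: int,
    distribution: CohortDistribution | None = None,
    outcome_params: OutcomeParams | None = None,
    seed: int = 0,
) -> tuple[list[UNCRSeries], list[ParticipantOutcome], SimulationTruth]:
    """Generate a full synthetic cohort (series, outcomes, ground truth).

    Outcomes are the linear model applied to each participant's true
    full-span exposures plus Gaussian noise; ages and binary sex come
    from the cohort distribution.
    """
    return generate_lagged_cohort(n, distribution, outcome_params, lag_weeks=0, seed=seed)
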