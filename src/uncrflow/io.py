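"""CSV/JSON readers and writers for the pipeline's file interfaces.

The on-disk dialect is plain UTF-8 comma-separated text with ISO-8601
dates.  Urine samples: ``participant_id, date, neopterin_nmol_per_L,
creatinine_mmol_per_L`` (one row per sample).  Outcomes:
``participant_id, cord_atrophy_pct_per_year, brain_atrophy_pct_per_year,
age_years, sex, exit_date`` plus an optional ``followup_years`` column
(written by the simulator; otherwise derived from the dates at join
time).  Sex accepts F/M, female/male or 1/0 and is stored as 1 = female.
"""

from __future__ import annotations

import datetime as dt
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from uncrflow.features import UNCRSeries, UrineSample, build_series
from uncrflow.models import ParticipantOutcome
from uncrflow.simulate import SimulationTruth

logger = logging.getLogger(__name__)

URINE_COLUMNS = ["participant_id", "date", "neopterin_nmol_per_L", "creatinine_mmol_per_L"]
OUTCOME_COLUMNS = [
    "participant_id",
    "cord_atrophy_pct_per_year",
    "brain_atrophy_pct_per_year",
    "age_years",
    "sex",
    "exit_date",
]

SEX_CODES = {"f": 1, "female": 1, "1": 1, "m": 0, "male": 0, "0": 0}

#: Simulated cohorts are given calendar dates by anchoring day 0 here.
SIM_EPOCH = dt.date(2015, 1, 5)


class SchemaError(ValueError):
    """A file does not match the documented column contract."""


class RowError(ValueError):
    """A row failed validation; the message cites the 1-based data line."""


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {missing}")


def _parse_date(value, line: int, path) -> dt.date:
    try:
        return dt.date.fromisoformat(str(value).strip())
    except ValueError as exc:
        raise RowError(f"{path} line {line}: unparseable ISO-8601 date {value!r}") from exc


def read_urine_csv(path) -> list[UrineSample]:
    """Read and validate a urine-sample table.

    Duplicate (participant, date) rows are averaged with a warning; rows
    with non-positive concentrations are rejected with their line number.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, URINE_COLUMNS, path)
    samples: list[UrineSample] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 is the header
        d = _parse_date(row.date, i, path)
        neo = float(row.neopterin_nmol_per_L)
        cre = float(row.creatinine_mmol_per_L)
        if not neo > 0 or not cre > 0:
            raise RowError(
                f"{path} line {i}: non-positive concentration "
                f"(neopterin={neo}, creatinine={cre})"
            )
        samples.append(UrineSample(str(row.participant_id), d, neo, cre))
    # duplicate averaging is handled when series are built; warn here so the
    # file-level contract is visible
    key = {(s.participant_id, s.collection_date) for s in samples}
    if len(key) < len(samples):
        logger.warning("%s: duplicate (participant, date) rows will be averaged", path)
    return samples


def read_outcome_csv(path) -> list[ParticipantOutcome]:
    """Read and validate a per-participant outcome table."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, OUTCOME_COLUMNS, path)
    has_followup = "followup_years" in df.columns
    outcomes = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        _parse_date(row.exit_date, i, path)
        sex_raw = str(row.sex).strip().lower()
        if sex_raw not in SEX_CODES:
            raise RowError(
                f"{path} line {i}: unknown sex code {row.sex!r} "
                f"(accepted: F/M, female/male, 1/0)"
            )
        followup = float(getattr(row, "followup_years")) if has_followup else np.nan
        if has_followup and not followup > 0:
            raise RowError(f"{path} line {i}: followup_years must be positive")
        try:
            outcomes.append(
                ParticipantOutcome(
                    participant_id=str(row.participant_id),
                    cord_atrophy=float(row.cord_atrophy_pct_per_year),
                    brain_atrophy=float(row.brain_atrophy_pct_per_year),
                    age=float(row.age_years),
                    sex=SEX_CODES[sex_raw],
                    followup_years=followup,
                )
            )
        except ValueError as exc:
            raise RowError(f"{path} line {i}: {exc}") from exc
    return outcomes


def exit_days_from_dates(samples: Sequence[UrineSample], outcomes: Sequence[ParticipantOutcome],
                         exit_dates: dict[str, dt.date]) -> dict[str, float]:
    """Study-exit day offset per participant, in series coordinates."""
    first: dict[str, dt.date] = {}
    for s in samples:
        if s.participant_id not in first or s.collection_date < first[s.participant_id]:
            first[s.participant_id] = s.collection_date
    return {
        pid: float((exit_dates[pid] - first[pid]).days)
        for pid in first
        if pid in exit_dates
    }


def write_urine_csv(path, series_list: Sequence[UNCRSeries], *, creatinine: float = 1.0) -> None:
    """Serialize synthetic series as a raw urine-sample table.

    Synthetic creatinine is held at ``creatinine`` mmol/L so neopterin
    in nmol/L equals UNCR × creatinine; reading the file back reproduces
    the UNCR values exactly.
    """
    rows = []
    for s in series_list:
        for day, value in zip(s.days, s.values):
            rows.append(
                {
                    "participant_id": s.participant_id,
                    "date": (SIM_EPOCH + dt.timedelta(days=float(day))).isoformat(),
                    "neopterin_nmol_per_L": value * creatinine,
                    "creatinine_mmol_per_L": creatinine,
                }
            )
    pd.DataFrame(rows, columns=URINE_COLUMNS).to_csv(path, index=False)


def write_outcome_csv(path, outcomes: Sequence[ParticipantOutcome],
                      exit_days: dict[str, float] | None = None) -> None:
    rows = []
    for o in outcomes:
        exit_day = (
            exit_days[o.participant_id]
            if exit_days is not None
            else o.followup_years * 365.25
        )
        rows.append(
            {
                "participant_id": o.participant_id,
                "cord_atrophy_pct_per_year": o.cord_atrophy,
                "brain_atrophy_pct_per_year": o.brain_atrophy,
                "age_years": o.age,
                "sex": o.sex,
                "exit_date": (SIM_EPOCH + dt.timedelta(days=float(exit_day))).isoformat(),
                "followup_years": o.followup_years,
            }
        )
    pd.DataFrame(rows, columns=OUTCOME_COLUMNS + ["followup_years"]).to_csv(path, index=False)


def write_truth_json(path, truth: SimulationTruth) -> None:
    Path(path).write_text(truth.to_json())


def read_truth_json(path) -> SimulationTruth:
    return SimulationTruth.from_json(Path(path).read_text())


def write_summary_csv(path, summaries) -> None:
    pd.DataFrame(
        [
            {
                "participant_id": s.participant_id,
                "background": s.background,
                "response": s.response,
                "window_start_day": s.window_start_day,
                "window_end_day": s.window_end_day,
                "n_samples": s.n_samples,
            }
            for s in summaries
        ]
    ).to_csv(path, index=False)


def read_config(path) -> dict:
    """Read a flat key→value YAML config file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: config must be a flat mapping")
    return raw
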