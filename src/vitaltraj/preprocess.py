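"""Ingest, validation, duplicate averaging and per-patient series assembly.

Long-format observation rows are validated against the physiologic bounds,
same-time duplicates are collapsed by arithmetic mean, and per-patient
time-ordered channel series are assembled with missingness kept explicit —
no value is ever imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .channels import CHANNELS, PHYSIOLOGIC_BOUNDS, TIME_WINDOW

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("patient_id", "channel", "time_hours", "value")

#: Recorded times are considered "the same" after rounding to 2 decimals.
TIME_DECIMALS = 2


class FormatError(ValueError):
    """Raised when an input file cannot be interpreted at all."""


@dataclass(frozen=True)
class VitalObservation:
    """One validated vital-sign measurement."""

    patient_id: str
    channel: str
    time_hours: float
    value: float


@dataclass
class PatientSeries:
    """One patient's per-channel time-ordered observations plus outcome.

    ``observed`` maps channel code to a ``(times, values)`` pair of float
    arrays, strictly increasing in time with no duplicate times. Channels
    without observations are simply absent.
    """

    patient_id: str
    observed: dict[str, tuple[np.ndarray, np.ndarray]]
    death30: bool | None = None
    age: float | None = None
    sex: str | None = None

    @property
    def n_observations(self) -> int:
        return sum(len(t) for t, _ in self.observed.values())

    def channel_mean(self, channel: str) -> float:
        """Mean observed value for ``channel`` (NaN if unobserved)."""
        if channel not in self.observed:
            return float("nan")
        return float(np.mean(self.observed[channel][1]))


def _row_reason(channel, time_hours, value) -> str | None:
    if channel not in PHYSIOLOGIC_BOUNDS:
        return f"unknown channel {channel!r}"
    if not np.isfinite(time_hours):
        return "unparseable time_hours"
    if not np.isfinite(value):
        return "unparseable value"
    lo_t, hi_t = TIME_WINDOW
    if not (lo_t <= time_hours <= hi_t):
        return "time outside 0-24 h window"
    lo, hi = PHYSIOLOGIC_BOUNDS[channel]
    if not (lo <= value <= hi):
        return f"value outside physiologic bounds [{lo}, {hi}] for {channel}"
    return None


def load_observations(
    path: str | Path,
) -> tuple[list[VitalObservation], list[str]]:
    """Parse an observation CSV, returning valid rows and a rejection log.

    A missing required column is fatal (:class:`FormatError`); individual
    bad rows (unparseable numerics, out-of-window times, out-of-bounds
    values) are rejected with a one-line reason each, never silently
    dropped.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "channel": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        logger.warning("%s: no observation rows", path)
        return [], []

    time_hours = pd.to_numeric(df["time_hours"], errors="coerce").to_numpy(float)
    value = pd.to_numeric(df["value"], errors="coerce").to_numpy(float)
    channels = df["channel"].to_numpy()
    pids = df["patient_id"].to_numpy()

    rows: list[VitalObservation] = []
    rejections: list[str] = []
    for i in range(len(df)):
        reason = _row_reason(channels[i], time_hours[i], value[i])
        if reason is None:
            rows.append(
                VitalObservation(str(pids[i]), channels[i],
                                 float(time_hours[i]), float(value[i]))
            )
        else:
            rejections.append(f"row {i + 2}: {reason}")  # +2: header + 1-based
    if rejections:
        logger.warning("%s: rejected %d row(s)", path, len(rejections))
    return rows, rejections


def observations_from_frame(df: pd.DataFrame) -> list[VitalObservation]:
    """Convert an in-memory long-format observation table to validated rows.

    Rows failing validation raise — use :func:`load_observations` for
    tolerant file ingest with a rejection log.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s) {missing}")
    rows = []
    for rec in df.itertuples(index=False):
        reason = _row_reason(rec.channel, float(rec.time_hours), float(rec.value))
        if reason is not None:
            raise ValueError(f"invalid observation row: {reason}")
        rows.append(VitalObservation(str(rec.patient_id), rec.channel,
                                     float(rec.time_hours), float(rec.value)))
    return rows


def collapse_duplicates(
    observations: Iterable[VitalObservation],
) -> list[VitalObservation]:
    """Average multiple measurements recorded at the same time.

    For every (patient, channel, time) key — time rounded to 2 decimals —
    a single row carries the arithmetic mean of the group's values. Output
    is sorted by (patient, channel, time). The number of distinct keys is
    unchanged.
    """
    groups: dict[tuple[str, str, float], list[float]] = {}
    for obs in observations:
        key = (obs.patient_id, obs.channel, round(obs.time_hours, TIME_DECIMALS))
        groups.setdefault(key, []).append(obs.value)
    return [
        VitalObservation(pid, ch, t, float(np.mean(vals)))
        for (pid, ch, t), vals in sorted(groups.items())
    ]


def assemble_series(
    observations: Sequence[VitalObservation],
    outcomes: pd.DataFrame,
) -> tuple[list[PatientSeries], list[str]]:
    """Build one :class:`PatientSeries` per patient; log exclusions.

    Every observed patient must have an outcome row (fatal otherwise).
    Outcome rows with zero valid observations are excluded and logged —
    not an error. Missing cells stay missing.
    """
    if "patient_id" not in outcomes.columns:
        raise FormatError("outcomes table missing 'patient_id' column")
    outcomes = outcomes.copy()
    outcomes["patient_id"] = outcomes["patient_id"].astype(str)
    if outcomes["patient_id"].duplicated().any():
        dupes = outcomes.loc[outcomes["patient_id"].duplicated(), "patient_id"]
        raise FormatError(f"outcomes table has duplicate patient rows: {sorted(set(dupes))}")
    outcome_map = outcomes.set_index("patient_id").to_dict("index")

    by_patient: dict[str, dict[str, list[tuple[float, float]]]] = {}
    for obs in observations:
        by_patient.setdefault(obs.patient_id, {}).setdefault(
            obs.channel, []
        ).append((obs.time_hours, obs.value))

    missing_outcomes = sorted(set(by_patient) - set(outcome_map))
    if missing_outcomes:
        raise FormatError(
            f"observed patients missing from outcomes table: {missing_outcomes}"
        )

    series: list[PatientSeries] = []
    exclusions: list[str] = []
    for pid in outcome_map:
        channels = by_patient.get(pid)
        if not channels:
            exclusions.append(f"{pid}: no valid observations, excluded")
            continue
        observed = {}
        for ch in CHANNELS:
            if ch not in channels:
                continue
            pairs = sorted(channels[ch])
            times = np.array([t for t, _ in pairs])
            if np.any(np.diff(times) <= 0):
                raise FormatError(
                    f"{pid}/{ch}: duplicate times remain; run collapse_duplicates first"
                )
            observed[ch] = (times, np.array([v for _, v in pairs]))
        out = outcome_map[pid]
        death = out.get("death30")
        series.append(
            PatientSeries(
                patient_id=pid,
                observed=observed,
                death30=None if pd.isna(death) else bool(int(death)),
                age=None if pd.isna(out.get("age")) else float(out["age"]),
                sex=None if pd.isna(out.get("sex")) else str(out["sex"]),
            )
        )
    if exclusions:
        logger.info("excluded %d patient(s) without observations", len(exclusions))
    return series, exclusions


@dataclass(frozen=True)
class StandardizationRecord:
    """Per-channel pooled observation mean and SD; inverts the z-transform."""

    means: dict[str, float]
    sds: dict[str, float] = field(default_factory=dict)

    def transform(self, channel: str, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, float) - self.means[channel]) / self.sds[channel]

    def invert(self, channel: str, values: np.ndarray) -> np.ndarray:
        return np.asarray(values, float) * self.sds[channel] + self.means[channel]

    def invert_coefficients(self, channel: str, beta: np.ndarray) -> np.ndarray:
        """Map polynomial coefficients from standardized to natural units."""
        beta = np.asarray(beta, float) * self.sds[channel]
        beta = beta.copy()
        beta[0] += self.means[channel]
        return beta

    def to_dict(self) -> dict:
        return {"means": dict(self.means), "sds": dict(self.sds)}

    @classmethod
    def from_dict(cls, d: dict) -> "StandardizationRecord":
        return cls(means=dict(d["means"]), sds=dict(d["sds"]))


def standardize(
    series_set: Sequence[PatientSeries],
) -> tuple[list[PatientSeries], StandardizationRecord]:
    """Z-score every channel by its cohort-pooled observation mean and SD.

    Returns new series plus the record needed to invert the transform for
    reporting trajectories in natural units. A channel with zero variance
    is fatal.
    """
    if not series_set:
        raise ValueError("empty series set")
    pooled: dict[str, list[np.ndarray]] = {ch: [] for ch in CHANNELS}
    for s in series_set:
        for ch, (_, vals) in s.observed.items():
            pooled[ch].append(vals)
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    for ch, chunks in pooled.items():
        if not chunks:
            continue
        allvals = np.concatenate(chunks)
        mu = float(np.mean(allvals))
        sd = float(np.std(allvals))
        if sd == 0.0:
            raise ValueError(f"channel {ch} has zero variance; cannot standardize")
        means[ch], sds[ch] = mu, sd
    record = StandardizationRecord(means=means, sds=sds)

    out = []
    for s in series_set:
        observed = {
            ch: (times.copy(), record.transform(ch, vals))
            for ch, (times, vals) in s.observed.items()
        }
        out.append(replace(s, observed=observed))
    return out, record
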