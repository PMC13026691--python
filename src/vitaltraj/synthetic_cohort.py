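"""Synthetic emergency-department cohort generator.

Produces a fully synthetic cohort with the statistical structure the
trajectory analysis assumes: five vital-sign channels sampled on a 4-hourly
schedule over the first 24 h, four latent trajectory archetypes (A: all
channels deranged; B: isolated hypertension; C: minimal derangement;
D: hypotension only), Gaussian measurement noise, completely-at-random
missingness, occasional duplicate same-time measurements, and a 30-day
death flag drawn per archetype.

The latent archetype is emitted only in a separate truth table so the
observation/outcome tables downstream stages see carry no leakage.
"""

from __future__ import annotations

from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .channels import CHANNELS, PHYSIOLOGIC_BOUNDS, TIME_WINDOW

ARCHETYPES: tuple[str, ...] = ("A", "B", "C", "D")

#: Cohort shares of the four archetypes (renormalized to sum to 1).
DEFAULT_GROUP_SHARES: tuple[float, ...] = (0.0266, 0.092, 0.19, 0.692)

#: 30-day death probability per archetype.
DEFAULT_MORTALITY_PROBS: tuple[float, ...] = (3 / 18, 4 / 62, 3 / 128, 48 / 467)

DEFAULT_SCHEDULE_HOURS: tuple[float, ...] = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0, 24.0)

#: Per-channel measurement noise SD, in channel units.
DEFAULT_RESIDUAL_SD: dict[str, float] = {
    "TEMP": 0.4,
    "HR": 9.0,
    "RR": 2.5,
    "SBP": 12.0,
    "DBP": 8.0,
}


class ChannelTemplate(BaseModel):
    """Polynomial mean trajectory plus noise SD for one channel.

    ``coefficients`` are (intercept, slope per hour[, curvature per hour²]);
    the evaluated mean must stay inside the channel's physiologic bounds
    over the 0–24 h window.
    """

    model_config = ConfigDict(frozen=True)

    channel: str
    coefficients: tuple[float, ...]
    # sd 0 is allowed so noiseless cohorts can exercise exact recovery
    residual_sd: float = Field(ge=0.0)

    @field_validator("channel")
    @classmethod
    def _known_channel(cls, v: str) -> str:
        if v not in PHYSIOLOGIC_BOUNDS:
            raise ValueError(f"unknown channel {v!r}")
        return v

    @field_validator("coefficients")
    @classmethod
    def _coef_length(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        if len(v) not in (2, 3):
            raise ValueError("coefficients must have length 2 (linear) or 3 (quadratic)")
        return v

    @model_validator(mode="after")
    def _mean_in_bounds(self) -> "ChannelTemplate":
        lo, hi = PHYSIOLOGIC_BOUNDS[self.channel]
        t = np.linspace(*TIME_WINDOW, 97)
        mean = self.mean(t)
        if mean.min() < lo or mean.max() > hi:
            raise ValueError(
                f"{self.channel} template mean leaves physiologic bounds "
                f"[{lo}, {hi}] over 0-24 h"
            )
        return self

    def mean(self, t: np.ndarray | float) -> np.ndarray:
        """Evaluate the polynomial mean at time(s) ``t`` (hours)."""
        return np.polyval(tuple(reversed(self.coefficients)), np.asarray(t, float))


class SyntheticConfig(BaseModel):
    """Full specification of one synthetic cohort draw."""

    model_config = ConfigDict(frozen=True)

    n_patients: int = Field(gt=0)
    group_shares: tuple[float, float, float, float]
    group_templates: dict[str, dict[str, ChannelTemplate]]
    mortality_probs: tuple[float, float, float, float]
    schedule_hours: tuple[float, ...] = DEFAULT_SCHEDULE_HOURS
    missing_rate: float = Field(default=0.05, ge=0.0, lt=1.0)
    duplicate_rate: float = Field(default=0.02, ge=0.0, lt=1.0)
    seed: int = 0

    @field_validator("group_shares")
    @classmethod
    def _shares_valid(cls, v):
        if any(s <= 0 for s in v):
            raise ValueError("group_shares must be positive")
        if abs(sum(v) - 1.0) > 1e-9:
            raise ValueError(f"group_shares must sum to 1 (got {sum(v)})")
        return v

    @field_validator("mortality_probs")
    @classmethod
    def _probs_valid(cls, v):
        if any(not (0.0 <= p <= 1.0) for p in v):
            raise ValueError("mortality_probs must lie in [0, 1]")
        return v

    @field_validator("schedule_hours")
    @classmethod
    def _schedule_valid(cls, v):
        arr = np.asarray(v, float)
        lo, hi = TIME_WINDOW
        if arr.size == 0 or arr.min() < lo or arr.max() > hi:
            raise ValueError("schedule_hours must lie within [0, 24]")
        if not np.all(np.diff(arr) > 0):
            raise ValueError("schedule_hours must be strictly increasing")
        return v

    @model_validator(mode="after")
    def _templates_complete(self) -> "SyntheticConfig":
        for arch in ARCHETYPES:
            templates = self.group_templates.get(arch)
            if templates is None:
                raise ValueError(f"group_templates missing archetype {arch!r}")
            for ch in CHANNELS:
                if ch not in templates:
                    raise ValueError(
                        f"group_templates[{arch!r}] missing channel {ch!r}"
                    )
        return self


class CohortTables(NamedTuple):
    """The three output tables of one synthetic draw."""

    observations: pd.DataFrame  # patient_id, channel, time_hours, value
    outcomes: pd.DataFrame  # patient_id, death30, age, sex
    truth: pd.DataFrame  # patient_id, archetype (never joined downstream)


def _template(channel: str, intercept: float, slope: float = 0.0,
              curvature: float | None = None,
              residual_sd: float | None = None) -> ChannelTemplate:
    coefs = (intercept, slope) if curvature is None else (intercept, slope, curvature)
    return ChannelTemplate(
        channel=channel,
        coefficients=coefs,
        residual_sd=DEFAULT_RESIDUAL_SD[channel] if residual_sd is None else residual_sd,
    )


def default_templates() -> dict[str, dict[str, ChannelTemplate]]:
    """Archetype mean trajectories at clinically plausible magnitudes.

    Abnormal channels start deranged and drift mildly toward normal;
    normal channels are flat. A: fever + tachycardia + tachypnea +
    hypotension; B: isolated hypertension; C: all normal; D: hypotension
    only.
    """
    normal = {
        "TEMP": (36.8, 0.0),
        "HR": (84.0, 0.0),
        "RR": (17.0, 0.0),
        "SBP": (122.0, 0.0),
        "DBP": (74.0, 0.0),
    }

    def build(overrides: dict[str, tuple[float, float]]) -> dict[str, ChannelTemplate]:
        spec = {**normal, **overrides}
        return {ch: _template(ch, *spec[ch]) for ch in CHANNELS}

    return {
        "A": build({
            "TEMP": (38.8, -0.03),
            "HR": (118.0, -0.5),
            "RR": (26.0, -0.10),
            "SBP": (88.0, 0.5),
            "DBP": (52.0, 0.3),
        }),
        "B": build({"SBP": (162.0, -0.5)}),
        "C": build({}),
        "D": build({"SBP": (88.0, 0.4), "DBP": (58.0, 0.2)}),
    }


def default_config(n_patients: int = 675, seed: int = 0, **overrides) -> SyntheticConfig:
    """Cohort configuration matching the reference study's group structure.

    Shares (2.66/9.2/19/69.2 %) and per-group death probabilities
    (3/18, 4/62, 3/128, 48/467) follow the published four-group cohort;
    observations are scheduled every 4 h over 0–24 h.
    """
    shares = np.asarray(DEFAULT_GROUP_SHARES, float)
    shares = shares / shares.sum()
    params: dict = dict(
        n_patients=n_patients,
        group_shares=tuple(shares),
        group_templates=default_templates(),
        mortality_probs=DEFAULT_MORTALITY_PROBS,
        schedule_hours=DEFAULT_SCHEDULE_HOURS,
        seed=seed,
    )
    params.update(overrides)
    return SyntheticConfig(**params)


def generate_cohort(config: SyntheticConfig) -> CohortTables:
    """Draw one cohort. Identical config (incl. seed) gives identical tables.

    Each patient gets a latent archetype from ``group_shares``; every
    scheduled (channel, time) cell is template mean + N(0, residual_sd),
    dropped with ``missing_rate`` and recorded twice (independent noise,
    same recorded time) with ``duplicate_rate``. Death is
    Bernoulli(mortality_prob of the archetype).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    width = max(4, len(str(n)))
    patient_ids = np.array([f"P{i:0{width}d}" for i in range(1, n + 1)])

    arch_idx = rng.choice(len(ARCHETYPES), size=n, p=np.asarray(config.group_shares))
    archetypes = np.asarray(ARCHETYPES)[arch_idx]

    sched = np.asarray(config.schedule_hours, float)
    n_t = sched.size

    frames: list[pd.DataFrame] = []
    # Per (channel, patient, time) cell: one noise draw, plus a second one
    # consumed only when the cell is duplicated. Draw order is fixed by the
    # channel loop so output is reproducible.
    for ch in CHANNELS:
        means = np.empty((n, n_t))
        sds = np.empty(n)
        for a, arch in enumerate(ARCHETYPES):
            tmpl = config.group_templates[arch][ch]
            mask = arch_idx == a
            means[mask] = tmpl.mean(sched)
            sds[mask] = tmpl.residual_sd
        values = means + rng.normal(size=(n, n_t)) * sds[:, None]
        dup_values = means + rng.normal(size=(n, n_t)) * sds[:, None]
        keep = rng.random(size=(n, n_t)) >= config.missing_rate
        dup = (rng.random(size=(n, n_t)) < config.duplicate_rate) & keep

        pid_grid = np.broadcast_to(patient_ids[:, None], (n, n_t))
        t_grid = np.broadcast_to(sched[None, :], (n, n_t))
        frame = pd.DataFrame({
            "patient_id": pid_grid[keep],
            "channel": ch,
            "time_hours": t_grid[keep],
            "value": values[keep],
            "_rep": 0,
        })
        dup_frame = pd.DataFrame({
            "patient_id": pid_grid[dup],
            "channel": ch,
            "time_hours": t_grid[dup],
            "value": dup_values[dup],
            "_rep": 1,
        })
        frames.append(frame)
        frames.append(dup_frame)

    observations = pd.concat(frames, ignore_index=True)
    observations = observations.sort_values(
        ["patient_id", "channel", "time_hours", "_rep"], kind="stable"
    ).drop(columns="_rep").reset_index(drop=True)
    # Clip stray noise excursions to the plausibility bounds so the
    # generator never emits rows ingest would reject.
    lo = observations["channel"].map({c: b[0] for c, b in PHYSIOLOGIC_BOUNDS.items()})
    hi = observations["channel"].map({c: b[1] for c, b in PHYSIOLOGIC_BOUNDS.items()})
    observations["value"] = observations["value"].clip(lo, hi)

    death_p = np.asarray(config.mortality_probs)[arch_idx]
    death30 = (rng.random(n) < death_p).astype(int)
    age = np.clip(np.round(rng.normal(59.2, 19.3, size=n)), 18, 96).astype(int)
    sex = np.where(rng.random(n) < 0.5, "F", "M")

    outcomes = pd.DataFrame({
        "patient_id": patient_ids,
        "death30": death30,
        "age": age,
        "sex": sex,
    })
    truth = pd.DataFrame({"patient_id": patient_ids, "archetype": archetypes})
    return CohortTables(observations, outcomes, truth)


def write_cohort(tables: CohortTables, outdir: str | Path) -> dict[str, Path]:
    """Write the three tables as UTF-8 CSV; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "observations": outdir / "observations.csv",
        "outcomes": outdir / "outcomes.csv",
        "truth": outdir / "truth.csv",
    }
    tables.observations.to_csv(paths["observations"], index=False)
    tables.outcomes.to_csv(paths["outcomes"], index=False)
    tables.truth.to_csv(paths["truth"], index=False)
    return paths
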