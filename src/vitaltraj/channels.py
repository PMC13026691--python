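"""Canonical vital-sign channel codes, units and physiologic bounds.

Five channels are modelled: temperature, heart rate, respiratory rate and
the two blood-pressure components (systolic/diastolic), so that each latent
group is described by five per-channel polynomial mean trajectories.
"""

from __future__ import annotations

#: Canonical channel order used everywhere (tables, matrices, reports).
CHANNELS: tuple[str, ...] = ("TEMP", "HR", "RR", "SBP", "DBP")

UNITS: dict[str, str] = {
    "TEMP": "degC",
    "HR": "bpm",
    "RR": "breaths/min",
    "SBP": "mmHg",
    "DBP": "mmHg",
}

#: Hard physiologic plausibility bounds; values outside are rejected at
#: ingest and synthetic templates must keep their mean curve inside them.
PHYSIOLOGIC_BOUNDS: dict[str, tuple[float, float]] = {
    "TEMP": (30.0, 43.0),
    "HR": (20.0, 220.0),
    "RR": (4.0, 60.0),
    "SBP": (40.0, 260.0),
    "DBP": (20.0, 160.0),
}

#: Observation window in hours since ED admission.
TIME_WINDOW: tuple[float, float] = (0.0, 24.0)

#: Clinical derangement cut-offs used for labelling fitted groups.
FEVER_TEMP = 38.0
TACHYCARDIA_HR = 100.0
TACHYPNEA_RR = 22.0
HYPERTENSION_SBP = 140.0
HYPOTENSION_SBP = 100.0


def validate_channel(channel: str) -> str:
    """Return the channel code, raising ``ValueError`` for unknown codes."""
    if channel not in PHYSIOLOGIC_BOUNDS:
        raise ValueError(
            f"unknown channel {channel!r}; expected one of {CHANNELS}"
        )
    return channel
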