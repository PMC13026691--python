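import numpy as np
import pytest

import vitaltraj as vt
from vitaltraj.model_selection import select_orders, sweep_groups
from vitaltraj.preprocess import (
    PatientSeries,
    assemble_series,
    collapse_duplicates,
    observations_from_frame,
    standardize,
)

#: Published four-group mortality counts: label -> (deaths, total).
TABLE1_COUNTS = {"A": (3, 18), "B": (4, 62), "C": (3, 128), "D": (48, 467)}

#: Fixed seed for the heavyweight recovery fixture.
RECOVERY_SEED = 7


def expand_counts(counts=TABLE1_COUNTS):
    """Per-patient (label, died) lists matching a counts table."""
    labels, died = [], []
    for lab, (d, tot) in counts.items():
        labels += [lab] * tot
        died += [1] * d + [0] * (tot - d)
    return labels, died


def make_series(rng, n_patients=8, channels=("TEMP", "HR"), n_times=5,
                scale=1.0, offsets=None):
    """Random small PatientSeries set on a standardized-ish scale."""
    out = []
    for i in range(n_patients):
        observed = {}
        for ch in channels:
            k = rng.integers(2, n_times + 1)
            times = np.sort(rng.uniform(0, 24, size=k))
            base = 0.0 if offsets is None else offsets.get(ch, 0.0)
            observed[ch] = (times, base + scale * rng.normal(size=k))
        out.append(PatientSeries(patient_id=f"S{i:03d}", observed=observed,
                                 death30=bool(rng.random() < 0.2)))
    return out


def cohort_to_series(tables, do_standardize=True):
    """Synthetic tables -> (series, std_record or None)."""
    obs = observations_from_frame(tables.observations)
    deduped = collapse_duplicates(obs)
    series, _ = assemble_series(deduped, tables.outcomes)
    if not do_standardize:
        return series, None
    return standardize(series)


@pytest.fixture(scope="session")
def default_cohort():
    """Moderate synthetic cohort for structural tests."""
    cfg = vt.default_config(n_patients=200, seed=123)
    return vt.generate_cohort(cfg)


@pytest.fixture(scope="session")
def recovery_sweep():
    """Full-size cohort, order LRT and 1-4 group sweep (shared: it is slow).

    Screens are evaluated but not allowed to veto, so every candidate's
    diagnostics are available; strict-screen selection can be re-derived
    from the candidate pass flags.
    """
    cfg = vt.default_config(n_patients=675, seed=RECOVERY_SEED)
    tables = vt.generate_cohort(cfg)
    series, record = cohort_to_series(tables)
    selections = select_orders(series)
    orders = {ch: s.order for ch, s in selections.items()}
    report = sweep_groups(series, orders, seed=RECOVERY_SEED, n_starts=10,
                          std_record=record, enforce_screens=False)
    truth = dict(zip(tables.truth.patient_id, tables.truth.archetype))
    return {
        "tables": tables,
        "series": series,
        "record": record,
        "orders": orders,
        "report": report,
        "truth": truth,
    }
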