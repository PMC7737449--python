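"""Synthetic patient-level event records.

Real ED administrative timestamp data are rarely shareable, so this module
generates cohorts with the exact statistical structure the five-state model
assumes: competing exponential sojourns in each transient state, log-linear
covariate effects on the intensities, clock-time arrivals with per-shift
weights, and (optionally) shift-dependent intensities.

A patient's trajectory starts at triage.  In each transient state the waiting
time is exponential with rate equal to the state's total exit intensity and
the destination follows the embedded jump chain — equivalent to racing
independent exponential clocks, one per allowed movement.  With a
shift-stratified model, the intensities used for a sojourn are those of the
shift in force at state entry (frozen for the whole sojourn), matching the
attribution rule of the estimator in :mod:`edflow.inference`.

Cohorts are exchanged as data frames / CSV with one row per patient::

    patient_id, arrival_iso8601, triage_level, age_group, category,
    t_triage_h, t_physician_h, t_observation_h, t_departure_h, disposition

State-entry times are decimal hours since arrival (``t_triage_h`` is 0);
``t_physician_h`` / ``t_observation_h`` are empty when the state was skipped.
The ISO-8601 arrival timestamp carries the clock/shift information.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import presets
from .state_model import (
    ADMISSION, DISCHARGE, OBSERVATION, PHYSICIAN, TRIAGE,
    RateModel, ShiftSchedule, StateSpace,
)

#: Arbitrary calendar anchor for synthetic arrival timestamps.
BASE_DATE = pd.Timestamp("2013-01-01 00:00:00")

CSV_COLUMNS = [
    "patient_id", "arrival_iso8601", "triage_level", "age_group", "category",
    "t_triage_h", "t_physician_h", "t_observation_h", "t_departure_h",
    "disposition",
]


@dataclass
class PatientRecord:
    """One synthetic ED visit: covariates, state-entry times, disposition."""

    patient_id: str
    arrival: pd.Timestamp
    triage_level: int
    age_group: int
    category: str
    state_entry_times: dict[int, float]  # state -> hours since arrival
    disposition: str  # "discharge" | "admission"
    departure_h: float

    def validate(self, space: StateSpace = StateSpace()) -> None:
        """Check timestamp monotonicity and path admissibility."""
        path = self.path + (DISCHARGE if self.disposition == "discharge" else ADMISSION,)
        times = [self.state_entry_times[s] for s in self.path] + [self.departure_h]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"{self.patient_id}: timestamps not strictly increasing")
        for step in zip(path, path[1:]):
            if step not in space.transitions:
                raise ValueError(f"{self.patient_id}: disallowed movement {step}")
        if (OBSERVATION in self.state_entry_times) != (OBSERVATION in path):
            raise ValueError(f"{self.patient_id}: observation entry inconsistent")

    @property
    def path(self) -> tuple[int, ...]:
        return tuple(sorted(self.state_entry_times, key=self.state_entry_times.get))


@dataclass
class CohortConfig:
    """Generating conditions for one synthetic cohort."""

    n_patients: int = 1000
    rate_model: RateModel = field(default_factory=presets.default_model)
    triage_probs: Sequence[float] = presets.TRIAGE_LEVEL_PROBS
    age_probs: Sequence[float] = presets.AGE_GROUP_PROBS
    category_probs: Sequence[float] = presets.CATEGORY_PROBS
    arrival_weights: Sequence[float] = presets.ARRIVAL_WEIGHTS
    n_days: int = 7
    seed: int = 0
    shift_schedule: ShiftSchedule = field(default_factory=ShiftSchedule)

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        for name in ("triage_probs", "age_probs", "category_probs"):
            p = np.asarray(getattr(self, name), dtype=float)
            if not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
                raise ValueError(f"{name} must sum to 1")
        if len(self.arrival_weights) != self.shift_schedule.n_shifts:
            raise ValueError("one arrival weight per shift required")


def sample_covariates(
    config: CohortConfig, rng: np.random.Generator, n: int | None = None
):
    """Draw (triage_level, age_group, category) from the cohort marginals.

    Returns scalars when ``n`` is None, else arrays of length ``n``.
    """
    size = 1 if n is None else n
    triage = rng.choice(np.arange(1, 6), size=size, p=np.asarray(_normalize_probs(config.triage_probs)))
    age = rng.choice(np.arange(1, 6), size=size, p=np.asarray(_normalize_probs(config.age_probs)))
    cat = rng.choice(np.asarray(presets.CATEGORIES), size=size, p=np.asarray(_normalize_probs(config.category_probs)))
    if n is None:
        return int(triage[0]), int(age[0]), str(cat[0])
    return triage, age, cat


def _normalize_probs(p: Sequence[float]) -> np.ndarray:
    """Renormalize a probability vector against rounding drift."""
    a = np.asarray(p, dtype=float)
    return a / a.sum()


# ---------------------------------------------------------------------------
# Path simulation
# ---------------------------------------------------------------------------

def _exit_rates(
    model: RateModel,
    state: int,
    covariates: Mapping[str, float],
    shift: int | None,
) -> dict[int, float]:
    return {
        j: model.rate((i, j), covariates, shift)
        for (i, j) in sorted(model.baseline)
        if i == state
    }


def simulate_path(
    model: RateModel,
    covariates: Mapping[str, float],
    start_clock: pd.Timestamp,
    rng: np.random.Generator,
    shift_schedule: ShiftSchedule = ShiftSchedule(),
    patient_id: str = "p0",
    triage_level: int = 3,
    age_group: int = 1,
    category: str = "adult-nontrauma",
) -> PatientRecord:
    """Simulate one trajectory from triage to absorption.

    In each transient state the sojourn is Exponential(total exit rate) and
    the destination is a draw from the embedded jump chain; with a
    shift-stratified model the rates are those of the shift containing the
    state-entry clock time.
    """
    start_clock = pd.Timestamp(start_clock)
    clock0 = (start_clock - start_clock.normalize()).total_seconds() / 3600.0
    state, elapsed = TRIAGE, 0.0
    entries: dict[int, float] = {TRIAGE: 0.0}
    space = model.state_space
    while state not in space.absorbing:
        shift = (
            shift_schedule.shift_of(clock0 + elapsed) if model.shifts is not None else None
        )
        rates = _exit_rates(model, state, covariates, shift)
        total = sum(rates.values())
        elapsed += rng.exponential(1.0 / total)
        dests = list(rates)
        probs = np.array([rates[j] / total for j in dests])
        state = int(rng.choice(dests, p=probs))
        if state not in space.absorbing:
            entries[state] = elapsed
    return PatientRecord(
        patient_id=patient_id,
        arrival=start_clock,
        triage_level=triage_level,
        age_group=age_group,
        category=category,
        state_entry_times=entries,
        disposition="discharge" if state == DISCHARGE else "admission",
        departure_h=elapsed,
    )


def _stage_rates(
    model: RateModel,
    state: int,
    cov: pd.DataFrame,
    shift_idx: np.ndarray | None,
) -> tuple[list[int], np.ndarray]:
    """Per-patient exit-rate matrix (n x n_dest) for one transient state."""
    trans = [t for t in sorted(model.baseline) if t[0] == state]
    dests = [j for _, j in trans]
    n = len(cov)
    rates = np.empty((n, len(trans)))
    for k, t in enumerate(trans):
        if model.shifts is not None and shift_idx is not None:
            per_shift = np.array(
                [model.shifts[s][t] for s in range(len(model.shifts))]
            )
            base = per_shift[shift_idx]
        else:
            base = np.full(n, model.baseline[t])
        log_rr = np.zeros(n)
        for name, beta in model.effects.get(t, {}).items():
            log_rr += beta * cov[name].to_numpy(dtype=float)
        rates[:, k] = base * np.exp(log_rr)
    return dests, rates


def _draw_stage(
    rng: np.random.Generator, rates: np.ndarray, dests: list[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Vector draw of (sojourn, destination) from competing exponentials."""
    total = rates.sum(axis=1)
    sojourn = rng.exponential(1.0 / total)
    cum = np.cumsum(rates, axis=1) / total[:, None]
    u = rng.random(len(total))
    choice = (u[:, None] > cum).sum(axis=1)
    dest = np.asarray(dests)[choice]
    return sojourn, dest


def simulate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Vectorized cohort simulation; returns the standard cohort frame.

    Stage-by-stage: all patients traverse triage, those routed to the
    physician state continue, and so on — each stage is a single set of
    vectorized exponential/categorical draws, so cohorts of hundreds of
    thousands of patients simulate in well under a second.
    """
    n = config.n_patients
    rng = np.random.default_rng(config.seed)
    model = config.rate_model
    sched = config.shift_schedule

    triage, age, cat = sample_covariates(config, rng, n=n)
    day = rng.integers(0, config.n_days, size=n)
    shift = rng.choice(sched.n_shifts, size=n, p=_normalize_probs(config.arrival_weights))
    b = np.asarray(sched.boundaries)
    clock = b[shift] + rng.random(n) * (b[shift + 1] - b[shift])
    arrival_h = day * 24.0 + clock

    cov = pd.DataFrame({"triage_level": triage, "age_group": age})
    use_shifts = model.shifts is not None

    t_phys = np.full(n, np.nan)
    t_obs = np.full(n, np.nan)
    t_dep = np.full(n, np.nan)
    final = np.zeros(n, dtype=int)

    # triage stage
    sidx = sched.shift_of(arrival_h % 24.0) if use_shifts else None
    dests, rates = _stage_rates(model, TRIAGE, cov, sidx)
    soj, dest = _draw_stage(rng, rates, dests)
    to_phys = dest == PHYSICIAN
    t_phys[to_phys] = soj[to_phys]
    t_dep[~to_phys] = soj[~to_phys]
    final[~to_phys] = dest[~to_phys]

    # physician stage
    idx2 = np.flatnonzero(to_phys)
    entry2 = arrival_h[idx2] + t_phys[idx2]
    sidx = sched.shift_of(entry2 % 24.0) if use_shifts else None
    dests, rates = _stage_rates(model, PHYSICIAN, cov.iloc[idx2], sidx)
    soj, dest = _draw_stage(rng, rates, dests)
    to_obs = dest == OBSERVATION
    t_obs[idx2[to_obs]] = t_phys[idx2[to_obs]] + soj[to_obs]
    t_dep[idx2[~to_obs]] = t_phys[idx2[~to_obs]] + soj[~to_obs]
    final[idx2[~to_obs]] = dest[~to_obs]

    # observation stage
    idx3 = idx2[to_obs]
    entry3 = arrival_h[idx3] + t_obs[idx3]
    sidx = sched.shift_of(entry3 % 24.0) if use_shifts else None
    dests, rates = _stage_rates(model, OBSERVATION, cov.iloc[idx3], sidx)
    soj, dest = _draw_stage(rng, rates, dests)
    t_dep[idx3] = t_obs[idx3] + soj
    final[idx3] = dest

    arrival_ts = BASE_DATE + pd.to_timedelta(arrival_h, unit="h")
    return pd.DataFrame(
        {
            "patient_id": [f"p{k:06d}" for k in range(n)],
            "arrival_iso8601": arrival_ts.strftime("%Y-%m-%dT%H:%M:%S.%f"),
            "triage_level": triage,
            "age_group": age,
            "category": cat,
            "t_triage_h": np.zeros(n),
            "t_physician_h": t_phys,
            "t_observation_h": t_obs,
            "t_departure_h": t_dep,
            "disposition": np.where(final == DISCHARGE, "discharge", "admission"),
        }
    )


def generate_cohort(
    config: CohortConfig, csv_path=None
) -> list[PatientRecord]:
    """Generate a cohort, optionally writing the CSV, and return records."""
    df = simulate_cohort(config)
    if csv_path is not None:
        write_cohort_csv(df, csv_path, seed=config.seed)
    return records_from_frame(df)


# ---------------------------------------------------------------------------
# Frame <-> record conversion and CSV I/O
# ---------------------------------------------------------------------------

def records_from_frame(df: pd.DataFrame) -> list[PatientRecord]:
    out = []
    for row in df.itertuples(index=False):
        entries = {TRIAGE: 0.0}
        if not pd.isna(row.t_physician_h):
            entries[PHYSICIAN] = float(row.t_physician_h)
        if not pd.isna(row.t_observation_h):
            entries[OBSERVATION] = float(row.t_observation_h)
        out.append(
            PatientRecord(
                patient_id=str(row.patient_id),
                arrival=pd.Timestamp(row.arrival_iso8601),
                triage_level=int(row.triage_level),
                age_group=int(row.age_group),
                category=str(row.category),
                state_entry_times=entries,
                disposition=str(row.disposition),
                departure_h=float(row.t_departure_h),
            )
        )
    return out


def frame_from_records(records: Sequence[PatientRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id,
                "arrival_iso8601": r.arrival.strftime("%Y-%m-%dT%H:%M:%S.%f"),
                "triage_level": r.triage_level,
                "age_group": r.age_group,
                "category": r.category,
                "t_triage_h": 0.0,
                "t_physician_h": r.state_entry_times.get(PHYSICIAN, np.nan),
                "t_observation_h": r.state_entry_times.get(OBSERVATION, np.nan),
                "t_departure_h": r.departure_h,
                "disposition": r.disposition,
            }
        )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_cohort_csv(df: pd.DataFrame, path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# edflow synthetic cohort; seed={seed}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    return df
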