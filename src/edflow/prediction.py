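"""Predictive dynamic state-occupancy distributions.

Given a fitted intensity model, the probability of occupying each of the
five states at time *t* after ED entry is the first row of the transition
matrix ``P(t) = expm(Q t)``.  With shift-stratified intensities the
generator is piecewise constant in clock time, so the occupancy distribution
is propagated by left-multiplying the matrix exponentials of successive
shift windows.  The in-system probability is one minus the absorbed mass.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from dataclasses import dataclass
from typing import Mapping

from scipy.linalg import expm

from .state_model import (
    ADMISSION, DISCHARGE, STATE_NAMES, TRIAGE,
    RateModel, ShiftSchedule, StateSpace, Transition,
    generator_matrix, steady_flow_counts,
)


@dataclass
class OccupancyCurve:
    """State-occupancy probabilities on a time grid (hours from entry)."""

    times: np.ndarray
    probs: np.ndarray  # shape (len(times), 5), columns in state order
    entry_clock: float | None = None
    entry_shift: int | None = None
    covariates: dict | None = None
    state_space: StateSpace = StateSpace()

    def to_frame(self) -> pd.DataFrame:
        """Tidy (time_h, state, probability) table for plotting/export."""
        rows = []
        for k, t in enumerate(self.times):
            for s_idx, s in enumerate(self.state_space.states):
                rows.append((float(t), STATE_NAMES[s], float(self.probs[k, s_idx])))
        return pd.DataFrame(rows, columns=["time_h", "state", "probability"])

    def probability_of(self, state: int) -> np.ndarray:
        return self.probs[:, self.state_space.index(state)]


def _grid(horizon: float, step: float) -> np.ndarray:
    n = int(round(horizon / step))
    g = np.linspace(0.0, n * step, n + 1)
    if g[-1] < horizon - 1e-12:
        g = np.append(g, horizon)
    return g


def occupancy(
    model: RateModel,
    horizon: float = 6.0,
    step: float = 0.1,
    covariates: Mapping[str, float] | None = None,
    entry_clock: float | None = None,
    shift_schedule: ShiftSchedule = ShiftSchedule(),
    start_state: int = TRIAGE,
) -> OccupancyCurve:
    """Occupancy distribution over ``[0, horizon]`` after entering at triage.

    For a homogeneous model the curve is a row of ``expm(Q t)``.  For a
    shift-stratified model ``entry_clock`` (clock hour of entry, 0-24) is
    required; the distribution is pushed through each shift window with that
    window's generator, evaluating at every grid time.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    space = model.state_space
    times = _grid(horizon, step)
    p = np.zeros(len(space.states))
    p[space.index(start_state)] = 1.0

    if model.shifts is None:
        Q = generator_matrix(model, covariates)
        probs = np.empty((len(times), len(p)))
        probs[0] = p
        E = expm(Q * step)
        for k in range(1, len(times)):
            dt = times[k] - times[k - 1]
            probs[k] = probs[k - 1] @ (E if abs(dt - step) < 1e-12 else expm(Q * dt))
        return OccupancyCurve(times=times, probs=probs, covariates=dict(covariates or {}))

    if entry_clock is None:
        raise ValueError("shift-stratified model requires entry_clock")
    entry_shift = int(shift_schedule.shift_of(entry_clock))
    Qs = {
        s: generator_matrix(model, covariates, shift=s)
        for s in range(shift_schedule.n_shifts)
    }
    probs = np.empty((len(times), len(p)))
    probs[0] = p
    t_now = 0.0
    for k in range(1, len(times)):
        t_next = times[k]
        while t_now < t_next - 1e-12:
            boundary = shift_schedule.next_boundary(entry_clock + t_now) - entry_clock
            t_stop = min(boundary, t_next)
            s = int(shift_schedule.shift_of(entry_clock + t_now))
            p = p @ expm(Qs[s] * (t_stop - t_now))
            t_now = t_stop
        probs[k] = p
    return OccupancyCurve(
        times=times, probs=probs, entry_clock=entry_clock,
        entry_shift=entry_shift, covariates=dict(covariates or {}),
    )


def in_system_probability(curve: OccupancyCurve) -> np.ndarray:
    """P(not yet absorbed) at each grid time: 1 - P(discharge) - P(admission)."""
    space = curve.state_space
    return 1.0 - curve.probs[:, space.index(DISCHARGE)] - curve.probs[:, space.index(ADMISSION)]


def empirical_occupancy(
    cohort: pd.DataFrame, times: np.ndarray, space: StateSpace = StateSpace()
) -> np.ndarray:
    """Monte-Carlo occupancy from a simulated cohort frame.

    For each time since arrival, the fraction of patients whose recorded
    entry/departure timestamps place them in each state.  Used as the
    simulation cross-check for :func:`occupancy`.
    """
    t_phys = pd.to_numeric(cohort["t_physician_h"], errors="coerce").to_numpy(float)
    t_obs = pd.to_numeric(cohort["t_observation_h"], errors="coerce").to_numpy(float)
    t_dep = pd.to_numeric(cohort["t_departure_h"], errors="coerce").to_numpy(float)
    absorbed_to = np.where(
        cohort["disposition"].to_numpy() == "discharge", DISCHARGE, ADMISSION
    )
    n = len(cohort)
    out = np.empty((len(times), len(space.states)))
    for k, t in enumerate(times):
        state = np.full(n, TRIAGE)
        in_phys = ~np.isnan(t_phys) & (t >= t_phys)
        state[in_phys] = 2
        in_obs = ~np.isnan(t_obs) & (t >= t_obs)
        state[in_obs] = 3
        gone = t >= t_dep
        state[gone] = absorbed_to[gone]
        out[k] = [(state == s).mean() for s in space.states]
    return out


def movement_report(
    model: RateModel,
    occupancy_counts: Mapping[int, float],
    rr: Mapping[tuple[Transition, str], tuple] | None = None,
    covariates: Mapping[str, float] | None = None,
) -> str:
    """Markdown table of movement rates and expected steady-state hourly counts.

    One row per allowed movement: the intensity, the expected number of
    movements per hour given the supplied state occupancy counts (a dash for
    states whose census is not supplied), and optional relative-rate columns.
    """
    counts = steady_flow_counts(model, occupancy_counts, covariates)
    cov_names: list[str] = []
    if rr:
        for (_, c) in rr:
            if c not in cov_names:
                cov_names.append(c)
    header = ["Patient movement", "Rate (/person-h)", "Moves/h (steady)"]
    header += [f"RR: {c}" for c in cov_names]
    lines = ["| " + " | ".join(header) + " |",
             "|" + "|".join(["---"] * len(header)) + "|"]
    for t in sorted(model.baseline):
        i, j = t
        name = f"{STATE_NAMES[i]} → {STATE_NAMES[j]}"
        count = str(counts[t]) if t in counts else "—"
        row = [name, f"{model.baseline[t]:g}", count]
        for c in cov_names:
            iv = rr.get((t, c)) if rr else None
            row.append(f"{iv[0]:.3f}" if iv is not None else "—")
        lines.append("| " + " | ".join(row) + " |")
    return "\n".join(lines) + "\n"
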