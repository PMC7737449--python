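"""Five-state continuous-time Markov model of emergency-department patient flow.

The state space is fixed by design: three transient states — triage (1),
physician management (2), observation / waiting-for-admission (3) — and two
absorbing states — discharge (4) and admission (5).  Seven transitions are
allowed::

    1 -> 2   triage to physician
    1 -> 4   departure directly from triage (left without being seen)
    2 -> 3   physician to observation room
    2 -> 4   physician to discharge
    2 -> 5   physician to admission
    3 -> 4   observation to discharge
    3 -> 5   observation to admission

Each transition carries an intensity ``q_ij`` (events per person-hour).
Covariates act multiplicatively on intensities through a log-linear model,
``q_ij(z) = q_ij0 * exp(sum_c beta_ijc * z_c)``, so ``exp(beta)`` is the
relative rate (RR) per unit covariate increment.  Intensities may optionally
be stratified by four six-hour clock shifts (piecewise-constant in clock
time).  All times are in hours; this is fixed, not configurable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import expm

TRIAGE, PHYSICIAN, OBSERVATION, DISCHARGE, ADMISSION = 1, 2, 3, 4, 5

STATE_NAMES: dict[int, str] = {
    TRIAGE: "triage",
    PHYSICIAN: "physician",
    OBSERVATION: "observation",
    DISCHARGE: "discharge",
    ADMISSION: "admission",
}

#: The seven permitted movements, ordered.
TRANSITIONS: tuple[tuple[int, int], ...] = (
    (1, 2), (1, 4), (2, 3), (2, 4), (2, 5), (3, 4), (3, 5),
)

Transition = tuple[int, int]


@dataclass(frozen=True)
class StateSpace:
    """The fixed five-state space with its allowed transitions.

    Invariants are checked on construction: absorbing states have no exits,
    every transient state has at least one exit, and transitions connect
    known states.
    """

    states: tuple[int, ...] = (1, 2, 3, 4, 5)
    transitions: frozenset[Transition] = frozenset(TRANSITIONS)
    absorbing: frozenset[int] = frozenset({DISCHARGE, ADMISSION})

    def __post_init__(self) -> None:
        for i, j in self.transitions:
            if i not in self.states or j not in self.states:
                raise ValueError(f"transition ({i},{j}) uses unknown state")
            if i in self.absorbing:
                raise ValueError(f"absorbing state {i} must not have exits")
        for s in self.states:
            if s not in self.absorbing and not any(i == s for i, _ in self.transitions):
                raise ValueError(f"transient state {s} has no outgoing transition")

    @property
    def transient(self) -> tuple[int, ...]:
        return tuple(s for s in self.states if s not in self.absorbing)

    def index(self, state: int) -> int:
        """0-based matrix index of a state label."""
        return self.states.index(state)


@dataclass(frozen=True)
class ShiftSchedule:
    """Partition of the 24-hour day into half-open clock intervals.

    Default: four six-hour shifts [0,6) night, [6,12) morning,
    [12,18) afternoon, [18,24) evening.
    """

    boundaries: tuple[float, ...] = (0.0, 6.0, 12.0, 18.0, 24.0)
    labels: tuple[str, ...] = ("night", "morning", "afternoon", "evening")

    def __post_init__(self) -> None:
        b = self.boundaries
        if b[0] != 0.0 or b[-1] != 24.0 or any(x >= y for x, y in zip(b, b[1:])):
            raise ValueError("boundaries must increase from 0 to 24")
        if len(self.labels) != len(b) - 1:
            raise ValueError("one label per interval required")

    @property
    def n_shifts(self) -> int:
        return len(self.labels)

    def shift_of(self, clock_hours):
        """Shift index containing a clock time (hours, wrapped modulo 24).

        Accepts scalars or arrays.
        """
        h = np.asarray(clock_hours, dtype=float) % 24.0
        idx = np.searchsorted(np.asarray(self.boundaries), h, side="right") - 1
        idx = np.clip(idx, 0, self.n_shifts - 1)
        return idx if idx.ndim else int(idx)

    def next_boundary(self, clock_hours: float) -> float:
        """Clock time of the first boundary strictly after ``clock_hours``."""
        h = clock_hours % 24.0
        for b in self.boundaries[1:]:
            if b > h:
                return clock_hours + (b - h)
        return clock_hours + (24.0 - h)


def _parse_transition(key: str) -> Transition:
    i, j = key.split("->")
    return int(i), int(j)


def _fmt_transition(t: Transition) -> str:
    return f"{t[0]}->{t[1]}"


@dataclass
class RateModel:
    """Transition intensities with log-linear covariate effects.

    Parameters
    ----------
    baseline
        Map transition -> intensity ``q_ij`` (per person-hour, > 0).
    effects
        Map transition -> {covariate name -> log-coefficient beta}.  The
        relative rate per unit covariate increment is ``exp(beta)``.
    shifts
        Optional map shift index -> full baseline override, one rate per
        transition, for piecewise-constant (shift-based) models.
    """

    baseline: dict[Transition, float]
    effects: dict[Transition, dict[str, float]] = field(default_factory=dict)
    shifts: dict[int, dict[Transition, float]] | None = None
    state_space: StateSpace = field(default_factory=StateSpace)

    def __post_init__(self) -> None:
        allowed = self.state_space.transitions
        for t, q in self.baseline.items():
            if t not in allowed:
                raise ValueError(f"rate on disallowed transition {t}")
            if not (0.0 < q < math.inf):
                raise ValueError(f"baseline rate for {t} must be positive finite, got {q}")
        for t in self.effects:
            if t not in allowed:
                raise ValueError(f"effect on disallowed transition {t}")
        if self.shifts is not None:
            for s, table in self.shifts.items():
                if set(table) != set(self.baseline):
                    raise ValueError(f"shift {s} must define a rate for every transition")
                for t, q in table.items():
                    if not (0.0 < q < math.inf):
                        raise ValueError(f"shift {s} rate for {t} must be positive finite")

    # -- covariates ---------------------------------------------------------

    @property
    def covariate_names(self) -> tuple[str, ...]:
        names: list[str] = []
        for table in self.effects.values():
            for c in table:
                if c not in names:
                    names.append(c)
        return tuple(names)

    def _check_covariates(self, covariates: Mapping[str, float] | None) -> Mapping[str, float]:
        covariates = dict(covariates or {})
        known = set(self.covariate_names)
        unknown = set(covariates) - known
        if unknown:
            raise KeyError(f"unknown covariate name(s): {sorted(unknown)}")
        missing = known - set(covariates)
        if missing:
            raise KeyError(f"missing covariate value(s): {sorted(missing)}")
        return covariates

    def rate(
        self,
        transition: Transition,
        covariates: Mapping[str, float] | None = None,
        shift: int | None = None,
    ) -> float:
        """Intensity of one transition at given covariates (and shift)."""
        covariates = self._check_covariates(covariates)
        base = self.baseline if shift is None or self.shifts is None else self.shifts[shift]
        q = base[transition]
        for name, beta in self.effects.get(transition, {}).items():
            q *= math.exp(beta * covariates[name])
        return q

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d: dict = {"baseline": {_fmt_transition(t): q for t, q in self.baseline.items()}}
        if self.effects:
            d["effects"] = {
                _fmt_transition(t): dict(tab) for t, tab in self.effects.items()
            }
        if self.shifts is not None:
            d["shifts"] = {
                str(s): {_fmt_transition(t): q for t, q in tab.items()}
                for s, tab in self.shifts.items()
            }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RateModel":
        baseline = {_parse_transition(k): float(v) for k, v in d["baseline"].items()}
        effects = {
            _parse_transition(k): {c: float(b) for c, b in tab.items()}
            for k, tab in d.get("effects", {}).items()
        }
        shifts = None
        if "shifts" in d:
            shifts = {
                int(s): {_parse_transition(k): float(v) for k, v in tab.items()}
                for s, tab in d["shifts"].items()
            }
        return cls(baseline=baseline, effects=effects, shifts=shifts)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "RateModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Closed-form quantities derived from a generator matrix
# ---------------------------------------------------------------------------

def generator_matrix(
    model: RateModel,
    covariates: Mapping[str, float] | None = None,
    shift: int | None = None,
) -> np.ndarray:
    """Build the 5x5 generator (intensity) matrix Q.

    Off-diagonal entries are ``q_ij * exp(sum beta*z)`` for allowed
    transitions and zero otherwise; each diagonal entry is minus its row sum,
    so rows sum to zero and absorbing rows are identically zero.
    """
    space = model.state_space
    n = len(space.states)
    Q = np.zeros((n, n))
    for t in model.baseline:
        q = model.rate(t, covariates, shift)
        if not q > 0.0:
            raise ValueError(f"nonpositive rate computed for {t}: corrupted model")
        Q[space.index(t[0]), space.index(t[1])] = q
    np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
    return Q


def _check_transient(Q: np.ndarray, state: int, space: StateSpace) -> int:
    if state in space.absorbing:
        raise ValueError(f"state {state} ({STATE_NAMES.get(state)}) is absorbing")
    return space.index(state)


def embedded_jump_probs(
    Q: np.ndarray, state: int, space: StateSpace = StateSpace()
) -> dict[int, float]:
    """Destination distribution of the embedded jump chain from one state.

    ``P(j) = Q[i,j] / (-Q[i,i])``; probabilities sum to one.
    """
    i = _check_transient(Q, state, space)
    total = -Q[i, i]
    return {
        space.states[j]: Q[i, j] / total
        for j in range(Q.shape[0])
        if j != i and Q[i, j] > 0.0
    }


def sojourn_stats(
    Q: np.ndarray, state: int, space: StateSpace = StateSpace()
) -> dict[str, float]:
    """Sojourn-time summaries for a transient state.

    The waiting time in state *i* before any movement is exponential with
    rate equal to the total exit intensity ``r = -Q[i,i]``: mean ``1/r``,
    median ``ln 2 / r`` (hours).  Note the mean waiting time for a
    *particular* destination j in isolation is ``1/q_ij``; what is reported
    here is the competing-risks waiting time in the state.
    """
    i = _check_transient(Q, state, space)
    rate = -Q[i, i]
    return {"rate": rate, "mean": 1.0 / rate, "median": math.log(2.0) / rate}


def absorption_probabilities(
    Q: np.ndarray, start: int, space: StateSpace = StateSpace()
) -> dict[int, float]:
    """First-passage (absorption) probabilities into each absorbing state.

    The transition graph is acyclic (states are topologically ordered by
    label), so the hitting probabilities solve by back-substitution from the
    absorbing states upward.
    """
    absorbing = sorted(space.absorbing)
    h: dict[int, dict[int, float]] = {a: {b: float(a == b) for b in absorbing} for a in absorbing}
    for s in sorted(space.transient, reverse=True):
        jumps = embedded_jump_probs(Q, s, space)
        h[s] = {
            a: sum(p * h[j][a] for j, p in jumps.items()) for a in absorbing
        }
    return h[start]


def transition_probability(
    Q: np.ndarray, t: float
) -> np.ndarray:
    """Transition-probability matrix ``P(t) = expm(Q t)``.

    Computed by scipy's scaling-and-squaring matrix exponential on the full
    generator.  Rows sum to one; entries lie in [0, 1].
    """
    if t < 0:
        raise ValueError("time must be nonnegative")
    return expm(Q * t)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def steady_flow_counts(
    model: RateModel,
    occupancy: Mapping[int, float],
    covariates: Mapping[str, float] | None = None,
    shift: int | None = None,
) -> dict[Transition, int]:
    """Expected hourly movement counts in a steady system.

    For each transition out of a state whose occupant count is supplied,
    ``count(i->j) = round(q_ij * occupancy[i])`` with round-half-away-from-
    zero.  Transitions out of states missing from ``occupancy`` are omitted
    (e.g. triage, whose census is typically not tracked as a bed count).
    """
    if any(v < 0 for v in occupancy.values()):
        raise ValueError("occupancy counts must be nonnegative")
    out: dict[Transition, int] = {}
    for t in sorted(model.baseline):
        if t[0] in occupancy:
            out[t] = _round_half_away(model.rate(t, covariates, shift) * occupancy[t[0]])
    return out
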