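"""Reference parameter values used as defaults throughout the package.

The numbers describe patient flow in a high-volume tertiary-centre emergency
department (~150,000 visits/year): baseline movement intensities per
person-hour, relative rates (RR) of the triage level (1 = most acute … 5)
and 20-year age group (1 = <20 … 5 = >80) on each movement, four-shift
values for the observation-to-admission intensity, and the marginal
covariate distributions of such a cohort.  They serve as the default
generating model for synthetic cohorts and as ground truth in the
simulate-and-refit tests.
"""

from __future__ import annotations

import math

from .state_model import RateModel, ShiftSchedule, Transition

#: Baseline movement intensities q_ij, per person-hour.
BASELINE_RATES: dict[Transition, float] = {
    (1, 2): 4.224,    # triage -> physician
    (1, 4): 0.0005,   # triage -> departure (left without being seen)
    (2, 3): 0.099,    # physician -> observation room
    (2, 4): 0.235,    # physician -> discharge
    (2, 5): 0.046,    # physician -> admission
    (3, 4): 0.0114,   # observation -> discharge
    (3, 5): 0.0189,   # observation -> admission
}

#: Relative rate of a one-level triage increase (toward lower acuity).
TRIAGE_RR: dict[Transition, float] = {
    (1, 2): 0.962,
    (1, 4): 1.481,
    (2, 3): 0.673,
    (2, 4): 1.891,
    (2, 5): 0.757,
    (3, 4): 1.650,
    (3, 5): 0.842,
}

#: Relative rate of a one-step (20-year) age-group increase.
AGE_RR: dict[Transition, float] = {
    (1, 2): 1.134,
    (1, 4): 1.174,
    (2, 3): 1.549,
    (2, 4): 0.773,
    (2, 5): 0.830,
    (3, 4): 0.619,
    (3, 5): 0.910,
}

#: Observation -> admission intensity by shift (night/morning/afternoon/evening).
SHIFT_Q35: tuple[float, float, float, float] = (0.0012, 0.0069, 0.0390, 0.0327)

def _from_counts(*counts: int) -> tuple[float, ...]:
    total = sum(counts)
    return tuple(n / total for n in counts)


# Cohort covariate marginals (normalized counts from a ~148k-visit year).
TRIAGE_LEVEL_PROBS: tuple[float, ...] = _from_counts(8253, 22483, 88546, 26138, 2477)
AGE_GROUP_PROBS: tuple[float, ...] = _from_counts(43318, 31694, 33867, 28501, 10527)
CATEGORIES: tuple[str, ...] = ("trauma", "adult-nontrauma", "pediatric-nontrauma")
CATEGORY_PROBS: tuple[float, ...] = _from_counts(26067, 87494, 34336)

#: Default arrival weight per shift (night, morning, afternoon, evening).
ARRIVAL_WEIGHTS: tuple[float, float, float, float] = (0.15, 0.30, 0.30, 0.25)

DEFAULT_SHIFT_SCHEDULE = ShiftSchedule()


def default_model(
    effects: dict[Transition, dict[str, float]] | None = None,
) -> RateModel:
    """Homogeneous reference model at the baseline intensities."""
    return RateModel(baseline=dict(BASELINE_RATES), effects=effects or {})


def effects_from_rr(
    rr_by_transition: dict[Transition, float], covariate: str
) -> dict[Transition, dict[str, float]]:
    """Convert per-transition relative rates into log-coefficient effects."""
    return {t: {covariate: math.log(rr)} for t, rr in rr_by_transition.items()}


def shift_model_q35() -> RateModel:
    """Shift-stratified reference model.

    All intensities are at baseline in every shift except observation ->
    admission, which takes its four per-shift values.
    """
    shifts = {}
    for s, q35 in enumerate(SHIFT_Q35):
        table = dict(BASELINE_RATES)
        table[(3, 5)] = q35
        shifts[s] = table
    return RateModel(baseline=dict(BASELINE_RATES), shifts=shifts)
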