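"""Estimation of transition intensities from event records.

The data are exact-observation: every state entry and exit is timestamped,
so the likelihood of a visit factorizes over its state spells.  A spell in
state *i* of length *t* ending with a movement to *j* contributes
``q_ij(z) * exp(-r_i(z) t)`` where ``r_i`` is the total exit intensity.
Consequences used throughout:

* Without covariates the MLE is closed-form, ``q_ij = N_ij / T_i`` (events
  over person-time), with Wald intervals on the log scale.
* With log-linear covariate effects ``q_ij(z) = q_ij0 exp(beta·z)``, each
  transition's likelihood is exactly that of a Poisson regression on the
  spell-level event indicator with a log person-time offset; it is maximized
  here by Newton iteration (IRLS).
* The likelihood factorizes over transitions, so shift-stratified fits
  partition spells by the shift in force at state entry, and the Metropolis
  sampler runs an independent chain per log-rate.
"""

from __future__ import annotations

import logging
import math
from collections import namedtuple
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .simulate import frame_from_records
from .state_model import (
    ADMISSION, DISCHARGE, OBSERVATION, PHYSICIAN, TRIAGE,
    TRANSITIONS, RateModel, ShiftSchedule, StateSpace, Transition,
)

logger = logging.getLogger(__name__)

#: Point estimate with a 95% interval.
Interval = namedtuple("Interval", ["estimate", "low", "high"])

#: Sojourns of exactly zero (tied timestamps) are nudged by one second.
ZERO_SOJOURN_JITTER_H = 1.0 / 3600.0

SPELL_COLUMNS = [
    "patient_id", "state", "entry_clock_h", "sojourn_h", "dest",
    "triage_level", "age_group",
]


@dataclass
class SufficientStats:
    """Per-transition event counts and per-state person-time at risk.

    ``spells`` retains the spell-level rows (one per patient-state visit)
    needed for covariate and shift-stratified fits; the aggregate
    ``n_events`` / ``person_time`` are all the closed-form MLE needs.
    """

    n_events: dict[Transition, int]
    person_time: dict[int, float]
    spells: pd.DataFrame | None = None
    n_jittered: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.n_events.values()):
            raise ValueError("event counts must be nonnegative")
        if any(v < 0 for v in self.person_time.values()):
            raise ValueError("person-time must be nonnegative")


@dataclass
class FitResult:
    """Estimated intensities and covariate relative rates with 95% intervals."""

    rates: dict[Transition, Interval]
    rr: dict[tuple[Transition, str], Interval] = field(default_factory=dict)
    loglik: float = float("nan")
    method: str = "mle"
    shift: int | None = None
    flagged: list = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    def rate_model(self) -> RateModel:
        """Point-estimate RateModel (positive rates only)."""
        baseline = {t: iv.estimate for t, iv in self.rates.items() if iv.estimate > 0}
        effects: dict[Transition, dict[str, float]] = {}
        for (t, cov), iv in self.rr.items():
            effects.setdefault(t, {})[cov] = math.log(iv.estimate)
        return RateModel(baseline=baseline, effects=effects)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "shift": self.shift,
            "loglik": self.loglik,
            "rates": {
                f"{i}->{j}": list(iv) for (i, j), iv in sorted(self.rates.items())
            },
            "rr": {
                f"{i}->{j}:{c}": list(iv)
                for ((i, j), c), iv in sorted(self.rr.items(), key=str)
            },
            "flagged": [str(x) for x in self.flagged],
            "diagnostics": self.diagnostics,
        }


# ---------------------------------------------------------------------------
# Sufficient statistics
# ---------------------------------------------------------------------------

def _arrival_clock_hours(arrival: pd.Series) -> np.ndarray:
    ts = pd.to_datetime(arrival)
    return ((ts - ts.dt.normalize()).dt.total_seconds() / 3600.0).to_numpy()


def spells_from_frame(
    df: pd.DataFrame, on_invalid: str = "raise"
) -> tuple[pd.DataFrame, int]:
    """Explode the one-row-per-patient frame into state spells.

    Returns ``(spells, n_jittered)``.  Records with non-monotone timestamps
    are rejected: ``on_invalid='raise'`` aborts naming the offending ids,
    ``'skip'`` drops them with a warning.  Zero-length sojourns (tied
    timestamps) are nudged forward by one second and counted.
    """
    df = df.reset_index(drop=True)
    t_phys = pd.to_numeric(df["t_physician_h"], errors="coerce").to_numpy(float)
    t_obs = pd.to_numeric(df["t_observation_h"], errors="coerce").to_numpy(float)
    t_dep = pd.to_numeric(df["t_departure_h"], errors="coerce").to_numpy(float)
    clock0 = _arrival_clock_hours(df["arrival_iso8601"])
    disp = np.where(df["disposition"].to_numpy() == "discharge", DISCHARGE, ADMISSION)

    has_phys, has_obs = ~np.isnan(t_phys), ~np.isnan(t_obs)
    end1 = np.where(has_phys, t_phys, t_dep)
    end2 = np.where(has_obs, t_obs, t_dep)

    bad = np.isnan(t_dep) | (end1 < 0)
    bad |= has_phys & (np.where(has_obs, t_obs, t_dep) < t_phys)
    bad |= has_obs & ((t_dep < t_obs) | ~has_phys)
    if bad.any():
        ids = df.loc[bad, "patient_id"].tolist()
        msg = f"{bad.sum()} record(s) with invalid timestamps: {ids[:10]}"
        if on_invalid == "skip":
            logger.warning("%s — skipped", msg)
        else:
            raise ValueError(msg)

    ok = ~bad
    pieces = []
    for state, sel, entry, sojourn, dest in [
        (TRIAGE, ok, np.zeros(len(df)), end1, np.where(has_phys, PHYSICIAN, disp)),
        (PHYSICIAN, ok & has_phys, t_phys, end2 - t_phys,
         np.where(has_obs, OBSERVATION, disp)),
        (OBSERVATION, ok & has_obs, t_obs, t_dep - t_obs, disp),
    ]:
        sub = pd.DataFrame(
            {
                "patient_id": df.loc[sel, "patient_id"].to_numpy(),
                "state": state,
                "entry_clock_h": (clock0[sel] + entry[sel]) % 24.0,
                "sojourn_h": sojourn[sel],
                "dest": dest[sel],
                "triage_level": df.loc[sel, "triage_level"].to_numpy(),
                "age_group": df.loc[sel, "age_group"].to_numpy(),
            }
        )
        pieces.append(sub)
    spells = pd.concat(pieces, ignore_index=True)

    zero = spells["sojourn_h"] <= 0.0
    n_jittered = int(zero.sum())
    if n_jittered:
        logger.info("jittered %d zero-length sojourn(s) by 1 s", n_jittered)
        spells.loc[zero, "sojourn_h"] = ZERO_SOJOURN_JITTER_H
    return spells, n_jittered


def extract_stats(
    records, shift_schedule: ShiftSchedule | None = None, on_invalid: str = "raise"
) -> SufficientStats:
    """Tally event counts and person-time from patient records.

    ``records`` may be a cohort frame or a sequence of
    :class:`~edflow.simulate.PatientRecord`.  With a shift schedule, each
    spell (and its event) is attributed wholly to the shift containing its
    state-entry clock time; the shift index is kept on the spell rows.
    """
    if not isinstance(records, pd.DataFrame):
        records = frame_from_records(list(records))
    if len(records) == 0:
        return SufficientStats(
            n_events={t: 0 for t in TRANSITIONS},
            person_time={s: 0.0 for s in (TRIAGE, PHYSICIAN, OBSERVATION)},
            spells=pd.DataFrame(columns=SPELL_COLUMNS),
        )
    spells, n_jittered = spells_from_frame(records, on_invalid=on_invalid)
    if shift_schedule is not None:
        spells["shift"] = shift_schedule.shift_of(spells["entry_clock_h"].to_numpy())
    grouped = spells.groupby(["state", "dest"]).size()
    n_events = {t: int(grouped.get(t, 0)) for t in TRANSITIONS}
    pt = spells.groupby("state")["sojourn_h"].sum()
    person_time = {s: float(pt.get(s, 0.0)) for s in (TRIAGE, PHYSICIAN, OBSERVATION)}
    return SufficientStats(
        n_events=n_events, person_time=person_time, spells=spells,
        n_jittered=n_jittered,
    )


# ---------------------------------------------------------------------------
# Maximum likelihood
# ---------------------------------------------------------------------------

def exact_loglik(stats: SufficientStats, model: RateModel) -> float:
    """Exact-observation log-likelihood of aggregate stats under fixed rates.

    ``sum_ij [N_ij log q_ij - q_ij T_i]`` — no omitted constant; this equals
    the sum over patients of log exponential densities times jump
    probabilities.
    """
    ll = 0.0
    for (i, j), q in model.baseline.items():
        n = stats.n_events.get((i, j), 0)
        ll += n * math.log(q) - q * stats.person_time.get(i, 0.0)
    return ll


def fit_mle(stats: SufficientStats, level: float = 0.95) -> FitResult:
    """Closed-form intensity MLE ``q_ij = N_ij / T_i`` with Wald intervals.

    Transitions with zero events get a rate estimate of 0 with an undefined
    interval and are flagged rather than raised.
    """
    z = norm.ppf(0.5 + level / 2.0)
    rates: dict[Transition, Interval] = {}
    flagged: list = []
    loglik = 0.0
    for t in TRANSITIONS:
        i, _ = t
        n = stats.n_events.get(t, 0)
        T = stats.person_time.get(i, 0.0)
        if n == 0:
            rates[t] = Interval(0.0, float("nan"), float("nan"))
            flagged.append(t)
            continue
        if T <= 0:
            raise ValueError(f"events on {t} but no person-time in state {i}")
        q = n / T
        half = z / math.sqrt(n)
        rates[t] = Interval(q, q * math.exp(-half), q * math.exp(half))
        loglik += n * math.log(q) - q * T
    return FitResult(rates=rates, loglik=loglik, method="mle", flagged=flagged)


def _transition_design(
    spells: pd.DataFrame, transition: Transition, covariates: list[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    sub = spells[spells["state"] == transition[0]]
    y = (sub["dest"].to_numpy() == transition[1]).astype(float)
    X = np.column_stack(
        [np.ones(len(sub))] + [sub[c].to_numpy(dtype=float) for c in covariates]
    )
    offset = np.log(sub["sojourn_h"].to_numpy(dtype=float))
    return X, y, offset


def _poisson_newton(
    X: np.ndarray, y: np.ndarray, offset: np.ndarray,
    tol: float = 1e-8, max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Newton/IRLS for the Poisson log-likelihood with offset.

    Returns (coefficients, covariance, converged).
    """
    beta = np.zeros(X.shape[1])
    # reasonable intercept start: log crude rate
    total_t = np.exp(offset).sum()
    if y.sum() > 0:
        beta[0] = math.log(y.sum() / total_t)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta + offset
        mu = np.exp(np.clip(eta, -700, 700))
        grad = X.T @ (y - mu)
        H = X.T @ (mu[:, None] * X)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # dampen huge steps (separation guard)
        norm_step = np.max(np.abs(step))
        if norm_step > 5.0:
            step *= 5.0 / norm_step
        beta = beta + step
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
    eta = X @ beta + offset
    mu = np.exp(np.clip(eta, -700, 700))
    H = X.T @ (mu[:, None] * X)
    cov = np.linalg.pinv(H)
    return beta, cov, converged


def fit_covariates(
    stats: SufficientStats,
    covariates: list[str],
    transitions: list[Transition] | None = None,
    level: float = 0.95,
) -> FitResult:
    """Proportional-intensity fit ``q_ij(z) = q_ij0 exp(beta·z)`` by Newton MLE.

    Each transition is a spell-level event-rate regression with log
    person-time offset; with an empty covariate list this reduces exactly to
    :func:`fit_mle`.  Relative rates are ``exp(beta)`` with Wald intervals.
    The reported log-likelihood is the exact-observation one, comparable
    across nested fits.
    """
    if stats.spells is None or len(stats.spells) == 0:
        raise ValueError("covariate fitting requires spell-level data")
    transitions = list(transitions) if transitions is not None else list(TRANSITIONS)
    z = norm.ppf(0.5 + level / 2.0)
    rates: dict[Transition, Interval] = {}
    rr: dict[tuple[Transition, str], Interval] = {}
    flagged: list = []
    loglik = 0.0
    n_iter_total = 0
    for t in transitions:
        X, y, offset = _transition_design(stats.spells, t, covariates)
        if len(y) == 0 or y.sum() == 0:
            rates[t] = Interval(0.0, float("nan"), float("nan"))
            flagged.append(t)
            continue
        beta, cov, converged = _poisson_newton(X, y, offset)
        if not converged:
            flagged.append((t, "non-convergence"))
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        if np.any(np.abs(beta[1:]) > 30):
            flagged.append((t, "possible separation"))
        q0 = math.exp(beta[0])
        rates[t] = Interval(
            q0, math.exp(beta[0] - z * se[0]), math.exp(beta[0] + z * se[0])
        )
        for k, c in enumerate(covariates, start=1):
            rr[(t, c)] = Interval(
                math.exp(beta[k]),
                math.exp(beta[k] - z * se[k]),
                math.exp(beta[k] + z * se[k]),
            )
        eta = X @ beta
        loglik += float(y @ eta - np.exp(eta + offset).sum())
    return FitResult(
        rates=rates, rr=rr, loglik=loglik, method="mle",
        flagged=flagged, diagnostics={"newton_iterations": n_iter_total},
    )


def fit_shift_model(
    records,
    shift_schedule: ShiftSchedule = ShiftSchedule(),
    covariates: list[str] | None = None,
) -> dict[int, FitResult]:
    """Shift-stratified fit: partition spells by state-entry shift, fit each.

    A shift with no spells for some state simply yields flagged zero-rate
    estimates for that state's transitions, as in :func:`fit_mle`.
    """
    stats = (
        records
        if isinstance(records, SufficientStats)
        else extract_stats(records, shift_schedule=shift_schedule)
    )
    spells = stats.spells
    if spells is None:
        raise ValueError("shift fitting requires spell-level data")
    if "shift" not in spells.columns:
        spells = spells.copy()
        spells["shift"] = shift_schedule.shift_of(spells["entry_clock_h"].to_numpy())
    results: dict[int, FitResult] = {}
    for s in range(shift_schedule.n_shifts):
        sub = spells[spells["shift"] == s]
        grouped = sub.groupby(["state", "dest"]).size()
        pt = sub.groupby("state")["sojourn_h"].sum()
        sub_stats = SufficientStats(
            n_events={t: int(grouped.get(t, 0)) for t in TRANSITIONS},
            person_time={
                st: float(pt.get(st, 0.0)) for st in (TRIAGE, PHYSICIAN, OBSERVATION)
            },
            spells=sub,
        )
        if covariates:
            res = fit_covariates(sub_stats, covariates)
        else:
            res = fit_mle(sub_stats)
        res.shift = s
        results[s] = res
    return results


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------

@dataclass
class McmcResult(FitResult):
    """Posterior summaries plus the retained draws per transition."""

    draws: dict[Transition, np.ndarray] = field(default_factory=dict)


def _log_posterior(x: float, n: int, T: float, prior) -> float:
    """Log posterior density of x = log q, up to a constant."""
    q = math.exp(x)
    ll = n * x - q * T
    kind = prior[0]
    if kind == "normal":
        _, mean, sd = prior
        ll += -0.5 * ((x - mean) / sd) ** 2
    elif kind == "gamma":
        # Gamma(a, rate b) on q, with log-Jacobian q for x = log q
        _, a, b = prior
        ll += a * x - b * q
    else:
        raise ValueError(f"unknown prior kind {kind!r}")
    return ll


def fit_mcmc(
    stats: SufficientStats,
    n_iter: int = 6000,
    burn_in: int = 1000,
    seed: int = 0,
    priors: dict[Transition, tuple] | None = None,
    init_scale: float = 0.3,
) -> McmcResult:
    """Random-walk Metropolis on the log intensities.

    The exact-observation likelihood factorizes over transitions, so each
    log-rate gets its own chain.  Default prior is Normal(0, 10) on
    ``log q`` (vague); a ``("gamma", a, b)`` prior on the rate scale is
    supported, for which the posterior is Gamma(a + N, b + T) in closed form
    and serves as a conjugate cross-check.  The proposal scale adapts toward
    ~35% acceptance during burn-in only.  Posterior medians and central 95%
    intervals are reported; acceptance rates outside [0.1, 0.6] are flagged.
    """
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    priors = priors or {}
    root = np.random.default_rng(seed)
    rates: dict[Transition, Interval] = {}
    draws: dict[Transition, np.ndarray] = {}
    flagged: list = []
    acc_rates: dict[str, float] = {}
    for t in TRANSITIONS:
        n = stats.n_events.get(t, 0)
        T = stats.person_time.get(t[0], 0.0)
        if T <= 0.0:
            rates[t] = Interval(0.0, float("nan"), float("nan"))
            flagged.append(t)
            continue
        prior = priors.get(t, ("normal", 0.0, 10.0))
        rng = np.random.default_rng(root.integers(2**31))
        x = math.log(max(n, 0.5) / T)
        lp = _log_posterior(x, n, T, prior)
        scale = init_scale
        chain = np.empty(n_iter - burn_in)
        accepted = 0
        window_acc = 0
        for it in range(n_iter):
            prop = x + scale * rng.standard_normal()
            lp_prop = _log_posterior(prop, n, T, prior)
            if math.log(rng.random()) < lp_prop - lp:
                x, lp = prop, lp_prop
                window_acc += 1
                if it >= burn_in:
                    accepted += 1
            if it < burn_in and (it + 1) % 100 == 0:
                scale *= math.exp((window_acc / 100.0) - 0.35)
                window_acc = 0
            if it >= burn_in:
                chain[it - burn_in] = x
        q_draws = np.exp(chain)
        lo, med, hi = np.quantile(q_draws, [0.025, 0.5, 0.975])
        rates[t] = Interval(float(med), float(lo), float(hi))
        draws[t] = q_draws
        acc = accepted / (n_iter - burn_in)
        acc_rates[f"{t[0]}->{t[1]}"] = acc
        if not 0.1 <= acc <= 0.6:
            flagged.append((t, f"acceptance rate {acc:.2f} outside [0.1, 0.6]"))
            logger.warning("transition %s: acceptance rate %.2f", t, acc)
    model = RateModel(
        baseline={t: iv.estimate for t, iv in rates.items() if iv.estimate > 0}
    )
    return McmcResult(
        rates=rates,
        loglik=exact_loglik(stats, model),
        method="mcmc",
        flagged=flagged,
        diagnostics={
            "n_iter": n_iter, "burn_in": burn_in, "acceptance_rates": acc_rates,
        },
        draws=draws,
    )
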