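"""End-to-end pipeline: describe → fit → predict → report, with a manifest.

Configuration travels as a YAML-serializable dataclass; every stage writes
its artifact into the output directory and the run closes with a manifest
(config echo, seed, package versions, stage timings).  Given the same
configuration and seed the artifacts are byte-identical.
"""

from __future__ import annotations

import json
import logging
import platform
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, presets
from .describe import describe, describe_markdown
from .inference import (
    extract_stats, fit_covariates, fit_mcmc, fit_mle, fit_shift_model,
)
from .prediction import in_system_probability, movement_report, occupancy
from .simulate import CohortConfig, read_cohort_csv, simulate_cohort, write_cohort_csv
from .state_model import RateModel, ShiftSchedule

logger = logging.getLogger(__name__)

#: Occupancy counts used in the steady-flow movement report:
#: treatment-bed area (physician state) and observation area.
DEFAULT_STEADY_OCCUPANCY = {2: 60, 3: 100}


@dataclass
class PipelineConfig:
    """Everything one run needs; YAML round-trippable."""

    input_csv: str | None = None        # simulate a cohort when None
    output_dir: str = "edflow_run"
    model_json: str | None = None       # generating/starting model; default preset
    estimator: str = "mle"              # "mle" | "mcmc"
    covariates: list[str] = field(default_factory=list)
    use_shifts: bool = False
    n_patients: int = 1000
    horizon_h: float = 6.0
    grid_step_h: float = 0.1
    entry_clock_h: float = 0.0
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.estimator not in ("mle", "mcmc"):
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _setup_logging(level: str, log_file: Path) -> None:
    root = logging.getLogger("edflow")
    root.setLevel(level.upper())
    root.handlers = [logging.StreamHandler(), logging.FileHandler(log_file)]
    fmt = logging.Formatter("%(asctime)s %(name)s %(levelname)s: %(message)s")
    for h in root.handlers:
        h.setFormatter(fmt)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute the full pipeline; returns {artifact name: path}.

    Stages: load-or-simulate → describe → fit → predict → report.  Any stage
    failure aborts with the stage named.  Deterministic given the seed.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(config.log_level, out / "run.log")
    artifacts: dict[str, Path] = {}
    timings: dict[str, float] = {}
    stage = "setup"
    try:
        model = (
            RateModel.from_json(config.model_json)
            if config.model_json
            else presets.default_model()
        )
        sched = ShiftSchedule()

        stage = "load"
        t0 = time.perf_counter()
        if config.input_csv:
            cohort = read_cohort_csv(config.input_csv)
        else:
            logger.info("no input CSV; simulating %d patients", config.n_patients)
            cohort = simulate_cohort(
                CohortConfig(
                    n_patients=config.n_patients, rate_model=model, seed=config.seed
                )
            )
            path = out / "cohort.csv"
            write_cohort_csv(cohort, path, seed=config.seed)
            artifacts["cohort"] = path
        timings[stage] = time.perf_counter() - t0

        stage = "describe"
        t0 = time.perf_counter()
        tables = describe(cohort)
        path = out / "describe.md"
        path.write_text(describe_markdown(tables))
        artifacts["describe"] = path
        timings[stage] = time.perf_counter() - t0

        stage = "fit"
        t0 = time.perf_counter()
        stats = extract_stats(cohort, shift_schedule=sched if config.use_shifts else None)
        if config.estimator == "mcmc":
            fit = fit_mcmc(stats, seed=config.seed)
        elif config.covariates:
            fit = fit_covariates(stats, list(config.covariates))
        else:
            fit = fit_mle(stats)
        payload = {"pooled": fit.to_dict()}
        if config.use_shifts:
            shift_fits = fit_shift_model(
                stats, sched, covariates=list(config.covariates) or None
            )
            payload["by_shift"] = {
                sched.labels[s]: r.to_dict() for s, r in shift_fits.items()
            }
        path = out / "fit.json"
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
        artifacts["fit"] = path
        timings[stage] = time.perf_counter() - t0

        stage = "predict"
        t0 = time.perf_counter()
        fitted = fit.rate_model()
        curve = occupancy(
            fitted, horizon=config.horizon_h, step=config.grid_step_h,
            entry_clock=config.entry_clock_h,
        )
        tidy = curve.to_frame()
        in_sys = pd.DataFrame(
            {"time_h": curve.times, "p_in_system": in_system_probability(curve)}
        )
        path = out / "occupancy.csv"
        tidy.to_csv(path, index=False)
        artifacts["occupancy"] = path
        path = out / "in_system.csv"
        in_sys.to_csv(path, index=False)
        artifacts["in_system"] = path
        timings[stage] = time.perf_counter() - t0

        stage = "report"
        t0 = time.perf_counter()
        path = out / "report.md"
        path.write_text(
            "# Movement rates and steady-state flow\n\n"
            + movement_report(fitted, DEFAULT_STEADY_OCCUPANCY, rr=fit.rr)
        )
        artifacts["report"] = path
        timings[stage] = time.perf_counter() - t0
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "versions": {
            "edflow": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "timings_s": {k: round(v, 4) for k, v in timings.items()},
        "artifacts": {k: str(v) for k, v in artifacts.items()},
    }
    path = out / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    artifacts["manifest"] = path
    return artifacts
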