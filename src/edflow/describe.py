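"""Descriptive statistics for a cohort: segment times, covariates, dispositions.

Times between care milestones are heavily right-skewed, so the centre and
spread reported are the median and interquartile range (Q3 - Q1, linear
interpolation).
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _segment_frames(df: pd.DataFrame) -> dict[str, np.ndarray]:
    t_phys = pd.to_numeric(df["t_physician_h"], errors="coerce").to_numpy(float)
    t_obs = pd.to_numeric(df["t_observation_h"], errors="coerce").to_numpy(float)
    t_dep = pd.to_numeric(df["t_departure_h"], errors="coerce").to_numpy(float)
    discharge = df["disposition"].to_numpy() == "discharge"
    has_phys, has_obs = ~np.isnan(t_phys), ~np.isnan(t_obs)

    direct = has_phys & ~has_obs  # departed straight from the physician state
    segments = {
        "total length of stay": t_dep,
        "triage to physician": t_phys[has_phys],
        "physician to observation room": (t_obs - t_phys)[has_obs],
        "triage (directly) to departure": t_dep[~has_phys],
        "physician (directly) to discharge": (t_dep - t_phys)[direct & discharge],
        "physician (directly) to admission": (t_dep - t_phys)[direct & ~discharge],
        "observation room to discharge": (t_dep - t_obs)[has_obs & discharge],
        "observation room to admission": (t_dep - t_obs)[has_obs & ~discharge],
    }
    return {k: v[~np.isnan(v)] for k, v in segments.items()}


def describe(df: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Summary tables for a cohort frame.

    Returns ``time_variables`` (per-segment n/median/IQR in hours),
    ``covariates`` (frequency tables for triage level, age group, category)
    and ``disposition`` (counts and fractions).
    """
    if len(df) == 0:
        raise ValueError("empty cohort")
    rows = []
    for name, x in _segment_frames(df).items():
        if len(x) == 0:
            rows.append((name, 0, float("nan"), float("nan")))
            continue
        q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])
        rows.append((name, len(x), med, q3 - q1))
    time_vars = pd.DataFrame(rows, columns=["segment", "n", "median_h", "iqr_h"])

    cov_rows = []
    for col in ("triage_level", "age_group", "category"):
        vc = df[col].value_counts().sort_index()
        for value, count in vc.items():
            cov_rows.append((col, value, int(count), count / len(df)))
    covariates = pd.DataFrame(cov_rows, columns=["variable", "value", "n", "fraction"])

    disp = df["disposition"].value_counts()
    disposition = pd.DataFrame(
        {
            "disposition": disp.index,
            "n": disp.to_numpy(),
            "fraction": disp.to_numpy() / len(df),
        }
    )
    return {
        "time_variables": time_vars,
        "covariates": covariates,
        "disposition": disposition,
    }


def frame_to_markdown(df: pd.DataFrame, floatfmt: str = ".3f") -> str:
    """Minimal markdown table rendering (no external table dependencies)."""
    def fmt(v):
        if isinstance(v, float):
            return format(v, floatfmt)
        return str(v)

    header = "| " + " | ".join(df.columns) + " |"
    sep = "|" + "|".join(["---"] * len(df.columns)) + "|"
    body = ["| " + " | ".join(fmt(v) for v in row) + " |" for row in df.itertuples(index=False)]
    return "\n".join([header, sep, *body])


def describe_markdown(tables: dict[str, pd.DataFrame]) -> str:
    """Render the describe() tables as a markdown report."""
    parts = []
    for title, df in tables.items():
        parts.append(f"## {title.replace('_', ' ')}\n")
        parts.append(frame_to_markdown(df))
        parts.append("")
    return "\n".join(parts) + "\n"
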