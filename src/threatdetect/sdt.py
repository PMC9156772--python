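"""Trial classification, exclusion handling, and SDT metrics.

Sensitivity and bias follow the equal-variance Gaussian model:
``d' = z(H) - z(F)`` and ``c = -(z(H) + z(F))/2`` with z the standard-normal
quantile function.  Extreme counts (no false alarms, or a perfect hit rate)
are corrected by a 0.25-count adjustment applied to the offending cell only
(0 -> 0.25 and n -> n - 0.25), so both metrics stay finite.

Trials are excluded from the behavioural analysis when the participant did
not respond, responded after 1500 ms, or the trial was flagged at design
time (extra/reinforced/shortened trials).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from threatdetect import schedule as sched
from threatdetect.errors import ContractError
from threatdetect.observer import RESPONSE_PRESENT, RESPONSE_NONE

RT_LIMIT_MS = 1500.0

HIT, MISS, FA, CR, EXCLUDED = "hit", "miss", "fa", "cr", "excluded"


@dataclass
class CellMetrics:
    """Per subject x design cell behavioural and physiological summary."""

    subject_id: int
    condition: str
    prior_context: str
    n_signal: int
    n_noise: int
    n_hit: float
    n_fa: float
    hit_rate: float
    fa_rate: float
    hit_rate_raw: float
    dprime: float
    criterion: float
    mean_rt_ms: float
    mean_delta_bpm: float
    mean_sqrt_scr: float


def classify_trial(trial: "sched.TrialSpec", result: dict) -> str:
    """Classify one trial as hit/miss/fa/cr or excluded."""
    response = result["response"]
    rt = result.get("rt_ms", float("nan"))
    if (
        not trial.included_in_analysis
        or response == RESPONSE_NONE
        or (np.isfinite(rt) and rt > RT_LIMIT_MS)
    ):
        return EXCLUDED
    present = response == RESPONSE_PRESENT
    if trial.stimulus == sched.TARGET:
        return HIT if present else MISS
    return FA if present else CR


def classify_trials(df: pd.DataFrame, rt_limit_ms: float = RT_LIMIT_MS) -> pd.DataFrame:
    """Vectorised classification; adds an ``outcome`` column to a copy of df.

    Expects the merged trial table (design columns plus ``response``/``rt_ms``).
    """
    out = df.copy()
    response = df["response"].to_numpy()
    rt = df["rt_ms"].to_numpy(float)
    included = df["included_in_analysis"].to_numpy(bool)
    is_target = df["stimulus"].to_numpy() == sched.TARGET
    present = response == RESPONSE_PRESENT

    outcome = np.where(is_target, np.where(present, HIT, MISS), np.where(present, FA, CR))
    outcome = outcome.astype(object)
    excluded = ~included | (response == RESPONSE_NONE) | (np.nan_to_num(rt) > rt_limit_ms)
    outcome[excluded] = EXCLUDED
    out["outcome"] = outcome
    return out


def corrected_rates(n_hit: float, n_signal: int, n_fa: float, n_noise: int):
    """Hit/FA rates with the 0.25-count correction for extreme cells.

    A cell with no false alarms gets 0.25 counts; a perfect hit cell loses
    0.25 counts.  Only the offending cell is touched (both, if both are
    extreme).  Rates are strictly inside (0, 1) afterwards.
    """
    if n_signal < 1 or n_noise < 1:
        raise ContractError("n_signal and n_noise must be at least 1")
    if n_hit < 0 or n_fa < 0:
        raise ContractError("counts must be non-negative")
    h = n_hit
    f = n_fa
    if h >= n_signal:
        h = n_signal - 0.25
    elif h <= 0:
        h = 0.25
    if f <= 0:
        f = 0.25
    elif f >= n_noise:
        f = n_noise - 0.25
    return h / n_signal, f / n_noise


def sdt_metrics(hit_rate: float, fa_rate: float) -> tuple[float, float]:
    """Equal-variance d' and criterion from rates strictly inside (0, 1)."""
    if not (0.0 < hit_rate < 1.0 and 0.0 < fa_rate < 1.0):
        raise ContractError("rates must lie strictly inside (0, 1); apply corrected_rates first")
    zh, zf = norm.ppf(hit_rate), norm.ppf(fa_rate)
    return float(zh - zf), float(-(zh + zf) / 2.0)


_POOLED = "pooled"


def aggregate_cells(
    df: pd.DataFrame,
    cells: str = "condition",
    rt_limit_ms: float = RT_LIMIT_MS,
) -> pd.DataFrame:
    """Per-subject cell metrics over the included experimental trials.

    ``cells`` selects the design partition: ``"condition"`` pools over the
    target-frequency manipulation (one threat and one safe row per subject);
    ``"condition_x_context"`` crosses threat/safe with rare/frequent;
    ``"context"`` pools over threat/safe (criterion-manipulation check).

    RT is averaged over responded target trials (hits and misses); the
    physiological columns, when present, are averaged over all classified
    trials of the cell.  Empty cells yield NaN metrics with a warning.
    """
    if cells == "overall":
        by = []
    elif cells == "condition":
        by = ["condition"]
    elif cells == "context":
        by = ["prior_context"]
    elif cells == "condition_x_context":
        by = ["condition", "prior_context"]
    else:
        raise ContractError(f"unknown cell partition {cells!r}")

    d = df if "outcome" in df.columns else classify_trials(df, rt_limit_ms)
    d = d[(d["phase"] == sched.EXPERIMENTAL) & (d["outcome"] != EXCLUDED)].copy()
    d["is_signal"] = d["outcome"].isin([HIT, MISS])
    d["is_noise"] = d["outcome"].isin([FA, CR])
    d["is_hit"] = d["outcome"] == HIT
    d["is_fa"] = d["outcome"] == FA
    d["rt_target"] = np.where(d["is_signal"], d["rt_ms"], np.nan)

    agg = {
        "is_signal": "sum",
        "is_noise": "sum",
        "is_hit": "sum",
        "is_fa": "sum",
        "rt_target": "mean",
    }
    for col, name in (("delta_bpm", "mean_delta_bpm"), ("sqrt_scr", "mean_sqrt_scr")):
        if col in d.columns:
            agg[col] = "mean"
    g = d.groupby(["subject_id"] + by, observed=True).agg(agg).reset_index()
    g = g.rename(
        columns={
            "is_signal": "n_signal",
            "is_noise": "n_noise",
            "is_hit": "n_hit",
            "is_fa": "n_fa",
            "rt_target": "mean_rt_ms",
            "delta_bpm": "mean_delta_bpm",
            "sqrt_scr": "mean_sqrt_scr",
        }
    )
    for col in ("mean_delta_bpm", "mean_sqrt_scr"):
        if col not in g.columns:
            g[col] = np.nan

    ok = (g["n_signal"] >= 1) & (g["n_noise"] >= 1)
    if not ok.all():
        warnings.warn(f"{(~ok).sum()} empty design cell(s); metrics set to NaN", stacklevel=2)
    hr = np.full(len(g), np.nan)
    fr = np.full(len(g), np.nan)
    for i in np.flatnonzero(ok.to_numpy()):
        hr[i], fr[i] = corrected_rates(
            g["n_hit"].iat[i], int(g["n_signal"].iat[i]), g["n_fa"].iat[i], int(g["n_noise"].iat[i])
        )
    g["hit_rate"] = hr
    g["fa_rate"] = fr
    g["hit_rate_raw"] = g["n_hit"] / g["n_signal"].where(g["n_signal"] > 0)
    with np.errstate(invalid="ignore"):
        zh, zf = norm.ppf(hr), norm.ppf(fr)
    g["dprime"] = zh - zf
    g["criterion"] = -(zh + zf) / 2.0
    if "condition" not in by:
        g["condition"] = _POOLED
    if "prior_context" not in by:
        g["prior_context"] = _POOLED

    cols = [
        "subject_id",
        "condition",
        "prior_context",
        "n_signal",
        "n_noise",
        "n_hit",
        "n_fa",
        "hit_rate",
        "fa_rate",
        "hit_rate_raw",
        "dprime",
        "criterion",
        "mean_rt_ms",
        "mean_delta_bpm",
        "mean_sqrt_scr",
    ]
    return g[cols]


def outcome_physio_cells(df: pd.DataFrame, value_col: str = "delta_bpm") -> pd.DataFrame:
    """Per-subject physiological means split by condition and hit/miss.

    Long-format table (subject_id, condition, detection, value) for the
    2x2 within-subject Threat x Target-detection ANOVA; only classified
    target trials enter.
    """
    d = df if "outcome" in df.columns else classify_trials(df)
    d = d[d["outcome"].isin([HIT, MISS])]
    if value_col not in d.columns:
        raise ContractError(f"column {value_col!r} not present in the trial table")
    g = (
        d.groupby(["subject_id", "condition", "outcome"], observed=True)[value_col]
        .mean()
        .reset_index()
        .rename(columns={"outcome": "detection", value_col: "value"})
    )
    return g
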