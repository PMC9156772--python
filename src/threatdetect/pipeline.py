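"""End-to-end study simulation and the full analysis battery.

``run_synthetic_study`` simulates a complete study (schedule -> staircase
calibration -> observer responses -> physiological traces -> scoring -> cell
aggregation) and runs every hypothesis test of the analysis plan;
``run_analysis`` applies the identical battery to an externally supplied
trial table (e.g. one written by an earlier run).

Subject recruitment mirrors the study's stopping rule: candidates are
screened (non-response rate > 33%, or task accuracy beyond 2 SD of the
pre-screening sample mean) and simulation continues until the configured
number of analysable subjects is reached.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from threatdetect import sdt
from threatdetect import schedule as sched
from threatdetect.errors import ContractError, ThreatDetectError
from threatdetect.observer import PopulationParams, sample_population, simulate_cohort
from threatdetect.physio_metrics import ScrScoringParams, bpm_series, detect_beats, score_trials
from threatdetect.physio_sim import (
    PhysioEffectParams,
    generate_bpm_trace,
    generate_eda_trace,
    generate_pulse_trace,
    session_timeline,
    subject_effects,
)
from threatdetect.staircase import StaircaseParams, calibrate_contrast
from threatdetect.stats import (
    GREATER,
    LESS,
    TWO,
    TestResult,
    art_anova_2x2,
    paired_t,
    rm_anova_2x2,
    spearman,
    wilcoxon_signed_rank,
)

PHYSIO_METRIC_COLUMNS = ["delta_bpm", "delta_bpm_stim", "scr_amplitude_us", "sqrt_scr"]


@dataclass
class StudyConfig:
    """Everything needed to reproduce one synthetic study."""

    seed: int = 0
    design: sched.DesignConfig = field(default_factory=sched.DesignConfig)
    population: PopulationParams = field(default_factory=PopulationParams)
    physio: PhysioEffectParams = field(default_factory=PhysioEffectParams)
    staircase: StaircaseParams = field(default_factory=StaircaseParams)
    scr_scoring: ScrScoringParams = field(default_factory=ScrScoringParams)
    include_physio: bool = True
    include_staircase: bool = True
    pulse_roundtrip: bool = True
    apply_exclusions: bool = True
    nonresponse_exclusion: float = 0.33
    accuracy_sd_exclusion: float = 2.0
    compute_ci: bool = True
    bootstrap_resamples: int = 2000
    block_break_s: float = 15.0

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "design": self.design.to_dict(),
            "population": self.population.to_dict(),
            "physio": self.physio.to_dict(),
            "staircase": self.staircase.__dict__.copy(),
            "scr_scoring": self.scr_scoring.__dict__.copy(),
            "include_physio": self.include_physio,
            "include_staircase": self.include_staircase,
            "pulse_roundtrip": self.pulse_roundtrip,
            "apply_exclusions": self.apply_exclusions,
            "nonresponse_exclusion": self.nonresponse_exclusion,
            "accuracy_sd_exclusion": self.accuracy_sd_exclusion,
            "compute_ci": self.compute_ci,
            "bootstrap_resamples": self.bootstrap_resamples,
            "block_break_s": self.block_break_s,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "StudyConfig":
        data = dict(data)
        cfg = cls(
            seed=data.pop("seed", 0),
            design=sched.DesignConfig.from_dict(data.pop("design", {})),
            population=PopulationParams.from_dict(data.pop("population", {})),
            physio=PhysioEffectParams.from_dict(data.pop("physio", {})),
            staircase=StaircaseParams(**data.pop("staircase", {})),
            scr_scoring=ScrScoringParams(**data.pop("scr_scoring", {})),
            **data,
        )
        cfg.scr_scoring.onset_window_s = tuple(cfg.scr_scoring.onset_window_s)
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class StudyResults:
    """Tidy outputs of one study: per-subject cells, hypothesis table, provenance."""

    subjects: pd.DataFrame
    trials: pd.DataFrame
    cells: dict[str, pd.DataFrame]
    hypotheses: pd.DataFrame
    provenance: dict

    def save(self, out_dir) -> None:
        from pathlib import Path

        from threatdetect import io as tdio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tdio.save_trials(self.trials, out / "trials.csv")
        self.subjects.to_csv(out / "subjects.csv", index=False)
        for name, cells in self.cells.items():
            cells.to_csv(out / f"cells_{name}.csv", index=False)
        self.hypotheses.to_csv(out / "hypotheses.csv", index=False)
        (out / "provenance.json").write_text(json.dumps(self.provenance, indent=1, default=float))


class _Stage:
    """Context manager that names the pipeline stage in any raised error."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and not isinstance(exc, ThreatDetectError):
            raise RuntimeError(f"pipeline stage '{self.name}' failed: {exc}") from exc
        if exc is not None:
            raise type(exc)(f"[stage {self.name}] {exc}") from exc


def _subject_summaries(trials: pd.DataFrame) -> pd.DataFrame:
    exp = trials[trials["phase"] == sched.EXPERIMENTAL]
    grp = exp.groupby("subject_id", observed=True)
    nonresponse = grp["response"].apply(lambda r: float(np.mean(r == "none")))
    classified = exp[exp["outcome"] != sdt.EXCLUDED]
    correct = (
        classified.assign(ok=classified["outcome"].isin([sdt.HIT, sdt.CR]))
        .groupby("subject_id", observed=True)["ok"]
        .mean()
    )
    out = pd.DataFrame({"nonresponse_fraction": nonresponse, "accuracy": correct})
    return out.reset_index()


def simulate_study_trials(config: StudyConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate behaviour (and physiology) for one study.

    Returns ``(subjects, trials)``: a per-subject table (latent parameters,
    screening outcome, staircase summary) and the flat trial table of the
    analysable subjects, with response columns, outcome classification, and
    -- when physiology is enabled -- per-trial heart-rate and SCR metrics.
    """
    pop = config.population
    n_target = pop.n_subjects
    pool_n = int(np.ceil(1.2 * n_target)) + 6 if config.apply_exclusions else n_target

    with _Stage("schedule"):
        frame = sched.build_cohort(config.design, pool_n, seed=config.seed)
    with _Stage("population"):
        observers = sample_population(replace(pop, n_subjects=pool_n), seed=[config.seed, 1])
    with _Stage("responses"):
        rng = np.random.default_rng([config.seed, 2])
        responses = simulate_cohort(
            observers, frame, rng, manip_mask_contrast=config.design.manip_mask_contrast
        )
        trials = pd.concat([frame, responses], axis=1)
        trials = sdt.classify_trials(trials)

    with _Stage("screening"):
        summaries = _subject_summaries(trials).set_index("subject_id")
        acc = summaries["accuracy"]
        wave = acc.iloc[:n_target]
        lo, hi = wave.mean() - config.accuracy_sd_exclusion * wave.std(ddof=1), wave.mean() + config.accuracy_sd_exclusion * wave.std(ddof=1)
        included, reasons = [], {}
        for sid in summaries.index:
            if not config.apply_exclusions:
                ok, why = True, ""
            elif summaries.loc[sid, "nonresponse_fraction"] > config.nonresponse_exclusion:
                ok, why = False, "nonresponse"
            elif not (lo <= summaries.loc[sid, "accuracy"] <= hi):
                ok, why = False, "accuracy"
            else:
                ok, why = True, ""
            reasons[sid] = why
            if ok:
                included.append(sid)
            if len(included) == n_target:
                break
        if len(included) < n_target:
            import warnings

            warnings.warn(
                f"recruited only {len(included)} of {n_target} analysable subjects",
                stacklevel=2,
            )

    subjects = pd.DataFrame({"subject_id": list(reasons.keys())})
    subjects["included"] = subjects["subject_id"].isin(included)
    subjects["exclusion_reason"] = subjects["subject_id"].map(reasons)
    subjects = subjects.merge(summaries.reset_index(), on="subject_id")
    obs_table = pd.DataFrame([o.to_dict() for o in observers])
    obs_table.insert(0, "subject_id", np.arange(pool_n))
    subjects = subjects.merge(
        obs_table[
            [
                "subject_id",
                "dprime_threat",
                "dprime_safe",
                "criterion_base",
                "criterion_shift_rare",
                "nonresponse_rate",
                "rt_mean_threat_ms",
                "rt_mean_safe_ms",
                "hr_coupling",
            ]
        ],
        on="subject_id",
    )

    trials = trials[trials["subject_id"].isin(included)].reset_index(drop=True)

    if config.include_staircase:
        with _Stage("staircase"):
            contrasts, accs = {}, {}
            for sid in included:
                srng = np.random.default_rng([config.seed, 3, int(sid)])
                cal = calibrate_contrast(observers[sid], params=config.staircase, rng=srng)
                contrasts[sid] = cal["contrast"]
                accs[sid] = cal["accuracy"]
            subjects["staircase_contrast"] = subjects["subject_id"].map(contrasts)
            subjects["staircase_accuracy"] = subjects["subject_id"].map(accs)

    if config.include_physio:
        with _Stage("physio"):
            metric_frames = []
            timed_frames = []
            for sid in included:
                sub = trials[trials["subject_id"] == sid].reset_index(drop=True)
                sub = session_timeline(sub, block_break_s=config.block_break_s)
                prng = np.random.default_rng([config.seed, 4, int(sid)])
                fx = subject_effects(config.physio, observers[sid].hr_coupling, prng)
                bpm = generate_bpm_trace(sub, sub[["response"]], fx, prng)
                if config.pulse_roundtrip:
                    pulse = generate_pulse_trace(bpm, prng)
                    beats = detect_beats(pulse)
                    bpm_scored = bpm_series(beats.times, rate_hz=fx.sample_rate_hz)
                else:
                    bpm_scored = bpm
                eda = generate_eda_trace(sub, sub[["response"]], fx, prng)
                metrics = score_trials(sub, bpm_scored, eda, config.scr_scoring)
                metrics.insert(0, "subject_id", sid)
                metric_frames.append(metrics)
                timed_frames.append(sub)
            trials = pd.concat(timed_frames, ignore_index=True)
            metrics_all = pd.concat(metric_frames, ignore_index=True)
            trials = trials.merge(metrics_all, on=["subject_id", "trial_index"], how="left")

    return subjects.reset_index(drop=True), trials


def _pivot(cells: pd.DataFrame, value: str, column: str) -> pd.DataFrame:
    return cells.pivot_table(index="subject_id", columns=column, values=value)


def _has_values(series: pd.Series) -> bool:
    return bool(series.notna().sum() >= 3)


def run_battery(
    trials: pd.DataFrame,
    compute_ci: bool = True,
    n_resamples: int = 2000,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Run the full hypothesis battery on a classified trial table.

    Returns the hypothesis-results table (one row per test) and the
    per-subject cell-metric tables the tests were computed from.  Tests whose
    inputs are unavailable (e.g. no physiological channels) are reported as
    rows with a ``missing input`` note instead of being dropped.
    """
    d = trials if "outcome" in trials.columns else sdt.classify_trials(trials)
    cells = {
        "condition": sdt.aggregate_cells(d, "condition"),
        "context": sdt.aggregate_cells(d, "context"),
        "condition_x_context": sdt.aggregate_cells(d, "condition_x_context"),
        "overall": sdt.aggregate_cells(d, "overall"),
    }
    rows: list[dict] = []
    counter = {"i": 0}

    def add(hypothesis: str, measure: str, result: TestResult | None, note: str = "") -> None:
        if result is None:
            rows.append(
                {
                    "hypothesis": hypothesis,
                    "measure": measure,
                    **TestResult(
                        "missing", float("nan"), "", None, float("nan"), TWO, float("nan"), "",
                        note=note or "missing input",
                    ).to_row(),
                }
            )
        else:
            rows.append({"hypothesis": hypothesis, "measure": measure, **result.to_row()})

    def ci_kwargs(level: float) -> dict:
        counter["i"] += 1
        if not compute_ci:
            return {}
        return {"ci_level": level, "n_resamples": n_resamples, "seed": seed + counter["i"]}

    cond = cells["condition"]
    ctx = cells["context"]
    both = cells["condition_x_context"]
    overall = cells["overall"]

    def paired(frame: pd.DataFrame, value: str, column: str, a: str, b: str):
        wide = _pivot(frame, value, column)
        if a not in wide.columns or b not in wide.columns:
            return None, None
        w = wide[[a, b]].dropna()
        return w[a].to_numpy(), w[b].to_numpy()

    # 1. criterion shift induced by the target-frequency manipulation
    x, y = paired(ctx, "criterion", "prior_context", sched.RARE, sched.FREQUENT)
    add(
        "criterion_manipulation",
        "criterion rare vs frequent",
        wilcoxon_signed_rank(x, y, tails=TWO, **ci_kwargs(0.95)) if x is not None else None,
    )

    # 2. autonomic threat responses (directional, one-tailed)
    x, y = paired(cond, "mean_delta_bpm", "condition", sched.THREAT, sched.SAFE)
    add(
        "hr_threat_vs_safe",
        "mean delta BPM",
        paired_t(x, y, tails=LESS, **ci_kwargs(0.90))
        if x is not None and _has_values(cond["mean_delta_bpm"])
        else None,
    )
    x, y = paired(cond, "mean_sqrt_scr", "condition", sched.THREAT, sched.SAFE)
    add(
        "scr_threat_vs_safe",
        "mean sqrt SCR",
        paired_t(x, y, tails=GREATER, **ci_kwargs(0.90))
        if x is not None and _has_values(cond["mean_sqrt_scr"])
        else None,
    )

    # 3. sensitivity under threat (directional)
    x, y = paired(cond, "hit_rate_raw", "condition", sched.THREAT, sched.SAFE)
    add(
        "hits_threat_vs_safe",
        "hit rate",
        paired_t(x, y, tails=GREATER, **ci_kwargs(0.90)) if x is not None else None,
    )
    x, y = paired(cond, "dprime", "condition", sched.THREAT, sched.SAFE)
    add(
        "dprime_threat_vs_safe",
        "d'",
        wilcoxon_signed_rank(x, y, tails=GREATER, **ci_kwargs(0.90)) if x is not None else None,
    )

    # 4. response bias under threat; threat x frequency interaction
    x, y = paired(cond, "criterion", "condition", sched.THREAT, sched.SAFE)
    add(
        "criterion_threat_vs_safe",
        "criterion",
        wilcoxon_signed_rank(x, y, tails=TWO, **ci_kwargs(0.95)) if x is not None else None,
    )
    wide = both.pivot_table(
        index="subject_id", columns=["condition", "prior_context"], values="criterion"
    )
    try:
        contrast = (
            wide[(sched.THREAT, sched.RARE)]
            - wide[(sched.THREAT, sched.FREQUENT)]
            - wide[(sched.SAFE, sched.RARE)]
            + wide[(sched.SAFE, sched.FREQUENT)]
        ).dropna()
    except KeyError:
        contrast = pd.Series(dtype=float)
    add(
        "criterion_interaction",
        "criterion (threat-safe) x (rare-frequent)",
        wilcoxon_signed_rank(
            contrast.to_numpy(), np.zeros(len(contrast)), tails=TWO, **ci_kwargs(0.95)
        )
        if len(contrast) >= 5
        else None,
    )
    # ART cross-check of the criterion analysis
    long = both.dropna(subset=["criterion"])[
        ["subject_id", "condition", "prior_context", "criterion"]
    ]
    complete = long.groupby("subject_id").size() == 4
    long = long[long["subject_id"].isin(complete[complete].index)]
    if long["subject_id"].nunique() >= 3:
        art = art_anova_2x2(
            long, subject="subject_id", factor_a="condition", factor_b="prior_context",
            value="criterion",
        )
        for key, label in (
            ("condition", "art_criterion_threat"),
            ("prior_context", "art_criterion_frequency"),
            ("condition x prior_context", "art_criterion_interaction"),
        ):
            add(label, "criterion (ART ranks)", art[key])
    else:
        for label in ("art_criterion_threat", "art_criterion_frequency", "art_criterion_interaction"):
            add(label, "criterion (ART ranks)", None)

    # 5. sensitivity vs manipulation-induced bias shift
    shift = _pivot(ctx, "criterion", "prior_context")
    if sched.RARE in shift.columns and sched.FREQUENT in shift.columns:
        merged = pd.DataFrame(
            {
                "dprime": overall.set_index("subject_id")["dprime"],
                "shift": shift[sched.RARE] - shift[sched.FREQUENT],
            }
        ).dropna()
        add(
            "dprime_vs_criterion_shift",
            "pooled d' vs criterion shift",
            spearman(merged["dprime"].to_numpy(), merged["shift"].to_numpy(), **ci_kwargs(0.95)),
        )
    else:
        add("dprime_vs_criterion_shift", "pooled d' vs criterion shift", None)

    # 6. threat x target-detection ANOVAs on the autonomic measures
    for value_col, label in (
        ("delta_bpm", "hr_trial_locked"),
        ("delta_bpm_stim", "hr_stimulus_locked"),
        ("sqrt_scr", "scr"),
    ):
        if value_col in d.columns and _has_values(d[value_col]):
            hm = sdt.outcome_physio_cells(d, value_col)
            counts = hm.groupby("subject_id").size()
            hm = hm[hm["subject_id"].isin(counts[counts == 4].index)]
            if hm["subject_id"].nunique() >= 3:
                res = rm_anova_2x2(
                    hm, subject="subject_id", factor_a="condition", factor_b="detection",
                    value="value",
                )
                add(f"{label}_threat", f"{value_col} threat main effect", res["condition"])
                add(f"{label}_hit_miss", f"{value_col} hit/miss main effect", res["detection"])
                add(
                    f"{label}_interaction",
                    f"{value_col} threat x detection",
                    res["condition x detection"],
                )
                continue
        for suffix in ("threat", "hit_miss", "interaction"):
            add(f"{label}_{suffix}", value_col, None)

    # 7. carryover: safe trials after threat vs after safe
    if "delta_bpm" in d.columns and _has_values(d[value_col := "delta_bpm"]):
        exp = d[d["phase"] == sched.EXPERIMENTAL].sort_values(["subject_id", "trial_index"])
        prev_cond = exp.groupby(["subject_id", "block_index"], observed=True)["condition"].shift(1)
        safe_rows = exp[
            (exp["condition"] == sched.SAFE)
            & prev_cond.isin([sched.THREAT, sched.SAFE])
            & exp["delta_bpm"].notna()
            & exp["included_in_analysis"]
        ]
        carry = (
            safe_rows.assign(prev=prev_cond[safe_rows.index])
            .groupby(["subject_id", "prev"], observed=True)["delta_bpm"]
            .mean()
            .unstack()
        )
        if {sched.THREAT, sched.SAFE} <= set(carry.columns):
            carry = carry.dropna()
            add(
                "hr_carryover",
                "safe-after-threat vs safe-after-safe delta BPM",
                paired_t(
                    carry[sched.THREAT].to_numpy(),
                    carry[sched.SAFE].to_numpy(),
                    tails=TWO,
                    **ci_kwargs(0.95),
                ),
            )
        else:
            add("hr_carryover", "delta BPM", None)
    else:
        add("hr_carryover", "delta BPM", None)

    # 8. reaction times under threat
    x, y = paired(cond, "mean_rt_ms", "condition", sched.THREAT, sched.SAFE)
    add(
        "rt_threat_vs_safe",
        "mean RT (target trials)",
        wilcoxon_signed_rank(x, y, tails=TWO, **ci_kwargs(0.95)) if x is not None else None,
    )

    # 9. RT / heart-rate associations across subjects
    if "delta_bpm" in d.columns and _has_values(cond["mean_delta_bpm"]):
        rt_w = _pivot(cond, "mean_rt_ms", "condition")
        hr_w = _pivot(cond, "mean_delta_bpm", "condition")
        diff = pd.DataFrame(
            {
                "rt": rt_w[sched.THREAT] - rt_w[sched.SAFE],
                "hr": hr_w[sched.THREAT] - hr_w[sched.SAFE],
            }
        ).dropna()
        add(
            "rt_diff_vs_hr_diff",
            "threat-safe RT vs threat-safe delta BPM",
            spearman(diff["rt"].to_numpy(), diff["hr"].to_numpy(), **ci_kwargs(0.95)),
        )
        mean_tbl = pd.DataFrame(
            {
                "rt": overall.set_index("subject_id")["mean_rt_ms"],
                "hr": overall.set_index("subject_id")["mean_delta_bpm"],
            }
        ).dropna()
        add(
            "rt_vs_hr",
            "mean RT vs mean delta BPM",
            spearman(mean_tbl["rt"].to_numpy(), mean_tbl["hr"].to_numpy(), **ci_kwargs(0.95)),
        )
    else:
        add("rt_diff_vs_hr_diff", "threat-safe RT vs threat-safe delta BPM", None)
        add("rt_vs_hr", "mean RT vs mean delta BPM", None)

    return pd.DataFrame(rows), cells


def run_synthetic_study(config: StudyConfig | None = None) -> StudyResults:
    """Simulate one study end to end and run the full analysis battery."""
    config = config or StudyConfig()
    subjects, trials = simulate_study_trials(config)
    with _Stage("battery"):
        hypotheses, cells = run_battery(
            trials,
            compute_ci=config.compute_ci,
            n_resamples=config.bootstrap_resamples,
            seed=config.seed,
        )
    from threatdetect import __version__ as _version

    provenance = {
        "package_version": _version,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "n_subjects_included": int(subjects["included"].sum()),
    }
    return StudyResults(
        subjects=subjects, trials=trials, cells=cells, hypotheses=hypotheses, provenance=provenance
    )


def run_analysis(
    trials: pd.DataFrame,
    compute_ci: bool = True,
    n_resamples: int = 2000,
    seed: int = 0,
) -> StudyResults:
    """Run the identical hypothesis battery on an externally supplied table.

    ``trials`` must follow the trial-table schema (design columns plus
    ``response``/``rt_ms``; physiological metric columns are optional --
    without them the physiological rows are marked missing).
    """
    required = {"subject_id", "phase", "condition", "prior_context", "stimulus", "response", "rt_ms"}
    missing = required - set(trials.columns)
    if missing:
        raise ContractError(f"trial table lacks required columns: {sorted(missing)}")
    d = sdt.classify_trials(trials)
    hypotheses, cells = run_battery(d, compute_ci=compute_ci, n_resamples=n_resamples, seed=seed)
    subjects = d.groupby("subject_id", observed=True).size().rename("n_trials").reset_index()
    from threatdetect import __version__ as _version

    provenance = {"package_version": _version, "seed": seed, "source": "external dataset"}
    return StudyResults(
        subjects=subjects, trials=d, cells=cells, hypotheses=hypotheses, provenance=provenance
    )
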