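"""Ready-made synthetic datasets binding schedule, observer and physiology.

Fixtures are complete simulated cohorts with a named effect profile:

- ``study_default`` -- the study-level condition means are programmed in
  (d' 1.66/1.55, criterion 0.53/0.20 after rare/frequent, RT 632.4/616.5 ms,
  non-response 1.35%, heart-rate change -4.38/-2.99 BPM, SCR 0.24/0.09 on
  the square-root scale);
- ``null`` -- every condition effect is zeroed (shared means at the midpoint
  of the two conditions), for type-I-error calibration;
- ``exaggerated`` -- condition effects doubled, for quick power demos.

Datasets are deterministic given the fixture seed and can be materialised on
disk (trial CSV plus manifest with content hashes) or kept in memory.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

from threatdetect import io as tdio
from threatdetect.errors import ConfigError
from threatdetect.observer import PopulationParams
from threatdetect.physio_sim import PhysioEffectParams
from threatdetect.pipeline import StudyConfig, simulate_study_trials

PROFILES = ("study_default", "null", "exaggerated")


@dataclass
class FixtureSpec:
    """Name, size, effect profile and seed of a fixture dataset."""

    name: str
    n_subjects: int = 52
    profile: str = "study_default"
    seed: int = 0
    include_physio: bool | None = None  # default: physiology for small cohorts only
    include_staircase: bool = False
    apply_exclusions: bool = False


@dataclass
class SyntheticDataset:
    """In-memory fixture: trial table, subject table, config, manifest."""

    spec: FixtureSpec
    subjects: pd.DataFrame
    trials: pd.DataFrame
    config: StudyConfig
    manifest: dict


def _profile_params(profile: str) -> tuple[PopulationParams, PhysioEffectParams]:
    pop = PopulationParams()
    fx = PhysioEffectParams()
    if profile == "study_default":
        return pop, fx
    if profile == "null":
        d_mid = (pop.dprime_threat_mean + pop.dprime_safe_mean) / 2
        rt_mid = (pop.rt_mean_threat_ms + pop.rt_mean_safe_ms) / 2
        pop = replace(
            pop,
            dprime_threat_mean=d_mid,
            dprime_safe_mean=d_mid,
            criterion_shift_mean=0.0,
            criterion_shift_sd=0.0,
            rt_mean_threat_ms=rt_mid,
            rt_mean_safe_ms=rt_mid,
            rt_diff_sd_ms=0.0,
        )
        hr_mid = (fx.decel_threat_bpm + fx.decel_safe_bpm) / 2
        scr_mid = ((fx.scr_amp_threat_us**0.5 + fx.scr_amp_safe_us**0.5) / 2) ** 2
        sd_hr = (fx.decel_subject_sd_threat_bpm + fx.decel_subject_sd_safe_bpm) / 2
        sd_scr = (fx.scr_subject_sqrt_sd_threat + fx.scr_subject_sqrt_sd_safe) / 2
        fx = replace(
            fx,
            decel_threat_bpm=hr_mid,
            decel_safe_bpm=hr_mid,
            decel_hit_extra_bpm=0.0,
            decel_subject_sd_threat_bpm=sd_hr,
            decel_subject_sd_safe_bpm=sd_hr,
            scr_amp_threat_us=scr_mid,
            scr_amp_safe_us=scr_mid,
            scr_subject_sqrt_sd_threat=sd_scr,
            scr_subject_sqrt_sd_safe=sd_scr,
        )
        return pop, fx
    if profile == "exaggerated":
        dd = pop.dprime_threat_mean - pop.dprime_safe_mean
        drt = pop.rt_mean_threat_ms - pop.rt_mean_safe_ms
        pop = replace(
            pop,
            dprime_threat_mean=pop.dprime_threat_mean + dd / 2,
            dprime_safe_mean=pop.dprime_safe_mean - dd / 2,
            criterion_shift_mean=2 * pop.criterion_shift_mean,
            rt_mean_threat_ms=pop.rt_mean_threat_ms + drt / 2,
            rt_mean_safe_ms=pop.rt_mean_safe_ms - drt / 2,
        )
        dhr = fx.decel_threat_bpm - fx.decel_safe_bpm
        fx = replace(
            fx,
            decel_threat_bpm=fx.decel_threat_bpm + dhr / 2,
            decel_safe_bpm=max(fx.decel_safe_bpm - dhr / 2, 0.0),
            decel_hit_extra_bpm=2 * fx.decel_hit_extra_bpm,
        )
        return pop, fx
    raise ConfigError(f"unknown fixture profile {profile!r}; expected one of {PROFILES}")


def fixture_config(spec: FixtureSpec) -> StudyConfig:
    """The StudyConfig a fixture is generated from."""
    pop, fx = _profile_params(spec.profile)
    include_physio = (
        spec.include_physio if spec.include_physio is not None else spec.n_subjects <= 60
    )
    return StudyConfig(
        seed=spec.seed,
        population=replace(pop, n_subjects=spec.n_subjects),
        physio=fx,
        include_physio=include_physio,
        include_staircase=spec.include_staircase,
        apply_exclusions=spec.apply_exclusions,
        compute_ci=False,
    )


def _frame_hash(frame: pd.DataFrame) -> str:
    payload = frame.round(9).to_csv(index=False).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def make_fixture(spec: FixtureSpec, out_dir=None) -> SyntheticDataset:
    """Generate a fixture dataset; optionally materialise it on disk.

    The manifest echoes the generating config and seed and carries content
    hashes of the tables, so identical specs yield identical manifests.
    """
    config = fixture_config(spec)
    subjects, trials = simulate_study_trials(config)
    manifest = {
        "name": spec.name,
        "profile": spec.profile,
        "n_subjects": spec.n_subjects,
        "seed": spec.seed,
        "config": config.to_dict(),
        "hashes": {"trials": _frame_hash(trials), "subjects": _frame_hash(subjects)},
    }
    dataset = SyntheticDataset(
        spec=spec, subjects=subjects, trials=trials, config=config, manifest=manifest
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tdio.save_trials(trials, out / "trials.csv")
        subjects.to_csv(out / "subjects.csv", index=False)
        manifest["files"] = ["trials.csv", "subjects.csv", "manifest.json"]
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=float))
    return dataset
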