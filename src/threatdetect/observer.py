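"""Latent equal-variance SDT observer and population model.

The observer sees on each trial a unit-variance Gaussian evidence sample with
mean d' (target present) or 0 (target absent) and reports "present" when the
evidence exceeds its decision cut.  The cut is parameterised as
``d'/2 + c`` where ``c`` is the criterion referenced to the equal-likelihood
midpoint -- the same convention the analysis-side formulas
``d' = z(H) - z(F)`` and ``c = -(z(H) + z(F))/2`` invert, so the criterion
parameter is recovered on the scale the study reports (positive = more
conservative, fewer "present" responses).

The reference study design reports hit rates and d'/criterion but no
false-alarm rates; the generator's implied FA level follows from the
reported means: with pooled
d' ~ 1.6 and base criterion ~ 0.37, F = Phi(-d'/2 - c) ~ 0.12.

Mask contrast enters through a logistic psychometric mapping
``d'(m) = d'_max / (1 + exp(k (m - m0)))`` used during familiarisation,
staircase and manipulation phases.  During experimental blocks sensitivity is
the condition-specific population value (the threat effect is modelled as an
additive population-level shift, not as contrast-mediated).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from threatdetect import schedule as sched
from threatdetect.errors import ConfigError

RESPONSE_PRESENT = "present"
RESPONSE_ABSENT = "absent"
RESPONSE_NONE = "none"

RESULT_COLUMNS = ["response", "rt_ms", "evidence"]


@dataclass
class ObserverParams:
    """Latent parameters of a single simulated participant.

    Sensitivity and RT means are condition-specific (threat vs safe);
    the criterion is a base level plus an additive shift induced by the
    preceding rare/frequent manipulation block.  ``hr_coupling`` is a
    standardised latent trait consumed by the physiology simulator: subjects
    with larger values show deeper event-locked bradycardia and (through the
    population correlation structure) faster responses.
    """

    dprime_threat: float = 1.66
    dprime_safe: float = 1.55
    criterion_base: float = 0.365
    criterion_shift_rare: float = 0.165
    criterion_shift_frequent: float = -0.165
    lapse_rate: float = 0.01
    nonresponse_rate: float = 0.0135
    rt_mean_threat_ms: float = 632.4
    rt_mean_safe_ms: float = 616.5
    rt_sd_ms: float = 150.0
    hr_coupling: float = 0.0
    # psychometric mapping of mask contrast to sensitivity
    dprime_max: float = 3.5
    contrast_slope: float = 8.0
    contrast_mid: float = 0.5

    def validate(self) -> None:
        for name in ("lapse_rate", "nonresponse_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}={p} outside [0, 1]")
        if self.rt_sd_ms <= 0:
            raise ConfigError("rt_sd_ms must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


def dprime_at_contrast(observer: ObserverParams, mask_contrast) -> float | np.ndarray:
    """Sensitivity at a given backward-mask Michelson contrast.

    Strictly decreasing in contrast; at contrast 0 the mask barely interferes
    and d' approaches ``dprime_max``.
    """
    m = np.asarray(mask_contrast, dtype=float)
    if np.any(m < 0) or np.any(m > 1):
        raise ConfigError("mask contrast must lie in [0, 1]")
    d = observer.dprime_max / (1.0 + np.exp(observer.contrast_slope * (m - observer.contrast_mid)))
    return float(d) if np.isscalar(mask_contrast) else d


def effective_criterion(observer: ObserverParams, prior_context: str, condition: str) -> float:
    """Midpoint-referenced criterion in a given prior context and cue condition.

    The criterion follows the preceding target-frequency manipulation
    (conservative after rare, liberal after frequent); by default the threat
    cue does not modulate it, mirroring the study's null finding.
    """
    if prior_context not in (sched.RARE, sched.FREQUENT):
        raise ConfigError(f"prior_context must be 'rare' or 'frequent', got {prior_context!r}")
    if condition not in (sched.THREAT, sched.SAFE, sched.NEUTRAL):
        raise ConfigError(f"unknown condition {condition!r}")
    shift = (
        observer.criterion_shift_rare
        if prior_context == sched.RARE
        else observer.criterion_shift_frequent
    )
    return observer.criterion_base + shift


def _lognormal_params(mean: np.ndarray, sd: float) -> tuple[np.ndarray, float]:
    sigma2 = np.log1p(sd**2 / mean**2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, np.sqrt(sigma2)


def simulate_cohort(
    observers: list[ObserverParams],
    trials: pd.DataFrame,
    rng: np.random.Generator,
    mask_contrast: float | None = None,
    manip_mask_contrast: float | None = None,
) -> pd.DataFrame:
    """Simulate responses for a (multi-subject) trial table in one pass.

    ``trials`` may carry a ``subject_id`` column whose distinct values, in
    order of appearance, correspond to the entries of ``observers``; a table
    without the column is treated as one subject.  For familiarisation and
    staircase trials sensitivity comes from the contrast mapping
    (``mask_contrast`` required); manipulation-block trials use
    ``manip_mask_contrast`` (default: the design's low-contrast mask); for
    experimental trials it is the condition-specific d'.  Returns a frame
    aligned with ``trials`` carrying ``response``, ``rt_ms`` and the latent
    ``evidence`` sample.
    """
    for obs in observers:
        obs.validate()
    n = len(trials)
    if "subject_id" in trials.columns:
        pos = pd.factorize(trials["subject_id"])[0]
        if pos.max() + 1 != len(observers):
            raise ConfigError("number of observers must match distinct subject ids")
    else:
        pos = np.zeros(n, dtype=int)
        if len(observers) != 1:
            raise ConfigError("trial table without subject_id implies a single observer")

    def per_subject(attr: str) -> np.ndarray:
        return np.array([getattr(o, attr) for o in observers])[pos]

    phase = trials["phase"].to_numpy()
    condition = trials["condition"].to_numpy()
    context = trials["prior_context"].to_numpy()
    is_target = trials["stimulus"].to_numpy() == sched.TARGET
    is_threat = condition == sched.THREAT

    dprime = np.where(is_threat, per_subject("dprime_threat"), per_subject("dprime_safe"))
    pre = phase != sched.EXPERIMENTAL
    if pre.any():
        manip = phase == sched.MANIPULATION
        contrast = np.empty(n)
        contrast[manip] = (
            manip_mask_contrast
            if manip_mask_contrast is not None
            else sched.DesignConfig().manip_mask_contrast
        )
        stairlike = pre & ~manip
        if stairlike.any():
            if mask_contrast is None:
                raise ConfigError("mask_contrast is required for staircase-phase trials")
            contrast[stairlike] = float(mask_contrast)
        if np.any((contrast[pre] < 0) | (contrast[pre] > 1)):
            raise ConfigError("mask contrast must lie in [0, 1]")
        dmax, k, m0 = per_subject("dprime_max"), per_subject("contrast_slope"), per_subject("contrast_mid")
        dprime[pre] = (dmax / (1.0 + np.exp(k * (contrast - m0))))[pre]

    criterion = per_subject("criterion_base")
    not_stair = phase != sched.STAIRCASE  # staircase/familiarisation: unshifted base
    rare = (context == sched.RARE) & not_stair
    freq = (context == sched.FREQUENT) & not_stair
    criterion = criterion + rare * per_subject("criterion_shift_rare")
    criterion = criterion + freq * per_subject("criterion_shift_frequent")

    cut = dprime / 2.0 + criterion
    evidence = rng.normal(loc=dprime * is_target, scale=1.0)
    present = evidence > cut

    lapse = rng.random(n) < per_subject("lapse_rate")
    if lapse.any():
        present[lapse] = rng.random(int(lapse.sum())) < 0.5
    none = rng.random(n) < per_subject("nonresponse_rate")

    rt_mean = np.where(is_threat, per_subject("rt_mean_threat_ms"), per_subject("rt_mean_safe_ms"))
    mu, sigma = _lognormal_params(rt_mean, per_subject("rt_sd_ms"))
    rt = rng.lognormal(mean=mu, sigma=sigma)
    rt[none] = np.nan

    response = np.where(present, RESPONSE_PRESENT, RESPONSE_ABSENT)
    response[none] = RESPONSE_NONE
    return pd.DataFrame({"response": response, "rt_ms": rt, "evidence": evidence}, index=trials.index)


def simulate_trials(
    observer: ObserverParams,
    trials: pd.DataFrame,
    rng: np.random.Generator,
    mask_contrast: float | None = None,
    manip_mask_contrast: float | None = None,
) -> pd.DataFrame:
    """Simulate present/absent/none responses and RTs for one observer."""
    return simulate_cohort([observer], trials, rng, mask_contrast, manip_mask_contrast)


def simulate_response(
    observer: ObserverParams,
    trial: "sched.TrialSpec",
    rng: np.random.Generator,
    mask_contrast: float | None = None,
) -> dict:
    """Simulate a single trial; scalar convenience wrapper over simulate_trials."""
    frame = pd.DataFrame([asdict(trial)])
    out = simulate_trials(observer, frame, rng, mask_contrast=mask_contrast).iloc[0]
    return {"response": out["response"], "rt_ms": out["rt_ms"], "evidence": out["evidence"]}


@dataclass
class PopulationParams:
    """Across-subject distribution of observer and coupling parameters.

    Means are the study-level condition means; SDs are latent between-subject
    SDs.  The reported cross-subject SDs of estimated d' include finite-trial
    estimation noise (64 targets + 64 lures per condition contribute
    ~0.26 SD), so the latent SD is set somewhat below them and is shared
    between conditions (one sensitivity trait; the threat effect is a fixed
    additive shift).  Two cross-trait correlations are modelled via a
    Gaussian copula: sensitivity vs criterion-shift magnitude (more sensitive
    observers are swayed less by the frequency manipulation) and the
    heart-rate trait vs mean RT (stronger decelerators respond faster).
    """

    n_subjects: int = 52
    dprime_threat_mean: float = 1.66
    dprime_safe_mean: float = 1.55
    dprime_sd: float = 0.60
    criterion_base_mean: float = 0.365
    criterion_base_sd: float = 0.30
    criterion_shift_mean: float = 0.165
    criterion_shift_sd: float = 0.08
    lapse_rate: float = 0.01
    nonresponse_mean: float = 0.0135
    nonresponse_sd: float = 0.0219
    rt_mean_threat_ms: float = 632.4
    rt_mean_safe_ms: float = 616.5
    rt_subject_sd_ms: float = 85.0
    rt_diff_sd_ms: float = 20.0
    rt_trial_sd_ms: float = 150.0
    rho_dprime_shift: float = -0.29
    rho_hr_rt: float = -0.32

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ConfigError("n_subjects must be at least 2")
        for name in ("rho_dprime_shift", "rho_hr_rt"):
            rho = getattr(self, name)
            if not -1.0 <= rho <= 1.0:
                raise ConfigError(f"{name}={rho} is not a valid correlation")
        for name in (
            "dprime_sd",
            "criterion_base_sd",
            "criterion_shift_sd",
            "nonresponse_sd",
            "rt_subject_sd_ms",
            "rt_diff_sd_ms",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PopulationParams":
        return cls(**data)


def _correlated_pair(rng: np.random.Generator, n: int, rho: float) -> tuple[np.ndarray, np.ndarray]:
    u = rng.standard_normal(n)
    v = rho * u + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    return u, v


def sample_population(pop: PopulationParams, seed: int = 0) -> list[ObserverParams]:
    """Draw a deterministic sample of observers from the population model."""
    pop.validate()
    rng = np.random.default_rng(seed)
    n = pop.n_subjects

    u_d, u_shift = _correlated_pair(rng, n, pop.rho_dprime_shift)
    u_hr, u_rt = _correlated_pair(rng, n, pop.rho_hr_rt)
    u_c = rng.standard_normal(n)
    u_rtdiff = rng.standard_normal(n)

    dprime_threat = np.maximum(pop.dprime_threat_mean + pop.dprime_sd * u_d, 0.05)
    dprime_safe = np.maximum(pop.dprime_safe_mean + pop.dprime_sd * u_d, 0.05)
    shift = np.maximum(pop.criterion_shift_mean + pop.criterion_shift_sd * u_shift, 0.0)
    criterion = pop.criterion_base_mean + pop.criterion_base_sd * u_c
    if pop.nonresponse_sd > 0 and pop.nonresponse_mean > 0:
        shape = (pop.nonresponse_mean / pop.nonresponse_sd) ** 2
        scale = pop.nonresponse_sd**2 / pop.nonresponse_mean
        nonresponse = np.minimum(rng.gamma(shape, scale, size=n), 0.30)
    else:
        nonresponse = np.full(n, pop.nonresponse_mean)
    rt_diff_dev = pop.rt_diff_sd_ms * u_rtdiff
    rt_threat = np.maximum(
        pop.rt_mean_threat_ms + pop.rt_subject_sd_ms * u_rt + rt_diff_dev / 2.0, 250.0
    )
    rt_safe = np.maximum(
        pop.rt_mean_safe_ms + pop.rt_subject_sd_ms * u_rt - rt_diff_dev / 2.0, 250.0
    )

    observers = []
    for i in range(n):
        observers.append(
            ObserverParams(
                dprime_threat=float(dprime_threat[i]),
                dprime_safe=float(dprime_safe[i]),
                criterion_base=float(criterion[i]),
                criterion_shift_rare=float(shift[i]),
                criterion_shift_frequent=float(-shift[i]),
                lapse_rate=pop.lapse_rate,
                nonresponse_rate=float(nonresponse[i]),
                rt_mean_threat_ms=float(rt_threat[i]),
                rt_mean_safe_ms=float(rt_safe[i]),
                rt_sd_ms=pop.rt_trial_sd_ms,
                hr_coupling=float(u_hr[i]),
            )
        )
    return observers
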