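"""Synthetic cardiac and electrodermal traces with event-locked responses.

Heart rate is modelled as a baseline plus event-locked anticipatory
bradycardia: a sustained plateau deceleration that sets in quickly after
trial onset (the threat/safe cue), holds through the anticipation period and
recovers before the next trial's baseline window.  The plateau shape has two
consequences that mirror the study: scored with the 1-5 s window against a
1 s pre-trial baseline, the heart-rate change equals the programmed depth;
and re-aligning the same windows to the (jittered, 1-3 s) stimulus onset
places window and baseline on the same plateau, so outcome-dependent depth
differences cancel -- hits decelerate more than misses only in trial-locked
scoring.  A transient dip kernel cannot do both, which is why the plateau
was chosen.

Skin conductance is a tonic level plus one event-locked phasic response per
trial (amplitude condition-dependent, onset latency drawn inside the scoring
window), with a smooth rise and exponential decay.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from threatdetect import schedule as sched
from threatdetect.errors import ConfigError, ContractError

CHANNEL_PULSE = "pulse"
CHANNEL_BPM = "bpm"
CHANNEL_EDA = "eda"


@dataclass
class PhysioTrace:
    """A uniformly sampled physiological channel with event markers."""

    channel: str
    sample_rate_hz: float
    samples: np.ndarray
    t0: float = 0.0
    events: list = field(default_factory=list)  # (time_s, label)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate_hz <= 0:
            raise ConfigError("sample_rate_hz must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ConfigError("trace samples must be finite")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.samples)) / self.sample_rate_hz

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate_hz


@dataclass
class PhysioEffectParams:
    """Programmed autonomic effects, on the scale the scoring recovers.

    Deceleration depths are positive magnitudes in BPM; the scored
    (window-minus-baseline) heart-rate change for a trial is minus the depth.
    SCR amplitudes are in microsiemens; the defaults are the squares of the
    square-root-scale means the analysis reports (0.24 / 0.09 sqrt-uS).
    """

    baseline_bpm: float = 70.0
    decel_threat_bpm: float = 4.38
    decel_safe_bpm: float = 2.99
    decel_hit_extra_bpm: float = 0.5
    decel_trial_sd_bpm: float = 0.8
    decel_onset_s: float = 0.5
    decel_hold_s: float = 6.5
    decel_recovery_s: float = 7.5
    decel_subject_sd_threat_bpm: float = 2.0
    decel_subject_sd_safe_bpm: float = 1.6
    decel_diff_sd_bpm: float = 1.25
    decel_hit_extra_sd_bpm: float = 1.5
    scr_amp_threat_us: float = 0.0576
    scr_amp_safe_us: float = 0.0081
    scr_sqrt_trial_sd: float = 0.03
    scr_subject_sqrt_sd_threat: float = 0.15
    scr_subject_sqrt_sd_safe: float = 0.05
    scr_sqrt_diff_sd: float = 0.17
    scr_latency_range_s: tuple[float, float] = (1.0, 3.0)
    scr_rise_s: float = 2.0
    scr_decay_s: float = 2.5
    eda_tonic_us: float = 2.0
    noise_bpm_sd: float = 1.5
    noise_bpm_tau_s: float = 4.0
    noise_eda_sd_us: float = 0.002
    sample_rate_hz: float = 50.0

    def validate(self) -> None:
        # condition depths are magnitudes; the hit/miss modulation is signed
        for name in ("decel_threat_bpm", "decel_safe_bpm"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be a non-negative magnitude")
        if not 0.5 <= self.scr_rise_s <= 5.0:
            raise ConfigError("scr_rise_s must lie in [0.5, 5] s")
        lo, hi = self.scr_latency_range_s
        if not (0.5 <= lo <= hi <= 5.133):
            raise ConfigError("scr_latency_range_s must lie inside the [0.5, 5.133] s window")
        if not (0 < self.decel_onset_s <= self.decel_hold_s < self.decel_recovery_s):
            raise ConfigError("deceleration kernel times must be ordered onset <= hold < recovery")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scr_latency_range_s"] = list(self.scr_latency_range_s)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PhysioEffectParams":
        p = cls(**data)
        p.scr_latency_range_s = tuple(p.scr_latency_range_s)
        return p


def subject_effects(
    fx: PhysioEffectParams, hr_coupling: float, rng: np.random.Generator
) -> PhysioEffectParams:
    """Per-subject autonomic effect parameters.

    The heart-rate trait scales both conditions' deceleration depths (one
    latent decelerator trait, correlated with RT at the population level);
    independent traits add between-subject variability to the threat-safe
    contrast (its scale is what determines the study-level paired-t effect
    sizes) and to the hit/miss modulation, and SCR reactivity varies on the
    square-root scale.  Condition-depth magnitudes are floored at zero; the
    signed modulations are not.
    """
    from dataclasses import replace

    u_scr = rng.standard_normal()
    u_hr_diff = rng.standard_normal()
    u_scr_diff = rng.standard_normal()
    u_hit = rng.standard_normal()
    hr_diff_dev = fx.decel_diff_sd_bpm * u_hr_diff
    sqrt_t = max(
        np.sqrt(fx.scr_amp_threat_us)
        + fx.scr_subject_sqrt_sd_threat * u_scr
        + fx.scr_sqrt_diff_sd * u_scr_diff / 2.0,
        0.0,
    )
    sqrt_s = max(
        np.sqrt(fx.scr_amp_safe_us)
        + fx.scr_subject_sqrt_sd_safe * u_scr
        - fx.scr_sqrt_diff_sd * u_scr_diff / 2.0,
        0.0,
    )
    return replace(
        fx,
        decel_threat_bpm=max(
            fx.decel_threat_bpm + fx.decel_subject_sd_threat_bpm * hr_coupling + hr_diff_dev / 2.0,
            0.0,
        ),
        decel_safe_bpm=max(
            fx.decel_safe_bpm + fx.decel_subject_sd_safe_bpm * hr_coupling - hr_diff_dev / 2.0,
            0.0,
        ),
        decel_hit_extra_bpm=fx.decel_hit_extra_bpm + fx.decel_hit_extra_sd_bpm * u_hit,
        scr_amp_threat_us=sqrt_t**2,
        scr_amp_safe_us=sqrt_s**2,
    )


def decel_kernel_shape(t, onset_s: float = 0.5, hold_s: float = 6.5, recovery_s: float = 7.5):
    """Unit plateau deceleration kernel (0 -> 1 -> 0) as a function of time.

    Cosine ramp to full depth over ``onset_s``, plateau until ``hold_s``,
    cosine recovery finished at ``recovery_s``.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    rising = (t >= 0) & (t < onset_s)
    out[rising] = 0.5 * (1.0 - np.cos(np.pi * t[rising] / onset_s))
    out[(t >= onset_s) & (t <= hold_s)] = 1.0
    falling = (t > hold_s) & (t < recovery_s)
    out[falling] = 0.5 * (1.0 + np.cos(np.pi * (t[falling] - hold_s) / (recovery_s - hold_s)))
    return out


def scr_kernel(t, amplitude: float, rise_s: float, decay_s: float):
    """Canonical phasic skin-conductance response.

    Zero before onset, smooth rise peaking at ``amplitude`` at ``t = rise_s``,
    exponential decay afterwards; pointwise linear in amplitude.
    """
    if rise_s <= 0 or decay_s <= 0:
        raise ConfigError("rise_s and decay_s must be positive")
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    rising = (t >= 0) & (t <= rise_s)
    out[rising] = 0.5 * (1.0 - np.cos(np.pi * t[rising] / rise_s))
    after = t > rise_s
    out[after] = np.exp(-(t[after] - rise_s) / decay_s)
    return amplitude * out


def session_timeline(trials: pd.DataFrame, block_break_s: float = 15.0) -> pd.DataFrame:
    """Attach absolute trial and stimulus onset times (s) to a trial table.

    Trials run back to back within a block; a short break separates blocks.
    """
    trials = trials.reset_index(drop=True).copy()
    durations = trials["trial_duration_ms"].to_numpy() / 1000.0
    new_block = trials["block_index"].diff().fillna(0).to_numpy() != 0
    starts = np.concatenate([[block_break_s], durations[:-1]]) + new_block * block_break_s
    onsets = np.cumsum(starts)
    trials["trial_onset_s"] = onsets
    trials["stimulus_onset_s"] = onsets + trials["stimulus_onset_ms"].to_numpy() / 1000.0
    return trials


def _ou_noise(n: int, dt: float, sd: float, tau: float, rng: np.random.Generator) -> np.ndarray:
    """Ornstein-Uhlenbeck noise: slow physiological variability."""
    if sd == 0:
        return np.zeros(n)
    from scipy.signal import lfilter

    a = np.exp(-dt / tau)
    innov = rng.standard_normal(n) * sd * np.sqrt(1 - a**2)
    innov[0] = rng.standard_normal() * sd
    return lfilter([1.0], [1.0, -a], innov)


def _check_alignment(trials: pd.DataFrame, results: pd.DataFrame) -> pd.DataFrame:
    if len(trials) != len(results):
        raise ContractError(
            f"schedule ({len(trials)}) and outcomes ({len(results)}) have mismatched lengths"
        )
    merged = trials.reset_index(drop=True).copy()
    for col in results.columns:
        merged[col] = results[col].to_numpy()
    if "trial_onset_s" not in merged.columns:
        merged = session_timeline(merged)
    return merged


def generate_bpm_trace(
    trials: pd.DataFrame,
    results: pd.DataFrame,
    fx: PhysioEffectParams | None = None,
    rng: np.random.Generator | None = None,
) -> PhysioTrace:
    """Generate a session-long BPM trace with event-locked decelerations.

    Experimental trials receive a plateau deceleration whose depth is the
    condition depth (threat deeper than safe) plus an extra increment on hit
    trials, plus optional per-trial jitter.  Event markers record trial and
    stimulus onsets for every experimental trial.
    """
    fx = fx or PhysioEffectParams()
    fx.validate()
    rng = rng or np.random.default_rng()
    merged = _check_alignment(trials, results)

    fs = fx.sample_rate_hz
    t_end = merged["trial_onset_s"].iloc[-1] + merged["trial_duration_ms"].iloc[-1] / 1000.0 + 12.0
    n = int(np.ceil(t_end * fs))
    samples = np.full(n, fx.baseline_bpm, dtype=float)
    samples += _ou_noise(n, 1.0 / fs, fx.noise_bpm_sd, fx.noise_bpm_tau_s, rng)

    is_exp = merged["phase"].to_numpy() == sched.EXPERIMENTAL
    is_threat = merged["condition"].to_numpy() == sched.THREAT
    is_target = merged["stimulus"].to_numpy() == sched.TARGET
    response = merged["response"].to_numpy()
    is_hit = is_target & (response == "present")
    is_miss = is_target & (response == "absent")
    depth = np.where(is_threat, fx.decel_threat_bpm, fx.decel_safe_bpm)
    # detection modulation is centred (hits deeper, misses shallower by the
    # same amount) so the programmed condition means are preserved
    depth = depth + 0.5 * fx.decel_hit_extra_bpm * (
        is_hit.astype(float) - is_miss.astype(float)
    )
    if fx.decel_trial_sd_bpm > 0:
        depth = depth + rng.normal(0.0, fx.decel_trial_sd_bpm, size=len(depth))
    depth = np.maximum(depth, 0.0)

    support = int(np.ceil(fx.decel_recovery_s * fs)) + 1
    rel_t = np.arange(support) / fs
    shape = decel_kernel_shape(rel_t, fx.decel_onset_s, fx.decel_hold_s, fx.decel_recovery_s)
    events = []
    onsets = merged["trial_onset_s"].to_numpy()
    stim_onsets = merged["stimulus_onset_s"].to_numpy()
    for i in np.flatnonzero(is_exp):
        k0 = int(round(onsets[i] * fs))
        samples[k0 : k0 + support] -= depth[i] * shape[: max(0, min(support, n - k0))]
        events.append((float(onsets[i]), f"trial_onset:{merged['trial_index'].iloc[i]}"))
        events.append((float(stim_onsets[i]), f"stimulus_onset:{merged['trial_index'].iloc[i]}"))
    return PhysioTrace(channel=CHANNEL_BPM, sample_rate_hz=fs, samples=samples, events=events)


def generate_eda_trace(
    trials: pd.DataFrame,
    results: pd.DataFrame,
    fx: PhysioEffectParams | None = None,
    rng: np.random.Generator | None = None,
) -> PhysioTrace:
    """Generate a session-long skin-conductance trace with per-trial SCRs.

    Each experimental trial elicits one phasic response whose onset latency
    falls inside the scoring window by construction; per-trial amplitude
    varies on the square-root scale around the condition mean.
    """
    fx = fx or PhysioEffectParams()
    fx.validate()
    rng = rng or np.random.default_rng()
    merged = _check_alignment(trials, results)

    fs = fx.sample_rate_hz
    t_end = merged["trial_onset_s"].iloc[-1] + merged["trial_duration_ms"].iloc[-1] / 1000.0 + 12.0
    n = int(np.ceil(t_end * fs))
    samples = np.full(n, fx.eda_tonic_us, dtype=float)
    if fx.noise_eda_sd_us > 0:
        samples += _ou_noise(n, 1.0 / fs, fx.noise_eda_sd_us, 2.0, rng)

    is_exp = merged["phase"].to_numpy() == sched.EXPERIMENTAL
    is_threat = merged["condition"].to_numpy() == sched.THREAT
    sqrt_amp = np.where(
        is_threat, np.sqrt(fx.scr_amp_threat_us), np.sqrt(fx.scr_amp_safe_us)
    )
    if fx.scr_sqrt_trial_sd > 0:
        sqrt_amp = sqrt_amp + rng.normal(0.0, fx.scr_sqrt_trial_sd, size=len(sqrt_amp))
    amp = np.maximum(sqrt_amp, 0.0) ** 2
    latency = rng.uniform(*fx.scr_latency_range_s, size=len(merged))

    support = int(np.ceil((fx.scr_rise_s + 6.0 * fx.scr_decay_s) * fs))
    rel_t = np.arange(support) / fs
    unit = scr_kernel(rel_t, 1.0, fx.scr_rise_s, fx.scr_decay_s)
    events = []
    stim_onsets = merged["stimulus_onset_s"].to_numpy()
    for i in np.flatnonzero(is_exp):
        k0 = int(round((stim_onsets[i] + latency[i]) * fs))
        seg = min(support, n - k0)
        samples[k0 : k0 + seg] += amp[i] * unit[:seg]
        events.append((float(stim_onsets[i]), f"stimulus_onset:{merged['trial_index'].iloc[i]}"))
    return PhysioTrace(channel=CHANNEL_EDA, sample_rate_hz=fs, samples=samples, events=events)


def generate_pulse_trace(
    bpm: PhysioTrace, rng: np.random.Generator | None = None
) -> PhysioTrace:
    """Synthesise a pulse waveform whose beat times follow a BPM trace.

    Beats occur where the integrated instantaneous rate crosses whole-beat
    counts (inter-beat interval = 60/BPM); each beat contributes one dominant
    Gaussian peak.  Enables end-to-end testing of beat detection.
    """
    rng = rng or np.random.default_rng()
    if np.any(bpm.samples <= 0):
        raise ConfigError("BPM trace must be positive everywhere")
    fs = bpm.sample_rate_hz
    t = bpm.times
    # cumulative beat count; beat k occurs when the integral reaches k
    beat_count = np.concatenate([[0.0], np.cumsum(bpm.samples / 60.0) / fs])
    t_edges = np.concatenate([t, [t[-1] + 1.0 / fs]])
    n_beats = int(np.floor(beat_count[-1]))
    beat_times = np.interp(np.arange(1, n_beats + 1), beat_count, t_edges)

    samples = np.zeros(len(bpm.samples))
    width_s = 0.08
    half = int(round(3 * width_s * fs))
    rel = np.arange(-half, half + 1) / fs
    bump = np.exp(-0.5 * (rel / width_s) ** 2)
    amps = 1.0 + 0.05 * rng.standard_normal(n_beats)
    for bt, a in zip(beat_times, amps):
        k = int(round((bt - bpm.t0) * fs))
        lo, hi = max(0, k - half), min(len(samples), k + half + 1)
        samples[lo:hi] += a * bump[lo - (k - half) : hi - (k - half)]
    return PhysioTrace(
        channel=CHANNEL_PULSE, sample_rate_hz=fs, samples=samples, t0=bpm.t0, events=list(bpm.events)
    )
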