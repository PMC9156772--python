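"""Trace generation: kernels, flat-trace degenerate cases, pulse round trip."""

import numpy as np
import pandas as pd
import pytest

from threatdetect.errors import ConfigError, ContractError
from threatdetect.observer import ObserverParams, simulate_trials
from threatdetect.physio_sim import (
    PhysioEffectParams,
    PhysioTrace,
    decel_kernel_shape,
    generate_bpm_trace,
    generate_eda_trace,
    generate_pulse_trace,
    scr_kernel,
    session_timeline,
    subject_effects,
)
from threatdetect.schedule import build_session


@pytest.fixture(scope="module")
def timed_session():
    s = build_session(seed=17, subject_id=0)
    trials = session_timeline(s.trials())
    rng = np.random.default_rng(17)
    responses = simulate_trials(ObserverParams(), trials, rng)
    return pd.concat([trials, responses.drop(columns=[])], axis=1), responses


def test_decel_kernel_is_zero_outside_support_and_one_on_plateau():
    fx = PhysioEffectParams()
    t = np.array([-1.0, 0.0, fx.decel_onset_s, 3.0, fx.decel_hold_s,
                  fx.decel_recovery_s, fx.decel_recovery_s + 1])
    shape = decel_kernel_shape(t, fx.decel_onset_s, fx.decel_hold_s, fx.decel_recovery_s)
    assert shape[0] == 0 and shape[1] == 0
    assert shape[2] == pytest.approx(1.0)
    assert shape[3] == 1.0 and shape[4] == 1.0
    assert shape[5] == 0 or shape[5] == pytest.approx(0.0, abs=1e-12)
    assert shape[6] == 0


def test_scr_kernel_shape_and_linearity():
    t = np.linspace(-1, 20, 4000)
    k1 = scr_kernel(t, 1.0, rise_s=2.0, decay_s=2.5)
    k2 = scr_kernel(t, 2.0, rise_s=2.0, decay_s=2.5)
    assert (k1[t < 0] == 0).all()
    np.testing.assert_allclose(k2, 2 * k1)  # pointwise linear in amplitude
    peak_t = t[np.argmax(k1)]
    assert 0.9 * 2.0 <= peak_t <= 1.1 * 2.0
    assert k1.max() == pytest.approx(1.0, abs=1e-3)
    with pytest.raises(ConfigError):
        scr_kernel(t, 1.0, rise_s=0.0, decay_s=1.0)


def test_zero_effects_and_noise_give_flat_traces(timed_session):
    trials, responses = timed_session
    fx = PhysioEffectParams(
        decel_threat_bpm=0, decel_safe_bpm=0, decel_hit_extra_bpm=0, decel_trial_sd_bpm=0,
        noise_bpm_sd=0, scr_amp_threat_us=0, scr_amp_safe_us=0, scr_sqrt_trial_sd=0,
        noise_eda_sd_us=0,
    )
    rng = np.random.default_rng(0)
    bpm = generate_bpm_trace(trials, responses, fx, rng)
    assert np.allclose(bpm.samples, fx.baseline_bpm)
    eda = generate_eda_trace(trials, responses, fx, rng)
    assert np.allclose(eda.samples, fx.eda_tonic_us)


def test_mismatched_lengths_raise(timed_session):
    trials, responses = timed_session
    with pytest.raises(ContractError):
        generate_bpm_trace(trials, responses.iloc[:-5], PhysioEffectParams(),
                           np.random.default_rng(0))


def test_invalid_effect_params_rejected():
    with pytest.raises(ConfigError):
        PhysioEffectParams(decel_threat_bpm=-1).validate()
    with pytest.raises(ConfigError):
        PhysioEffectParams(scr_latency_range_s=(0.1, 3.0)).validate()
    with pytest.raises(ConfigError):
        PhysioEffectParams(scr_rise_s=6.0).validate()


@pytest.mark.parametrize("bpm_value,ibi", [(60.0, 1.0), (75.0, 0.8)])
def test_constant_rate_pulse_has_regular_beats(bpm_value, ibi):
    trace = PhysioTrace(channel="bpm", sample_rate_hz=50.0,
                        samples=np.full(500, bpm_value))
    pulse = generate_pulse_trace(trace, np.random.default_rng(0))
    from threatdetect.physio_metrics import detect_beats

    det = detect_beats(pulse)
    # 10 s at the given rate; allow edge beats to fall off the grid
    assert len(det.times) in {int(10 / ibi) - 1, int(10 / ibi), int(10 / ibi) + 1}
    ibis = np.diff(det.times)
    assert np.allclose(ibis, ibi, atol=1.5 / 50.0)


def test_pulse_round_trip_recovers_bpm_within_1bpm():
    rng = np.random.default_rng(3)
    t = np.arange(0, 120, 1 / 50.0)
    bpm = 70 + 5 * np.sin(2 * np.pi * t / 30)  # slow modulation
    trace = PhysioTrace(channel="bpm", sample_rate_hz=50.0, samples=bpm)
    pulse = generate_pulse_trace(trace, rng)
    from threatdetect.physio_metrics import bpm_series, detect_beats

    det = detect_beats(pulse)
    rec = bpm_series(det.times, rate_hz=50.0)
    # compare on the overlapping interior
    lo, hi = det.times[0], det.times[-1]
    mask = (t >= lo) & (t < hi)
    rec_on_t = np.interp(t[mask], rec.times, rec.samples)
    rmse = np.sqrt(np.mean((rec_on_t - bpm[mask]) ** 2))
    assert rmse < 1.0


def test_nonpositive_bpm_rejected_for_pulse_synthesis():
    trace = PhysioTrace(channel="bpm", sample_rate_hz=50.0, samples=np.full(200, -1.0))
    with pytest.raises(ConfigError):
        generate_pulse_trace(trace, np.random.default_rng(0))


def test_traces_reproducible_under_fixed_seed(timed_session):
    trials, responses = timed_session
    fx = PhysioEffectParams()
    a = generate_bpm_trace(trials, responses, fx, np.random.default_rng(4))
    b = generate_bpm_trace(trials, responses, fx, np.random.default_rng(4))
    np.testing.assert_array_equal(a.samples, b.samples)


def test_subject_effects_scale_with_trait_and_floor_at_zero():
    fx = PhysioEffectParams()
    strong = subject_effects(fx, hr_coupling=1.0, rng=np.random.default_rng(0))
    weak = subject_effects(fx, hr_coupling=-5.0, rng=np.random.default_rng(0))
    assert strong.decel_threat_bpm > fx.decel_threat_bpm
    assert weak.decel_threat_bpm == 0.0 and weak.decel_safe_bpm == 0.0


def test_session_timeline_orders_trials_with_block_breaks(timed_session):
    trials, _ = timed_session
    onsets = trials["trial_onset_s"].to_numpy()
    assert np.all(np.diff(onsets) > 0)
    durations = trials["trial_duration_ms"].to_numpy() / 1000
    gaps = np.diff(onsets) - durations[:-1]
    new_block = trials["block_index"].diff().iloc[1:].to_numpy() != 0
    assert np.allclose(gaps[~new_block], 0, atol=1e-9)
    assert np.allclose(gaps[new_block], 15.0, atol=1e-9)
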