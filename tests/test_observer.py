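"""SDT observer: psychometric mapping, response generation, population moments."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from threatdetect.errors import ConfigError
from threatdetect.observer import (
    ObserverParams,
    PopulationParams,
    dprime_at_contrast,
    effective_criterion,
    sample_population,
    simulate_response,
    simulate_trials,
)
from threatdetect.schedule import TrialSpec


def _exp_trials(n, stimulus="target", condition="threat", context="rare"):
    return pd.DataFrame(
        {
            "phase": ["experimental"] * n,
            "prior_context": [context] * n,
            "condition": [condition] * n,
            "stimulus": [stimulus] * n,
        }
    )


def test_dprime_decreases_with_mask_contrast(observer):
    grid = np.linspace(0, 1, 21)
    d = dprime_at_contrast(observer, grid)
    assert np.all(np.diff(d) < 0)
    assert d[0] == pytest.approx(observer.dprime_max, rel=0.05)
    with pytest.raises(ConfigError):
        dprime_at_contrast(observer, 1.2)


def test_effective_criterion_reproduces_reported_context_means():
    obs = ObserverParams(criterion_base=0.365, criterion_shift_rare=0.165,
                         criterion_shift_frequent=-0.165)
    assert effective_criterion(obs, "rare", "threat") == pytest.approx(0.53)
    assert effective_criterion(obs, "frequent", "safe") == pytest.approx(0.20)
    flat = ObserverParams(criterion_shift_rare=0.0, criterion_shift_frequent=0.0)
    assert effective_criterion(flat, "rare", "safe") == effective_criterion(flat, "frequent", "safe")
    with pytest.raises(ConfigError):
        effective_criterion(obs, "sometimes", "threat")


def test_unboundedly_liberal_observer_always_reports_present(rng):
    obs = ObserverParams(lapse_rate=0.0, nonresponse_rate=0.0, criterion_base=-1e9,
                         criterion_shift_rare=0.0, criterion_shift_frequent=0.0)
    out = simulate_trials(obs, _exp_trials(500, stimulus="lure"), rng)
    assert (out["response"] == "present").all()


def test_zero_sensitivity_gives_equal_hit_and_fa_rates(rng):
    obs = ObserverParams(dprime_threat=0.0, dprime_safe=0.0, lapse_rate=0.0,
                         nonresponse_rate=0.0)
    hits = (simulate_trials(obs, _exp_trials(10_000, "target"), rng)["response"] == "present").mean()
    fas = (simulate_trials(obs, _exp_trials(10_000, "lure"), rng)["response"] == "present").mean()
    assert hits == pytest.approx(fas, abs=0.02)


def test_nonresponse_fraction_matches_parameter(rng):
    obs = ObserverParams(nonresponse_rate=0.0135)
    out = simulate_trials(obs, _exp_trials(50_000), rng)
    assert (out["response"] == "none").mean() == pytest.approx(0.0135, abs=0.002)
    assert out.loc[out["response"] == "none", "rt_ms"].isna().all()


def test_hit_and_fa_rates_match_closed_form_predictions(rng):
    obs = ObserverParams(lapse_rate=0.0, nonresponse_rate=0.0)
    n = 100_000
    hit = (simulate_trials(obs, _exp_trials(n, "target", context="frequent"), rng)["response"]
           == "present").mean()
    fa = (simulate_trials(obs, _exp_trials(n, "lure", context="frequent"), rng)["response"]
          == "present").mean()
    c = obs.criterion_base + obs.criterion_shift_frequent
    h_pred = norm.sf(c - obs.dprime_threat / 2)
    f_pred = norm.sf(c + obs.dprime_threat / 2)
    assert hit == pytest.approx(h_pred, abs=4 * np.sqrt(h_pred * (1 - h_pred) / n))
    assert fa == pytest.approx(f_pred, abs=4 * np.sqrt(f_pred * (1 - f_pred) / n))


def test_simulate_response_scalar_wrapper(rng):
    trial = TrialSpec(
        trial_index=0, block_index=1, phase="experimental", prior_context="rare",
        condition="threat", stimulus="target", target_orientation="vertical",
        fixation_duration_ms=1500.0, stimulus_onset_ms=1500.0, response_onset_ms=5633.4,
        response_window_ms=1500.0, iti_ms=2000.0, trial_duration_ms=9133.4,
        reinforced=False, extra_trial=False, shortened_response=False,
        included_in_analysis=True,
    )
    out = simulate_response(ObserverParams(), trial, rng)
    assert out["response"] in {"present", "absent", "none"}
    assert np.isfinite(out["evidence"])


def test_population_moments_converge_to_reported_means():
    pop = sample_population(PopulationParams(n_subjects=5000), seed=7)
    dp_t = np.mean([o.dprime_threat for o in pop])
    dp_s = np.mean([o.dprime_safe for o in pop])
    rt_t = np.mean([o.rt_mean_threat_ms for o in pop])
    rt_s = np.mean([o.rt_mean_safe_ms for o in pop])
    assert dp_t == pytest.approx(1.66, abs=0.03)
    assert dp_s == pytest.approx(1.55, abs=0.03)
    assert rt_t == pytest.approx(632.4, abs=4)
    assert rt_s == pytest.approx(616.5, abs=4)
    # programmed across-subject couplings carry through
    hr = np.array([o.hr_coupling for o in pop])
    rt = np.array([(o.rt_mean_threat_ms + o.rt_mean_safe_ms) / 2 for o in pop])
    assert np.corrcoef(hr, rt)[0, 1] == pytest.approx(-0.32, abs=0.06)


def test_population_sampling_is_deterministic_and_degenerate_sds_collapse():
    a = sample_population(PopulationParams(n_subjects=10), seed=3)
    b = sample_population(PopulationParams(n_subjects=10), seed=3)
    assert [o.to_dict() for o in a] == [o.to_dict() for o in b]
    frozen = PopulationParams(
        n_subjects=5, dprime_sd=0, criterion_base_sd=0, criterion_shift_sd=0,
        nonresponse_sd=0, rt_subject_sd_ms=0, rt_diff_sd_ms=0,
    )
    pop = sample_population(frozen, seed=1)
    base = {k: v for k, v in pop[0].to_dict().items() if k != "hr_coupling"}
    assert all({k: v for k, v in o.to_dict().items() if k != "hr_coupling"} == base for o in pop)


def test_invalid_correlation_rejected():
    with pytest.raises(ConfigError):
        sample_population(PopulationParams(rho_hr_rt=-1.5), seed=0)
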