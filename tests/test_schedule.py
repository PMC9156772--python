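"""Design-generation invariants: block structure, counts, exclusions, timing."""

import numpy as np
import pandas as pd
import pytest

from threatdetect import io as tdio
from threatdetect.errors import ConfigError, ContractError
from threatdetect.schedule import (
    DesignConfig,
    build_cohort,
    build_experimental_block,
    build_manipulation_block,
    build_session,
    inclusion_flags,
)


def test_default_session_block_structure():
    s = build_session(DesignConfig(), seed=1)
    kinds = [b.kind for b in s.blocks]
    assert len(s.blocks) == 16
    assert kinds.count("experimental") == 8
    assert kinds.count("manipulation_rare") == 4
    assert kinds.count("manipulation_frequent") == 4
    # manipulation and experimental blocks alternate
    assert all(k.startswith("manipulation") for k in kinds[::2])
    assert all(k == "experimental" for k in kinds[1::2])


def test_single_block_pair_trial_counts():
    s = build_session(DesignConfig(n_blocks=1), seed=3)
    t = s.trials()
    assert (t["phase"] == "manipulation").sum() == 20
    assert (t["phase"] == "experimental").sum() == 38


def test_sessions_are_bit_reproducible():
    a = build_session(DesignConfig(), seed=11, subject_id=4).trials()
    b = build_session(DesignConfig(), seed=11, subject_id=4).trials()
    pd.testing.assert_frame_equal(a, b)
    c = build_session(DesignConfig(), seed=12, subject_id=4).trials()
    assert not a["stimulus"].equals(c["stimulus"])


@pytest.mark.parametrize("seed", range(8))
def test_experimental_block_composition(seed):
    block = build_experimental_block(DesignConfig(), np.random.default_rng(seed))
    t = block.trials
    assert len(t) == 38
    assert (t["stimulus"] == "target").sum() == 19
    assert (t["condition"] == "threat").sum() == 20
    assert t["reinforced"].sum() == 3
    assert t["shortened_response"].sum() == 4
    assert t["extra_trial"].sum() == 6
    # analysed core: 32 trials, 16/16 threat/safe, no reinforced/shortened
    core = t[t["included_in_analysis"]]
    assert len(core) == 32
    assert (core["condition"] == "threat").sum() == 16
    assert (core["condition"] == "safe").sum() == 16
    assert not core["reinforced"].any()
    assert not core["shortened_response"].any()
    # reinforced trials are threat trials
    assert (t.loc[t["reinforced"], "condition"] == "threat").all()


@pytest.mark.parametrize("kind,n_targets", [("rare", 4), ("frequent", 16)])
def test_manipulation_block_target_counts(kind, n_targets):
    block = build_manipulation_block(kind, DesignConfig(), np.random.default_rng(0))
    t = block.trials
    assert len(t) == 20
    assert (t["stimulus"] == "target").sum() == n_targets
    assert (t["condition"] == "neutral").all()
    assert not t["included_in_analysis"].any()


def test_zero_extras_config_yields_fully_included_block():
    cfg = DesignConfig(
        trials_per_experimental=32,
        n_extra_threat=0,
        n_extra_safe=0,
        n_extra_targets=0,
        n_reinforced=0,
        n_shortened=0,
    )
    block = build_experimental_block(cfg, np.random.default_rng(0))
    assert len(block.trials) == 32
    assert block.trials["included_in_analysis"].all()


def test_inclusion_flags_match_block_flags_and_reject_manipulation():
    rng = np.random.default_rng(5)
    block = build_experimental_block(DesignConfig(), rng)
    flags = inclusion_flags(block)
    assert flags.sum() == 32
    np.testing.assert_array_equal(flags, block.trials["included_in_analysis"].to_numpy())
    manip = build_manipulation_block("rare", DesignConfig(), rng)
    with pytest.raises(ContractError):
        inclusion_flags(manip)


@pytest.mark.parametrize(
    "bad",
    [
        dict(rare_rate=1.2),
        dict(n_core_threat=14),  # uneven split vs n_core_safe=16
        dict(n_reinforced=5),  # exceeds extra threat capacity
        dict(n_blocks=0),
    ],
)
def test_invalid_configs_raise(bad):
    with pytest.raises(ConfigError):
        build_session(DesignConfig(**bad), seed=0)


def test_experimental_timing_ranges():
    t = build_session(DesignConfig(), seed=2).trials()
    exp = t[t["phase"] == "experimental"]
    assert exp["fixation_duration_ms"].between(1000, 3000).all()
    assert exp["iti_ms"].between(2000, 4000).all()
    short = exp[exp["shortened_response"]]
    assert short["response_window_ms"].between(800, 3000).all()
    full = exp[~exp["shortened_response"]]
    assert (full["response_window_ms"] == 1500).all()
    manip = t[t["phase"] == "manipulation"]
    assert (manip["fixation_duration_ms"] == 500).all()


def test_counterbalancing_by_subject_parity():
    even = build_session(DesignConfig(), seed=1, subject_id=0)
    odd = build_session(DesignConfig(), seed=1, subject_id=1)
    assert even.manipulation_order[0] == "rare"
    assert odd.manipulation_order[0] == "frequent"
    assert even.colour_assignment == "orange_threat"
    assert odd.colour_assignment == "blue_threat"
    forced = build_session(
        DesignConfig(colour_assignment="blue_threat", manipulation_order=["rare"] * 8),
        seed=1,
        subject_id=0,
    )
    assert forced.colour_assignment == "blue_threat"
    assert forced.manipulation_order == ["rare"] * 8


def test_cohort_matches_session_schema_and_is_deterministic():
    cohort = build_cohort(DesignConfig(), 3, seed=21)
    assert cohort["subject_id"].nunique() == 3
    per_subject = cohort.groupby("subject_id").size()
    assert (per_subject == 464).all()
    again = build_cohort(DesignConfig(), 3, seed=21)
    pd.testing.assert_frame_equal(cohort, again)
    # per-block invariants hold inside the cohort table
    exp = cohort[cohort["phase"] == "experimental"]
    grp = exp.groupby(["subject_id", "block_index"])
    assert (grp["included_in_analysis"].sum() == 32).all()
    assert (grp["reinforced"].sum() == 3).all()


def test_trial_table_round_trips_through_csv(tmp_path, session):
    trials = session.trials()
    path = tdio.save_trials(trials, tmp_path / "trials.csv")
    loaded = tdio.load_trials(path)
    assert loaded["included_in_analysis"].dtype == bool
    pd.testing.assert_frame_equal(
        trials.reset_index(drop=True), loaded[trials.columns], check_dtype=False
    )
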