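"""Session design generation for the threat-of-shock target-detection paradigm.

A session consists of eight paired blocks.  Each pair is a criterion-shift
*manipulation* block (20 trials, target presence 20% "rare" or 80% "frequent",
black fixation, explicitly shock-free) followed by an *experimental* block of
38 trials in which the fixation colour cues threat-of-shock or safety on half
the trials and the target presence rate is 50%.

Of the 38 experimental trials, 32 form the analysed core (16 threat, 16 safe,
half targets each).  The remaining six "extra" trials -- four threat (three of
them shock-reinforced, i.e. a 15% reinforcement rate over the 20 threat
trials) and two safe, four of the six with a shortened response window --
exist to deliver shocks and keep participants attentive, and are excluded
from analysis.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from threatdetect.errors import ConfigError, ContractError

# phase labels
FAMILIARISATION = "familiarisation"
STAIRCASE = "staircase"
MANIPULATION = "manipulation"
EXPERIMENTAL = "experimental"

# condition labels
THREAT = "threat"
SAFE = "safe"
NEUTRAL = "neutral"

# stimulus labels
TARGET = "target"
LURE = "lure"

# prior-context labels
RARE = "rare"
FREQUENT = "frequent"

#: Column order of the flat trial table (one row per trial).
TRIAL_COLUMNS = [
    "trial_index",
    "block_index",
    "phase",
    "prior_context",
    "condition",
    "stimulus",
    "target_orientation",
    "fixation_duration_ms",
    "stimulus_onset_ms",
    "response_onset_ms",
    "response_window_ms",
    "iti_ms",
    "trial_duration_ms",
    "reinforced",
    "extra_trial",
    "shortened_response",
    "included_in_analysis",
]

BOOL_COLUMNS = ["reinforced", "extra_trial", "shortened_response", "included_in_analysis"]


@dataclass
class TrialSpec:
    """One trial's design cell."""

    trial_index: int
    block_index: int
    phase: str
    prior_context: str
    condition: str
    stimulus: str
    target_orientation: str
    fixation_duration_ms: float
    stimulus_onset_ms: float
    response_onset_ms: float
    response_window_ms: float
    iti_ms: float
    trial_duration_ms: float
    reinforced: bool
    extra_trial: bool
    shortened_response: bool
    included_in_analysis: bool


@dataclass
class BlockSpec:
    """An ordered block of trials of one kind."""

    kind: str  # "manipulation_rare", "manipulation_frequent", "experimental"
    trials: pd.DataFrame

    @property
    def is_experimental(self) -> bool:
        return self.kind == EXPERIMENTAL

    def trial_specs(self) -> list[TrialSpec]:
        """The block's trials as typed records."""
        return [TrialSpec(**rec) for rec in self.trials[TRIAL_COLUMNS].to_dict("records")]


@dataclass
class SessionSchedule:
    """A full session: manipulation/experimental block pairs plus metadata."""

    subject_id: int
    colour_assignment: str  # "orange_threat" or "blue_threat"
    manipulation_order: list[str]
    blocks: list[BlockSpec]
    seed: int

    def trials(self) -> pd.DataFrame:
        """All trials of the session as one flat table, in presentation order."""
        return pd.concat([b.trials for b in self.blocks], ignore_index=True)

    def experimental_trials(self) -> pd.DataFrame:
        t = self.trials()
        return t[t["phase"] == EXPERIMENTAL].reset_index(drop=True)


@dataclass
class DesignConfig:
    """Design parameters of a session.

    Defaults reproduce the published paradigm: 8 block pairs, 20-trial
    manipulation blocks at 20%/80% target rate, 38-trial experimental blocks
    with a 32-trial analysed core and six excluded extras.
    """

    n_blocks: int = 8
    trials_per_manipulation: int = 20
    trials_per_experimental: int = 38
    rare_rate: float = 0.20
    frequent_rate: float = 0.80
    experimental_rate: float = 0.50
    n_core_threat: int = 16
    n_core_safe: int = 16
    n_extra_threat: int = 4
    n_extra_safe: int = 2
    n_extra_targets: int = 3
    n_reinforced: int = 3
    n_shortened: int = 4
    # timing (ms)
    fixation_range_ms: tuple[float, float] = (1000.0, 3000.0)
    manip_fixation_ms: float = 500.0
    stimulus_ms: float = 16.7
    isi1_ms: float = 16.7
    mask_ms: float = 100.0
    isi2_ms: float = 4000.0
    manip_isi2_ms: float = 800.0
    response_window_ms: float = 1500.0
    shortened_response_range_ms: tuple[float, float] = (800.0, 3000.0)
    iti_range_ms: tuple[float, float] = (2000.0, 4000.0)
    manip_iti_ms: float = 2000.0
    manip_mask_contrast: float = 0.05
    # counterbalancing overrides (None -> subject-index parity)
    colour_assignment: str | None = None
    manipulation_order: list[str] | None = None

    def validate(self) -> None:
        for name in ("rare_rate", "frequent_rate", "experimental_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"{name}={rate} outside [0, 1]")
        for name in ("n_blocks", "trials_per_manipulation", "trials_per_experimental"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be a positive integer")
        if self.n_core_threat != self.n_core_safe:
            raise ConfigError(
                "core trials must split evenly between threat and safe "
                f"(got {self.n_core_threat}/{self.n_core_safe})"
            )
        if self.n_core_threat % 2:
            raise ConfigError("core threat/safe counts must be even (half targets each)")
        n_extra = self.n_extra_threat + self.n_extra_safe
        if self.n_core_threat + self.n_core_safe + n_extra != self.trials_per_experimental:
            raise ConfigError("core + extra trial counts must equal trials_per_experimental")
        if self.n_reinforced > self.n_extra_threat:
            raise ConfigError(
                f"cannot reinforce {self.n_reinforced} trials with only "
                f"{self.n_extra_threat} extra threat trials available"
            )
        if self.n_shortened > n_extra:
            raise ConfigError("n_shortened exceeds the number of extra trials")
        if self.n_extra_targets > n_extra:
            raise ConfigError("n_extra_targets exceeds the number of extra trials")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "DesignConfig":
        cfg = cls(**data)
        for name in ("fixation_range_ms", "shortened_response_range_ms", "iti_range_ms"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        if cfg.manipulation_order is not None:
            cfg.manipulation_order = list(cfg.manipulation_order)
        return cfg


def _order_and_time(cols: dict, config: DesignConfig, rng: np.random.Generator) -> dict:
    """Shuffle trial order within a block and attach per-trial timing."""
    n = len(cols["condition"])
    order = rng.permutation(n)
    out = {k: np.asarray(v, dtype=object if isinstance(v[0], str) else None)[order] for k, v in cols.items()}
    is_manip = out["phase"][0] == MANIPULATION
    if is_manip:
        fixation = np.full(n, config.manip_fixation_ms)
        isi2 = config.manip_isi2_ms
        iti = np.full(n, config.manip_iti_ms)
    else:
        fixation = rng.uniform(*config.fixation_range_ms, size=n)
        isi2 = config.isi2_ms
        iti = rng.uniform(*config.iti_range_ms, size=n)
    response = np.full(n, config.response_window_ms)
    shortened = out["shortened_response"].astype(bool)
    if shortened.any():
        response[shortened] = rng.uniform(
            *config.shortened_response_range_ms, size=int(shortened.sum())
        )
    out["fixation_duration_ms"] = fixation
    out["stimulus_onset_ms"] = fixation
    out["response_onset_ms"] = fixation + config.stimulus_ms + config.isi1_ms + config.mask_ms + isi2
    out["response_window_ms"] = response
    out["iti_ms"] = iti
    out["trial_duration_ms"] = out["response_onset_ms"] + response + iti
    out["trial_index"] = np.arange(n)
    return out


def _orientations(stimulus: list, rng: np.random.Generator) -> list:
    picks = rng.integers(0, 2, size=len(stimulus))
    return [
        ("vertical", "horizontal")[p] if s == TARGET else "none" for s, p in zip(stimulus, picks)
    ]


def _manipulation_cols(
    kind: str, config: DesignConfig, rng: np.random.Generator, block_index: int
) -> dict:
    if kind not in (RARE, FREQUENT):
        raise ConfigError(f"manipulation kind must be 'rare' or 'frequent', got {kind!r}")
    n = config.trials_per_manipulation
    rate = config.rare_rate if kind == RARE else config.frequent_rate
    n_targets = round(n * rate)
    stimulus = [TARGET] * n_targets + [LURE] * (n - n_targets)
    cols = {
        "block_index": [block_index] * n,
        "phase": [MANIPULATION] * n,
        "prior_context": [kind] * n,
        "condition": [NEUTRAL] * n,
        "stimulus": stimulus,
        "target_orientation": _orientations(stimulus, rng),
        "reinforced": [False] * n,
        "extra_trial": [False] * n,
        "shortened_response": [False] * n,
        "included_in_analysis": [False] * n,
    }
    return _order_and_time(cols, config, rng)


def _experimental_cols(
    config: DesignConfig, rng: np.random.Generator, block_index: int, prior_context: str
) -> dict:
    n_threat, n_safe = config.n_core_threat, config.n_core_safe
    n_extra = config.n_extra_threat + config.n_extra_safe

    condition = [THREAT] * n_threat + [SAFE] * n_safe
    stimulus = [TARGET, LURE] * (n_threat // 2) + [TARGET, LURE] * (n_safe // 2)
    extra = [False] * (n_threat + n_safe)
    reinforced = [False] * (n_threat + n_safe)
    shortened = [False] * (n_threat + n_safe)

    # extras: threat slots first, then safe; composition randomised where free
    extra_condition = [THREAT] * config.n_extra_threat + [SAFE] * config.n_extra_safe
    extra_stimulus = [TARGET] * config.n_extra_targets + [LURE] * (n_extra - config.n_extra_targets)
    rng.shuffle(extra_stimulus)
    reinforce_idx = set(
        rng.choice(config.n_extra_threat, size=config.n_reinforced, replace=False).tolist()
    )
    shorten_idx = set(rng.choice(n_extra, size=config.n_shortened, replace=False).tolist())

    condition += extra_condition
    stimulus += extra_stimulus
    extra += [True] * n_extra
    reinforced += [i in reinforce_idx for i in range(n_extra)]
    shortened += [i in shorten_idx for i in range(n_extra)]

    n = len(condition)
    cols = {
        "block_index": [block_index] * n,
        "phase": [EXPERIMENTAL] * n,
        "prior_context": [prior_context] * n,
        "condition": condition,
        "stimulus": stimulus,
        "target_orientation": _orientations(stimulus, rng),
        "reinforced": reinforced,
        "extra_trial": extra,
        "shortened_response": shortened,
        "included_in_analysis": [not e for e in extra],
    }
    return _order_and_time(cols, config, rng)


def build_manipulation_block(
    kind: str,
    config: DesignConfig | None = None,
    rng: np.random.Generator | None = None,
    block_index: int = 0,
) -> BlockSpec:
    """Build one criterion-shift manipulation block.

    Target counts are exact (rate times trial count), the order is random,
    the fixation is black (neutral condition: no shock possible) and every
    trial is excluded from the d'/criterion analysis.
    """
    config = config or DesignConfig()
    config.validate()
    rng = rng or np.random.default_rng()
    cols = _manipulation_cols(kind, config, rng, block_index)
    return BlockSpec(kind=f"manipulation_{kind}", trials=pd.DataFrame(cols)[TRIAL_COLUMNS])


def build_experimental_block(
    config: DesignConfig | None = None,
    rng: np.random.Generator | None = None,
    block_index: int = 0,
    prior_context: str = RARE,
) -> BlockSpec:
    """Build one experimental block (38 trials by default).

    The 32-trial core is 16 threat + 16 safe, half targets each.  Which six
    trials are "extra" is random subject to the stated composition: four
    threat (three reinforced) and two safe, three targets and three lures
    overall (preserving the 50% target rate), four of the six with a
    shortened response window.
    """
    config = config or DesignConfig()
    config.validate()
    rng = rng or np.random.default_rng()
    cols = _experimental_cols(config, rng, block_index, prior_context)
    return BlockSpec(kind=EXPERIMENTAL, trials=pd.DataFrame(cols)[TRIAL_COLUMNS])


def inclusion_flags(block: BlockSpec) -> np.ndarray:
    """Analysis-inclusion flags of an experimental block.

    A trial is included iff it is not an extra trial, not reinforced, and its
    response window was not shortened (reinforced and shortened trials are a
    subset of the extras by construction).
    """
    if not block.is_experimental:
        raise ContractError("inclusion flags are defined for experimental blocks only")
    t = block.trials
    return (
        ~t["extra_trial"].to_numpy(bool)
        & ~t["reinforced"].to_numpy(bool)
        & ~t["shortened_response"].to_numpy(bool)
    )


def _session_order_and_colour(
    config: DesignConfig, subject_id: int
) -> tuple[list[str], str]:
    if config.manipulation_order is not None:
        order = list(config.manipulation_order)
        if len(order) != config.n_blocks or not set(order) <= {RARE, FREQUENT}:
            raise ConfigError("manipulation_order must list 'rare'/'frequent' per block")
    else:
        first = (RARE, FREQUENT) if subject_id % 2 == 0 else (FREQUENT, RARE)
        order = list(itertools.islice(itertools.cycle(first), config.n_blocks))
    colour = config.colour_assignment or (
        "orange_threat" if subject_id % 2 == 0 else "blue_threat"
    )
    if colour not in ("orange_threat", "blue_threat"):
        raise ConfigError(f"unknown colour assignment {colour!r}")
    return order, colour


def _session_cols(config: DesignConfig, rng: np.random.Generator, order: list[str]) -> list[dict]:
    cols_list = []
    for i, kind in enumerate(order):
        cols_list.append(_manipulation_cols(kind, config, rng, block_index=2 * i))
        cols_list.append(_experimental_cols(config, rng, block_index=2 * i + 1, prior_context=kind))
    return cols_list


def build_session(
    config: DesignConfig | None = None,
    seed: int = 0,
    subject_id: int = 0,
) -> SessionSchedule:
    """Build a full session schedule, deterministically for a given seed.

    Manipulation-block order and threat-colour assignment are counterbalanced
    by subject-index parity (rare-first and orange-threat for even subjects)
    unless overridden in the config.
    """
    config = config or DesignConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    order, colour = _session_order_and_colour(config, subject_id)

    cols_list = _session_cols(config, rng, order)
    frame = pd.DataFrame(
        {k: np.concatenate([np.asarray(c[k]) for c in cols_list]) for k in cols_list[0]}
    )
    frame["trial_index"] = np.arange(len(frame))
    frame = frame[TRIAL_COLUMNS]
    for col in BOOL_COLUMNS:
        frame[col] = frame[col].astype(bool)

    blocks = []
    lo = 0
    for i, kind in enumerate(order):
        for length, bkind in (
            (config.trials_per_manipulation, f"manipulation_{kind}"),
            (config.trials_per_experimental, EXPERIMENTAL),
        ):
            blocks.append(BlockSpec(kind=bkind, trials=frame.iloc[lo : lo + length]))
            lo += length
    return SessionSchedule(
        subject_id=subject_id,
        colour_assignment=colour,
        manipulation_order=order,
        blocks=blocks,
        seed=seed,
    )


def build_cohort(
    config: DesignConfig | None = None,
    n_subjects: int = 52,
    seed: int = 0,
    subject_ids: list[int] | None = None,
) -> pd.DataFrame:
    """Build many sessions into one flat trial table (fast path).

    Column layout matches :func:`build_session` plus a leading ``subject_id``;
    per-subject randomisation streams are derived deterministically from the
    base seed.
    """
    config = config or DesignConfig()
    config.validate()
    subject_ids = list(range(n_subjects)) if subject_ids is None else list(subject_ids)
    all_cols: list[dict] = []
    sizes = []
    for sid in subject_ids:
        rng = np.random.default_rng([seed, sid])
        order, _ = _session_order_and_colour(config, sid)
        cols_list = _session_cols(config, rng, order)
        all_cols.extend(cols_list)
        sizes.append(sum(len(c["condition"]) for c in cols_list))
    frame = pd.DataFrame(
        {k: np.concatenate([np.asarray(c[k]) for c in all_cols]) for k in all_cols[0]}
    )
    frame["subject_id"] = np.repeat(subject_ids, sizes)
    frame["trial_index"] = np.concatenate([np.arange(s) for s in sizes])
    for col in BOOL_COLUMNS:
        frame[col] = frame[col].astype(bool)
    return frame[["subject_id"] + TRIAL_COLUMNS]
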