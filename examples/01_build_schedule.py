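"""Build one session schedule and inspect its design invariants.

The paradigm alternates 20-trial target-frequency manipulation blocks (20% or
80% targets, shock-free) with 38-trial experimental blocks (50% targets,
threat/safe cue on the fixation colour).  Six trials per experimental block
exist only to deliver shocks or probe attentiveness and are excluded from
analysis, leaving a 32-trial core split 16/16 between threat and safe.
"""

from threatdetect.schedule import DesignConfig, build_session

session = build_session(DesignConfig(), seed=1, subject_id=0)
trials = session.trials()
print(f"blocks: {len(session.blocks)}, manipulation order: {session.manipulation_order}")
print(f"threat colour: {session.colour_assignment}")

exp = trials[trials["phase"] == "experimental"]
per_block = exp.groupby("block_index").agg(
    included=("included_in_analysis", "sum"),
    reinforced=("reinforced", "sum"),
    targets=("stimulus", lambda s: (s == "target").sum()),
)
print(per_block)
# Every experimental block: 32 analysed trials, 3 reinforced, 19 targets of 38.
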