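# Methods

`threatdetect` couples a generative model of a threat-of-shock visual
target-detection study to the exact scoring and inference chain such a study
would apply to its data. This note records the model, the default
parameters and why they have those values, the numerical conventions, and
what the synthetic data do and do not emulate.

## Design generator

A session is eight pairs of blocks. Each *manipulation* block has 20 trials
with a target rate of exactly 20% (rare) or 80% (frequent), a black fixation
(no shock possible), a 5% Michelson-contrast mask for high visibility, and is
never scored for d′/criterion — its role is to push the decision criterion.
Each *experimental* block has 38 trials at a 50% target rate: a 32-trial
analysed core (16 threat / 16 safe, half targets each) plus six extra trials
— four threat (three of them shock-reinforced, giving the 15% reinforcement
rate over 20 threat trials) and two safe, four of the six with a shortened
response window (800–3000 ms) — which are excluded from analysis because
they either contain a shock or too little time to measure the cardiac
response. Which six trials are "extra" is random per block subject to those
marginals; nothing constrains the three reinforced trials to be
non-consecutive. Timing: threat/safe cue (fixation colour) 1000–3000 ms,
stimulus 16.7 ms, ISI 16.7 ms, mask 100 ms, ISI 4000 ms, response window
1500 ms, ITI 2000–4000 ms; manipulation trials use the shorter fixed
schedule (500 ms fixation, 800 ms post-mask ISI, 2000 ms ITI). Rare/frequent
order alternates starting with rare for even-numbered subjects and frequent
for odd (an explicit counterbalancing convention; only "counterbalanced" is
given), and likewise for the orange/blue threat-colour assignment.

## Observer

Equal-variance Gaussian SDT: evidence X ~ N(d′·1[target], 1), response
"present" iff X > d′/2 + c. The criterion parameter c is referenced to the
equal-likelihood midpoint so that the analysis-side formulas
d′ = z(H) − z(F), c = −(z(H)+z(F))/2 recover exactly the parameters the
generator was given — the convention under which the study-level criterion
values (0.53 after rare, 0.20 after frequent blocks) are meaningful. The
criterion is base + context shift (±0.165 by default); the threat cue does
not move it, mirroring the study's null result. Sensitivity during
experimental blocks is the condition value (threat 1.66, safe 1.55 —
an additive population-level threat gain of 0.11); during
familiarisation/staircase/manipulation phases it comes from the logistic
contrast mapping d′(m) = d′max/(1+exp(k(m−m₀))) with d′max = 3.5, k = 8,
m₀ = 0.5, chosen so the 79.4%-correct point sits near 50% mask contrast
(the titrated contrast scale reported for the paradigm). No false-alarm
rates are reported for the task, so the generator's FA level is implied:
F = Φ(−d′/2 − c) ≈ 0.12 at the default parameters, consistent with the
reported hit rate (0.68 threat / 0.65 safe).

Responses can also be non-responses (rate 0.0135, matching the reported
exclusion rate; gamma-distributed across subjects with SD 0.0219) and
lapses (uniform guessing). The default lapse rate is 0.01: the reported
d′/criterion are finite-trial estimates, and at 64 targets + 64 lures per
condition the convexity of the normal quantile transform biases estimated d′
upward by ≈ +0.02; a 1% lapse offsets this almost exactly (delta-method
calculation), so the cohort's *observed* means sit on the reported values. A
small lapse rate is also the standard psychophysical observer assumption.

RTs are lognormal with condition-shifted means (632.4 ms threat, 616.5 ms
safe; trial SD 150 ms). The 4-s gap between stimulus and response window
means the task is unspeeded; the RT model is purely descriptive.

### Population

Between-subject structure uses latent standard-normal traits with a Gaussian
copula:

| trait | feeds | default scale | rationale |
| --- | --- | --- | --- |
| sensitivity | d′ threat and safe jointly | SD 0.60 | reported cross-subject SDs (0.68/0.62) minus the ≈0.26 finite-trial estimation noise; one shared trait keeps the latent threat gain constant |
| criterion level | base c | SD 0.30 | reported per-context SDs (0.37–0.49) minus estimation noise |
| shift magnitude | ±shift | SD 0.08, floored at 0 | modest heterogeneity in manipulation efficacy |
| heart-rate trait | deceleration depths | SD 2.0/1.6 BPM | reported ΔBPM SDs (2.12/1.68) |
| RT trait | mean RT | SD 85 ms | reported RT SDs (~90 ms) |

Two correlations are modelled: sensitivity × shift magnitude −0.29 (more
sensitive observers are swayed less by the frequency manipulation) and
heart-rate trait × RT −0.32 on the trait scale, so that mean ΔBPM and mean
RT correlate positively ≈ +0.32 across subjects (stronger decelerators
respond faster).

## Staircase

3-down-1-up on mask contrast, start 0.60, fixed step 0.05 in both directions
(equal steps preserve the 0.794³ = ½ equilibrium; no step size is reported,
so a single conventional value is used). The converged level is the mean of
all reversals except the first three. Track acceptance replaces the original
visual inspection with a numeric rule: a least-squares slope of contrast on
trial beyond ±0.005 per trial marks a drifting track and triggers a restart
at 0.50 (downward drift) or 0.70 (upward). The threshold was calibrated on
the sampling distribution of healthy tracks: the settle-in from the 0.60
start to the ~0.50 equilibrium alone contributes slope ≈ −0.0025 over 40
trials and equilibrium wander routinely reaches 0.003, while observers whose
psychometric range cannot bracket the 79.4% point drift at ≈0.01 or steeper
— a tighter cut would send the majority of perfectly good runs back for a
restart. Observers pinned near chance or
ceiling at every contrast are flagged as convergence failures (too few
reversals, or >20% of trials at a clipped boundary) rather than raising. Two
independent 40-trial staircases (one per target orientation) are run per
subject and their reversal averages averaged.

One deliberate decoupling: the experimental-phase d′ values are the sampled
population parameters, not d′(titrated contrast). The staircase stage runs in
the pipeline (and its convergence statistics are validated against the
75%-mean-accuracy and 79.4%-asymptote properties), but tying experimental
sensitivity to each subject's noisy 40-trial titration would make the
cohort's d′ distribution a function of staircase luck rather than of the
population model the study reports. The generator therefore treats titration
as what it is operationally — a visibility-equating procedure — and draws
experimental sensitivity directly from the population.

## Physiology

Sampling is at 50 Hz for generation and analysis (the analysis rates of the
original recordings after downsampling; synthesising at an acquisition-level
5 kHz would add nothing testable). Heart rate: baseline 70 BPM +
Ornstein–Uhlenbeck noise (SD 1.5 BPM, τ = 4 s) + an event-locked
*plateau* deceleration per experimental trial: cosine drop over 0.5 s, hold
at full depth until 6.5 s, cosine recovery ending 7.5 s after trial onset.
Depth = condition depth (threat 4.38, safe 2.99 BPM) ± half the detection
modulation (hits deeper, misses shallower by 0.25 BPM each with the default
0.5 BPM hit–miss gap, keeping condition means unchanged) + trial jitter
(SD 0.8 BPM, floored at 0).

The plateau shape is a deliberate choice. Scored with the study's windows
(mean BPM 1–5 s post-onset minus a 1-s pre-onset baseline) the plateau
yields exactly −depth, so programmed values are recovered on the scale the
analysis reports. And when the same windows are re-aligned to the stimulus
(which onsets 1–3 s into the trial), window and baseline both sit on the
plateau and the outcome-dependent depth difference cancels — reproducing the
study's signature dissociation (hit/miss difference present trial-locked,
absent stimulus-locked). A transient dip kernel cannot do both: re-aligned,
it leaves a residue of either sign comparable to the effect itself. The
sustained-anticipation reading is also physiologically coherent: the
deceleration tracks the threat-anticipation period, not the stimulus.

A synthetic pulse waveform (one Gaussian peak per beat, beat times from the
integrated instantaneous rate) feeds the beat-detection path: smoothed
peak-picking with a 0.33-s refractory period, implausible inter-beat
intervals (<0.33 s or >2 s) flagged, and a step-interpolated BPM series
(step vs linear differs by well under 0.1 BPM at 4-s windows). The pipeline
runs this full pulse→beats→BPM→scoring loop by default.

Skin conductance: tonic 2 µS + per-trial phasic response (smooth cosine rise
peaking at 2 s, exponential decay τ = 2.5 s), onset latency uniform in
1–3 s after the stimulus — inside the scoring window by construction.
Trial amplitudes vary on the square-root scale (SD 0.03 √µS) around
condition means whose squares are 0.24² and 0.09² µS: the reported means are
on the square-root scale (amplitudes are root-transformed before analysis),
so the generator is parameterised to make the *transformed* scored means
land on 0.24/0.09. Scoring finds prominence-filtered trough/peak pairs in
the smoothed trace, keeps those with onset latency in [0.5, 5.133] s and
trough-to-peak rise time in [0.5, 5] s ("maximum rise time after response
onset" is read as rise time from SCR onset), scores the largest qualifying
amplitude, and returns 0 when none qualifies. The minimum-amplitude floor
defaults to 0.001 µS: the safe-condition mean response is ≈0.008 µS raw, so
any floor near the conventional 0.01 µS would delete the very responses the
analysis averages; the floor is configurable for noisier data.

## Analysis battery

Trials are excluded when flagged at design time, unanswered, or answered
after 1500 ms. Cells use the 0.25-count correction (0 → 0.25, n → n−0.25,
applied to the offending cell only; both if both are extreme). Subject
screening mirrors the study: non-response rate > 33%, or accuracy beyond
±2 SD of the pre-screening sample mean (thresholds computed on the first
wave of recruits); recruitment continues until the configured number of
analysable subjects is reached, as in the original stopping rule.

Tests and conventions: Wilcoxon signed-rank drops zero differences,
mid-ranks ties, reports a continuity-corrected normal-approximation Z (exact
enumeration of sign assignments when ≤12 non-zero differences), effect
r = |Z|/√n with n the pairs entered. Paired t reports d = t/√n. The 2×2
within-subject ANOVA is computed from per-subject contrasts (each effect's
F(1, n−1) is the squared paired t on its contrast) with partial
η² = F·df₁/(F·df₁+df₂). The ART procedure aligns responses per effect with
cell-mean estimates, ranks across the whole sample, and runs the parametric
ANOVA on ranks — implemented for the 2×2 within-subject case only.
One-tailed tests are used exactly for the directional threat-vs-safe
hypotheses on heart rate, SCR, hits and d′; everything else is two-tailed.
Effect-size CIs are subject-level percentile bootstrap (2000 resamples;
90% for the one-tailed analyses, 95% otherwise). The battery covers: the
criterion manipulation check; HR and SCR threat effects; hits and d′ under
threat; criterion under threat and the threat × frequency interaction
contrast, with an ART cross-check; pooled d′ vs criterion-shift Spearman;
Threat × Hit/Miss ANOVAs on ΔBPM (trial- and stimulus-locked) and on √SCR;
the safe-after-threat carryover t; RT under threat; and the RT/ΔBPM
correlations.

## Problem sizes and what the tests show

The calibration and recovery checks run at sizes chosen to make Monte-Carlo
error small relative to the asserted tolerances: parameter recovery uses
≈5100 trials per condition (40 cohort subjects) for the autonomic means and
5000 subjects for the behavioural means; staircase properties use 500
40-trial blocks and a 2000-trial long run; test-level type-I rates use 2000
replicates at n = 52; pipeline-level null rates use 1000 replicate
effect-free studies; power properties use 200 replicate default-profile
studies. Replicate-study batteries run behaviour-only (the d′/criterion/RT
hypotheses do not depend on the physiological channels).

One power property deserves its own note. At this design's trial counts
(64 targets + 64 lures per condition per subject), the sampling variance of
an estimated d′ is ≈0.069 per condition, so the per-subject threat−safe d′
difference cannot have an SD below ≈0.37 no matter how homogeneous the true
effect is. With a true gain of 0.11 that caps the standardised effect near
dz ≈ 0.30 and the one-tailed power of the d′ test at n = 52 near two-thirds;
the measured replication rate here is ≈0.60. An empirical study of this size
that observes a significant d′ effect is therefore somewhat lucky; the
criterion-shift manipulation, by contrast, replicates essentially always.

## What the generator does not emulate

Stimulus rendering (gratings, masks, gamma), shock hardware and work-up,
trial-to-trial criterion learning dynamics inside manipulation blocks
(the context shift is applied as a constant), drift-diffusion-style RT
mechanisms, respiratory sinus arrhythmia and pulse-waveform morphology,
tonic skin-conductance drift, motion artefacts, and any EEG/fMRI channel.
Passing tests therefore demonstrate that the *scoring and inference chain*
is correct and calibrated and that the generator reproduces the study-level
statistical structure — not that real recordings are this clean. In real
data, beat detection and SCR scoring would face artefacts the automated
implausible-IBI flag and amplitude floor only approximate; the original
workflows included manual inspection.

## Known limitations

- The ART implementation covers the balanced 2×2 within-subject design only.
- `run_analysis` expects the package's trial-table schema; arbitrary
  external layouts need mapping first.
- The screening rule evaluates replacement recruits against thresholds fixed
  from the first wave; a study that re-derived thresholds after every
  replacement would differ microscopically.
- Percentile-bootstrap CIs undercover for standardised effect sizes at very
  small n (≲20 subjects); at the study scale (n ≈ 50) coverage is nominal.
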