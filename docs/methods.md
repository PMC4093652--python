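# Methods

## Model

The core is a discrete-time temporal-difference (TD) learner over binary
*event* vectors. "Event" is deliberately generic: task stimuli, pre-cues,
fixation marks, and response-outcome feedback all live in one catalog of K
channels, can all be predicted, and can all serve as predictors. This
uniform treatment is the substantive claim the package implements: the same
prediction/discrepancy computation that explains performance-monitoring
signals in medial prefrontal cortex also explains purely stimulus-related
ones.

Time within a run is a sequence of 10 ms iterations. Event history enters
through a tapped-delay line — unit (j, k) is active exactly j − 1
iterations after an occurrence of event k — so a delay bank of J units per
event provides a temporally precise, strictly feed-forward basis for
prediction. Predictions are linear in the delay units with nonnegative
weights W[i, j, k]; the weight update is a vector TD(λ) rule with an
accumulating eligibility trace (decay 0.95 per iteration) and a
rectification W ≥ 0 applied after every update. The activity readout is
*negative surprise*, ω^N(t) = Σ_i max(0, P_i(t) − E_i(t)): the aggregate
mass of predictions not met by events this iteration. Per-channel
(unsummed) terms serve as model single units.

Assumptions worth making explicit:

* **Deterministic within-trial timing.** TD learning over a tapped-delay
  line only converges to calibrated predictions when event lags repeat
  exactly; generators therefore never jitter inter-stimulus or inter-trial
  intervals. Response-dependent feedback timing varies by a few iterations
  with reaction time; predictions smear accordingly.
* **Continuous learning.** Neither weights, traces, nor the delay line
  reset at trial boundaries. Predictions bridge trials (feedback predicts
  the next trial's onset), which is precisely what lets stimulus-only
  paradigms work.
* **Binary events, identity not value.** Events mark that something
  happened, never how valuable it was; the reward events of the
  expect-reward task are identity markers.

### Eligibility-trace timing

Within one iteration the implementation: reads the prediction P_t from the
current delay state; refreshes the trace with *that same* (pre-advance)
state; observes events and advances the delay line; bootstraps P_{t+1}
from the advanced state with the pre-update weights; forms
δ = E + γP_{t+1} − P_t; updates the weights through the trace.

The one genuinely open choice here is which state refreshes the trace
before the update. Refreshing with the *post*-advance state (so the
current events' own delay-1 units immediately carry eligibility for the
concurrent δ) looks equally self-consistent but is unstable: the
bootstrap term rewards predicting an event one iteration after itself, the
resulting one-step-late weights inflate δ at the event, and the W ≥ 0
rectification blocks the symmetric correction. On a periodic stream the
learner then settles into a limit cycle with prediction spikes several
times larger than the discounted-return ceiling, and TD errors never
converge. The pre-advance convention — the standard TD(λ) accumulating
trace, which credits the features of the state whose prediction the error
corrects — converges exactly, for every learning rate we use (see below).
The package therefore uses the pre-advance convention.

### Parameters

| parameter | default | units | notes |
|---|---|---|---|
| γ (discount) | 0.95 | per iteration | fixed property of the model |
| trace decay | 0.95 | per iteration | fixed property of the model |
| α (learning rate) | 0.1 | — | convergence-rate setting; the core's convergence and surprise properties hold for α ∈ [0.05, 0.3] |
| J (delay horizon) | 150 | iterations | must cover the longest predictive lag, including feedback → next-trial onset; the omission task trims it to twice the repetition interval |
| iteration | 10 | ms | interpretation only |

Because γ = 0.95 per 10 ms, predictions are temporally sharp: an event
d iterations away contributes γ^d, so anticipatory activity is visible
mainly within a few hundred milliseconds of the predicted event, and a
perfectly predicted periodic event still carries P slightly above 1 at its
onset (the discounted sum over future repetitions; 1/(1 − γ^30) ≈ 1.27 for
a 300 ms period). The rectified readout consequently shows a baseline of
anticipatory "surprise" during event-free stretches; condition effects ride
on top of it.

## Actor

Tasks with a behavioral component need response-outcome conjunction events.
A minimal fixed actor provides them: per response, a noisy accumulator
integrates its summed stimulus drive plus zero-mean Gaussian noise
(sd 0.1/iteration), clipped at zero; the first accumulator to cross
threshold 1.0 within the 100-iteration response window responds, ties
breaking uniformly; the conjunction event (response × correct/error)
follows 20 iterations later. Omitted responses are scored as errors on the
correct-response channel — the catalogs contain no "no response" event.
Stimulus-response drive is fixed, not learned: target 0.08, distractor
0.04 per iteration (go drive 0.06 and stop-signal inhibition −0.6 in the
stop task, stop-signal delay 150 ms). These values were set once to give
conventional behavior — ~0% congruent and ~12–14% incongruent errors, a
3–4 iteration congruency RT cost, and roughly even stop-trial outcomes —
mirroring the error-rate regime the original behavioral fits produced.
Noise enters an accumulator only alongside nonzero drive, so zeroing the
drive (`sr_scale = 0`) is a complete lesion of response generation:
stimulus-only tasks provably emit no responses and no feedback events.

The actor is open-loop: model predictions do not bias responding (no
proactive/reactive control), and no claim in this package depends on
fitted reaction-time distributions.

## Task environments and timing templates

All generators sample trial types i.i.d. from a seeded generator and are
bit-exact reproducible from (parameters, seed). The default timing
template places the fixation/cue at iteration 0, the imperative stimulus
at iteration 50 where a cue exists (else 0), a 100-iteration response
window, feedback 20 iterations after the response, and a 50-iteration
inter-trial interval; the omission task repeats its stimulus every 30
iterations, and the expect-reward task uses cue 0 / go-cue 100 / reward
150 within a 200-iteration trial.

* **Flanker frequency** (8 events): frequent trial type 75%; target and
  flanker fire together at onset; left/right sides balanced.
* **Item-specific Stroop** (12 events): two equiprobable two-color
  classes; class-conditional incongruent rates (0.1, 0.5), (0.5, 0.5),
  (0.5, 0.9) across the three experiments, so the global rates 0.3, 0.5,
  0.7 follow as the class means. Responses name the font color by
  within-class position, keeping four conjunction events shared across
  classes. (The source text's stated total of eight events is mutually
  inconsistent with its own itemization for two two-color classes; the
  itemized catalog is implemented.)
* **Omission/mismatch** (1 event, lesioned): 200 training repetitions,
  then omissions after 1–7 further repetitions, five cycles through the
  seven counts in shuffled order.
* **Cued Stroop** (10 events): three equiprobable cue types; informative
  cues are always valid; uninformative cues precede either trial type with
  probability ½.
* **Stop signal** (7 events): 25% stop trials; fixation, go at 50, stop at
  go + 15 on stop trials.
* **Expect reward** (10 events, lesioned): equiprobable magnitudes;
  go-phase cue repeats the initial cue except on 25% of small/large
  trials, where it swaps to the opposite magnitude; the reward-identity
  event always matches the go-phase cue.

## Measurement conventions

Cohorts default to 10 independent subjects; each subject's weights start
at zero and every stochastic component draws from seeds spawned off one
master seed. Activity is summarized as means over iteration windows
anchored at event onsets — 20 iterations (200 ms) by default, 100
iterations for the low-temporal-resolution comparison, window = [onset,
onset + width). Cohort statistics are means of subject means with the
standard error across subjects.

Three analysis choices deserve note:

* **Burn-in.** Stimulus-window condition contrasts (flanker, Stroop, cued
  Stroop) exclude the first third of each run. The contrasts are
  properties of the trained model's predictions; during acquisition the
  frequent trial type accrues predictive mass first, which transiently
  biases the comparison the other way.
* **Omission summary.** The omission analysis reports activity at the
  expected-onset iteration itself (plus the full −400 ms…+200 ms
  timecourse). A 200 ms window average would be dominated by the
  anticipatory ramp toward the *next* stimulus, which is higher after a
  presented stimulus than after an omission and would mask the omission
  transient.
* **Stop-probability split.** The per-trial stop-probability estimate is
  the stop fraction over the previous ten trials; the first ten trials
  have no estimate and are excluded by the median split, which is
  recomputed from each run's own estimates with ties assigned to "low".
  Stop-trial activity is anchored at the stop-signal onset, go-trial
  activity at the go signal.

## What the generators do and do not emulate

The generators reproduce the published trial-type statistics, event
catalogs, and (where stated) timing of the six paradigms, with all other
timing fixed by the template above. They do not emulate jittered
intervals, staircased stop-signal delays, learned or adaptive response
policies, stimulus persistence (every event is a single-iteration pulse),
or any physiological forward model (activity is read out directly, not
convolved with a hemodynamic or ERP kernel). Passing tests therefore show
that the *model's* computations produce the qualitative activity patterns
under these idealized protocols; they do not show that the patterns
survive realistic timing variability — the model's known sensitivity to
timing jitter is the main caveat — nor do they calibrate activity to any
empirical measurement scale.

## Numerical choices and degenerate inputs

Weights, traces, and predictions are double precision; the vectorized
runner is verified against a straight-line loop reference to 1e−12. The
weight rectification is a clip at zero (W ≥ 0), the only reading
compatible with zero initialization. Dimension mismatches raise
configuration errors; windows that would extend past the end of a log
raise rather than truncate; accumulator ties break by seeded choice;
feedback scheduled beyond the trial end is an error (the default template
cannot produce one). Derived seeds stay below 2^31.

## Known limitations

* Sensitivity to event timing is intrinsic: the delay-line basis has no
  temporal generalization, so small lag changes require relearning.
* The nonnegativity constraint induces a small upward bias on weights
  whose true value is zero; this is visible as slightly elevated
  predictions for never-occurring contingencies (and contributes to the
  informative-cue effect in the cued-Stroop simulation).
* At the published scale (300 trials, 10 subjects) the flanker
  trial-frequency contrast within a frequency condition does not separate
  reliably from sampling noise in this implementation: the asymptotic
  effect measured at small learning rates is under ~2% of the windowed
  baseline, while the matched per-subject sampling noise at 300 trials is
  of the same order. The corresponding acceptance checks document this
  honestly rather than asserting a pattern the mechanism does not
  reliably produce at that scale; the remaining five paradigms' patterns
  are stable across master seeds.
* Item-specific proportion-congruency effects carry a small global-rate
  leak (~4% relative): the overall error rate enters the marginal
  feedback-conjunction predictions present at trial onset, so activity in
  a matched 0.5-incongruent class is slightly lower when the task's other
  class is mostly congruent. The idealized "global rate is immaterial"
  statement holds only approximately.
* The actor is a deliberately minimal open-loop device; reaction-time
  distributions and control adjustments are out of scope.
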