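# prosim

Simulation toolkit for the *predicted response-outcome* (PRO) account of
medial prefrontal cortex (mPFC), in its generalized **event-prediction**
form: mPFC learns to predict any salient event — stimuli, cues, feedback —
and signals the *unexpected non-occurrence* of predicted events. The
package is aimed at computational cognitive neuroscientists who want to
regenerate, probe, or extend the model's accounts of trial-frequency
effects, item-specific proportion congruency, the mismatch/omission
response, cue-based preparation, trial-history (Bayesian-surprise) effects
in the stop-signal task, and reward-magnitude single-unit signatures.

## The model

Time is discretized into 10 ms iterations. The recent event history is held
in a tapped-delay line: unit *(j, k)* is active exactly *j − 1* iterations
after event *k* occurred. Predictions, learning, and the activity readout
are:

    P_i(t)     = Σ_jk  E_jk(t) · W_ijk(t)                    (prediction)
    δ_i(t)     = E_i(t) + γ · P_i(t+1) − P_i(t)              (vector TD error)
    Ē_jk(t+1)  = E_jk(t) + 0.95 · Ē_jk(t)                    (eligibility trace)
    W_ijk(t+1) = max(0, W_ijk(t) + α · δ_i(t) · Ē_jk(t))     (learning, W ≥ 0)
    ω^N(t)     = Σ_i max(0, P_i(t) − E_i(t))                 (negative surprise)

with discount γ = 0.95 per iteration and learning rate α = 0.1 by default.
ω^N — rectified predicted-but-unobserved event mass — is the model's proxy
for mPFC activity; left unsummed, its per-channel terms model single units.
Learning is continuous across trial boundaries, so feedback from one trial
predicts the next trial's stimuli.

Around this core the package provides six task environments (flanker with
manipulated trial-type frequency, item-specific Stroop, stimulus-omission
mismatch, cued Stroop, stop-signal, and a cued reward-magnitude task), a
minimal noisy-accumulator actor that turns stimuli into responses and
response-outcome conjunction events, cohort runners with the corresponding
measurement conventions, and a thin `prosim` command line.

## Worked example

Learn that event A predicts event B 50 ms later, then withhold B
(`python examples/learn_event_pair.py`):

```
TD error on B at its onset, first 3 cycles: [1.    0.904 0.668]
TD error on B at its onset, last 3 cycles:  [0. 0. 0.]
learned prediction of B at its expected onset: 1.559
negative surprise at the omitted onset:        2.281
```

The prediction error at B's onset decays from 1 to 0 as the association is
learned; withholding B then produces a surprise transient reflecting the
converged prediction (above 1 because the prediction also counts
discounted future occurrences). At task scale
(`python examples/stop_signal_probability.py`, 4 subjects):

```
trial_type stop_probability     mean      sem  n_subjects
        go             high 0.444148 0.013399           4
        go              low 0.358094 0.005416           4
      stop             high 0.533193 0.022449           4
      stop              low 0.640654 0.006437           4

learned stop-signal prediction at its scheduled onset (final 100 trials): 0.267
generative stop rate: 0.250
```

Stop trials are most surprising when stop trials have been locally rare;
go trials show the reverse — the crossed pattern that links the model to
Bayesian-surprise accounts — and the learned prediction on the stop channel
recovers the generative 25% stop rate.

Each script in `examples/` demonstrates one capability end to end;
`prosim sim1 … sim6 | all` runs the full cohort simulations from the shell
and writes per-panel CSV summaries.

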