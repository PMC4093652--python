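"""Flanker task with manipulated trial-type frequency.

Generates the two frequency conditions (75% congruent vs 75% incongruent),
lets the accumulator actor perform the task, and summarizes behavior and
stimulus-window model activity by trial type.
"""

from prosim.experiments import CohortConfig, run_sim1, run_subject
from prosim.tasks import gen_flanker_frequency

# behavior of the built-in actor
sched = gen_flanker_frequency("frequent-congruent", 500, seed=1)
log = run_subject(sched, seed=2)
for label in ("congruent", "incongruent"):
    sub = log.trials[log.trials.condition == label]
    err = (sub.outcome == "error").mean()
    rt = 10 * sub.response_iteration.mean()  # iterations -> ms
    print(f"{label:<12} error rate {err:5.1%}   mean RT {rt:5.0f} ms")

summary = run_sim1(CohortConfig(n_subjects=4, master_seed=1))
print("\nStimulus-window activity by frequency condition and trial type:")
print(summary.to_string(index=False))
print("\nIncongruent flankers drive the wrong response, producing the")
print("classic congruency cost in errors and reaction time. The windowed")
print("activity contrast between frequent and infrequent trial types is")
print("small relative to sampling noise at this scale (see the methods")
print("note), so expect its direction to vary across seeds.")
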