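"""Cohort simulation and measurement conventions.

This module runs the event-prediction model through the task environments
and reduces the iteration-level logs the way the figures summarize them:
activity averaged over short iteration windows anchored at event onsets
(default width 20 iterations = 200 ms; an extended 100-iteration window for
the low-temporal-resolution comparison), condition means per subject with
cohort mean and standard error across subjects, a local stop-probability
estimator with median split for the stop-signal analysis, and per-channel
(unsummed) surprise for the single-unit analysis.

A cohort is a set of independent simulated subjects (default 10); each
subject starts with all prediction weights at zero and learns continuously
across that subject's whole trial sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from prosim.core_model import ModelConfig, PROModel
from prosim.response_control import (
    ResponseConfig,
    score_outcome,
    simulate_trial_response,
)
from prosim.tasks import (
    TaskSchedule,
    gen_cued_stroop,
    gen_expect_reward,
    gen_flanker_frequency,
    gen_item_stroop,
    gen_mmn,
    gen_stop_signal,
)

__all__ = [
    "CohortConfig",
    "SubjectLog",
    "run_subject",
    "window_mean",
    "local_stop_probability",
    "median_split",
    "unit_summary",
    "condition_summary",
    "log_to_frame",
    "weights_to_frame",
    "run_sim1",
    "run_sim2",
    "run_sim3",
    "run_sim4",
    "run_sim5",
    "run_sim6",
    "stop_prediction_recovery",
]


@dataclass(frozen=True)
class CohortConfig:
    """Cohort size and seeding for one simulated experiment."""

    n_subjects: int = 10
    n_trials: int = 300
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


@dataclass
class SubjectLog:
    """Iteration-level record of one subject's run.

    ``pred``, ``delta`` are ``(T, K)``; ``omega`` is the scalar negative
    surprise per iteration; ``events`` the binary event stream actually
    experienced (stimuli plus actor-generated feedback). ``trials`` carries
    one row per trial (absolute start iteration, condition, response,
    outcome, and task metadata).
    """

    schedule: TaskSchedule
    omega: np.ndarray
    pred: np.ndarray
    delta: np.ndarray
    events: np.ndarray
    trials: pd.DataFrame

    @property
    def unit(self) -> np.ndarray:
        """Per-channel negative surprise, ``max(0, P - E)`` per iteration."""
        return np.maximum(self.pred - self.events, 0.0)

    def onsets(self, event_name: str, fallback: int | None = None) -> np.ndarray:
        """Absolute onset iteration of ``event_name`` per trial.

        Trials lacking the event get NaN, or ``start + fallback`` when a
        fallback within-trial iteration is given (used e.g. for the
        *expected* onset of an omitted stimulus).
        """
        starts = self.schedule.trial_starts
        out = np.full(len(starts), np.nan)
        for i, trial in enumerate(self.schedule.trials):
            onset = trial.onsets.get(event_name, fallback)
            if onset is not None:
                out[i] = starts[i] + onset
        return out


def run_subject(
    schedule: TaskSchedule,
    model_cfg: ModelConfig | None = None,
    response_cfg: ResponseConfig | None = None,
    seed: int = 0,
) -> SubjectLog:
    """Simulate one subject: actor behavior, event stream, model learning.

    Behavior is resolved first (the actor does not depend on the model's
    predictions), the resulting event stream — scheduled stimuli plus
    response-outcome conjunction events — is then fed through a freshly
    initialized model in one continuous pass. ``seed`` drives the actor's
    accumulator noise and tie-breaking only; the schedule carries its own
    generator seed.
    """
    catalog = schedule.catalog
    k = len(catalog)
    if model_cfg is None:
        model_cfg = ModelConfig(n_events=k)
    if model_cfg.n_events != k:
        raise ValueError(
            f"model configured for {model_cfg.n_events} events, catalog has {k}"
        )
    if response_cfg is None:
        response_cfg = ResponseConfig()
    rng = np.random.default_rng(seed)

    events = np.zeros((schedule.n_iterations, k), dtype=np.uint8)
    starts = schedule.trial_starts
    rows = []
    for i, trial in enumerate(schedule.trials):
        start = int(starts[i])
        for name, onset in trial.onsets.items():
            events[start + onset, catalog.index(name)] = 1

        response = None
        response_iteration = None
        outcome = None
        conjunction = None
        feedback_iteration = None
        actable = (
            trial.response_window_start is not None
            and trial.drives
            and schedule.responses
            and response_cfg.sr_scale > 0.0
        )
        if actable:
            ws = int(trial.response_window_start)
            drive = np.zeros((response_cfg.response_deadline, len(schedule.responses)))
            for ev, dmap in trial.drives.items():
                onset = trial.onsets.get(ev)
                if onset is None:
                    continue
                row0 = max(onset - ws, 0)
                for rname, w in dmap.items():
                    drive[row0:, schedule.responses.index(rname)] += w
            response, response_iteration = simulate_trial_response(
                drive, schedule.responses, ws, response_cfg, rng
            )
            scored = score_outcome(
                response,
                response_iteration,
                trial.correct_response,
                dict(trial.conjunction_map),
                response_cfg,
                deadline_iteration=ws + response_cfg.response_deadline,
            )
            outcome = scored.outcome
            conjunction = scored.conjunction_event
            feedback_iteration = scored.feedback_iteration
            if conjunction is not None:
                if feedback_iteration >= trial.length:
                    raise ValueError(
                        f"trial {i}: feedback at {feedback_iteration} falls outside "
                        f"trial of length {trial.length}"
                    )
                events[start + feedback_iteration, catalog.index(conjunction)] = 1

        row = {
            "trial": i,
            "start": start,
            "length": trial.length,
            "condition": trial.condition,
            "response": response,
            "response_iteration": response_iteration,
            "outcome": outcome,
            "conjunction": conjunction,
            "feedback_iteration": feedback_iteration,
        }
        row.update(trial.meta)
        rows.append(row)

    model = PROModel(model_cfg)
    pred, delta, omega = model.run(events)
    return SubjectLog(
        schedule=schedule,
        omega=omega,
        pred=pred,
        delta=delta,
        events=events,
        trials=pd.DataFrame(rows),
    )


def window_mean(
    values: np.ndarray,
    anchors: np.ndarray,
    width: int = 20,
    offset: int = 0,
) -> np.ndarray:
    """Mean of ``values`` over ``[anchor + offset, anchor + offset + width)``.

    ``anchors`` may contain NaN (no anchor on that trial), which propagates.
    A window extending past the end of the log raises a truncation error.
    """
    if width < 1:
        raise ValueError("window width must be >= 1")
    values = np.asarray(values)
    if values.ndim != 1:
        raise ValueError("window_mean expects a 1-D activity trace")
    anchors = np.asarray(anchors, dtype=float)
    out = np.full(anchors.shape, np.nan)
    for i, a in enumerate(anchors):
        if np.isnan(a):
            continue
        lo = int(a) + offset
        hi = lo + width
        if lo < 0 or hi > len(values):
            raise ValueError(
                f"window [{lo}, {hi}) exceeds log of length {len(values)}"
            )
        out[i] = values[lo:hi].mean()
    return out


def local_stop_probability(trial_types: np.ndarray, window: int = 10) -> np.ndarray:
    """Proportion of stop trials among the previous ``window`` trials.

    ``trial_types`` is a boolean array (True = stop). The first ``window``
    trials have no defined estimate and are returned as NaN; downstream
    analyses exclude them.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    trial_types = np.asarray(trial_types, dtype=float)
    out = np.full(trial_types.shape, np.nan)
    for t in range(window, len(trial_types)):
        out[t] = trial_types[t - window : t].mean()
    return out


def median_split(estimates: np.ndarray) -> np.ndarray:
    """Label each estimate "high" or "low" against the run's own median.

    The median is recomputed from the supplied estimates (NaN entries are
    excluded and labelled ``None``); ties at the median go to "low".
    """
    estimates = np.asarray(estimates, dtype=float)
    valid = ~np.isnan(estimates)
    if not valid.any():
        raise ValueError("median_split needs at least one defined estimate")
    median = float(np.median(estimates[valid]))
    labels = np.empty(estimates.shape, dtype=object)
    labels[:] = None
    labels[valid & (estimates > median)] = "high"
    labels[valid & (estimates <= median)] = "low"
    return labels


def unit_summary(
    log: SubjectLog,
    anchors: np.ndarray,
    width: int = 20,
    offset: int = 0,
) -> np.ndarray:
    """Per-channel windowed mean surprise, one row per anchor.

    Returns an ``(n_anchors, K)`` array; rows for NaN anchors are NaN.
    Summing across channels reproduces the scalar windowed readout.
    """
    unit = log.unit
    anchors = np.asarray(anchors, dtype=float)
    out = np.full((len(anchors), unit.shape[1]), np.nan)
    for i, a in enumerate(anchors):
        if np.isnan(a):
            continue
        lo = int(a) + offset
        hi = lo + width
        if lo < 0 or hi > len(unit):
            raise ValueError(
                f"window [{lo}, {hi}) exceeds log of length {len(unit)}"
            )
        out[i] = unit[lo:hi].mean(axis=0)
    return out


def condition_summary(
    per_trial: pd.DataFrame,
    group_cols: list[str],
    value_col: str = "value",
) -> pd.DataFrame:
    """Cohort summary: subject means per condition, then mean ± s.e.

    ``per_trial`` must contain a ``subject`` column, the grouping columns,
    and ``value_col``. The cohort mean is the mean of subject means; the
    standard error is across subjects.
    """
    subject_means = (
        per_trial.dropna(subset=[value_col])
        .groupby(["subject", *group_cols], sort=True)[value_col]
        .mean()
        .reset_index()
    )
    grouped = subject_means.groupby(group_cols, sort=True)[value_col]
    out = grouped.agg(
        mean="mean",
        sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0,
        n_subjects="count",
    ).reset_index()
    return out


def weights_to_frame(weights: np.ndarray, catalog) -> pd.DataFrame:
    """Nonzero prediction weights as a long table for inspection.

    Columns: predicted event, delay (1-based), source event, weight.
    """
    idx = np.argwhere(weights > 0)
    return pd.DataFrame(
        {
            "predicted_event": [catalog.names[i] for i, _, _ in idx],
            "delay": [j + 1 for _, j, _ in idx],
            "source_event": [catalog.names[k] for _, _, k in idx],
            "weight": weights[tuple(idx.T)],
        }
    )


def log_to_frame(log: SubjectLog, subject: int = 0) -> pd.DataFrame:
    """Columnar iteration-level export (for inspection / CSV dumps)."""
    names = log.schedule.catalog.names
    t = np.arange(len(log.omega))
    trial_of_iter = np.searchsorted(
        log.schedule.trial_starts, t, side="right") - 1
    data = {"subject": subject, "trial": trial_of_iter, "iteration": t}
    for j, name in enumerate(names):
        data[f"event_{name}"] = log.events[:, j]
    for j, name in enumerate(names):
        data[f"P_{name}"] = log.pred[:, j]
    for j, name in enumerate(names):
        data[f"delta_{name}"] = log.delta[:, j]
    data["omega_N"] = log.omega
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# cohort seeding


def _subject_seeds(master_seed: int, salt: int, n_subjects: int) -> list[tuple[int, int]]:
    """Independent (task, actor) seed pairs per subject, below 2**31."""
    ss = np.random.SeedSequence([int(master_seed), int(salt)])
    pairs = []
    for child in ss.spawn(n_subjects):
        a, b = child.generate_state(2)
        pairs.append((int(a % 2**31), int(b % 2**31)))
    return pairs


# ---------------------------------------------------------------------------
# per-simulation cohort analyses


def run_sim1(
    cohort: CohortConfig = CohortConfig(),
    model_cfg: ModelConfig | None = None,
    response_cfg: ResponseConfig | None = None,
    width: int = 20,
    burn_in: int | None = None,
) -> pd.DataFrame:
    """Flanker frequency manipulation: stimulus-window activity by
    frequency condition and trial type.

    The first ``burn_in`` trials (default: a third of the run) are excluded
    from the condition means: the frequency effects are properties of the
    trained model's predictions and are diluted by acquisition transients.
    """
    if burn_in is None:
        burn_in = cohort.n_trials // 3
    rows = []
    for salt, condition in enumerate(["frequent-congruent", "frequent-incongruent"]):
        for subj, (task_seed, actor_seed) in enumerate(
            _subject_seeds(cohort.master_seed, salt, cohort.n_subjects)
        ):
            sched = gen_flanker_frequency(condition, cohort.n_trials, task_seed)
            log = run_subject(sched, model_cfg, response_cfg, actor_seed)
            anchors = log.schedule.trial_starts.astype(float)  # stimulus at 0
            vals = window_mean(log.omega, anchors, width)
            frame = pd.DataFrame(
                {
                    "subject": subj,
                    "frequency_condition": condition,
                    "trial_type": log.trials["condition"],
                    "value": vals,
                }
            )
            rows.append(frame.iloc[burn_in:])
    per_trial = pd.concat(rows, ignore_index=True)
    return condition_summary(per_trial, ["frequency_condition", "trial_type"])


def run_sim2(
    cohort: CohortConfig = CohortConfig(n_trials=200),
    model_cfg: ModelConfig | None = None,
    response_cfg: ResponseConfig | None = None,
    width: int = 20,
    burn_in: int | None = None,
) -> pd.DataFrame:
    """Item-specific Stroop: stimulus-window activity by experiment,
    item-specific incongruent rate, and trial type.

    As in the flanker analysis, the first ``burn_in`` trials (default: a
    third of the run) are excluded from the condition means.
    """
    if burn_in is None:
        burn_in = cohort.n_trials // 3
    rows = []
    for experiment in (1, 2, 3):
        for subj, (task_seed, actor_seed) in enumerate(
            _subject_seeds(cohort.master_seed, 10 + experiment, cohort.n_subjects)
        ):
            sched = gen_item_stroop(experiment, cohort.n_trials, task_seed)
            log = run_subject(sched, model_cfg, response_cfg, actor_seed)
            anchors = log.schedule.trial_starts.astype(float)
            vals = window_mean(log.omega, anchors, width)
            frame = pd.DataFrame(
                {
                    "subject": subj,
                    "experiment": experiment,
                    "item_rate": log.trials["item_rate"],
                    "trial_type": log.trials["condition"],
                    "value": vals,
                }
            )
            rows.append(frame.iloc[burn_in:])
    per_trial = pd.concat(rows, ignore_index=True)
    return condition_summary(per_trial, ["experiment", "item_rate", "trial_type"])


def run_sim3(
    cohort: CohortConfig = CohortConfig(n_trials=200),
    model_cfg: ModelConfig | None = None,
    pre: int = 40,
    post: int = 20,
) -> dict[str, pd.DataFrame]:
    """Omission paradigm: activity around the expected stimulus onset.

    Returns a per-iteration timecourse (cohort mean activity from ``pre``
    iterations before to ``post`` after the expected onset, separately for
    omission and standard trials) and a summary of activity at the expected
    onset iteration itself — where the stimulus is presented on standard
    trials and withheld on omission trials. ``cohort.n_trials`` is the
    number of training repetitions. The model's delay horizon is trimmed to
    twice the repetition interval (the only lags the task contains).
    """
    tc_rows = []
    sum_rows = []
    rel = np.arange(-pre, post)
    for subj, (task_seed, _) in enumerate(
        _subject_seeds(cohort.master_seed, 30, cohort.n_subjects)
    ):
        sched = gen_mmn(n_repetitions=cohort.n_trials, seed=task_seed)
        if model_cfg is None:
            interval = int(sched.params["interval"])
            cfg = ModelConfig(n_events=len(sched.catalog), n_delays=2 * interval)
        else:
            cfg = model_cfg
        log = run_subject(sched, cfg, ResponseConfig(sr_scale=0.0), task_seed)
        expected = log.onsets("tone", fallback=0)
        ok = expected >= pre  # need a full pre-onset window
        for label in ("omission", "standard"):
            mask = (log.trials["condition"] == label).to_numpy() & ok
            traces = np.stack(
                [log.omega[int(a) - pre : int(a) + post] for a in expected[mask]]
            )
            mean_trace = traces.mean(axis=0)
            tc_rows.append(
                pd.DataFrame(
                    {
                        "subject": subj,
                        "condition": label,
                        "rel_iteration": rel,
                        "value": mean_trace,
                    }
                )
            )
            sum_rows.append(
                {
                    "subject": subj,
                    "condition": label,
                    "value": float(mean_trace[pre]),
                }
            )
    timecourse = (
        pd.concat(tc_rows, ignore_index=True)
        .groupby(["condition", "rel_iteration"], sort=True)["value"]
        .mean()
        .reset_index()
    )
    summary = condition_summary(pd.DataFrame(sum_rows), ["condition"])
    return {"timecourse": timecourse, "summary": summary}


def run_sim4(
    cohort: CohortConfig = CohortConfig(),
    model_cfg: ModelConfig | None = None,
    response_cfg: ResponseConfig | None = None,
    burn_in: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Cued Stroop: cue-window activity by cue informativeness and
    task-window activity (20- and 100-iteration windows) by cue
    informativeness and trial type.

    The first ``burn_in`` trials (default: a third of the run) are excluded
    from the condition means, as in the other stimulus-window analyses.
    """
    if burn_in is None:
        burn_in = cohort.n_trials // 3
    cue_rows = []
    task_rows = {20: [], 100: []}
    for subj, (task_seed, actor_seed) in enumerate(
        _subject_seeds(cohort.master_seed, 40, cohort.n_subjects)
    ):
        sched = gen_cued_stroop(cohort.n_trials, task_seed)
        log = run_subject(sched, model_cfg, response_cfg, actor_seed)
        starts = log.schedule.trial_starts.astype(float)
        informed = np.where(
            log.trials["cue"].eq("uninformative"), "uninformative", "informative"
        )
        cue_vals = window_mean(log.omega, starts, 20)
        cue_rows.append(
            pd.DataFrame(
                {"subject": subj, "cue": informed, "value": cue_vals}
            ).iloc[burn_in:]
        )
        task_anchors = starts + 50
        for width in (20, 100):
            vals = window_mean(log.omega, task_anchors, width)
            task_rows[width].append(
                pd.DataFrame(
                    {
                        "subject": subj,
                        "cue": informed,
                        "trial_type": log.trials["condition"],
                        "value": vals,
                    }
                ).iloc[burn_in:]
            )
    return {
        "cue": condition_summary(
            pd.concat(cue_rows, ignore_index=True), ["cue"]
        ),
        "task20": condition_summary(
            pd.concat(task_rows[20], ignore_index=True), ["cue", "trial_type"]
        ),
        "task100": condition_summary(
            pd.concat(task_rows[100], ignore_index=True), ["cue", "trial_type"]
        ),
    }


def run_sim5(
    cohort: CohortConfig = CohortConfig(),
    model_cfg: ModelConfig | None = None,
    response_cfg: ResponseConfig | None = None,
    width: int = 20,
    estimator_window: int = 10,
) -> pd.DataFrame:
    """Stop-signal task: windowed activity by trial type and the
    median-split local stop-probability estimate.

    Stop-trial activity is anchored at the stop-signal onset, go-trial
    activity at the go-signal onset. Trials without a defined 10-back
    estimate (the first ten) are excluded by the median split.
    """
    rows = []
    for subj, (task_seed, actor_seed) in enumerate(
        _subject_seeds(cohort.master_seed, 50, cohort.n_subjects)
    ):
        sched = gen_stop_signal(cohort.n_trials, task_seed)
        log = run_subject(sched, model_cfg, response_cfg, actor_seed)
        starts = log.schedule.trial_starts.astype(float)
        is_stop = log.trials["stop"].to_numpy(dtype=bool)
        estimates = local_stop_probability(is_stop, estimator_window)
        labels = median_split(estimates)
        anchors = np.where(
            is_stop, log.onsets("stop"), log.onsets("go")
        )
        vals = window_mean(log.omega, anchors, width)
        frame = pd.DataFrame(
            {
                "subject": subj,
                "trial_type": np.where(is_stop, "stop", "go"),
                "stop_probability": labels,
                "value": vals,
            }
        )
        rows.append(frame[frame["stop_probability"].notna()])
    per_trial = pd.concat(rows, ignore_index=True)
    return condition_summary(per_trial, ["trial_type", "stop_probability"])


def stop_prediction_recovery(
    cohort: CohortConfig = CohortConfig(),
    model_cfg: ModelConfig | None = None,
    response_cfg: ResponseConfig | None = None,
    final_trials: int = 100,
) -> float:
    """Learned stop-trial probability read from the prediction vector.

    After training on the stop-signal task, returns the model's prediction
    on the stop-signal channel at the iteration where the stop signal is
    scheduled to occur (whether or not it does), averaged over the final
    ``final_trials`` trials and the cohort. At convergence this recovers
    the generative stop rate.
    """
    means = []
    for subj, (task_seed, actor_seed) in enumerate(
        _subject_seeds(cohort.master_seed, 51, cohort.n_subjects)
    ):
        sched = gen_stop_signal(cohort.n_trials, task_seed)
        log = run_subject(sched, model_cfg, response_cfg, actor_seed)
        stop_idx = sched.catalog.index("stop")
        starts = log.schedule.trial_starts
        stop_onsets = np.array(
            [starts[i] + t.meta["stop_onset"] for i, t in enumerate(sched.trials)]
        )
        sel = stop_onsets[-final_trials:]
        means.append(float(log.pred[sel, stop_idx].mean()))
    return float(np.mean(means))


def run_sim6(
    cohort: CohortConfig = CohortConfig(n_trials=200),
    model_cfg: ModelConfig | None = None,
    width: int = 20,
) -> pd.DataFrame:
    """Expect-reward task: per-channel windowed surprise by trial type.

    For every event channel, mean unsummed surprise in the 20 iterations
    following the first (cue-phase) and second (go-phase) cues, grouped by
    the first-cue and second-cue magnitudes.
    """
    rows = []
    for subj, (task_seed, _) in enumerate(
        _subject_seeds(cohort.master_seed, 60, cohort.n_subjects)
    ):
        sched = gen_expect_reward(cohort.n_trials, task_seed)
        log = run_subject(sched, model_cfg, ResponseConfig(sr_scale=0.0), task_seed)
        starts = log.schedule.trial_starts.astype(float)
        names = sched.catalog.names
        for window, anchors in (("cue1", starts), ("cue2", starts + 100)):
            per_channel = unit_summary(log, anchors, width)
            for j, name in enumerate(names):
                frame = pd.DataFrame(
                    {
                        "subject": subj,
                        "channel": name,
                        "window": window,
                        "first_cue": log.trials["magnitude"],
                        "second_cue": log.trials["go_magnitude"],
                        "value": per_channel[:, j],
                    }
                )
                rows.append(frame)
    per_trial = pd.concat(rows, ignore_index=True)
    return condition_summary(
        per_trial, ["channel", "window", "first_cue", "second_cue"]
    )
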