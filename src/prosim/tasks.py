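"""Task-environment generators.

Each generator produces a fully resolved :class:`TaskSchedule`: an ordered
sequence of trials with deterministic within-trial event timing and
stochastic trial-type sampling from an explicitly seeded generator. The six
environments are

* flanker task with manipulated congruent/incongruent frequency (75/25),
* item-specific proportion-congruency Stroop (three experiments with
  class-conditional incongruent rates 0.1/0.5, 0.5/0.5, 0.5/0.9),
* a repeating-stimulus (mismatch/omission) paradigm with a 30-iteration
  onset-to-onset interval and response machinery lesioned,
* a cued arrow-word Stroop with informative and uninformative pre-cues
  (each cue type ~1/3 of trials; informative cues always valid),
* a stop-signal task with 75% go / 25% stop trials,
* a cued reward-magnitude (expect-reward) task in which the go-phase cue
  repeats the initial cue on 75% of small/large trials and swaps it on 25%
  (medium trials never switch).

Timing template (iterations of 10 ms): fixation/cue at 0; the task stimulus
at 50 when a cue exists, else at 0; a 100-iteration response window;
feedback 20 iterations after the response; a 50-iteration inter-trial
interval. The reward task uses cue at 0, go cue at 100, reward at 150.
Inter-trial and inter-stimulus intervals are never jittered: the
tapped-delay representation needs consistent event timing to converge.

Trial types are sampled i.i.d. per trial; schedules are bit-exact
reproducible from (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EventCatalog",
    "TrialSpec",
    "TaskSchedule",
    "gen_flanker_frequency",
    "gen_item_stroop",
    "gen_mmn",
    "gen_cued_stroop",
    "gen_stop_signal",
    "gen_expect_reward",
    "schedule_to_frame",
]

# timing template (iterations)
RESPONSE_WINDOW = 100
FEEDBACK_LAG = 20
INTER_TRIAL_INTERVAL = 50
CUE_STIMULUS_LAG = 50


@dataclass(frozen=True)
class EventCatalog:
    """Ordered event names of a task plus role annotations.

    ``roles`` maps each role ("cue", "stimulus", "conjunction", "reward")
    to the subset of event names playing it.
    """

    names: tuple[str, ...]
    roles: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("catalog event names must be unique")
        for role, members in self.roles.items():
            unknown = members - set(self.names)
            if unknown:
                raise ValueError(f"role {role!r} names not in catalog: {unknown}")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"event {name!r} not in catalog {self.names}") from None

    @property
    def conjunctions(self) -> frozenset[str]:
        return self.roles.get("conjunction", frozenset())


@dataclass(frozen=True)
class TrialSpec:
    """One fully specified trial.

    ``onsets`` maps event names to within-trial onset iterations (the
    stimulus part of the trial only; response-outcome conjunction events are
    produced at run time by the actor). ``drives`` maps stimulus event names
    to per-response drive weights; ``conjunction_map`` maps each response
    label (and ``None`` for an omission) onto the conjunction event name to
    schedule. ``meta`` carries condition details used by the analyses.
    """

    condition: str
    onsets: Mapping[str, int]
    length: int
    correct_response: str | None = None
    response_window_start: int | None = None
    drives: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    conjunction_map: Mapping[str | None, str] = field(default_factory=dict)
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, onset in self.onsets.items():
            if not 0 <= onset < self.length:
                raise ValueError(
                    f"onset of {name!r} ({onset}) outside trial of length {self.length}"
                )


@dataclass(frozen=True)
class TaskSchedule:
    """A resolved event-stream specification for one simulated subject."""

    catalog: EventCatalog
    trials: tuple[TrialSpec, ...]
    responses: tuple[str, ...]
    seed: int
    params: Mapping[str, object] = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def trial_starts(self) -> np.ndarray:
        lengths = np.fromiter((t.length for t in self.trials), dtype=int)
        starts = np.zeros(len(lengths), dtype=int)
        np.cumsum(lengths[:-1], out=starts[1:])
        return starts

    @property
    def n_iterations(self) -> int:
        return int(sum(t.length for t in self.trials))

    @property
    def lesioned(self) -> bool:
        """True when the schedule drives no responses at all."""
        return len(self.responses) == 0


def schedule_to_frame(schedule: TaskSchedule) -> pd.DataFrame:
    """Long-format view of a schedule (trial, condition, event, onset)."""
    rows = [
        (i, trial.condition, name, onset)
        for i, trial in enumerate(schedule.trials)
        for name, onset in sorted(trial.onsets.items(), key=lambda kv: kv[1])
    ]
    return pd.DataFrame(
        rows, columns=["trial", "condition", "event_name", "onset_iteration"]
    )


def _sides_conjunction_map(correct: str, sides: Sequence[str]) -> dict[str | None, str]:
    cmap: dict[str | None, str] = {
        s: f"{s}_{'correct' if s == correct else 'error'}" for s in sides
    }
    cmap[None] = f"{correct}_error"  # omitted response scored as error
    return cmap


# ---------------------------------------------------------------------------
# Simulation 1: flanker task, frequent vs. infrequent trial types


def gen_flanker_frequency(
    condition: str,
    n_trials: int = 300,
    seed: int = 0,
    frequent_rate: float = 0.75,
    target_drive: float = 0.08,
    flanker_drive: float = 0.04,
) -> TaskSchedule:
    """Flanker task with a 75/25 congruent/incongruent frequency split.

    ``condition`` selects which trial type is frequent
    (``"frequent-congruent"`` or ``"frequent-incongruent"``). Target and
    flanker events fire simultaneously at trial onset; the four
    response-outcome conjunctions (left/right x correct/error) are produced
    by the actor. Eight events total.
    """
    if condition not in ("frequent-congruent", "frequent-incongruent"):
        raise ValueError(f"unknown condition {condition!r}")
    if n_trials < 1:
        raise ValueError("n_trials must be positive")
    catalog = EventCatalog(
        names=(
            "target_left",
            "target_right",
            "flanker_left",
            "flanker_right",
            "left_correct",
            "left_error",
            "right_correct",
            "right_error",
        ),
        roles={
            "stimulus": frozenset(
                {"target_left", "target_right", "flanker_left", "flanker_right"}
            ),
            "conjunction": frozenset(
                {"left_correct", "left_error", "right_correct", "right_error"}
            ),
        },
    )
    rng = np.random.default_rng(seed)
    sides = ("left", "right")
    length = RESPONSE_WINDOW + FEEDBACK_LAG + INTER_TRIAL_INTERVAL
    trials = []
    for _ in range(n_trials):
        frequent = rng.random() < frequent_rate
        congruent = frequent if condition == "frequent-congruent" else not frequent
        side = sides[rng.integers(2)]
        flank = side if congruent else sides[1 - sides.index(side)]
        trials.append(
            TrialSpec(
                condition="congruent" if congruent else "incongruent",
                onsets={f"target_{side}": 0, f"flanker_{flank}": 0},
                length=length,
                correct_response=side,
                response_window_start=0,
                drives={
                    f"target_{side}": {side: target_drive},
                    f"flanker_{flank}": {flank: flanker_drive},
                },
                conjunction_map=_sides_conjunction_map(side, sides),
                meta={"frequent": frequent, "congruent": congruent, "side": side},
            )
        )
    return TaskSchedule(
        catalog=catalog,
        trials=tuple(trials),
        responses=sides,
        seed=seed,
        params={"condition": condition, "n_trials": n_trials,
                "frequent_rate": frequent_rate},
    )


# ---------------------------------------------------------------------------
# Simulation 2: item-specific proportion-congruency Stroop

_STROOP_RATES = {1: (0.1, 0.5), 2: (0.5, 0.5), 3: (0.5, 0.9)}
_STROOP_CLASSES = (("red", "green"), ("blue", "yellow"))


def gen_item_stroop(
    experiment: int,
    n_trials: int = 200,
    seed: int = 0,
    font_drive: float = 0.08,
    word_drive: float = 0.04,
) -> TaskSchedule:
    """Color-word Stroop with class-conditional incongruent rates.

    Two equiprobable stimulus classes of two colors each; within a class a
    trial is incongruent with the experiment's item-specific probability
    (experiment 1: 0.1/0.5, 2: 0.5/0.5, 3: 0.5/0.9; the implied global
    incongruent rate is the mean of the two). Word and font-color events
    fire simultaneously at trial onset. Responses name the font color by
    its within-class position, so the four conjunctions are shared across
    classes (color1/color2 x correct/error).
    """
    if experiment not in _STROOP_RATES:
        raise ValueError(f"experiment must be 1, 2 or 3, got {experiment}")
    if n_trials < 1:
        raise ValueError("n_trials must be positive")
    words = tuple(f"word_{c}" for pair in _STROOP_CLASSES for c in pair)
    fonts = tuple(f"font_{c}" for pair in _STROOP_CLASSES for c in pair)
    responses = ("color1", "color2")
    conj = ("color1_correct", "color1_error", "color2_correct", "color2_error")
    catalog = EventCatalog(
        names=words + fonts + conj,
        roles={
            "stimulus": frozenset(words + fonts),
            "conjunction": frozenset(conj),
        },
    )
    rates = _STROOP_RATES[experiment]
    rng = np.random.default_rng(seed)
    length = RESPONSE_WINDOW + FEEDBACK_LAG + INTER_TRIAL_INTERVAL
    trials = []
    for _ in range(n_trials):
        cls = int(rng.integers(2))
        incongruent = rng.random() < rates[cls]
        word_pos = int(rng.integers(2))
        colors = _STROOP_CLASSES[cls]
        word = colors[word_pos]
        font_pos = 1 - word_pos if incongruent else word_pos
        font = colors[font_pos]
        correct = responses[font_pos]
        cmap: dict[str | None, str] = {
            r: f"{r}_{'correct' if r == correct else 'error'}" for r in responses
        }
        cmap[None] = f"{correct}_error"
        trials.append(
            TrialSpec(
                condition="incongruent" if incongruent else "congruent",
                onsets={f"word_{word}": 0, f"font_{font}": 0},
                length=length,
                correct_response=correct,
                response_window_start=0,
                drives={
                    f"font_{font}": {correct: font_drive},
                    f"word_{word}": {responses[word_pos]: word_drive},
                },
                conjunction_map=cmap,
                meta={
                    "stimulus_class": "AB"[cls],
                    "item_rate": rates[cls],
                    "congruent": not incongruent,
                },
            )
        )
    return TaskSchedule(
        catalog=catalog,
        trials=tuple(trials),
        responses=responses,
        seed=seed,
        params={"experiment": experiment, "n_trials": n_trials,
                "item_rates": rates},
    )


# ---------------------------------------------------------------------------
# Simulation 3: repeating stimulus with omissions (mismatch paradigm)


def gen_mmn(
    n_repetitions: int = 200,
    omission_after: Sequence[int] = (1, 2, 3, 4, 5, 6, 7),
    n_test_cycles: int = 5,
    seed: int = 0,
    interval: int = 30,
) -> TaskSchedule:
    """Repeating punctate stimulus with occasional omissions.

    A single stimulus event repeats every ``interval`` iterations (default
    30 = 300 ms). Training presents ``n_repetitions`` stimuli; the test
    phase then cycles ``n_test_cycles`` times through the ``omission_after``
    values, presenting that many stimuli and then withholding one. Response
    machinery is lesioned (no responses, no conjunction events).
    """
    if n_repetitions < 1:
        raise ValueError("n_repetitions must be >= 1")
    omission_after = tuple(int(v) for v in omission_after)
    if not omission_after or any(not 1 <= v <= 7 for v in omission_after):
        raise ValueError(
            f"omission_after values must lie in 1..7, got {omission_after}"
        )
    if n_test_cycles < 1:
        raise ValueError("n_test_cycles must be >= 1")
    catalog = EventCatalog(
        names=("tone",), roles={"stimulus": frozenset({"tone"})}
    )
    standard = TrialSpec(
        condition="standard", onsets={"tone": 0}, length=interval,
        meta={"phase": "train"},
    )
    trials: list[TrialSpec] = [standard] * n_repetitions
    rng = np.random.default_rng(seed)
    for _ in range(n_test_cycles):
        order = rng.permutation(len(omission_after))
        for idx in order:
            reps = omission_after[idx]
            trials.extend(
                [
                    TrialSpec(
                        condition="standard", onsets={"tone": 0}, length=interval,
                        meta={"phase": "test"},
                    )
                ]
                * reps
            )
            trials.append(
                TrialSpec(
                    condition="omission", onsets={}, length=interval,
                    meta={"phase": "test", "after_repetitions": reps},
                )
            )
    return TaskSchedule(
        catalog=catalog,
        trials=tuple(trials),
        responses=(),
        seed=seed,
        params={
            "n_repetitions": n_repetitions,
            "omission_after": omission_after,
            "n_test_cycles": n_test_cycles,
            "interval": interval,
        },
    )


# ---------------------------------------------------------------------------
# Simulation 4: cued (arrow-word) Stroop with informative/uninformative cues


def gen_cued_stroop(
    n_trials: int = 300,
    seed: int = 0,
    target_drive: float = 0.08,
    flanker_drive: float = 0.04,
) -> TaskSchedule:
    """Cued Stroop: a pre-cue announces the upcoming trial type.

    Cue types (informed-congruent, informed-incongruent, uninformative) are
    equiprobable; informative cues are always valid, uninformative cues
    precede congruent and incongruent tasks with probability 1/2 each. The
    cue fires at iteration 0, the task stimulus (central target plus a
    congruent or incongruent flanker) 50 iterations later. Ten events.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be positive")
    sides = ("left", "right")
    conj = ("left_correct", "left_error", "right_correct", "right_error")
    catalog = EventCatalog(
        names=(
            "cue_congruent",
            "cue_incongruent",
            "cue_neutral",
            "target",
            "flanker_congruent",
            "flanker_incongruent",
        )
        + conj,
        roles={
            "cue": frozenset({"cue_congruent", "cue_incongruent", "cue_neutral"}),
            "stimulus": frozenset(
                {"target", "flanker_congruent", "flanker_incongruent"}
            ),
            "conjunction": frozenset(conj),
        },
    )
    rng = np.random.default_rng(seed)
    stim = CUE_STIMULUS_LAG
    length = stim + RESPONSE_WINDOW + FEEDBACK_LAG + INTER_TRIAL_INTERVAL
    cue_types = ("informed-congruent", "informed-incongruent", "uninformative")
    cue_events = {"informed-congruent": "cue_congruent",
                  "informed-incongruent": "cue_incongruent",
                  "uninformative": "cue_neutral"}
    trials = []
    for _ in range(n_trials):
        cue = cue_types[rng.integers(3)]
        if cue == "uninformative":
            congruent = rng.random() < 0.5
        else:
            congruent = cue == "informed-congruent"
        side = sides[rng.integers(2)]
        other = sides[1 - sides.index(side)]
        flanker = "flanker_congruent" if congruent else "flanker_incongruent"
        trials.append(
            TrialSpec(
                condition="congruent" if congruent else "incongruent",
                onsets={cue_events[cue]: 0, "target": stim, flanker: stim},
                length=length,
                correct_response=side,
                response_window_start=stim,
                drives={
                    "target": {side: target_drive},
                    flanker: {side if congruent else other: flanker_drive},
                },
                conjunction_map=_sides_conjunction_map(side, sides),
                meta={"cue": cue, "congruent": congruent, "side": side},
            )
        )
    return TaskSchedule(
        catalog=catalog,
        trials=tuple(trials),
        responses=sides,
        seed=seed,
        params={"n_trials": n_trials},
    )


# ---------------------------------------------------------------------------
# Simulation 5: stop-signal task


def gen_stop_signal(
    n_trials: int = 300,
    seed: int = 0,
    stop_rate: float = 0.25,
    stop_signal_delay: int = 15,
    go_drive: float = 0.06,
    stop_drive: float = -0.6,
) -> TaskSchedule:
    """Stop-signal task with 75% go and 25% stop trials.

    Every trial begins with a fixation event at iteration 0 and a go signal
    50 iterations later; on stop trials a stop signal follows the go signal
    at a fixed stop-signal delay (default 15 iterations = 150 ms) and
    inhibits the go accumulator. Seven events: fixation, go, stop and the
    four conjunctions (go/correct, go/error, stop/correct, stop/error).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be positive")
    if stop_signal_delay < 1:
        raise ValueError("stop_signal_delay must be >= 1")
    conj = ("go_correct", "go_error", "stop_correct", "stop_error")
    catalog = EventCatalog(
        names=("fixation", "go", "stop") + conj,
        roles={
            "cue": frozenset({"fixation"}),
            "stimulus": frozenset({"go", "stop"}),
            "conjunction": frozenset(conj),
        },
    )
    rng = np.random.default_rng(seed)
    go_onset = CUE_STIMULUS_LAG
    length = go_onset + RESPONSE_WINDOW + FEEDBACK_LAG + INTER_TRIAL_INTERVAL
    trials = []
    for _ in range(n_trials):
        stop = rng.random() < stop_rate
        onsets = {"fixation": 0, "go": go_onset}
        drives = {"go": {"go": go_drive}}
        if stop:
            onsets["stop"] = go_onset + stop_signal_delay
            drives["stop"] = {"go": stop_drive}
            cmap: dict[str | None, str] = {"go": "stop_error", None: "stop_correct"}
            correct = None
        else:
            cmap = {"go": "go_correct", None: "go_error"}
            correct = "go"
        trials.append(
            TrialSpec(
                condition="stop" if stop else "go",
                onsets=onsets,
                length=length,
                correct_response=correct,
                response_window_start=go_onset,
                drives=drives,
                conjunction_map=cmap,
                meta={"stop": stop,
                      "stop_onset": go_onset + stop_signal_delay},
            )
        )
    return TaskSchedule(
        catalog=catalog,
        trials=tuple(trials),
        responses=("go",),
        seed=seed,
        params={
            "n_trials": n_trials,
            "stop_rate": stop_rate,
            "stop_signal_delay": stop_signal_delay,
        },
    )


# ---------------------------------------------------------------------------
# Simulation 6: cued reward magnitude (expect-reward) task

_MAGNITUDES = ("small", "medium", "large")
_SWAP = {"small": "large", "large": "small", "medium": "medium"}


def gen_expect_reward(
    n_trials: int = 200,
    seed: int = 0,
    switch_rate: float = 0.25,
) -> TaskSchedule:
    """Cued reward-magnitude task with occasional cue switches.

    Each trial presents a start event plus an initial magnitude cue (small,
    medium or large; equiprobable) at iteration 0, a go-phase cue at 100,
    and a binary reward-identity event at 150 matching the go-phase cue. On
    small- and large-cue trials the go-phase cue swaps to the opposite
    magnitude with probability 0.25; medium trials never switch. Reward
    events mark reward identity only, not value. Ten events; no responses.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be positive")
    if not 0 <= switch_rate <= 1:
        raise ValueError(f"switch_rate must be in [0, 1], got {switch_rate}")
    cues = tuple(f"cue_{m}" for m in _MAGNITUDES)
    gos = tuple(f"go_{m}" for m in _MAGNITUDES)
    rewards = tuple(f"reward_{m}" for m in _MAGNITUDES)
    catalog = EventCatalog(
        names=("start",) + cues + gos + rewards,
        roles={
            "cue": frozenset(("start",) + cues + gos),
            "reward": frozenset(rewards),
        },
    )
    rng = np.random.default_rng(seed)
    length = 150 + INTER_TRIAL_INTERVAL
    trials = []
    for _ in range(n_trials):
        magnitude = _MAGNITUDES[rng.integers(3)]
        switch = magnitude != "medium" and rng.random() < switch_rate
        go_magnitude = _SWAP[magnitude] if switch else magnitude
        trials.append(
            TrialSpec(
                condition="switch" if switch else "consistent",
                onsets={
                    "start": 0,
                    f"cue_{magnitude}": 0,
                    f"go_{go_magnitude}": 100,
                    f"reward_{go_magnitude}": 150,
                },
                length=length,
                meta={"magnitude": magnitude, "go_magnitude": go_magnitude,
                      "switch": switch},
            )
        )
    return TaskSchedule(
        catalog=catalog,
        trials=tuple(trials),
        responses=(),
        seed=seed,
        params={"n_trials": n_trials, "switch_rate": switch_rate},
    )
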