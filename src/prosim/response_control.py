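"""Minimal actor converting task stimuli into responses and feedback events.

The event-prediction core only consumes event streams; for tasks with a
behavioral component it needs something to *produce* the response-outcome
conjunction events (left/correct, left/error, ...). This module provides a
deliberately minimal actor: leaky-free, noisy threshold-crossing
accumulators with fixed (unlearned) stimulus-response drive. Each iteration
of the response window, every response accumulator integrates its summed
stimulus drive plus independent zero-mean Gaussian noise and is clipped at
zero; the first accumulator to cross threshold emits its response, and a
response-outcome conjunction event is scheduled a fixed feedback lag later.

Distractor stimuli (e.g. incongruent flankers) drive the wrong accumulator,
which yields slower and more error-prone responses on incongruent trials —
the only behavioral realism the surprise readout needs.

Setting the drive scale to zero lesions the actor: no accumulation occurs,
no responses are emitted, and no conjunction events are scheduled (used for
stimulus-only tasks such as the omission/mismatch paradigm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ResponseConfig",
    "TrialOutcome",
    "accumulate",
    "emit_response",
    "score_outcome",
    "simulate_trial_response",
]


@dataclass(frozen=True)
class ResponseConfig:
    """Fixed parameters of the accumulator actor.

    ``sr_scale`` multiplies the task's stimulus-response drive matrix; 0
    lesions response generation entirely. ``noise_sd`` is the standard
    deviation of the per-iteration accumulator noise; ``threshold`` the
    response bound; ``response_deadline`` the response window length in
    iterations; ``feedback_lag`` the fixed delay (iterations) between the
    response and its outcome event.
    """

    noise_sd: float = 0.1
    threshold: float = 1.0
    response_deadline: int = 100
    feedback_lag: int = 20
    sr_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.threshold <= 0:
            raise ValueError(f"threshold must be > 0, got {self.threshold}")
        if self.response_deadline < 1:
            raise ValueError(
                f"response_deadline must be >= 1, got {self.response_deadline}"
            )
        if self.feedback_lag < 0:
            raise ValueError(f"feedback_lag must be >= 0, got {self.feedback_lag}")
        if self.sr_scale < 0:
            raise ValueError(f"sr_scale must be >= 0, got {self.sr_scale}")


@dataclass(frozen=True)
class TrialOutcome:
    """Scored result of one trial's response episode."""

    response: str | None
    response_iteration: int | None
    outcome: str  # "correct" | "error"
    conjunction_event: str | None
    feedback_iteration: int | None


def accumulate(
    accumulators: np.ndarray,
    drive: np.ndarray,
    cfg: ResponseConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One iteration of evidence accumulation.

    ``drive`` holds the summed stimulus drive per response accumulator.
    Noise only enters accumulators that receive some stimulus drive this
    trial, so a lesioned actor (all-zero drive) provably never responds.
    Accumulators are clipped at zero.
    """
    accumulators = np.asarray(accumulators, dtype=float)
    drive = np.asarray(drive, dtype=float)
    if drive.shape != accumulators.shape:
        raise ValueError(
            f"drive shape {drive.shape} != accumulators {accumulators.shape}"
        )
    active = drive != 0.0
    noise = np.where(active, rng.normal(0.0, cfg.noise_sd, accumulators.shape), 0.0)
    out = accumulators + cfg.sr_scale * drive + noise
    np.maximum(out, 0.0, out=out)
    return out


def emit_response(
    accumulators: np.ndarray,
    responses: tuple[str, ...],
    cfg: ResponseConfig,
    rng: np.random.Generator,
) -> str | None:
    """Return the response whose accumulator crossed threshold, or None.

    Simultaneous crossings are broken by a seeded uniform choice.
    """
    accumulators = np.asarray(accumulators, dtype=float)
    above = np.flatnonzero(accumulators >= cfg.threshold)
    if above.size == 0:
        return None
    if above.size == 1:
        return responses[above[0]]
    return responses[rng.choice(above)]


def score_outcome(
    response: str | None,
    response_iteration: int | None,
    correct_response: str | None,
    conjunction_map: dict[str | None, str],
    cfg: ResponseConfig,
    deadline_iteration: int,
) -> TrialOutcome:
    """Map a (response, correct response) pair onto a conjunction event.

    ``conjunction_map`` maps each response label — and ``None`` for an
    omitted response — onto the catalog name of the conjunction event to
    schedule. Omitted responses are scored as errors on the correct-response
    channel (the catalogs contain no dedicated "no response" event). The
    conjunction is scheduled ``feedback_lag`` iterations after the response
    (after the deadline, for omissions).
    """
    if response is not None and response not in conjunction_map:
        raise KeyError(f"response {response!r} not in conjunction map")
    outcome = "correct" if response == correct_response else "error"
    conj = conjunction_map.get(response)
    anchor = response_iteration if response_iteration is not None else deadline_iteration
    feedback_iteration = None if conj is None else anchor + cfg.feedback_lag
    return TrialOutcome(
        response=response,
        response_iteration=response_iteration,
        outcome=outcome,
        conjunction_event=conj,
        feedback_iteration=feedback_iteration,
    )


def simulate_trial_response(
    drive: np.ndarray,
    responses: tuple[str, ...],
    window_start: int,
    cfg: ResponseConfig,
    rng: np.random.Generator,
) -> tuple[str | None, int | None]:
    """Run the accumulators over one trial's response window.

    ``drive`` is either a length-``R`` vector (constant drive while the
    stimulus is on) or a ``(response_deadline, R)`` matrix for drive that
    changes within the window (e.g. stop-signal inhibition arriving at the
    stop-signal delay). Returns the winning response and its absolute
    within-trial iteration, or ``(None, None)`` if the deadline passes.
    A trial with all-zero effective drive emits no response.
    """
    drive = np.asarray(drive, dtype=float)
    if cfg.sr_scale == 0.0 or not np.any(drive):
        return None, None
    if drive.ndim == 1:
        drive = np.broadcast_to(drive, (cfg.response_deadline, drive.shape[0]))
    elif drive.shape[0] != cfg.response_deadline:
        raise ValueError(
            f"per-iteration drive must have {cfg.response_deadline} rows, "
            f"got {drive.shape[0]}"
        )
    acc = np.zeros(len(responses))
    for t in range(cfg.response_deadline):
        acc = accumulate(acc, drive[t], cfg, rng)
        response = emit_response(acc, responses, cfg, rng)
        if response is not None:
            return response, window_start + t
    return None, None
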