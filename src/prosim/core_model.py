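"""Core event-prediction learner.

A discrete-time temporal-difference (TD) learner over binary event vectors.
Time within the model is represented by a tapped-delay line: unit ``(j, k)``
is active exactly ``j - 1`` iterations after event ``k`` occurred, so each
event sweeps through the delay bank and provides a temporally precise basis
for predicting later events. Predictions are linear in the delay units
through a nonnegative weight tensor ``W[i, j, k]`` (delayed event ``k``
predicting event ``i``); learning is driven by a vector-valued TD error with
exponentially decaying eligibility traces. Model "activity" — the proxy for
medial prefrontal cortex signal — is the rectified *negative surprise*
``sum_i max(0, P_i - E_i)``, the aggregate predicted-but-unobserved event
mass at each iteration.

Each iteration is interpreted as 10 ms of real time. Learning is fully
continuous: neither the delay line, the eligibility trace, nor the weights
are reset at trial boundaries, so feedback events from one trial serve as
predictors of the next trial's stimuli.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ModelConfig",
    "StepRecord",
    "PROModel",
    "advance_delay_line",
    "compute_prediction",
    "compute_td_error",
    "update_eligibility",
    "update_weights",
    "negative_surprise",
    "unit_surprise",
]


@dataclass(frozen=True)
class ModelConfig:
    """Parameters of the event-prediction learner.

    Parameters
    ----------
    n_events
        Number of event channels ``K``. Every channel can both occur and be
        predicted.
    n_delays
        Number of tapped-delay units ``J`` per event. The delay horizon
        ``J`` iterations (default 150 = 1500 ms) bounds how far back a
        predictor event may lie; it should cover the longest inter-event
        lag of interest, including the gap from one trial's feedback to the
        next trial's onset.
    learning_rate
        TD learning rate ``alpha`` (default 0.1).
    discount
        Temporal discount ``gamma`` per 10 ms iteration (default 0.95).
    trace_decay
        Eligibility-trace decay per iteration (default 0.95).
    iteration_ms
        Duration of one model iteration in milliseconds (default 10).
    """

    n_events: int
    n_delays: int = 150
    learning_rate: float = 0.1
    discount: float = 0.95
    trace_decay: float = 0.95
    iteration_ms: float = 10.0

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ValueError(f"n_events must be positive, got {self.n_events}")
        if self.n_delays < 1:
            raise ValueError(f"n_delays must be positive, got {self.n_delays}")
        if self.learning_rate < 0:
            raise ValueError(f"learning_rate must be >= 0, got {self.learning_rate}")
        if not 0.0 <= self.discount <= 1.0:
            raise ValueError(f"discount must be in [0, 1], got {self.discount}")
        if not 0.0 <= self.trace_decay <= 1.0:
            raise ValueError(f"trace_decay must be in [0, 1], got {self.trace_decay}")
        if self.iteration_ms <= 0:
            raise ValueError(f"iteration_ms must be > 0, got {self.iteration_ms}")


@dataclass(frozen=True)
class StepRecord:
    """Per-iteration log entry.

    ``prediction`` and ``td_error`` are length-``K`` vectors; ``neg_surprise``
    is the scalar rectified readout and always equals ``unit_surprise.sum()``.
    """

    iteration: int
    prediction: np.ndarray
    td_error: np.ndarray
    neg_surprise: float
    unit_surprise: np.ndarray


def _check_shape(name: str, arr: np.ndarray, shape: tuple[int, ...]) -> None:
    if arr.shape != shape:
        raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")


def advance_delay_line(state: np.ndarray, events: np.ndarray) -> np.ndarray:
    """Shift the tapped-delay line one iteration and load new events.

    Row 1 (index 0) of the returned ``(J, K)`` state equals ``events``;
    row ``j`` equals the previous row ``j - 1``; history older than ``J``
    iterations is dropped.
    """
    state = np.asarray(state)
    events = np.asarray(events)
    if state.ndim != 2:
        raise ValueError(f"delay-line state must be 2-D, got ndim={state.ndim}")
    _check_shape("events", events, (state.shape[1],))
    out = np.empty_like(state)
    out[0] = events
    out[1:] = state[:-1]
    return out


def compute_prediction(weights: np.ndarray, state: np.ndarray) -> np.ndarray:
    """Linear prediction ``P_i = sum_{j,k} E_jk * W_ijk``.

    Nonnegative whenever weights are nonnegative and the state is binary.
    """
    weights = np.asarray(weights)
    state = np.asarray(state)
    _check_shape("state", state, weights.shape[1:])
    return weights.reshape(weights.shape[0], -1) @ state.ravel()


def compute_td_error(
    events: np.ndarray,
    pred_now: np.ndarray,
    pred_next: np.ndarray,
    discount: float,
) -> np.ndarray:
    """Vector TD error ``delta_i = E_i + gamma * P_i,t+1 - P_i,t``."""
    events = np.asarray(events, dtype=float)
    _check_shape("pred_now", np.asarray(pred_now), events.shape)
    _check_shape("pred_next", np.asarray(pred_next), events.shape)
    return events + discount * np.asarray(pred_next) - np.asarray(pred_now)


def update_eligibility(
    trace: np.ndarray, state: np.ndarray, trace_decay: float = 0.95
) -> np.ndarray:
    """Eligibility update ``trace <- state + decay * trace`` (elementwise)."""
    trace = np.asarray(trace)
    state = np.asarray(state)
    _check_shape("state", state, trace.shape)
    return state + trace_decay * trace


def update_weights(
    weights: np.ndarray,
    td_error: np.ndarray,
    trace: np.ndarray,
    learning_rate: float,
) -> np.ndarray:
    """Trace-gated update ``W_ijk <- max(0, W_ijk + alpha*delta_i*trace_jk)``.

    Weights are clipped at zero after every update; the model never carries
    inhibitory (negative) prediction weights.
    """
    weights = np.asarray(weights)
    td_error = np.asarray(td_error)
    trace = np.asarray(trace)
    _check_shape("td_error", td_error, (weights.shape[0],))
    _check_shape("trace", trace, weights.shape[1:])
    if learning_rate < 0:
        raise ValueError(f"learning_rate must be >= 0, got {learning_rate}")
    new = weights + learning_rate * td_error[:, None, None] * trace[None, :, :]
    np.maximum(new, 0.0, out=new)
    return new


def negative_surprise(pred: np.ndarray, events: np.ndarray) -> float:
    """Scalar readout ``sum_i max(0, P_i - E_i)``: predicted events that
    failed to occur this iteration."""
    pred = np.asarray(pred, dtype=float)
    events = np.asarray(events, dtype=float)
    _check_shape("events", events, pred.shape)
    return float(np.maximum(pred - events, 0.0).sum())


def unit_surprise(pred: np.ndarray, events: np.ndarray) -> np.ndarray:
    """Per-channel negative surprise ``max(0, P_i - E_i)``; sums to the
    scalar readout."""
    pred = np.asarray(pred, dtype=float)
    events = np.asarray(events, dtype=float)
    _check_shape("events", events, pred.shape)
    return np.maximum(pred - events, 0.0)


class PROModel:
    """Stateful learner orchestrating one TD update per iteration.

    The per-iteration order is: compute the prediction ``P_t`` from the
    current delay state (which does not yet contain this iteration's
    events); refresh the eligibility trace with that same state — the
    state whose prediction the TD error corrects, as in standard TD(lambda)
    credit assignment; observe the events; advance the delay line;
    bootstrap ``P_{t+1}`` from the advanced state using the current
    (pre-update) weights; form the TD error; apply the trace-gated weight
    update. Refreshing the trace with the *post*-advance state instead
    would let each event's own delay unit collect the concurrent TD error,
    and the bootstrap term then turns that one-iteration-late association
    into a positive feedback loop that diverges on periodic streams; the
    pre-advance convention is the one under which the learner converges.
    Negative surprise compares ``P_t`` against the observed events, so it
    measures what the model expected *before* seeing them.

    All adjustable weights start at zero, so an untrained model is never
    surprised.
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        k, j = config.n_events, config.n_delays
        self.weights = np.zeros((k, j, k))
        self.state = np.zeros((j, k))
        self.trace = np.zeros((j, k))
        self.iteration = 0

    def step(self, events: np.ndarray) -> StepRecord:
        """Process one iteration of observed events and learn from it."""
        events = np.asarray(events, dtype=float)
        cfg = self.config
        _check_shape("events", events, (cfg.n_events,))

        pred_now = compute_prediction(self.weights, self.state)
        self.trace = update_eligibility(self.trace, self.state, cfg.trace_decay)
        new_state = advance_delay_line(self.state, events)
        pred_next = compute_prediction(self.weights, new_state)
        delta = compute_td_error(events, pred_now, pred_next, cfg.discount)
        self.weights = update_weights(
            self.weights, delta, self.trace, cfg.learning_rate
        )
        self.state = new_state

        surprise = unit_surprise(pred_now, events)
        record = StepRecord(
            iteration=self.iteration,
            prediction=pred_now,
            td_error=delta,
            neg_surprise=float(surprise.sum()),
            unit_surprise=surprise,
        )
        self.iteration += 1
        return record

    def run(
        self, event_matrix: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Run over a ``(T, K)`` event matrix without building StepRecords.

        Vectorized fast path used by the cohort runner; algebraically
        identical to calling :meth:`step` ``T`` times. Returns
        ``(pred, delta, omega)`` with shapes ``(T, K)``, ``(T, K)``, ``(T,)``
        where ``pred[t]`` is the pre-observation prediction at ``t``.
        """
        event_matrix = np.asarray(event_matrix, dtype=float)
        cfg = self.config
        if event_matrix.ndim != 2 or event_matrix.shape[1] != cfg.n_events:
            raise ValueError(
                f"event matrix must be (T, {cfg.n_events}), got {event_matrix.shape}"
            )
        n_iter, k = event_matrix.shape
        j = cfg.n_delays
        alpha, gamma, lam = cfg.learning_rate, cfg.discount, cfg.trace_decay

        weights = np.ascontiguousarray(self.weights)
        w2d = weights.reshape(k, j * k)
        state = np.ascontiguousarray(self.state)
        state_flat = state.ravel()
        trace = np.ascontiguousarray(self.trace)
        trace_flat = trace.ravel()
        buf = np.empty((k, j * k))

        pred_log = np.empty((n_iter, k))
        delta_log = np.empty((n_iter, k))
        omega_log = np.empty(n_iter)

        for t in range(n_iter):
            events = event_matrix[t]
            pred_now = w2d @ state_flat
            trace_flat *= lam
            trace_flat += state_flat
            # advance delay line in place (numpy evaluates the RHS first)
            state[1:] = state[:-1]
            state[0] = events
            pred_next = w2d @ state_flat
            delta = events + gamma * pred_next - pred_now
            np.multiply.outer(alpha * delta, trace_flat, out=buf)
            w2d += buf
            np.maximum(w2d, 0.0, out=w2d)
            pred_log[t] = pred_now
            delta_log[t] = delta
            omega_log[t] = np.maximum(pred_now - events, 0.0).sum()

        self.state = state
        self.trace = trace
        self.weights = weights
        self.iteration += n_iter
        return pred_log, delta_log, omega_log
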