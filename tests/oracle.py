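"""Independent straight-line reference implementation of the learner.

Written deliberately without numpy vectorization (plain Python floats and
nested loops, one equation at a time) so it can serve as an oracle for the
vectorized core. Any change to the core must keep agreement with this
reference to machine precision.
"""

from __future__ import annotations


def oracle_run(
    event_stream,
    n_delays: int,
    learning_rate: float = 0.1,
    discount: float = 0.95,
    trace_decay: float = 0.95,
):
    """Run the TD learner over ``event_stream`` (sequence of 0/1 rows).

    Returns ``(preds, deltas, omegas, weights)`` as nested Python lists.
    Per iteration: prediction from the current delay state; trace refreshed
    with that same (pre-advance) state; delay line advanced with the new
    events; bootstrap prediction from the advanced state; TD error; weight
    update clipped at zero.
    """
    n_events = len(event_stream[0])
    J, K = n_delays, n_events
    weights = [[[0.0] * K for _ in range(J)] for _ in range(K)]
    state = [[0.0] * K for _ in range(J)]
    trace = [[0.0] * K for _ in range(J)]
    preds, deltas, omegas = [], [], []

    for events in event_stream:
        pred_now = [0.0] * K
        for i in range(K):
            for j in range(J):
                for k in range(K):
                    pred_now[i] += state[j][k] * weights[i][j][k]

        for j in range(J):
            for k in range(K):
                trace[j][k] = state[j][k] + trace_decay * trace[j][k]

        state = [[float(e) for e in events]] + state[:-1]

        pred_next = [0.0] * K
        for i in range(K):
            for j in range(J):
                for k in range(K):
                    pred_next[i] += state[j][k] * weights[i][j][k]

        delta = [
            float(events[i]) + discount * pred_next[i] - pred_now[i]
            for i in range(K)
        ]

        for i in range(K):
            for j in range(J):
                for k in range(K):
                    w = weights[i][j][k] + learning_rate * delta[i] * trace[j][k]
                    weights[i][j][k] = w if w > 0.0 else 0.0

        omega = 0.0
        for i in range(K):
            diff = pred_now[i] - float(events[i])
            if diff > 0.0:
                omega += diff

        preds.append(pred_now)
        deltas.append(delta)
        omegas.append(omega)

    return preds, deltas, omegas, weights
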