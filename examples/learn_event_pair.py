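"""Core API demo: learn that event A predicts event B five iterations later.

Builds a periodic two-event stream, trains the TD learner, and shows that
the prediction error at B's onset vanishes while omitting B produces a
negative-surprise transient equal to the learned prediction.
"""

import numpy as np

from prosim import ModelConfig, PROModel

CYCLE, LAG, REPS = 20, 5, 200

stream = np.zeros((REPS * CYCLE, 2))
stream[::CYCLE, 0] = 1          # event A starts each cycle
stream[LAG::CYCLE, 1] = 1       # event B follows 5 iterations (50 ms) later

model = PROModel(ModelConfig(n_events=2, n_delays=25))
_, delta, _ = model.run(stream)

b_onsets = np.flatnonzero(stream[:, 1])
print(f"TD error on B at its onset, first 3 cycles: "
      f"{np.round(delta[b_onsets[:3], 1], 3)}")
print(f"TD error on B at its onset, last 3 cycles:  "
      f"{np.round(delta[b_onsets[-3:], 1], 3)}")

# one more cycle, with B withheld
tail = np.zeros((CYCLE, 2))
tail[0, 0] = 1
pred, _, omega = model.run(tail)
print(f"learned prediction of B at its expected onset: {pred[LAG, 1]:.3f}")
print(f"negative surprise at the omitted onset:        {omega[LAG]:.3f}")
print("\nThe error at B's onset decays from 1 toward 0 as the A->B")
print("association is learned; withholding B then yields a surprise")
print("transient close to the converged prediction (>1 because the")
print("prediction also counts discounted future occurrences of B).")
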