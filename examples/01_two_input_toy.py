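"""The simplest structure-from-function inference: two inputs, one neuron.

The neuron responds (y = 1) to the input pattern (1, 1) and stays silent for
(1, -1).  Every weight vector reproducing this lies on the ray
w1 + w2 = 1, w1 - w2 <= 0; within a weight-norm bound W the second synapse is
present and excitatory in every solution, while the first synapse has a
consistent sign only when W < W-critical = 1.
"""

import numpy as np

from certgeom import NoiseModel, certain_synapses, sample_solutions, synth
from certgeom.geometry import classify_dimensions, decompose_recurrent

spec, patterns = synth.fig2_toy()

for r in certain_synapses(spec, patterns, NoiseModel(epsilon=0.0, W=1.0)):
    name = f"x{r.presyn}" if r.presyn > 0 else "self"
    print(
        f"synapse {name} -> y: y_cr = {r.y_cr:.4f}, W_cr = {r.W_cr:.4f}, "
        f"certain = {r.certain}, sign = {r.predicted_sign:+d}"
    )

problem = decompose_recurrent(spec, patterns)[0]
labels = classify_dimensions(problem.y_target, problem.n_synapses)
for W in (1.0, 1.3):
    samples = sample_solutions(problem, labels, W=W, n=2000, seed=0)
    w = np.array([s.weights for s in samples])
    note = "w1 pinned nonnegative" if W <= 1.0 else "w1 sign now varies"
    print(f"\nsampled {len(w)} exact solutions at W = {W}:")
    print(f"  w1 range: [{w[:, 0].min():+.3f}, {w[:, 0].max():+.3f}]  ({note})")
    print(f"  w2 range: [{w[:, 1].min():+.3f}, {w[:, 1].max():+.3f}]  (always positive)")
print(
    "\nW_cr = 1 means: if synaptic weight vectors are biologically bounded "
    "below 1,\nthe x1 -> y synapse must also exist and be excitatory."
)
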