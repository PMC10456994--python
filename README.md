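# certgeom

Predicting required synapses from steady-state neural activity in
threshold-linear recurrent networks.

## The problem

Many different synaptic weight matrices can produce the same neural
responses, so fitting a single network model to activity data says little
about which connections a real circuit must contain.  `certgeom` takes the
opposite approach: given a set of stimulus-evoked steady-state responses, it
characterizes *every* weight matrix consistent with them and reports the
synapses whose presence and sign are shared by the entire ensemble — the
**certain synapses**.  These are rigorous, experimentally testable anatomical
predictions that follow from the response data and the model class alone.
The intended users are systems neuroscientists with cellular-resolution
activity data (e.g. whole-brain imaging in small organisms) and theorists
studying degenerate solution spaces of rectified-linear networks.

## The model

A population of D driven neurons with firing rates `y_i` receives input
rates `x_m` and evolves as

    tau_i dy_i/dt = -y_i + Phi( sum_m w_im y_m + sum_m w_im x_(m-D) ),

with `Phi(s) = max(0, s)`.  Specifying P steady-state response patterns
(with P at most the number N of synapses per neuron) decouples the problem
into one feedforward problem per neuron.  Writing a target neuron's weight
vector in the basis of its presynaptic pattern matrix (`eta = Z w`), each
pattern pins one coordinate (`eta_mu = y_mu` where the response is positive)
or restricts it to a half-line (`eta_mu <= 0` where the neuron is silent —
a *semiconstrained* dimension born of the threshold), while leftover
coordinates stay free.

For orthonormal presynaptic patterns, synapse `m` is certain — nonzero with
a single sign across all solutions with `|w| <= W` — exactly when the
response magnitude `y = |y_vec|` exceeds

    y_cr = W * sqrt( (e_s*^2 + e_u^2) / (e_y^2 + e_s*^2 + e_u^2) ),

where `e_y` is the normalized pre/post activity correlation (its sign is the
predicted synapse sign), `e_u` the projection of the synapse direction onto
the unconstrained subspace, and `e_s*` the "adverse" semiconstrained
projection — presynaptic activity, aligned with the overall correlation, in
patterns where the target stayed silent.  Solving the same condition for the
bound gives `W_cr`, the weight bound below which the synapse is certain;
ranking synapses by decreasing `W_cr` orders the predictions from strongest
to weakest.  With an error budget `eps`, certainty requires every
nonnegative denoised response within `eps` to satisfy its own condition;
closed-form lower/upper bounds and an exact optimization-based decision are
provided, including the topological transitions where zeroing a small
response opens new semiconstrained dimensions.  For merely linearly
independent (non-orthonormal) patterns a conservative encompassing-sphere
bound is used.

## A worked example

`python examples/01_two_input_toy.py` analyzes a neuron that responds
(y = 1) to inputs (1, 1) and is silent for (1, -1):

```
synapse x1 -> y: y_cr = 0.7071, W_cr = 1.0000, certain = False, sign = +0
synapse x2 -> y: y_cr = 0.0000, W_cr = inf, certain = True, sign = +1

sampled 2000 exact solutions at W = 1.0:
  w1 range: [+0.000, +0.500]  (w1 pinned nonnegative)
  w2 range: [+0.500, +1.000]  (always positive)

sampled 2000 exact solutions at W = 1.3:
  w1 range: [-0.271, +0.500]  (w1 sign now varies)
  w2 range: [+0.500, +1.271]  (always positive)
```

The `x2 -> y` synapse is present and excitatory in every solution
(`W_cr = inf`): without it the silent pattern could not be silent while the
other pattern drives the neuron.  The `x1 -> y` synapse is excitatory in all
solutions only if weights are bounded below `W_cr = 1` — the sampled
solution sets confirm both readings.  The other examples cover a recurrent
network with a self-synapse whose certainty flips exactly at a 45-degree
response angle, uniform sampling of the solution space with dynamical
verification, noise-dependent certainty bounds against an exact oracle, and
the linear scaling of certain-synapse counts with network size.

A thin CLI mirrors the library: `certgeom certainty --problem manifest.json
--W 1.0`, plus `report`, `sample`, `simulate`, `screen`, `fit` and `synth`
subcommands operating on JSON-manifest problem files.

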