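# Methods

## Model and scope

`certgeom` analyzes recurrent networks of threshold-linear rate neurons,
`tau_i dy_i/dt = -y_i + Phi(W y + V x)` with `Phi(s) = max(0, s)`, whose
function is specified as P steady-state responses to P input patterns.  The
package assumes P does not exceed the number N of permitted synapses per
driven neuron (activity data is typically scarce relative to connectivity),
and treats each driven neuron's incoming weight vector independently: at a
fixed point, neuron i's responses depend only on its own row of the weight
matrix and on the steady-state activities of its presynaptic partners, so a
recurrent inference problem decouples into D feedforward problems.

Everything downstream works in the eta coordinates `eta = Z w`, where the
P x N presynaptic pattern matrix is extended to a full-rank N x N matrix by
an orthonormal basis of its null space.  The extension rows' signs are fixed
(first nonzero entry positive) so results are reproducible across platforms.
With this choice the extension is orthogonal exactly when the pattern rows
are orthonormal, which the exact certainty formulas require.  Pattern rows
that are mutually orthogonal but not unit norm are rescaled together with
their responses; this is exact because `Phi` is positively homogeneous.
Rows that are genuinely correlated fall back to a conservative bound (below).

## Zero-error certainty

Each eta coordinate is constrained (`eta_mu = y_mu` when `y_mu > 0`),
semiconstrained (`eta_mu <= 0` when `y_mu = 0`), or unconstrained
(`mu > P`).  Classification uses an absolute tolerance of 1e-9 on exact
synthetic data; noisy responses must go through the error-aware path
instead.  A synapse is certain when the hyperplane `w_m = 0` misses the
solution region inside the weight ball `|w| <= W`.  For orthonormal
patterns this reduces to `y > y_cr` with

    y_cr = W sqrt( (e_s*^2 + e_u^2) / (e_y^2 + e_s*^2 + e_u^2) ),

computed from three projections of the synapse's basis direction: the signed
response correlation `e_y`, the unconstrained mass `e_u`, and the adverse
semiconstrained mass `e_s*` (components whose presynaptic activity shares
the sign of `e_y` in patterns where the target was silent; the selection
uses a strict inequality, so zero components contribute nothing, matching
the empty-sum convention).  The equivalent two-angle/`alpha`/`gamma` form is
implemented only as a cross-check; the projection form is primary because it
avoids trigonometric edge cases.  Conventions at degenerate inputs:
`Sgn(0) := +1` for the adverse-side selection (irrelevant to `y_cr`, which
equals `W` whenever `e_y = 0`); `gamma := pi/2` when the semiconstrained
projection vanishes; `y_cr := 0` when all three projections vanish (the
synapse direction lies entirely inside the constrained data, and any
positive response certifies it).  Critical values are capped at `W`; a value
of `W` means the synapse cannot be certified under any feasible response
magnitude.  `W_cr = y sqrt((e_y^2 + e_s*^2 + e_u^2)/(e_s*^2 + e_u^2))`
inverts the condition in the bound and is reported as infinite when the
denominator vanishes.

## Certainty under an error budget

With noise, a synapse is certain iff every nonnegative denoised response
vector within Euclidean distance `eps` of the data satisfies its own
zero-error condition.  Zeroing a response component opens a semiconstrained
dimension — the topological transitions of the error surface — and the
admissible transitions are the response subsets whose root-sum-square cost
fits the budget.

Exact decision.  The package minimizes the certainty margin
`|y~| - y_cr(y~)` over the budget ball, enumerating which components of the
denoised response are pinned to zero (each pinned set fixes the
semiconstrained geometry, leaving a smooth low-dimensional subproblem) and
splitting each subproblem by the sign of the activity correlation.  Branches
whose sign constraint cannot be met inside the ball are skipped by an exact
interval test.  Subproblems are solved by SLSQP with analytic gradients from
five deterministic starts; the enumeration is capped at 2^20 subsets (the
result is flagged bound-only if the cap is hit, which cannot happen at the
problem sizes used here).  The minimizer was validated against dense random
search of the margin landscape: across randomized suites the decision never
reported certainty when random search found a violating denoised response.

Closed-form bounds.  Without transitions, the bounds used are

    y_cr_min = W [ sqrt(A) + eps/W ],
    y_cr_max = W [ sqrt(A) + (eps/W)^2 (1 + B) + (eps/W) sqrt(1 + B) ],

with `A = (e_s*^2 + e_u^2)/(e_y^2 + e_s*^2 + e_u^2)` and
`B = e_y^2 (e_p^2 - e_y^2)/(e_y^2 + e_s*^2 + e_u^2)^2`, both capped at `W`.
These forms were fixed by three requirements: they reduce to `y_cr` as
`eps -> 0`; they coincide to leading order in `eps/W` when `e_y` is small
relative to the dominant uncertain mass; and on randomized validation suites
the interval [y_cr_min, y_cr_max] brackets the exact optimization-based
critical magnitude with zero violations (200 engineered-transition
configurations plus broader random suites).  Transition-aware values take
the maximum over admissible subsets of the bound recomputed with the
subset's dimensions moved to the semiconstrained side, the correlation
re-normalized to the surviving components, the residual budget
`sqrt(eps^2 - cost^2)`, and the threshold mapped back to the full response
norm via `sqrt(t^2 + cost^2)`.  Because subset admissibility itself depends
on the response magnitude, the reported bounds are computed
self-consistently along the ray through the given response vector: the
returned value is the magnitude above which the bound certifies the synapse
when costs are evaluated at that same magnitude.  At `eps = 0` this
reproduces `y_cr` exactly.

Non-orthonormal patterns.  The weight ball maps to an ellipsoid in eta
coordinates; enclosing it in the sphere of radius `W * sigma_max(Z)` and
applying the orthonormal machinery to the unit normal of the `w_m = 0`
hyperplane in eta coordinates yields a conservative critical magnitude
(never smaller than the truth, exact in the orthonormal limit).  This path
does not support a nonzero error budget; results carry an explanatory note.

## Solution-space sampling and error surfaces

Sampling fixes the constrained coordinates and draws the free coordinates
uniformly from the intersection of the nonpositive-semiconstrained region
with the ellipsoid the weight ball induces (an exact affine transform of a
uniform ball; a ball itself in the orthonormal case), rejecting draws with
positive semiconstrained coordinates.  Rejection costs a factor 2^S, so
beyond 20 semiconstrained dimensions a seeded Gibbs sweep over the free
coordinates (each conditional is a uniform draw from an interval) takes
over, with 100 burn-in sweeps and a thinning of 5.  A rounding slack of
1e-12 W on the sign check keeps the degenerate case `W = |y|` (a
zero-radius residual region) from rejecting its unique point forever;
accepted coordinates are clipped back to nonpositive.  Membership testing
uses an absolute tolerance of 1e-8 on constrained equalities and the same
one-sided slack on semiconstrained inequalities.

The transition schedule enumerates response subsets in increasing
root-sum-square cost with pruning and a 2^20 cap; zero responses appear as
zero-cost events, and negative responses (noisy data) contribute a
feasibility offset that joins every event.

## Dynamics

Steady states are found by explicit Euler integration (`dt = min(tau)/20`,
default horizon 200 time units, convergence when the rate of change falls
below 1e-9) finished by direct fixed-point iteration; the dynamics are
piecewise linear, so neither step is stiff.  Divergence is declared past
1000 times the larger of 1 and the initial state norm.  Time constants
default to 1 — steady states do not depend on them.  The network error of a
weight matrix initializes each pattern at its specified responses and
accumulates the distance to the reached fixed points; non-convergence means
infinite error by default.  A late-time mode instead uses the bounded state
at the end of the horizon: configurations with more patterns than inputs
necessarily sustain activity through exactly-critical recurrent loops, so
their fixed points are marginally stable and approximate models drift
slowly rather than settle; the late-time mode is what the gradient-fit
ensemble evaluation uses.

## Numerical verification machinery

Random screening rescales the response vector along its own direction,
samples exact solutions at each level, and reports the largest level at
which both synapse signs occur.  The minority-sign volume vanishes
continuously at the true critical magnitude, so small censuses under-detect
just below it; when a maximum budget is given, the level just above the
current estimate is re-screened with up to that many draws.  Screening is
guarded to at most 8 synapses (rejection sampling).

Gradient fitting minimizes the feedforward proxy cost (each driven neuron's
row against its presynaptic patterns, the conventional subgradient 0 at the
rectifier kink) by per-row projected gradient descent with backtracking,
rows projected onto the weight ball after every step, initialized with
small random weights (scale 0.01 W).  Dead-unit local minima — precisely
the semiconstrained traps the error-surface analysis predicts — are
mitigated by up to five random restarts per row; models that still miss the
target are kept with their achieved error, since variable-accuracy
ensembles are themselves the object of study.

## Synthetic configurations

Random orthonormal pattern matrices are exponentials of random antisymmetric
matrices (upper-triangle entries N(0, 1/n); any full-measure scale gives
orthogonality, the value only shapes the distribution).  Response vectors
place C positive components with direction uniform on the positive orthant
of the C-sphere (absolute values of an isotropic Gaussian — the minimal
unbiased choice) at norm `1 - ln2/C`, the median norm of a uniform vector in
the unit C-ball.  Transition-engineered configurations make one constrained
component small (uniform in [0.02, 0.1] of the norm — an implementation
default) and concentrate the rest so only that one transition fits small
budgets.

Recurrent configurations with orthonormal target-neuron patterns keep the
other neurons' response columns nonnegative.  When P exceeds the input
count, some pattern rows must carry unit driven-only activity (the input
Gram matrix cannot span all P directions); these rows use disjoint pairs of
driven neurons at activity 1/sqrt(2) each, so the pair can drive itself
within a unit weight bound once the target neuron also responds in those
patterns — which is why the input-free patterns are always among the
target's constrained ones.  Only the target neuron's problem is promised
orthonormal (and the other neurons' problems can be genuinely degenerate);
the certainty API records such per-neuron failures instead of aborting.

What the generators do not emulate: correlated (non-orthogonal) stimulus
responses beyond the conservative-bound path, trial-to-trial variability
with a known noise covariance (the error budget is a worst-case ball),
unobserved neurons, and Dale-type sign constraints.  Passing tests therefore
demonstrate correctness of the geometry and its certainty conditions under
the stated assumptions, not robustness to those forms of model mismatch.

## Verification problem sizes

The test suite checks the two-input toy problem exactly; the self-synapse
condition on a 5-degree grid with 20000-sample sign censuses; empirical
critical magnitudes of the three-synapse family at 8 angle pairs on a 0.02
grid (20000 draws per level, escalating to 400000 near the detection
boundary; the angle pairs are spread over both branches and chosen so the
analytic value does not sit within sampling-detection distance of a grid
level); the noisy-bound bracket on 200 engineered-transition configurations
at `eps = 0.1` via two-point oracle queries just outside each bound; 12
gradient-fit ensembles of 25 models per response level at target error 0.1;
and certain-fraction Monte Carlo over 200 configurations per scaling family
at network size 100.  The acceptance script reuses the toy problem and the
two 200-configuration Monte Carlo estimates.

## Known limitations

Exact certainty for strongly correlated patterns is out of scope (only the
conservative bound); the noisy path requires orthonormal patterns; error
surfaces for recurrent networks are treated in the feedforward
approximation, which ignores that noise in one neuron's response perturbs
its targets' presynaptic patterns; stability of fixed points is not
analyzed, only reported through the dynamics module's convergence behavior;
and no attempt is made to estimate sign probabilities for uncertain
synapses.
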