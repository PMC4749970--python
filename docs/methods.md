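# Methods

## Model-error representation

A nominal model `dx/dt = f(x, u, p, t)`, `y = h(x)` encodes the modeller's
current assumptions: `x` are the dynamic states (typically concentrations),
`u` a known external input, `p` the calibrated parameters, and `h` the map
onto the experimentally accessible outputs. Every discrepancy between this
draft and the real system — a missing reaction, misspecified kinetics,
an unmodelled exogenous influence — is represented *non-parametrically* as
an additive hidden input `w(t)` on the state derivatives:

    dx/dt = f(x, u, p, t) + w(t).

`w_k(t)` is the net unexplained flux into state `k`. This representation is
complete (any smooth discrepancy between true and nominal rate of change can
be written this way) but deliberately agnostic about mechanism: the fit
tells you *which states* are mis-modelled and *what the missing flux looks
like over time*, not which specific reaction to add.

## The estimator

`w` is estimated by minimising the error functional

    J(w) = Σ_i ‖y(t_i) − ŷ(t_i)‖²_{W_i} + λ₁ Σ_k ∫|w_k| dt + λ₂ Σ_k ∫w_k² dt

subject to the observer dynamics (a copy of the nominal model driven by
`w`). The weighted square norm uses per-sample symmetric PSD matrices
`W_i`; the default is `diag(1/sd²)` when per-point standard deviations are
supplied and identity otherwise. The elastic-net penalty combines sparsity
across components (L1, rate λ₁ per unit of integrated |w|) with smoothness
and boundedness (L2). A pure L1 functional penalty is not usable here: the
optimal-control solution degenerates to unbounded or boundary-riding
(bang-bang) inputs, which is why the quadratic term is always present.

Optional endpoint constraints bound the weighted output misfit at the first
and/or last sample time by preset tolerances δ₀/δ_N (readable off the error
bars); with the δ₀ form the observer's initial state becomes a free
variable instead of being fixed to the nominal initial state (the default).

## Numerics

*Discretization.* `w` is piecewise-linear (optionally piecewise-constant)
on a control grid of `n_intervals + 1` knots spanning the measurement
horizon; the library default is 100 intervals, and the bundled benchmarks
use grids whose knot spacing matches the data's sample spacing (see below).
The nonsmooth L1 term is made smooth by the exact split `w = w⁺ − w⁻` with
`w± ≥ 0`; at any optimum `∫(w⁺+w⁻) = ∫|w|`.

*Transcription and gradient.* The observer ODE is integrated by fixed-step
classical RK4 on a refinement of the control grid (default 3 substeps per
interval, with every sample time inserted as an exact step boundary). The
gradient of this *discrete* objective is computed exactly by reverse-mode
differentiation of the RK4 recursion (a discrete adjoint using the model's
analytic state Jacobian, derived symbolically for all built-in models;
finite differences for models given as raw callables). Exact gradients are
what lets the quasi-Newton iterations converge to tight tolerances — the
adjoint is verified against central finite differences to ~1e-8 in the test
suite. Bound-constrained problems are solved with L-BFGS-B (projected
gradient tolerance 1e-7 by default); runs with endpoint constraints switch
to SLSQP with analytically propagated constraint Jacobians (one extra
adjoint sweep per constraint). Trial points whose forward pass diverges
(e.g. a mass-action state pushed negative through a quadratic term) return
a large objective so the line search backtracks.

*Reported quantities.* The standalone `penalty` and `compute_auc` use the
exact closed-form quadrature of the piecewise-linear interpolant, including
sign-crossing segments; the solver's internal L1 term uses the trapezoid
rule on the split variables, which coincides with the exact value at any
optimum without intra-segment sign changes. The reported objective breakdown
(`total = fit + l1 + l2` to 1e-9 relative) refers to the discrete objective
actually minimised. The returned state estimate is the transcription
trajectory; re-integrating the nominal model under the returned `ŵ` with an
adaptive solver reproduces it to ~1e-4 relative at the default substep
count.

*Choosing λ.* `select_lambdas` fits a (λ₁, λ₂) grid and returns the
sparsest acceptable point: the largest λ₁ (ties to the largest λ₂) whose
fit term is within a factor (default 1.1) of the best fit on the path. Two
scale regimes matter in practice: with identity output weighting and O(1)
outputs, λ₁ ≈ 0.01–0.1 is a reasonable starting range; with `1/sd²`
weighting, each output contributes an O(N) incentive to chase noise
regardless of the noise size, so λ₁ must be of order `N/∫|w_noise|` —
tens to hundreds — before noise-chasing is suppressed. The bundled
benchmark configurations record the concrete values used.

## Error localisation

`AUC_k = ∫|ŵ_k| dt` summarises each component. The target set is the
smallest prefix of components, sorted by descending AUC (ties to the lower
state index), whose cumulative share reaches the criterion (default 85%).
When a ground-truth target set is known, *recovered* requires exact set
equality — a pair with one correct member does not count — and the truth
set's own cumulative fraction is recorded separately.

*Thresholding-and-refit* pins components below an AUC-fraction cutoff
(default 5%) to exactly zero and re-solves, debiasing the doubly-penalised
estimate; it never increases the number of nonzero components. The refit is
typically run with ~10× weaker λ₁ and, under noise, on a coarser control
grid (fewer degrees of freedom act as extra regularisation against
noise-driven wiggles between samples).

*Alternative solutions.* Some errors are unobservable: a different input on
different nodes reproduces the same outputs. `explore_alternatives` re-runs
the fit with subsets of the primary target nodes pinned to zero; an
alternative is *acceptable* if its fit degrades by at most a factor
(default 1.25, reported) and its own target set is no larger than the
primary one. On the deliberately symmetric motif this reproduces the
expected phenomenology: the primary fit splits the unobservable pair evenly
(the L2 term favours the even split along the exactly-flat direction),
either single exclusion yields an equally good one-node explanation, and
excluding the whole pair destroys the fit.

## Built-in models and what the benchmarks emulate

*JAK-STAT (4 states).* EPO-receptor-driven STAT5 phosphorylation,
dimerisation, nuclear import, and instantaneous nuclear export back to the
cytoplasm (rate k4); outputs are phosphorylated and total cytoplasmic
STAT5. The monomer-equivalent total `x1 + x2 + 2x3 + 2x4` is conserved
(verified symbolically). Rate constants follow the published Swameye-model
parameterization (k1=0.021, k2=2.46, k3=0.1066, k4=0.10658, scales 1).
The bundled synthetic experiment perturbs cytoplasmic and nuclear STAT5
with opposite-signed smooth pulses — the signature of unmodelled,
*delayed* nucleocytoplasmic cycling — and checks that the monomer
component `w2` is driven to exactly zero.

*UV-B surrogate (11 states, 10 reactions).* A purpose-built synthetic
stand-in for a published plant UV-B photoreceptor signalling model whose
curated equations could not be bundled: a photoreceptor dimer/monomer cycle
driven by a UV-dose-like input, monomer–effector complex formation, a
five-step downstream cascade, and two terminal product states that do not
feed back into any observed quantity (hidden inputs targeting them have
provably zero output effect). Five outputs mix seven distinct states.
Labelled synthetic throughout: results on it characterise the estimator on
a network of this size and observation density, not the published network.

*Motifs (3 states each).* `chain3`, `feedforward` and `feedback` observe
every state (scaled identity outputs) and are the package's *observable*
ground-truth cases; `symmetric` contains an exactly unobservable node pair.
The full-observation choice is deliberate: with a single output, a hidden
input on the output-proximal node can reproduce any upstream error's output
signature at equal or lower penalty cost, so single-output motifs cannot
support unique single-node localisation at all — we measured the smeared
mixture beating the true sparse input on the objective. Observability in
the localisation sense is a property of the output map, not of the
estimator.

## Benchmark conditions and their rationale

Synthetic truths are generated by simulating the nominal model plus
prescribed waveforms (constant / smooth sin² pulse / ramp / sinusoid /
tabulated) on chosen target nodes, sampling outputs at discrete times and
adding seeded Gaussian noise. `amplitude A = max_{t,k} |w_k(t)|` normalises
reconstruction error; the state discrepancy is the Euclidean norm over
states at each time. Default noise, where not stated otherwise, is 5% of
each output's range, recorded per output in the truth object.

The motif suite uses 25 samples over 12 time units with a 24-interval
control grid (knot spacing = sample spacing — a deliberately matched design:
when knots are denser than samples, the inter-sample null space of the
sampling operator admits sawtooth modes that noise excites), pulses with
seeded amplitude 0.6–1.4 and seeded onset/offset, λ₁=0.05 λ₂=0.005 for
localisation and λ₁=0.005 λ₂=0.002 for the debiasing refit. Under these
conditions single-node recovery is 100% across 180 seeded cases and the
refit reconstructs the pulse within ~2% of its amplitude.

The surrogate benchmark uses 21 samples over 20 time units, a 20-interval
localisation grid and a 14-interval refit grid, with λ₁=30 λ₂=3 /
refit λ₁=1 λ₂=5 under `1/sd²` weighting. Its default noise is 0.5% of
each output's range, lower than the generator default, and the headline
reconstruction bound (≤10% of A) is evaluated on the noise-free variant:
pointwise reconstruction of `w` from sampled outputs amounts to
differentiating noise, and we measured the sup-norm error growing roughly
linearly with the noise fraction (≈0.6·A at 1.5% noise), while
*localisation* of the two target nodes stays exact throughout the 0.5–5%
range. The noise-free bound therefore isolates what it is meant to measure
— discretization and solver error — and the robustness studies, not the
benchmark, characterise noise sensitivity.

Robustness studies follow the perturbation design of the noise/parameter
sensitivity analyses: per level, data are re-noised with `N(0,(level·sd)²)`
(or parameters redrawn uniformly from `point ± level·halfwidth`, clipped at
zero for rate constants) with per-sample seeds derived deterministically
from the master seed, one fit per replicate, failures recorded and excluded
from the median/quartile summaries. The library default is 500 replicates;
the test suite and acceptance script run 25 for tractability — the
summaries are medians and quartiles, whose precision, not location, depends
on the replicate count.

## What passing the synthetic studies does and does not show

The generator draws additive, homoscedastic Gaussian noise; real
time-course data have correlated, heteroscedastic, sometimes non-Gaussian
errors. Truth inputs are smooth low-frequency waveforms well inside the
control basis; discontinuous or fast model errors would incur
representation bias. The nominal models used as truth scaffolds are exactly
known apart from the injected inputs — parameter error appears only in the
dedicated parameter study. And the observable motifs observe all states;
real applications sit between that and the surrogate's 5-of-11 observation
density, where localisation held but pointwise reconstruction was
noise-limited. Passing therefore demonstrates correctness of the estimator
and its analysis pipeline under the stated conditions, not performance
guarantees on arbitrary experimental data.

## Degenerate inputs and edge behaviour

Zero total AUC flags the fractions as undefined and yields an empty target
set. Thresholding with every component below the cutoff returns the `w≡0`
solution with a warning flag. Masked components are exactly zero at every
knot by construction (they are removed from the decision vector, not
penalised). Endpoint constraints that cannot be met surface as
`solver_status="infeasible"` with the best iterate returned. Known inputs
are held constant outside their tabulated range. Duplicate (λ₁, λ₂) grid
points are deduplicated before a path fit; a path on which every fit fails
raises an explicit path-failure error.

## Limitations

The estimator returns a stationary point of a nonconvex problem for
nonlinear models (convex for linear ones); the deterministic zero warm
start makes runs reproducible but a sufficiently wrong basin is possible —
seeded multi-start is available but off by default. Errors on states with
no output influence are invisible by construction and are flagged and
omitted in recovery studies rather than guessed at. The method localises
net unexplained flux per state; it cannot distinguish a missing reaction
from a wrong rate law targeting the same state. SBML support covers the
ODE-expressible core (species, reactions with kinetic laws, rate rules,
constant species/compartments); events, function definitions and
assignment/algebraic rules are rejected explicitly.
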