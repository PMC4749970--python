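# denet — dynamic elastic-net estimation of model errors in ODE models

Mechanistic ODE models in systems biology are almost always incomplete:
reactions are missing, kinetics are simplified, and the modelled subsystem is
open to unmodelled exogenous influences. `denet` treats every such
discrepancy as a *hidden input* — an additive, time-varying term `w(t)` on
the state derivatives of the nominal model

```
dx/dt = f(x, u, p, t) + w(t),        y = h(x),
```

and estimates `w(t)` directly from measured output time courses by solving a
regularised optimal-control problem (the **dynamic elastic-net**):

```
min_w   Σ_i ‖y(t_i) − ŷ(t_i)‖²_{W_i}  +  λ₁ Σ_k ∫ |w_k(t)| dt  +  λ₂ Σ_k ∫ w_k(t)² dt
s.t.    dx̂/dt = f(x̂, u, p, t) + w(t),   ŷ = h(x̂).
```

The combined L1+L2 functional penalty mirrors the elastic net of regression:
the L1 part drives whole components of `w` to zero, *localising* the model
error to a few target state variables; the L2 part keeps the estimate smooth
and bounded (a pure L1 penalty degenerates to unbounded or bang-bang
controls in the dynamic setting). Alongside the error signal, the fit yields
a bias-corrected state estimate `x̂(t)` — useful when most states are not
measured — and per-component AUC scores `∫|ŵ_k| dt` that rank candidate
error locations. Low-AUC components can be pinned to zero and the problem
re-solved (*thresholding-and-refit*) to debias the remaining estimates, and
candidate target nodes can be excluded one by one to probe alternative
explanations when the error is not uniquely observable.

The package is intended for modellers who have a draft ODE model and
time-course data that it does not quite fit, and who want to know *where*
the model is wrong, *what* the missing influence looks like over time, and
*what the true states were* despite the model error.

## What is in the box

- `denet.models` — model container with symbolic rate/output expressions
  (analytic Jacobians via sympy), known tabulated inputs, an adaptive-step
  simulator, and built-in examples: a 4-state JAK-STAT signalling model, an
  11-state synthetic surrogate of a plant UV-B photoreceptor network, and
  small network motifs with known observability properties.
- `denet.solver` — the estimator: piecewise-linear control parameterization,
  smooth `w = w⁺ − w⁻` split of the L1 term, fixed-step RK4 transcription
  with an exact discrete adjoint gradient, L-BFGS-B / SLSQP solves, optional
  endpoint-fit constraints, and a regularisation-path selector.
- `denet.analysis` — AUC tables, 85%-criterion target identification,
  thresholding-and-refit, exclusion-based alternative solutions, and
  systematic recovery studies over simulated single/pair errors.
- `denet.robustness` — measurement-noise and parameter-uncertainty
  perturbation studies of the AUC estimates.
- `denet.bench` — ground-truth benchmark generation (waveform specs, seeded
  noise, reconstruction scoring against the true `w` and `x`).
- `denet.io` / `denet.sbml` / `denet.cli` — CSV measurement/input tables,
  JSON run reports, a minimal SBML import/export, and a `denet` command-line
  tool (`fit`, `benchmark`, `robustness`, `alternatives`, `template`).

## Worked example

A draft 3-step cascade model (`u → x1 → x2 → x3`) is fitted to simulated
data from a "real" system that carries a transient extra influx into `x2`
the draft knows nothing about:

```python
import numpy as np
from denet import *

model = motif_models()["chain3"]
u = KnownInput(np.array([0.0, 12.0]), np.array([[1.0], [1.0]]))

spec = HiddenInputSpec(target_nodes=(1,), waveform="pulse",
                       amplitude=1.0, onset=2.0, offset=9.0)
truth = generate_truth(model, u, spec, np.linspace(0, 12, 25),
                       noise_sd=0.0, seed=1)

grid = ControlGrid.for_data(truth.measurements, n_intervals=24)
cfg = RegularizationConfig(lambda1=0.05, lambda2=0.005)
fit = solve_den(model, u, truth.measurements, cfg, grid)

auc = compute_auc(fit.hidden_input)
targets = identify_targets(auc, criterion=0.85)
print(auc.as_frame(model.state_labels).round(4))
print("targets:", [model.state_labels[i] for i in targets.nodes])

refit = threshold_and_refit(model, u, truth.measurements,
                            RegularizationConfig(lambda1=0.005, lambda2=0.002),
                            grid, fit)
score = score_reconstruction(truth, refit)
print("max |w - w_hat| / A  : %.3f" % score.max_input_error_rel)
print("max ||x - x_hat||    : %.4f" % score.state_discrepancy.max())
print("max ||x - x_nominal||: %.4f" % score.nominal_state_discrepancy.max())
```

prints

```
  component     auc  fraction
0        x1  0.0081    0.0023
1        x2  3.4652    0.9977
2        x3  0.0000    0.0000
targets: ['x2']
max |w - w_hat| / A  : 0.017
max ||x - x_hat||    : 0.0020
max ||x - x_nominal||: 1.4976
```

The AUC table localises the model error: component `x2` carries 99.8% of
the total integrated error magnitude, so the fit names exactly the state the
simulated truth perturbed. After the debiasing refit, the estimated error
time course deviates from the true pulse by at most 1.7% of its amplitude,
and the corrected state trajectory is within 0.002 of the truth where the
uncorrected draft model drifts off by 1.5.

The same pipeline is available from the shell: `denet template -o run.yaml`,
edit, then `denet fit run.yaml` (exit codes: 0 success, 2 validation error,
3 solver failure).

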