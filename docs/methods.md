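# Methods

## The model

squadflow builds continuous-logic (SQUAD-type) ODE models of gene
regulation from a signed interaction graph. Each non-constant node j has an
activity level x_j ∈ [0, 1] obeying

    dx_j/dt = A(w_j, h_j) − γ_j x_j + r_j .

`A` is a normalized sigmoid,

    A(w, h) = (−e^{h/2} + e^{−h(w−1/2)}) / ((1 − e^{h/2})(1 + e^{−h(w−1/2)})) ,

which maps [0, 1] onto [0, 1] exactly — A(0)=0, A(1/2)=1/2, A(1)=1 for every
steepness h > 0 — and is strictly increasing in the combined regulatory
input w_j. The combined input aggregates weighted activator activities
(weights α_n ≥ 0) and inhibitor activities (β_m ≥ 0) through saturating
Michaelis-type ratios with prefactor (1+Σ)/Σ so that full activation maps
to w=1; when both classes are present the activator part is multiplied by
one minus the inhibitor part. Unregulated nodes have activation term 0 and
decay unless stimulated; constant nodes are clamped (derivative 0).

External stimuli enter as r_j = δ_k u_k (1 − x_j) for an up-regulating
channel and −δ_k u_k x_j for a down-regulating one: the (1−x_j) / x_j
factors make stimulation self-limiting at the boundaries, which together
with γ_j = 1 keeps trajectories inside [0, 1]. This boundedness is a model
property, not an enforcement: the simulator never clips states, it asserts
the invariant and attaches a warning on breach so modeling errors surface.

### Decay γ_j

γ_j defaults to 1 for every node and is excluded from the default free
parameter set. With γ = 1 the decay term spans the same [0, 1] range as the
activation term and the inward-flow argument at the state-space boundary
holds unconditionally. Freeing γ is possible (it has bounds in the box),
but then boundedness is only monitored, not guaranteed.

## Simulation

`simulate` integrates with SciPy's LSODA (stiffness-switching; fitted
steepness values up to 50 make the sigmoids sharp) at rtol 1e-8 /
atol 1e-10, restarting the solver at every breakpoint of the
piecewise-constant stimulus profile so control discontinuities never
degrade accuracy. Measurement times are solver evaluation points (dense
evaluation, not post-hoc interpolation). `relax_to_equilibrium` integrates
in chunks until the right-hand side max-norm falls below a tolerance.

## Data preparation

The single-cell front-end maps per-timepoint count matrices (cells × genes,
raw or log-transformed) to fit-ready series per gene:

1. **dropout removal** — zeros are treated as missing measurements and
   deleted, per time point;
2. **max-normalization** — all remaining values of a gene, across all cells
   and time points, are divided by the gene's global maximum;
3. **summary** — per time point: mean (the best value x̃), sample standard
   deviation (ddof 1), standard error, and cell count.

The chi-square weight σ defaults to the standard deviation; the standard
error (smaller by √n) can be written instead (`--use-sem`). Both are in
field use; the choice is deliberately exposed rather than hard-coded. A
time point where all retained cells agree exactly would produce σ = 0 and
an infinite weight; such σ are floored at 1e-3. A time point with a single
retained cell has no sample SD; it is excluded and flagged.

**Known property of max-normalization.** With multiplicative cell noise the
divisor is an extreme-value statistic: it grows slowly with the number of
cells, so the absolute level of the summarized series is shrunk by a
noise-dependent factor that does not vanish as cells are added. The
temporal shape (the series divided by its own maximum) is unaffected — the
common divisor cancels — and that is what the recovery tests assert. Fits
of absolute levels against such data inherit this scale compression.

## Fitting

The objective is the weighted sum of squares

    χ²(p) = Σ_l Σ_i Σ_j ((x_{l,j}(t_i; p) − x̃_{l,j,i}) / σ_{l,j,i})² ,

summed over experiments l (each with its own stimulus schedule and initial
state), measurement times and observed genes only. Optimization is
trust-region-reflective bounded least squares on the residual vector with
finite-difference Jacobians; one simulation per experiment per residual
evaluation. Multi-start uses seeded Latin-hypercube samples of the box.

Default box D (user-overridable per parameter): α, β ∈ [1e-3, 50]
(the lower bound keeps the (1+Σ)/Σ prefactor finite); h ∈ [1, 50];
δ ∈ [0, 50]; x0 ∈ [0, 1]. Default starts: weights 1, h 10, δ 1, x0 at the
first measured value (0.5 if unobserved). Convergence is tolerance-based
(ftol/xtol/gtol 1e-10) with an optional evaluation cap; the returned
chi-square never exceeds the start's.

`warm_start` carries shared parameter values from a previous fit into a
modified topology (clipped into the new box, with a report of what was
carried/defaulted/clipped) so iterative topology refinement only fits the
new parameters from scratch. An edge that changed sign is refused by
default: its old weight was estimated under the opposite regulatory role.

## Goodness of fit

Under the white-noise null each weighted residual is standard normal, so
χ² is chi-square distributed with dof = n_data − n_free: every fitted
parameter lets the model absorb one direction of noise. The p-value is the
upper-tail probability at the observed χ²; "cannot reject" iff p ≥ level
(default 5%). dof ≤ 0 (more free parameters than data points) leaves the
test undefined and is reported as such, not as a pass.

The dof correction is exact only for models linear in their parameters; for
these nonlinear dynamics it is an approximation. The suite's calibration
check therefore accepts a wide band around the nominal rejection rate
(0–12% at level 5%, 60 replicate refits of a 2-gene model warm-started at
the truth — sized to keep the suite fast; the band's upper edge is the
meaningful one, guarding against systematic over-rejection).

## Optimal control

Given fixed (fitted) parameters, candidate stimulus channels u_k ≥ 0 and a
desired state {θ_j, ϱ_j}, the problem is

    min_u ∫₀ᵀ Σ_j ϱ_j (x_j − θ_j)² dt + α ∫₀ᵀ Σ_k u_k dt ,
    ẋ = f(x, u), x(0) = x0, 0 ≤ u_k ≤ u_max .

The α-term is an L1 control cost; because u ≥ 0 it is linear on the
feasible set, so no prox/soft-threshold machinery is needed — projection
onto [0, u_max] handles the kink at zero. Increasing α forces channels
whose steering benefit does not repay their cost to identically zero; the
survivors are the most effective intervention points.

Method: first-discretize-then-optimize single shooting with piecewise
constant controls (default 50 uniform segments; the shipped fixtures use
10, which exhaustive search shows is enough for their horizons). Gradients
come from the adjoint ODE λ̇ = −(∂f/∂x)ᵀλ − 2ϱ(x−θ), λ(T)=0, integrated
backward segment-wise with the analytic state Jacobian; the tracking term
is accumulated as an extra quadrature state during the forward pass, so
the reported tracking + cost = total identity is exact. The descent is
projected gradient with Armijo backtracking: feasibility holds exactly at
every iterate and accepted steps never increase the objective. Stopping:
projected-gradient max-norm below 1e-6, or two consecutive accepted
decreases below 1e-9 relative (without the latter the method grinds
negligible improvements to the iteration cap).

Local optimality caveat: the dynamics are nonconvex in u, so solutions are
local. The alpha sweep warm-starts each solve from the previous optimum;
`scenario_report` warm-starts every channel subset from the best embedded
solution of its already-solved sub-subsets, which guarantees (by monotone
descent) that a superset never reports a worse objective than a subset —
the property the synergy comparison relies on. The active-set threshold is
max_t u_k > 1e-3·max(1, u_max); no principled universal constant exists,
this one separates the observed "identically zero" channels from active
ones by many orders of magnitude on all fixtures.

Correctness evidence computed by the suite: the adjoint gradient matches
central finite differences to <1e-4 relative on both control fixtures, and
the solver lands within 2% of exhaustive search over constant controls on
the 1-gene toy (in fact it matches it exactly: the toy's optimum saturates
the u_max bound).

## Synthetic data

Generators are seeded and bit-reproducible. Measurement noise is additive
Gaussian on normalized activities — the error model the chi-square
objective assumes — clipped to [0, 1], with the generating σ attached as
the per-point dispersion. The count generator emulates the raw single-cell
stage instead: counts ∝ activity × scale with lognormal multiplicative
noise and Bernoulli zero-inflation (dropouts). It does not model
library-size or gene-length effects, cell-to-cell regulatory heterogeneity
or batch structure, so passing pipeline tests demonstrate correctness of
the computations, not robustness to those real-data features.

Study conditions of the shipped fixtures:

- **3-gene recovery cascade** — G1 self-activating (holding a high initial
  state), G1→G2→G3; weights 2.0–2.5, h = 6, x0 = (0.9, 0.1, 0.1); 8 time
  points over [0, 8] h, noise σ = 0.02. Sized like a small time-series
  experiment: few points, moderate noise, identifiable trajectories (the
  parameters themselves are sloppy, which the recovery criterion — 
  trajectory error < 0.05 — deliberately does not penalize).
- **bistable switch** — one self-activating gene (α=4, h=10); starts 0.02
  and 0.9 fall on either side of the numerically verified basin boundary.
- **1-gene control toy** — unregulated decaying gene, one up-channel
  (δ=1), θ=1 with ϱ=10, T=5, α=0.1, 10 segments, u_max=3; small enough for
  exhaustive search over constant controls.
- **4-node synergy fixture** — two independent driver→target branches with
  one up-channel per driver (δ=1.5, u_max=2, T=6, 10 segments): each
  stimulus rescues exactly one target, only the pair rescues both — a
  miniature of the combination-therapy comparison.

## Degenerate inputs and tie-breaks

- A present regulator class whose weights sum to 0 is an error (the
  combined-input prefactor is undefined), not a silent zero.
- Piecewise-constant profiles use right-open segments: the value on
  [t_i, t_{i+1}) is the value at t_i.
- All-dropout gene/time points raise at the gene level; a fully dropped-out
  single time point is treated as unobserved.
- `chi2_test` at χ²=0 returns p=1; negative χ² is a domain error.

## Limitations

- Analytic Jacobians serve the adjoint; the least-squares fit uses
  finite-difference residual Jacobians (adequate at fixture scale, the
  dominant cost for large models).
- No profile-likelihood uncertainty, no state-constrained fitting with free
  decay, no model selection beyond χ²/p reporting.
- Control solutions are local optima; multi-start over control space is not
  automated beyond the warm-start strategies described above.
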