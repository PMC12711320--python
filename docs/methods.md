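# Methods

`brdtr` estimates benefit-risk dynamic treatment regimens (BR-DTRs): a
sequence of decision rules `D_t(H_t) = sign(f_t(H_t))`, one per treatment
stage, chosen to maximize the expected cumulative reward `E[sum_t Y_t]`
subject to a pre-specified budget on the expected *acute* risk of each
stage, `E^D[R_t] <= tau_t`.

## Model and assumptions

Data come from a sequential multiple-assignment randomized trial (or an
observational study with estimated propensities): for each subject and
stage `t = 1..T` we observe history `H_t` (nested, `H_1 ⊂ ... ⊂ H_T`),
binary treatment `A_t ∈ {-1,+1}` with assignment probability
`p(A_t | H_t)` bounded away from 0 and 1, reward `Y_t` and risk `R_t`.
Identification of the stagewise decomposition relies on the usual causal
assumptions (consistency, no unmeasured confounding, positivity) plus the
**acute risk assumption**: the stage-t risk depends only on the stage-t
treatment, not on earlier ones. Under it, the constrained T-stage problem
decomposes into T single-stage, single-constraint problems solved by
backward induction, each of the form

    min_f  (1/n) Σ_i (W_i / P_i) φ(Âᵢ f(H_i))  +  λ ‖f‖²
    s.t.   (1/n) Σ_i (R_i / P_i) ψ(A_i f(H_i), η)  ≤  τ,

where `φ(x) = (1-x)₊` is the hinge loss on the benefit side and
`ψ(x, η)` is the shifted ramp loss — 1 for `x ≥ 0`, linear on `(-η, 0)`,
0 below `-η`. Because `ψ` dominates the indicator `I(x ≥ 0)`, any rule
feasible for the surrogate constraint is feasible for the 0-1 risk; the
surrogate is conservative for every `η ∈ (0, 1]` and tightens as `η → 0`.
`f` lives in an RKHS with a linear kernel (solved in its primal weight
space) or a Gaussian kernel `k(h,h') = exp(-σ²‖h-h'‖²)` whose inverse
bandwidth is fixed by the across-arm median heuristic,
`1/σ = 2·median{‖H_i - H_j‖ : A_i ≠ A_j}`. All features are centered to
mean 0 and rescaled into `[-1, 1]` using transforms fitted on the training
sample and stored with the policy.

## Augmented weights

Plain outcome-weighted learning zeroes out every subject whose later
observed treatments disagree with the already-fitted later rules. The
augmented weights restore them: with `Q̂_{T+1} = 0`,

    Ŷ_t = |Y_t + Q̂_{t+1} - μ̂_t(H_t)| ,   Â_t = A_t · sign(Y_t + Q̂_{t+1} - μ̂_t(H_t)),

where `Q̂_{t+1}` combines the IPW future reward with regression corrections
`μ̂_{t+1,j}(H_j)` for subjects whose stage-j treatment is not the
recommended one, and `μ̂_t` removes the main effect to reduce weight
variance. Both nuisance families are linear least-squares fits (the
`μ_{t,j}` weighted by agreement indicators of stages `t+1..T` and the
printed propensity products); misspecifying them costs efficiency, not
consistency. Sign flips change the hinge objective only by a constant (an
identity that is exact on the hinge's linear region `|f| ≤ 1`), so the
risk constraint always uses the *original* treatments and the hinge the
pseudo-treatments. `sign(0) := +1` everywhere.

Modes: `brdtr` (full procedure), `unconstrained` (`τ = ∞` everywhere; the
augmented-OWL comparator), `naive` (stage 1 weighs the raw cumulative
outcome `Σ_t Y_t` with no delayed-effect adjustment, keeping the stage-1
constraint; later stages as in `brdtr`).

## DC iteration and the stage QP

`ψ` is a difference of convex functions, and the stage problem is solved
by iterating convex QPs: keep one convex piece of each point's risk term
as a slack variable, linearize the other at the current iterate, solve,
re-linearize. Two decompositions are implemented:

- **progressive** (default): `ψ = (m+η)₊/η − (m)₊/η`. A point currently
  on its observed-treatment side contributes its full risk no matter the
  margin size, so the subproblem can re-select the risky set in one step.
- **anchored**: `ψ = [1 + (−m−η)₊/η] − (−m)₊/η`. Risk relief is granted
  only at the rate earned at the current margins, so iterates stay close
  to their initialization.

The split is applied pointwise by the **sign of the risk**: the generative
models (and real risks after recentering) can produce negative `R_i`, and
keeping a slack with a negative coefficient in the constraint row would
let the solver void the constraint; negative-risk points therefore swap
which piece is kept as slack. Both splits over-approximate `ψ`, so every
feasible iterate is ramp-feasible and the hinge objective is monotone
nonincreasing along DC iterations (stopping at absolute change < 1e-6 or
50 iterations).

The inner QP is solved by an in-package dense primal-dual interior-point
method (Mehrotra predictor-corrector, infeasible start, common
primal-dual step length). It works in explicit feature coordinates — raw
features for the linear kernel, `Q Λ^{1/2}` from the eigendecomposition of
the jittered Gram matrix (`+1e-8·I`) for the Gaussian — so the Newton
system reduces, after analytic elimination of the diagonal slack blocks
and a Sherman-Morrison update for the single risk row, to a
`(p+1)×(p+1)` ridge system whose Cholesky cannot fail. Scaling weights
are capped at 1e10 and the risk row is norm-equilibrated; the iteration
targets a scaled KKT merit of 1e-8 and accepts the best iterate below
1e-4 when degenerate active sets stall further progress (margins pinned
exactly at the ramp kinks make some degeneracy intrinsic). A final
"polish" re-solves the last subproblem with the budget tightened by any
finite-precision excess, so returned feasible fits satisfy the empirical
ramp constraint to 1e-6.

**Initialization.** DC starts from the unconstrained hinge-SVM solution
(one QP; if it already satisfies the constraint it is returned as the
optimum). When the linearized subproblem at that warm start is infeasible
— common when the unconstrained rule's follower risk exceeds the budget —
the iteration restarts from the most permissive linearization (a virtual
iterate granting every point its maximal relief), which is feasible
whenever any ramp-feasible rule of unrestricted magnitude is.

**Unattainable budgets.** With a restricted function class (notably linear
kernels) the budget can sit below the class's attainable risk. A phase-1
DC that minimizes the empirical ramp risk itself (risk term moved into the
QP objective, always well-posed) then certifies attainability: if its
least-risk rule meets the budget, constrained DC restarts from it;
otherwise that rule is returned flagged infeasible with the attainable
minimum in the diagnostics. This replaces a hard error because the
near-boundary regime is scientifically meaningful (the reference
simulation setting I runs its stage-2 budget essentially at the linear
class's attainable minimum) and a least-risk rule is the natural answer
there.

## Tuning

The cost `C = (2nλ)⁻¹` is selected per stage by 2-fold cross-validation
over powers of two, `2^-10..2^10` (full 21-point grid, or the every-other
11-point subgrid as the fast default). The default criterion,
`safe_value`, maximizes the held-out weighted value among costs whose
held-out 0-1 risk is within the budget plus one standard error of that
estimate (the CV 1-SE rule), falling back to the minimum-held-out-risk
cost when no candidate passes. The screening matters: the constraint
binds on the training half only, and with a flexible kernel an aggressive
cost can exhaust the budget with overfitted margins whose held-out risk
far exceeds it — a pure value criterion selects exactly those fits.
Unscreened `value` and a QP-dual criterion are selectable; both readings
of a "maximize the Lagrange dual" rule turn out to be monotone in the
cost and select an endpoint of the grid, which is why neither is the
default. Stage-wise `η` may differ; `η` itself is a prespecified input
(default 0.02), not tuned.

## Synthetic settings

Two built-in two-stage generators draw `X ~ U[0,1]^8`, randomize both
treatments with probability 1/2, add `N(0,1)` reward noise and
`U[-0.5,0.5]` risk noise, and record `H_1 = X`,
`H_2 = (X, A_1, Y_1, R_1)`. Setting I is linear in the evolving history
with a delayed effect (the stage-2 reward depends on the realized stage-1
reward and treatment; its printed stage-2 risk also depends on the
realized stage-2 reward, which we transcribe literally by generating `Y_2`
first). Setting II makes the stage-2 benefit quadratic in `(X_1, X_2)` —
the optimal stage-2 boundary is a circle — and loads the stage-2 risk
entirely on the stage-1 arm (`R_2 = 1 + A_2(2A_1+2) + ε`), which makes the
stage-2 risk effect degenerate on the `A_1 = -1` arm (flagged by the
feasibility diagnostics) and produces negative risks on part of the
support. Covariate and noise streams are seeded separately from the
treatment stream, so evaluating a policy regenerates identical covariates.
These generators emulate the benefit-risk tension of staged trials; they
do not emulate missingness, censoring, non-randomized assignment (beyond
the logistic-propensity toggle), or risks violating the acute-risk
assumption — passing tests say nothing about those features of real data.

`feasible_tau_range` reports Monte-Carlo estimates of the minimum
(risk-minimizing rule) and maximum (reward-maximizing rule) achievable
stage risks from the known treatment-effect terms; a meaningful budget
lies strictly between them.

## Evaluation

Two estimators: the **normalized IPW** estimator on held-out randomized
data (agreement indicators over propensities, normalized by the weight
sum; stage risks use single-stage weights, valid under the acute-risk
assumption) and the **oracle** estimator (regenerate a large population
with treatments assigned by the policy; plain means). They agree within
Monte-Carlo error for value and stage-1 quantities but differ for stage-2
ones, whose test population composition depends on the stage-1 policy;
the replicate harness defaults to the normalized IPW estimator on a
randomized draw, which is how simulation tables are conventionally
reported. Replicate summaries give the median and the median absolute
deviation from the median.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| `eta` | 0.02 | ramp shift (surrogate tightness), unitless margin scale |
| `tau` | `inf` | per-stage risk budget, units of the risk outcome |
| `cost` grid | `2^-10..2^10` (step 2²) | SVM cost `C = (2nλ)⁻¹` |
| `cv_folds` | 2 | cross-validation folds |
| `dc_tol` | 1e-6 | absolute objective change stopping DC |
| `dc_max_iter` | 50 | DC iteration cap |
| `qp_tol` | 1e-6 | feasibility tolerance on the returned fit |
| Gram jitter | 1e-8 | strict positive definiteness of training Grams |

Test-suite problem sizes: unit tests use n = 10–80; the end-to-end checks
use single n = 400 fits and 10-replicate studies with the 11-point grid
and N = 20000 test draws, which keeps the default run at desk scale; the
full 21-point grid and larger replicate counts are available through the
same interfaces.

## Known limitations

- The DC iteration finds a local optimum of a nonconvex problem; results
  can depend on the initialization (deliberately deterministic here).
  With heavily delayed benefit and tight budgets, different
  initializations can land on risk-conservative versus budget-exhausting
  local solutions with very different values.
- Budgets near the class-attainable minimum produce fits whose held-out
  risk can exceed the budget by the generalization gap of the
  near-minimal-risk rule.
- Error accumulates backward over stages; many-stage problems (large T)
  will be driven mostly by the risk constraints.
- Nuisance models are linear; no cross-fitting.
- One binary treatment and one risk constraint per stage.
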