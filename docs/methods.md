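# Methods

## Problem class

`sigbvp` approximates solutions of nonlinear singular two-point
boundary-value problems

    y''(x) + (a + m/x) y'(x) = f(x, y),   0 <= x <= 1,

with Robin boundary rows `eta1*y(0) + xi1*y'(0) = gamma1` and
`eta2*y(1) + xi2*y'(1) = gamma2`. The advection coefficient `m/x` blows up
at the left endpoint, which is what makes this class awkward for standard
shooting and collocation codes. Problems of this shape arise in
physiological modelling: oxygen diffusion in a spherical cell with
Michaelis–Menten uptake kinetics (a = 0, m = 2), heat distribution in the
human head (a = 0, m = 2), tumour-growth models (a = 0, m = 0, 1, 2), and
thermal explosion in a cylindrical vessel (m = 1).

Three benchmarks with closed-form solutions are bundled:

| name | ODE | left BC | right BC | exact |
|---|---|---|---|---|
| example1 | `y'' + y'/x = -e^y` | `y'(0)=0` | `y(1)=0` | `2 ln((c+1)/(c x^2+1))`, `c = 3-2*sqrt(2)` |
| example2(m) | `y'' + (1+m/x) y' = 5x^3 (5x^5 e^y - x - m - 4)/(4+x^5)` | `y'(0)=0` | `y(1)+5y'(1) = ln(1/5)-5` | `-ln(4+x^5)` |
| example3(m) | same as example2 | `y(0)=ln(1/4)` | same as example2 | same as example2 |

Each bundled problem stores the analytic first *and* second derivative of
its exact solution, so residual checks and error tables involve no
numerical differentiation.

## Trial solution

The approximation is a linear combination of n log-sigmoid basis functions

    y(x) = sum_i alpha_i * phi(b_i x + c_i),    phi(z) = 1/(1+e^-z),

with 3n free parameters (default n = 10, hence a 30-dimensional search).
Because `phi' = phi(1-phi)` and `phi'' = phi(1-phi)(1-2phi)`, the first and
second derivatives of the trial solution are exact closed forms — no
autodiff, no finite differences. The chromosome layout is
`[alpha_1..alpha_n, b_1..b_n, c_1..c_n]`; the printed reference optima are
transcribed per basis index, so the layout choice only affects seeding
reproducibility, and one layout had to be fixed.

## Fitness

Parameters are judged by `eps = eps1 + eps2`:

* `eps1` — mean squared ODE residual over a collocation grid. The default
  grid is the 11 closed equispaced points `i/10, i = 0..10`. At the
  singular endpoint the term `m y'/x` is replaced by its limit `m y''(0)`
  (L'Hôpital; exact whenever `y'(0) = 0`, which holds for every bundled
  problem's solution including the Dirichlet-left case). An open grid
  `i/11, i = 1..11` that simply avoids x = 0 is selectable
  (`grid_scheme="open-equispaced"`); the two schemes correspond to the two
  grid renderings in the source material and the closed one is the default
  because it is the general statement of the functional.
* `eps2` — half the sum of squared Robin-row violations at both endpoints,
  with unit weight by default (`bc_weight` is exposed but 1 preserves the
  reference formulation).

Wild parameter vectors can overflow `e^y`; non-finite residuals map to an
infinite total rather than an exception, so optimizers discard such
individuals naturally.

## Optimization

**Genetic algorithm** (global stage), all settings exposed in `GAConfig`
with the benchmark defaults: population 240, chromosome length 30, up to
2000 generations, genes bounded in [-15, 15], elitism (2), stochastic
uniform selection, heuristic crossover, adaptive feasible mutation,
function tolerance 1e-18 with a 50-generation stall window. The named
operators are toolbox conventions rather than uniquely defined algorithms;
the concrete semantics used here are:

* *selection*: rank scaling with expectation `1/sqrt(rank)` followed by
  stochastic-universal sampling (one spin, k equally spaced pointers).
  Rank scaling is necessary because raw fitness spans many orders of
  magnitude; proportional selection on raw values collapses instantly.
* *crossover* (80% of non-elite slots): `child = worse + r*R*(better -
  worse)` with one `r ~ U(0,1)` per child and ratio R = 1.2, clipped to the
  box.
* *mutation* (remaining slots): per-gene step `scale * U(0,1) *
  (range/100)` with random sign, clipped; `scale` starts at 1, multiplies
  by 4 after a generation that improved the best fitness and by 1/4
  otherwise, clamped to [1e-6, 1].

The whole population is evaluated vectorized (one einsum over
population × basis × grid), which is what makes the full benchmark
settings run in about two seconds per GA stage on one core.

**Local refinement** (`refine`): bound-constrained minimization from the
GA's best vector, as an adapter over `scipy.optimize.minimize` —
`trust-constr` for the interior-point flavour (cap 1000 iterations),
`SLSQP` for the active-set/SQP flavour (cap 400), both with the 150000
function-evaluation cap and the printed 1e-18 tolerances passed through
(anything below double-precision resolution simply defers termination to
the iteration cap). The returned point is never worse than the start; a
non-finite start is perturbed once and otherwise rejected.

Gradients are analytic by default: the fitness is exactly differentiable
through the sigmoid chain (`phi'`, `phi''`, `phi'''`) and `df/dy`, which
every bundled problem supplies. Central differences (step 1e-6) remain
available as `gradient="central"`. For the interior-point flavour the
solver is additionally given the Gauss–Newton Hessian `J^T J` of the
sum-of-squares objective (exact at a zero-residual minimum); with a
quasi-Newton model alone the 1000-iteration cap strands the polish several
orders of magnitude short, whereas the Gauss–Newton model reliably reaches
fitness ~1e-11 and below. This curvature choice is this package's own
numerical decision and the only place it deliberately departs from the
quasi-Newton description of the reference settings.

**Hybrids and restarts**: `GA-IPA` / `GA-ASA` feed the GA best into the
refiner; standalone `IPA` / `ASA` start from a seed-pinned uniform random
point in the box (the reference description is ambiguous about standalone
starts; this is flagged as an interpretation). With `restarts = k` the
pipeline repeats with seeds `base, base+1, ..., base+k-1` and the winner is
chosen by **total fitness only** — the exact solution is never consulted
during optimization, mirroring real use where no exact solution exists.

## Error reporting

`error_report` evaluates the expansion on the reporting grid 0, 0.1, ..., 1
(fixed independently of the collocation grid, matching all printed tables)
and uses the signed convention `error = exact - approx`; the published
"absolute error" tables actually print these signed values, which is how
the convention was pinned down. `max_abs_error` is the max over the grid.

## Reference parameter sets

Eight 30-parameter reference optima are bundled as plain-text tables
(`sigbvp/tables/*.tsv`) and addressable by `load_fixture` and the CLI
`reconstruct` subcommand. Six of the eight reproduce their printed solution
columns to every printed digit; they serve as the anti-drift regression on
the expansion evaluation. Two source defects were found while transcribing
and are handled as follows:

* In the example1 solution table the columns labelled "GA-IPA" and "ASA"
  are swapped relative to the parameter and error tables. The signed-error
  columns are self-consistent with the parameter sets (the GA-IPA
  parameter block yields exactly the printed GA-IPA error column, maximum
  3.99e-6), so the parameter tables are taken as authoritative and tests
  assert against the swap-corrected columns.
* The example3 (m = 0.25) GA-IPA parameter block is corrupted at source:
  its last bias duplicates the first verbatim, and the block does not
  reproduce any printed solution column (value -0.447 instead of -1.609 at
  x = 1). Exhaustive least-squares repairs of up to three entries and of
  every row pair leave residuals >= 1.7e-5, far above print precision, so
  no defensible reconstruction exists. The block ships as transcribed,
  flagged in its file header, and the corresponding reconstruction test is
  expected to fail — it documents the defect rather than hiding it.

## Verification strategy

* Exact solutions and both boundary rows are checked symbolically-in-spirit:
  the closed forms with their analytic derivatives must annihilate the
  assembled residual (`eps1 < 1e-10`, `eps2 < 1e-12`) on both grid schemes
  for every example and m in {0.25, 0.75, 1, 2, 8} — the strongest check of
  the residual assembly including the singular-limit rule.
* Expansion derivatives are cross-checked against central finite
  differences on random expansions across the whole search box, and the
  analytic fitness gradient against a numeric gradient.
* Optimizer invariants: elitism makes the best-fitness trace
  non-increasing; every evaluated individual stays in the box (asserted by
  instrumenting the objective); identical seeds give identical traces;
  refinement never worsens its start.
* End to end, the hybrid GA + interior-point pipeline under the full
  benchmark settings, best of 10 restarts, reaches a maximum absolute error
  of ~5e-7 on example1 — comfortably below the reported 3.99e-6 — in about
  45 seconds on one core.

## Limitations

* The named GA operators and the commercial optimizer internals they
  allude to have no unique published definitions; this implementation fixes
  reasonable semantics and exposes every knob, but does not bit-reproduce
  any particular toolbox trajectory.
* The method is heuristic: per-seed GA outcomes scatter over one to two
  orders of magnitude in fitness, and only the restart-and-refine pipeline
  is accuracy-stable. Standalone GA/IPA/ASA error magnitudes are
  order-of-magnitude outcomes, not regression surfaces.
* Scope is the scalar problem class above on [0, 1]: no systems, no other
  domains, no alternative basis families (tanh, RBF, polynomials).
* n = 10 sigmoids cap the attainable accuracy near 1e-7 on these
  benchmarks; the limit is representational, not an optimizer failure.
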