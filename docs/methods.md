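# Methods

## Model class

Each target gene *i* is modeled independently by a complex-valued ODE

    dZ_i/dt = Σ_k β_k · e_k(Z),

with complex coefficients β_k and expressions e_k over the complex gene
states Z_1…Z_m drawn from the grammar below.  Relative to a real-valued
ODE of the same shape, the complex coefficients double the parameter space
per term and let a single term encode damped/rotational couplings; the
real-valued model class is the special case of real coefficients with the
`embed` conversion (an invariant checked in the tests).

A directed edge j→i is declared whenever x_j occurs anywhere in gene i's
fitted equation.  No coefficient-magnitude threshold is applied: a term
kept by the search counts, however small its coefficient.  The candidate
edge space is all m² ordered pairs, self-loops included — network
sensitivity/specificity are computed over exactly that universe, which is
also the convention under which the reference benchmark counts are
consistent (e.g. 6 genes, 7 true regulations, 29 negatives).

## Expression grammar

Structures are derivation trees of the context-free grammar

    s    → expr
    expr → expr op expr | pre expr | var
    pre  → sin | cos
    op   → + | − | × | ÷
    var  → x_1 | … | x_m

Tree depth is counted in node levels; the minimal complete derivation
s→expr→var→x_k has depth 4.  Initial trees are drawn with depth budget 6;
genetic operators enforce a hard cap of 10 and retry (crossover) or bound
the regrowth budget (mutation) otherwise.  During random derivation a
production is only eligible if it can still complete within the remaining
budget, which guarantees termination; eligible productions are chosen
uniformly.  Integer powers are expressed as repeated multiplication
(x² ≡ x·x), so the grammar covers every published benchmark equation shape
with the minimal terminal set.

Decoding to a model splits the tree's outermost chain of +/− operators
into signed additive terms, one complex coefficient per term; −
contributes the sign, so a coefficient vector of length K always pairs
with exactly K top-level terms.  Evaluation always walks the tree —
sentences (token yields) exist for display and testing only.

## Data pipeline

Expression matrices are min–max normalized, g′ = (g − min)/(max − min),
per gene by default (each series spans [0,1]; a global scope is available
by flag).  A constant series maps to zeros with a warning.

Real↔complex conversion supports three invertible modes:

| mode | forward | inverse | note |
| --- | --- | --- | --- |
| `embed` | z = g + 0i | Re z | lossless for real dynamics |
| `phase45` (default) | z = g·e^{iπ/4} | \|z\| | equal re/im loading |
| `unit_phase` | z = e^{iπg} | arccos(Re z)/π | unit-circle embedding |

`phase45` is the pipeline default because a purely real embedding makes
the imaginary parts of coefficients nearly unobservable in a real-valued
fitness.  The mode is recorded in every result's config snapshot, and
model output is always back-converted with the same mode the input used.

## Fitness and integration

Fitness is the training-window prediction RMSE: the candidate equation is
integrated from the first training sample and the back-converted real
trajectory is compared with the observed series.  Trajectory fitting
(rather than derivative matching) is what the held-out benchmark metric
actually measures, so the search optimizes the quantity that is reported.

Integration is classic RK4 with a fixed step of one sample interval split
into 4 substeps (configurable).  Fitting is *decoupled*: only the target
gene is integrated, the other genes entering as linear interpolations of
the observed data at the RK4 stage times.  Division is protected — a
denominator with |b| < 1e-6 is replaced by 1e-6·b/|b| (or 1e-6 when b = 0)
— because quotients over data normalized to [0,1] routinely meet
near-zeros.  If |Z| exceeds 1e6, or any evaluation overflows, the
candidate is marked divergent and assigned a penalty fitness of 1e9
instead of being discarded, which keeps the population size constant.

## Structure search (GGGP)

Tournament selection (size 3) with elitism 1, subtree crossover at a
shared nonterminal (probability 0.9), grammar-guided point mutation
(probability 0.1): a nonterminal node is regrown from its own symbol
within the depth cap, a terminal leaf is replaced by a terminal admissible
in the same production slot.  Population 50, 100 generations by default
(the validation studies use 30), early stop when the best RMSE falls
below 1e-8.

Coefficients of structurally new individuals are initialized by complex
least squares on finite differences: β̂ = argmin ‖ΔZ_i/Δt − Σ β_k e_k(Z)‖²
with term values taken at interval midpoints (second-order pairing — the
left-endpoint variant is visibly biased and misleads the search).  This
classic two-step surrogate makes a correct structure recognizably good the
moment it appears, at the cost of one small lstsq per individual; the
trajectory-RMSE fitness, not the surrogate, remains the selection signal.

Selection and the returned best use fitness plus a parsimony penalty of
5e-4 per tree node; reported fitness is always the pure RMSE.  The penalty
scale is set to the order of the decoupled-integration residual on
unit-scaled data: below it, a spurious extra term can always buy an RMSE
improvement smaller than the modeling error it exploits, silently
inflating the regulator set.  The best-RMSE trace reported by `evolve` is
tracked separately and is non-increasing by construction.

## Coefficient search (CFA)

A swarm of complex coefficient vectors scored by the same fitness.
Canonical firefly updates act on the 2K-dimensional real/imaginary
unfolding — real and imaginary parts move in parallel.  Per iteration,
fireflies are ranked once (ties by index); for each firefly from the
brightest down, every strictly dimmer firefly takes one
attraction-plus-random step toward its current position; the single
brightest firefly takes a pure random step (a standard anti-stagnation
variant); then the whole swarm is re-scored.  This round formulation
vectorizes the O(P²) pair loop without changing the per-pair rule.

Defaults: population 100, step size α = 0.02 (the published operating
point of the method), attractiveness β₀ = 1, initialization uniform in
[−5, 5]² per coefficient, 50 iterations, no α-decay (a geometric decay
flag exists).  The absorption coefficient is γ = 1/(2·init_radius)² =
0.01: with γ = 1 the attraction kernel exp(−γr²) underflows at typical
inter-firefly distances in more than one complex dimension and the swarm
measurably degenerates into a pure random walk (its convex-objective
improvement guarantee fails).  Scaling γ to the squared domain width is
the standard remedy.

CFA refits the coefficients of the current best individual (structure
fixed) every 5 generations and once more at the end.  The incumbent
vector is seeded as firefly 0, so a refit can never return something
worse than the incumbent.

## Per-gene orchestration

`infer_network` normalizes, embeds, evolves one model per gene on the
first n_train samples, and assembles the network as the union of per-gene
regulator sets.  Gene i's random generator is seeded as seed + i, so runs
are deterministic and independent of execution order.  Held-out RMSE
integrates each fitted model from the last training sample across the
test window.  The result carries a full config snapshot (all parameters,
seed, conversion mode).

## Synthetic generator

`random_system` draws, per gene, a regulator set (each ordered pair kept
with probability edge_density, at least one regulator forced), then 1–2
shallow random term trees over those regulators with coefficients uniform
in a complex box of half-width 1.  Defaults — 2 genes, 40 samples at
spacing 0.2, no noise — describe the small noise-free benchmark regime
the validation studies use.  Three screens make the ground truth
meaningful:

* stability: the coupled trajectory must stay within |Z| ≤ 1e3
  (rejection-resampled up to 100 draws);
* functional dependence: every syntactic regulator must actually move the
  RHS (finite-difference probe), excluding degenerate terms like x/x or
  x−x whose edges no method could recover from data;
* dynamic range: every gene's converted series must move by at least 0.05.

Simulation integrates the full system *coupled* (all genes at once) —
deliberately not the decoupled scheme used in fitting, mirroring how the
method meets real data — then converts to real, adds Gaussian noise, and
min–max normalizes.  Initial states are the complex conversion of uniform
values in [0.2, 0.8], avoiding the normalization boundaries.

The canonical recovery study (`cvgrn.studies`) uses real generating
coefficients with the `embed` mode, normalization off, 46 points split
40/6.  With complex coefficients every conversion mode's real projection
is lossy, so the projected data is not generated by any member of the
search class under decoupled integration and "exact recovery" would be
ill-posed; the real/embed configuration keeps the generating system as
the exact ground truth of what the fitter observes, while the fitter
itself still searches complex coefficients.  What passing this study
shows: the pipeline identifies exact regulator sets and near-zero
held-out error on small identifiable systems.  What it does not show:
performance on lossy projections, larger networks, or real microarray
noise — the generator has no measurement model beyond additive Gaussian
noise, no missing data, and no unobserved regulators.

## Numerical and reporting conventions

* RMSE per gene over the evaluation window, then the arithmetic mean
  across genes for "averaged" rows; sensitivity Sn = TP/(TP+FN) and
  specificity Sp = TN/(TN+FP) over all m² ordered pairs.  Reporting uses
  4 decimals for Sn/Sp and 6 for RMSE (full precision internally).
* Ranking ties everywhere break by index; all stochastic components draw
  from one numpy Generator per gene, so fixed seeds give bit-identical
  results.
* Study sizes in the test suite (2-gene systems, populations 10–50, 3–30
  generations, 10 seeds) were chosen as the smallest instances that
  exercise every pipeline stage with clearly interpretable ground truth.

## Known limitations

* Per-gene decoupled fitting cannot represent feedback tighter than the
  sampling interval and inherits an O(dt²) residual from interpolating
  regulator trajectories.
* The regulator read-off has no significance control; on noisy data the
  parsimony penalty is the only guard against spurious edges.
* Grammar-guided search scales poorly beyond tens of genes; the variable
  set grows the search space linearly but the identifiability of sparse
  regulator sets degrades much faster.
* The three conversion modes are design choices, not mechanistic claims;
  conclusions that depend on the specific complex embedding should be
  checked under more than one mode.
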