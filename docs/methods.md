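# Methods

This note documents the models, numerical choices and limitations of
`l1dynamics`. Everything quantitative stated here is computed by the test
suite or the analysis scripts; nothing is asserted that the code does not
verify.

## Model and units

All rates are per expected nucleotide substitution per site — the unit of the
input trees' branch lengths. Time runs from 0 at the tips (present) toward
the root. Epoch boundaries for change-point models are supplied in
generations before present and converted by multiplying with the substitution
rate (default 2.5×10⁻⁸ per nucleotide per generation, the value standardly
used for human L1 phylogenies); `UnitConversion` owns this constant and the
conversion is exercised at the published boundaries (140 generations →
3.5×10⁻⁶; 4720 → 1.18×10⁻⁴ substitutions/site).

The BiSSE likelihood interprets each internal node as an L1 insertion event:
λ_i is the rate at which a lineage in activity state i gives rise to a new
detectable insertion, μ_i the rate at which an insertion lineage is removed,
and q01/q10 the activity transition rates. Activity is binarized at 25% of
the reference element L1_RP; a value exactly at the threshold is coded
*high* (the threshold and the tie rule are configurable). Tips without an
activity value are coded *unknown* and enter the pruning with partial
likelihood 1 in both states rather than being dropped.

## BiSSE likelihood: numerics

The canonical extinction/partial-likelihood ODE system is integrated along
branches tipward-to-rootward. Two structural facts are exploited:

- On an ultrametric tree E(t) is one global function, so it is integrated
  once per likelihood call (LSODA, rtol 1e-8, atol 1e-12) and evaluated by
  cubic Hermite interpolation on a rate-scaled grid (≥50 points per unit of
  total-rate × time). The interpolation, rather than the integrator's dense
  output, is what makes the likelihood cheap enough for multi-start ML.
- Given E(t), the D-system is linear, so each branch segment contributes a
  2×2 transfer matrix, computed by an exponential midpoint rule: the
  segment is split into substeps (count scaled by the E-change across the
  segment and capped at total-rate × h ≤ 0.003; a flat-E segment needs one,
  then exact, step), A(t) is frozen at each substep midpoint, and the
  closed-form 2×2 exponentials are composed by a log-depth pairwise
  reduction, all vectorized across the whole tree. Pruning then reduces to
  2×2 matrix algebra with per-node renormalization (a log-scale accumulator
  prevents underflow at rates of several hundred per unit branch length).
- When μ0 = μ1 = 0 (the best-fitting regime for L1 data), E ≡ 0 and each
  segment's transfer matrix has the closed form
  e^{mt}[cosh(Δt)I + sinh(Δt)/Δ (B − mI)], computed in a stable
  exponential-difference form. This path is exact and ~50× faster; it makes
  the parameter-recovery experiments tractable on one CPU.

Agreement between this path and an independent fixed-step RK4 pruning
oracle (tests/oracles.py, step chosen so total-rate × h ≤ 5e-3) is verified
to ≤1e-6 relative on 50 random instances; observed discrepancies are ≤5e-8
(≤1e-9 in the no-extinction regime, where the path is exact). Negative partial likelihoods in [−1e-9·scale, 0) are clamped to
zero; anything lower raises an error naming the node. Trees are accepted as
ultrametric when the root-to-tip spread is ≤1e-3 of the depth (posterior
samples carry numerical slack); the Mk2 path imposes no such restriction.

Change points: both speciation rates are multiplied by a shared per-epoch
factor in epochs older than each boundary; μ and q are unchanged. Branches
spanning a boundary are split there (segmentation memoized per tree ×
change-point specification), so E and D are continuous across boundaries. A
time exactly on a boundary belongs to the older epoch — hence a boundary at
the present rescales the whole process, and one older than the root has no
effect (warned, since there is no root edge to absorb it).

Root treatment: the data do not determine it, so it is an explicit option
recorded in every fit — default weights each root state by its relative
partial likelihood (the standard default of diversification software), with
flat, q-stationary and fixed-state alternatives; conditioning on survival of
the two root lineages is off by default. Likelihood pooling over a tree
sample is the log of the *sum* of per-tree likelihoods (log-sum-exp); versus
a mean this differs by log N, constant across models, so AIC differences are
unaffected.

## Constrained ML fitting

Nine constraint sets (unconstrained; μ0=μ1; λ0=λ1; q01=q10; μ0=μ1=0; λ0=0;
q01=0; μ0=μ1=λ0=0; μ0=μ1=q01=0) with df 6,5,5,5,4,5,5,3,3. Optimization is
L-BFGS-B on log-transformed free parameters — equivalent optimum to a
linear-scale constrained optimizer, but unconstrained internally and far
better conditioned when rates span λ0≈10 to λ1≈400. Multi-start: one
deterministic start at the Yule scale ((n−1)/T for speciation rates, half
that for transitions, a tenth for extinctions) plus seeded log-uniform draws
on [1e-2, 1e4]; default 10 starts (3 suffice in practice: in 60 paired
trials the 3-start and 10-start optima agreed to <1e-3 log-units).
Non-finite likelihoods during search are penalized, not fatal. AIC is
computed from full-precision log-likelihoods; ranking ties are broken by
fewer df, then constraint id. Change-point fits add one free multiplier per
boundary (log-scale, started at 1); a boundary deeper than every tree in the
sample leaves its multiplier unidentifiable and is flagged rather than
rejected. Pinning multipliers (e.g. at 1) still counts them in df — the
"wasted df" diagnostic that must cost exactly +2 AIC per boundary.

## Growth dynamics

The 2×2 system dx/dt = [[λ0−μ0−q01, q10],[q01, λ1−μ1−q10]]x has a real
spectrum whenever the off-diagonals are non-negative, so the dominant
eigenvalue is solved from the quadratic in closed form and the dominant
eigenvector taken non-negative and normalized to sum 1 (its second entry is
the equilibrium fraction of high-activity copies). For a diagonal matrix the
fraction degenerates to 0 or 1 (0.5 on an exact tie). A forward integration
oracle propagates composition and log-total separately (no overflow at large
t) and must reproduce the eigenvalue to 0.1% and the stationary fractions to
0.5 percentage points on random matrices. At the published best-fit rates
the matrix is [[−21, 360],[31, 52]], the growth rate 127.27 insertions per
substitution (3.18×10⁻⁶ per generation; doubling time 2.18×10⁵ generations)
and the equilibrium fraction of high-activity copies 29.2%. The published
equilibrium figure of 25% is not reproduced from the rounded published
rates; the difference presumably reflects unrounded internal estimates, and
this package reports what its inputs imply rather than forcing the printed
value.

## Mk2 and reversible-jump MCMC

The two-state CTMC transition matrix is closed-form; Felsenstein pruning
with per-node rescaling gives the likelihood on arbitrary rooted trees, with
root frequencies defaulting to the stationary pair (q10, q01)/(q01+q10).

Priors are independent exponentials with mean 100 per free rate — matched to
the scale of L1 activity-transition estimates, and a declared choice (the
original Bayesian analysis does not state its priors). The sampler updates,
per iteration: the tree index (uniform proposal over the sample,
Metropolis-accepted — a proper joint sampler over (rates, tree), slightly
stricter than the always-swap heuristic of trait-evolution packages); each
free rate (log-normal random walk, sd 0.5, acceptance-rate warning outside
[0.05, 0.9]); and with probability 0.3 a reversible jump to one of the other
three constraint models, drawing the new model's rates from their priors so
that proposal and prior densities cancel and the acceptance ratio reduces to
the likelihood ratio. Burn-in defaults to 25%, thinning to 10. Sampler
correctness is checked by switching the likelihood off: the chain must then
reproduce the prior's model probabilities (¼ each) and the exponential
moments within Monte-Carlo error. A model with q01 = 0 assigns likelihood
zero to any dataset whose high-activity tips require a low→high transition,
so its posterior probability collapses on such data — the mechanism behind
the published <0.0002.

## Synthetic data

The Gillespie simulator draws per-lineage waiting times from the total rate
λ_i(+multiplier)+μ_i+q_i and picks events proportionally. Stop rules:

- *n-tips*: the tree is cut at a uniformly drawn time inside the interval
  during which exactly n lineages coexist (cutting at the n-th birth itself
  would create zero-length tip branches and bias the tip-adjacent branch
  lengths short).
- *max-time*: fixed duration; required for change-point truths, whose
  boundaries are ages before present and are only known in forward time when
  the end is fixed.

Extinct lineages are pruned and pass-through nodes suppressed, so the
reconstructed tree is exactly ultrametric by construction. Defaults emulate
the study's data shape: 155 tips, truth rates (10, 412, 0, 0, 31, 360), 150
trees. Under that truth the expected tip composition (the dominant
eigenvector, ~29% high) brackets the 24.5% observed in the real data.
Posterior spread is emulated by multiplicative log-normal jitter (sd 0.05)
of internal node heights, clipped above children to preserve
ultrametricity — a labeled stand-in, *not* a posterior: it perturbs branch
lengths but never topology, so pooled fits on the bundle understate real
phylogenetic uncertainty. Raw activities are drawn conditional on the binary
state (truncated exponential, scale 8, below 25; 25 plus a log-normal with
log-mean log 30, log-sd 1 above), so binarization at 25% recovers the
generating states exactly; the real activity distribution is not modeled
beyond respecting the threshold, as no generative description of assay
values exists to calibrate against.

What a green test establishes: that the inference machinery recovers the
parameters of its own generating process at realistic sizes. What it cannot
establish: anything about alignment, tree-estimation or ascertainment errors
in real L1 data — trees are consumed here, never inferred.

## Known limitations

- A change-point boundary only a few hundred generations old corresponds to
  a sliver of ~1e-6..1e-5 substitutions at the tips. The tree's internal
  nodes then constrain only the product of multiplier and base rates, so
  the multiplier itself sits on a near-flat likelihood ridge and ordinary
  overfitting gains (~χ²₁-scale, about one log-unit per extra df) can carry
  it far from 1 on data with no true rate shift. Judge such models by
  their AIC, not by the multiplier's point value.

- Single-tree ML at 150 tips cannot reliably order λ1 (412) against q10
  (360): their estimates cross in roughly a fifth of replicates, although
  median relative errors are ~10%. Rank claims about parameters this close
  need either more data or model-averaged inference.
- No MuSSE/HiSSE generalizations, no sampling-fraction correction, no
  density-dependence or host-coevolution feedback; growth is exponential by
  construction.
- The reversible-jump proposal draws new rates from the prior; mixing across
  models is adequate for the four-model space but would not scale to larger
  model sets without smarter bridge proposals.
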