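# l1dynamics

State-dependent diversification analysis of LINE-1 (L1) retrotransposition
activity in human genomes.

L1 elements are the only autonomously active retrotransposons in humans. Each
full-length genomic L1 insertion can be placed on a phylogeny, and its
cell-culture retrotransposition activity (percent of the reference element
L1_RP, binarized at 25%) treated as a binary character. This package
implements the comparative machinery to ask, from such data:

1. do high-activity L1s spawn new detectable insertions faster?
2. is there an evolutionary drift from high toward low activity?
3. did the population-level insertion rate change at known human
   demographic events (140 and 4720 generations ago)?
4. is the genomic L1 count growing, and how fast?

## The models

**BiSSE** (Binary State Speciation and Extinction). A lineage in activity
state *i* ∈ {0 = low, 1 = high} speciates (produces a new detectable
insertion) at rate λ_i, goes extinct (is removed from the population) at rate
μ_i, and flips state with rates q01, q10, all per substitution/site. The
likelihood of binary tip states on an ultrametric tree is computed by
post-order pruning with per-branch integration of

    dE_i/dt = μ_i − (λ_i + μ_i + q_ij) E_i + q_ij E_j + λ_i E_i²
    dD_i/dt = −(λ_i + μ_i + q_ij) D_i + q_ij D_j + 2 λ_i E_i D_i

and node joins D_i = λ_i D_i^left D_i^right. Nine constraint sets on the six
rates are fitted by constrained maximum likelihood (pooled over a tree sample
by log-sum-exp) and ranked by AIC = 2·df − 2·logL. A change-point extension
multiplies both speciation rates by a shared per-epoch factor in epochs older
than boundaries given in generations (converted at 2.5×10⁻⁸ substitutions per
nucleotide per generation).

**Growth dynamics.** The fitted rates define linear dynamics for the expected
numbers x = (n_low, n_high) of L1 copies:

    dx/dt = [[λ0−μ0−q01, q10], [q01, λ1−μ1−q10]] x

whose dominant eigenvalue is the asymptotic L1 growth rate (insertions per
nucleotide substitution) and whose eigenvector is the equilibrium
low/high-activity mix. Dividing ln 2 by the per-generation rate gives the
doubling time of the genomic L1 count.

**Mk2 + reversible-jump MCMC.** The diversification-free counterpart: the
activity state evolves as a two-state Markov chain on the tree (any branch
lengths), and a reversible-jump sampler moves among the four rate-constraint
models (free, q01=q10, q01=0, q10=0), yielding posterior model probabilities
and rate posteriors while resampling trees to integrate over phylogenetic
uncertainty.

**Synthetic data.** A Gillespie simulator of the state-dependent
birth–death–transition process generates ultrametric trees with tip states
(plus raw activity values and posterior-like branch-length jitter), so every
inference stage is testable against known truth without any sequence data.

## Worked example

```python
from l1dynamics import (BisseParams, SimConfig, TreeSample, simulate_bisse,
                        builtin_constraints, fit_model, build_matrix,
                        asymptotic_growth)

truth = BisseParams(lambda0=10, lambda1=412, mu0=0, mu1=0, q01=31, q10=360)
sim = simulate_bisse(SimConfig(params=truth, n_tips=150, seed=11))
constraint = {c.id: c for c in builtin_constraints()}["mu0=mu1=0"]
fit = fit_model(TreeSample([sim.tree]), sim.states, constraint, n_starts=3, seed=0)
print({k: round(v, 1) for k, v in fit.params.as_dict().items()})
res = asymptotic_growth(build_matrix(fit.params))
print(round(res.r_sub, 1), round(res.fraction_high, 3))
```

prints (estimates from one simulated 150-tip dataset; truth above)

```
{'lambda0': 14.0, 'lambda1': 418.3, 'mu0': 0.0, 'mu1': 0.0, 'q01': 22.2, 'q10': 299.8}
158.4 0.357
```

i.e. the fit recovers the strong asymmetries of the truth (λ1 ≫ λ0, q10 ≫
q01), and the implied asymptotic growth rate is ~158 insertions per
substitution with ~36% high-activity copies at equilibrium.

With the published best-fit rates themselves, `asymptotic_growth` gives
127.27 insertions per nucleotide substitution, a per-generation growth rate
of 3.18×10⁻⁶ and a doubling time of 2.18×10⁵ generations.

## Analysis pipeline

Numbered drivers under `analysis/` write tables to `results/` (the bulky
simulated tree bundle from 01 goes to `scratch/fixtures/` and is regenerated
on demand):

| script | what it does |
| --- | --- |
| `01_simulate.py` | synthetic stand-in dataset: 155-tip tree at the best-fit rates, 150 jittered copies, activity table |
| `02_fit_models.py` | nine constrained ML fits, AIC model table |
| `03_fit_changepoints.py` | change-point extensions (140; 140+4720 generations) of the best model |
| `04_growth_rate.py` | growth matrix, dominant eigenvalue, doubling time, equilibrium mix |
| `05_mcmc_transitions.py` | reversible-jump MCMC over Mk2 rate constraints |

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
recomputes the growth-dynamics numbers from scratch: it builds the 2×2
dynamics matrix from the best-fitting rates, extracts the dominant eigenvalue
in closed form, cross-checks it by forward integration of the linear system,
converts units at 2.5×10⁻⁸ substitutions/nucleotide/generation, and writes
the asymptotic growth rate, per-generation rate and doubling times as JSON.
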