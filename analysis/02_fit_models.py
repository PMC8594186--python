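"""Fit the nine constraint models and build the AIC comparison table.

Pools the likelihood (log-sum-exp over trees) across a subsample of the
fixture bundle's trees — 5 of the 150, which keeps the free-extinction
models tractable on one CPU while exercising the pooling path — and
ranks the models by AIC.  On data simulated under mu0 = mu1 = 0, the
mu0 = mu1 = 0 constraint should tie the unconstrained log-likelihood and
win on parsimony, mirroring the published comparison.
"""

from pathlib import Path

from l1dynamics import (
    TreeSample,
    binarize_activity,
    builtin_constraints,
    fit_model,
    model_table,
    read_tip_states,
    read_tree_sample,
)
from l1dynamics.fitting import save_fits

ROOT = Path(__file__).resolve().parent.parent
FIX = ROOT / "scratch" / "fixtures"
N_TREES = 5
N_STARTS = 2
SEED = 1


def main() -> None:
    sample = read_tree_sample(str(FIX / "trees.nwk"))
    sample = TreeSample(sample.trees[:N_TREES])
    states = binarize_activity(read_tip_states(str(FIX / "activities.tsv")))
    # fit the no-extinction model first and warm-start the slower
    # free-extinction fits from its optimum (nested-model sequence)
    cons = builtin_constraints()
    cons.sort(key=lambda c: 0 if c.id == "mu0=mu1=0" else 1)
    warm = None
    fits = []
    for c in cons:
        fit = fit_model(sample, states, c, n_starts=N_STARTS, seed=SEED, init=warm)
        if c.id == "mu0=mu1=0":
            warm = fit.params
        fits.append(fit)
        pstr = ", ".join(f"{k}={v:.3g}" for k, v in fit.params.as_dict().items() if v)
        print(f"{c.id:24s} df={fit.df}  logL={fit.loglik:9.3f}  AIC={fit.aic:9.3f}  {pstr}")
    tbl = model_table(fits)
    out_tsv = ROOT / "results" / "model_table.tsv"
    tbl.to_csv(out_tsv, sep="\t", index=False)
    save_fits(fits, str(ROOT / "results" / "fits.json"))
    best = tbl.iloc[0]
    print(f"\nbest model: {best['constraint']} (AIC {best['aic']:.2f}); table -> {out_tsv}")


if __name__ == "__main__":
    main()
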