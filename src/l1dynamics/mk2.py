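"""Two-state Markov (Mk2) trait model and Bayesian transition-rate inference.

This is the diversification-free counterpart of the BiSSE analysis: the
binary activity state evolves along the tree as a continuous-time Markov
chain with rates q01 (low -> high) and q10 (high -> low), with no effect
on branching.  The likelihood is Felsenstein pruning with the closed-form
2-state transition probabilities, so arbitrary (non-ultrametric) branch
lengths are allowed.  Posterior inference runs Metropolis-Hastings on
log-rates, integrates over phylogenetic uncertainty by Metropolis moves
on the tree index within a posterior-like tree sample, and (optionally)
jumps between four rate-constraint models by reversible jump, yielding
posterior model probabilities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .treeio import UNKNOWN, PhyloTree, TipStates, TreeSample

__all__ = [
    "Mk2Params",
    "MK2_MODELS",
    "Mk2Priors",
    "McmcTrace",
    "mk2_transition_probs",
    "mk2_stationary",
    "mk2_loglik",
    "run_mcmc",
    "posterior_summary",
]


@dataclass(frozen=True)
class Mk2Params:
    q01: float
    q10: float

    def __post_init__(self) -> None:
        for name in ("q01", "q10"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


#: The four rate-constraint models visited by the reversible-jump sampler.
MK2_MODELS = ("free", "equal", "q01_zero", "q10_zero")


def mk2_transition_probs(p: Mk2Params, t: float) -> np.ndarray:
    """Closed-form 2-state CTMC transition matrix P(t); rows sum to 1.

    P00(t) = (q10 + q01 e^{-(q01+q10) t}) / (q01 + q10); identity when
    both rates are zero.
    """
    if t < 0:
        raise ValueError(f"branch length must be >= 0, got {t}")
    s = p.q01 + p.q10
    if s == 0:
        return np.eye(2)
    e = math.exp(-s * t)
    p00 = (p.q10 + p.q01 * e) / s
    p11 = (p.q01 + p.q10 * e) / s
    return np.array([[p00, 1.0 - p00], [1.0 - p11, p11]])


def mk2_stationary(p: Mk2Params) -> np.ndarray:
    """Stationary state frequencies (uniform when both rates are zero)."""
    s = p.q01 + p.q10
    if s == 0:
        return np.array([0.5, 0.5])
    return np.array([p.q10 / s, p.q01 / s])


def mk2_loglik(
    tree: PhyloTree,
    states: TipStates,
    p: Mk2Params,
    root_freqs: np.ndarray | None = None,
) -> float:
    """Felsenstein-pruning log-likelihood of binary tip states under Mk2.

    No ultrametricity requirement.  ``root_freqs`` defaults to the
    stationary frequencies of the rate pair.  Unknown tips contribute a
    partial likelihood of 1 in both states.
    """
    if root_freqs is None:
        root_freqs = mk2_stationary(p)
    root_freqs = np.asarray(root_freqs, dtype=float)
    state_arr = states.state_array(tree)

    # per-node transition matrix along the edge above the node
    s = p.q01 + p.q10
    bl = tree.branch_length
    if s == 0:
        P = np.tile(np.eye(2), (tree.n_nodes, 1, 1))
    else:
        e = np.exp(-s * bl)
        p00 = (p.q10 + p.q01 * e) / s
        p11 = (p.q01 + p.q10 * e) / s
        P = np.empty((tree.n_nodes, 2, 2))
        P[:, 0, 0] = p00
        P[:, 0, 1] = 1.0 - p00
        P[:, 1, 1] = p11
        P[:, 1, 0] = 1.0 - p11

    L = np.zeros((tree.n_nodes, 2))
    L[: tree.n_tips][state_arr == 0, 0] = 1.0
    L[: tree.n_tips][state_arr == 1, 1] = 1.0
    L[: tree.n_tips][state_arr == UNKNOWN] = 1.0
    logscale = 0.0
    for node in tree.postorder_internal():
        node = int(node)
        lft, rgt = int(tree.left[node]), int(tree.right[node])
        down = (P[lft] @ L[lft]) * (P[rgt] @ L[rgt])
        tot = down.sum()
        if tot <= 0:
            return -math.inf
        L[node] = down / tot
        logscale += math.log(tot)
    lik = float(root_freqs @ L[tree.root])
    if lik <= 0:
        return -math.inf
    return math.log(lik) + logscale


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Mk2Priors:
    """Independent exponential priors on each free rate.

    The default mean of 100 (per substitution/site) matches the scale of
    transition rates seen for L1 activity evolution; it is a declared
    choice, not inferred from any published analysis.
    """

    mean_q01: float = 100.0
    mean_q10: float = 100.0

    def logpdf(self, name: str, value: float) -> float:
        mean = self.mean_q01 if name == "q01" else self.mean_q10
        if value < 0:
            return -math.inf
        return -math.log(mean) - value / mean

    def draw(self, name: str, rng: np.random.Generator) -> float:
        mean = self.mean_q01 if name == "q01" else self.mean_q10
        return float(rng.exponential(mean))


@dataclass
class McmcTrace:
    """Thinned MCMC samples plus the chain settings that produced them."""

    data: pd.DataFrame  # iteration, model, q01, q10, tree_index, loglik
    seed: int
    n_iter: int
    thin: int
    rj: bool
    acceptance: dict[str, float]

    def __len__(self) -> int:
        return len(self.data)

    def to_tsv(self, path: str) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def _rates_of(model: str, free: dict[str, float]) -> Mk2Params:
    if model == "free":
        return Mk2Params(free["q01"], free["q10"])
    if model == "equal":
        return Mk2Params(free["q"], free["q"])
    if model == "q01_zero":
        return Mk2Params(0.0, free["q10"])
    return Mk2Params(free["q01"], 0.0)


_FREE_NAMES = {
    "free": ("q01", "q10"),
    "equal": ("q",),
    "q01_zero": ("q10",),
    "q10_zero": ("q01",),
}


def _prior_name(free_name: str) -> str:
    # the shared rate of the equal model uses the q01 prior
    return "q10" if free_name == "q10" else "q01"


def run_mcmc(
    sample: TreeSample,
    states: TipStates,
    priors: Mk2Priors = Mk2Priors(),
    n_iter: int = 10_000,
    seed: int = 0,
    rj: bool = True,
    thin: int = 10,
    proposal_sd: float = 0.5,
    rj_prob: float = 0.3,
    sample_prior: bool = False,
    init_model: str = "free",
) -> McmcTrace:
    """Metropolis-Hastings sampler for the Mk2 transition rates.

    Each iteration updates, in order: the tree index (uniform proposal
    over the sample, Metropolis-accepted, which integrates over
    phylogenetic uncertainty), every free rate (log-normal random walk),
    and, when ``rj`` is on, the model indicator (uniform proposal among
    the other constraint models with the new free rates drawn from their
    priors, so prior and proposal densities cancel and the acceptance
    ratio is the likelihood ratio times the model-prior ratio, here 1).
    With ``sample_prior`` the likelihood is switched off, which must
    reproduce the prior — a standard sampler-correctness check.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    model = init_model if rj else "free"
    free = {name: priors.draw(_prior_name(name), rng) for name in _FREE_NAMES[model]}
    tree_idx = int(rng.integers(len(sample)))

    def loglik(m: str, fr: dict[str, float], k: int) -> float:
        if sample_prior:
            return 0.0
        return mk2_loglik(sample[k], states, _rates_of(m, fr))

    def logprior(fr: dict[str, float]) -> float:
        return sum(priors.logpdf(_prior_name(n), v) for n, v in fr.items())

    ll = loglik(model, free, tree_idx)
    n_models = len(MK2_MODELS)
    acc = {"tree": 0, "rate": 0, "jump": 0}
    tries = {"tree": 0, "rate": 0, "jump": 0}
    rows = []

    for it in range(n_iter):
        # -- tree move
        if len(sample) > 1:
            tries["tree"] += 1
            k_new = int(rng.integers(len(sample)))
            ll_new = loglik(model, free, k_new)
            if math.log(rng.random()) < ll_new - ll:
                tree_idx, ll = k_new, ll_new
                acc["tree"] += 1

        # -- rate moves (log-normal random walk; Jacobian term r'/r)
        for name in _FREE_NAMES[model]:
            tries["rate"] += 1
            old = free[name]
            new = old * math.exp(proposal_sd * rng.standard_normal())
            free_new = dict(free)
            free_new[name] = new
            ll_new = loglik(model, free_new, tree_idx)
            pn = _prior_name(name)
            logr = (
                ll_new
                - ll
                + priors.logpdf(pn, new)
                - priors.logpdf(pn, old)
                + math.log(new)
                - math.log(old)
            )
            if math.log(rng.random()) < logr:
                free, ll = free_new, ll_new
                acc["rate"] += 1

        # -- reversible jump between constraint models
        if rj and rng.random() < rj_prob:
            tries["jump"] += 1
            others = [m for m in MK2_MODELS if m != model]
            m_new = others[int(rng.integers(len(others)))]
            free_new = {
                name: priors.draw(_prior_name(name), rng) for name in _FREE_NAMES[m_new]
            }
            ll_new = loglik(m_new, free_new, tree_idx)
            # uniform model prior; prior == proposal for the new rates
            if math.log(rng.random()) < ll_new - ll:
                model, free, ll = m_new, free_new, ll_new
                acc["jump"] += 1

        if (it + 1) % thin == 0 or it == n_iter - 1:
            p = _rates_of(model, free)
            rows.append(
                {
                    "iteration": it + 1,
                    "model": model,
                    "q01": p.q01,
                    "q10": p.q10,
                    "tree_index": tree_idx,
                    "loglik": ll,
                }
            )

    rates_acc = acc["rate"] / max(tries["rate"], 1)
    if not (0.05 <= rates_acc <= 0.9) and tries["rate"] >= 200:
        warnings.warn(
            f"rate-move acceptance {rates_acc:.2f} outside [0.05, 0.9]; "
            "consider adjusting proposal_sd",
            stacklevel=2,
        )
    acceptance = {k: acc[k] / max(tries[k], 1) for k in acc}
    return McmcTrace(
        data=pd.DataFrame(rows),
        seed=seed,
        n_iter=n_iter,
        thin=thin,
        rj=rj,
        acceptance=acceptance,
    )


def posterior_summary(trace: McmcTrace, burnin_frac: float = 0.25) -> dict:
    """Model posterior probabilities and rate summaries after burn-in."""
    if len(trace) == 0:
        raise ValueError("empty trace")
    n_burn = int(len(trace) * burnin_frac)
    post = trace.data.iloc[n_burn:]
    if len(post) == 0:
        raise ValueError("burn-in removed every sample")
    model_probs = {m: float((post["model"] == m).mean()) for m in MK2_MODELS}
    out = {"n_samples": int(len(post)), "model_probs": model_probs}
    for rate in ("q01", "q10"):
        v = post[rate].to_numpy()
        out[rate] = {
            "mean": float(v.mean()),
            "median": float(np.median(v)),
            "ci95": [float(np.quantile(v, 0.025)), float(np.quantile(v, 0.975))],
        }
    return out
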