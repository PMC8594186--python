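"""Independent brute-force oracles used only by the test suite.

These deliberately share no code with the package's likelihood path:
classic per-branch pruning carrying (E0, E1, D0, D1) jointly with a
fixed-step fourth-order Runge-Kutta integrator, scalar Python arithmetic
throughout.  Slow but transparent.
"""

from __future__ import annotations

import math

import numpy as np

from l1dynamics.bisse import BisseParams, ChangePointSpec, RootOptions
from l1dynamics.treeio import UNKNOWN, PhyloTree, TipStates, UnitConversion


def _rhs(y, lam0, lam1, mu0, mu1, q01, q10):
    E0, E1, D0, D1 = y
    return (
        mu0 - (lam0 + mu0 + q01) * E0 + q01 * E1 + lam0 * E0 * E0,
        mu1 - (lam1 + mu1 + q10) * E1 + q10 * E0 + lam1 * E1 * E1,
        -(lam0 + mu0 + q01) * D0 + q01 * D1 + 2.0 * lam0 * E0 * D0,
        -(lam1 + mu1 + q10) * D1 + q10 * D0 + 2.0 * lam1 * E1 * D1,
    )


def _rk4_segment(y, t0, t1, rates, max_rate_h=5e-3):
    lam0, lam1, mu0, mu1, q01, q10 = rates
    total = max(lam0 + mu0 + q01, lam1 + mu1 + q10, 1.0)
    length = t1 - t0
    if length <= 0:
        return y
    n = max(20, int(math.ceil(total * length / max_rate_h)))
    h = length / n
    for _ in range(n):
        k1 = _rhs(y, *rates)
        y2 = tuple(a + 0.5 * h * b for a, b in zip(y, k1))
        k2 = _rhs(y2, *rates)
        y3 = tuple(a + 0.5 * h * b for a, b in zip(y, k2))
        k3 = _rhs(y3, *rates)
        y4 = tuple(a + h * b for a, b in zip(y, k3))
        k4 = _rhs(y4, *rates)
        y = tuple(
            a + (h / 6.0) * (b1 + 2 * b2 + 2 * b3 + b4)
            for a, b1, b2, b3, b4 in zip(y, k1, k2, k3, k4)
        )
    return y


def rk4_bisse_loglik(
    tree: PhyloTree,
    states: TipStates,
    params: BisseParams,
    cp: ChangePointSpec | None = None,
    conv: UnitConversion = UnitConversion(),
    root: RootOptions = RootOptions(),
    max_rate_h: float = 5e-3,
) -> float:
    """Fixed-step RK4 pruning oracle for the (possibly change-point) BiSSE likelihood."""
    p = params
    cp_sub = cp.in_substitutions(conv) if cp is not None else None
    times = tree.node_times()
    state_by_tip = states.state_array(tree)

    def mult_at(t: float) -> float:
        return cp_sub.multiplier_at(t) if cp_sub is not None else 1.0

    def integrate_branch(y, lo, hi):
        bounds = []
        if cp_sub is not None:
            bounds = [b for b in cp_sub.boundaries if lo < b < hi]
        cuts = [lo] + bounds + [hi]
        for a, b in zip(cuts[:-1], cuts[1:]):
            m = mult_at(0.5 * (a + b))
            rates = (p.lambda0 * m, p.lambda1 * m, p.mu0, p.mu1, p.q01, p.q10)
            y = _rk4_segment(y, a, b, rates, max_rate_h)
        return y

    logscale = 0.0
    partial: dict[int, tuple] = {}
    for i in range(tree.n_tips):
        s = state_by_tip[i]
        if s == 0:
            D = (1.0, 0.0)
        elif s == 1:
            D = (0.0, 1.0)
        else:
            D = (1.0, 1.0)
        partial[i] = (0.0, 0.0) + D  # E starts at 0 at the present

    E_root = None
    for node in tree.postorder_internal():
        node = int(node)
        children = (int(tree.left[node]), int(tree.right[node]))
        tops = []
        for c in children:
            lo = max(float(times[c]), 0.0)
            hi = float(times[node])
            tops.append(integrate_branch(partial[c], lo, hi))
        m = mult_at(float(times[node]))
        lam = (p.lambda0 * m, p.lambda1 * m)
        E = (0.5 * (tops[0][0] + tops[1][0]), 0.5 * (tops[0][1] + tops[1][1]))
        D = (lam[0] * tops[0][2] * tops[1][2], lam[1] * tops[0][3] * tops[1][3])
        scale = D[0] + D[1]
        if scale <= 0:
            return -math.inf
        logscale += math.log(scale)
        partial[node] = E + (D[0] / scale, D[1] / scale)
        if node == tree.root:
            E_root = E

    E0, E1, D0, D1 = partial[tree.root]
    if root.mode == "weighted":
        tot = D0 + D1
        w = (D0 / tot, D1 / tot)
    elif root.mode == "flat":
        w = (0.5, 0.5)
    elif root.mode == "equilibrium":
        qs = p.q01 + p.q10
        w = (p.q10 / qs, p.q01 / qs) if qs > 0 else (0.5, 0.5)
    else:
        w = (1.0, 0.0) if root.fixed_state == 0 else (0.0, 1.0)
    lik = w[0] * D0 + w[1] * D1
    if root.condition_on_survival:
        m = mult_at(float(times[tree.root]))
        denom = w[0] * p.lambda0 * m * (1 - E0) ** 2 + w[1] * p.lambda1 * m * (1 - E1) ** 2
        lik /= denom
    return math.log(lik) + logscale


def logsumexp_highprec(values) -> float:
    """Log-sum-exp via extended-precision accumulation."""
    vals = [v for v in values if v != -math.inf]
    if not vals:
        return -math.inf
    m = max(vals)
    acc = np.longdouble(0)
    for v in vals:
        acc += np.exp(np.longdouble(v - m))
    return float(np.log(acc) + np.longdouble(m))


def expm_transition_probs(q01: float, q10: float, t: float) -> np.ndarray:
    """Matrix-exponential oracle for the 2-state CTMC transition matrix."""
    from scipy.linalg import expm

    Q = np.array([[-q01, q01], [q10, -q10]])
    return expm(Q * t)
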