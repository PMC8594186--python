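"""Forward simulation of trees and tip activities under known parameters.

Gillespie simulation of the state-dependent birth-death-transition
process: each lineage in activity state i speciates at rate lambda_i
(times the epoch multiplier under a change-point truth), goes extinct at
rate mu_i, and flips state at rate q_ij.  Extinct lineages are pruned to
produce the reconstructed (ultrametric) tree that the inference stages
consume; raw activity values are layered on top of the binary states so
the binarization step can be exercised end to end.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .bisse import BisseParams, ChangePointSpec
from .treeio import (
    UNKNOWN,
    PhyloTree,
    TipStates,
    TreeSample,
    UnitConversion,
    write_tip_states,
    write_tree_sample,
)

__all__ = [
    "SimConfig",
    "ActivityModel",
    "SimResult",
    "simulate_bisse",
    "simulate_activities",
    "jitter_tree",
    "make_fixture_bundle",
]


@dataclass(frozen=True)
class SimConfig:
    """Truth parameters and stop rule for one simulated dataset.

    Exactly one of ``n_tips`` (stop when the n-th extant lineage is born;
    the tree is cut at a uniform time inside the interval during which n
    lineages coexist, which avoids the bias of cutting at the birth event
    itself) or ``max_time`` (simulate a fixed duration) must be set.
    Change-point truths require ``max_time``: epoch boundaries are ages
    before present and are only known in forward time when the total
    duration is fixed.
    """

    params: BisseParams
    n_tips: int | None = None
    max_time: float | None = None
    cp: ChangePointSpec | None = None
    conv: UnitConversion = UnitConversion()
    root_state: int | str = "stationary"
    seed: int = 0
    max_retries: int = 1000

    def __post_init__(self) -> None:
        if (self.n_tips is None) == (self.max_time is None):
            raise ValueError("set exactly one of n_tips or max_time")
        if self.n_tips is not None and self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        if self.max_time is not None and not self.max_time > 0:
            raise ValueError("max_time must be > 0")
        if self.cp is not None and self.max_time is None:
            raise ValueError("change-point truths require the max_time stop rule")
        if isinstance(self.root_state, int) and self.root_state not in (0, 1):
            raise ValueError("root_state must be 0, 1 or 'stationary'")


@dataclass(frozen=True)
class ActivityModel:
    """Distribution of raw activity (percent of L1_RP) given the binary state.

    Low-activity tips draw from an exponential (scale ``low_scale``)
    truncated to [0, threshold); high-activity tips draw threshold plus a
    log-normal spread, emulating the wide range of hot-element assay
    values.  By construction binarizing the simulated activities at
    ``threshold`` returns exactly the input states.
    """

    threshold: float = 25.0
    low_scale: float = 8.0
    high_log_mean: float = math.log(30.0)
    high_log_sd: float = 1.0

    def draw(self, state: int, rng: np.random.Generator) -> float:
        u = rng.random()
        if state == 1:
            z = rng.standard_normal()
            return self.threshold + math.exp(self.high_log_mean + self.high_log_sd * z)
        # inverse-CDF truncated exponential keeps draws strictly below threshold
        cap = 1.0 - math.exp(-self.threshold / self.low_scale)
        return -self.low_scale * math.log1p(-u * cap)


@dataclass
class SimResult:
    """Output of one forward simulation."""

    tree: PhyloTree  # reconstructed, ultrametric, extant tips only
    complete_tree: PhyloTree | None  # includes extinct tips (None if identical)
    states: TipStates
    cut_time: float
    n_retries: int
    root_state: int


class _Lineage:
    __slots__ = ("parent", "t_birth", "state", "t_end", "children", "alive", "tip_state")

    def __init__(self, parent: int, t_birth: float, state: int) -> None:
        self.parent = parent
        self.t_birth = t_birth
        self.state = state
        self.t_end: float | None = None
        self.children: list[int] = []
        self.alive = True
        self.tip_state: int | None = None


def _forward_multiplier(cfg: SimConfig, t: float) -> float:
    """Speciation multiplier at forward time t (0 = root side)."""
    if cfg.cp is None:
        return 1.0
    age = cfg.max_time - t  # type: ignore[operator]
    return cfg.cp.in_substitutions(cfg.conv).multiplier_at(max(age, 0.0))


def _epoch_edges_forward(cfg: SimConfig) -> list[float]:
    if cfg.cp is None or cfg.max_time is None:
        return []
    cp_sub = cfg.cp.in_substitutions(cfg.conv)
    return sorted(cfg.max_time - b for b in cp_sub.boundaries if 0 < b < cfg.max_time)


def simulate_bisse(cfg: SimConfig, rng: np.random.Generator | None = None) -> SimResult:
    """Simulate one dataset; retries (up to ``cfg.max_retries``) on extinction."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    p = cfg.params
    for attempt in range(cfg.max_retries + 1):
        result = _simulate_once(cfg, p, rng)
        if result is not None:
            tree, complete, tip_states, cut_time, root_state = result
            labels = tree.tip_labels
            states = TipStates({lab: tip_states[lab] for lab in labels})
            return SimResult(tree, complete, states, cut_time, attempt, root_state)
    raise RuntimeError(
        f"all lineages went extinct in {cfg.max_retries + 1} attempts; "
        "the parameter regime appears subcritical for this stop rule"
    )


def _simulate_once(cfg, p, rng):
    if cfg.root_state == "stationary":
        qsum = p.q01 + p.q10
        p_high = p.q01 / qsum if qsum > 0 else 0.5
        root_state = int(rng.random() < p_high)
    else:
        root_state = int(cfg.root_state)

    lineages = [_Lineage(-1, 0.0, root_state)]
    active = [0]
    t = 0.0
    epoch_edges = _epoch_edges_forward(cfg)
    target = cfg.n_tips
    cut_time: float | None = None

    while True:
        mult = _forward_multiplier(cfg, t)
        rates = np.array(
            [
                (p.lambda0 * mult + p.mu0 + p.q01)
                if lineages[i].state == 0
                else (p.lambda1 * mult + p.mu1 + p.q10)
                for i in active
            ]
        )
        total = float(rates.sum())
        if total <= 0:
            if cfg.max_time is not None:
                t = cfg.max_time
                cut_time = t
                break
            return None
        dt = rng.exponential(1.0 / total)
        next_edge = next((e for e in epoch_edges if e > t + 1e-15), None)
        if next_edge is not None and t + dt > next_edge:
            t = next_edge  # rate regime changes; redraw waiting time
            continue
        if cfg.max_time is not None and t + dt >= cfg.max_time:
            t = cfg.max_time
            cut_time = t
            break
        if target is not None and len(active) == target:
            # n lineages coexist on [t, t+dt); cut uniformly inside
            cut_time = t + rng.random() * dt
            break
        t += dt
        idx = active[int(rng.choice(len(active), p=rates / total))]
        lin = lineages[idx]
        s = lin.state
        lam = (p.lambda0 if s == 0 else p.lambda1) * mult
        mu = p.mu0 if s == 0 else p.mu1
        q = p.q01 if s == 0 else p.q10
        u = rng.random() * (lam + mu + q)
        if u < lam:  # speciation: two daughters
            lin.t_end = t
            lin.alive = False
            for _ in range(2):
                lineages.append(_Lineage(idx, t, s))
                lin.children.append(len(lineages) - 1)
            active.remove(idx)
            active.append(lin.children[0])
            active.append(lin.children[1])
        elif u < lam + mu:  # extinction
            lin.t_end = t
            lin.alive = False
            active.remove(idx)
            if not active:
                if cfg.max_time is not None:
                    return None
                return None
        else:  # state flip
            lin.state = 1 - s

    survivors = [i for i in active]
    if target is not None and len(survivors) != target:
        return None
    if cfg.max_time is not None and len(survivors) < 2:
        return None
    for i in survivors:
        lineages[i].t_end = cut_time
        lineages[i].tip_state = lineages[i].state

    recon = _build_reconstructed(lineages, survivors, cut_time)
    complete = None  # complete tree retained only when extinction occurred
    if any((not lineages[i].alive) and not lineages[i].children for i in range(len(lineages))):
        complete = _build_complete(lineages, survivors, cut_time)
    tree, tip_states = recon
    return tree, complete, tip_states, cut_time, root_state


def _build_reconstructed(lineages, survivors, cut_time):
    """Prune extinct lineages and suppress pass-through nodes."""
    keep = set()
    for i in survivors:
        j = i
        while j != -1 and j not in keep:
            keep.add(j)
            j = lineages[j].parent

    # children within the kept subgraph, after suppressing unary nodes
    def kept_children(i):
        out = []
        for c in lineages[i].children:
            if c in keep:
                out.append(c)
        return out

    def resolve(i):
        """Follow unary chains down to the next branching or surviving tip."""
        while True:
            ch = kept_children(i)
            if len(ch) == 1 and i not in survivors:
                i = ch[0]
            else:
                return i

    root = resolve(0)
    n_tips = len(survivors)
    tip_ids = sorted(survivors, key=lambda i: lineages[i].t_birth)
    tip_index = {lin_id: k for k, lin_id in enumerate(tip_ids)}
    labels = [f"t{k + 1}" for k in range(n_tips)]
    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    left = np.full(n_nodes, -1, dtype=np.int64)
    right = np.full(n_nodes, -1, dtype=np.int64)
    blen = np.zeros(n_nodes)
    next_internal = [n_tips]
    tip_states: dict[str, int] = {}

    def node_time(i):
        return lineages[i].t_end if lineages[i].t_end is not None else cut_time

    def build(i, top_time):
        """Returns the flat index for resolved lineage i."""
        i = resolve(i)
        ch = kept_children(i)
        if i in survivors and not ch:
            k = tip_index[i]
            tip_states[labels[k]] = lineages[i].tip_state
            blen[k] = cut_time - top_time
            return k
        assert len(ch) == 2
        me = next_internal[0]
        next_internal[0] += 1
        t_me = node_time(i)
        blen[me] = t_me - top_time
        a = build(ch[0], t_me)
        b = build(ch[1], t_me)
        left[me], right[me] = a, b
        parent[a] = me
        parent[b] = me
        return me

    root_idx = build(root, lineages[root].t_birth)
    blen[root_idx] = 0.0
    tree = PhyloTree(labels, parent, left, right, blen, root_idx)
    return tree, tip_states


def _build_complete(lineages, survivors, cut_time):
    """Binary tree over all lineages (extinct tips included); may be non-ultrametric."""
    tips = [
        i
        for i in range(len(lineages))
        if not lineages[i].children and (lineages[i].t_end is not None)
    ]
    n_tips = len(tips)
    if n_tips < 2:
        return None
    tip_index = {lin_id: k for k, lin_id in enumerate(tips)}
    labels = [
        (f"x{k + 1}" if tips[k] not in survivors else f"s{k + 1}") for k in range(n_tips)
    ]
    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    left = np.full(n_nodes, -1, dtype=np.int64)
    right = np.full(n_nodes, -1, dtype=np.int64)
    blen = np.zeros(n_nodes)
    counter = [n_tips]

    def build(i, top_time):
        lin = lineages[i]
        if not lin.children:
            k = tip_index[i]
            blen[k] = lin.t_end - top_time
            return k
        me = counter[0]
        counter[0] += 1
        blen[me] = lin.t_end - top_time
        a = build(lin.children[0], lin.t_end)
        b = build(lin.children[1], lin.t_end)
        left[me], right[me] = a, b
        parent[a] = me
        parent[b] = me
        return me

    root_idx = build(0, 0.0)
    blen[root_idx] = 0.0
    return PhyloTree(labels, parent, left, right, blen, root_idx)


def simulate_activities(
    states: TipStates,
    model: ActivityModel = ActivityModel(),
    seed: int = 0,
) -> TipStates:
    """Draw raw activity values consistent with the given binary states.

    Binarizing the result at ``model.threshold`` recovers the input states
    exactly; tips with UNKNOWN state receive no activity value.
    """
    rng = np.random.default_rng(seed)
    activity: dict[str, float] = {}
    for label in states.states:
        s = states.states[label]
        if s == UNKNOWN:
            continue
        activity[label] = model.draw(s, rng)
    return TipStates(dict(states.states), activity)


def jitter_tree(
    tree: PhyloTree, sd: float, rng: np.random.Generator
) -> PhyloTree:
    """Multiplicative log-normal jitter of internal node heights.

    A cheap stand-in for posterior branch-length spread: each internal
    node height is scaled by exp(sd * z) and clipped above its children,
    preserving ultrametricity and topology.  NOT a posterior sample.
    """
    times = tree.node_times().copy()
    new_times = times.copy()
    new_times[: tree.n_tips] = 0.0
    for node in tree.postorder_internal():
        node = int(node)
        z = rng.standard_normal()
        h = times[node] * math.exp(sd * z)
        lo = max(new_times[int(tree.left[node])], new_times[int(tree.right[node])])
        new_times[node] = max(h, lo * (1.0 + 1e-12))
    blen = tree.branch_length.copy()
    for node in range(tree.n_nodes):
        if node == tree.root:
            blen[node] = 0.0
        else:
            blen[node] = new_times[int(tree.parent[node])] - new_times[node]
    return PhyloTree(
        tree.tip_labels, tree.parent.copy(), tree.left.copy(), tree.right.copy(),
        blen, tree.root,
    )


def make_fixture_bundle(
    cfg: SimConfig,
    n_trees: int,
    out_dir: str,
    jitter_sd: float = 0.05,
    activity_model: ActivityModel = ActivityModel(),
) -> dict[str, str]:
    """Write a synthetic stand-in for the study's inputs.

    Produces ``trees.nwk`` (n_trees ultrametric trees: the simulated truth
    with per-tree branch-length jitter emulating posterior spread),
    ``activities.tsv`` (tip_label, activity_percent, state) and
    ``truth.json`` recording the generating parameters and seed.  Byte
    identical for identical inputs.
    """
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    sim = simulate_bisse(cfg, rng)
    states = simulate_activities(sim.states, activity_model, seed=cfg.seed + 1)
    trees = [jitter_tree(sim.tree, jitter_sd, rng) for _ in range(n_trees)]
    paths = {
        "trees": os.path.join(out_dir, "trees.nwk"),
        "activities": os.path.join(out_dir, "activities.tsv"),
        "truth": os.path.join(out_dir, "truth.json"),
    }
    write_tree_sample(TreeSample(trees), paths["trees"])
    write_tip_states(states, paths["activities"])
    n_low, n_high, n_unknown = sim.states.counts()
    truth = {
        "params": cfg.params.as_dict(),
        "change_points": (
            None
            if cfg.cp is None
            else {"boundaries": list(cfg.cp.boundaries), "multipliers": list(cfg.cp.multipliers)}
        ),
        "subst_rate": cfg.conv.subst_rate,
        "seed": cfg.seed,
        "n_tips": sim.tree.n_tips,
        "n_trees": n_trees,
        "jitter_sd": jitter_sd,
        "root_state": sim.root_state,
        "cut_time": sim.cut_time,
        "n_high": n_high,
        "n_low": n_low,
        "fraction_high": n_high / (n_high + n_low),
        "synthetic": "generated stand-in; not derived from any sequence data",
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
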