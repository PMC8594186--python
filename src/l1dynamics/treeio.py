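"""Trees, tip states and unit conversions.

All rates and branch lengths in this package are measured in expected
nucleotide substitutions per site, the unit of the input trees.  Epoch
boundaries for change-point models are specified in generations before
present and converted with :class:`UnitConversion` before any likelihood
sees them.  Time runs from 0 at the tips (present) toward the root.
"""

from __future__ import annotations

import hashlib
import io
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "UNKNOWN",
    "PhyloTree",
    "TreeSample",
    "TipStates",
    "UnitConversion",
    "UltrametryReport",
    "TreeFormatError",
    "TreeValidationError",
    "read_tree_sample",
    "write_tree_sample",
    "check_ultrametric",
    "generations_to_substitutions",
    "binarize_activity",
    "read_tip_states",
    "write_tip_states",
]

#: Sentinel for a tip whose binary activity state is not known.  Unknown
#: tips contribute a partial likelihood of 1 for both states.
UNKNOWN = -1


class TreeFormatError(ValueError):
    """Raised when a newick file cannot be parsed."""


class TreeValidationError(ValueError):
    """Raised when a parsed tree violates the package's structural contract."""


@dataclass(frozen=True)
class UnitConversion:
    """Conversion between generations and substitutions/site.

    Parameters
    ----------
    subst_rate:
        Substitutions per nucleotide per generation.  The default is the
        human germline point-mutation rate of 2.5e-8 commonly used for
        L1 phylogenies.
    """

    subst_rate: float = 2.5e-8

    def __post_init__(self) -> None:
        if not (self.subst_rate > 0 and math.isfinite(self.subst_rate)):
            raise ValueError(f"subst_rate must be positive and finite, got {self.subst_rate}")

    def generations_to_substitutions(self, generations: float) -> float:
        if generations < 0:
            raise ValueError(f"generations must be >= 0, got {generations}")
        return generations * self.subst_rate

    def substitutions_to_generations(self, substitutions: float) -> float:
        if substitutions < 0:
            raise ValueError(f"substitutions must be >= 0, got {substitutions}")
        return substitutions / self.subst_rate


def generations_to_substitutions(generations: float, conv: UnitConversion) -> float:
    """Convert a time in generations before present to branch-length units."""
    return conv.generations_to_substitutions(generations)


class PhyloTree:
    """A rooted binary tree in a flat array representation.

    Nodes ``0 .. n_tips-1`` are tips, in the order of ``tip_labels``;
    internal nodes follow.  ``branch_length[i]`` is the length of the edge
    above node ``i`` (0 for the root).  The representation is immutable by
    convention; transformations return new trees.
    """

    __slots__ = (
        "tip_labels",
        "parent",
        "left",
        "right",
        "branch_length",
        "root",
        "_postorder",
        "_times",
        "_depths",
        "_cache",
    )

    def __init__(
        self,
        tip_labels: Sequence[str],
        parent: np.ndarray,
        left: np.ndarray,
        right: np.ndarray,
        branch_length: np.ndarray,
        root: int,
        validate: bool = True,
    ) -> None:
        self.tip_labels = list(tip_labels)
        self.parent = np.asarray(parent, dtype=np.int64)
        self.left = np.asarray(left, dtype=np.int64)
        self.right = np.asarray(right, dtype=np.int64)
        self.branch_length = np.asarray(branch_length, dtype=float)
        self.root = int(root)
        self._postorder = None
        self._times = None
        self._depths = None
        self._cache = {}  # scratch memo for likelihood segmentations
        if validate:
            self._validate()

    # -- structural properties -------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return self.parent.shape[0]

    def _validate(self) -> None:
        n = self.n_nodes
        ntip = self.n_tips
        if n != 2 * ntip - 1:
            raise TreeValidationError(
                f"binary tree with {ntip} tips must have {2 * ntip - 1} nodes, got {n}"
            )
        if len(set(self.tip_labels)) != ntip:
            raise TreeValidationError("tip labels are not unique")
        if not np.all(np.isfinite(self.branch_length)) or np.any(self.branch_length < 0):
            raise TreeValidationError("branch lengths must be finite and non-negative")
        if self.parent[self.root] != -1:
            raise TreeValidationError("root must have parent -1")
        for i in range(ntip):
            if self.left[i] != -1 or self.right[i] != -1:
                raise TreeValidationError(f"tip {i} has children")
        for i in range(ntip, n):
            if self.left[i] < 0 or self.right[i] < 0:
                raise TreeValidationError(f"internal node {i} is not binary")

    def postorder_internal(self) -> np.ndarray:
        """Internal node indices, children-before-parents."""
        if self._postorder is None:
            order: list[int] = []
            stack = [(self.root, False)]
            while stack:
                node, expanded = stack.pop()
                if node < self.n_tips:
                    continue
                if expanded:
                    order.append(node)
                else:
                    stack.append((node, True))
                    stack.append((int(self.left[node]), False))
                    stack.append((int(self.right[node]), False))
            self._postorder = np.asarray(order, dtype=np.int64)
        return self._postorder

    def depths_from_root(self) -> np.ndarray:
        if self._depths is None:
            depth = np.zeros(self.n_nodes)
            for node in self.postorder_internal()[::-1]:
                for child in (int(self.left[node]), int(self.right[node])):
                    depth[child] = depth[node] + self.branch_length[child]
            self._depths = depth
        return self._depths

    @property
    def depth(self) -> float:
        """Height of the root above the deepest tip."""
        return float(self.depths_from_root()[: self.n_tips].max())

    def node_times(self) -> np.ndarray:
        """Node heights above the present (time 0 at the deepest tips).

        For an ultrametric tree this is exact; for a near-ultrametric tree
        it is the ultrametric reading (tree depth minus root distance).
        """
        if self._times is None:
            self._times = self.depth - self.depths_from_root()
        return self._times

    @property
    def total_branch_length(self) -> float:
        return float(self.branch_length.sum() - self.branch_length[self.root])

    # -- conversion ------------------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "PhyloTree":
        tree = tree.clone(depth=1)
        tree.suppress_unifurcations()
        leaves = [lf for lf in tree.leaf_node_iter()]
        for nd in tree.preorder_node_iter():
            nch = len(nd.child_nodes())
            if nch not in (0, 2):
                raise TreeValidationError(
                    f"tree is not strictly binary: a node has {nch} children"
                )
        tip_labels = []
        for lf in leaves:
            if lf.taxon is not None and lf.taxon.label is not None:
                tip_labels.append(str(lf.taxon.label))
            elif lf.label is not None:
                tip_labels.append(str(lf.label))
            else:
                raise TreeValidationError("unlabeled tip")
        ntip = len(leaves)
        n = 2 * ntip - 1
        parent = np.full(n, -1, dtype=np.int64)
        left = np.full(n, -1, dtype=np.int64)
        right = np.full(n, -1, dtype=np.int64)
        blen = np.zeros(n)
        index = {id(lf): i for i, lf in enumerate(leaves)}
        next_internal = ntip
        for nd in tree.postorder_node_iter():
            if nd.is_leaf():
                continue
            index[id(nd)] = next_internal
            next_internal += 1
        for nd in tree.postorder_node_iter():
            i = index[id(nd)]
            blen[i] = float(nd.edge.length) if nd.edge.length is not None else 0.0
            if not nd.is_leaf():
                ch = nd.child_nodes()
                left[i] = index[id(ch[0])]
                right[i] = index[id(ch[1])]
                parent[left[i]] = i
                parent[right[i]] = i
        root = index[id(tree.seed_node)]
        blen[root] = 0.0
        return cls(tip_labels, parent, left, right, blen, root)

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except Exception as exc:  # dendropy raises various error types
            raise TreeFormatError(f"could not parse newick: {exc}") from exc
        return cls.from_dendropy(tree)

    def to_newick(self) -> str:
        parts: dict[int, str] = {}
        for i in range(self.n_tips):
            parts[i] = f"{_quote_label(self.tip_labels[i])}:{float(self.branch_length[i])!r}"
        for node in self.postorder_internal():
            node = int(node)
            inner = f"({parts[int(self.left[node])]},{parts[int(self.right[node])]})"
            if node == self.root:
                parts[node] = inner + ";"
            else:
                parts[node] = f"{inner}:{float(self.branch_length[node])!r}"
        return parts[self.root]

    def copy(self) -> "PhyloTree":
        return PhyloTree(
            list(self.tip_labels),
            self.parent.copy(),
            self.left.copy(),
            self.right.copy(),
            self.branch_length.copy(),
            self.root,
            validate=False,
        )


def _quote_label(label: str) -> str:
    if any(c in label for c in "()[]{}:;,= \t\n'\""):
        return "'" + label.replace("'", "''") + "'"
    return label


@dataclass
class TreeSample:
    """An ordered collection of trees over an identical tip set.

    Emulates a posterior sample of trees (the study pooled likelihoods over
    150 trees drawn from a BEAST posterior).
    """

    trees: list[PhyloTree]

    def __post_init__(self) -> None:
        if len(self.trees) < 1:
            raise TreeValidationError("TreeSample requires at least one tree")
        ref = set(self.trees[0].tip_labels)
        for k, t in enumerate(self.trees):
            if set(t.tip_labels) != ref:
                raise TreeValidationError(
                    f"tree {k} has a different tip set than tree 0"
                )

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self) -> Iterator[PhyloTree]:
        return iter(self.trees)

    def __getitem__(self, k: int) -> PhyloTree:
        return self.trees[k]

    @property
    def tip_labels(self) -> list[str]:
        return list(self.trees[0].tip_labels)

    def data_hash(self, states: "TipStates | None" = None) -> str:
        """Stable fingerprint of the sample (and optionally tip data)."""
        h = hashlib.md5()
        for t in self.trees:
            h.update(t.to_newick().encode())
        if states is not None:
            for label in sorted(states.states):
                h.update(f"{label}={states.states[label]};".encode())
        return h.hexdigest()


def read_tree_sample(path: str) -> TreeSample:
    """Read a multi-tree newick file (one tree per line) into a TreeSample."""
    try:
        tl = dendropy.TreeList.get(path=path, schema="newick", preserve_underscores=True)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise TreeFormatError(f"could not parse newick file {path!r}: {exc}") from exc
    if len(tl) == 0:
        raise TreeFormatError(f"no trees found in {path!r}")
    trees = []
    for k, t in enumerate(tl):
        try:
            trees.append(PhyloTree.from_dendropy(t))
        except TreeValidationError as exc:
            raise TreeValidationError(f"tree {k} in {path!r}: {exc}") from exc
    return TreeSample(trees)


def write_tree_sample(sample: TreeSample | Iterable[PhyloTree], path: str) -> None:
    trees = sample.trees if isinstance(sample, TreeSample) else list(sample)
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.to_newick() + "\n")


@dataclass(frozen=True)
class UltrametryReport:
    is_ultrametric: bool
    max_deviation: float
    depth: float


def check_ultrametric(tree: PhyloTree, rel_tol: float = 1e-3) -> UltrametryReport:
    """Report whether all root-to-tip path lengths agree within ``rel_tol``.

    The deviation is the spread (max minus min) of root-to-tip distances;
    the tree passes when the spread is at most ``rel_tol`` times its depth.
    """
    d = tree.depths_from_root()[: tree.n_tips]
    depth = float(d.max())
    dev = float(d.max() - d.min())
    ok = dev <= rel_tol * depth if depth > 0 else dev == 0.0
    return UltrametryReport(bool(ok), dev, depth)


@dataclass
class TipStates:
    """Binary activity states (and optionally raw activities) per tip.

    ``states`` maps tip label to 0 (low activity), 1 (high activity) or
    :data:`UNKNOWN`.  ``activity`` optionally carries the raw cell-culture
    retrotransposition activity as percent of the reference element L1_RP.
    """

    states: dict[str, int]
    activity: dict[str, float] | None = None

    def __post_init__(self) -> None:
        for label, s in self.states.items():
            if s not in (0, 1, UNKNOWN):
                raise ValueError(f"state for tip {label!r} must be 0, 1 or UNKNOWN, got {s}")
        if self.activity is not None:
            for label, a in self.activity.items():
                if not math.isfinite(a) or a < 0:
                    raise ValueError(
                        f"activity for tip {label!r} must be finite and >= 0, got {a}"
                    )

    @classmethod
    def from_activity(cls, activity: Mapping[str, float]) -> "TipStates":
        """Wrap raw activities with all states unknown (binarize separately)."""
        return cls({k: UNKNOWN for k in activity}, dict(activity))

    def state_array(self, tree: PhyloTree) -> np.ndarray:
        """States aligned to the tree's tip order; every tip must have an entry."""
        out = np.empty(tree.n_tips, dtype=np.int64)
        for i, label in enumerate(tree.tip_labels):
            if label not in self.states:
                raise KeyError(f"no state entry for tip {label!r}")
            out[i] = self.states[label]
        return out

    def counts(self) -> tuple[int, int, int]:
        """(n_low, n_high, n_unknown)."""
        vals = list(self.states.values())
        return vals.count(0), vals.count(1), vals.count(UNKNOWN)


def binarize_activity(states: TipStates, threshold: float = 25.0) -> TipStates:
    """Binarize raw activities at ``threshold`` percent of L1_RP.

    Activity >= threshold is coded high (1); below, low (0).  The tie at
    exactly the threshold is deliberately coded high; the cut is the 25%
    convention used for L1 activity assays.  Tips without a raw activity
    value become UNKNOWN.
    """
    if states.activity is None:
        raise ValueError("binarize_activity requires raw activity values")
    new: dict[str, int] = {}
    for label in states.states:
        a = states.activity.get(label)
        if a is None:
            new[label] = UNKNOWN
        else:
            if a < 0:
                raise ValueError(f"negative activity for tip {label!r}")
            new[label] = 1 if a >= threshold else 0
    return TipStates(new, dict(states.activity))


def read_tip_states(path: str) -> TipStates:
    """Read a TSV with columns tip_label, activity_percent[, state]."""
    df = pd.read_csv(path, sep="\t", dtype={"tip_label": str})
    if "tip_label" not in df.columns:
        raise ValueError(f"{path!r}: missing required column 'tip_label'")
    activity = None
    if "activity_percent" in df.columns:
        activity = {
            str(r.tip_label): float(r.activity_percent)
            for r in df.itertuples()
            if pd.notna(r.activity_percent)
        }
    if "state" in df.columns:
        states = {
            str(r.tip_label): (int(r.state) if pd.notna(r.state) else UNKNOWN)
            for r in df.itertuples()
        }
    else:
        states = {str(t): UNKNOWN for t in df.tip_label}
    return TipStates(states, activity)


def write_tip_states(states: TipStates, path: str) -> None:
    rows = []
    for label in states.states:
        act = states.activity.get(label) if states.activity else None
        rows.append(
            {
                "tip_label": label,
                "activity_percent": act,
                "state": states.states[label],
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
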