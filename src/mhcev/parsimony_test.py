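"""Fitch parsimony length of a categorical tip character and the permutation
test of species clustering against random topologies."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import dendropy
import numpy as np

from mhcev.errors import LabelingError, SizeError
from mhcev.phylo import random_labeled_topology, tip_labels


@dataclass(frozen=True)
class PermutationTestResult:
    observed_steps: int
    null_steps: tuple[int, ...]
    p_value: float
    seed: int | None = None

    @property
    def null_min(self) -> int:
        return min(self.null_steps)

    @property
    def null_max(self) -> int:
        return max(self.null_steps)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "observed_steps": self.observed_steps,
            "null_min": self.null_min,
            "null_max": self.null_max,
            "null_mean": float(np.mean(self.null_steps)),
            "n_rand": len(self.null_steps),
            "p_value": self.p_value,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def _resolve_root(node: dendropy.Node) -> None:
    """Binarize a multifurcation by nesting surplus children; Fitch length on
    an unrooted tree is invariant to how the root polytomy is resolved."""
    children = node.child_nodes()
    while len(children) > 2:
        a, b = children[0], children[1]
        joint = dendropy.Node()
        node.remove_child(a)
        node.remove_child(b)
        joint.add_child(a)
        joint.add_child(b)
        node.insert_child(0, joint)
        children = node.child_nodes()


def fitch_length(tree: dendropy.Tree, tip_states: Mapping[str, str]) -> int:
    """Minimum number of unordered state changes of the character on the tree.

    Post-order set intersection/union; +1 per empty intersection.  A
    trifurcating (or multifurcating) root is binarized internally, which does
    not change the unrooted parsimony length.
    """
    for label in tip_labels(tree):
        if label not in tip_states:
            raise LabelingError(f"tip {label!r} has no state")
    t = tree.clone(depth=1)
    for node in list(t.preorder_node_iter()):
        if not node.is_leaf() and len(node.child_nodes()) > 2:
            _resolve_root(node)
    changes = 0
    state_sets: dict[dendropy.Node, frozenset[str]] = {}
    for node in t.postorder_node_iter():
        if node.is_leaf():
            state_sets[node] = frozenset([str(tip_states[node.taxon.label])])
            continue
        kids = node.child_nodes()
        acc = state_sets[kids[0]]
        for kid in kids[1:]:
            inter = acc & state_sets[kid]
            if inter:
                acc = inter
            else:
                acc = acc | state_sets[kid]
                changes += 1
        state_sets[node] = acc
    return changes


def species_clustering_test(
    tree: dendropy.Tree,
    tip_states: Mapping[str, str],
    n_rand: int = 1000,
    seed: int | None = None,
    mode: str = "random_topology",
) -> PermutationTestResult:
    """Permutation test: is the character more clustered on the observed tree
    than expected?

    The null distribution is the Fitch length of the same tip-state map on
    `n_rand` uniform random topologies (``mode="random_topology"``), or on the
    observed topology with shuffled tip labels (``mode="shuffle_labels"``).
    p = (1 + #{null <= observed}) / (n_rand + 1).
    """
    if n_rand < 1:
        raise SizeError("n_rand must be >= 1")
    if mode not in {"random_topology", "shuffle_labels"}:
        raise ValueError(f"unknown mode {mode!r}")
    observed = fitch_length(tree, tip_states)
    labels = sorted(tip_labels(tree))
    rng = np.random.default_rng(seed)
    null: list[int] = []
    for _ in range(n_rand):
        if mode == "random_topology":
            rand_tree = random_labeled_topology(labels, rng)
            null.append(fitch_length(rand_tree, tip_states))
        else:
            perm = rng.permutation(len(labels))
            shuffled = {labels[i]: tip_states[labels[int(j)]] for i, j in enumerate(perm)}
            null.append(fitch_length(tree, shuffled))
    p = (1 + sum(1 for x in null if x <= observed)) / (n_rand + 1)
    return PermutationTestResult(
        observed_steps=observed,
        null_steps=tuple(null),
        p_value=p,
        seed=seed,
    )
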