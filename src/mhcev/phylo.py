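"""Distance-based phylogenetics: K2P/TN93(+Gamma) distances, neighbor joining,
bootstrap support, ultrametricization, stem scaling and random topologies.

Trees are :class:`dendropy.Tree` objects throughout; unrooted trees are
represented with a trifurcating root.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
import numpy as np

from mhcev.errors import CladeError, ShapeError, SizeError
from mhcev.seqio import CodonAlignment

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def encode_alignment(aln: CodonAlignment) -> np.ndarray:
    """(n_seq, n_sites) uint8 matrix; A/C/G/T -> 0..3, gap/N -> 4."""
    mat = np.full((len(aln), aln.length), 4, dtype=np.uint8)
    for i, seq in enumerate(aln):
        for j, ch in enumerate(seq.bases):
            mat[i, j] = _CODE.get(ch, 4)
    return mat


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray  # symmetric, zero diagonal; saturated entries are +inf

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("diagonal must be zero")
        finite = np.isfinite(self.d)
        if not np.allclose(self.d[finite & finite.T], self.d.T[finite & finite.T]):
            raise ValueError("matrix must be symmetric")

    @property
    def has_saturated(self) -> bool:
        return bool(np.isinf(self.d).any())

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.d, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t"
        )


def _gamma_log(w: float, alpha: float | None) -> float:
    """-ln(w), or its gamma-rates analogue alpha*(w**(-1/alpha) - 1)."""
    if w <= 0.0:
        return math.inf
    if alpha is None:
        return -math.log(w)
    return alpha * (w ** (-1.0 / alpha) - 1.0)


def _k2p(p: float, q: float, alpha: float | None) -> float:
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    return 0.5 * _gamma_log(w1, alpha) + 0.25 * _gamma_log(w2, alpha)


def _tn93(
    p1: float, p2: float, q: float, freqs: np.ndarray, alpha: float | None
) -> float:
    """Tamura–Nei distance from observed proportions and base frequencies."""
    fa, fc, fg, ft = freqs
    fr = fa + fg
    fy = fc + ft
    if fr <= 0.0 or fy <= 0.0:
        return math.inf
    k1 = 2.0 * fa * fg / fr
    k2 = 2.0 * ft * fc / fy
    k3 = 2.0 * (fr * fy - fa * fg * fy / fr - ft * fc * fr / fy)
    d = 0.0
    if k1 > 0.0:
        d += k1 * _gamma_log(1.0 - p1 / k1 - q / (2.0 * fr), alpha)
    elif p1 > 0.0:
        return math.inf
    if k2 > 0.0:
        d += k2 * _gamma_log(1.0 - p2 / k2 - q / (2.0 * fy), alpha)
    elif p2 > 0.0:
        return math.inf
    if k3 > 0.0:
        d += k3 * _gamma_log(1.0 - q / (2.0 * fr * fy), alpha)
    elif q > 0.0:
        return math.inf
    return d


def pairwise_distance(
    aln: CodonAlignment,
    model: str = "TN93G",
    alpha: float | None = 0.78,
    columns: Sequence[int] | None = None,
) -> DistanceMatrix:
    """Pairwise distances with pairwise deletion of gap/N sites.

    Models: ``K2P`` (no rate variation), ``TN93`` (no rate variation) and
    ``TN93G`` (gamma rate variation at shape `alpha`).  Saturated pairs
    (non-positive log arguments) get +inf entries.
    """
    if len(aln) < 2:
        raise SizeError("need at least 2 sequences")
    model = model.upper()
    if model not in {"K2P", "TN93", "TN93G"}:
        raise ValueError(f"unknown model {model!r}")
    use_alpha = alpha if model == "TN93G" else None
    mat = encode_alignment(aln)
    if columns is not None:
        mat = mat[:, list(columns)]
    n = len(aln)
    d = np.zeros((n, n), dtype=float)
    is_purine = np.array([True, False, True, False])
    for i in range(n):
        for j in range(i + 1, n):
            a, b = mat[i], mat[j]
            valid = (a < 4) & (b < 4)
            nc = int(valid.sum())
            if nc == 0:
                d[i, j] = d[j, i] = math.inf
                continue
            av, bv = a[valid], b[valid]
            diff = av != bv
            ts = diff & (is_purine[av] == is_purine[bv])
            p1 = float((ts & is_purine[av]).sum()) / nc  # A<->G
            p2 = float((ts & ~is_purine[av]).sum()) / nc  # C<->T
            q = float((diff & ~ts).sum()) / nc
            if model == "K2P":
                dist = _k2p(p1 + p2, q, use_alpha)
            else:
                counts = np.bincount(av, minlength=4) + np.bincount(bv, minlength=4)
                freqs = counts / counts.sum()
                dist = _tn93(p1, p2, q, freqs, use_alpha)
            d[i, j] = d[j, i] = max(dist, 0.0) if math.isfinite(dist) else math.inf
    return DistanceMatrix(labels=aln.ids(), d=d)


def _new_taxon_namespace(labels: Iterable[str]) -> dendropy.TaxonNamespace:
    return dendropy.TaxonNamespace([str(l) for l in labels])


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Classic neighbor joining with Studier–Keppler updates.

    Ties in the Q matrix are broken by the lowest (row, column) index pair;
    negative branch-length estimates are clamped to zero.  The returned tree
    is unrooted, represented with a trifurcating root.
    """
    n0 = len(dm.labels)
    if n0 < 3:
        raise SizeError("neighbor joining needs at least 3 taxa")
    if dm.has_saturated:
        raise ValueError("distance matrix contains saturated (infinite) entries")

    ns = _new_taxon_namespace(dm.labels)
    tree = dendropy.Tree(taxon_namespace=ns)
    nodes: list[dendropy.Node] = []
    for label in dm.labels:
        node = dendropy.Node(taxon=ns.get_taxon(str(label)))
        nodes.append(node)

    d = dm.d.copy()
    active = list(range(n0))  # indices into rows of d / nodes list
    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        best_pair = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                qv = (m - 2) * d[i, j] - r[i] - r[j]
                if best is None or qv < best - 1e-12:
                    best = qv
                    best_pair = (i, j)
        i, j = best_pair
        vi = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = d[i, j] - vi
        vi, vj = max(vi, 0.0), max(vj, 0.0)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = vi
        nodes[j].edge.length = vj

        # grow matrix by one row/col for the new node
        k = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for x in active:
            if x in (i, j):
                continue
            d[k, x] = d[x, k] = 0.5 * (d[i, x] + d[j, x] - d[i, j])
        nodes.append(parent)
        active = [x for x in active if x not in (i, j)] + [k]

    a, b, c = active
    root = tree.seed_node
    for x, la in ((a, 0), (b, 1), (c, 2)):
        root.add_child(nodes[x])
    nodes[a].edge.length = max(0.5 * (d[a, b] + d[a, c] - d[b, c]), 0.0)
    nodes[b].edge.length = max(0.5 * (d[a, b] + d[b, c] - d[a, c]), 0.0)
    nodes[c].edge.length = max(0.5 * (d[a, c] + d[b, c] - d[a, b]), 0.0)
    tree.is_rooted = False
    return tree


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial splits as frozensets of tip labels, complement-normalized."""
    all_tips = frozenset(tip_labels(tree))
    ref = min(all_tips)
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        if ref in below:
            below = all_tips - below
        if 2 <= len(below) <= len(all_tips) - 2:
            splits.add(below)
    return splits


def bootstrap_support(
    aln: CodonAlignment,
    model: str = "TN93G",
    alpha: float | None = 0.78,
    n: int = 1000,
    seed: int | None = None,
) -> dendropy.Tree:
    """NJ point-estimate tree with bootstrap proportions on internal edges.

    Columns are resampled with replacement `n` times; each replicate tree's
    bipartitions are tallied against the point tree.  Replicates yielding
    saturated distances are dropped (counted in ``tree.n_dropped_replicates``).
    `n=0` returns the point tree without support annotations.
    """
    dm = pairwise_distance(aln, model=model, alpha=alpha)
    tree = neighbor_joining(dm)
    tree.n_dropped_replicates = 0
    if n == 0:
        return tree

    all_tips = frozenset(tip_labels(tree))
    ref = min(all_tips)
    counts: dict[frozenset[str], int] = {}
    rng = np.random.default_rng(seed)
    n_used = 0
    for _ in range(n):
        cols = rng.integers(0, aln.length, size=aln.length)
        dmb = pairwise_distance(aln, model=model, alpha=alpha, columns=cols)
        if dmb.has_saturated:
            tree.n_dropped_replicates += 1
            continue
        rep = neighbor_joining(dmb)
        n_used += 1
        for split in bipartitions(rep):
            counts[split] = counts.get(split, 0) + 1

    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        if ref in below:
            below = all_tips - below
        if 2 <= len(below) <= len(all_tips) - 2 and n_used > 0:
            node.label = f"{counts.get(below, 0) / n_used:.3f}"
            node.support = counts.get(below, 0) / n_used
    tree.n_bootstrap_used = n_used
    return tree


def root_on_outgroup(tree: dendropy.Tree, outgroup_label: str) -> dendropy.Tree:
    """Root the tree on the edge above the outgroup tip (clone; input untouched)."""
    t = tree.clone(depth=1)
    og = None
    for leaf in t.leaf_node_iter():
        if leaf.taxon.label == outgroup_label:
            og = leaf
            break
    if og is None:
        raise CladeError(f"outgroup {outgroup_label!r} not found in tree")
    length = og.edge.length or 0.0
    t.reroot_at_edge(og.edge, length1=length / 2.0, length2=length / 2.0)
    t.is_rooted = True
    return t


def prune_outgroup(tree: dendropy.Tree, outgroup_label: str) -> dendropy.Tree:
    """Root on the outgroup, then remove it; the root becomes the ingroup node."""
    t = root_on_outgroup(tree, outgroup_label)
    t.prune_taxa_with_labels([outgroup_label], suppress_unifurcations=True)
    t.seed_node.edge.length = None
    return t


def node_depths(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    depths: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    return depths


def is_ultrametric(tree: dendropy.Tree, rel_tol: float = 1e-6) -> bool:
    depths = node_depths(tree)
    tips = [depths[l] for l in tree.leaf_node_iter()]
    depth = max(tips)
    if depth == 0.0:
        return True
    return (max(tips) - min(tips)) <= rel_tol * depth


def ultrametricize(tree: dendropy.Tree, method: str = "mean_path_length") -> dendropy.Tree:
    """Equalize root-to-tip path lengths by averaging child heights.

    Each internal node's height becomes the mean of its children's implied
    heights (child height + connecting branch), floored at the deepest child
    so no branch goes negative; edge lengths are then height differences.
    Requires a rooted tree.
    """
    if method != "mean_path_length":
        raise ValueError(f"unknown method {method!r}")
    if not tree.is_rooted and len(tree.seed_node.child_nodes()) > 2:
        raise ShapeError("ultrametricize requires a rooted tree")
    t = tree.clone(depth=1)
    height: dict[dendropy.Node, float] = {}
    for node in t.postorder_node_iter():
        if node.is_leaf():
            height[node] = 0.0
        else:
            implied = [height[c] + (c.edge.length or 0.0) for c in node.child_nodes()]
            height[node] = max(sum(implied) / len(implied), max(height[c] for c in node.child_nodes()))
    for node in t.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = height[node.parent_node] - height[node]
    return t


def find_mrca(tree: dendropy.Tree, tips: Iterable[str]) -> dendropy.Node:
    wanted = set(tips)
    mrca = tree.mrca(taxa=[t for t in tree.taxon_namespace if t.label in wanted])
    if mrca is None:
        raise CladeError("could not locate MRCA of the given tips")
    return mrca


def clade_is_monophyletic(tree: dendropy.Tree, tips: Iterable[str]) -> bool:
    wanted = set(tips)
    mrca = find_mrca(tree, wanted)
    below = {l.taxon.label for l in mrca.leaf_iter()}
    return below == wanted


def scale_clade_stem(
    tree: dendropy.Tree, clade_tips: Iterable[str], factor: float
) -> dendropy.Tree:
    """Multiply the branch subtending the MRCA of `clade_tips` by `factor`."""
    if factor <= 0.0:
        raise ValueError("factor must be positive")
    wanted = set(clade_tips)
    t = tree.clone(depth=1)
    mrca = find_mrca(t, wanted)
    below = {l.taxon.label for l in mrca.leaf_iter()}
    if below != wanted:
        raise CladeError(
            f"tip set is not monophyletic (MRCA spans {len(below)} tips, "
            f"expected {len(wanted)})"
        )
    if mrca.parent_node is None:
        raise CladeError("clade MRCA is the root: no stem branch to scale")
    mrca.edge.length = (mrca.edge.length or 0.0) * factor
    return t


def random_labeled_topology(
    labels: Sequence[str], rng: np.random.Generator
) -> dendropy.Tree:
    """Uniform random unrooted binary labeled topology, unit branch lengths.

    Taxa are attached one at a time to a uniformly chosen existing edge,
    which yields the uniform distribution over the (2n-5)!! topologies.
    """
    labels = [str(l) for l in labels]
    if len(labels) < 3:
        raise SizeError("need at least 3 labels")
    ns = _new_taxon_namespace(labels)
    tree = dendropy.Tree(taxon_namespace=ns)
    root = tree.seed_node
    edges: list[dendropy.Node] = []  # identify each edge by its child node
    for label in labels[:3]:
        leaf = dendropy.Node(taxon=ns.get_taxon(label))
        root.add_child(leaf)
        edges.append(leaf)
    for label in labels[3:]:
        target = edges[int(rng.integers(0, len(edges)))]
        parent = target.parent_node
        mid = dendropy.Node()
        parent.remove_child(target)
        parent.add_child(mid)
        mid.add_child(target)
        leaf = dendropy.Node(taxon=ns.get_taxon(label))
        mid.add_child(leaf)
        edges.append(mid)
        edges.append(leaf)
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = 1.0
    tree.is_rooted = False
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_newick(path, rooted: bool = True) -> dendropy.Tree:
    return dendropy.Tree.get(
        path=str(path),
        schema="newick",
        rooting="force-rooted" if rooted else "force-unrooted",
        preserve_underscores=True,
    )
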