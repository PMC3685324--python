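import numpy as np
import pytest

from mhcev.seqio import AlignedSequence, CodonAlignment


def make_seq(sid, bases, species="sp1", clade="songbird", family="fam1"):
    return AlignedSequence(id=sid, species=species, clade=clade, family=family, bases=bases)


def make_aln(*rows, **kwargs):
    """rows: (id, bases) or (id, bases, species) tuples."""
    seqs = []
    for row in rows:
        if len(row) == 2:
            seqs.append(make_seq(row[0], row[1], **kwargs))
        else:
            seqs.append(make_seq(row[0], row[1], species=row[2], **kwargs))
    return CodonAlignment(seqs)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_alignment():
    return make_aln(
        ("s1", "ATGGCTAAA"),
        ("s2", "ATGGCGAAA"),
        ("s3", "ATGTCGAGA"),
    )


def random_codon(rng, no_stop=True):
    from mhcev.seqio import STANDARD_STOPS

    bases = "ACGT"
    while True:
        codon = "".join(bases[i] for i in rng.integers(0, 4, size=3))
        if not (no_stop and codon in STANDARD_STOPS):
            return codon


def random_binary_tree_with_lengths(labels, rng, min_len=0.05, max_len=1.0):
    """Random rooted binary tree with random branch lengths (dendropy)."""
    import dendropy

    ns = dendropy.TaxonNamespace(list(labels))
    tree = dendropy.Tree(taxon_namespace=ns)
    nodes = [dendropy.Node(taxon=ns.get_taxon(l)) for l in labels]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = __import__("dendropy").Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = tree.seed_node
    for n in nodes:
        root.add_child(n)
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = float(rng.uniform(min_len, max_len))
    tree.is_rooted = True
    return tree


def tree_path_distances(tree):
    """Dict of leaf-pair -> path length, computed by brute-force root paths."""
    paths = {}
    for leaf in tree.leaf_node_iter():
        chain = []
        node = leaf
        while node is not None:
            chain.append(node)
            node = node.parent_node
        paths[leaf.taxon.label] = chain
    out = {}
    labels = sorted(paths)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            chain_a = paths[a]
            set_b = set(id(n) for n in paths[b])
            mrca = next(n for n in chain_a if id(n) in set_b)

            def dist_up(leaf_chain, stop):
                d = 0.0
                for n in leaf_chain:
                    if n is stop:
                        break
                    d += n.edge.length or 0.0
                return d

            out[(a, b)] = dist_up(paths[a], mrca) + dist_up(paths[b], mrca)
    return out
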