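"""Synthetic trees, codon alignments and traits with the structure the
analysis assumes: two clades of species each carrying several allele-like
paralog sequences, elevated nonsynonymous substitution confined to a stated
PBR codon set, clade-specific third-position GC targets, and an optional
outgroup.

Selection is a mutation–selection caricature: proposed mutations that create
stop codons are rejected; nonsynonymous proposals are accepted with
probability min(1, omega) for the codon's partition; synonymous proposals are
always accepted.  GC bias enters only through the replacement-base proposal
distribution at third codon positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import dendropy
import numpy as np

from mhcev.errors import ShapeError
from mhcev.seqio import (
    AlignedSequence,
    CodonAlignment,
    STANDARD_STOPS,
    translate_codon,
    write_codon_alignment,
)
from mhcev.selection import PartitionScheme, is_transition
import mhcev.phylo as phylo

BASES = "ACGT"
OUTGROUP_LABEL = "outgroup1"


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_species_a: int = 16
    n_species_b: int = 17
    alleles_per_species: tuple[int, int] = (3, 13)
    n_codons: int = 88
    omega_pbr: float = 4.0
    omega_nonpbr: float = 0.5
    kappa: float = 2.0
    gc3_target_a: float = 0.70
    gc3_target_b: float = 0.78
    tree_depth: float = 0.25
    outgroup: bool = True

    def __post_init__(self) -> None:
        if min(self.n_species_a, self.n_species_b, self.n_codons) < 1:
            raise ValueError("counts must be >= 1")
        if self.omega_pbr <= 0 or self.omega_nonpbr <= 0:
            raise ValueError("omega targets must be positive")
        for g in (self.gc3_target_a, self.gc3_target_b):
            if not 0.0 < g < 1.0:
                raise ValueError("gc3 targets must lie in (0, 1)")
        lo, hi = self.alleles_per_species
        if lo < 1 or hi < lo:
            raise ValueError("alleles_per_species must be a valid range")


def species_label(clade: str, i: int) -> str:
    return f"sp{clade}{i:02d}"


def allele_label(species: str, j: int) -> str:
    return f"{species}-{j}"


def parse_label(label: str) -> tuple[str, str]:
    """(species, clade) from a simulated tip label."""
    if label == OUTGROUP_LABEL:
        return label, "outgroup"
    species = label.split("-", 1)[0]
    clade = "songbird" if species.startswith("spA") else "nonpasserine"
    return species, clade


def _attach_subtree(
    parent: dendropy.Node,
    labels: list[str],
    top: float,
    tip_height: float,
    heights: dict,
    rng: np.random.Generator,
    ns: dendropy.TaxonNamespace,
) -> None:
    """Random ultrametric subtree over `labels`, hanging from `parent`
    (which sits at height `top`); tips end at `tip_height`."""
    if len(labels) == 1:
        leaf = dendropy.Node(taxon=ns.get_taxon(labels[0]))
        parent.add_child(leaf)
        heights[leaf] = tip_height
        return
    node = dendropy.Node()
    parent.add_child(node)
    h = tip_height + (top - tip_height) * rng.uniform(0.5, 0.95)
    heights[node] = h
    perm = [labels[i] for i in rng.permutation(len(labels))]
    cut = int(rng.integers(1, len(labels)))
    _attach_subtree(node, perm[:cut], h, tip_height, heights, rng, ns)
    _attach_subtree(node, perm[cut:], h, tip_height, heights, rng, ns)


def simulate_two_clade_tree(cfg: SimulationConfig) -> dendropy.Tree:
    """Rooted tree: (optional outgroup, (clade A, clade B)); within each clade
    a random species tree whose tips are shallow allele subtrees."""
    rng = np.random.default_rng(cfg.seed)
    counts: dict[str, int] = {}
    tip_names: list[str] = []
    for clade, n_sp in (("A", cfg.n_species_a), ("B", cfg.n_species_b)):
        for i in range(1, n_sp + 1):
            sp = species_label(clade, i)
            lo, hi = cfg.alleles_per_species
            counts[sp] = int(rng.integers(lo, hi + 1))
            tip_names.extend(allele_label(sp, j) for j in range(1, counts[sp] + 1))
    if cfg.outgroup:
        tip_names.append(OUTGROUP_LABEL)
    ns = dendropy.TaxonNamespace(tip_names)
    tree = dendropy.Tree(taxon_namespace=ns)

    depth = cfg.tree_depth
    heights: dict[dendropy.Node, float] = {}
    if cfg.outgroup:
        root = tree.seed_node
        heights[root] = 1.6 * depth
        og = dendropy.Node(taxon=ns.get_taxon(OUTGROUP_LABEL))
        root.add_child(og)
        heights[og] = 0.0
        split = dendropy.Node()
        root.add_child(split)
        heights[split] = depth
    else:
        split = tree.seed_node
        heights[split] = depth

    allele_top = 0.08 * depth
    for clade, n_sp in (("A", cfg.n_species_a), ("B", cfg.n_species_b)):
        clade_node = dendropy.Node()
        split.add_child(clade_node)
        heights[clade_node] = depth * rng.uniform(0.45, 0.7)
        species = [species_label(clade, i) for i in range(1, n_sp + 1)]
        _species_tree(clade_node, species, heights[clade_node], allele_top,
                      counts, heights, rng, ns)

    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = heights[node.parent_node] - heights[node]
    tree.is_rooted = True
    return tree


def _species_tree(
    parent: dendropy.Node,
    species: list[str],
    top: float,
    allele_top: float,
    counts: Mapping[str, int],
    heights: dict,
    rng: np.random.Generator,
    ns: dendropy.TaxonNamespace,
) -> None:
    if len(species) == 1:
        sp = species[0]
        labels = [allele_label(sp, j) for j in range(1, counts[sp] + 1)]
        if len(labels) == 1:
            leaf = dendropy.Node(taxon=ns.get_taxon(labels[0]))
            parent.add_child(leaf)
            heights[leaf] = 0.0
        else:
            _attach_subtree(parent, labels, min(allele_top, top), 0.0, heights, rng, ns)
        return
    node = dendropy.Node()
    parent.add_child(node)
    h = allele_top + (top - allele_top) * rng.uniform(0.5, 0.95)
    heights[node] = h
    perm = [species[i] for i in rng.permutation(len(species))]
    cut = int(rng.integers(1, len(species)))
    _species_tree(node, perm[:cut], h, allele_top, counts, heights, rng, ns)
    _species_tree(node, perm[cut:], h, allele_top, counts, heights, rng, ns)


def _draw_root_codons(n_codons: int, gc3: float, rng: np.random.Generator) -> list[str]:
    codons = []
    while len(codons) < n_codons:
        c1, c2 = rng.choice(list(BASES)), rng.choice(list(BASES))
        if rng.random() < gc3:
            c3 = rng.choice(["G", "C"])
        else:
            c3 = rng.choice(["A", "T"])
        codon = c1 + c2 + c3
        if codon in STANDARD_STOPS:
            continue
        codons.append(codon)
    return codons


def _propose_base(current: str, kappa: float, rng: np.random.Generator) -> str:
    """Transition-biased proposal; the same normalization for every current
    base, so the kernel is symmetric between the AT and GC base classes."""
    candidates = [b for b in BASES if b != current]
    weights = np.array(
        [kappa if is_transition(current, b) else 1.0 for b in candidates]
    )
    return candidates[int(rng.choice(len(candidates), p=weights / weights.sum()))]


def _gc_accept_prob(old: str, new: str, gc_target: float) -> float:
    """Metropolis factor whose stationary GC-class frequency is `gc_target`."""
    old_gc, new_gc = old in "GC", new in "GC"
    if old_gc == new_gc:
        return 1.0
    ratio = gc_target / (1.0 - gc_target)
    return min(1.0, ratio if new_gc else 1.0 / ratio)


def _node_clade(node: dendropy.Node) -> str | None:
    clades = {parse_label(l.taxon.label)[1] for l in node.leaf_iter()}
    if clades == {"songbird"}:
        return "A"
    if clades == {"nonpasserine"}:
        return "B"
    return None


def simulate_codon_alignment(
    tree: dendropy.Tree, cfg: SimulationConfig, scheme: PartitionScheme
) -> CodonAlignment:
    """Evolve a stop-free codon alignment down the tree.

    Mutation proposals occur at rate 3*n_codons per unit branch length; each
    proposal picks a uniform site and a replacement base with transition bias
    `kappa` and (at third positions) GC bias toward the lineage's clade
    target; stop-creating proposals are rejected and nonsynonymous proposals
    accepted with probability min(1, omega) for the codon's partition.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    pbr = scheme.alignment_codon_indices(cfg.n_codons)
    root_codons = _draw_root_codons(cfg.n_codons, cfg.gc3_target_a, rng)
    seqs: dict[dendropy.Node, list[str]] = {tree.seed_node: root_codons}
    n_sites = 3 * cfg.n_codons

    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        codons = list(seqs[node.parent_node])
        clade = _node_clade(node)
        gc_target = cfg.gc3_target_b if clade == "B" else cfg.gc3_target_a
        n_events = rng.poisson((node.edge.length or 0.0) * n_sites)
        for _ in range(n_events):
            site = int(rng.integers(0, n_sites))
            ci, pos = divmod(site, 3)
            codon = codons[ci]
            new_base = _propose_base(codon[pos], cfg.kappa, rng)
            mutant = codon[:pos] + new_base + codon[pos + 1 :]
            if mutant in STANDARD_STOPS:
                continue
            if pos == 2 and rng.random() >= _gc_accept_prob(codon[pos], new_base, gc_target):
                continue
            if translate_codon(mutant) != translate_codon(codon):
                omega = cfg.omega_pbr if ci in pbr else cfg.omega_nonpbr
                if rng.random() >= min(1.0, omega):
                    continue
            codons[ci] = mutant
        seqs[node] = codons

    sequences = []
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        species, clade = parse_label(label)
        sequences.append(
            AlignedSequence(
                id=label,
                species=species,
                clade=clade,
                family=species,
                bases="".join(seqs[leaf]),
            )
        )
    return CodonAlignment(sequences)


def simulate_bm_trait(
    tree: dendropy.Tree,
    split,
    mu_a: float,
    mu_b: float,
    sigma2: float,
    rel_rate_a: float = 1.0,
    seed: int | None = None,
) -> dict[str, float]:
    """Brownian trait values at the tips of an ultrametric two-clade tree.

    Each root child starts at its clade's mean; every edge adds a normal
    increment with variance sigma2 * rate * length (clade A edges, including
    the stem, run at `rel_rate_a`).
    """
    if not phylo.is_ultrametric(tree):
        raise ShapeError("simulate_bm_trait requires an ultrametric tree")
    rng = np.random.default_rng(seed)
    values: dict[dendropy.Node, float] = {}
    clade_a = set(split.clade_a_tips)
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[node] = 0.0  # never used: children restart at clade means
            continue
        tips_below = {l.taxon.label for l in node.leaf_iter()}
        in_a = tips_below <= clade_a
        if node.parent_node is tree.seed_node:
            start = mu_a if in_a else mu_b
        else:
            start = values[node.parent_node]
        rate = rel_rate_a if in_a else 1.0
        var = sigma2 * rate * (node.edge.length or 0.0)
        values[node] = start + (math.sqrt(var) * rng.standard_normal() if var > 0 else 0.0)
    return {l.taxon.label: values[l] for l in tree.leaf_node_iter()}


def write_bundle(
    outdir: str | Path,
    cfg: SimulationConfig,
    scheme: PartitionScheme | None = None,
) -> dict[str, Path]:
    """Simulate a full dataset and write FASTA, metadata TSV and newick."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scheme = scheme or PartitionScheme.default_pbr()
    tree = simulate_two_clade_tree(cfg)
    aln = simulate_codon_alignment(tree, cfg, scheme)
    paths = {
        "fasta": outdir / "alignment.fasta",
        "metadata": outdir / "metadata.tsv",
        "tree": outdir / "tree.nwk",
    }
    write_codon_alignment(aln, paths["fasta"], paths["metadata"])
    phylo.write_newick(tree, paths["tree"])
    return paths
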