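"""Simulate a small panel of bacterial strains descending from one ancestor.

A random (or user-supplied newick) tree is decorated with point mutations:
each branch receives a Poisson number of substitutions with a fixed expected
count per branch, placed uniformly along the genome.  The generator returns
the ancestral genome, one genome per leaf strain, the generating tree, and the
exact variant table obtained by construction — the ground truth every
downstream SNP-panel test compares against.  Substitutions only; no indels.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .._rng import substream

__all__ = ["StrainSimConfig", "StrainSet", "simulate_strain_set"]

_BASES = np.array(list("ACGT"))


@dataclass
class StrainSimConfig:
    n_strains: int = 8
    genome_length: int = 50_000
    tree: str = "random"  # newick string, or "random" for a random bifurcating topology
    subs_per_branch: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strains < 2:
            raise ValueError("n_strains must be >= 2")
        if self.genome_length < 1000:
            raise ValueError("genome_length must be >= 1000")
        if self.subs_per_branch < 0:
            raise ValueError("subs_per_branch must be >= 0")


@dataclass
class StrainSet:
    """Genomes plus the ground truth that generated them."""

    config: StrainSimConfig
    contig: str
    ancestor: str
    genomes: dict  # strain name -> genome string
    tree_newick: str
    # true variant table: list of (pos 1-based, ref base, {strain -> base})
    variant_sites: list = field(default_factory=list)

    @property
    def strain_names(self) -> list:
        return list(self.genomes)

    def true_tree(self) -> dendropy.Tree:
        return dendropy.Tree.get(data=self.tree_newick, schema="newick")


def _random_tree(n: int, rng: np.random.Generator) -> dendropy.Tree:
    """Random bifurcating topology by sequential joining; exp(1) branch lengths."""
    taxa = dendropy.TaxonNamespace([f"strain_{i:02d}" for i in range(n)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for t in taxa:
        leaf = dendropy.Node(taxon=t)
        leaf.edge.length = float(rng.exponential(1.0))
        nodes.append(leaf)
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = float(rng.exponential(1.0))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    root = dendropy.Node()
    for x in nodes:
        root.add_child(x)
    tree.seed_node = root
    return tree


def _parse_tree(newick: str) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(data=newick, schema="newick")
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"invalid newick tree: {exc}") from exc


def simulate_strain_set(config: StrainSimConfig) -> StrainSet:
    """Generate an ancestral genome and mutated descendant genomes on a tree.

    Each edge of the tree receives ``Poisson(subs_per_branch)`` substitutions
    at positions drawn uniformly without replacement; each substitution
    replaces the current base with a uniformly chosen different base, so a
    site can mutate more than once along a root-to-leaf path (and can revert).
    """
    rng = substream(config.seed, "strains")
    if config.tree == "random":
        tree = _random_tree(config.n_strains, rng)
    else:
        tree = _parse_tree(config.tree)
        leaves = tree.leaf_nodes()
        if len(leaves) != config.n_strains:
            raise ValueError(
                f"tree has {len(leaves)} leaves but n_strains={config.n_strains}"
            )

    L = config.genome_length
    ancestor = rng.choice(_BASES, size=L)

    # walk the tree, mutating a copy of the parent genome along each edge
    genomes: dict = {}
    tree.seed_node.genome = ancestor.copy()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        g = node.parent_node.genome.copy()
        n_subs = rng.poisson(config.subs_per_branch)
        n_subs = min(n_subs, L)
        if n_subs:
            positions = rng.choice(L, size=n_subs, replace=False)
            for p in positions:
                alternatives = _BASES[_BASES != g[p]]
                g[p] = rng.choice(alternatives)
        # branch lengths on the emitted tree are realized substitution counts,
        # so true patristic distances are on the same scale as genome diffs
        node.edge.length = float(n_subs)
        node.genome = g
        if node.is_leaf():
            genomes[node.taxon.label] = "".join(g)

    anc_str = "".join(ancestor)
    variant_sites = []
    diff_mask = np.zeros(L, dtype=bool)
    leaf_arrays = {name: np.array(list(g)) for name, g in genomes.items()}
    for arr in leaf_arrays.values():
        diff_mask |= arr != ancestor
    for p in np.flatnonzero(diff_mask):
        variant_sites.append(
            (int(p) + 1, anc_str[p], {name: str(arr[p]) for name, arr in leaf_arrays.items()})
        )

    sio = io.StringIO()
    tree.write(file=sio, schema="newick", suppress_rooting=True)
    return StrainSet(
        config=config,
        contig="ref",
        ancestor=anc_str,
        genomes=genomes,
        tree_newick=sio.getvalue().strip(),
        variant_sites=variant_sites,
    )
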