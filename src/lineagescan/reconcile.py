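"""Gene-tree / species-tree reconciliation by most-parsimonious LCA mapping.

Each gene-tree node ``v`` is mapped to ``M(v)``, the species-tree last
common ancestor of the species sampled below ``v``.  An internal node is a
duplication exactly when it maps to the same species node as at least one
of its children — the standard parsimony criterion.  Branches of the gene
tree are localised on the species tree as the ordered list of species-tree
edges between the mappings of their endpoints; a branch whose endpoints
map to the same species node (e.g. a post-duplication branch) occupies a
single self-lineage "X to X".
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .trees import GeneTree, Node, SpeciesTree

__all__ = [
    "ReconciledFamily",
    "lca_reconcile",
    "map_branch_lineage",
    "family_root_age",
    "count_duplications",
]


@dataclass
class ReconciledFamily:
    """Result of reconciling one gene family against the species tree."""

    family_id: str
    gene_tree: GeneTree
    species_tree: SpeciesTree
    #: gene-node label -> species-node label
    mapping: dict[str, str] = field(default_factory=dict)
    #: labels of gene-tree nodes inferred to be duplications
    duplication_nodes: set[str] = field(default_factory=set)

    @property
    def duplication_count(self) -> int:
        return len(self.duplication_nodes)

    @property
    def root_species(self) -> str:
        return self.mapping[self.gene_tree.root.label]

    @property
    def root_age(self) -> float:
        return self.species_tree.age(self.root_species)


def lca_reconcile(
    gene_tree: GeneTree,
    species_tree: SpeciesTree,
    family_id: str = "",
) -> ReconciledFamily:
    """Map every gene-tree node to the species tree and label duplications.

    Raises ``KeyError`` naming the species if a gene leaf carries a species
    label absent from the species tree.
    """
    mapping: dict[str, Node] = {}
    duplications: set[str] = set()
    for node in gene_tree.root.postorder():
        if node.is_leaf:
            species = gene_tree.species_of(node)
            if species not in species_tree:
                raise KeyError(
                    f"gene leaf {node.label!r} names species {species!r} "
                    "not present in the species tree"
                )
            mapping[node.label] = species_tree[species]
        else:
            snode = mapping[node.children[0].label]
            for child in node.children[1:]:
                snode = species_tree.lca(snode, mapping[child.label])
            mapping[node.label] = snode
            if any(mapping[c.label] is snode for c in node.children):
                duplications.add(node.label)
    return ReconciledFamily(
        family_id=family_id,
        gene_tree=gene_tree,
        species_tree=species_tree,
        mapping={k: v.label for k, v in mapping.items()},
        duplication_nodes=duplications,
    )


def map_branch_lineage(
    branch: str | Node,
    reconciled: ReconciledFamily,
    species_tree: SpeciesTree | None = None,
) -> list[str]:
    """Species-tree lineages spanned by one gene-tree branch.

    The branch is identified by its child node (label or node).  Returns
    the labels of the species-tree nodes entered along the path from the
    mapping of the branch's parent down to the mapping of its child —
    each label names the species-tree edge ending in it.  When both
    endpoints map to the same species node the branch lies on the single
    self-lineage ``[X]`` ("X to X").
    """
    stree = species_tree or reconciled.species_tree
    child = branch if isinstance(branch, Node) else reconciled.gene_tree[branch]
    if child.parent is None:
        raise ValueError("the root has no branch above it")
    top = stree[reconciled.mapping[child.parent.label]]
    bottom = stree[reconciled.mapping[child.label]]
    if top is bottom:
        return [top.label]
    return [n.label for n in stree.path_down(top, bottom)]


def family_root_age(
    reconciled: ReconciledFamily,
    species_tree: SpeciesTree | None = None,
) -> float:
    """Age in MYA of the species-tree node the family root maps to."""
    stree = species_tree or reconciled.species_tree
    return stree.age(reconciled.root_species)


def count_duplications(reconciled: ReconciledFamily) -> int:
    """Number of gene-tree nodes labelled as duplications."""
    return reconciled.duplication_count
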