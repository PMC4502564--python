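"""Parsimony dating of duplications and parent/child designation.

A duplication is dated by single-gain parsimony on a rooted species tree:
if the species carrying two gene copies are exactly the leaf set of one
clade and every other species carries a single copy, the duplication is
placed on that clade's stem branch (identified by its child-node name).
Patterns requiring losses, non-monophyletic two-copy sets, and families
duplicated in all species are left unresolved and excluded downstream.

Parent and child copies are told apart by whole-genome-alignment outcome
(supplied as flags): the copy that aligns to outgroup genomes sits at the
ancestral locus and is the parent; the copy that does not is the child at
a novel locus. Families where both or neither copy aligns (e.g. tandem
duplicates) are unresolvable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy

from .config import DEFAULT_SPECIES

UNRESOLVED = "UNRESOLVED"

__all__ = [
    "SpeciesTree",
    "DuplicationDate",
    "ParentChildAssignment",
    "UNRESOLVED",
    "infer_duplication_branch",
    "assign_parent_child",
    "select_outgroup_species",
    "enumerate_species_pairs",
]


class SpeciesTree:
    """Rooted species tree with named leaves, wrapping a dendropy tree.

    Branches are identified by their child node: the species name for
    terminal branches, the internal node's label otherwise. Unlabeled
    internal nodes get a deterministic label (sorted leaf names joined
    with '+').
    """

    def __init__(self, newick: str):
        self.tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        self.tree.is_rooted = True
        self.leaf_names = tuple(
            leaf.taxon.label for leaf in self.tree.leaf_node_iter()
        )
        if len(set(self.leaf_names)) != len(self.leaf_names):
            raise ValueError("duplicate leaf names in species tree")
        for node in self.tree.preorder_node_iter():
            if node.is_leaf():
                node.branch_name = node.taxon.label
            elif node.label:
                node.branch_name = node.label
            else:
                node.branch_name = "+".join(
                    sorted(l.taxon.label for l in node.leaf_iter())
                )
        self._has_lengths = all(
            e.length is not None for e in self.tree.preorder_edge_iter() if e.head_node.parent_node
        )
        self._pdm = None

    @classmethod
    def from_file(cls, path) -> "SpeciesTree":
        from pathlib import Path

        return cls(Path(path).read_text())

    def leaf_distance(self, species_1: str, species_2: str) -> float:
        """Path distance between two leaves: branch-length sum when lengths
        are present, node (edge) count otherwise."""
        if self._pdm is None:
            self._pdm = self.tree.phylogenetic_distance_matrix()
        t1 = self.tree.taxon_namespace.get_taxon(species_1)
        t2 = self.tree.taxon_namespace.get_taxon(species_2)
        if t1 is None or t2 is None:
            raise ValueError("species not on tree")
        if self._has_lengths:
            return float(self._pdm.patristic_distance(t1, t2))
        return float(self._pdm.path_edge_count(t1, t2))

    def mrca(self, species: Sequence[str]) -> dendropy.Node:
        taxa = [self.tree.taxon_namespace.get_taxon(s) for s in species]
        if any(t is None for t in taxa):
            missing = [s for s, t in zip(species, taxa) if t is None]
            raise ValueError(f"species not on tree: {missing}")
        if len(taxa) == 1:
            return self.tree.find_node_for_taxon(taxa[0])
        return self.tree.mrca(taxa=taxa)


@dataclass
class DuplicationDate:
    family_id: str
    origin_branch: str
    resolved: bool


@dataclass
class ParentChildAssignment:
    family_id: str
    parent: str | None
    child: str | None
    resolved: bool


def infer_duplication_branch(
    pattern: Mapping[str, int],
    tree: SpeciesTree,
    family_id: str = "",
    require_full_coverage: bool = False,
) -> DuplicationDate:
    """Place a duplication by single-gain parsimony from a copy-number pattern.

    ``pattern`` maps species to copy number in {0, 1, 2}. The duplication is
    resolved iff the two-copy species form exactly one clade (restricted to
    the observed species; absent species are uninformative unless
    ``require_full_coverage``), every other observed species has one copy,
    and the clade is not the whole tree. With missing species the most
    recent (shallowest) consistent branch is reported.
    """
    unknown = [s for s in pattern if s not in tree.leaf_names]
    if unknown:
        raise ValueError(f"pattern species not on tree: {unknown}")
    bad = {s: c for s, c in pattern.items() if c not in (0, 1, 2)}
    if bad:
        raise ValueError(f"copy numbers must be in {{0,1,2}}: {bad}")
    if require_full_coverage and set(pattern) != set(tree.leaf_names):
        missing = sorted(set(tree.leaf_names) - set(pattern))
        raise ValueError(f"pattern missing species: {missing}")

    observed = set(pattern)
    two_copy = {s for s, c in pattern.items() if c == 2}
    unresolved = DuplicationDate(family_id, UNRESOLVED, False)
    if not two_copy:
        return unresolved
    if any(c == 0 for c in pattern.values()):
        return unresolved  # a loss event would be required
    if two_copy == observed:
        return unresolved  # duplicates present in all (observed) species
    node = tree.mrca(sorted(two_copy))
    clade_observed = {
        l.taxon.label for l in node.leaf_iter() if l.taxon.label in observed
    }
    if clade_observed != two_copy:
        return unresolved  # two-copy set is not a clade: >1 gain required
    if node.parent_node is None:
        return unresolved  # root branch is not a valid origin
    return DuplicationDate(family_id, node.branch_name, True)


def assign_parent_child(
    flags: Mapping[str, bool], family_id: str = ""
) -> ParentChildAssignment:
    """Designate parent/child from per-copy outgroup-alignment flags.

    Resolved iff exactly one of the two copies aligns to the outgroup
    genomes: that copy is the parent (ancestral locus), the other the child.
    """
    if len(flags) != 2:
        raise ValueError("exactly two gene copies are required")
    aligned = [g for g, f in flags.items() if f]
    if len(aligned) != 1:
        return ParentChildAssignment(family_id, None, None, False)
    (parent,) = aligned
    (child,) = [g for g in flags if g != parent]
    return ParentChildAssignment(family_id, parent, child, True)


def select_outgroup_species(
    tree: SpeciesTree,
    focal: str,
    available: Sequence[str],
    priority: Sequence[str] = DEFAULT_SPECIES,
) -> str:
    """The most closely related species with available expression data.

    Minimizes tree path distance to the focal species; ties break by the
    configured species priority list (then lexicographically).
    """
    available = list(available)
    if not available:
        raise ValueError("no available outgroup species")
    if focal in available:
        raise ValueError("focal species cannot be its own outgroup")
    rank = {s: i for i, s in enumerate(priority)}

    def sort_key(s: str):
        return (tree.leaf_distance(focal, s), rank.get(s, len(rank)), s)

    return min(available, key=sort_key)


def enumerate_species_pairs(species: Sequence[str]) -> list[tuple[str, str]]:
    """All n(n-1)/2 unordered species pairs, in input order."""
    species = list(species)
    if len(species) < 2:
        raise ValueError("at least two species are required")
    if len(set(species)) != len(species):
        raise ValueError("species must be unique")
    return list(itertools.combinations(species, 2))
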