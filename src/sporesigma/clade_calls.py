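"""Phylogenetic clade-membership calls for sigma-factor trees.

A sigma-factor phylogeny mixes phage-encoded proteins with bacterial
reference sequences.  A phage protein is called sporulation-like when it
falls inside the clade spanned by the bacterial sporulation-specific
references (the sigF/sigG forespore and sigE/sigK mother-cell regulators),
excluding the nested subclade of sigB and its general-stress relatives,
which sits inside that clade but is not sporulation-associated.  The module
also extracts maximal phage-only monophyletic clades and quantifies
agreement between the phylogenetic and HMM classification methods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import dendropy
import pandas as pd

__all__ = [
    "AnnotatedTree",
    "CladeCall",
    "read_annotated_newick",
    "sporulation_clade_members",
    "phage_only_clades",
    "method_agreement",
]

SOURCES = frozenset({"phage", "bacterial"})


@dataclass
class AnnotatedTree:
    """Rooted tree with per-tip source (phage|bacterial) and family labels."""

    tree: dendropy.Tree
    source: dict[str, str]
    family: dict[str, str]

    @property
    def tip_labels(self) -> set[str]:
        return {lf.taxon.label for lf in self.tree.leaf_node_iter()}

    def phage_tips(self) -> set[str]:
        return {t for t in self.tip_labels if self.source[t] == "phage"}


def _leaf_set(node: dendropy.Node) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def read_annotated_newick(
    newick: str,
    metadata: pd.DataFrame,
    rooting: str | None = None,
    outgroup: Iterable[str] | None = None,
) -> AnnotatedTree:
    """Parse a newick tree and join per-tip metadata.

    ``metadata`` needs columns tip, source (phage|bacterial) and optionally
    family (for bacterial reference tips).  Unrooted inputs (basal
    multifurcation) must come with a rooting directive: ``outgroup`` tips or
    ``rooting="midpoint"``.
    """
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True, rooting="force-rooted"
    )
    labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    meta = metadata.copy()
    if "tip" not in meta.columns or "source" not in meta.columns:
        raise ValueError("metadata needs 'tip' and 'source' columns")
    meta["tip"] = meta["tip"].astype(str)
    missing = sorted(labels - set(meta["tip"]))
    if missing:
        raise KeyError(f"tips missing metadata: {missing}")
    bad = set(meta["source"]) - SOURCES
    if bad:
        raise ValueError(f"unknown source labels: {sorted(bad)}; expected {sorted(SOURCES)}")
    if outgroup is not None:
        og = set(outgroup)
        if not og <= labels:
            raise KeyError(f"outgroup tips absent from tree: {sorted(og - labels)}")
        mrca = tree.mrca(taxon_labels=sorted(og))
        if mrca is tree.seed_node:
            raise ValueError("outgroup spans the whole tree; cannot root on it")
        tree.reroot_at_edge(mrca.edge, update_bipartitions=False)
    elif rooting == "midpoint":
        tree.reroot_at_midpoint(update_bipartitions=False)
    elif len(tree.seed_node.child_nodes()) > 2:
        raise ValueError(
            "tree root is multifurcating (unrooted input): supply an outgroup "
            "or request midpoint rooting"
        )
    source = dict(zip(meta["tip"], meta["source"]))
    family = (
        dict(zip(meta["tip"], meta["family"].astype(str)))
        if "family" in meta.columns
        else {}
    )
    return AnnotatedTree(tree=tree, source=source, family=family)


@dataclass(frozen=True)
class CladeCall:
    """Membership call for the sporulation clade with the sigB exclusion."""

    clade_tips: frozenset[str]
    member_phage_tips: frozenset[str]
    excluded_subclade_tips: frozenset[str]


def sporulation_clade_members(
    atree: AnnotatedTree,
    spore_reference_tips: Iterable[str],
    sigb_reference_tips: Iterable[str],
) -> CladeCall:
    """Phage tips inside the sporulation clade, minus the sigB subclade.

    The sporulation clade is the tip set of the MRCA of the sporulation
    reference tips; the excluded subclade is the tip set of the MRCA of the
    sigB references.  Membership is set-wise, so a sigB subclade that is not
    nested inside the sporulation clade still excludes its tips (with a
    warning).
    """
    spore_refs = set(spore_reference_tips)
    sigb_refs = set(sigb_reference_tips)
    if not spore_refs or not sigb_refs:
        raise ValueError("both reference tip sets must be non-empty")
    labels = atree.tip_labels
    absent = sorted((spore_refs | sigb_refs) - labels)
    if absent:
        raise KeyError(f"reference tips absent from tree: {absent}")
    spore_mrca = atree.tree.mrca(taxon_labels=sorted(spore_refs))
    sigb_mrca = atree.tree.mrca(taxon_labels=sorted(sigb_refs))
    clade = _leaf_set(spore_mrca)
    excluded = _leaf_set(sigb_mrca)
    if not excluded <= clade:
        warnings.warn(
            "sigB subclade is not nested within the sporulation clade; "
            "exclusion applied set-wise",
            stacklevel=2,
        )
    members = frozenset(t for t in clade - excluded if atree.source[t] == "phage")
    return CladeCall(clade_tips=clade, member_phage_tips=members, excluded_subclade_tips=excluded)


def phage_only_clades(atree: AnnotatedTree) -> list[frozenset[str]]:
    """Maximal monophyletic clades containing only phage tips.

    Returned clades are disjoint, each maximal (its parent clade contains a
    bacterial tip), and together cover every phage tip; singletons are
    allowed.  Traversal order is canonicalised so the result is invariant to
    newick child rotation.
    """
    tree = atree.tree
    phage_only: dict[dendropy.Node, bool] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            phage_only[node] = atree.source[node.taxon.label] == "phage"
        else:
            phage_only[node] = all(phage_only[c] for c in node.child_nodes())
    clades = []
    for node in tree.preorder_node_iter():
        if phage_only[node] and (node.parent_node is None or not phage_only[node.parent_node]):
            clades.append(_leaf_set(node))
    return sorted(clades, key=lambda s: (min(s), len(s)))


def method_agreement(
    set_phylo: Iterable[str], set_hmm: Iterable[str]
) -> Mapping[str, float]:
    """Overlap between phylogenetic and HMM sporulation-like calls."""
    a = set(set_phylo)
    b = set(set_hmm)
    union = a | b
    return {
        "n_phylo": len(a),
        "n_hmm": len(b),
        "n_both": len(a & b),
        "jaccard": (len(a & b) / len(union)) if union else 0.0,
    }
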