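"""Clade-membership calls against brute-force clade enumeration."""

import warnings

import numpy as np
import pandas as pd
import pytest

from sporesigma import clade_calls
from sporesigma.clade_calls import (
    method_agreement,
    phage_only_clades,
    read_annotated_newick,
    sporulation_clade_members,
)
from sporesigma.synthetic import _random_subtree, gen_tree


def brute_force_minimal_clade(atree, refs):
    """Smallest internal-node tip set containing all reference tips."""
    best = None
    for node in atree.tree.preorder_node_iter():
        tips = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if set(refs) <= tips and (best is None or len(tips) < len(best)):
            best = tips
    return best


def random_annotated_tree(rng, max_tips=64):
    n = int(rng.integers(5, max_tips + 1))
    labels = [f"t{i}" for i in range(n)]
    sources = ["bacterial"] * 3 + list(rng.choice(["phage", "bacterial"], size=n - 3))
    rng.shuffle(sources)
    # guarantee at least 3 bacterial tips for reference drawing
    bact = [l for l, s in zip(labels, sources) if s == "bacterial"]
    while len(bact) < 3:
        i = int(rng.integers(n))
        sources[i] = "bacterial"
        bact = [l for l, s in zip(labels, sources) if s == "bacterial"]
    newick = _random_subtree(list(labels), rng) + ";"
    meta = pd.DataFrame({"tip": labels, "source": sources})
    return read_annotated_newick(newick, meta), bact


def rotated(atree):
    """Same rooted topology with every node's children reversed."""
    for node in atree.tree.preorder_node_iter():
        children = node.child_nodes()
        if children:
            node.set_child_nodes(list(reversed(children)))
    return atree


class TestReadAnnotatedNewick:
    def test_four_tip_tree(self):
        meta = pd.DataFrame({"tip": list("ABCD"), "source": ["phage"] * 4})
        at = read_annotated_newick("((A,B),(C,D));", meta)
        assert at.tip_labels == set("ABCD")

    def test_missing_metadata_names_tip(self):
        meta = pd.DataFrame({"tip": list("ABCD"), "source": ["phage"] * 4})
        with pytest.raises(KeyError, match="E"):
            read_annotated_newick("((A,B),(C,E));", meta)

    def test_unrooted_needs_directive(self):
        meta = pd.DataFrame({"tip": list("ABC"), "source": ["phage"] * 3})
        with pytest.raises(ValueError, match="outgroup|midpoint"):
            read_annotated_newick("(A,B,C);", meta)

    def test_outgroup_rooting(self):
        meta = pd.DataFrame(
            {"tip": list("ABC"), "source": ["bacterial", "phage", "phage"]}
        )
        at = read_annotated_newick("(A:1,B:1,C:1);", meta, outgroup=["A"])
        # A sits on its own side of the root
        root_children = at.tree.seed_node.child_nodes()
        sides = [frozenset(lf.taxon.label for lf in c.leaf_iter()) for c in root_children]
        assert frozenset({"A"}) in sides


class TestSporulationCladeMembers:
    def test_hand_built_example(self):
        """Six-tip tree: minimal clade spans the refs, sigB tip excluded."""
        meta = pd.DataFrame(
            {
                "tip": ["sigF", "P1", "sigG", "sigB", "P2", "out"],
                "source": ["bacterial", "phage", "bacterial", "bacterial", "phage", "bacterial"],
            }
        )
        at = read_annotated_newick("(((sigF,(P1,sigG)),(sigB,P2)),out);", meta)
        call = sporulation_clade_members(at, ["sigF", "sigG"], ["sigB"])
        # brute force: the smallest superset of {sigF, sigG} is the inner 3-tip
        # clade, so only P1 is a member
        assert call.clade_tips == frozenset({"sigF", "P1", "sigG"})
        assert call.member_phage_tips == frozenset({"P1"})
        assert call.excluded_subclade_tips == frozenset({"sigB"})

    def test_no_phage_tips_means_no_members(self):
        meta = pd.DataFrame({"tip": list("ABCD"), "source": ["bacterial"] * 4})
        at = read_annotated_newick("((A,B),(C,D));", meta)
        call = sporulation_clade_members(at, ["A", "B"], ["C"])
        assert call.member_phage_tips == frozenset()

    def test_all_phage_inside_sigb_subclade_excluded(self):
        newick, meta, truth = gen_tree(0, 0, n_phage_in_sigb=3, seed=4)
        at = read_annotated_newick(newick, meta)
        call = sporulation_clade_members(
            at, ["sigF_ref", "sigG_ref", "sigE_ref", "sigK_ref"], ["sigB_ref", "sigB_rel_ref"]
        )
        assert call.member_phage_tips == frozenset()
        assert truth.sigb_phage_tips <= call.excluded_subclade_tips

    def test_missing_reference_rejected(self):
        meta = pd.DataFrame({"tip": list("AB"), "source": ["bacterial"] * 2})
        at = read_annotated_newick("(A,B);", meta)
        with pytest.raises(KeyError):
            sporulation_clade_members(at, ["A", "Z"], ["B"])

    def test_non_nested_sigb_warns_but_excludes(self):
        meta = pd.DataFrame(
            {"tip": list("ABCD"), "source": ["bacterial", "bacterial", "bacterial", "phage"]}
        )
        at = read_annotated_newick("((A,B),(C,D));", meta)
        with pytest.warns(UserWarning, match="not nested"):
            call = sporulation_clade_members(at, ["A", "B"], ["C"])
        assert call.member_phage_tips == frozenset()

    def test_matches_brute_force_on_random_trees(self, rng):
        for _ in range(40):
            at, bact = random_annotated_tree(rng, max_tips=64)
            spore_refs = list(rng.choice(bact, size=2, replace=False))
            sigb_refs = [b for b in bact if b not in spore_refs][:1]
            with warnings.catch_warnings():
                # random reference picks legitimately produce non-nested sigB sets
                warnings.simplefilter("ignore", UserWarning)
                call = sporulation_clade_members(at, spore_refs, sigb_refs)
            clade = brute_force_minimal_clade(at, spore_refs)
            excluded = brute_force_minimal_clade(at, sigb_refs)
            assert call.clade_tips == clade
            assert call.excluded_subclade_tips == excluded
            assert call.member_phage_tips == frozenset(
                t for t in clade - excluded if at.source[t] == "phage"
            )

    def test_generated_tree_truth_recovered(self):
        for seed in range(5):
            newick, meta, truth = gen_tree(4, 6, n_phage_in_sigb=1, seed=seed)
            at = read_annotated_newick(newick, meta)
            call = sporulation_clade_members(
                at,
                ["sigF_ref", "sigG_ref", "sigE_ref", "sigK_ref"],
                ["sigB_ref", "sigB_rel_ref"],
            )
            assert call.member_phage_tips == truth.member_phage_tips


class TestPhageOnlyClades:
    def _tree(self, newick, sources):
        meta = pd.DataFrame({"tip": list(sources), "source": list(sources.values())})
        return read_annotated_newick(newick, meta)

    def test_simple_pair(self):
        at = self._tree("((P1,P2),B1);", {"P1": "phage", "P2": "phage", "B1": "bacterial"})
        assert phage_only_clades(at) == [frozenset({"P1", "P2"})]

    def test_maximality_forces_singletons(self):
        at = self._tree(
            "((P1,B1),(P2,B2));",
            {"P1": "phage", "B1": "bacterial", "P2": "phage", "B2": "bacterial"},
        )
        assert phage_only_clades(at) == [frozenset({"P1"}), frozenset({"P2"})]

    def test_fully_phage_tree_is_one_clade(self):
        at = self._tree("((P1,P2),P3);", {f"P{i}": "phage" for i in (1, 2, 3)})
        assert phage_only_clades(at) == [frozenset({"P1", "P2", "P3"})]

    def test_no_phage_tips_gives_empty_list(self):
        at = self._tree("(B1,B2);", {"B1": "bacterial", "B2": "bacterial"})
        assert phage_only_clades(at) == []

    def test_partition_property_on_random_trees(self, rng):
        for _ in range(40):
            at, _ = random_annotated_tree(rng, max_tips=64)
            clades = phage_only_clades(at)
            tips = [t for c in clades for t in c]
            assert len(tips) == len(set(tips))  # pairwise disjoint
            assert set(tips) == at.phage_tips()  # cover every phage tip
            # maximality: no returned clade is a strict subset of another
            # phage-only clade enumerated by brute force
            all_clades = [
                frozenset(lf.taxon.label for lf in node.leaf_iter())
                for node in at.tree.preorder_node_iter()
                if all(at.source[lf.taxon.label] == "phage" for lf in node.leaf_iter())
            ]
            for c in clades:
                assert not any(c < other for other in all_clades)

    def test_rotation_invariance(self, rng):
        for _ in range(10):
            at, bact = random_annotated_tree(rng, max_tips=32)
            spore_refs = list(rng.choice(bact, size=2, replace=False))
            sigb_refs = [b for b in bact if b not in spore_refs][:1]
            before = phage_only_clades(at)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                call_before = sporulation_clade_members(at, spore_refs, sigb_refs)
                rot = rotated(at)
                assert phage_only_clades(rot) == before
                assert sporulation_clade_members(rot, spore_refs, sigb_refs) == call_before


class TestMethodAgreement:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ({"x", "y", "z"}, {"y", "z", "w"}, (3, 3, 2)),
            ({"x", "y"}, {"x", "y"}, (2, 2, 2)),
            ({"x"}, {"y"}, (1, 1, 0)),
        ],
    )
    def test_counts(self, a, b, expected):
        r = method_agreement(a, b)
        assert (r["n_phylo"], r["n_hmm"], r["n_both"]) == expected

    def test_jaccard(self):
        assert method_agreement({"x"}, {"y"})["jaccard"] == 0.0
        assert method_agreement({"x"}, {"x"})["jaccard"] == 1.0
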