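"""Presence-matrix construction, tree mapping, parsimony against exhaustive
oracles, Dollo-simulation recovery, monophyly, and iTOL round trips."""

import numpy as np
import pandas as pd
import pytest

from _oracles import exhaustive_fitch_changes
from mlascan.phyletics import (
    build_matrix,
    check_monophyly,
    dollo_root_inference,
    export_itol,
    fitch_parsimony,
    map_to_tree,
    read_itol,
    read_tree,
)
from mlascan.synthetic_data import random_rooted_tree, simulate_dollo
from mlascan.types import PhyleticProfile


def _profile(data, taxa):
    return PhyleticProfile(matrix=pd.DataFrame(data, index=pd.Index(taxa, name="taxon")))


class TestBuildMatrix:
    def test_one_genome_per_taxon_is_identity(self):
        pres = pd.DataFrame({"MlaD": [True, False]}, index=["g1", "g2"])
        prof = build_matrix(pres, {"g1": "t1", "g2": "t2"})
        assert prof.matrix.loc["t1", "MlaD"] and not prof.matrix.loc["t2", "MlaD"]

    def test_or_semantics_over_genomes_of_a_taxon(self):
        pres = pd.DataFrame({"MlaD": [True, False], "MlaA": [False, False]},
                            index=["g1", "g2"])
        prof = build_matrix(pres, {"g1": "t", "g2": "t"})
        assert prof.matrix.loc["t", "MlaD"]
        assert not prof.matrix.loc["t", "MlaA"]

    def test_unmapped_genome_is_error(self):
        pres = pd.DataFrame({"MlaD": [True]}, index=["orphan"])
        with pytest.raises(ValueError, match="orphan"):
            build_matrix(pres, {})

    def test_derived_barrel_column(self):
        from mlascan.architecture import classify_architecture

        pres = pd.DataFrame({"MlaD": [True, True]}, index=["g1", "g2"])
        barrel = classify_architecture(
            "p1", 419, (36, 140), [(300 + 12 * k, 307 + 12 * k) for k in range(10)]
        )
        short = classify_architecture("p2", 183, (36, 140), [])
        prof = build_matrix(
            pres, {"g1": "t1", "g2": "t2"},
            architecture_calls=[barrel, short],
            genome_of_protein={"p1": "g1", "p2": "g2"},
        )
        assert prof.matrix.loc["t1", "MlaD_barrel"]
        assert not prof.matrix.loc["t2", "MlaD_barrel"]


class TestMapToTree:
    def test_full_overlap_annotates_every_leaf(self):
        tree = read_tree("((A:1,B:1):1,(C:1,D:1):1);", is_path=False)
        prof = _profile({"MlaD": [True, True, False, False]}, ["A", "B", "C", "D"])
        vecs, missing, unknown = map_to_tree(prof, tree)
        assert set(vecs) == {"A", "B", "C", "D"} and not missing and not unknown

    def test_extra_profile_taxon_reported(self):
        tree = read_tree("((A:1,B:1):1,C:1);", is_path=False)
        prof = _profile({"MlaD": [True, True, True, False]}, ["A", "B", "C", "Zed"])
        _, missing, _ = map_to_tree(prof, tree)
        assert missing == ["Zed"]

    def test_annotation_invariant_to_taxon_order(self):
        tree = read_tree("((A:1,B:1):1,(C:1,D:1):1);", is_path=False)
        taxa = ["A", "B", "C", "D"]
        prof1 = _profile({"MlaD": [True, False, True, False]}, taxa)
        perm = [2, 0, 3, 1]
        prof2 = PhyleticProfile(matrix=prof1.matrix.iloc[perm])
        v1, _, _ = map_to_tree(prof1, tree)
        v2, _, _ = map_to_tree(prof2, tree)
        assert v1 == v2

    def test_zero_overlap_is_error(self):
        tree = read_tree("(A:1,B:1);", is_path=False)
        prof = _profile({"MlaD": [True]}, ["Zebra"])
        with pytest.raises(ValueError, match="naming"):
            map_to_tree(prof, tree)

    def test_normalization_bridges_label_drift(self):
        tree = read_tree("(Veillonella_parvula:1,E.coli:1);", is_path=False)
        prof = _profile({"MlaD": [True, False]}, ["Veillonella parvula", "e coli"])
        vecs, missing, unknown = map_to_tree(prof, tree)
        assert not missing and not unknown


class TestFitchParsimony:
    def test_uniform_presence_needs_no_change(self):
        tree = read_tree("((A:1,B:1):1,(C:1,D:1):1);", is_path=False)
        anc = fitch_parsimony(tree, {t: True for t in "ABCD"})
        assert anc.n_changes == 0 and anc.root_state is True

    def test_textbook_two_clade_split(self):
        tree = read_tree("((A:1,B:1):1,(C:1,D:1):1);", is_path=False)
        anc = fitch_parsimony(tree, {"A": True, "B": True, "C": False, "D": False})
        assert anc.n_changes == 1
        assert anc.root_state is True and anc.ambiguous_root

    def test_matches_exhaustive_minimization_on_random_trees(self):
        rng = np.random.default_rng(51)
        for trial in range(100):
            n = int(rng.integers(4, 11))
            tree = random_rooted_tree(n, seed=int(rng.integers(0, 2**31)))
            states = {f"L{i + 1}": bool(rng.integers(0, 2)) for i in range(n)}
            anc = fitch_parsimony(tree, states)
            assert anc.n_changes == exhaustive_fitch_changes(tree, states), f"trial {trial}"

    def test_change_count_equals_realized_branch_differences(self):
        rng = np.random.default_rng(52)
        for _ in range(50):
            n = int(rng.integers(4, 12))
            tree = random_rooted_tree(n, seed=int(rng.integers(0, 2**31)))
            states = {f"L{i + 1}": bool(rng.integers(0, 2)) for i in range(n)}
            anc = fitch_parsimony(tree, states)
            realized = 0
            for node in tree.preorder_node_iter():
                if node.parent_node is None:
                    continue
                lbl = node.label if not node.is_leaf() else node.taxon.label
                plbl = node.parent_node.label
                realized += anc.states[lbl] != anc.states[plbl]
            assert realized == anc.n_changes

    def test_unscored_leaves_are_ignored(self):
        tree = read_tree("((A:1,B:1):1,(C:1,D:1):1);", is_path=False)
        anc = fitch_parsimony(tree, {"A": True, "B": True, "C": False})
        assert anc.n_changes == 1


class TestDolloRootInference:
    def test_presence_in_one_root_subtree_puts_gain_inside(self):
        tree = read_tree("((A:1,B:1):1,(C:1,D:1):1);", is_path=False)
        anc = dollo_root_inference(tree, {"A": True, "B": True, "C": False, "D": False})
        assert anc.root_state is False
        assert anc.states["A"] and anc.states["B"]

    def test_presence_in_both_basal_clades_implies_ancestral(self):
        # Terrabacteria-like and Gracilicutes-like subtrees both retain the system
        tree = read_tree(
            "((vparvula:1,mtuberculosis:1)Terra:1,(ecoli:1,bacteroides:1)Gracil:1)Root;",
            is_path=False,
        )
        anc = dollo_root_inference(
            tree, {"vparvula": True, "mtuberculosis": False, "ecoli": True, "bacteroides": False}
        )
        assert anc.root_state is True

    def test_simulation_recovery_in_recoverable_cases(self):
        recovered = total = 0
        for rep in range(200):
            tree = random_rooted_tree(16, seed=rep)
            leaves, nodes = simulate_dollo(tree, True, 0.1, seed=10_000 + rep)
            root = tree.seed_node
            sides = [
                any(leaves[l.taxon.label] for l in child.leaf_iter())
                for child in root.child_nodes()
            ]
            anc = dollo_root_inference(tree, leaves)
            if sum(sides) >= 2:  # recoverable: presence on both sides of the root
                total += 1
                recovered += anc.root_state is True
        assert total > 50
        assert recovered == total

    def test_loss_count_at_least_fitch_minus_one(self):
        rng = np.random.default_rng(53)
        for _ in range(50):
            n = int(rng.integers(4, 12))
            tree = random_rooted_tree(n, seed=int(rng.integers(0, 2**31)))
            states = {f"L{i + 1}": bool(rng.integers(0, 2)) for i in range(n)}
            fitch = fitch_parsimony(tree, states)
            dollo = dollo_root_inference(tree, states)
            assert dollo.n_changes >= fitch.n_changes - 1

    def test_rotation_of_children_does_not_change_results(self):
        states = {"A": True, "B": False, "C": True, "D": False, "E": True}
        t1 = read_tree("(((A:1,B:1):1,C:1):1,(D:1,E:1):1);", is_path=False)
        t2 = read_tree("((E:1,D:1):1,(C:1,(B:1,A:1):1):1);", is_path=False)
        f1, f2 = fitch_parsimony(t1, states), fitch_parsimony(t2, states)
        d1, d2 = dollo_root_inference(t1, states), dollo_root_inference(t2, states)
        assert f1.n_changes == f2.n_changes and f1.root_state == f2.root_state
        assert d1.n_changes == d2.n_changes and d1.root_state == d2.root_state


class TestMonophyly:
    def test_supported_clade(self):
        tree = read_tree("((A:1,B:1)95:1,(C:1,D:1):1);", is_path=False)
        assert check_monophyly(tree, {"A", "B"}) == (True, 95.0)

    def test_non_clade(self):
        tree = read_tree("((A:1,B:1)95:1,(C:1,D:1):1);", is_path=False)
        is_mono, support = check_monophyly(tree, {"A", "C"})
        assert not is_mono and support is None

    def test_matches_leafset_comparison_on_random_trees(self):
        rng = np.random.default_rng(54)
        for _ in range(30):
            n = int(rng.integers(4, 10))
            tree = random_rooted_tree(n, seed=int(rng.integers(0, 2**31)))
            k = int(rng.integers(1, n))
            subset = {f"L{i + 1}" for i in rng.choice(n, size=k, replace=False)}
            is_mono, _ = check_monophyly(tree, subset)
            # oracle: some node's exact leaf set
            leafsets = set()
            for node in tree.preorder_node_iter():
                leafsets.add(frozenset(l.taxon.label for l in node.leaf_iter()))
            assert is_mono == (frozenset(subset) in leafsets)

    def test_empty_set_is_error(self):
        tree = read_tree("(A:1,B:1);", is_path=False)
        with pytest.raises(ValueError):
            check_monophyly(tree, set())


class TestItolExport:
    def test_block_and_line_counts(self):
        prof = _profile(
            {c: [True, False] for c in ["MlaA", "MlaB", "MlaC", "MlaD", "MlaE", "MlaF", "TamB"]},
            ["t1", "t2"],
        )
        text = export_itol(prof)
        assert text.count("DATASET_BINARY") == 7
        assert text.count("\nt1\t") + text.count("\nt2\t") == 14

    def test_round_trip_preserves_matrix(self):
        rng = np.random.default_rng(55)
        mat = pd.DataFrame(
            rng.integers(0, 2, size=(5, 4)).astype(bool),
            index=pd.Index([f"tax{i}" for i in range(5)], name="taxon"),
            columns=["MlaD", "MlaE", "MlaF", "MlaD_barrel"],
        )
        prof = PhyleticProfile(matrix=mat)
        back = read_itol(export_itol(prof))
        pd.testing.assert_frame_equal(back.matrix, mat)

    def test_all_absent_component_still_exported(self):
        prof = _profile({"MlaA": [False, False], "MlaD": [True, True]}, ["t1", "t2"])
        text = export_itol(prof)
        assert "DATASET_LABEL\tMlaA" in text
        assert "t1\t0" in text
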