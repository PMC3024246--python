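import itertools

import numpy as np
import pytest

from cnetrace.dollo import (
    annotated_newick,
    dollo_reconstruct,
    event_report,
    fitch_events,
    list_synapomorphies,
)
from cnetrace.io import CharacterMatrix, parse_newick
from cnetrace.scenario import dlx_scenario
from oracles import min_dollo_events, random_tree_newick, rooted_binary_shapes

FISH_NEWICK = (
    "(zebrafish,((Takifugu,Tetraodon),(stickleback,(medaka,A.burtoni))));"
)


def matrix_of(column, taxa):
    return CharacterMatrix.from_dict({"c": dict(zip(taxa, column))}, taxa=taxa)


class TestDolloReconstruct:
    def test_character_present_everywhere_gains_on_root_stem(self):
        tree = parse_newick("((A,B)ab,(C,D)cd)root;")
        matrix = matrix_of("1111", list("ABCD"))
        rec = dollo_reconstruct(matrix, tree)
        history = rec.history("c")
        assert history.gain_branch == "root"
        assert history.loss_branches == frozenset()
        assert history.n_events == 1

    def test_cichlid_specific_loss_of_shared_element(self):
        # present in zebrafish, both pufferfishes, stickleback and medaka;
        # absent only in the cichlid: one gain at the teleost root, one
        # loss on the terminal cichlid branch
        tree = parse_newick(FISH_NEWICK)
        taxa = ["zebrafish", "Takifugu", "Tetraodon", "stickleback", "medaka", "A.burtoni"]
        matrix = matrix_of("111110", taxa)
        rec = dollo_reconstruct(matrix, tree)
        history = rec.history("c")
        assert history.gain_branch == tree.root.label
        assert history.loss_branches == {"A.burtoni"}
        assert history.n_events == 2

    def test_missing_taxon_error_names_it(self):
        tree = parse_newick("((A,B),C);")
        matrix = matrix_of("11", ["A", "ghost"])
        with pytest.raises(ValueError, match="ghost"):
            dollo_reconstruct(matrix, tree)

    def test_vacuous_character_skipped_and_flagged(self):
        tree = parse_newick("((A,B),C);")
        matrix = matrix_of("00?", ["A", "B", "C"])
        rec = dollo_reconstruct(matrix, tree)
        assert rec.histories == ()
        assert rec.vacuous == ("c",)

    def test_unknown_sister_lineages_pull_gain_to_root_stem(self):
        # all observed leaves present, outgroup unknown: the gain resolves
        # to the root stem (presence costs nothing and ties go to parent)
        tree = parse_newick("(out,(A,(B,C)bc)ingroup)root;")
        matrix = matrix_of("?111", ["out", "A", "B", "C"])
        history = dollo_reconstruct(matrix, tree).history("c")
        assert history.gain_branch == "root"
        assert history.loss_branches == frozenset()

    def test_observed_absence_blocks_gain_raising(self):
        tree = parse_newick("(out,(A,(B,C)bc)ingroup)root;")
        matrix = matrix_of("0111", ["out", "A", "B", "C"])
        history = dollo_reconstruct(matrix, tree).history("c")
        assert history.gain_branch == "ingroup"

    def test_leaf_consistency_invariant(self, rng):
        tree = parse_newick(random_tree_newick(rng, 7))
        taxa = tree.leaf_labels
        for _ in range(50):
            column = "".join(rng.choice(list("01?"), size=len(taxa)))
            if "1" not in column:
                continue
            matrix = matrix_of(column, taxa)
            history = dollo_reconstruct(matrix, tree).history("c")
            for taxon, state in zip(taxa, column):
                if state == "?":
                    continue
                assert history.node_states[taxon] == int(state)

    def test_matches_brute_force_on_all_small_shapes(self):
        for n in range(2, 6):
            for newick in rooted_binary_shapes(n):
                tree = parse_newick(newick)
                taxa = tree.leaf_labels
                for bits in itertools.product("01", repeat=n):
                    if "1" not in bits:
                        continue
                    matrix = matrix_of("".join(bits), taxa)
                    got = dollo_reconstruct(matrix, tree).history("c").n_events
                    assert got == min_dollo_events(tree, {
                        t: int(b) for t, b in zip(taxa, bits)
                    })

    def test_taxon_order_never_changes_reconstruction(self, rng):
        tree = parse_newick(FISH_NEWICK)
        taxa = tree.leaf_labels
        column = dict(zip(taxa, "1?0110"))
        base = None
        for perm in itertools.islice(itertools.permutations(taxa), 8):
            matrix = CharacterMatrix.from_dict(
                {"c": {t: column[t] for t in perm}}, taxa=list(perm)
            )
            history = dollo_reconstruct(matrix, tree).history("c")
            key = (history.gain_branch, history.loss_branches)
            if base is None:
                base = key
            assert key == base

    def test_adding_unknown_observation_never_increases_events(self, rng):
        tree = parse_newick(random_tree_newick(rng, 6))
        taxa = tree.leaf_labels
        for _ in range(40):
            column = list(rng.choice(list("01"), size=len(taxa)))
            if "1" not in column:
                continue
            before = dollo_reconstruct(matrix_of("".join(column), taxa), tree)
            idx = int(rng.integers(len(taxa)))
            column[idx] = "?"
            if "1" not in column:
                continue
            after = dollo_reconstruct(matrix_of("".join(column), taxa), tree)
            assert after.history("c").n_events <= before.history("c").n_events


class TestForcedGains:
    def test_all_absent_character_with_known_origin_gains_and_loses(self):
        tree = parse_newick(FISH_NEWICK)
        taxa = tree.leaf_labels
        matrix = matrix_of("0" * 6, taxa)
        rec = dollo_reconstruct(matrix, tree, forced_gains={"c": tree.root.label})
        history = rec.history("c")
        assert history.gain_branch == tree.root.label
        assert history.loss_branches == {tree.root.label}
        assert history.n_events == 2

    def test_forced_gain_excluding_present_taxon_rejected(self):
        tree = parse_newick("((A,B)ab,C)root;")
        matrix = matrix_of("101", ["A", "B", "C"])
        with pytest.raises(ValueError, match="forced gain"):
            dollo_reconstruct(matrix, tree, forced_gains={"c": "ab"})

    def test_unknown_forced_branch_rejected(self):
        tree = parse_newick("((A,B),C);")
        matrix = matrix_of("110", ["A", "B", "C"])
        with pytest.raises(ValueError, match="not in tree"):
            dollo_reconstruct(matrix, tree, forced_gains={"c": "nowhere"})


@pytest.fixture(scope="module")
def reconstruction():
    scenario = dlx_scenario()
    return dollo_reconstruct(
        scenario.matrix, scenario.tree, forced_gains=scenario.gene_origins
    )


class TestScenarioQueries:
    def test_stickleback_medaka_cichlid_stem_synapomorphies(self, reconstruction):
        gains = list_synapomorphies(reconstruction, "smc")
        for char in ("I12.3ab", "I56.2", "F56.10"):
            assert char in gains

    def test_root_stem_carries_deeply_conserved_elements(self, reconstruction):
        gains = list_synapomorphies(reconstruction, "Osteichthyes")
        assert "F56.9" in gains
        assert "I12.5" in gains

    def test_branch_without_gains_lists_empty(self, reconstruction):
        assert list_synapomorphies(reconstruction, "Tetraodon") == []

    def test_unknown_branch_rejected(self, reconstruction):
        with pytest.raises(KeyError):
            list_synapomorphies(reconstruction, "no_such_branch")


class TestEventReport:
    def test_counts_sum_to_total_events(self, rng):
        tree = parse_newick(random_tree_newick(rng, 6))
        taxa = tree.leaf_labels
        states = {
            f"c{i}": dict(zip(taxa, rng.choice(list("011?"), size=len(taxa))))
            for i in range(10)
        }
        matrix = CharacterMatrix.from_dict(states, taxa=taxa)
        matrix = CharacterMatrix(
            matrix.frame[[c for c in matrix.characters if c not in matrix.vacuous_characters]]
        )
        rec = dollo_reconstruct(matrix, tree)
        report = event_report(rec)
        assert report["n_gains"].sum() + report["n_losses"].sum() == rec.total_events

    def test_all_present_character_reports_single_root_gain(self):
        tree = parse_newick("((A,B)ab,C)root;")
        rec = dollo_reconstruct(matrix_of("111", ["A", "B", "C"]), tree)
        report = event_report(rec).set_index("branch")
        assert report.at["root", "gained"] == "c"
        assert (report["n_losses"] == 0).all()

    def test_annotated_newick_contains_event_comments(self):
        tree = parse_newick("((A,B)ab,C)root;")
        rec = dollo_reconstruct(matrix_of("110", ["A", "B", "C"]), tree)
        text = annotated_newick(rec)
        assert text.endswith(";")
        assert "[&gains=1,losses=0]" in text


class TestFitchComparison:
    def test_fitch_never_needs_more_changes_than_dollo_events(self, rng):
        tree = parse_newick(random_tree_newick(rng, 6))
        taxa = tree.leaf_labels
        for _ in range(30):
            column = "".join(rng.choice(list("01"), size=len(taxa)))
            if "1" not in column:
                continue
            matrix = matrix_of(column, taxa)
            dollo_events = dollo_reconstruct(matrix, tree).history("c").n_events
            assert fitch_events(matrix, tree)["c"] <= dollo_events
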