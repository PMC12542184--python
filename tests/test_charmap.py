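"""Fitch parsimony and ACCTRAN/DELTRAN resolution.

Oracle: exhaustive enumeration of all internal-node state assignments
on small trees, counting state changes along every branch directly.
"""

import itertools
import random

import pytest

from phyloconcord.charmap import (
    CharacterError,
    CharacterMatrix,
    acctran,
    deltran,
    fitch_length,
    map_diagnoses,
)
from phyloconcord.simulate import simulate_reference_tree
from phyloconcord.treeio import parse_newick


def brute_force_min_steps(tree, char, states):
    """Minimum changes over every assignment of states to internal nodes."""
    internals = [n for n in tree.preorder() if not n.is_leaf]
    best = None
    for combo in itertools.product(states, repeat=len(internals)):
        assigned = dict(zip((id(n) for n in internals), combo))

        def state_of(node):
            if node.is_leaf:
                return char.get(node.taxon, "?")
            return assigned[id(node)]

        steps = 0
        feasible = True
        for node in tree.preorder():
            if node is tree.root:
                continue
            s, p = state_of(node), state_of(node.parent)
            if s == "?":
                continue  # missing leaf: free to match, contributes no step
            if s != p:
                steps += 1
        if feasible and (best is None or steps < best):
            best = steps
    return best


def brute_force_optimal_assignments(tree, char, states):
    """All internal assignments realizing the minimum step count."""
    internals = [n for n in tree.preorder() if not n.is_leaf]
    best = brute_force_min_steps(tree, char, states)
    out = []
    for combo in itertools.product(states, repeat=len(internals)):
        assigned = dict(zip((id(n) for n in internals), combo))
        steps = 0
        for node in tree.preorder():
            if node is tree.root:
                continue
            s = (
                char.get(node.taxon, "?")
                if node.is_leaf
                else assigned[id(node)]
            )
            p = assigned[id(node.parent)]
            if s != "?" and s != p:
                steps += 1
        if steps == best:
            out.append({id(n): assigned[id(n)] for n in internals})
    return best, out


class TestFitchLength:
    def test_constant_character_zero_steps(self):
        t = parse_newick("[&R] (((A,B),C),D);")
        assert fitch_length(t, {x: "0" for x in "ABCD"}) == 0

    def test_single_clean_split_one_step(self):
        t = parse_newick("[&R] ((A,B),(C,D));")
        assert fitch_length(t, {"A": "1", "B": "1", "C": "0", "D": "0"}) == 1

    def test_zero_observed_states_rejected(self):
        t = parse_newick("[&R] ((A,B),(C,D));")
        with pytest.raises(CharacterError):
            fitch_length(t, {x: "?" for x in "ABCD"})

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_exhaustive_oracle(self, trial):
        rng = random.Random(trial)
        n = rng.randint(4, 8)
        tree = simulate_reference_tree(n, seed=7000 + trial)
        n_states = rng.choice([2, 2, 3])
        states = [str(i) for i in range(n_states)]
        char = {
            t: rng.choice(states + (["?"] if trial % 4 == 0 else []))
            for t in tree.tips
        }
        if all(v == "?" for v in char.values()):
            char[sorted(char)[0]] = "0"
        assert fitch_length(tree, char) == brute_force_min_steps(
            tree, char, states
        )

    @pytest.mark.parametrize("trial", range(10))
    def test_exact_on_polytomies(self, trial):
        """Collapsing branches never lets the step count fall below the
        exhaustive minimum of the collapsed tree."""
        rng = random.Random(trial)
        tree = simulate_reference_tree(7, seed=7100 + trial)
        for node in tree.preorder():
            if node.support is not None:
                node.support = rng.choice([5, 100])
        poly = tree.collapse_low_support(30)
        states = ["0", "1"]
        char = {t: rng.choice(states) for t in poly.tips}
        assert fitch_length(poly, char) == brute_force_min_steps(
            poly, char, states
        )

    def test_missing_taxon_never_increases_length(self):
        rng = random.Random(99)
        for trial in range(10):
            tree = simulate_reference_tree(8, seed=7200 + trial)
            char = {t: rng.choice("01") for t in tree.tips}
            base = fitch_length(tree, char)
            knocked = dict(char)
            knocked[sorted(char)[trial % 8]] = "?"
            assert fitch_length(tree, knocked) <= base


class TestResolutions:
    def test_unambiguous_character_identical_maps(self):
        t = parse_newick("[&R] ((A,B),(C,D));")
        char = {"A": "1", "B": "1", "C": "0", "D": "0"}
        a, d = acctran(t, char), deltran(t, char)
        assert a.node_states == d.node_states
        assert a.total_steps == d.total_steps == 1

    def test_four_tip_unique_reconstruction(self):
        """((A:1,B:0),(C:0,D:0)) has a single optimum: the change sits on
        A's pendant edge, so both resolutions agree (verified against the
        brute-force enumeration of optimal assignments)."""
        t = parse_newick("[&R] ((A,B),(C,D));")
        char = {"A": "1", "B": "0", "C": "0", "D": "0"}
        best, optima = brute_force_optimal_assignments(t, char, ["0", "1"])
        assert best == 1 and len(optima) == 1
        a, d = acctran(t, char), deltran(t, char)
        assert a.change_list == d.change_list
        assert a.change_list[0][0] == frozenset({"A"})

    def test_acctran_change_nearer_root_than_deltran(self):
        """With a missing intermediate, ACCTRAN pushes the gain root-ward
        and DELTRAN tip-ward; both stay optimal."""
        t = parse_newick("[&R] ((((A,B),C),D),E);")
        char = {"A": "1", "B": "1", "C": "?", "D": "0", "E": "0"}
        a, d = acctran(t, char), deltran(t, char)
        assert a.total_steps == d.total_steps == fitch_length(t, char) == 1
        (a_clade, _, _), = a.change_list
        (d_clade, _, _), = d.change_list
        assert a_clade == frozenset({"A", "B", "C"})
        assert d_clade == frozenset({"A", "B"})
        assert len(a_clade) > len(d_clade)  # closer to the root

    @pytest.mark.parametrize("trial", range(30))
    def test_step_counts_equal_fitch_length(self, trial):
        rng = random.Random(trial)
        n = rng.randint(5, 12)
        tree = simulate_reference_tree(n, seed=7300 + trial)
        states = [str(i) for i in range(rng.choice([2, 3]))]
        char = {t: rng.choice(states) for t in tree.tips}
        expected = fitch_length(tree, char)
        assert acctran(tree, char).total_steps == expected
        assert deltran(tree, char).total_steps == expected

    @pytest.mark.parametrize("trial", range(8))
    def test_resolutions_are_globally_optimal(self, trial):
        """Every resolved map realizes the exhaustive minimum."""
        rng = random.Random(trial)
        tree = simulate_reference_tree(7, seed=7400 + trial)
        states = ["0", "1"]
        char = {t: rng.choice(states) for t in tree.tips}
        best = brute_force_min_steps(tree, char, states)
        assert acctran(tree, char).total_steps == best
        assert deltran(tree, char).total_steps == best

    def test_state_relabeling_symmetry(self):
        tree = simulate_reference_tree(8, seed=55)
        rng = random.Random(55)
        char = {t: rng.choice("01") for t in tree.tips}
        swapped = {t: {"0": "1", "1": "0"}[s] for t, s in char.items()}
        a1 = acctran(tree, char)
        a2 = acctran(tree, swapped)
        assert a1.total_steps == a2.total_steps
        assert {k: {"0": "1", "1": "0"}[v] for k, v in a1.node_states.items()} == \
            a2.node_states


class TestMatrixAndDiagnoses:
    def test_matrix_from_tsv(self, tmp_path):
        path = tmp_path / "chars.tsv"
        path.write_text(
            "taxon\tc1\tc2\nA\t0\t1\nB\t0\t?\nC\t1\t1\nD\t1\t0\n"
        )
        m = CharacterMatrix.from_tsv(str(path))
        assert m.characters == ["c1", "c2"]
        assert m.observed_states("c2") == ["0", "1"]
        assert m.states[("B", "c2")] == "?"

    def test_nonrectangular_rejected(self):
        with pytest.raises(CharacterError, match="rectangular"):
            CharacterMatrix(taxa=["A", "B"], characters=["c1"],
                            states={("A", "c1"): "0"})

    def test_stem_synapomorphy_listed_under_both_methods(self):
        t = parse_newick("[&R] (((A,B),C),(D,E));")
        matrix = CharacterMatrix(
            taxa=list("ABCDE"),
            characters=["wing"],
            states={(x, "wing"): ("1" if x in "AB" else "0") for x in "ABCDE"},
        )
        report = map_diagnoses(t, matrix, {"pair": {"A", "B"}})
        assert report["pair"]["acctran"] == ["wing"]
        assert report["pair"]["deltran"] == ["wing"]

    def test_constant_character_no_group(self):
        t = parse_newick("[&R] (((A,B),C),(D,E));")
        matrix = CharacterMatrix(
            taxa=list("ABCDE"),
            characters=["fixed"],
            states={(x, "fixed"): "0" for x in "ABCDE"},
        )
        report = map_diagnoses(t, matrix, {"pair": {"A", "B"}})
        assert report["pair"] == {"acctran": [], "deltran": []}

    def test_non_monophyletic_group_skipped_with_warning(self):
        t = parse_newick("[&R] (((A,B),C),(D,E));")
        matrix = CharacterMatrix(
            taxa=list("ABCDE"),
            characters=["c"],
            states={(x, "c"): "0" for x in "ABCDE"},
        )
        with pytest.warns(UserWarning, match="not a proper clade"):
            report = map_diagnoses(t, matrix, {"scattered": {"A", "D"}})
        assert "scattered" not in report

    @pytest.mark.parametrize("trial", range(5))
    def test_diagnoses_against_brute_force_optima(self, trial):
        """A character listed for a group's stem must change on that stem
        in at least one brute-force optimal assignment."""
        rng = random.Random(trial)
        tree = simulate_reference_tree(6, seed=7500 + trial)
        states = ["0", "1"]
        char = {t: rng.choice(states) for t in tree.tips}
        matrix = CharacterMatrix(
            taxa=sorted(tree.tips),
            characters=["c"],
            states={(t, "c"): char[t] for t in tree.tips},
        )
        clades = [
            n.leaf_taxa()
            for n in tree.preorder()
            if not n.is_leaf and n is not tree.root
        ]
        groups = {f"g{i}": c for i, c in enumerate(clades)}
        report = map_diagnoses(tree, matrix, groups)
        _, optima = brute_force_optimal_assignments(tree, char, states)

        def stem_changes_in_some_optimum(clade):
            node = tree.find_clade(clade)
            for opt in optima:
                parent_state = opt[id(node.parent)]
                node_state = (
                    char[node.taxon] if node.is_leaf else opt[id(node)]
                )
                if node_state != parent_state:
                    return True
            return False

        for name, clade in groups.items():
            if name not in report:
                continue
            for method in ("acctran", "deltran"):
                if report[name][method] == ["c"]:
                    assert stem_changes_in_some_optimum(clade)
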