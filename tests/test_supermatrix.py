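"""Locus stats, filtering, concatenation and anchor partitioning."""

import itertools
import random

import pytest

from phyloconcord.simulate import LocusSetConfig, simulate_locus_set
from phyloconcord.supermatrix import (
    MISSING_CHARS,
    AlignmentError,
    LocusAlignment,
    concatenate,
    filter_loci,
    locus_stats,
    partition_with_anchors,
)


def make_locus(locus_id, rows, is_anchor=False):
    return LocusAlignment(locus_id=locus_id, sequences=dict(rows),
                          is_anchor=is_anchor)


def brute_pi_count(locus):
    """Per-column census straight from the definition."""
    pi = 0
    for col in zip(*locus.sequences.values()):
        from collections import Counter

        counts = Counter(c for c in col if c not in MISSING_CHARS)
        if sum(1 for v in counts.values() if v >= 2) >= 2:
            pi += 1
    return pi


class TestLocusStats:
    def test_constant_columns_zero_pi(self):
        locus = make_locus("l1", {"a": "AAAA", "b": "AAAA", "c": "AAAA"})
        assert locus_stats(locus).parsimony_informative_sites == 0

    def test_two_by_two_column_is_pi(self):
        locus = make_locus("l1", {"a": "A", "b": "A", "c": "C", "d": "C"})
        assert locus_stats(locus).parsimony_informative_sites == 1

    def test_singleton_variant_not_pi(self):
        locus = make_locus("l1", {"a": "A", "b": "A", "c": "A", "d": "C"})
        assert locus_stats(locus).parsimony_informative_sites == 0

    def test_missing_fraction(self):
        locus = make_locus("l1", {"a": "AC-?", "b": "ACGN"})
        s = locus_stats(locus)
        assert s.missing_fraction == pytest.approx(3 / 8)

    def test_ragged_rejected(self):
        with pytest.raises(AlignmentError, match="ragged"):
            make_locus("l1", {"a": "ACGT", "b": "ACG"})

    @pytest.mark.parametrize("seed", range(10))
    def test_pi_matches_column_oracle(self, seed):
        rng = random.Random(seed)
        n, L = rng.randint(4, 12), rng.randint(10, 60)
        rows = {
            f"t{i}": "".join(rng.choice("ACGT-N?") for _ in range(L))
            for i in range(n)
        }
        try:
            locus = make_locus("x", rows)
        except AlignmentError:
            return
        assert locus_stats(locus).parsimony_informative_sites == brute_pi_count(locus)


class TestFilter:
    def test_exact_899_retained(self):
        loci, _ = simulate_locus_set(
            LocusSetConfig(n_loci=936, n_taxa=64, n_anchors=9,
                           n_low_coverage=37),
            seed=3,
        )
        retained, excluded = filter_loci(loci, min_sequences=4)
        assert len(retained) == 899
        assert len(excluded) == 37
        assert all("fewer than 4" in rule for _, rule in excluded)

    def test_zero_thresholds_identity(self):
        loci, _ = simulate_locus_set(
            LocusSetConfig(n_loci=20, n_taxa=10, n_anchors=2), seed=4
        )
        retained, excluded = filter_loci(loci, min_sequences=0, min_length=0,
                                         min_taxa=0)
        assert len(retained) == 20 and not excluded

    def test_strict_length_and_taxa_thresholds(self):
        short = make_locus("short", {f"t{i}": "A" * 250 for i in range(30)})
        ok = make_locus("ok", {f"t{i}": "A" * 251 for i in range(30)})
        few = make_locus("few", {f"t{i}": "A" * 300 for i in range(20)})
        retained, excluded = filter_loci(
            [short, ok, few], min_sequences=4, min_length=250, min_taxa=20
        )
        assert [l.locus_id for l in retained] == ["ok"]
        assert dict(excluded) == {
            "short": "length <= 250",
            "few": "taxa <= 20",
        }

    def test_joint_equals_sequential_in_any_order(self):
        loci, _ = simulate_locus_set(
            LocusSetConfig(n_loci=40, n_taxa=30, n_anchors=3,
                           length_range=(200, 320), n_low_coverage=5),
            seed=5,
        )
        joint, _ = filter_loci(loci, min_sequences=4, min_length=250,
                               min_taxa=8)
        joint_ids = {l.locus_id for l in joint}
        filters = [
            lambda ls: filter_loci(ls, min_sequences=4)[0],
            lambda ls: filter_loci(ls, min_length=250, min_sequences=0)[0],
            lambda ls: filter_loci(ls, min_taxa=8, min_sequences=0)[0],
        ]
        for order in itertools.permutations(filters):
            seq = list(loci)
            for f in order:
                seq = f(seq)
            assert {l.locus_id for l in seq} == joint_ids


class TestConcatenate:
    def test_single_locus_identity(self):
        locus = make_locus("l1", {"a": "ACGT", "b": "AC-T"})
        m = concatenate([locus], ["a", "b"])
        assert m.sequences == locus.sequences
        assert m.partitions == [("l1", 1, 4)]

    def test_absent_taxa_gap_filled_and_counted(self):
        l1 = make_locus("l1", {"a": "ACGT", "b": "ACGT"})
        l2 = make_locus("l2", {"a": "GG", "c": "CC"})
        m = concatenate([l1, l2], ["a", "b", "c"])
        assert m.total_length == 6
        assert m.sequences["c"] == "----CC"
        assert m.sequences["b"] == "ACGT--"
        # missing cells: c over l1 (4) + b over l2 (2) = 6 of 18
        assert m.missing_fraction == pytest.approx(6 / 18)
        assert m.absent_block_fraction == pytest.approx(6 / 18)

    def test_taxon_outside_panel_rejected(self):
        locus = make_locus("l1", {"a": "AC", "z": "AC"})
        with pytest.raises(AlignmentError, match="outside panel"):
            concatenate([locus], ["a", "b"])

    def test_partition_coordinates_one_based_inclusive(self):
        l1 = make_locus("l1", {"a": "AAA"})
        l2 = make_locus("l2", {"a": "CC"})
        m = concatenate([l1, l2], ["a"])
        assert m.partitions == [("l1", 1, 3), ("l2", 4, 5)]

    @pytest.mark.parametrize("seed", range(5))
    def test_missing_census_matches_brute_force(self, seed):
        loci, panel = simulate_locus_set(
            LocusSetConfig(n_loci=12, n_taxa=10, n_anchors=2,
                           length_range=(5, 30), missing_rate=0.1),
            seed=seed,
        )
        m = concatenate(loci, panel)
        brute = sum(
            1
            for t in panel
            for c in m.sequences[t]
            if c in MISSING_CHARS
        )
        assert m.missing_fraction == pytest.approx(
            brute / (len(panel) * m.total_length)
        )
        assert m.total_length == sum(l.length for l in loci)

    def test_mean_species_per_locus_rounded(self):
        l1 = make_locus("l1", {"a": "A", "b": "A"})
        l2 = make_locus("l2", {"a": "C", "b": "C", "c": "C"})
        m = concatenate([l1, l2], ["a", "b", "c"])
        assert m.mean_species_per_locus == 3  # mean 2.5 rounds away from zero


class TestPartition:
    @pytest.fixture(scope="class")
    @staticmethod
    def study_shape():
        loci, _ = simulate_locus_set(
            LocusSetConfig(n_loci=936, n_taxa=64, n_anchors=9,
                           n_low_coverage=37),
            seed=3,
        )
        anchors = [l.locus_id for l in loci if l.is_anchor]
        return loci, anchors

    def test_full_set_three_subsets_of_318(self, study_shape):
        loci, anchors = study_shape
        scheme = partition_with_anchors(loci, anchors, k=3)
        assert scheme.subset_sizes() == [318, 318, 318]
        assert scheme.non_anchor_counts() == [309, 309, 309]

    def test_filtered_set_with_coi_307_307_306(self, study_shape):
        loci, anchors = study_shape
        retained, _ = filter_loci(loci, min_sequences=4)
        scheme = partition_with_anchors(retained, anchors, k=3,
                                        extras=["COI"])
        assert sorted(scheme.subset_sizes(), reverse=True) == [307, 307, 306]

    def test_k1_single_subset_everything(self):
        loci, _ = simulate_locus_set(
            LocusSetConfig(n_loci=10, n_taxa=8, n_anchors=2), seed=6
        )
        anchors = [l.locus_id for l in loci if l.is_anchor]
        scheme = partition_with_anchors(loci, anchors, k=1)
        assert sorted(scheme.subset_ids(0)) == sorted(l.locus_id for l in loci)

    def test_k_exceeding_non_anchors_rejected(self):
        loci, _ = simulate_locus_set(
            LocusSetConfig(n_loci=5, n_taxa=6, n_anchors=2), seed=7
        )
        anchors = [l.locus_id for l in loci if l.is_anchor]
        with pytest.raises(ValueError, match="exceeds"):
            partition_with_anchors(loci, anchors, k=4)

    def test_unknown_anchor_rejected(self):
        loci, _ = simulate_locus_set(
            LocusSetConfig(n_loci=5, n_taxa=6, n_anchors=0), seed=8
        )
        with pytest.raises(ValueError, match="anchors"):
            partition_with_anchors(loci, ["nope"], k=2)

    @pytest.mark.parametrize("k", [2, 3, 5])
    def test_conservation_and_balance(self, k):
        loci, _ = simulate_locus_set(
            LocusSetConfig(n_loci=101, n_taxa=20, n_anchors=7,
                           length_range=(50, 200)),
            seed=9,
        )
        anchors = [l.locus_id for l in loci if l.is_anchor]
        scheme = partition_with_anchors(loci, anchors, k=k)
        counts = scheme.non_anchor_counts()
        assert sum(counts) == 101 - 7
        assert max(counts) - min(counts) <= 1
        for i in range(k):
            assert set(anchors) <= set(scheme.subset_ids(i))
        # disjoint non-anchor coverage
        seen = [
            l for i in range(k)
            for l in scheme.subset_ids(i) if l not in anchors
        ]
        assert len(seen) == len(set(seen))
        # PI sums near-balanced
        from phyloconcord.supermatrix import locus_stats as ls

        pi = {l.locus_id: ls(l).parsimony_informative_sites for l in loci}
        sums = [
            sum(pi[l] for l in scheme.subset_ids(i) if l not in anchors)
            for i in range(k)
        ]
        assert max(sums) - min(sums) <= max(pi.values())

    def test_deterministic(self):
        loci, _ = simulate_locus_set(
            LocusSetConfig(n_loci=30, n_taxa=12, n_anchors=3), seed=10
        )
        anchors = [l.locus_id for l in loci if l.is_anchor]
        s1 = partition_with_anchors(loci, anchors, k=3)
        s2 = partition_with_anchors(list(reversed(loci)), anchors, k=3)
        assert s1.assignment == s2.assignment


class TestFastaIO:
    def test_roundtrip(self, tmp_path):
        locus = make_locus("l9", {"tax_a": "ACGT-N", "tax_b": "ACGTAC"})
        path = tmp_path / "l9.fasta"
        locus.to_fasta(str(path))
        again = LocusAlignment.from_fasta(str(path))
        assert again.sequences == locus.sequences
        assert again.locus_id == "l9"
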