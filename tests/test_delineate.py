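"""Threshold clustering, nested delineation, tree refinement, naming."""

import itertools
import re

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myxotax.core import RANKS, ValidationError
from myxotax.delineate import (
    NAME_PATTERN,
    AnchorConflictError,
    RankThresholds,
    TaxonomyAssignment,
    cluster_at_threshold,
    name_taxa,
    nested_delineation,
    refine_with_tree,
    summarize_taxonomy,
    taxon_table_from_counts,
)
from myxotax.distance import DistanceMatrix, identity_matrix


def ident_dm(ids, pairs, default=0.5):
    """Build an identity DistanceMatrix from {frozenset(pair): value}."""
    n = len(ids)
    m = np.full((n, n), default)
    np.fill_diagonal(m, 1.0)
    for (a, b), v in pairs.items():
        i, j = ids.index(a), ids.index(b)
        m[i, j] = m[j, i] = v
    return DistanceMatrix(list(ids), m, "identity")


def as_sets(clusters):
    return {frozenset(c) for c in clusters}


def brute_force_complete_linkage(dm, t):
    """All terminal partitions reachable by complete-linkage agglomeration,
    exploring every tie order (oracle for small n)."""
    ids = dm.ids
    look = {
        frozenset((a, b)): dm.get(a, b) for a, b in itertools.combinations(ids, 2)
    }

    def linkage(c1, c2):
        return min(look[frozenset((a, b))] for a in c1 for b in c2)

    results = set()

    def rec(clusters):
        pairs = list(itertools.combinations(clusters, 2))
        if not pairs:
            results.add(frozenset(clusters))
            return
        values = [linkage(c1, c2) for c1, c2 in pairs]
        best = max(values)
        if not best > t:
            results.add(frozenset(clusters))
            return
        for (c1, c2), v in zip(pairs, values):
            if v == best:
                rec((clusters - {c1, c2}) | {c1 | c2})

    rec(frozenset(frozenset({s}) for s in ids))
    return results


class TestClusterAtThreshold:
    def test_close_pair_joins_far_singleton_stays(self):
        dm = ident_dm(
            ["a", "b", "c"],
            {("a", "b"): 0.99, ("a", "c"): 0.80, ("b", "c"): 0.80},
        )
        assert as_sets(cluster_at_threshold(dm, 0.97)) == {
            frozenset({"a", "b"}),
            frozenset({"c"}),
        }

    def test_all_identical_collapse_to_one_cluster(self):
        dm = ident_dm(["a", "b", "c", "d"], {}, default=1.0)
        assert len(cluster_at_threshold(dm, 0.97)) == 1

    def test_identity_exactly_at_threshold_splits(self):
        # "97.0% or lower" means distinct: the boundary is exclusive
        dm = ident_dm(["a", "b"], {("a", "b"): 0.970})
        assert len(cluster_at_threshold(dm, 0.97)) == 2

    def test_within_cluster_identity_guarantee(self, default_community):
        aln, _, _ = default_community
        dm = identity_matrix(aln)
        for t in (0.970, 0.945, 0.890, 0.850):
            for cluster in cluster_at_threshold(dm, t):
                if len(cluster) > 1:
                    sub = dm.submatrix(cluster).values
                    off = sub[~np.eye(len(cluster), dtype=bool)]
                    assert off.min() > t

    @given(st.data())
    @settings(max_examples=25)
    def test_matches_brute_force_enumeration(self, data):
        n = data.draw(st.integers(3, 7))
        ids = [f"s{i}" for i in range(n)]
        # coarse grid of identity values provokes plenty of linkage ties
        vals = data.draw(
            st.lists(
                st.sampled_from([0.80, 0.90, 0.95, 0.96, 0.98, 0.99]),
                min_size=n * (n - 1) // 2,
                max_size=n * (n - 1) // 2,
            )
        )
        pairs = dict(zip(itertools.combinations(ids, 2), vals))
        dm = ident_dm(ids, pairs)
        t = data.draw(st.sampled_from([0.945, 0.970]))
        ours = as_sets(cluster_at_threshold(dm, t))
        assert ours in brute_force_complete_linkage(dm, t)

    @given(st.randoms(use_true_random=False))
    def test_partition_invariant_under_input_order(self, small_community, rnd):
        aln, _, _ = small_community
        dm = identity_matrix(aln)
        order = list(range(len(dm.ids)))
        rnd.shuffle(order)
        shuffled = DistanceMatrix(
            [dm.ids[i] for i in order], dm.values[np.ix_(order, order)], "identity"
        )
        assert as_sets(cluster_at_threshold(dm, 0.97)) == as_sets(
            cluster_at_threshold(shuffled, 0.97)
        )


class TestNestedDelineation:
    def test_two_separated_blocks(self):
        ids = ["a", "b", "c", "d"]
        pairs = {("a", "b"): 0.99, ("c", "d"): 0.99}
        dm = ident_dm(ids, pairs, default=0.80)
        counts = nested_delineation(dm).counts()
        assert counts == {"suborder": 2, "family": 2, "genus": 2, "species": 2}

    def test_single_sequence_is_one_taxon_everywhere(self):
        dm = DistanceMatrix(["only"], np.ones((1, 1)), "identity")
        assert nested_delineation(dm).counts() == dict.fromkeys(RANKS, 1)

    def test_recovers_planted_counts(self, small_community):
        aln, _, truth = small_community
        counts = nested_delineation(identity_matrix(aln)).counts()
        assert counts == truth.planted_counts

    def test_nesting_invariant(self, small_community):
        aln, _, _ = small_community
        assignment = nested_delineation(identity_matrix(aln))
        for parent_rank, child_rank in zip(RANKS, RANKS[1:]):
            parents = assignment.partition(parent_rank)
            for members in assignment.partition(child_rank).values():
                containing = [p for p in parents.values() if members <= p]
                assert len(containing) == 1

    def test_thresholds_must_be_ordered(self):
        with pytest.raises(ValidationError):
            RankThresholds(species=0.9, genus=0.95, family=0.89, suborder=0.85)


class TestRefineWithTree:
    def tree(self, newick):
        return dendropy.Tree.get(data=newick, schema="newick")

    def test_monophyletic_taxa_unchanged(self):
        assignment = TaxonomyAssignment(
            {"a": (1, 1, 1, 1), "b": (1, 1, 1, 1), "c": (2, 1, 1, 1)}
        )
        refined = refine_with_tree(assignment, self.tree("((a,b),c);"))
        assert refined.partition("species") == assignment.partition("species")

    def test_paraphyletic_species_is_split(self):
        assignment = TaxonomyAssignment(
            {
                "a": (1, 1, 1, 1),
                "b": (1, 1, 1, 1),
                "x": (1, 1, 1, 1),
                "c": (2, 1, 1, 1),
            }
        )
        refined = refine_with_tree(assignment, self.tree("((a,b),(x,c));"))
        species = {frozenset(m) for m in refined.partition("species").values()}
        assert frozenset({"a", "b"}) in species
        assert frozenset({"x"}) in species

    def test_result_invariant_to_tip_order_in_newick(self):
        assignment = TaxonomyAssignment(
            {
                "a": (1, 1, 1, 1),
                "b": (1, 1, 1, 1),
                "x": (1, 1, 1, 1),
                "c": (2, 1, 1, 1),
            }
        )
        r1 = refine_with_tree(assignment, self.tree("((a,b),(x,c));"))
        r2 = refine_with_tree(assignment, self.tree("((c,x),(b,a));"))
        for rank in RANKS:
            assert {frozenset(m) for m in r1.partition(rank).values()} == {
                frozenset(m) for m in r2.partition(rank).values()
            }

    def test_missing_tips_listed(self):
        assignment = TaxonomyAssignment({"a": (1, 1, 1, 1), "z": (1, 1, 1, 1)})
        with pytest.raises(ValidationError, match="z"):
            refine_with_tree(assignment, self.tree("(a,b);"))


class TestNaming:
    def test_unanchored_numbering_by_descending_size(self):
        paths = {f"m{i}": (1, 1, 1, 1) for i in range(10)}
        paths.update({f"n{i}": (2, 1, 1, 1) for i in range(3)})
        named = name_taxa(TaxonomyAssignment(paths))
        assert named.name_of((1,)) == "Suborder_1"  # ten members
        assert named.name_of((2,)) == "Suborder_2"

    def test_anchored_suborder_takes_anchor_name_and_is_skipped(self):
        paths = {f"m{i}": (1, 1, 1, 1) for i in range(10)}
        paths.update({f"n{i}": (2, 1, 1, 1) for i in range(3)})
        named = name_taxa(TaxonomyAssignment(paths), anchors={"m0": "Sorangiineae"})
        assert named.name_of((1,)) == "Sorangiineae"
        assert named.name_of((2,)) == "Suborder_1"

    def test_conflicting_anchors_rejected(self):
        paths = {"a": (1, 1, 1, 1), "b": (1, 1, 1, 1)}
        with pytest.raises(AnchorConflictError):
            name_taxa(
                TaxonomyAssignment(paths),
                anchors={"a": "Sorangiineae", "b": "Cystobacterineae"},
            )

    def test_all_names_match_hierarchical_pattern(self, small_community):
        aln, _, _ = small_community
        named = name_taxa(nested_delineation(identity_matrix(aln)))
        pattern = re.compile(NAME_PATTERN)
        for rank in RANKS:
            for label in named.partition(rank):
                assert pattern.match(named.name_of(label))


class TestSummary:
    def test_single_suborder_is_hundred_percent(self):
        assignment = TaxonomyAssignment(
            {"a": (1, 1, 1, 1), "b": (1, 1, 1, 2), "c": (1, 1, 2, 1)}
        )
        table = summarize_taxonomy(assignment)
        assert len(table) == 2  # one suborder + totals
        row = table.iloc[0]
        assert (row["families"], row["genera"], row["species"]) == (1, 2, 3)
        assert row["percent"] == 100.0

    def test_totals_row_sums_columns(self, small_community):
        aln, _, _ = small_community
        table = summarize_taxonomy(nested_delineation(identity_matrix(aln)))
        body, totals = table.iloc[:-1], table.iloc[-1]
        for col in ("families", "genera", "species", "sequences"):
            assert totals[col] == body[col].sum()
        assert body["percent"].sum() == pytest.approx(100.0, abs=0.05)

    def test_counts_table_requires_all_columns(self):
        import pandas as pd

        with pytest.raises(ValidationError):
            taxon_table_from_counts(pd.DataFrame({"suborder": ["x"]}))
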