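"""Abundance classes, environment distributions, specificity, culturability."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from myxotax.biogeo import (
    COSMOPOLITAN,
    SPECIALIST,
    SpecificityParams,
    classify_abundance,
    classify_specificity,
    culturability_breakdown,
    distribution_matrix,
    specificity_profile,
)
from myxotax.core import ENV_CATEGORIES, RANKS, ValidationError
from myxotax.delineate import TaxonomyAssignment

from conftest import make_record

SEQ = "ACGT" * 300


def env_vector(**counts):
    return [counts.get(env, 0) for env in ENV_CATEGORIES]


class TestAbundance:
    @pytest.mark.parametrize(
        "count,total,expected",
        [
            (144, 4997, "abundant"),  # 2.88% of the full collection
            (15, 4997, "rare"),  # 0.30%
            (5, 1000, "abundant"),  # exactly 0.5%: inclusive boundary
            (4, 1000, "rare"),
        ],
    )
    def test_cutoff_semantics(self, count, total, expected):
        assert classify_abundance(count, total) == expected

    def test_zero_total_is_an_error(self):
        with pytest.raises(ValidationError):
            classify_abundance(0, 0)


class TestDistributionMatrix:
    def records(self, envs):
        return [
            make_record(f"r{i}", SEQ, env_category=env) for i, env in enumerate(envs)
        ]

    def assignment(self, n):
        return TaxonomyAssignment({f"r{i}": (1, 1, 1, 1) for i in range(n)})

    def test_counts_by_environment(self):
        records = self.records(["Soil", "Soil", "Seawater"])
        table = distribution_matrix(self.assignment(3), records, "species")
        row = table.iloc[0]
        assert row["Soil"] == 2 and row["Seawater"] == 1
        assert row.sum() == 3
        assert list(table.columns) == list(ENV_CATEGORIES)

    def test_unknown_environment_is_a_real_column(self):
        records = self.records(["The_unknown"])
        table = distribution_matrix(self.assignment(1), records, "species")
        assert table.iloc[0]["The_unknown"] == 1

    def test_missing_record_listed(self):
        with pytest.raises(ValidationError, match="r1"):
            distribution_matrix(self.assignment(2), self.records(["Soil"]), "species")

    def test_column_sums_identical_across_ranks(self, default_community):
        aln, records, truth = default_community
        assignment = TaxonomyAssignment(dict(truth.paths))
        sums = [
            distribution_matrix(assignment, records, rank).sum(axis=0)
            for rank in RANKS
        ]
        for other in sums[1:]:
            assert (sums[0] == other).all()

    def test_row_sums_match_truth_taxon_sizes(self, small_community):
        aln, records, truth = small_community
        assignment = TaxonomyAssignment(dict(truth.paths))
        table = distribution_matrix(assignment, records, "species")
        sizes = {}
        for path in truth.paths.values():
            sizes[path] = sizes.get(path, 0) + 1
        assert sorted(table.sum(axis=1)) == sorted(sizes.values())


class TestSpecificity:
    def test_five_in_one_category_is_specialist(self):
        assert classify_specificity(env_vector(Soil=5)) == SPECIALIST

    def test_four_observations_fail_min_obs(self):
        assert classify_specificity(env_vector(Soil=4)) == COSMOPOLITAN

    def test_dominance_boundary_inclusive(self):
        assert classify_specificity(env_vector(Soil=8, Seawater=2)) == SPECIALIST
        assert classify_specificity(env_vector(Soil=7, Seawater=3)) == COSMOPOLITAN

    def test_all_zero_vector_is_an_error(self):
        with pytest.raises(ValidationError):
            classify_specificity(env_vector())

    def test_unknown_category_can_be_excluded_from_dominance(self):
        # half the observations are of unknown origin: counted by
        # default, the taxon is cosmopolitan; excluded, it is a
        # specialist on its five Soil observations
        counts = env_vector(Soil=5, The_unknown=5)
        assert classify_specificity(counts) == COSMOPOLITAN
        params = SpecificityParams(include_unknown=False)
        assert classify_specificity(counts, params) == SPECIALIST

    @given(
        st.lists(st.integers(0, 30), min_size=10, max_size=10).filter(
            lambda v: sum(v) > 0
        ),
        st.integers(2, 4),
    )
    def test_scaling_counts_never_flips_specialist_to_cosmopolitan(self, counts, k):
        before = classify_specificity(counts)
        after = classify_specificity([k * c for c in counts])
        if before == SPECIALIST:
            assert after == SPECIALIST


class TestSpecificityProfile:
    def test_single_environment_taxa_are_all_specialist(self):
        paths = {f"r{i}": (1, 1, 1, 1) for i in range(5)}
        paths.update({f"q{i}": (2, 1, 1, 1) for i in range(5)})
        records = [make_record(s, SEQ, env_category="Soil") for s in paths]
        profile = specificity_profile(TaxonomyAssignment(paths), records)
        assert (profile["specialist_fraction"] == 1.0).all()
        assert (profile["cosmopolitan_fraction"] == 0.0).all()

    def test_under_observed_taxa_are_all_cosmopolitan(self):
        paths = {f"r{i}": (1, 1, 1, 1) for i in range(3)}
        records = [make_record(s, SEQ, env_category="Soil") for s in paths]
        profile = specificity_profile(TaxonomyAssignment(paths), records)
        assert (profile["specialist_fraction"] == 0.0).all()

    def test_fractions_sum_to_one_per_rank(self, small_community):
        aln, records, truth = small_community
        profile = specificity_profile(TaxonomyAssignment(dict(truth.paths)), records)
        assert np.allclose(
            profile["specialist_fraction"] + profile["cosmopolitan_fraction"], 1.0
        )


class TestCulturability:
    def test_even_split(self):
        records = [
            make_record("a", SEQ, env_category="Soil", cultured="cultured"),
            make_record("b", SEQ, env_category="Soil", cultured="cultured"),
            make_record("c", SEQ, env_category="Soil", cultured="uncultured"),
            make_record("d", SEQ, env_category="Soil", cultured="uncultured"),
        ]
        per_env, counts, _ = culturability_breakdown(records)
        soil = per_env.set_index("env_category").loc["Soil"]
        assert (soil["pct_cultured"], soil["pct_uncultured"], soil["pct_unknown"]) == (
            50.0,
            50.0,
            0.0,
        )
        assert counts == {"cultured": 2, "uncultured": 2, "unknown": 0}

    def test_all_unknown(self):
        records = [make_record("a", SEQ), make_record("b", SEQ)]
        per_env, counts, _ = culturability_breakdown(records)
        row = per_env.set_index("env_category").loc["The_unknown"]
        assert row["pct_unknown"] == 100.0
        assert counts["unknown"] == 2

    def test_percentages_sum_to_hundred_per_nonempty_env(self, default_community):
        _, records, _ = default_community
        per_env, _, _ = culturability_breakdown(records)
        nonempty = per_env[per_env["n"] > 0]
        totals = (
            nonempty["pct_cultured"]
            + nonempty["pct_uncultured"]
            + nonempty["pct_unknown"]
        )
        assert np.allclose(totals, 100.0)

    def test_planted_culturability_recovered_within_sampling_error(
        self, default_community
    ):
        _, records, truth = default_community
        _, counts, _ = culturability_breakdown(records)
        n = len(records)
        for cls, want in truth.spec.culturability.items():
            got = counts[cls] / n
            se = np.sqrt(want * (1 - want) / n)
            assert abs(got - want) <= max(3 * se, 2 / n)
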