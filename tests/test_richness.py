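"""Richness estimators against hand evaluations and closed-form oracles."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from elevgrad import (
    ValidationError,
    chao1,
    expected_rarefied_richness,
    observed_richness,
    pooled_richness,
    rarefy_taxon,
    sample_coverage,
)
from elevgrad.richness import coverage_elevation_report, richness_table

from conftest import make_community

count_vectors = st.lists(st.integers(min_value=0, max_value=8), min_size=1,
                         max_size=12).filter(lambda v: sum(v) > 0)


class TestObservedRichness:
    def test_direct_count(self, tiny_community):
        assert observed_richness(tiny_community).tolist() == [2, 0, 3]

    def test_empty_species_set(self):
        com = make_community(np.zeros((4, 0), dtype=int))
        assert observed_richness(com).tolist() == [0, 0, 0, 0]

    def test_column_permutation_invariance(self, tiny_community):
        perm = tiny_community.matrix.iloc[:, [2, 0, 1]]
        com2 = make_community(perm.to_numpy())
        assert observed_richness(com2).tolist() == observed_richness(tiny_community).tolist()


class TestChao1:
    @pytest.mark.parametrize("counts, expected", [
        ([2, 2, 3], 3.0),        # no singletons: estimate = S_obs
        ([1, 1, 2, 3], 4.5),     # 4 + 2*1/(2*2)
        ([1, 1], 3.0),           # 2 + 2*1/2, defined despite f2=0
    ])
    def test_hand_evaluations(self, counts, expected):
        assert chao1(counts) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            chao1([])

    @given(count_vectors)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_never_below_observed(self, counts):
        s_obs = sum(1 for c in counts if c > 0)
        est = chao1(counts)
        assert est >= s_obs
        f1 = counts.count(1)
        if f1 * (f1 - 1) == 0:
            assert est == pytest.approx(s_obs)
        else:
            assert est > s_obs


class TestSampleCoverage:
    @pytest.mark.parametrize("counts, expected", [
        ([5, 3], 1.0),
        ([1, 1, 2, 3], 1 - (2 / 7) * (12 / 14)),
        ([1], 0.0),
    ])
    def test_hand_evaluations(self, counts, expected):
        assert sample_coverage(counts) == pytest.approx(expected)

    @given(count_vectors)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_bounds_and_doubleton_monotonicity(self, counts):
        c = sample_coverage(counts)
        assert 0.0 <= c <= 1.0
        # appending a doubleton never decreases estimated completeness
        assert sample_coverage(counts + [2]) >= c - 1e-12


class TestRarefaction:
    def test_full_draw_is_identity(self, tiny_community):
        total = tiny_community.total_individuals()
        reps = rarefy_taxon(tiny_community, total, reps=5, seed=0)
        obs = observed_richness(tiny_community)
        for _, row in reps.iterrows():
            assert row.tolist() == obs.tolist()

    def test_single_individual(self, tiny_community):
        reps = rarefy_taxon(tiny_community, 1, reps=20, seed=1)
        assert (reps.sum(axis=1) == 1).all()

    def test_overdraw_rejected(self, tiny_community):
        with pytest.raises(ValidationError, match="short"):
            rarefy_taxon(tiny_community, 10**6, reps=1)

    def test_census_taxon_refused(self):
        com = make_community([[1, 0], [1, 1]], is_census=True)
        with pytest.raises(ValidationError, match="census"):
            rarefy_taxon(com, 1, reps=1)

    def test_matches_hypergeometric_expectation(self):
        """Monte-Carlo taxon-wide richness agrees with the closed-form
        hypergeometric expectation within 3 Monte-Carlo standard errors."""
        rng = np.random.default_rng(7)
        counts = rng.integers(0, 6, size=(6, 10))
        counts[0, 0] += 3
        com = make_community(counts)
        flat = counts.ravel()
        n_draw = int(flat.sum() * 0.4)
        reps = rarefy_taxon(com, n_draw, reps=1000, seed=11)
        # summed per-site richness counts occupied (site, species) cells,
        # whose expectation is hypergeometric over the cell abundances
        expected_per_cell = expected_rarefied_richness(flat, n_draw)
        mc = reps.sum(axis=1)
        se = mc.std(ddof=1) / np.sqrt(len(mc))
        assert abs(mc.mean() - expected_per_cell) <= 3 * se

    def test_exhaustive_small_case_oracle(self):
        """On a tiny community, the analytic expectation equals exhaustive
        enumeration over all subsets, and Monte Carlo agrees."""
        counts = np.array([[2, 1, 0], [0, 1, 3]])
        flat = counts.ravel()
        labels = np.repeat(np.arange(flat.size), flat)
        n_draw = 4
        vals = []
        for subset in combinations(range(labels.size), n_draw):
            drawn = np.bincount(labels[list(subset)], minlength=flat.size)
            vals.append((drawn > 0).sum())
        enum_mean = np.mean(vals)
        assert expected_rarefied_richness(flat, n_draw) == pytest.approx(enum_mean)
        reps = rarefy_taxon(make_community(counts), n_draw, reps=1000, seed=3)
        mc = reps.sum(axis=1)
        se = mc.std(ddof=1) / np.sqrt(len(mc))
        assert abs(mc.mean() - enum_mean) <= 3 * se

    def test_replicates_never_exceed_observed(self, tiny_community):
        obs = observed_richness(tiny_community).to_numpy()
        reps = rarefy_taxon(tiny_community, 3, reps=50, seed=5)
        assert (reps.to_numpy() <= obs[None, :]).all()


class TestPooledRichness:
    def test_single_taxon_identity(self, tiny_community):
        pooled = pooled_richness([tiny_community], [tiny_community.taxon_name])
        assert pooled.tolist() == observed_richness(tiny_community).tolist()

    def test_additivity(self):
        a = make_community([[1, 1, 1], [1, 0, 0]], name="a")
        b = make_community([[2, 3], [1, 1]], name="b")
        assert pooled_richness([a, b], ["a", "b"]).tolist() == [5, 3]

    def test_monotone_under_inclusion(self):
        rng = np.random.default_rng(0)
        coms = [make_community(rng.integers(0, 3, (4, 5)), name=f"t{i}")
                for i in range(3)]
        p12 = pooled_richness(coms, ["t0", "t1"])
        p123 = pooled_richness(coms, ["t0", "t1", "t2"])
        assert (p123 >= p12).all()

    def test_unknown_taxon_rejected(self, tiny_community):
        with pytest.raises(ValidationError, match="unknown"):
            pooled_richness([tiny_community], ["nope"])


class TestReports:
    def test_richness_table_invariants(self):
        com = make_community([[1, 1, 2, 0], [3, 3, 3, 1]])
        t = richness_table(com, ("observed", "chao1", "coverage"))
        assert (t["chao1"] >= t["observed"]).all()
        assert t["coverage"].between(0, 1).all()

    def test_coverage_report_skips_census(self, sites30):
        from elevgrad import TaxonSpec, generate_taxon

        com = generate_taxon(
            TaxonSpec("x", n_species_pool=80, occupancy=0.3), sites30, seed=4)
        census = generate_taxon(
            TaxonSpec("y", n_species_pool=10, is_census=True), sites30, seed=5)
        rep = coverage_elevation_report([com, census], sites30)
        assert rep["taxon"].tolist() == ["x"]
        assert rep["mean_coverage"].between(0, 1).all()
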