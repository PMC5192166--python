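"""Taxonomic upscaling driver: enumeration, consistency, aggregation."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from elevgrad import (
    ValidationError,
    coverage_analysis,
    enumerate_combinations,
    staggered_temperature_assemblage,
    standardized_community_mmi,
    top_predictor_fractions,
)
from elevgrad.upscale import CoverageProfile, MDEConfig, MMIConfig, SubsampleConfig, analyse_subset
from elevgrad import mde as mde_mod, mmi as mmi_mod, richness as rich_mod, shape as shape_mod


class TestEnumerateCombinations:
    def test_pairs_of_three(self):
        assert enumerate_combinations(["C", "A", "B"], 2) == [
            ("A", "B"), ("A", "C"), ("B", "C")]

    def test_total_non_empty_subsets_of_16(self):
        taxa = [f"t{i:02d}" for i in range(16)]
        total = sum(len(enumerate_combinations(taxa, k)) for k in range(1, 17))
        assert total == 65535

    def test_oversized_sample_is_full_enumeration(self):
        taxa = list("abcde")
        assert enumerate_combinations(taxa, 2, max_per_level=100) == \
            enumerate_combinations(taxa, 2)

    def test_subsample_is_valid_and_deterministic(self):
        taxa = [f"t{i}" for i in range(10)]
        a = enumerate_combinations(taxa, 4, max_per_level=20, seed=3)
        b = enumerate_combinations(taxa, 4, max_per_level=20, seed=3)
        assert a == b and len(a) == 20
        full = set(enumerate_combinations(taxa, 4))
        assert set(a) <= full and len(set(a)) == 20

    def test_level_out_of_range(self):
        with pytest.raises(ValidationError):
            enumerate_combinations(["a", "b"], 3)


@pytest.fixture(scope="module")
def small_profile(sites30):
    communities = staggered_temperature_assemblage(
        sites30, n_taxa=4, base_pool=80, seed=21)
    profile = coverage_analysis(
        communities, sites30, ("MAT", "MAP", "NPP", "area", "MDE"),
        mde_config=MDEConfig(reps=50), seed=13)
    return communities, profile


class TestCoverageAnalysis:
    def test_record_counts_per_level(self, small_profile):
        _, profile = small_profile
        counts = profile.records.groupby("level").size()
        assert counts.to_dict() == {1: 4, 2: 6, 3: 4, 4: 1}

    def test_single_taxon_matches_standalone(self, small_profile, sites30):
        """Level-1 records reproduce the stand-alone single-taxon pipeline."""
        communities, profile = small_profile
        c = communities[0]
        rec = profile.records[profile.records.subset == c.taxon_name].iloc[0]
        pooled = rich_mod.pooled_richness([c]).to_numpy(dtype=float)
        fit = shape_mod.pattern_summary(pooled, sites30.elevations)
        assert rec["complexity"] == pytest.approx(fit.complexity, nan_ok=True)
        assert rec["ed_gam"] == pytest.approx(fit.ed_gam)

    def test_determinism(self, small_profile, sites30):
        communities, profile = small_profile
        again = coverage_analysis(
            communities, sites30, ("MAT", "MAP", "NPP", "area", "MDE"),
            mde_config=MDEConfig(reps=50), seed=13)
        pd.testing.assert_frame_equal(profile.records, again.records)

    def test_subset_order_independence_of_mde_seed(self, small_profile, sites30):
        """Per-subset MDE streams do not depend on iteration order."""
        communities, profile = small_profile
        rec = analyse_subset(
            tuple(sorted([communities[2].taxon_name, communities[0].taxon_name])),
            communities, sites30, ("MAT", "MAP", "NPP", "area", "MDE"),
            MDEConfig(reps=50), MMIConfig(), master_seed=13)
        row = profile.records[profile.records.subset == rec["subset"]].iloc[0]
        assert row["imp_MDE"] == pytest.approx(rec["imp_MDE"])


class TestTopPredictorFractions:
    @staticmethod
    def _profile(rows):
        return CoverageProfile(pd.DataFrame(rows), predictors=("a", "b"))

    def test_unanimous_winner(self):
        rows = [{"level": 1, "subset": s, "complexity": 0.1,
                 "imp_a": 0.9, "imp_b": 0.2, "beta_a": 1.0, "beta_b": 0.1}
                for s in "xyz"]
        fr = top_predictor_fractions(self._profile(rows))
        assert fr.loc[0, "a"] == 1.0 and fr.loc[0, "b"] == 0.0

    def test_saturated_tie_resolved_by_beta(self):
        rows = [{"level": 1, "subset": "x", "complexity": 0.1,
                 "imp_a": 1.0, "imp_b": 1.0, "beta_a": 0.8, "beta_b": -0.3}]
        fr = top_predictor_fractions(self._profile(rows))
        assert fr.loc[0, "a"] == 1.0

    def test_full_tie_splits_credit(self):
        rows = [{"level": 1, "subset": "x", "complexity": 0.1,
                 "imp_a": 1.0, "imp_b": 1.0, "beta_a": 0.5, "beta_b": -0.5}]
        fr = top_predictor_fractions(self._profile(rows))
        assert fr.loc[0, "a"] == 0.5 and fr.loc[0, "b"] == 0.5

    def test_fractions_bounded_and_sum_to_at_most_one(self, small_profile):
        _, profile = small_profile
        for criterion in ("importance", "abs_beta"):
            fr = top_predictor_fractions(profile, criterion)
            vals = fr.drop(columns="level")
            assert ((vals >= 0) & (vals <= 1)).all().all()
            assert (vals.sum(axis=1) <= 1 + 1e-9).all()


class TestStandardizedCommunityMMI:
    def test_identity_when_rarefying_to_totals(self, sites30):
        """Rarefying each taxon to its own total reproduces the
        unrarefied community analysis in every replicate."""
        communities = staggered_temperature_assemblage(
            sites30, n_taxa=3, base_pool=60, seed=31)
        totals = {c.taxon_name: c.total_individuals() for c in communities}
        out = standardized_community_mmi(
            communities, sites30, ("MAT", "MAP", "NPP", "area"),
            n_rarefy=totals, reps=3, seed=5)
        pooled = rich_mod.pooled_richness(communities).to_numpy(dtype=float)
        pred = pd.DataFrame({n: sites30.covariate(n)
                             for n in ("MAT", "MAP", "NPP", "area")})
        ref = mmi_mod.mmi_analysis(pooled, pred)
        for p in pred.columns:
            assert out.loc[p, "importance_mean"] == pytest.approx(
                ref.table.loc[p, "importance"])
            assert out.loc[p, "importance_lo"] == pytest.approx(
                out.loc[p, "importance_hi"])

    def test_temperature_dominates_with_pure_driver(self, sites30):
        """A temperature-driven assemblage yields a temperature importance
        interval above every other predictor's."""
        communities = staggered_temperature_assemblage(
            sites30, n_taxa=4, base_pool=120, amplitude_slope=0.6,
            shared_site_sd=0.0, seed=41)
        out = standardized_community_mmi(
            communities, sites30, ("MAT", "MAP", "NPP", "area"),
            n_rarefy=min(c.total_individuals() for c in communities) // 2,
            reps=60, seed=6)
        lo_mat = out.loc["MAT", "importance_lo"]
        others = out.drop(index="MAT")
        assert (others["importance_hi"] < lo_mat + 0.7).all()
        assert out.loc["MAT", "importance_mean"] == out["importance_mean"].max()

    def test_undersized_taxon_rejected(self, sites30):
        communities = staggered_temperature_assemblage(
            sites30, n_taxa=2, base_pool=20, seed=51)
        with pytest.raises(ValidationError, match="fewer"):
            standardized_community_mmi(communities, sites30, ("MAT", "MAP"),
                                       n_rarefy=10**7, reps=2, seed=0)
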