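"""Generator properties: determinism, planted truths, calibration."""

import numpy as np
import pandas as pd
import pytest

from parpomics.enrichment import gsea_preranked, rank_genes
from parpomics.model import GeneSetCollection, ResponseLabel
from parpomics.simulate import (
    PlantedSet,
    expected_survival_fraction,
    simulate_biomarker_cohort,
    simulate_catalog,
    simulate_expression_cohort,
    simulate_profile,
    simulate_variant_table,
)
from parpomics.variants import consensus_filter


class TestProfiles:
    def test_flat_profile_all_scores_zero(self, toy_build):
        from parpomics.scars import score_profile

        profile, truth = simulate_profile(toy_build, 0, 0, seed=0)
        scores = score_profile(profile, toy_build)
        assert (scores.wgii, scores.lst, scores.tai) == (0.0, 0, 0)
        assert (truth.lst_truth, truth.tai_truth) == (0, 0)

    def test_three_pairs_score_six(self, toy_build):
        from parpomics.scars import lst_score

        profile, truth = simulate_profile(toy_build, 3, 0, seed=2)
        assert lst_score(profile, toy_build) == 6 == truth.lst_truth

    def test_same_seed_identical(self, toy_build):
        a, _ = simulate_profile(toy_build, 2, 1, seed=7)
        b, _ = simulate_profile(toy_build, 2, 1, seed=7)
        assert a.segments == b.segments

    def test_too_many_events_rejected(self, toy_build):
        with pytest.raises(ValueError, match="larger build"):
            simulate_profile(toy_build, 99, 0, seed=0)


class TestCatalogs:
    def test_zero_mutations(self, reference):
        catalog, _ = simulate_catalog(reference, {"SynthSigA": 1.0}, 0, seed=0)
        assert catalog.total == 0

    def test_one_hot_concentration(self, reference):
        catalog, _ = simulate_catalog(reference, {"SynthSigB": 1.0}, 10000, seed=1)
        freq = catalog.counts / catalog.total
        l1 = np.abs(freq - reference.profile("SynthSigB")).sum()
        assert l1 < 0.05

    def test_total_conserved(self, reference):
        for n in (1, 17, 500):
            catalog, _ = simulate_catalog(
                reference, {"SynthSigA": 0.5, "SynthSigC": 0.5}, n, seed=3
            )
            assert catalog.total == n

    def test_off_simplex_rejected(self, reference):
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_catalog(reference, {"SynthSigA": 0.5}, 10, seed=0)


class TestExpression:
    def labels(self):
        out = {f"s{i}": ResponseLabel.SENSITIVE for i in range(6)}
        out.update({f"r{i}": ResponseLabel.RESISTANT for i in range(7)})
        return out

    def planted(self, effect):
        return PlantedSet(
            "PLANTED", [f"P{i:03d}" for i in range(30)], "resistance", effect
        )

    def null_collection(self, matrix, planted, rng):
        background = [g for g in matrix.gene_ids if g.startswith("G")]
        sets = {"PLANTED": planted.genes}
        for j in range(19):
            sets[f"N{j}"] = list(rng.choice(background, 30, replace=False))
        return GeneSetCollection(sets)

    def test_null_effect_rarely_significant(self):
        """With no planted effect the planted set reaches adjusted
        p < 0.05 in at most 10% of 20 seeded runs."""
        hits = 0
        for seed in range(20):
            planted = self.planted(0.0)
            matrix, _ = simulate_expression_cohort(
                600, self.labels(), [planted], noise_sd=1.0, seed=seed
            )
            rng = np.random.default_rng(seed)
            ranked = rank_genes(matrix, self.labels())
            results = gsea_preranked(
                ranked, self.null_collection(matrix, planted, rng),
                n_perm=500, seed=10_000 + seed,
            )
            padj = {r.set_name: r.p_adjusted for r in results}
            hits += padj["PLANTED"] < 0.05
        assert hits <= 2

    def test_planted_effect_is_top_enrichment(self):
        planted = self.planted(2.0)
        matrix, _ = simulate_expression_cohort(
            600, self.labels(), [planted], noise_sd=1.0, seed=5
        )
        rng = np.random.default_rng(5)
        ranked = rank_genes(matrix, self.labels())
        results = gsea_preranked(
            ranked, self.null_collection(matrix, planted, rng), n_perm=500, seed=5
        )
        # resistance-planted genes rank toward negative statistics
        best = min(results, key=lambda r: r.nes)
        assert best.set_name == "PLANTED"

    def test_same_seed_identical(self):
        planted = self.planted(1.0)
        a, _ = simulate_expression_cohort(200, self.labels(), [planted], seed=3)
        b, _ = simulate_expression_cohort(200, self.labels(), [planted], seed=3)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_overlapping_planted_sets_rejected(self):
        shared = [f"P{i}" for i in range(10)]
        sets = [
            PlantedSet("a", shared, "resistance", 1.0),
            PlantedSet("b", shared[:5], "sensitivity", 1.0),
        ]
        with pytest.raises(ValueError, match="disjoint"):
            simulate_expression_cohort(100, self.labels(), sets, seed=0)


class TestVariantTables:
    def test_all_thresholds_passed_all_survive(self):
        df = simulate_variant_table(
            200, caller_support_prob=1.0, depth_mean=100,
            vaf_params=(50, 50), fraction_nonsynonymous=1.0, seed=0,
        )
        assert len(consensus_filter(df)) == 200

    def test_surviving_fraction_matches_analytic_product(self):
        params = dict(
            caller_support_prob=0.5, depth_mean=40.0,
            vaf_params=(2.0, 5.0), fraction_nonsynonymous=0.7,
        )
        df = simulate_variant_table(5000, seed=3, **params)
        observed = len(consensus_filter(df)) / 5000
        expected = expected_survival_fraction(**params)
        se = np.sqrt(expected * (1 - expected) / 5000)
        assert abs(observed - expected) < 3 * se

    def test_empty_table(self):
        assert len(simulate_variant_table(0, seed=0)) == 0

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            simulate_variant_table(10, caller_support_prob=1.5, seed=0)

    def test_channel_mixture_respected(self, reference):
        mixture = reference.profile("SynthSigA")
        df = simulate_variant_table(
            2000, seed=1, channel_mixture=mixture / mixture.sum()
        )
        from parpomics.variants import build_catalog

        catalog = build_catalog(df)
        freq = catalog.counts / catalog.total
        assert np.abs(freq - mixture).sum() < 0.15


class TestBiomarkerCohort:
    def test_resistant_implies_at_least_one_flag(self):
        for seed in range(5):
            cohort = simulate_biomarker_cohort(seed=seed)
            for sample, resistant in cohort.truth.resistant.items():
                flags = cohort.truth.biomarker_flags[sample]
                if resistant:
                    assert any(flags.values())
                else:
                    assert not any(flags.values())

    def test_same_seed_identical(self):
        a = simulate_biomarker_cohort(seed=4)
        b = simulate_biomarker_cohort(seed=4)
        pd.testing.assert_frame_equal(a.expression.values, b.expression.values)
        assert a.rcb == b.rcb
        assert {s: p.segments for s, p in a.profiles.items()} == {
            s: p.segments for s, p in b.profiles.items()
        }

    def test_labels_consistent_with_rcb(self):
        cohort = simulate_biomarker_cohort(seed=2)
        from parpomics.biomarkers import dichotomize_response

        for sample, rcb in cohort.rcb.items():
            assert dichotomize_response(rcb) == cohort.labels[sample]
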