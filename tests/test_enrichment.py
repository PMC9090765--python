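"""Expression normalization, ranking, GSEA, ORA and signature scores."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from parpomics.enrichment import (
    RankedGeneList,
    benjamini_hochberg,
    enrichment_score,
    gsea_preranked,
    leading_edge,
    log2_tpm,
    overrepresentation_test,
    rank_genes,
    signature_score,
)
from parpomics.model import ExpressionMatrix, GeneSetCollection, ResponseLabel


def expr(values, genes, samples, scale="log2tpm", lengths=None):
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        scale=scale,
        gene_lengths=lengths,
    )


class TestLog2Tpm:
    def test_closed_form(self):
        m = expr(
            [[10], [90]], ["a", "b"], ["s1"], scale="counts",
            lengths=pd.Series({"a": 1000, "b": 1000}),
        )
        out = log2_tpm(m)
        assert out.values.loc["a", "s1"] == pytest.approx(np.log2(1e5 + 1))
        assert out.values.loc["b", "s1"] == pytest.approx(np.log2(9e5 + 1))

    def test_zero_gene(self):
        m = expr(
            [[0], [10]], ["a", "b"], ["s1"], scale="counts",
            lengths=pd.Series({"a": 500, "b": 500}),
        )
        assert log2_tpm(m).values.loc["a", "s1"] == 0.0

    def test_depth_invariance(self):
        lengths = pd.Series({"a": 1000, "b": 2500, "c": 700})
        m1 = expr([[10, 20], [5, 2], [8, 16]], list("abc"), ["s1", "s2"],
                  scale="counts", lengths=lengths)
        m2 = expr([[20, 20], [10, 2], [16, 16]], list("abc"), ["s1", "s2"],
                  scale="counts", lengths=lengths)
        pd.testing.assert_series_equal(
            log2_tpm(m1).values["s1"], log2_tpm(m2).values["s1"]
        )

    def test_missing_lengths_rejected(self):
        m = expr([[1]], ["a"], ["s1"], scale="counts")
        with pytest.raises(ValueError, match="gene_lengths"):
            log2_tpm(m)


class TestRankGenes:
    def labels(self, n_sens, n_res):
        out = {f"a{i}": ResponseLabel.SENSITIVE for i in range(n_sens)}
        out.update({f"b{i}": ResponseLabel.RESISTANT for i in range(n_res)})
        return out

    def test_identical_values_rank_zero(self):
        labels = self.labels(3, 3)
        m = expr(np.ones((2, 6)), ["g1", "g2"], list(labels))
        ranked = rank_genes(m, labels)
        assert np.all(ranked.statistic == 0)

    def test_planted_gene_ranks_first(self):
        rng = np.random.default_rng(0)
        labels = self.labels(5, 5)
        values = rng.normal(0, 1, size=(101, 10))
        values[0, :5] += 5.0  # 5 SD shift toward SENSITIVE
        genes = ["PLANT"] + [f"g{i}" for i in range(100)]
        ranked = rank_genes(expr(values, genes, list(labels)), labels)
        assert ranked.genes[0] == "PLANT"

    def test_label_swap_negates_and_reverses(self):
        rng = np.random.default_rng(1)
        labels = self.labels(3, 4)
        flipped = {
            s: (
                ResponseLabel.RESISTANT
                if v == ResponseLabel.SENSITIVE
                else ResponseLabel.SENSITIVE
            )
            for s, v in labels.items()
        }
        m = expr(rng.normal(size=(40, 7)), [f"g{i}" for i in range(40)], list(labels))
        fwd = rank_genes(m, labels)
        rev = rank_genes(m, flipped)
        assert fwd.genes == rev.genes[::-1]
        assert np.allclose(np.sort(fwd.statistic), np.sort(-rev.statistic))

    def test_small_group_rejected(self):
        labels = self.labels(1, 4)
        m = expr(np.ones((2, 5)), ["g1", "g2"], list(labels))
        with pytest.raises(ValueError, match=">= 2 samples"):
            rank_genes(m, labels)


class TestEnrichmentScore:
    def ranking(self):
        return RankedGeneList(
            genes=["g1", "g2", "g3", "g4", "g5", "g6"],
            statistic=[3, 2, 1, -1, -2, -3],
        )

    def test_hand_worked_example(self):
        es, peak = enrichment_score(self.ranking(), ["g1", "g4"])
        assert es == pytest.approx(0.75)
        assert peak == 0

    def test_all_genes_degenerate_set(self):
        ranked = self.ranking()
        es, _ = enrichment_score(ranked, ranked.genes)
        assert es == 1.0

    def test_leading_edge_positive(self):
        ranked = self.ranking()
        es, peak = enrichment_score(ranked, ["g1", "g4"])
        assert leading_edge(ranked, ["g1", "g4"], es, peak) == ["g1"]

    def test_leading_edge_negative_mirror(self):
        ranked = self.ranking()
        es, peak = enrichment_score(ranked, ["g5", "g6"])
        assert es < 0
        assert leading_edge(ranked, ["g5", "g6"], es, peak) == ["g5", "g6"]

    def test_leading_edge_subset_of_set(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            genes = [f"g{i}" for i in range(50)]
            ranked = RankedGeneList(genes=genes, statistic=rng.normal(size=50))
            members = list(rng.choice(genes, size=8, replace=False))
            es, peak = enrichment_score(ranked, members)
            lead = leading_edge(ranked, members, es, peak)
            assert set(lead) <= set(members)
            assert lead  # the extremum hit itself is always included

    def test_sign_flips_under_ranking_reversal(self):
        ranked = self.ranking()
        reversed_ranking = RankedGeneList(
            genes=ranked.genes, statistic=-ranked.statistic
        )
        es_fwd, _ = enrichment_score(ranked, ["g1", "g2"])
        es_rev, _ = enrichment_score(reversed_ranking, ["g1", "g2"])
        assert es_fwd == pytest.approx(-es_rev)

    def test_unweighted_es_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(30)]
        stats = rng.normal(size=30)
        members = list(rng.choice(genes, size=6, replace=False))
        a = RankedGeneList(genes=genes, statistic=stats)
        b = RankedGeneList(genes=genes, statistic=np.exp(stats))  # same order
        es_a, _ = enrichment_score(a, members, weight_exponent=0)
        es_b, _ = enrichment_score(b, members, weight_exponent=0)
        assert es_a == pytest.approx(es_b)

    def test_matches_fgsea_reference_implementation(self, tmp_path):
        """Dual-route check: our running-sum ES against Bioconductor
        fgsea::calcGseaStat on random rankings."""
        rng = np.random.default_rng(7)
        stats = np.sort(rng.standard_normal(100))[::-1]
        genes = [f"g{i:03d}" for i in range(100)]
        ranked = RankedGeneList(genes=genes, statistic=stats)
        cases = [
            sorted(rng.choice(100, size=k, replace=False).tolist())
            for k in (5, 12, 25)
        ]
        np.savetxt(tmp_path / "stats.txt", ranked.statistic)
        script = (
            'suppressMessages(library(fgsea));'
            f's <- scan("{tmp_path}/stats.txt", quiet=TRUE);'
            f'idx <- read.table("{tmp_path}/idx.txt");'
            'for (r in seq_len(nrow(idx))) {'
            ' v <- as.numeric(idx[r, idx[r,] > 0]);'
            ' cat(sprintf("%.12f\\n", calcGseaStat(s, v))) }'
        )
        width = max(len(c) for c in cases)
        padded = [c + [-1] * (width - len(c)) for c in cases]  # -1 = padding
        np.savetxt(
            tmp_path / "idx.txt",
            np.array(padded) + 1,  # 1-based for R; padding becomes 0
            fmt="%d",
        )
        out = subprocess.run(
            ["Rscript", "--vanilla", "-e", script],
            capture_output=True, text=True, check=True,
        )
        fgsea_es = [float(x) for x in out.stdout.split()]
        ours = [enrichment_score(ranked, [genes[i] for i in c])[0] for c in cases]
        assert ours == pytest.approx(fgsea_es, abs=1e-9)


class TestGseaPreranked:
    def test_fixed_seed_bit_identical(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(300)]
        ranked = RankedGeneList(genes=genes, statistic=rng.normal(size=300))
        sets = GeneSetCollection(
            {f"s{j}": list(rng.choice(genes, 20, replace=False)) for j in range(5)}
        )
        a = gsea_preranked(ranked, sets, n_perm=200, seed=99)
        b = gsea_preranked(ranked, sets, n_perm=200, seed=99)
        for ra, rb in zip(a, b):
            assert (ra.es, ra.nes, ra.p_nominal, ra.p_adjusted) == (
                rb.es, rb.nes, rb.p_nominal, rb.p_adjusted
            )

    def test_nes_sign_matches_es(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(300)]
        ranked = RankedGeneList(genes=genes, statistic=rng.normal(size=300))
        sets = GeneSetCollection(
            {f"s{j}": list(rng.choice(genes, 15, replace=False)) for j in range(10)}
        )
        for r in gsea_preranked(ranked, sets, n_perm=200, seed=1):
            assert np.sign(r.nes) == np.sign(r.es)
            assert 0 <= r.p_nominal <= 1 and 0 <= r.p_adjusted <= 1

    def test_small_sets_skipped(self):
        ranked = RankedGeneList(genes=list("abcdef"), statistic=[3, 2, 1, -1, -2, -3])
        sets = GeneSetCollection({"tiny": ["a", "b"], "absent": ["zz"]})
        assert gsea_preranked(ranked, sets, n_perm=100, seed=0, min_size=3) == []


class TestBenjaminiHochberg:
    def test_hand_example_with_step_up(self):
        assert benjamini_hochberg([0.01, 0.02, 0.04]) == pytest.approx(
            [0.03, 0.03, 0.04]
        )

    def test_single_and_constant(self):
        assert benjamini_hochberg([0.2]) == pytest.approx([0.2])
        assert benjamini_hochberg([0.3, 0.3, 0.3]) == pytest.approx([0.3] * 3)

    def test_monotone_and_at_least_raw(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=50)
        adj = benjamini_hochberg(p)
        assert np.all(adj >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])


class TestOverrepresentation:
    def test_exact_hypergeometric(self):
        sets = GeneSetCollection({"s": list("abcde")})
        df = overrepresentation_test(list("abcde"), sets, background_size=10)
        assert df.loc[0, "p_value"] == pytest.approx(1 / 252, rel=1e-9)

    def test_disjoint_set_p_one(self):
        sets = GeneSetCollection({"s": ["x", "y"]})
        df = overrepresentation_test(["a", "b"], sets, background_size=100)
        assert df.loc[0, "p_value"] == pytest.approx(1.0)

    def test_larger_background_never_less_significant(self):
        sets = GeneSetCollection({"s": [f"m{i}" for i in range(10)]})
        query = [f"m{i}" for i in range(5)] + ["q1", "q2"]
        p_small = overrepresentation_test(query, sets, 50).loc[0, "p_value"]
        p_large = overrepresentation_test(query, sets, 100).loc[0, "p_value"]
        assert p_large <= p_small

    def test_background_smaller_than_query_rejected(self):
        with pytest.raises(ValueError, match="background"):
            overrepresentation_test(list("abc"), GeneSetCollection({"s": ["a"]}), 2)


class TestSignatureScore:
    def test_constant_matrix_scores_zero(self):
        m = expr(np.full((5, 4), 3.0), [f"g{i}" for i in range(5)], list("wxyz"))
        assert np.allclose(signature_score(m, ["g0", "g1"]), 0.0)

    def test_shifted_sample_is_maximum(self):
        rng = np.random.default_rng(8)
        values = rng.normal(0, 1, size=(20, 6))
        values[:10, 0] += 2 * values[:10].std()
        m = expr(values, [f"g{i}" for i in range(20)], [f"s{i}" for i in range(6)])
        scores = signature_score(m, [f"g{i}" for i in range(10)])
        assert scores.idxmax() == "s0"
        assert scores["s0"] > 0

    def test_scores_center_to_zero(self):
        rng = np.random.default_rng(9)
        m = expr(rng.normal(size=(15, 8)), [f"g{i}" for i in range(15)],
                 [f"s{i}" for i in range(8)])
        scores = signature_score(m, [f"g{i}" for i in range(15)])
        assert scores.sum() == pytest.approx(0.0, abs=1e-9)

    def test_empty_intersection_rejected(self):
        m = expr(np.ones((2, 3)), ["g1", "g2"], list("abc"))
        with pytest.raises(ValueError, match="intersect"):
            signature_score(m, ["zz"])
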