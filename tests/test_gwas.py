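"""SNP-to-gene mapping, gene scoring, cutoff enrichment and locus overlap."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crosstalknet.gwas import (
    best_snp_joint_significance,
    cutoff_enrichment,
    map_snps_to_genes,
    score_genes,
    trait_locus_overlap,
)
from crosstalknet.io_formats import GeneAnnotation, SummaryStatRecord


def snp(snp_id, pos, p=0.5, chrom="1", beta=0.1, se=0.05):
    return SummaryStatRecord(
        snp=snp_id, chrom=chrom, pos=pos, effect_allele="A", other_allele="G",
        beta=beta, se=se, p=p,
    )


GENE = GeneAnnotation(gene="GX", chrom="1", start=1_000_000, end=1_050_000)


class TestMapping:
    def test_window_boundary_inclusive(self):
        inside = snp("rs_in", GENE.end + 499_999)
        outside = snp("rs_out", GENE.end + 500_001)
        mapping = map_snps_to_genes([inside, outside], [GENE], window_bp=500_000)
        assert [r.snp for r in mapping["GX"]] == ["rs_in"]

    def test_snp_in_gene_body_mapped(self):
        mapping = map_snps_to_genes([snp("rs1", GENE.start + 10)], [GENE])
        assert len(mapping["GX"]) == 1

    def test_wrong_chromosome_not_mapped(self):
        mapping = map_snps_to_genes([snp("rs1", GENE.start, chrom="2")], [GENE])
        assert mapping["GX"] == []

    def test_negative_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            map_snps_to_genes([], [GENE], window_bp=-1)

    def test_matches_brute_force_interval_check(self, rng):
        genes = []
        for i in range(25):
            start = int(rng.integers(1, 5 * 10**6))
            genes.append(
                GeneAnnotation(
                    gene=f"G{i}", chrom=str(rng.integers(1, 4)),
                    start=start, end=start + int(rng.integers(1, 100_000)),
                )
            )
        snps = [
            snp(f"rs{i}", int(rng.integers(1, 6 * 10**6)), chrom=str(rng.integers(1, 4)))
            for i in range(300)
        ]
        window = 200_000
        mapping = map_snps_to_genes(snps, genes, window_bp=window)
        for g in genes:
            expected = {
                s.snp for s in snps
                if s.chrom == g.chrom and g.start - window <= s.pos <= g.end + window
            }
            assert {s.snp for s in mapping[g.gene]} == expected

    def test_shrinking_window_never_adds_snps(self, rng):
        snps = [snp(f"rs{i}", int(rng.integers(1, 3 * 10**6))) for i in range(200)]
        wide = {s.snp for s in map_snps_to_genes(snps, [GENE], 500_000)["GX"]}
        narrow = {s.snp for s in map_snps_to_genes(snps, [GENE], 100_000)["GX"]}
        assert narrow <= wide


class TestScoreGenes:
    def _inputs(self, best_ps, n_snps_per_gene=None):
        annotation, mapping = [], {}
        for i, p in enumerate(best_ps):
            gene = f"G{i:03d}"
            start = 1 + i * 3_000_000
            annotation.append(GeneAnnotation(gene=gene, chrom="1", start=start, end=start + 10_000))
            n = 1 if n_snps_per_gene is None else n_snps_per_gene[i]
            snps = [snp(f"{gene}_b", start, p=p)]
            snps += [snp(f"{gene}_{j}", start + j + 1, p=min(1.0, p + (1 - p) * 0.5)) for j in range(n - 1)]
            mapping[gene] = snps
        return mapping, annotation

    def test_constant_confounders_preserve_ranking(self, rng):
        ps = rng.uniform(1e-6, 1, size=30)
        mapping, annotation = self._inputs(ps, n_snps_per_gene=[5] * 30)
        scores = score_genes(mapping, annotation)
        raw_order = [s.gene for s in sorted(scores, key=lambda s: -s.raw_score)]
        corrected_order = [s.gene for s in sorted(scores, key=lambda s: -s.corrected_score)]
        assert raw_order == corrected_order

    def test_best_p_one_gives_zero_raw_score(self):
        mapping, annotation = self._inputs([1.0])
        (score,) = score_genes(mapping, annotation)
        assert score.raw_score == 0.0
        assert score.corrected_score == score.raw_score  # single gene, flagged path

    def test_tie_broken_by_lowest_position(self):
        gene = GeneAnnotation(gene="G", chrom="1", start=100, end=200)
        mapping = {"G": [snp("rs_late", 180, p=0.01), snp("rs_early", 120, p=0.01)]}
        (score,) = score_genes(mapping, [gene])
        assert score.best_snp == "rs_early"

    def test_residual_orthogonal_to_confounder(self, rng):
        # raw score driven mechanically by SNP count: correction removes it
        n_genes = 2000
        n_snps = rng.integers(1, 200, size=n_genes)
        annotation, mapping = [], {}
        for i in range(n_genes):
            gene = f"G{i:04d}"
            start = 1 + i * 2_000_000
            annotation.append(GeneAnnotation(gene=gene, chrom="1", start=start, end=start + 10_000))
            raw = 2 * math.log10(n_snps[i]) + rng.normal(scale=0.3) if n_snps[i] > 1 else abs(rng.normal(scale=0.3))
            best_p = 10 ** (-max(raw, 0.0))
            records = [snp(f"{gene}_best", start, p=max(best_p, 1e-300))]
            records += [snp(f"{gene}_{j}", start + j + 1, p=1.0) for j in range(int(n_snps[i]) - 1)]
            mapping[gene] = records
        scores = score_genes(mapping, annotation)
        corrected = np.array([s.corrected_score for s in scores])
        logn = np.array([math.log10(s.n_snps) for s in scores])
        assert abs(np.corrcoef(corrected, logn)[0, 1]) < 0.05

    def test_percentile_uses_average_ranks(self):
        mapping, annotation = self._inputs([0.5, 0.5, 0.01])
        scores = {s.gene: s for s in score_genes(mapping, annotation)}
        # two tied raw scores share an average-rank percentile
        tied = [s for s in scores.values() if s.best_p == 0.5]
        assert len({s.percentile for s in tied}) in {1, 2}  # equal after identical correction


class TestCutoffEnrichment:
    def test_rank_scores_match_hypergeometric_tail(self):
        # scores are ranks 1..100: exactly 5 genes above the 95th percentile;
        # a 20-gene set containing all 5 has the hypergeometric tail p
        lookup = {f"G{i:03d}": float(i + 1) for i in range(100)}
        top5 = sorted(lookup, key=lookup.get, reverse=True)[:5]
        gene_set = top5 + sorted(set(lookup) - set(top5))[:15]
        res = cutoff_enrichment(lookup, gene_set, percentile_cutoff=0.95, n_sim=20_000, seed=3)
        assert res.observed_above == 5
        p_exact = stats.hypergeom.sf(4, 100, 5, 20)
        mc_se = math.sqrt(p_exact * (1 - p_exact) / 20_000)
        assert abs(res.p_empirical - p_exact) < 3 * mc_se + 1 / 20_001
        assert abs(res.expected_above - 20 * 5 / 100) < 0.05

    def test_whole_universe_set_is_null(self):
        lookup = {f"G{i:02d}": float(i) for i in range(50)}
        res = cutoff_enrichment(lookup, list(lookup), n_sim=200, seed=0)
        assert res.observed_above == pytest.approx(res.expected_above)
        assert res.p_empirical == 1.0

    def test_deterministic_under_seed(self):
        lookup = {f"G{i:02d}": float(i) for i in range(60)}
        gene_set = list(lookup)[:10]
        r1 = cutoff_enrichment(lookup, gene_set, n_sim=500, seed=9)
        r2 = cutoff_enrichment(lookup, gene_set, n_sim=500, seed=9)
        assert r1 == r2

    def test_unscored_set_rejected(self):
        with pytest.raises(ValueError, match="no scored genes"):
            cutoff_enrichment({"A": 1.0}, ["Z"], n_sim=10, seed=0)


class TestJointSignificance:
    @staticmethod
    def _statistic(selected):
        from crosstalknet.risk_score import score_effect

        records = [
            SummaryStatRecord(
                snp=s.best_snp, chrom="1", pos=1, effect_allele="A", other_allele="G",
                beta=s.raw_score / 10, se=0.1, p=s.best_p,
            )
            for s in selected
        ]
        result = score_effect(records)
        return result.p, result.beta_score

    def _scores(self, rng, n=50):
        from crosstalknet.gwas import GeneScore

        ps = rng.uniform(0.001, 1, size=n)
        ranks = stats.rankdata(-np.log10(ps))
        return [
            GeneScore(
                gene=f"G{i:03d}", best_snp=f"rs{i}", best_p=float(ps[i]),
                raw_score=float(-np.log10(ps[i])), corrected_score=float(-np.log10(ps[i])),
                percentile=float(ranks[i] / n), gene_length_bp=10_000, n_snps=5,
            )
            for i in range(n)
        ]

    def test_planted_signal_hits_floor(self, rng):
        scores = self._scores(rng)
        strong = sorted(scores, key=lambda s: -s.percentile)[:5]
        ep = best_snp_joint_significance(
            scores, [s.gene for s in strong], self._statistic,
            n_sim=200, seed=1, percentile_cutoff=0.9,
        )
        assert ep.p <= 0.05

    def test_deterministic(self, rng):
        scores = self._scores(rng)
        genes = [s.gene for s in scores[:10]]
        e1 = best_snp_joint_significance(
            scores, genes, self._statistic, n_sim=100, seed=4, percentile_cutoff=None
        )
        e2 = best_snp_joint_significance(
            scores, genes, self._statistic, n_sim=100, seed=4, percentile_cutoff=None
        )
        assert e1 == e2


class TestTraitLocusOverlap:
    def _annotation(self, n=30):
        return [
            GeneAnnotation(gene=f"G{i:02d}", chrom="1", start=1 + i * 2_000_000,
                           end=1 + i * 2_000_000 + 10_000)
            for i in range(n)
        ]

    def test_empty_catalog_gives_p_one(self):
        catalog = pd.DataFrame(columns=["snp", "chrom", "pos", "trait"])
        ep = trait_locus_overlap(["G00", "G01"], catalog, self._annotation(), n_sim=50, seed=0)
        assert ep.observed == 0 and ep.p == 1.0

    def test_every_gene_near_snp_gives_p_one(self):
        annotation = self._annotation(10)
        catalog = pd.DataFrame(
            {
                "snp": [f"rs{i}" for i in range(10)],
                "chrom": ["1"] * 10,
                "pos": [a.start for a in annotation],
                "trait": ["T2D"] * 10,
            }
        )
        ep = trait_locus_overlap(
            [a.gene for a in annotation[:4]], catalog, annotation, n_sim=100, seed=0
        )
        assert ep.observed == 4 and ep.p == 1.0

    def test_planted_enrichment_detected_and_counts_exact(self, rng):
        annotation = self._annotation(40)
        target = [a.gene for a in annotation[:8]]
        catalog = pd.DataFrame(
            {
                "snp": [f"rs{i}" for i in range(8)],
                "chrom": ["1"] * 8,
                "pos": [annotation[i].start + 1000 for i in range(8)],
                "trait": ["T2D"] * 8,
            }
        )
        ep = trait_locus_overlap(target, catalog, annotation, window_bp=250_000, n_sim=2000, seed=5)
        # brute-force observed count
        observed = 0
        for gene in target:
            ann = next(a for a in annotation if a.gene == gene)
            observed += any(
                abs(pos - ann.start) <= 250_000 + ann.length for pos in catalog["pos"]
                if ann.start - 250_000 <= pos <= ann.end + 250_000
            )
        assert ep.observed == observed == 8
        assert ep.p < 0.05
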