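"""End-to-end orchestration: assembly -> crosstalk -> optional evaluations.

Each stage writes TSV outputs prefixed with a header comment carrying the
config hash and seed, so every file can be traced to the run that produced
it.  Optional stages (signature enrichment, GSEA, GWAS scan, risk score) are
skipped with a logged notice when their inputs are absent from the config.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from crosstalknet import io_formats
from crosstalknet.config import RunConfig
from crosstalknet.crosstalk import (
    build_crosstalk_network,
    export_network,
    high_confidence_subset,
    internodes_to_frame,
    system_connectivity,
)
from crosstalknet.gsea import nes_and_significance, rank_genes
from crosstalknet.gwas import cutoff_enrichment, map_snps_to_genes, score_genes, trait_locus_overlap
from crosstalknet.interactome import (
    Interactome,
    TissueExpressionCalls,
    assemble,
    complex_edges,
    derive_ppicorr,
    filter_ppi_high,
    metabolic_adjacency,
    pathway_edges,
)
from crosstalknet.risk_score import score_test_for_gene_set
from crosstalknet.signature_enrichment import enrich

logger = logging.getLogger(__name__)


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(config.header_comment())
        df.to_csv(fh, sep="\t", index=False)


def build_interactome_from_config(config: RunConfig) -> Interactome:
    """Run the per-source filters on the configured inputs and assemble."""
    calls = TissueExpressionCalls(calls=io_formats.read_tissue_calls(config.tissue_calls))
    evidence = []
    if config.ppi:
        ppi = io_formats.read_edge_evidence(config.ppi)
        high = [e for e in ppi if e.lab_count is not None and e.lab_count >= config.lab_count_min]
        single = [e for e in ppi if e.lab_count == 1]
        evidence.append(filter_ppi_high(high, calls))
        if config.coexpr and single:
            coexpr = pd.read_csv(config.coexpr, sep="\t", index_col=0)
            evidence.append(
                derive_ppicorr(
                    single, coexpr, calls,
                    corr_method=config.corr_method, alpha=config.corr_fdr_alpha,
                )
            )
    if config.complexes:
        evidence.append(complex_edges(io_formats.read_complexes(config.complexes)))
    if config.reactions:
        evidence.append(metabolic_adjacency(io_formats.read_reactions(config.reactions)))
    if config.pathways:
        evidence.append(pathway_edges(io_formats.read_pathway_relations(config.pathways)))
    return assemble(*evidence)


def run_all(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute every configured stage; returns the output directory."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    # --- assembly and crosstalk -------------------------------------------
    interactome = build_interactome_from_config(config)
    parts_a = io_formats.read_parts_list(config.parts_a, "A")
    parts_b = io_formats.read_parts_list(config.parts_b, "B")
    network = build_crosstalk_network(interactome, parts_a, parts_b)
    export_network(network, interactome, out)
    confident = high_confidence_subset(
        network.internodes, config.min_evidence, config.min_evidence
    )
    _write_tsv(internodes_to_frame(confident), out / "internodes_high_confidence.tsv", config)
    conn_a, conn_b = system_connectivity(interactome, parts_a, parts_b)
    _write_tsv(
        pd.DataFrame(conn_a, columns=["gene", "indirect_connections"]),
        out / "connectivity_A.tsv", config,
    )
    _write_tsv(
        pd.DataFrame(conn_b, columns=["gene", "indirect_connections"]),
        out / "connectivity_B.tsv", config,
    )
    internode_genes = [r.gene for r in network.internodes]
    io_formats.write_gmt(
        {
            "internodes": internode_genes,
            "systemA": sorted(parts_a.genes & interactome.universe),
            "systemB": sorted(parts_b.genes & interactome.universe),
        },
        out / "signatures.gmt",
    )

    # --- signature enrichment ---------------------------------------------
    if config.gmt:
        results = enrich(
            set(internode_genes) & interactome.universe,
            io_formats.read_gmt(config.gmt),
            interactome.universe,
            min_overlap=config.min_overlap,
            alpha=config.alpha,
        )
        _write_tsv(
            pd.DataFrame(
                [
                    {
                        "set_name": r.set_name, "k": r.k, "K": r.K, "n": r.n, "N": r.N,
                        "odds_ratio": r.odds_ratio, "chi2_stat": r.chi2_stat,
                        "p": r.p, "significant": r.significant,
                    }
                    for r in results
                ]
            ),
            out / "signature_enrichment.tsv", config,
        )
    else:
        logger.info("no GMT configured; signature enrichment skipped")

    # --- expression GSEA ---------------------------------------------------
    if config.expression and config.expression_labels:
        expr = io_formats.read_expression(config.expression, config.expression_labels)
        shared = [g for g in expr.genes if g in interactome.universe]
        expr_bg = io_formats.ExpressionMatrix(
            values=expr.values.loc[shared], condition=expr.condition
        )
        ranked = rank_genes(expr_bg)
        signatures = {
            "internodes": set(internode_genes),
            "systemA": parts_a.genes & interactome.universe,
            "systemB": parts_b.genes & interactome.universe,
        }
        signatures = {
            k: v & set(shared) for k, v in signatures.items() if v & set(shared)
        }
        gsea_results = nes_and_significance(
            ranked, signatures, n_perm=config.n_perm, seed=config.seed, expr=expr_bg
        )
        _write_tsv(
            pd.DataFrame(
                [
                    {
                        "set_name": r.set_name, "es": r.es, "nes": r.nes,
                        "p_sign_restricted": r.p_sign_restricted, "fdr_q": r.fdr_q,
                        "n_hits": r.n_hits,
                    }
                    for r in gsea_results
                ]
            ),
            out / "gsea.tsv", config,
        )
    else:
        logger.info("no expression input configured; GSEA skipped")

    # --- GWAS gene-score scan ----------------------------------------------
    scores = None
    if config.sumstats and config.annotation:
        sumstats = io_formats.read_sumstats(config.sumstats)
        annotation = io_formats.read_gene_annotation(config.annotation, config.annotation_dialect)
        mapping = map_snps_to_genes(sumstats, annotation, window_bp=config.window_bp)
        scores = score_genes(mapping, annotation, window_bp=config.window_bp)
        _write_tsv(
            pd.DataFrame(
                [
                    {
                        "gene": s.gene, "best_snp": s.best_snp, "best_p": s.best_p,
                        "raw_score": s.raw_score, "corrected_score": s.corrected_score,
                        "percentile": s.percentile, "n_snps": s.n_snps,
                    }
                    for s in scores
                ]
            ),
            out / "gene_scores.tsv", config,
        )
        scored_internodes = set(internode_genes) & {s.gene for s in scores}
        if scored_internodes:
            ce = cutoff_enrichment(
                scores, scored_internodes,
                percentile_cutoff=config.percentile_cutoff,
                n_sim=config.n_sim, seed=config.seed,
            )
            _write_tsv(
                pd.DataFrame(
                    [
                        {
                            "set_size_scored": ce.set_size_scored,
                            "observed_above": ce.observed_above,
                            "expected_above": ce.expected_above,
                            "p_empirical": ce.p_empirical,
                            "cutoff_value": ce.cutoff_value,
                            "n_sim": ce.n_sim,
                        }
                    ]
                ),
                out / "gwas_cutoff_enrichment.tsv", config,
            )
        if config.catalog_snps:
            catalog = io_formats.read_catalog_snps(config.catalog_snps)
            overlap = trait_locus_overlap(
                set(internode_genes), catalog, annotation,
                window_bp=config.catalog_window_bp,
                n_sim=config.n_sim, seed=config.seed,
            )
            _write_tsv(
                pd.DataFrame(
                    [
                        {
                            "observed": overlap.observed, "n_sim": overlap.n_sim,
                            "n_as_extreme": overlap.n_as_extreme, "p": overlap.p,
                        }
                    ]
                ),
                out / "trait_locus_overlap.tsv", config,
            )
    else:
        logger.info("no GWAS inputs configured; gene-score scan skipped")

    # --- risk score ---------------------------------------------------------
    if config.trait_sumstats and scores is not None:
        trait = io_formats.read_sumstats(config.trait_sumstats)
        top = [
            s for s in scores
            if s.gene in set(internode_genes) and s.percentile > config.percentile_cutoff
        ]
        if top:
            result = score_test_for_gene_set(
                [s.best_snp for s in top], trait, weighting=config.risk_weighting
            )
            _write_tsv(
                pd.DataFrame(
                    [
                        {
                            "n_snps": result.n_snps, "beta_score": result.beta_score,
                            "se_score": result.se_score, "z": result.z, "p": result.p,
                            "weighting": result.weighting,
                        }
                    ]
                ),
                out / "risk_score.tsv", config,
            )
        else:
            logger.info("no internode genes above the score cutoff; risk score skipped")
    elif config.trait_sumstats:
        logger.info("risk score requires the GWAS scan stage; skipped")
    return out
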