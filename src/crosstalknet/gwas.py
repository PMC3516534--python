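"""Gene-based GWAS enrichment scan in the style of MAGENTA.

Each gene is assigned the SNPs falling within a fixed window (default 500 kb)
of its most extreme transcript boundaries and scored by its most significant
SNP, -log10(best p).  Raw scores are residualized on confounders that inflate
best-SNP statistics mechanically — log10 scored-region length and log10 SNP
count — by ordinary least squares.  A candidate gene set is then tested for
over-representation above a score percentile cutoff (default 95th) against
size-matched random sets drawn from the scored universe.

The confounder set is a deliberate simplification of MAGENTA's (which also
uses linkage-disequilibrium-derived covariates from a reference panel); the
regression accepts extra covariate columns when the caller has them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from crosstalknet.io_formats import GeneAnnotation, SummaryStatRecord
from crosstalknet.null_models import EmpiricalP, empirical_p, sample_gene_sets

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneScore:
    gene: str
    best_snp: str
    best_p: float
    raw_score: float
    corrected_score: float
    percentile: float
    gene_length_bp: int
    n_snps: int

    def __post_init__(self) -> None:
        if not (0 < self.best_p <= 1):
            raise ValueError(f"{self.gene}: best_p outside (0, 1]")


@dataclass(frozen=True)
class CutoffEnrichment:
    set_size_scored: int
    observed_above: int
    expected_above: float
    p_empirical: float
    cutoff_value: float
    n_sim: int


def map_snps_to_genes(
    sumstats: Sequence[SummaryStatRecord],
    annotation: Sequence[GeneAnnotation],
    window_bp: int = 500_000,
) -> dict[str, list[SummaryStatRecord]]:
    """Assign each SNP to every gene within ``window_bp`` of its boundaries.

    A SNP maps to gene g iff it is on g's chromosome and
    start - window <= pos <= end + window (1-based inclusive).  Genes with no
    mapped SNPs are present with an empty list so callers can report them as
    unscored.  Positions and annotation must share a genome build.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    by_chrom: dict[str, list[SummaryStatRecord]] = {}
    for rec in sumstats:
        by_chrom.setdefault(rec.chrom, []).append(rec)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda r: r.pos)
    mapping: dict[str, list[SummaryStatRecord]] = {}
    for ann in annotation:
        snps = by_chrom.get(ann.chrom, [])
        positions = [r.pos for r in snps]
        lo = np.searchsorted(positions, ann.start - window_bp, side="left")
        hi = np.searchsorted(positions, ann.end + window_bp, side="right")
        mapping[ann.gene] = snps[lo:hi]
    n_unscored = sum(1 for v in mapping.values() if not v)
    if n_unscored:
        logger.info("%d genes have no SNP within %d bp and are unscored", n_unscored, window_bp)
    return mapping


def score_genes(
    mapping: Mapping[str, Sequence[SummaryStatRecord]],
    annotation: Sequence[GeneAnnotation],
    window_bp: int = 500_000,
    extra_covariates: pd.DataFrame | None = None,
) -> list[GeneScore]:
    """Best-SNP gene scores with confounder correction.

    raw_score = -log10(min SNP p) (ties broken by lowest genomic position);
    corrected_score is the OLS residual of raw_score on log10(scored-region
    length) and log10(n SNPs), plus any ``extra_covariates`` columns (indexed
    by gene).  Percentiles use average ranks on the corrected score.
    """
    ann_by_gene = {a.gene: a for a in annotation}
    rows = []
    for gene in sorted(mapping):
        snps = mapping[gene]
        if not snps:
            continue
        best = min(snps, key=lambda r: (r.p, r.pos))
        ann = ann_by_gene[gene]
        rows.append(
            {
                "gene": gene,
                "best_snp": best.snp,
                "best_p": best.p,
                "raw_score": -math.log10(best.p),
                "gene_length_bp": ann.length,
                "n_snps": len(snps),
            }
        )
    if not rows:
        raise ValueError("no scored genes")
    df = pd.DataFrame(rows).set_index("gene")
    if len(df) == 1:
        logger.warning("single scored gene: no confounder correction possible")
        df["corrected_score"] = df["raw_score"]
    else:
        x_cols = [
            np.log10(df["gene_length_bp"].to_numpy(float) + 2 * window_bp),
            np.log10(df["n_snps"].to_numpy(float)),
        ]
        if extra_covariates is not None:
            extra = extra_covariates.reindex(df.index)
            if extra.isna().any().any():
                raise ValueError("extra covariates missing for some scored genes")
            x_cols.extend(extra[c].to_numpy(float) for c in extra.columns)
        X = np.column_stack([np.ones(len(df)), *x_cols])
        y = df["raw_score"].to_numpy(float)
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        df["corrected_score"] = y - X @ coef
    ranks = stats.rankdata(df["corrected_score"].to_numpy(), method="average")
    df["percentile"] = ranks / len(df)
    return [
        GeneScore(
            gene=gene,
            best_snp=row.best_snp,
            best_p=float(row.best_p),
            raw_score=float(row.raw_score),
            corrected_score=float(row.corrected_score),
            percentile=float(row.percentile),
            gene_length_bp=int(row.gene_length_bp),
            n_snps=int(row.n_snps),
        )
        for gene, row in df.iterrows()
    ]


def _score_lookup(scores: Sequence[GeneScore] | Mapping[str, float]) -> dict[str, float]:
    if isinstance(scores, Mapping):
        return dict(scores)
    return {s.gene: s.corrected_score for s in scores}


def cutoff_enrichment(
    scores: Sequence[GeneScore] | Mapping[str, float],
    gene_set: Iterable[str],
    percentile_cutoff: float = 0.95,
    n_sim: int = 10_000,
    seed: int = 0,
) -> CutoffEnrichment:
    """Over-representation of a gene set above a score percentile cutoff.

    The cutoff is the empirical ``percentile_cutoff`` quantile of all
    (corrected) gene scores; counting is strictly above the cutoff value, so
    ties sitting exactly at the cutoff are excluded.  The null distribution
    comes from ``n_sim`` random sets of the same scored size drawn from the
    scored universe; p is the add-one empirical frequency (direction greater).
    """
    lookup = _score_lookup(scores)
    members = sorted(set(gene_set) & set(lookup))
    if not members:
        raise ValueError("gene set has no scored genes")
    values = np.array([lookup[g] for g in sorted(lookup)])
    cutoff_value = float(np.quantile(values, percentile_cutoff))
    observed = sum(lookup[g] > cutoff_value for g in members)
    universe = sorted(lookup)
    rng_sets = sample_gene_sets(universe, size=len(members), n_sets=n_sim, seed=seed)
    null_counts = np.array(
        [sum(lookup[g] > cutoff_value for g in s) for s in rng_sets], dtype=float
    )
    emp = empirical_p(float(observed), null_counts, direction="greater")
    return CutoffEnrichment(
        set_size_scored=len(members),
        observed_above=int(observed),
        expected_above=float(null_counts.mean()),
        p_empirical=emp.p,
        cutoff_value=cutoff_value,
        n_sim=n_sim,
    )


def best_snp_joint_significance(
    scores: Sequence[GeneScore],
    gene_set: Iterable[str],
    statistic: Callable[[Sequence[GeneScore]], tuple[float, float]],
    n_sim: int = 1000,
    seed: int = 0,
    percentile_cutoff: float | None = 0.95,
) -> EmpiricalP:
    """Empirical significance of a joint statistic over a set's best SNPs.

    ``statistic`` maps a list of GeneScores (their best SNPs) to
    (p_value, effect); the typical choice is a pooled multi-SNP risk-score
    test.  When ``percentile_cutoff`` is given, only set genes whose score
    percentile exceeds it contribute, and each null draw samples a
    size-matched random gene set and applies the same statistic to its
    members' best SNPs.  Extremeness is the compound condition
    "null p smaller than observed AND null effect > 0".
    """
    by_gene = {s.gene: s for s in scores}
    members = sorted(set(gene_set) & set(by_gene))
    if not members:
        raise ValueError("gene set has no scored genes")
    if percentile_cutoff is not None:
        selected = [by_gene[g] for g in members if by_gene[g].percentile > percentile_cutoff]
    else:
        selected = [by_gene[g] for g in members]
    if not selected:
        raise ValueError("no set genes above the percentile cutoff")
    obs_p, obs_effect = statistic(selected)
    universe = sorted(by_gene)
    null_sets = sample_gene_sets(universe, size=len(members), n_sets=n_sim, seed=seed)
    null_draws: list[tuple[float, float]] = []
    for s in null_sets:
        if percentile_cutoff is not None:
            sel = [by_gene[g] for g in sorted(s) if by_gene[g].percentile > percentile_cutoff]
        else:
            sel = [by_gene[g] for g in sorted(s)]
        if not sel:
            null_draws.append((1.0, 0.0))
            continue
        null_draws.append(statistic(sel))
    return empirical_p(
        obs_p,
        null_draws,
        direction=lambda draw: draw[0] < obs_p and draw[1] > 0,
    )


def trait_locus_overlap(
    gene_set: Iterable[str],
    catalog_snps: pd.DataFrame,
    annotation: Sequence[GeneAnnotation],
    window_bp: int = 250_000,
    n_sim: int = 10_000,
    seed: int = 0,
    universe: Iterable[str] | None = None,
) -> EmpiricalP:
    """How many set genes sit near a trait-associated catalog SNP, vs chance.

    observed = number of set genes with >=1 catalog SNP within ``window_bp``
    of their boundaries; the null counts the same for size-matched random
    sets drawn from ``universe`` (default: all annotated genes).
    """
    ann_by_gene = {a.gene: a for a in annotation}
    members = sorted(set(gene_set) & set(ann_by_gene))
    if not members:
        raise ValueError("gene set has no annotated genes")
    by_chrom: dict[str, np.ndarray] = {
        str(chrom): np.sort(grp["pos"].to_numpy())
        for chrom, grp in catalog_snps.groupby("chrom")
    }

    def near_snp(gene: str) -> bool:
        ann = ann_by_gene[gene]
        positions = by_chrom.get(ann.chrom)
        if positions is None or len(positions) == 0:
            return False
        lo = np.searchsorted(positions, ann.start - window_bp, side="left")
        hi = np.searchsorted(positions, ann.end + window_bp, side="right")
        return hi > lo

    hit = {g: near_snp(g) for g in ann_by_gene}
    observed = sum(hit[g] for g in members)
    pool = sorted(set(universe) & set(ann_by_gene)) if universe is not None else sorted(ann_by_gene)
    null_sets = sample_gene_sets(pool, size=len(members), n_sets=n_sim, seed=seed)
    null_counts = np.array([sum(hit[g] for g in s) for s in null_sets], dtype=float)
    return empirical_p(float(observed), null_counts, direction="greater")
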