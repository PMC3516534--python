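"""Multi-SNP genetic risk score effect from GWAS summary statistics.

For a set of SNPs in linkage equilibrium, the effect of the unweighted risk
score (per-individual sum of risk-increasing allele counts) on a quantitative
trait can be estimated from per-SNP summary statistics alone: a weighted
average of the per-SNP effects,

    beta_score = sum_j w_j * beta_j / sum_j w_j,

with standard error derived from the same weights, and z = beta_score / se
referred to the standard normal.  Two weighting conventions are provided:

``ivw`` (default)
    w_j = 1 / se_j^2.  This inverse-variance weighting is the convention
    under which the summary-level estimate converges to the individual-level
    least-squares regression of the trait on the unweighted allele-count
    score (se_j^2 is inversely proportional to the allele-count variance of
    SNP j, which is exactly each SNP's leverage in that regression).
``inv_se``
    w_j = 1 / se_j, the literal "inverse of the standard error" reading.

Linkage equilibrium among the SNPs is assumed and is the caller's
responsibility; under correlated SNPs the standard error is invalid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from crosstalknet.io_formats import SummaryStatRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RiskScoreResult:
    n_snps: int
    beta_score: float
    se_score: float
    weighting: str

    @property
    def z(self) -> float:
        return self.beta_score / self.se_score

    @property
    def p(self) -> float:
        return float(2 * stats.norm.sf(abs(self.z)))


def orient_to_risk(
    records: Sequence[SummaryStatRecord],
    risk_alleles: Mapping[str, str] | None = None,
) -> list[SummaryStatRecord]:
    """Align each record to its risk-increasing allele.

    With ``risk_alleles`` (SNP id -> allele, typically taken from the
    *discovery* trait), records whose effect allele differs from the risk
    allele are flipped (alleles swapped, beta negated).  Without it, records
    are oriented by their own effect sign so all betas come out >= 0 — only
    appropriate on the discovery statistics themselves, since self-orientation
    on a test trait would bias the pooled effect upward under the null.

    SNPs with beta exactly 0 (self-orientation) have no defined risk
    direction; they are kept unchanged with a warning.
    """

    def flip(rec: SummaryStatRecord) -> SummaryStatRecord:
        return replace(
            rec,
            beta=-rec.beta,
            effect_allele=rec.other_allele,
            other_allele=rec.effect_allele,
        )

    out: list[SummaryStatRecord] = []
    for rec in records:
        if risk_alleles is not None:
            risk = risk_alleles[rec.snp]
            if risk == rec.effect_allele:
                out.append(rec)
            elif risk == rec.other_allele:
                out.append(flip(rec))
            else:
                raise ValueError(
                    f"{rec.snp}: risk allele {risk!r} matches neither "
                    f"{rec.effect_allele!r} nor {rec.other_allele!r}"
                )
        elif rec.beta < 0:
            out.append(flip(rec))
        else:
            if rec.beta == 0:
                logger.warning("%s: beta is 0, risk direction undefined", rec.snp)
            out.append(rec)
    return out


def score_effect(
    records: Sequence[SummaryStatRecord], weighting: str = "ivw"
) -> RiskScoreResult:
    """Pooled per-risk-allele effect of the unweighted multi-SNP score."""
    if not records:
        raise ValueError("no SNP records")
    betas = np.array([r.beta for r in records], dtype=float)
    ses = np.array([r.se for r in records], dtype=float)
    if np.any(ses <= 0):
        raise ValueError("all standard errors must be > 0")
    if weighting == "ivw":
        w = 1.0 / ses**2
    elif weighting == "inv_se":
        w = 1.0 / ses
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    w_sum = w.sum()
    beta_score = float(np.sum(w * betas) / w_sum)
    se_score = float(np.sqrt(np.sum(w**2 * ses**2)) / w_sum)
    return RiskScoreResult(
        n_snps=len(records), beta_score=beta_score, se_score=se_score, weighting=weighting
    )


def score_test_for_gene_set(
    best_snps_per_gene: Iterable[str],
    trait_sumstats: Sequence[SummaryStatRecord] | Mapping[str, SummaryStatRecord],
    risk_alleles: Mapping[str, str] | None = None,
    weighting: str = "ivw",
) -> RiskScoreResult:
    """Risk-score test for one best SNP per gene region against a trait.

    ``risk_alleles`` carries the discovery-trait risk direction per SNP;
    without it the trait records are self-oriented (see
    :func:`orient_to_risk` for the caveat).  Duplicate SNP ids are pooled
    once; SNPs absent from the trait summary statistics are dropped with a
    logged count.
    """
    if isinstance(trait_sumstats, Mapping):
        lookup = dict(trait_sumstats)
    else:
        lookup = {r.snp: r for r in trait_sumstats}
    wanted = sorted(set(best_snps_per_gene))
    found = [lookup[s] for s in wanted if s in lookup]
    n_missing = len(wanted) - len(found)
    if n_missing:
        logger.info(
            "risk score: %d of %d SNPs absent from trait summary statistics",
            n_missing, len(wanted),
        )
    if not found:
        raise ValueError("no risk-score SNPs found in the trait summary statistics")
    return score_effect(orient_to_risk(found, risk_alleles), weighting=weighting)
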