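"""Gene set enrichment analysis on a two-condition expression contrast.

Genes are ranked by a differential-expression statistic (signal-to-noise by
default), and each signature's enrichment score (ES) is the signed maximum
deviation of the weighted Kolmogorov-Smirnov-style running sum: hits add
|stat|^exponent normalized by the sum over hits, misses subtract
1/(N - n_hits).

Significance uses a permutation null restricted to the sign of the observed
ES: p is the add-one frequency of same-sign null ES at least as large in
magnitude, and NES is the ES divided by the mean magnitude of same-sign null
ES.  The FDR q-value compares same-sign null and observed NES distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from crosstalknet.io_formats import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class RankedList:
    """Genes ordered by a ranking statistic, descending; ties broken by symbol."""

    series: pd.Series  # index: gene, values: statistic, sorted descending

    def __post_init__(self) -> None:
        if self.series.index.duplicated().any():
            raise ValueError("duplicate genes in ranked list")
        if not np.all(np.isfinite(self.series.to_numpy(dtype=float))):
            raise ValueError("non-finite ranking statistics")

    @property
    def genes(self) -> list[str]:
        return list(self.series.index)

    @property
    def stats(self) -> np.ndarray:
        return self.series.to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.series)


@dataclass(frozen=True)
class GseaResult:
    set_name: str
    es: float
    nes: float
    p_sign_restricted: float
    fdr_q: float
    n_hits: int
    n_same_sign_null: int

    @property
    def flagged_no_same_sign_null(self) -> bool:
        return self.n_same_sign_null == 0


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------


def _signal_to_noise(x: np.ndarray, mask1: np.ndarray) -> np.ndarray:
    """Per-row signal-to-noise statistic (group 1 vs group 0).

    Standard deviations are floored at max(0.2 * |group mean|, 0.2) so genes
    with tiny variance cannot dominate the ranking.
    """
    g1, g0 = x[:, mask1], x[:, ~mask1]
    mu1, mu0 = g1.mean(axis=1), g0.mean(axis=1)
    sd1, sd0 = g1.std(axis=1, ddof=1), g0.std(axis=1, ddof=1)
    sd1 = np.maximum(sd1, np.maximum(0.2 * np.abs(mu1), 0.2))
    sd0 = np.maximum(sd0, np.maximum(0.2 * np.abs(mu0), 0.2))
    return (mu1 - mu0) / (sd1 + sd0)


def _t_statistic(x: np.ndarray, mask1: np.ndarray) -> np.ndarray:
    """Welch t statistic per row (group 1 vs group 0)."""
    g1, g0 = x[:, mask1], x[:, ~mask1]
    n1, n0 = g1.shape[1], g0.shape[1]
    v1, v0 = g1.var(axis=1, ddof=1), g0.var(axis=1, ddof=1)
    denom = np.sqrt(np.maximum(v1 / n1 + v0 / n0, 1e-12))
    return (g1.mean(axis=1) - g0.mean(axis=1)) / denom

_METRICS = {"s2n": _signal_to_noise, "t": _t_statistic}


def rank_genes(expr: ExpressionMatrix, metric: str = "s2n") -> RankedList:
    """Rank genes by differential expression (second condition level vs first)."""
    if metric not in _METRICS:
        raise ValueError(f"unknown ranking metric {metric!r}")
    ref, alt = expr.groups()
    mask1 = (expr.condition.astype(str) == alt).to_numpy()
    if mask1.sum() < 2 or (~mask1).sum() < 2:
        raise ValueError("need >=2 samples per condition group")
    stats = _METRICS[metric](expr.values.to_numpy(dtype=float), mask1)
    # mergesort is stable, so pre-sorting the index makes symbol the tiebreak
    frame = (
        pd.DataFrame({"stat": stats}, index=expr.values.index)
        .sort_index()
        .sort_values(by="stat", ascending=False, kind="mergesort")
    )
    return RankedList(series=frame["stat"])


# ---------------------------------------------------------------------------
# enrichment score
# ---------------------------------------------------------------------------


def _es_core(stats: np.ndarray, member: np.ndarray, weight_exponent: float) -> tuple[float, np.ndarray]:
    n = len(stats)
    n_hits = int(member.sum())
    if n_hits == 0:
        raise ValueError("gene set has no genes in the ranked list")
    if n_hits == n:
        raise ValueError("no miss steps: gene set covers all ranked genes")
    weights = np.where(member, np.abs(stats) ** weight_exponent, 0.0)
    denom = weights.sum()
    if denom == 0:  # all hit statistics exactly zero; fall back to equal weights
        increments = np.where(member, 1.0 / n_hits, -1.0 / (n - n_hits))
    else:
        increments = np.where(member, weights / denom, -1.0 / (n - n_hits))
    running = np.cumsum(increments)
    idx = int(np.argmax(np.abs(running)))
    return float(running[idx]), running


def enrichment_score(
    ranked: RankedList, gene_set: Iterable[str], weight_exponent: float = 1
) -> tuple[float, np.ndarray]:
    """(ES, running sum) of a gene set against the ranked list."""
    members = frozenset(gene_set)
    member = np.fromiter((g in members for g in ranked.genes), dtype=bool, count=len(ranked))
    return _es_core(ranked.stats, member, weight_exponent)


# ---------------------------------------------------------------------------
# permutation significance
# ---------------------------------------------------------------------------


def _null_es_gene_mode(
    ranked: RankedList, n_hits: int, n_perm: int, weight_exponent: float, rng: np.random.Generator
) -> np.ndarray:
    n = len(ranked)
    stats = ranked.stats
    out = np.empty(n_perm)
    for i in range(n_perm):
        member = np.zeros(n, dtype=bool)
        member[rng.choice(n, size=n_hits, replace=False)] = True
        out[i], _ = _es_core(stats, member, weight_exponent)
    return out


def _null_es_sample_mode(
    expr: ExpressionMatrix,
    memberships: Mapping[str, np.ndarray],
    n_perm: int,
    metric: str,
    weight_exponent: float,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Null ES per set from condition-label permutations with re-ranking."""
    x = expr.values.to_numpy(dtype=float)
    genes_sorted_idx = np.argsort(expr.values.index.to_numpy())  # symbol tiebreak
    x = x[genes_sorted_idx]
    member_by_set = {name: m[genes_sorted_idx] for name, m in memberships.items()}
    ref, alt = expr.groups()
    n1 = int((expr.condition.astype(str) == alt).sum())
    n_samples = x.shape[1]
    metric_fn = _METRICS[metric]
    nulls = {name: np.empty(n_perm) for name in memberships}
    for i in range(n_perm):
        mask1 = np.zeros(n_samples, dtype=bool)
        mask1[rng.choice(n_samples, size=n1, replace=False)] = True
        stats = metric_fn(x, mask1)
        order = np.argsort(-stats, kind="stable")
        stats_sorted = stats[order]
        for name, member in member_by_set.items():
            nulls[name][i], _ = _es_core(stats_sorted, member[order], weight_exponent)
    return nulls


def nes_and_significance(
    ranked: RankedList,
    gene_sets: Mapping[str, Iterable[str]],
    n_perm: int = 1000,
    perm_mode: str = "auto",
    seed: int = 0,
    expr: ExpressionMatrix | None = None,
    metric: str = "s2n",
    weight_exponent: float = 1,
) -> list[GseaResult]:
    """NES, sign-restricted permutation p and FDR q for each gene set.

    ``perm_mode`` is 'sample' (permute condition labels and re-rank; requires
    ``expr``), 'gene' (permute set membership over the fixed ranking), or
    'auto' (sample mode when ``expr`` is given with >=7 samples per group,
    gene mode otherwise).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    ranked_genes = ranked.genes
    memberships: dict[str, np.ndarray] = {}
    for name in gene_sets:
        members = frozenset(gene_sets[name])
        memberships[name] = np.fromiter(
            (g in members for g in ranked_genes), dtype=bool, count=len(ranked)
        )

    if perm_mode == "auto":
        if expr is not None:
            ref, alt = expr.groups()
            counts = expr.condition.astype(str).value_counts()
            perm_mode = "sample" if min(counts.get(ref, 0), counts.get(alt, 0)) >= 7 else "gene"
        else:
            perm_mode = "gene"
    if perm_mode == "sample":
        if expr is None:
            raise ValueError("sample-label permutation requires the expression matrix")
        # membership masks are aligned to the observed ranking; rebuild on raw gene order
        raw_memberships = {
            name: np.fromiter(
                (g in frozenset(gene_sets[name]) for g in expr.values.index),
                dtype=bool,
                count=expr.values.shape[0],
            )
            for name in gene_sets
        }
        nulls = _null_es_sample_mode(expr, raw_memberships, n_perm, metric, weight_exponent, rng)
    elif perm_mode == "gene":
        nulls = {
            name: _null_es_gene_mode(
                ranked, int(member.sum()), n_perm, weight_exponent, rng
            )
            for name, member in memberships.items()
        }
    else:
        raise ValueError(f"unknown permutation mode {perm_mode!r}")

    es_obs: dict[str, float] = {}
    for name, member in memberships.items():
        es_obs[name], _ = _es_core(ranked.stats, member, weight_exponent)

    # same-sign normalization per set
    nes_obs: dict[str, float] = {}
    nes_null_pool: list[np.ndarray] = []
    p_vals: dict[str, float] = {}
    n_same: dict[str, int] = {}
    for name, es in es_obs.items():
        null = nulls[name]
        same = null[np.sign(null) == np.sign(es)] if es != 0 else null
        n_same[name] = len(same)
        if len(same) == 0:
            logger.warning("%s: no same-sign null ES; p set to add-one floor", name)
            p_vals[name] = 1.0  # (0 + 1) / (0 + 1)
            nes_obs[name] = 0.0
            continue
        mean_mag = np.abs(same).mean()
        nes_obs[name] = es / mean_mag if mean_mag > 0 else 0.0
        p_vals[name] = (np.sum(np.abs(same) >= abs(es)) + 1) / (len(same) + 1)
        # normalize the null the same way for the FDR pool
        pos, neg = null[null > 0], null[null < 0]
        normed = np.concatenate(
            [
                pos / pos.mean() if len(pos) else pos,
                neg / np.abs(neg).mean() if len(neg) else neg,
            ]
        )
        nes_null_pool.append(normed)

    pool = np.concatenate(nes_null_pool) if nes_null_pool else np.empty(0)
    all_obs = np.array(list(nes_obs.values()))
    results: list[GseaResult] = []
    for name in gene_sets:
        nes = nes_obs[name]
        if nes == 0 or len(pool) == 0:
            q = 1.0
        else:
            sign = np.sign(nes)
            null_same = pool[np.sign(pool) == sign]
            obs_same = all_obs[np.sign(all_obs) == sign]
            num = np.mean(np.abs(null_same) >= abs(nes)) if len(null_same) else 1.0
            den = np.mean(np.abs(obs_same) >= abs(nes)) if len(obs_same) else 1.0
            q = min(1.0, num / den) if den > 0 else 1.0
        results.append(
            GseaResult(
                set_name=name,
                es=es_obs[name],
                nes=float(nes_obs[name]),
                p_sign_restricted=float(p_vals[name]),
                fdr_q=float(q),
                n_hits=int(memberships[name].sum()),
                n_same_sign_null=n_same[name],
            )
        )
    return results
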