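"""Per-source evidence filters and assembly of the high-confidence interactome.

Five evidence streams feed one collapsed undirected gene-pair graph:

``PPIhigh``
    protein-protein interactions reported independently by >=2 laboratories,
    with both genes expressed in at least one insulin-sensitive tissue.
``PPIcorr``
    single-laboratory interactions rescued by significant co-expression
    (Benjamini-Hochberg FDR on the pairwise correlation test) plus the same
    tissue-expression requirement.
``COMPLEX``
    clique expansion of protein-complex co-membership.
``MET_adj``
    gene pairs whose enzymes catalyze adjacent metabolic reactions (sharing a
    non-currency metabolite, direction ignored).
``PATH``
    gene pairs co-annotated to a signaling pathway.

Evidence multiplicity is preserved: a pair supported twice carries two
evidence records, and downstream "lines of evidence" tallies count records,
not sources.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from crosstalknet.io_formats import RawEdge, Reaction, canonical_pair

logger = logging.getLogger(__name__)

EVIDENCE_SOURCES = frozenset({"PPIhigh", "PPIcorr", "COMPLEX", "MET_adj", "PATH", "RANDOM"})

DEFAULT_TISSUES = ("adipose", "muscle", "liver", "heart")

#: metabolites excluded from reaction adjacency: they take part in so many
#: reactions that sharing one is not evidence of a functional link
DEFAULT_CURRENCY_METABOLITES = frozenset(
    {
        "ATP", "ADP", "AMP", "NAD", "NADH", "NADP", "NADPH",
        "H2O", "H+", "CO2", "PI", "COA",
    }
)


@dataclass(frozen=True)
class EvidenceEdge:
    """One line of evidence supporting an undirected gene pair."""

    pair: tuple[str, str]
    source: str
    provenance: str = ""
    lab_count: int | None = None
    correlation: float | None = None

    def __post_init__(self) -> None:
        if self.pair[0] == self.pair[1]:
            raise ValueError(f"self-loop evidence on {self.pair[0]}")
        if self.source not in EVIDENCE_SOURCES:
            raise ValueError(f"unknown evidence source {self.source!r}")


@dataclass
class TissueExpressionCalls:
    """Boolean expression calls per gene over the insulin-sensitive tissues."""

    calls: Mapping[str, Mapping[str, bool]]
    tissues: tuple[str, ...] = DEFAULT_TISSUES

    def is_expressed(self, gene: str) -> bool:
        """True when the gene is called expressed in at least one tissue.

        Genes absent from the table are treated as not expressed.
        """
        gene_calls = self.calls.get(gene)
        if gene_calls is None:
            return False
        return any(bool(gene_calls.get(t, False)) for t in self.tissues)


class Interactome:
    """Collapsed pair graph with the per-pair evidence multiset."""

    def __init__(self, pairs: Mapping[tuple[str, str], Sequence[EvidenceEdge]]):
        if not pairs:
            raise ValueError("empty interactome")
        self.pairs: dict[tuple[str, str], list[EvidenceEdge]] = {}
        for pair in sorted(pairs):
            records = list(pairs[pair])
            if not records:
                raise ValueError(f"pair {pair} has no evidence records")
            self.pairs[pair] = records
        self.universe: frozenset[str] = frozenset(g for pair in self.pairs for g in pair)
        self._adjacency: dict[str, set[str]] | None = None

    def __len__(self) -> int:
        return len(self.pairs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Interactome):
            return NotImplemented
        if set(self.pairs) != set(other.pairs):
            return False
        key = lambda e: (e.source, e.provenance)
        return all(
            sorted(self.pairs[p], key=key) == sorted(other.pairs[p], key=key)
            for p in self.pairs
        )

    @property
    def adjacency(self) -> dict[str, set[str]]:
        if self._adjacency is None:
            adj: dict[str, set[str]] = {g: set() for g in self.universe}
            for a, b in self.pairs:
                adj[a].add(b)
                adj[b].add(a)
            self._adjacency = adj
        return self._adjacency

    def neighbors(self, gene: str) -> set[str]:
        return self.adjacency.get(gene, set())

    def evidence_count(self, a: str, b: str) -> int:
        return len(self.pairs.get(canonical_pair(a, b), ()))

    def graph(self) -> nx.Graph:
        """The collapsed pair graph as a networkx Graph (n_evidence attribute)."""
        g = nx.Graph()
        g.add_nodes_from(sorted(self.universe))
        for (a, b), records in self.pairs.items():
            g.add_edge(a, b, n_evidence=len(records))
        return g

    def source_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for records in self.pairs.values():
            for rec in records:
                counts[rec.source] = counts.get(rec.source, 0) + 1
        return dict(sorted(counts.items()))


# ---------------------------------------------------------------------------
# per-source filters
# ---------------------------------------------------------------------------


def filter_ppi_high(
    ppi_edges: Iterable[RawEdge], calls: TissueExpressionCalls
) -> list[EvidenceEdge]:
    """Keep PPIs replicated by >=2 labs with both genes tissue-expressed."""
    kept: list[EvidenceEdge] = []
    n_dropped_expr = 0
    for edge in ppi_edges:
        if edge.lab_count is None:
            raise ValueError(f"PPI edge {edge.pair} lacks a lab count")
        if edge.lab_count < 2:
            continue
        if not (calls.is_expressed(edge.pair[0]) and calls.is_expressed(edge.pair[1])):
            n_dropped_expr += 1
            continue
        kept.append(
            EvidenceEdge(
                pair=edge.pair,
                source="PPIhigh",
                provenance=f"labs={edge.lab_count}",
                lab_count=edge.lab_count,
            )
        )
    if n_dropped_expr:
        logger.info("PPIhigh: dropped %d replicated edges failing tissue expression", n_dropped_expr)
    return kept


def derive_ppicorr(
    single_lab_edges: Iterable[RawEdge],
    coexpr_matrix: pd.DataFrame,
    calls: TissueExpressionCalls,
    corr_method: str = "pearson",
    alpha: float = 0.05,
) -> list[EvidenceEdge]:
    """Rescue single-lab PPIs by significant co-expression.

    ``coexpr_matrix`` is genes x samples (the reference co-expression compendium,
    e.g. a large liver panel).  The pairwise correlation of each candidate edge
    is tested and edges significant at Benjamini-Hochberg FDR < ``alpha``
    (either correlation sign) are kept, subject to the tissue-expression
    requirement on both genes.
    """
    if coexpr_matrix.shape[1] < 3:
        raise ValueError("insufficient samples for correlation")
    if corr_method not in {"pearson", "spearman"}:
        raise ValueError(f"unknown correlation method {corr_method!r}")
    corr_fn = stats.pearsonr if corr_method == "pearson" else stats.spearmanr

    candidates: list[RawEdge] = []
    n_unexpr = 0
    n_missing = 0
    for edge in single_lab_edges:
        if edge.lab_count != 1:
            raise ValueError(f"edge {edge.pair} has lab_count {edge.lab_count}, expected 1")
        a, b = edge.pair
        if not (calls.is_expressed(a) and calls.is_expressed(b)):
            n_unexpr += 1
            continue
        if a not in coexpr_matrix.index or b not in coexpr_matrix.index:
            n_missing += 1
            continue
        candidates.append(edge)
    if n_unexpr:
        logger.info("PPIcorr: dropped %d edges failing tissue expression", n_unexpr)
    if n_missing:
        logger.info("PPIcorr: dropped %d edges with genes absent from co-expression matrix", n_missing)
    if not candidates:
        return []

    rs, ps = [], []
    for edge in candidates:
        a, b = edge.pair
        r, p = corr_fn(coexpr_matrix.loc[a].to_numpy(), coexpr_matrix.loc[b].to_numpy())
        rs.append(float(r))
        ps.append(float(p))
    reject, _, _, _ = multipletests(ps, alpha=alpha, method="fdr_bh")
    return [
        EvidenceEdge(
            pair=edge.pair,
            source="PPIcorr",
            provenance=f"r={r:.4f}",
            lab_count=1,
            correlation=r,
        )
        for edge, r, keep in zip(candidates, rs, reject)
        if keep
    ]


def complex_edges(complex_memberships: Mapping[str, Iterable[str]]) -> list[EvidenceEdge]:
    """Clique-expand complex memberships: every within-complex pair is linked."""
    out: list[EvidenceEdge] = []
    for cid in sorted(complex_memberships):
        members = sorted(set(complex_memberships[cid]))
        if len(members) < 2:
            logger.warning("complex %s has <2 members; skipped", cid)
            continue
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                out.append(EvidenceEdge(pair=(a, b), source="COMPLEX", provenance=str(cid)))
    return out


def metabolic_adjacency(
    reactions: Sequence[Reaction],
    currency_metabolites: Iterable[str] = DEFAULT_CURRENCY_METABOLITES,
) -> list[EvidenceEdge]:
    """Link genes of reactions sharing a non-currency metabolite.

    Reaction direction is ignored (substrates and products pooled).  For each
    adjacent reaction pair every cross-reaction gene pair is emitted, with the
    shared metabolite recorded in the provenance.
    """
    currency = {m.upper() for m in currency_metabolites}
    usable = []
    for r in reactions:
        if not r.genes:
            logger.warning("reaction %s has no genes; skipped", r.reaction_id)
            continue
        usable.append((r, {m.upper() for m in r.metabolites} - currency))
    out: list[EvidenceEdge] = []
    for i, (r1, mets1) in enumerate(usable):
        for r2, mets2 in usable[i + 1 :]:
            shared = mets1 & mets2
            if not shared:
                continue
            via = min(shared)
            for g1 in sorted(r1.genes):
                for g2 in sorted(r2.genes):
                    if g1 == g2:
                        continue
                    out.append(
                        EvidenceEdge(
                            pair=canonical_pair(g1, g2),
                            source="MET_adj",
                            provenance=f"{r1.reaction_id}~{r2.reaction_id} via {via}",
                        )
                    )
    return out


def pathway_edges(pathway_relations: Iterable[tuple[str, str, str]]) -> list[EvidenceEdge]:
    """Undirected, per-pathway-deduplicated pathway co-membership links."""
    seen: set[tuple[tuple[str, str], str]] = set()
    out: list[EvidenceEdge] = []
    for a, b, pathway in pathway_relations:
        if a == b:
            logger.warning("pathway relation self-loop on %s; skipped", a)
            continue
        key = (canonical_pair(a, b), pathway)
        if key in seen:
            continue
        seen.add(key)
        out.append(EvidenceEdge(pair=key[0], source="PATH", provenance=pathway))
    return out


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def assemble(*evidence_lists: Iterable[EvidenceEdge]) -> Interactome:
    """Collapse all surviving evidence into one Interactome.

    Order-insensitive: per-pair evidence records are sorted canonically so
    permuting the input lists yields an identical object.
    """
    pairs: dict[tuple[str, str], list[EvidenceEdge]] = {}
    for records in evidence_lists:
        for rec in records:
            pairs.setdefault(rec.pair, []).append(rec)
    if not pairs:
        raise ValueError("empty interactome")
    for pair in pairs:
        pairs[pair].sort(key=lambda e: (e.source, e.provenance))
    interactome = Interactome(pairs)
    logger.info(
        "assembled interactome: %d genes, %d pairs, evidence by source %s",
        len(interactome.universe),
        len(interactome),
        interactome.source_counts(),
    )
    return interactome
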