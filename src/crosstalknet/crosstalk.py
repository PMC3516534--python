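"""Direct system-to-system links and internode (linker) gene extraction.

Given the assembled interactome and two parts lists A and B, the crosstalk
network consists of

* **direct links** — interactome pairs with one endpoint in each system, and
* **internodes** — genes outside both parts lists that are simultaneously
  connected to at least one gene of each system.

Internode records carry per-system partner sets, link counts (distinct
partners) and evidence counts (total evidence records on the connecting
edges); ranking is by total evidence, then total links, then symbol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from crosstalknet.interactome import Interactome
from crosstalknet.io_formats import PartsList, canonical_pair

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InternodeRecord:
    """A linker gene with its per-system partners and evidence tallies."""

    gene: str
    partners_A: frozenset[str]
    partners_B: frozenset[str]
    evid_A: int
    evid_B: int

    def __post_init__(self) -> None:
        if not self.partners_A or not self.partners_B:
            raise ValueError(f"{self.gene}: internode must link both systems")
        if self.evid_A < len(self.partners_A) or self.evid_B < len(self.partners_B):
            raise ValueError(f"{self.gene}: evidence count below link count")

    @property
    def links_A(self) -> int:
        return len(self.partners_A)

    @property
    def links_B(self) -> int:
        return len(self.partners_B)

    @property
    def total_links(self) -> int:
        return self.links_A + self.links_B

    @property
    def total_evid(self) -> int:
        return self.evid_A + self.evid_B


@dataclass(frozen=True)
class DirectLink:
    """An interactome pair with one endpoint in each system."""

    gene_A: str
    gene_B: str
    n_evidence: int
    sources: tuple[str, ...]


@dataclass
class CrosstalkNetwork:
    """Direct edges plus ranked internodes between two systems."""

    parts_A: PartsList
    parts_B: PartsList
    direct: list[DirectLink]
    internodes: list[InternodeRecord]
    source_contributions: dict[str, dict[str, int]]

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for link in self.direct:
            out.update({link.gene_A, link.gene_B})
        for rec in self.internodes:
            out.add(rec.gene)
            out.update(rec.partners_A)
            out.update(rec.partners_B)
        return out

    @property
    def n_interactions(self) -> int:
        """Direct pairs plus internode-system pairs (one per distinct partner)."""
        return len(self.direct) + sum(rec.total_links for rec in self.internodes)


def _rank_key(rec: InternodeRecord) -> tuple[int, int, str]:
    return (-rec.total_evid, -rec.total_links, rec.gene)


def find_direct_links(
    interactome: Interactome, A: PartsList, B: PartsList
) -> list[DirectLink]:
    """All interactome pairs with one member in A and one in B.

    Genes belonging to both parts lists count for either side, so an edge
    between two such genes is a direct link.
    """
    overlap = A.genes & B.genes
    if overlap:
        logger.warning("parts lists share %d genes: %s", len(overlap), sorted(overlap))
    out: list[DirectLink] = []
    for (x, y), records in interactome.pairs.items():
        if (x in A and y in B) or (y in A and x in B):
            a, b = (x, y) if x in A else (y, x)
            out.append(
                DirectLink(
                    gene_A=a,
                    gene_B=b,
                    n_evidence=len(records),
                    sources=tuple(sorted(r.source for r in records)),
                )
            )
    out.sort(key=lambda d: (d.gene_A, d.gene_B))
    return out


def find_internodes(
    interactome: Interactome, A: PartsList, B: PartsList
) -> list[InternodeRecord]:
    """Genes outside A and B connected to at least one gene of each system.

    Genes present in both parts lists are excluded from internode candidacy
    (they are system members, not linkers).
    """
    members = A.genes | B.genes
    records: list[InternodeRecord] = []
    for gene in sorted(interactome.universe - members):
        nbrs = interactome.neighbors(gene)
        partners_a = frozenset(nbrs & A.genes)
        partners_b = frozenset(nbrs & B.genes)
        if not partners_a or not partners_b:
            continue
        evid_a = sum(interactome.evidence_count(gene, p) for p in partners_a)
        evid_b = sum(interactome.evidence_count(gene, p) for p in partners_b)
        records.append(
            InternodeRecord(
                gene=gene,
                partners_A=partners_a,
                partners_B=partners_b,
                evid_A=evid_a,
                evid_B=evid_b,
            )
        )
    records.sort(key=_rank_key)
    return records


def summarize_from_partner_lists(
    partner_table: Iterable[tuple[str, Sequence[str], Sequence[str]]],
) -> list[InternodeRecord]:
    """Build records from explicit per-system partner lists.

    Each row is (gene, partners in system A, partners in system B), the
    layout of a published candidate table.  Duplicate partners within a cell
    are deduplicated with a warning; evidence counts default to the link
    counts (one record per partner) since the listing carries no multiplicity.
    """
    records: list[InternodeRecord] = []
    for gene, partners_a, partners_b in partner_table:
        pa, pb = list(partners_a), list(partners_b)
        set_a, set_b = frozenset(pa), frozenset(pb)
        if len(set_a) < len(pa) or len(set_b) < len(pb):
            logger.warning("%s: duplicate partners in listing; deduplicated", gene)
        records.append(
            InternodeRecord(
                gene=gene,
                partners_A=set_a,
                partners_B=set_b,
                evid_A=len(set_a),
                evid_B=len(set_b),
            )
        )
    records.sort(key=_rank_key)
    return records


def high_confidence_subset(
    records: Sequence[InternodeRecord], min_evid_A: int = 3, min_evid_B: int = 3
) -> list[InternodeRecord]:
    """Internodes with at least ``min_evid`` lines of evidence to each system."""
    return [r for r in records if r.evid_A >= min_evid_A and r.evid_B >= min_evid_B]


def system_connectivity(
    interactome: Interactome, A: PartsList, B: PartsList
) -> tuple[list[tuple[str, int]], list[tuple[str, int]]]:
    """Per-gene indirect-connection counts through internodes.

    For each gene a in A, counts the distinct (internode, b in B) pairs such
    that a-internode and internode-b are interactome edges (paths of length
    two through a linker), and symmetrically for B.  Returned sorted by count
    descending, then symbol.
    """
    internodes = find_internodes(interactome, A, B)
    counts_a: dict[str, int] = {}
    counts_b: dict[str, int] = {}
    for rec in internodes:
        for a in rec.partners_A:
            counts_a[a] = counts_a.get(a, 0) + len(rec.partners_B)
        for b in rec.partners_B:
            counts_b[b] = counts_b.get(b, 0) + len(rec.partners_A)
    order = lambda d: sorted(d.items(), key=lambda kv: (-kv[1], kv[0]))
    return order(counts_a), order(counts_b)


def build_crosstalk_network(
    interactome: Interactome, A: PartsList, B: PartsList
) -> CrosstalkNetwork:
    """Assemble direct links, internodes and per-source contribution tallies."""
    direct = find_direct_links(interactome, A, B)
    internodes = find_internodes(interactome, A, B)
    direct_sources: dict[str, int] = {}
    for link in direct:
        for s in link.sources:
            direct_sources[s] = direct_sources.get(s, 0) + 1
    indirect_sources: dict[str, int] = {}
    for rec in internodes:
        for partner in rec.partners_A | rec.partners_B:
            for ev in interactome.pairs[canonical_pair(rec.gene, partner)]:
                indirect_sources[ev.source] = indirect_sources.get(ev.source, 0) + 1
    return CrosstalkNetwork(
        parts_A=A,
        parts_B=B,
        direct=direct,
        internodes=internodes,
        source_contributions={
            "direct": dict(sorted(direct_sources.items())),
            "indirect": dict(sorted(indirect_sources.items())),
        },
    )


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def internodes_to_frame(records: Sequence[InternodeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "total_links": r.total_links,
                "total_evid": r.total_evid,
                "links_A": r.links_A,
                "evid_A": r.evid_A,
                "links_B": r.links_B,
                "evid_B": r.evid_B,
                "partners_A": " | ".join(sorted(r.partners_A)),
                "partners_B": " | ".join(sorted(r.partners_B)),
            }
            for r in records
        ],
        columns=[
            "gene", "total_links", "total_evid", "links_A", "evid_A",
            "links_B", "evid_B", "partners_A", "partners_B",
        ],
    )


def export_network(
    network: CrosstalkNetwork, interactome: Interactome, out_dir: str | Path
) -> dict[str, Path]:
    """Write node and edge tables importable by graph viewers, plus summaries.

    The node table assigns each gene a role (A, B, A+B or internode); the
    edge table lists every crosstalk edge with its ';'-joined sources and
    evidence count.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    internode_genes = {r.gene for r in network.internodes}

    def role(gene: str) -> str:
        in_a, in_b = gene in network.parts_A, gene in network.parts_B
        if in_a and in_b:
            return "A+B"
        if in_a:
            return "A"
        if in_b:
            return "B"
        return "internode"

    node_genes = sorted(
        (network.parts_A.genes | network.parts_B.genes) & interactome.universe
        | internode_genes
    )
    nodes = pd.DataFrame({"gene": node_genes, "role": [role(g) for g in node_genes]})

    edge_rows = []
    for link in network.direct:
        edge_rows.append(
            {
                "geneA": link.gene_A,
                "geneB": link.gene_B,
                "kind": "direct",
                "sources": ";".join(link.sources),
                "n_evidence": link.n_evidence,
            }
        )
    for rec in network.internodes:
        for partner in sorted(rec.partners_A | rec.partners_B):
            records = interactome.pairs[canonical_pair(rec.gene, partner)]
            edge_rows.append(
                {
                    "geneA": rec.gene,
                    "geneB": partner,
                    "kind": "indirect",
                    "sources": ";".join(sorted(r.source for r in records)),
                    "n_evidence": len(records),
                }
            )
    edges = pd.DataFrame(
        edge_rows, columns=["geneA", "geneB", "kind", "sources", "n_evidence"]
    )

    paths = {
        "nodes": out / "nodes.tsv",
        "edges": out / "edges.tsv",
        "internodes": out / "internodes.tsv",
        "direct": out / "direct.tsv",
    }
    nodes.to_csv(paths["nodes"], sep="\t", index=False)
    edges.to_csv(paths["edges"], sep="\t", index=False)
    internodes_to_frame(network.internodes).to_csv(paths["internodes"], sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "gene_A": d.gene_A,
                "gene_B": d.gene_B,
                "n_evidence": d.n_evidence,
                "sources": ";".join(d.sources),
            }
            for d in network.direct
        ],
        columns=["gene_A", "gene_B", "n_evidence", "sources"],
    ).to_csv(paths["direct"], sep="\t", index=False)
    return paths
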