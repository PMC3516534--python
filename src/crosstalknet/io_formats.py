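"""Readers and writers for the tabular formats the pipeline consumes.

All gene identifiers are plain uppercase symbols; no identifier mapping is
performed.  Undirected gene pairs are canonicalized lexicographically at read
time.  The gene-annotation reader supports two coordinate dialects which must
be declared explicitly (``tsv``: 1-based inclusive; ``bed``: 0-based
half-open) — dialects are never sniffed, because a silent off-by-one is the
classic failure mode of genomic interval code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RAW_EDGE_SOURCES = frozenset({"PPI", "COMPLEX", "MET", "PATH"})


class FormatError(ValueError):
    """Raised when an input file violates the declared format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PartsList:
    """A named biological system given as a set of gene symbols."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"parts list {self.name!r} is empty")
        for g in self.genes:
            if not g or not isinstance(g, str):
                raise ValueError(f"parts list {self.name!r} contains a blank symbol")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


@dataclass(frozen=True)
class GeneAnnotation:
    """Genomic extent of one gene, 1-based inclusive coordinates."""

    gene: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start <= 0 or self.end <= 0:
            raise ValueError(f"{self.gene}: coordinates must be positive")
        if self.start > self.end:
            raise ValueError(f"{self.gene}: start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SummaryStatRecord:
    """One SNP row of a GWAS summary-statistics file."""

    snp: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    p: float

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"{self.snp}: se must be > 0, got {self.se}")
        if not (0 < self.p <= 1):
            raise ValueError(f"{self.snp}: p must be in (0, 1], got {self.p}")


@dataclass
class ExpressionMatrix:
    """Normalized (log-scale) expression values with a binary condition label.

    ``values`` is a genes x samples DataFrame; ``condition`` maps each sample
    to one of exactly two levels.
    """

    values: pd.DataFrame
    condition: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.hasnans or self.values.columns.hasnans:
            raise ValueError("expression matrix has missing row/column labels")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene labels in expression matrix")
        missing = set(self.values.columns) - set(self.condition.index)
        if missing:
            raise ValueError(f"samples without condition label: {sorted(missing)}")
        self.condition = self.condition.loc[list(self.values.columns)]

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def groups(self) -> tuple[object, object]:
        """The two condition levels, sorted for determinism (reference first)."""
        levels = sorted(map(str, set(self.condition)))
        if len(levels) != 2:
            raise ValueError(f"expected exactly 2 condition levels, got {levels}")
        return levels[0], levels[1]


@dataclass(frozen=True)
class RawEdge:
    """One evidence row as read from disk, before any filtering.

    ``lab_count`` is populated for PPI rows only (number of independent
    laboratories reporting the interaction).
    """

    pair: tuple[str, str]
    source: str
    provenance: str
    lab_count: int | None = None


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Lexicographically ordered undirected pair."""
    return (a, b) if a <= b else (b, a)


# ---------------------------------------------------------------------------
# parts lists
# ---------------------------------------------------------------------------


def read_parts_list(path: str | Path, name: str) -> PartsList:
    """Read a one-symbol-per-line gene list ('#' starts a comment line)."""
    genes: set[str] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if line.startswith("#"):
            continue
        sym = line.strip()
        if not sym:
            if line:  # whitespace-only payload
                raise FormatError(f"{path}:{lineno}: blank symbol")
            continue
        genes.add(sym.upper())
    if not genes:
        raise FormatError(f"{path}: empty parts list")
    return PartsList(name=name, genes=frozenset(genes))


def write_parts_list(parts: PartsList, path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(parts.genes)) + "\n")


# ---------------------------------------------------------------------------
# GMT gene-set collections
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read an MSigDB-dialect GMT file: name TAB description TAB gene...

    Returns an insertion-ordered mapping set name -> deduplicated symbols.
    """
    sets: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line has <3 tab-separated fields")
        name = fields[0]
        sets[name] = {g.strip().upper() for g in fields[2:] if g.strip()}
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *sorted(set(genes))]) + "\n")


# ---------------------------------------------------------------------------
# edge evidence
# ---------------------------------------------------------------------------


def read_edge_evidence(path: str | Path) -> list[RawEdge]:
    """Read a TSV of raw evidence rows: geneA, geneB, source, provenance.

    Source must be one of PPI/COMPLEX/MET/PATH; for PPI rows the provenance
    field is an integer lab count.  Self-loops are dropped with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"geneA", "geneB", "source", "provenance"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    edges: list[RawEdge] = []
    n_self = 0
    for row in df.itertuples(index=False):
        a, b = str(row.geneA).upper(), str(row.geneB).upper()
        source = str(row.source)
        if source not in RAW_EDGE_SOURCES:
            raise FormatError(f"{path}: unknown source tag {source!r}")
        if a == b:
            n_self += 1
            continue
        lab_count = None
        if source == "PPI":
            try:
                lab_count = int(str(row.provenance))
            except ValueError:
                raise FormatError(
                    f"{path}: non-integer lab count {row.provenance!r} for PPI edge {a}-{b}"
                ) from None
        edges.append(
            RawEdge(
                pair=canonical_pair(a, b),
                source=source,
                provenance=str(row.provenance),
                lab_count=lab_count,
            )
        )
    if n_self:
        logger.warning("%s: dropped %d self-loop edges", path, n_self)
    return edges


def write_edge_evidence(edges: Sequence[RawEdge], path: str | Path) -> None:
    rows = [
        {
            "geneA": e.pair[0],
            "geneB": e.pair[1],
            "source": e.source,
            "provenance": e.provenance,
        }
        for e in edges
    ]
    pd.DataFrame(rows, columns=["geneA", "geneB", "source", "provenance"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

_SUMSTAT_COLS = ["snp", "chr", "pos", "a1", "a2", "beta", "se", "p"]


def read_sumstats(path: str | Path) -> list[SummaryStatRecord]:
    """Read GWAS summary statistics (TSV, header: snp chr pos a1 a2 beta se p)."""
    df = pd.read_csv(path, sep="\t", dtype={"snp": str, "chr": str}, float_precision="round_trip")
    missing = set(_SUMSTAT_COLS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    records: list[SummaryStatRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.snp in seen:
            raise FormatError(f"{path}: row {i}: duplicate SNP id {row.snp!r}")
        seen.add(row.snp)
        try:
            records.append(
                SummaryStatRecord(
                    snp=row.snp,
                    chrom=str(row.chr),
                    pos=int(row.pos),
                    effect_allele=str(row.a1),
                    other_allele=str(row.a2),
                    beta=float(row.beta),
                    se=float(row.se),
                    p=float(row.p),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: row {i}: {exc}") from None
    return records


def write_sumstats(records: Sequence[SummaryStatRecord], path: str | Path) -> None:
    rows = [
        {
            "snp": r.snp,
            "chr": r.chrom,
            "pos": r.pos,
            "a1": r.effect_allele,
            "a2": r.other_allele,
            "beta": repr(r.beta),
            "se": repr(r.se),
            "p": repr(r.p),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_SUMSTAT_COLS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------


def read_gene_annotation(path: str | Path, dialect: str) -> list[GeneAnnotation]:
    """Read gene coordinates; ``dialect`` is 'tsv' (1-based inclusive) or 'bed'.

    BED intervals (0-based half-open) are converted to 1-based inclusive
    (start+1, end unchanged).  The dialect is never guessed from content.
    """
    if dialect not in {"tsv", "bed"}:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    if dialect == "bed":
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            names=["chrom", "start", "end", "gene", "score", "strand"],
            usecols=[0, 1, 2, 3, 4, 5],
        )
        df["start"] = df["start"].astype(int) + 1
    else:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, comment="#")
        missing = {"gene", "chrom", "start", "end"} - set(df.columns)
        if missing:
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
    annotations: list[GeneAnnotation] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        gene = str(row.gene).upper()
        if gene in seen:
            raise FormatError(f"{path}: row {i}: duplicate gene {gene!r}")
        seen.add(gene)
        strand = getattr(row, "strand", ".")
        if pd.isna(strand) or strand not in {"+", "-"}:
            strand = "."
        try:
            annotations.append(
                GeneAnnotation(
                    gene=gene,
                    chrom=str(row.chrom),
                    start=int(row.start),
                    end=int(row.end),
                    strand=strand,
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: row {i}: {exc}") from None
    return annotations


def write_gene_annotation(annotations: Sequence[GeneAnnotation], path: str | Path) -> None:
    """Write annotations in the 1-based inclusive TSV dialect."""
    rows = [
        {"gene": a.gene, "chrom": a.chrom, "start": a.start, "end": a.end, "strand": a.strand}
        for a in annotations
    ]
    pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "strand"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def read_expression(path: str | Path, labels: str | Path | Mapping[str, str]) -> ExpressionMatrix:
    """Read a genes x samples TSV plus a sample->condition assignment.

    ``labels`` is either a mapping or the path of a two-column TSV
    (sample, condition) without header requirements beyond those two columns.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str).str.upper()
    if isinstance(labels, (str, Path)):
        lab_df = pd.read_csv(labels, sep="\t", dtype=str)
        if lab_df.shape[1] < 2:
            raise FormatError(f"{labels}: expected two columns (sample, condition)")
        condition = pd.Series(
            lab_df.iloc[:, 1].values, index=lab_df.iloc[:, 0].values, name="condition"
        )
    else:
        condition = pd.Series(dict(labels), name="condition")
    return ExpressionMatrix(values=values.astype(float), condition=condition.astype(str))


def write_expression(expr: ExpressionMatrix, path: str | Path, labels_path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene")
    pd.DataFrame(
        {"sample": expr.samples, "condition": [expr.condition[s] for s in expr.samples]}
    ).to_csv(labels_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# auxiliary tables used by the assembly stage
# ---------------------------------------------------------------------------


def read_tissue_calls(
    path: str | Path, tissues: Sequence[str] = ("adipose", "muscle", "liver", "heart")
) -> dict[str, dict[str, bool]]:
    """Read boolean tissue-expression calls (gene + one 0/1 column per tissue)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    missing = set(tissues) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing tissue columns {sorted(missing)}")
    calls: dict[str, dict[str, bool]] = {}
    for row in df.itertuples(index=False):
        calls[str(row.gene).upper()] = {t: bool(int(getattr(row, t))) for t in tissues}
    return calls


def write_tissue_calls(
    calls: Mapping[str, Mapping[str, bool]],
    path: str | Path,
    tissues: Sequence[str] = ("adipose", "muscle", "liver", "heart"),
) -> None:
    rows = [
        {"gene": g, **{t: int(bool(v.get(t, False))) for t in tissues}}
        for g, v in sorted(calls.items())
    ]
    pd.DataFrame(rows, columns=["gene", *tissues]).to_csv(path, sep="\t", index=False)


def read_complexes(path: str | Path) -> dict[str, set[str]]:
    """Read complex memberships (TSV: complex_id, gene)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"complex_id", "gene"}.issubset(df.columns):
        raise FormatError(f"{path}: expected columns complex_id, gene")
    out: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.complex_id), set()).add(str(row.gene).upper())
    return out


def write_complexes(memberships: Mapping[str, Iterable[str]], path: str | Path) -> None:
    rows = [
        {"complex_id": cid, "gene": g}
        for cid, genes in memberships.items()
        for g in sorted(set(genes))
    ]
    pd.DataFrame(rows, columns=["complex_id", "gene"]).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class Reaction:
    """One metabolic reaction: substrates/products and catalyzing genes."""

    reaction_id: str
    substrates: frozenset[str]
    products: frozenset[str]
    genes: frozenset[str]

    @property
    def metabolites(self) -> frozenset[str]:
        return self.substrates | self.products


def read_reactions(path: str | Path) -> list[Reaction]:
    """Read a reaction table (TSV: reaction_id, substrates, products, genes; ';'-joined)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"reaction_id", "substrates", "products", "genes"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(required - set(df.columns))}")

    def split(cell: str) -> frozenset[str]:
        return frozenset(x.strip() for x in str(cell).split(";") if x.strip())

    return [
        Reaction(
            reaction_id=str(row.reaction_id),
            substrates=split(row.substrates),
            products=split(row.products),
            genes=frozenset(g.upper() for g in split(row.genes)),
        )
        for row in df.itertuples(index=False)
    ]


def write_reactions(reactions: Sequence[Reaction], path: str | Path) -> None:
    rows = [
        {
            "reaction_id": r.reaction_id,
            "substrates": ";".join(sorted(r.substrates)),
            "products": ";".join(sorted(r.products)),
            "genes": ";".join(sorted(r.genes)),
        }
        for r in reactions
    ]
    pd.DataFrame(rows, columns=["reaction_id", "substrates", "products", "genes"]).to_csv(
        path, sep="\t", index=False
    )


def read_pathway_relations(path: str | Path) -> list[tuple[str, str, str]]:
    """Read pathway relations (TSV: geneA, geneB, pathway_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"geneA", "geneB", "pathway_id"}.issubset(df.columns):
        raise FormatError(f"{path}: expected columns geneA, geneB, pathway_id")
    return [
        (str(r.geneA).upper(), str(r.geneB).upper(), str(r.pathway_id))
        for r in df.itertuples(index=False)
    ]


def write_pathway_relations(relations: Sequence[tuple[str, str, str]], path: str | Path) -> None:
    rows = [{"geneA": a, "geneB": b, "pathway_id": p} for a, b, p in relations]
    pd.DataFrame(rows, columns=["geneA", "geneB", "pathway_id"]).to_csv(path, sep="\t", index=False)


def read_catalog_snps(path: str | Path) -> pd.DataFrame:
    """Read a trait-association catalog (TSV: snp, chrom, pos, trait)."""
    df = pd.read_csv(path, sep="\t", dtype={"snp": str, "chrom": str, "trait": str})
    if not {"snp", "chrom", "pos", "trait"}.issubset(df.columns):
        raise FormatError(f"{path}: expected columns snp, chrom, pos, trait")
    df["pos"] = df["pos"].astype(int)
    return df
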