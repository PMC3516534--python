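"""Synthetic inputs with planted structure for every pipeline stage.

Three generators emulate the statistical shape of the pipeline's real-world
inputs without any external download:

* :func:`gen_interactome` — multi-source edge evidence over two gene systems
  with planted internode (linker) genes and background genes confined to one
  system, plus the tissue calls and co-expression matrix the assembly filters
  need.  Every generated truth (which genes are internodes, how many links
  and evidence records each has per side) is recorded in a ledger.
* :func:`gen_expression` — a two-condition expression matrix with planted
  differential gene sets shifted by a chosen number of noise standard
  deviations.
* :func:`gen_sumstats` — linkage-equilibrium GWAS summary statistics from an
  explicit individual-level simulation (genotypes ~ Binomial(2, maf),
  phenotype = sum of true effects + standard normal noise, per-SNP marginal
  least squares), with a gene annotation laid out so every SNP's gene
  assignment at the mapping windows is known.

All generators are pure functions of their seed and parameters.  The bundled
candidate-table fixture (31 published internode records) is exposed by
:func:`table1_fixture`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from crosstalknet import io_formats
from crosstalknet.crosstalk import InternodeRecord
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
from crosstalknet.io_formats import (
    ExpressionMatrix,
    GeneAnnotation,
    PartsList,
    RawEdge,
    Reaction,
    SummaryStatRecord,
    canonical_pair,
)

EVIDENCE_SOURCE_CHOICES = ("PPIhigh", "PPIcorr", "COMPLEX", "MET_adj", "PATH")


@dataclass(frozen=True)
class EvidenceProfile:
    """How much and what kind of evidence planted internode edges receive."""

    links_per_side: tuple[int, int] = (1, 3)  # inclusive range of partners per system
    evidence_per_edge: tuple[int, int] = (1, 2)  # evidence records per edge
    sources: tuple[str, ...] = EVIDENCE_SOURCE_CHOICES

    def __post_init__(self) -> None:
        if self.links_per_side[0] < 1 or self.links_per_side[0] > self.links_per_side[1]:
            raise ValueError("inconsistent links_per_side range")
        if self.evidence_per_edge[0] < 1 or self.evidence_per_edge[0] > self.evidence_per_edge[1]:
            raise ValueError("inconsistent evidence_per_edge range")
        unknown = set(self.sources) - set(EVIDENCE_SOURCE_CHOICES)
        if unknown:
            raise ValueError(f"unknown evidence sources {sorted(unknown)}")


@dataclass
class SyntheticInteractome:
    """Generated assembly inputs plus the ground-truth ledger."""

    parts_A: PartsList
    parts_B: PartsList
    ppi_edges: list[RawEdge]
    complexes: dict[str, set[str]]
    reactions: list[Reaction]
    pathway_relations: list[tuple[str, str, str]]
    tissue_calls: TissueExpressionCalls
    coexpr: pd.DataFrame
    ledger: dict

    def build_interactome(self, corr_alpha: float = 0.05) -> Interactome:
        """Run the assembly filters on the generated inputs."""
        high = [e for e in self.ppi_edges if e.lab_count is not None and e.lab_count >= 2]
        single = [e for e in self.ppi_edges if e.lab_count == 1]
        return assemble(
            filter_ppi_high(high, self.tissue_calls),
            derive_ppicorr(single, self.coexpr, self.tissue_calls, alpha=corr_alpha),
            complex_edges(self.complexes),
            metabolic_adjacency(self.reactions),
            pathway_edges(self.pathway_relations),
        )

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "parts_a": out / "parts_a.txt",
            "parts_b": out / "parts_b.txt",
            "ppi": out / "ppi.tsv",
            "complexes": out / "complexes.tsv",
            "reactions": out / "reactions.tsv",
            "pathways": out / "pathways.tsv",
            "tissue_calls": out / "tissue_calls.tsv",
            "coexpr": out / "coexpr.tsv",
            "ledger": out / "ledger.yaml",
        }
        io_formats.write_parts_list(self.parts_A, paths["parts_a"])
        io_formats.write_parts_list(self.parts_B, paths["parts_b"])
        io_formats.write_edge_evidence(self.ppi_edges, paths["ppi"])
        io_formats.write_complexes(self.complexes, paths["complexes"])
        io_formats.write_reactions(self.reactions, paths["reactions"])
        io_formats.write_pathway_relations(self.pathway_relations, paths["pathways"])
        io_formats.write_tissue_calls(self.tissue_calls.calls, paths["tissue_calls"])
        self.coexpr.to_csv(paths["coexpr"], sep="\t", index_label="gene")
        paths["ledger"].write_text(yaml.safe_dump(self.ledger, sort_keys=True))
        return paths


def gen_interactome(
    n_A: int = 20,
    n_B: int = 30,
    n_internodes: int = 8,
    n_background: int = 40,
    evidence_profile: EvidenceProfile | None = None,
    seed: int = 0,
    n_direct: int = 5,
    n_coexpr_samples: int = 60,
) -> SyntheticInteractome:
    """Two systems, planted internodes, and one-system background genes.

    Every planted internode gets >=1 edge to each system with evidence drawn
    from ``evidence_profile``.  Background genes receive edges to at most one
    system, so the planted internode set is exactly the set of linker genes
    recoverable by the pipeline.  Direct system-to-system edges are added as
    replicated PPIs.
    """
    if min(n_A, n_B, n_internodes + 1, n_background) < 1:
        raise ValueError("all counts must be >= 1 (n_internodes may be 0)")
    profile = evidence_profile or EvidenceProfile()
    rng = np.random.default_rng(seed)

    genes_a = [f"INS{i:03d}" for i in range(n_A)]
    genes_b = [f"MIT{i:03d}" for i in range(n_B)]
    linkers = [f"LNK{i:03d}" for i in range(n_internodes)]
    background = [f"BG{i:03d}" for i in range(n_background)]

    ppi_edges: list[RawEdge] = []
    complexes: dict[str, set[str]] = {}
    reactions: list[Reaction] = []
    relations: list[tuple[str, str, str]] = []
    corr_pairs: list[tuple[str, str]] = []
    counters = {"complex": 0, "reaction": 0, "pathway": 0, "metabolite": 0}

    def add_evidence(gene: str, partner: str, source: str) -> None:
        pair = canonical_pair(gene, partner)
        if source == "PPIhigh":
            ppi_edges.append(
                RawEdge(pair=pair, source="PPI", provenance="2", lab_count=2)
            )
        elif source == "PPIcorr":
            ppi_edges.append(
                RawEdge(pair=pair, source="PPI", provenance="1", lab_count=1)
            )
            corr_pairs.append(pair)
        elif source == "COMPLEX":
            counters["complex"] += 1
            complexes[f"CPX{counters['complex']:04d}"] = {gene, partner}
        elif source == "MET_adj":
            counters["metabolite"] += 1
            met = f"MET{counters['metabolite']:04d}"
            for g, suffix in ((gene, "a"), (partner, "b")):
                counters["reaction"] += 1
                reactions.append(
                    Reaction(
                        reaction_id=f"R{counters['reaction']:04d}{suffix}",
                        substrates=frozenset({met}),
                        products=frozenset({f"X{counters['reaction']:04d}"}),
                        genes=frozenset({g}),
                    )
                )
        elif source == "PATH":
            counters["pathway"] += 1
            relations.append((gene, partner, f"PATH{counters['pathway']:04d}"))
        else:  # pragma: no cover
            raise ValueError(source)

    def edge_sources(n_ev: int) -> list[str]:
        # PPI sources at most once per edge; extra records become complexes
        picks = list(rng.choice(profile.sources, size=n_ev, replace=True))
        seen_ppi: set[str] = set()
        fixed = []
        for s in picks:
            if s in {"PPIhigh", "PPIcorr"}:
                if s in seen_ppi:
                    s = "COMPLEX"
                else:
                    seen_ppi.add(s)
            fixed.append(s)
        return fixed

    truth: dict[str, dict[str, int]] = {}
    for linker in linkers:
        record = {}
        for side, pool in (("A", genes_a), ("B", genes_b)):
            lo, hi = profile.links_per_side
            n_links = int(rng.integers(lo, min(hi, len(pool)) + 1))
            partners = rng.choice(pool, size=n_links, replace=False)
            n_evid = 0
            for partner in partners:
                n_ev = int(rng.integers(profile.evidence_per_edge[0], profile.evidence_per_edge[1] + 1))
                for source in edge_sources(n_ev):
                    add_evidence(linker, str(partner), source)
                n_evid += n_ev
            record[f"links_{side}"] = n_links
            record[f"evid_{side}"] = n_evid
            record[f"partners_{side}"] = sorted(str(p) for p in partners)
        truth[linker] = record

    # background genes: edges to exactly one system, deterministic sources
    for gene in background:
        pool = genes_a if rng.random() < 0.5 else genes_b
        n_links = int(rng.integers(1, 3))
        partners = rng.choice(pool, size=min(n_links, len(pool)), replace=False)
        for partner in partners:
            source = str(rng.choice(["PPIhigh", "COMPLEX", "PATH"]))
            add_evidence(gene, str(partner), source)
        # exercise the PPIcorr rejection path: an uncorrelated single-lab PPI
        if rng.random() < 0.3:
            partner = str(rng.choice(pool))
            if partner != gene:
                ppi_edges.append(
                    RawEdge(pair=canonical_pair(gene, partner), source="PPI",
                            provenance="1", lab_count=1)
                )

    direct_pairs: list[tuple[str, str]] = []
    if n_direct:
        for _ in range(n_direct):
            a = str(rng.choice(genes_a))
            b = str(rng.choice(genes_b))
            pair = canonical_pair(a, b)
            if pair in direct_pairs:
                continue
            direct_pairs.append(pair)
            ppi_edges.append(RawEdge(pair=pair, source="PPI", provenance="2", lab_count=2))

    all_genes = sorted(set(genes_a) | set(genes_b) | set(linkers) | set(background))
    calls = TissueExpressionCalls(
        calls={g: {"adipose": False, "muscle": False, "liver": True, "heart": False} for g in all_genes}
    )

    # co-expression: shared latent factor per correlated component
    parent: dict[str, str] = {}

    def find(g: str) -> str:
        parent.setdefault(g, g)
        while parent[g] != g:
            parent[g] = parent[parent[g]]
            g = parent[g]
        return g

    for a, b in corr_pairs:
        parent[find(a)] = find(b)
    coexpr = pd.DataFrame(
        rng.normal(size=(len(all_genes), n_coexpr_samples)),
        index=all_genes,
        columns=[f"S{i:02d}" for i in range(n_coexpr_samples)],
    )
    components: dict[str, list[str]] = {}
    for g in parent:
        components.setdefault(find(g), []).append(g)
    for root, members in components.items():
        latent = rng.normal(size=n_coexpr_samples)
        for g in members:
            coexpr.loc[g] = latent + 0.15 * rng.normal(size=n_coexpr_samples)

    ledger = {
        "seed": int(seed),
        "n_A": n_A,
        "n_B": n_B,
        "n_internodes": n_internodes,
        "n_background": n_background,
        "n_direct_planted": len(direct_pairs),
        "profile": {
            "links_per_side": list(profile.links_per_side),
            "evidence_per_edge": list(profile.evidence_per_edge),
            "sources": list(profile.sources),
        },
        "internodes": sorted(linkers),
        "truth": truth,
        "direct_pairs": [list(p) for p in sorted(direct_pairs)],
    }
    return SyntheticInteractome(
        parts_A=PartsList(name="systemA", genes=frozenset(genes_a)),
        parts_B=PartsList(name="systemB", genes=frozenset(genes_b)),
        ppi_edges=ppi_edges,
        complexes=complexes,
        reactions=reactions,
        pathway_relations=relations,
        tissue_calls=calls,
        coexpr=coexpr,
        ledger=ledger,
    )


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


@dataclass
class SyntheticExpression:
    expr: ExpressionMatrix
    signal_sets: dict[str, set[str]]
    ledger: dict

    def write(self, expr_path: str | Path, labels_path: str | Path) -> None:
        io_formats.write_expression(self.expr, expr_path, labels_path)


def gen_expression(
    n_genes: int = 2000,
    n_per_group: int = 10,
    signal_sets: Mapping[str, tuple[int | Iterable[str], float]] | None = None,
    seed: int = 0,
) -> SyntheticExpression:
    """Two-condition expression with planted differential gene sets.

    ``signal_sets`` maps a set name to (genes or a set size to sample, shift
    in noise-sd units applied to condition '1').  Overlapping sets whose
    shifts disagree in sign are rejected: a gene cannot be planted both up-
    and downregulated.
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    samples = [f"C0_{i:02d}" for i in range(n_per_group)] + [
        f"C1_{i:02d}" for i in range(n_per_group)
    ]
    condition = pd.Series(
        ["0"] * n_per_group + ["1"] * n_per_group, index=samples, name="condition"
    )
    values = pd.DataFrame(
        rng.normal(size=(n_genes, 2 * n_per_group)), index=genes, columns=samples
    )

    resolved: dict[str, set[str]] = {}
    shifts: dict[str, float] = {}
    gene_sign: dict[str, float] = {}
    for name, (members, effect) in (signal_sets or {}).items():
        if isinstance(members, int):
            chosen = set(rng.choice(genes, size=members, replace=False).tolist())
        else:
            chosen = set(members)
            unknown = chosen - set(genes)
            if unknown:
                raise ValueError(f"signal set {name!r} references unknown genes {sorted(unknown)[:5]}")
        for g in chosen:
            sign = np.sign(effect)
            if g in gene_sign and sign and gene_sign[g] and sign != gene_sign[g]:
                raise ValueError(f"gene {g} planted with conflicting shift signs")
            gene_sign[g] = sign or gene_sign.get(g, 0.0)
        resolved[name] = chosen
        shifts[name] = float(effect)
        cond1 = [s for s in samples if s.startswith("C1")]
        values.loc[sorted(chosen), cond1] += effect

    expr = ExpressionMatrix(values=values, condition=condition)
    ledger = {
        "seed": int(seed),
        "n_genes": n_genes,
        "n_per_group": n_per_group,
        "signal_sets": {k: sorted(v) for k, v in resolved.items()},
        "effects": shifts,
    }
    return SyntheticExpression(expr=expr, signal_sets=resolved, ledger=ledger)


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------


@dataclass
class SyntheticGwas:
    sumstats: list[SummaryStatRecord]
    annotation: list[GeneAnnotation]
    genotypes: np.ndarray  # individuals x SNPs
    phenotype: np.ndarray
    ledger: dict

    def write(self, sumstats_path: str | Path, annotation_path: str | Path) -> None:
        io_formats.write_sumstats(self.sumstats, sumstats_path)
        io_formats.write_gene_annotation(self.annotation, annotation_path)


def marginal_sumstats(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    snp_ids: Sequence[str],
    chroms: Sequence[str],
    positions: Sequence[int],
) -> list[SummaryStatRecord]:
    """Per-SNP marginal least-squares summary statistics (beta, se, p)."""
    from scipy import stats as sps

    n = len(phenotype)
    g = genotypes.astype(float)
    y = phenotype.astype(float)
    gc = g - g.mean(axis=0)
    yc = y - y.mean()
    var_g = (gc**2).sum(axis=0)
    var_g = np.where(var_g == 0, np.nan, var_g)
    beta = gc.T @ yc / var_g
    resid_ss = (yc**2).sum() - beta**2 * var_g
    sigma2 = resid_ss / (n - 2)
    se = np.sqrt(sigma2 / var_g)
    tstat = beta / se
    p = 2 * sps.t.sf(np.abs(tstat), df=n - 2)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    records = []
    for j, snp in enumerate(snp_ids):
        if not np.isfinite(beta[j]):
            continue  # monomorphic SNP
        records.append(
            SummaryStatRecord(
                snp=snp,
                chrom=str(chroms[j]),
                pos=int(positions[j]),
                effect_allele="A",
                other_allele="G",
                beta=float(beta[j]),
                se=float(se[j]),
                p=float(p[j]),
            )
        )
    return records


def gen_sumstats(
    n_genes: int = 40,
    snps_per_gene: int = 10,
    true_effects: Mapping[str, float] | None = None,
    n_individuals: int = 2000,
    maf_range: tuple[float, float] = (0.1, 0.5),
    seed: int = 0,
    gene_length: int = 20_000,
    gene_spacing: int = 2_200_000,
    snp_flank: int = 100_000,
) -> SyntheticGwas:
    """Linkage-equilibrium GWAS simulation with a known SNP-to-gene layout.

    Genes sit on one chromosome, ``gene_spacing`` bp apart (wide enough that
    each SNP falls in exactly one gene's 500 kb mapping window); each gene's
    SNPs lie within ``snp_flank`` of its body.  ``true_effects`` maps SNP ids
    ('GENE000_SNP00', ...) or gene ids ('GENE000', applied to the gene's
    first SNP) to per-allele effects in phenotype-sd units.
    """
    if n_individuals < 50:
        raise ValueError("n_individuals must be >= 50 for stable se estimates")
    rng = np.random.default_rng(seed)
    annotation: list[GeneAnnotation] = []
    snp_ids: list[str] = []
    positions: list[int] = []
    snp_gene: dict[str, str] = {}
    for i in range(n_genes):
        gene = f"GENE{i:03d}"
        start = 1 + snp_flank + i * gene_spacing
        annotation.append(
            GeneAnnotation(gene=gene, chrom="1", start=start, end=start + gene_length - 1)
        )
        offsets = np.sort(
            rng.integers(-snp_flank, gene_length + snp_flank, size=snps_per_gene)
        )
        for j, off in enumerate(offsets):
            snp = f"{gene}_SNP{j:02d}"
            snp_ids.append(snp)
            positions.append(int(start + off))
            snp_gene[snp] = gene

    effects = np.zeros(len(snp_ids))
    resolved_effects: dict[str, float] = {}
    for key, eff in (true_effects or {}).items():
        snp = f"{key}_SNP00" if key in {a.gene for a in annotation} else key
        if snp not in snp_gene:
            raise ValueError(f"unknown SNP or gene {key!r} in true_effects")
        effects[snp_ids.index(snp)] = float(eff)
        resolved_effects[snp] = float(eff)

    mafs = rng.uniform(maf_range[0], maf_range[1], size=len(snp_ids))
    genotypes = rng.binomial(2, mafs, size=(n_individuals, len(snp_ids)))
    phenotype = genotypes @ effects + rng.normal(size=n_individuals)
    sumstats = marginal_sumstats(
        genotypes, phenotype, snp_ids, ["1"] * len(snp_ids), positions
    )
    ledger = {
        "seed": int(seed),
        "n_genes": n_genes,
        "snps_per_gene": snps_per_gene,
        "n_individuals": n_individuals,
        "maf_range": list(maf_range),
        "snp_gene": snp_gene,
        "true_effects": resolved_effects,
        "mafs": {s: float(m) for s, m in zip(snp_ids, mafs)},
    }
    return SyntheticGwas(
        sumstats=sumstats,
        annotation=annotation,
        genotypes=genotypes,
        phenotype=phenotype,
        ledger=ledger,
    )


# ---------------------------------------------------------------------------
# published candidate-table fixture
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Table1Row:
    """One published strong-candidate internode row, transcribed verbatim.

    The printed count columns are kept alongside the partner listings; one
    row (RELA) lists a partner twice, so its printed insulin link count (4)
    exceeds its distinct-partner count (3).
    """

    gene: str
    total_links: int
    total_evid: int
    links_insulin: int
    evid_insulin: int
    links_mito: int
    evid_mito: int
    partners_insulin: tuple[str, ...]
    partners_mito: tuple[str, ...]

    def to_record(self) -> InternodeRecord:
        """As an InternodeRecord (distinct partners; printed evidence counts)."""
        return InternodeRecord(
            gene=self.gene,
            partners_A=frozenset(self.partners_insulin),
            partners_B=frozenset(self.partners_mito),
            evid_A=self.evid_insulin,
            evid_B=self.evid_mito,
        )


def table1_fixture() -> list[Table1Row]:
    """The 31 published strong-candidate internode rows."""
    path = resources.files("crosstalknet.data").joinpath("table1_internodes.tsv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", dtype={"gene": str})
    rows = []
    for r in df.itertuples(index=False):
        rows.append(
            Table1Row(
                gene=r.gene,
                total_links=int(r.total_links),
                total_evid=int(r.total_evid),
                links_insulin=int(r.links_insulin),
                evid_insulin=int(r.evid_insulin),
                links_mito=int(r.links_mito),
                evid_mito=int(r.evid_mito),
                partners_insulin=tuple(r.partners_insulin.split("|")),
                partners_mito=tuple(r.partners_mito.split("|")),
            )
        )
    return rows
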