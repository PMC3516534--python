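"""Per-source evidence filters and interactome assembly."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crosstalknet.interactome import (
    EvidenceEdge,
    TissueExpressionCalls,
    assemble,
    complex_edges,
    derive_ppicorr,
    filter_ppi_high,
    metabolic_adjacency,
    pathway_edges,
)
from crosstalknet.io_formats import RawEdge, Reaction, canonical_pair


def calls_for(expressed, unexpressed=()):
    zero = {"adipose": False, "muscle": False, "liver": False, "heart": False}
    table = {g: {**zero, "liver": True} for g in expressed}
    table.update({g: dict(zero) for g in unexpressed})
    return TissueExpressionCalls(calls=table)


def ppi(a, b, labs):
    return RawEdge(pair=canonical_pair(a, b), source="PPI", provenance=str(labs), lab_count=labs)


class TestPpiHigh:
    def test_replicated_expressed_edge_kept(self):
        kept = filter_ppi_high([ppi("A", "B", 2)], calls_for({"A", "B"}))
        assert len(kept) == 1 and kept[0].source == "PPIhigh"

    def test_single_lab_edge_excluded(self):
        assert filter_ppi_high([ppi("A", "B", 1)], calls_for({"A", "B"})) == []

    def test_gene_missing_from_calls_treated_unexpressed(self):
        assert filter_ppi_high([ppi("A", "B", 3)], calls_for({"A"})) == []

    def test_matches_brute_force_predicate(self, rng):
        genes = [f"G{i}" for i in range(40)]
        expressed = set(rng.choice(genes, size=25, replace=False))
        calls = calls_for(expressed, set(genes) - expressed)
        edges = []
        for _ in range(500):
            a, b = rng.choice(genes, size=2, replace=False)
            edges.append(ppi(a, b, int(rng.integers(1, 5))))
        kept = {(e.pair, e.lab_count) for e in filter_ppi_high(edges, calls)}
        expected = {
            (e.pair, e.lab_count)
            for e in edges
            if e.lab_count >= 2 and e.pair[0] in expressed and e.pair[1] in expressed
        }
        assert kept == expected


class TestPpiCorr:
    def _matrix(self, data):
        return pd.DataFrame(data)

    def test_perfect_correlation_kept(self, rng):
        v = rng.normal(size=10)
        coexpr = pd.DataFrame([v, v], index=["A", "B"])
        kept = derive_ppicorr([ppi("A", "B", 1)], coexpr, calls_for({"A", "B"}))
        assert len(kept) == 1
        assert kept[0].correlation == pytest.approx(1.0)

    def test_p_matches_t_transform_oracle(self, rng):
        # independent standard normals: the Pearson test p must equal the
        # closed-form t transform t = r sqrt(n-2) / sqrt(1 - r^2)
        n = 10
        x, y = rng.normal(size=n), rng.normal(size=n)
        r, p = stats.pearsonr(x, y)
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
        p_oracle = 2 * stats.t.sf(abs(t), df=n - 2)
        assert p == pytest.approx(p_oracle, rel=1e-10)

    def test_unexpressed_pair_dropped_despite_correlation(self, rng):
        v = rng.normal(size=10)
        coexpr = pd.DataFrame([v, v], index=["A", "B"])
        assert derive_ppicorr([ppi("A", "B", 1)], coexpr, calls_for(set(), {"A", "B"})) == []

    def test_gene_missing_from_matrix_dropped(self, rng):
        coexpr = pd.DataFrame([rng.normal(size=10)], index=["A"])
        assert derive_ppicorr([ppi("A", "B", 1)], coexpr, calls_for({"A", "B"})) == []

    def test_too_few_samples_rejected(self, rng):
        coexpr = pd.DataFrame(rng.normal(size=(2, 2)), index=["A", "B"])
        with pytest.raises(ValueError, match="insufficient samples"):
            derive_ppicorr([ppi("A", "B", 1)], coexpr, calls_for({"A", "B"}))

    def test_uncorrelated_pairs_rejected_correlated_kept(self, rng):
        n = 60
        z = rng.normal(size=n)
        coexpr = pd.DataFrame(
            {
                "A": z,
                "B": z + 0.1 * rng.normal(size=n),
                "C": rng.normal(size=n),
                "D": rng.normal(size=n),
            }
        ).T
        kept = derive_ppicorr(
            [ppi("A", "B", 1), ppi("C", "D", 1)], coexpr, calls_for({"A", "B", "C", "D"})
        )
        assert [e.pair for e in kept] == [("A", "B")]


class TestComplexes:
    def test_clique_expansion_counts(self):
        edges = complex_edges({"C1": {"A", "B", "C"}})
        assert len(edges) == 3

    def test_repeated_complex_gives_two_records(self):
        edges = complex_edges({"C1": {"A", "B"}, "C2": {"A", "B"}})
        assert len(edges) == 2 and {e.pair for e in edges} == {("A", "B")}

    def test_singleton_complex_skipped(self):
        assert complex_edges({"C1": {"A"}}) == []

    def test_matches_brute_force_double_loop(self, rng):
        genes = [f"G{i}" for i in range(15)]
        complexes = {
            f"C{i}": set(rng.choice(genes, size=rng.integers(1, 6), replace=False))
            for i in range(20)
        }
        got = sorted((e.pair, e.provenance) for e in complex_edges(complexes))
        expected = []
        for cid, members in complexes.items():
            mem = sorted(members)
            for i in range(len(mem)):
                for j in range(i + 1, len(mem)):
                    expected.append(((mem[i], mem[j]), cid))
        assert got == sorted(expected)


class TestMetabolicAdjacency:
    def test_chain_links_consecutive_enzymes(self):
        reactions = [
            Reaction("R1", frozenset({"MA"}), frozenset({"MB"}), frozenset({"E1"})),
            Reaction("R2", frozenset({"MB"}), frozenset({"MC"}), frozenset({"E2"})),
        ]
        (edge,) = metabolic_adjacency(reactions, currency_metabolites=())
        assert edge.pair == ("E1", "E2") and "MB" in edge.provenance

    def test_currency_metabolite_excluded(self):
        reactions = [
            Reaction("R1", frozenset({"MA"}), frozenset({"ATP"}), frozenset({"E1"})),
            Reaction("R2", frozenset({"ATP"}), frozenset({"MC"}), frozenset({"E2"})),
        ]
        assert metabolic_adjacency(reactions) == []

    def test_geneless_reaction_skipped(self):
        reactions = [
            Reaction("R1", frozenset({"MA"}), frozenset({"MB"}), frozenset()),
            Reaction("R2", frozenset({"MB"}), frozenset({"MC"}), frozenset({"E2"})),
        ]
        assert metabolic_adjacency(reactions, currency_metabolites=()) == []

    def test_matches_brute_force_over_reaction_pairs(self, rng):
        mets = [f"M{i}" for i in range(10)]
        reactions = [
            Reaction(
                f"R{i}",
                frozenset(rng.choice(mets, size=2, replace=False)),
                frozenset(rng.choice(mets, size=2, replace=False)),
                frozenset({f"E{rng.integers(0, 8)}", f"E{rng.integers(0, 8)}"}),
            )
            for i in range(15)
        ]
        got = sorted(e.pair for e in metabolic_adjacency(reactions, currency_metabolites=("M0",)))
        expected = []
        for i in range(len(reactions)):
            for j in range(i + 1, len(reactions)):
                r1, r2 = reactions[i], reactions[j]
                shared = (r1.metabolites & r2.metabolites) - {"M0"}
                if not shared:
                    continue
                for g1 in r1.genes:
                    for g2 in r2.genes:
                        if g1 != g2:
                            expected.append(canonical_pair(g1, g2))
        assert got == sorted(expected)


class TestPathways:
    def test_reversed_relation_deduplicated(self):
        edges = pathway_edges([("A", "B", "p1"), ("B", "A", "p1")])
        assert len(edges) == 1

    def test_distinct_pathways_kept_separately(self):
        edges = pathway_edges([("A", "B", "p1"), ("A", "B", "p2")])
        assert len(edges) == 2

    def test_matches_brute_force_dedup(self, rng):
        genes = [f"G{i}" for i in range(10)]
        relations = [
            (str(rng.choice(genes)), str(rng.choice(genes)), f"p{rng.integers(0, 4)}")
            for _ in range(80)
        ]
        got = sorted((e.pair, e.provenance) for e in pathway_edges(relations))
        expected = sorted(
            {(canonical_pair(a, b), p) for a, b, p in relations if a != b}
        )
        assert got == expected


class TestAssemble:
    def test_collapses_pairs_across_sources(self):
        e1 = EvidenceEdge(pair=("A", "B"), source="PPIhigh", lab_count=2)
        e2 = EvidenceEdge(pair=("A", "B"), source="COMPLEX", provenance="C1")
        inter = assemble([e1], [e2])
        assert len(inter) == 1 and len(inter.pairs[("A", "B")]) == 2

    def test_universe_is_union_of_pair_members(self):
        inter = assemble(
            [EvidenceEdge(pair=("A", "B"), source="PATH", provenance="p")],
            [EvidenceEdge(pair=("C", "D"), source="PATH", provenance="p")],
        )
        assert inter.universe == {"A", "B", "C", "D"} and len(inter) == 2

    def test_empty_union_rejected(self):
        with pytest.raises(ValueError, match="empty interactome"):
            assemble([], [])

    def test_order_insensitive(self, rng):
        lists = [
            [EvidenceEdge(pair=canonical_pair(f"G{i}", f"G{i + 1}"), source="PATH", provenance=f"p{i}")]
            for i in range(10)
        ]
        a = assemble(*lists)
        b = assemble(*reversed(lists))
        assert a == b

    def test_synthetic_source_counts_match_ledger(self):
        from crosstalknet.synthetic import gen_interactome

        sim = gen_interactome(seed=7)
        inter = sim.build_interactome()
        # every PPIhigh record has lab_count >= 2, every PPIcorr exactly 1
        for records in inter.pairs.values():
            for rec in records:
                if rec.source == "PPIhigh":
                    assert rec.lab_count >= 2
                if rec.source == "PPIcorr":
                    assert rec.lab_count == 1
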