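"""Randomization machinery: network rewiring, random gene sets, empirical p.

Empirical p-values use add-one smoothing, p = (b + 1) / (n + 1) where b is
the number of null draws at least as extreme as the observed statistic; the
raw frequency b / n is kept alongside.  Add-one smoothing keeps p away from
zero at finite simulation counts and bounds it below by 1 / (n + 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import networkx as nx
import numpy as np

from crosstalknet.interactome import EvidenceEdge, Interactome


@dataclass(frozen=True)
class EmpiricalP:
    """Simulation-based significance of an observed statistic."""

    observed: float
    n_sim: int
    n_as_extreme: int
    direction: str

    @property
    def p(self) -> float:
        return (self.n_as_extreme + 1) / (self.n_sim + 1)

    @property
    def raw_frequency(self) -> float:
        return self.n_as_extreme / self.n_sim


def rewire(interactome: Interactome, n_swaps: int, seed: int, mode: str = "degree") -> Interactome:
    """Randomize the collapsed pair graph.

    ``mode='degree'`` (default) performs repeated double-edge swaps, which
    preserve every node's degree exactly and introduce no self-loops or
    parallel edges.  ``mode='er'`` draws an Erdos-Renyi graph over the same
    nodes with the same edge count (matched density, free degrees).  Each
    rewired pair carries one synthetic evidence record (source RANDOM).
    """
    if n_swaps < 1:
        raise ValueError("n_swaps must be >= 1")
    g = interactome.graph()
    if g.number_of_edges() < 2:
        raise ValueError("graph too small to swap")
    rng = np.random.default_rng(seed)
    if mode == "degree":
        nx_seed = int(rng.integers(0, 2**31 - 1))
        try:
            nx.double_edge_swap(
                g, nswap=n_swaps, max_tries=max(100 * n_swaps, 1000), seed=nx_seed
            )
        except nx.NetworkXAlgorithmError:
            pass  # hit max_tries; the partially rewired graph is still degree-preserving
    elif mode == "er":
        nodes = sorted(g.nodes)
        n_edges = g.number_of_edges()
        g = nx.Graph()
        g.add_nodes_from(nodes)
        possible = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1 :]]
        idx = rng.choice(len(possible), size=n_edges, replace=False)
        g.add_edges_from(possible[i] for i in sorted(idx))
    else:
        raise ValueError(f"unknown rewire mode {mode!r}")
    pairs = {
        (min(a, b), max(a, b)): [
            EvidenceEdge(pair=(min(a, b), max(a, b)), source="RANDOM", provenance=f"seed={seed}")
        ]
        for a, b in g.edges
    }
    return Interactome(pairs)


def sample_gene_sets(
    universe: Iterable[str], size: int, n_sets: int, seed: int
) -> list[frozenset[str]]:
    """Draw ``n_sets`` gene sets of ``size`` without replacement within each set."""
    pool = sorted(universe)
    if size > len(pool):
        raise ValueError(f"set size {size} exceeds universe size {len(pool)}")
    rng = np.random.default_rng(seed)
    pool_arr = np.array(pool, dtype=object)
    return [
        frozenset(pool_arr[rng.choice(len(pool_arr), size=size, replace=False)])
        for _ in range(n_sets)
    ]


def empirical_p(
    observed: float,
    null_draws: Sequence[float],
    direction: str | Callable[[float], bool] = "greater",
) -> EmpiricalP:
    """Add-one smoothed empirical p-value against simulated null draws.

    ``direction`` is 'greater' (null >= observed counts as extreme), 'less',
    or a callable predicate evaluated on each null draw for compound
    extremeness conditions (e.g. "p smaller AND effect positive").
    """
    nulls = np.asarray(null_draws, dtype=float) if not callable(direction) else null_draws
    n_sim = len(nulls)
    if n_sim == 0:
        raise ValueError("empty null draws")
    if callable(direction):
        n_extreme = sum(bool(direction(d)) for d in nulls)
        label = "predicate"
    elif direction == "greater":
        n_extreme = int(np.sum(nulls >= observed))
        label = direction
    elif direction == "less":
        n_extreme = int(np.sum(nulls <= observed))
        label = direction
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return EmpiricalP(
        observed=float(observed), n_sim=n_sim, n_as_extreme=n_extreme, direction=label
    )
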