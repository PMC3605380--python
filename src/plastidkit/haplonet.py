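"""Chlorotypes and median-joining haplotype networks.

A chlorotype is the concatenation of a plant's alleles at the scored
chloroplast SNP loci.  Identical strings are grouped into chlorotypes with
population membership counts; relationships between chlorotypes are then
summarized as a median-joining network: minimum-spanning links relaxed by
a parameter epsilon, augmented with inferred intermediate haplotypes
(quasi-medians, the per-locus majority of a connected triplet) whenever
they shorten the network.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import pandas as pd


@dataclass
class Chlorotype:
    haplotype: str
    members: list[str] = field(default_factory=list)
    population_counts: dict[str, int] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.members)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("haplotype strings differ in length")
    return sum(1 for x, y in zip(a, b) if x != y)


def build_chlorotypes(
    genotypes: pd.DataFrame,
    populations: dict[str, str] | None = None,
    locus_blacklist: set[str] | None = None,
) -> list[Chlorotype]:
    """Group individuals with identical haplotype strings.

    ``genotypes``: DataFrame indexed by individual id, one column per SNP
    locus (allele symbols).  ``populations`` maps individual -> population
    (falls back to a 'population' column if present).  Loci in
    ``locus_blacklist`` (e.g. homopolymer-region SNPs) are excluded before
    grouping.  Individuals with any missing allele are dropped.  Chlorotype
    order is by first occurrence.
    """
    df = genotypes.copy()
    if populations is None and "population" in df.columns:
        populations = df["population"].to_dict()
    df = df.drop(columns=[c for c in ("population",) if c in df.columns])
    if locus_blacklist:
        df = df.drop(columns=[c for c in df.columns if c in locus_blacklist])
    populations = populations or {}
    order: list[str] = []
    groups: dict[str, Chlorotype] = {}
    for ind, row in df.iterrows():
        if row.isna().any():
            continue
        hap = "".join(str(a) for a in row.values)
        if hap not in groups:
            groups[hap] = Chlorotype(haplotype=hap)
            order.append(hap)
        ct = groups[hap]
        ct.members.append(str(ind))
        pop = populations.get(ind, "unknown")
        ct.population_counts[pop] = ct.population_counts.get(pop, 0) + 1
    return [groups[h] for h in order]


def _feasible_links(nodes: list[str], epsilon: int) -> list[tuple[str, str, int]]:
    """Epsilon-relaxed minimum-spanning links (Bandelt's connection rule).

    Distances are processed in ascending order; a link is feasible when its
    weight is within epsilon of the smallest weight that first connects the
    two (current) components.
    """
    parent = {n: n for n in nodes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges = sorted(
        (hamming(u, v), u, v) for u, v in combinations(nodes, 2)
    )
    feasible: list[tuple[str, str, int]] = []
    i = 0
    while i < len(edges):
        w = edges[i][0]
        batch = []
        while i < len(edges) and edges[i][0] <= w + epsilon:
            batch.append(edges[i])
            i += 1
        # snapshot components before this weight class
        comp_before = {n: find(n) for n in nodes}
        for bw, u, v in batch:
            if comp_before[u] != comp_before[v]:
                feasible.append((u, v, bw))
        for _bw, u, v in batch:
            ru, rv = find(u), find(v)
            if ru != rv:
                parent[ru] = rv
        roots = {find(n) for n in nodes}
        if len(roots) == 1:
            break
    return feasible


def _quasi_medians(triplet: tuple[str, str, str]) -> list[str]:
    """Per-locus majority of a triplet; ties spawn all tied variants."""
    options: list[list[str]] = []
    for alleles in zip(*triplet):
        counts = Counter(alleles)
        top = max(counts.values())
        options.append(sorted(a for a, n in counts.items() if n == top))
    medians = [""]
    for opts in options:
        medians = [m + o for m in medians for o in opts]
    return sorted(medians)


def _network_length(nodes: list[str]) -> int:
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for u, v in combinations(nodes, 2):
        g.add_edge(u, v, weight=hamming(u, v))
    return int(sum(d["weight"] for *_e, d in nx.minimum_spanning_edges(g, data=True)))


def mj_network(chlorotypes: list[Chlorotype], epsilon: int = 0) -> nx.Graph:
    """Median-joining network over observed chlorotypes.

    Iterates: build the epsilon-relaxed minimum-spanning link graph, scan
    mutually linked triplets, and add any quasi-median that strictly
    shortens the network (its minimum spanning length); repeat to fixpoint,
    then prune median vectors of degree <= 1.  With epsilon 0 and tree-like
    data the result is the unique minimum spanning tree.  The original
    algorithm's maximum-parsimony cleanup step is not applied.
    """
    if not chlorotypes:
        raise ValueError("at least one chlorotype required")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    observed = {c.haplotype: c for c in chlorotypes}
    nodes = sorted(observed)
    medians: set[str] = set()
    for _ in range(20):  # fixpoint iteration guard
        all_nodes = sorted(set(nodes) | medians)
        links = _feasible_links(all_nodes, epsilon)
        adj = nx.Graph()
        adj.add_nodes_from(all_nodes)
        adj.add_weighted_edges_from(links)
        current_len = _network_length(all_nodes)
        added = False
        candidates: list[str] = []
        for u, v, w in combinations(all_nodes, 3):
            n_links = sum(
                1 for a, b in ((u, v), (u, w), (v, w)) if adj.has_edge(a, b)
            )
            if n_links < 2:  # triplet not connected in the link graph
                continue
            for m in _quasi_medians((u, v, w)):
                if m not in observed and m not in medians and m not in candidates:
                    candidates.append(m)
        for m in sorted(candidates):
            if _network_length(all_nodes + [m]) < current_len:
                medians.add(m)
                added = True
                all_nodes = sorted(set(nodes) | medians)
                current_len = _network_length(all_nodes)
        if not added:
            break
    # final link graph and pruning of unused medians
    while True:
        all_nodes = sorted(set(nodes) | medians)
        links = _feasible_links(all_nodes, epsilon)
        g = nx.Graph()
        g.add_nodes_from(all_nodes)
        g.add_weighted_edges_from(links)
        prune = {n for n in medians if g.degree(n) <= 1}
        if not prune:
            break
        medians -= prune
    for n in g.nodes:
        ct = observed.get(n)
        g.nodes[n]["is_median"] = ct is None
        g.nodes[n]["size"] = ct.size if ct else 0
        g.nodes[n]["populations"] = (
            ",".join(f"{p}:{c}" for p, c in sorted(ct.population_counts.items()))
            if ct
            else ""
        )
    return g


def population_summary(
    chlorotypes: list[Chlorotype],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-population chlorotype counts and the shared-type report."""
    ids = {c.haplotype: f"chlorotype_{i + 1}" for i, c in enumerate(chlorotypes)}
    pop_rows = []
    pops: dict[str, dict[str, int]] = {}
    for c in chlorotypes:
        for pop, count in c.population_counts.items():
            pops.setdefault(pop, {})[ids[c.haplotype]] = count
    for pop in sorted(pops):
        types = pops[pop]
        pop_rows.append(
            {
                "population": pop,
                "n_individuals": sum(types.values()),
                "n_chlorotypes": len(types),
                "chlorotypes": ",".join(sorted(types)),
            }
        )
    shared_rows = [
        {
            "chlorotype": ids[c.haplotype],
            "haplotype": c.haplotype,
            "n_populations": len(c.population_counts),
            "populations": ",".join(sorted(c.population_counts)),
        }
        for c in chlorotypes
        if len(c.population_counts) > 1
    ]
    return (
        pd.DataFrame(pop_rows, columns=["population", "n_individuals", "n_chlorotypes", "chlorotypes"]),
        pd.DataFrame(shared_rows, columns=["chlorotype", "haplotype", "n_populations", "populations"]),
    )
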