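"""Integrated ranking of selected group members by network degree and pathway hits.

Index one: a member's link count within the group-induced subgraph,
normalized by the total number of links among all group members. Index two:
the number of reference pathways containing the member, as a percentage of
the declared reference-pathway count. The integrated index is a weighted
mean of the two (equal weights by default; the combination rule is this
package's explicit choice and fully configurable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from dnbkit.io_expr import GeneNetwork, PathwayCollection

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RankedGene:
    gene: str
    degree: int
    index_one: float
    pathway_hits: int
    index_two: float  # percent
    integrated_index: float
    rank: int
    tied: bool


def network_degree_index(
    group: Iterable[str], network: GeneNetwork, whole_network: bool = False
) -> dict[str, tuple[int, float]]:
    """Per-gene (degree, index_one) for the group.

    Degrees are counted within the subgraph induced by the group (links to
    other group members), and normalized by L, the total number of such
    links. ``whole_network=True`` instead counts degree in the full network,
    normalized by the number of network edges incident to the group. Genes
    absent from the network get degree 0; if L = 0 every index_one is 0
    (flagged in the log).
    """
    group = sorted(set(group))
    if not group:
        raise ValueError("group must be non-empty")
    present = [g for g in group if g in network.graph]
    if len(present) < len(group):
        log.info("%d of %d group gene(s) absent from the network", len(group) - len(present), len(group))
    if whole_network:
        degrees = {g: (network.graph.degree(g) if g in network.graph else 0) for g in group}
        total = len({frozenset(e) for g in present for e in network.graph.edges(g)})
    else:
        sub = network.graph.subgraph(present)
        degrees = {g: (sub.degree(g) if g in sub else 0) for g in group}
        total = sub.number_of_edges()
    if total == 0:
        log.warning("no links among group genes; all index_one values are 0")
        return {g: (degrees[g], 0.0) for g in group}
    return {g: (degrees[g], degrees[g] / total) for g in group}


def pathway_hit_index(
    group: Iterable[str], pathways: PathwayCollection
) -> dict[str, tuple[int, float]]:
    """Per-gene (pathway hit count, index_two-as-percent) for the group."""
    group = sorted(set(group))
    total = pathways.total_reference_count
    out = {}
    for g in group:
        h = pathways.hits(g)
        out[g] = (h, 100.0 * h / total)
    return out


def integrated_rank(
    members: Iterable[str],
    network: GeneNetwork,
    pathways: PathwayCollection,
    weights: Sequence[float] = (0.5, 0.5),
    whole_network: bool = False,
) -> list[RankedGene]:
    """Rank members by ``w1 * index_one + w2 * (index_two / 100)``, descending.

    Ties get adjacent ranks in lexicographic gene order and are flagged.
    With the default equal weights the integrated index lies in [0, 1].
    """
    members = sorted(set(members))
    if not members:
        raise ValueError("members must be non-empty")
    w1, w2 = (float(w) for w in weights)
    if w1 < 0 or w2 < 0:
        raise ValueError("weights must be non-negative")

    deg = network_degree_index(members, network, whole_network=whole_network)
    hits = pathway_hit_index(members, pathways)
    scored = []
    for g in members:
        d, i1 = deg[g]
        h, i2 = hits[g]
        scored.append((g, d, i1, h, i2, w1 * i1 + w2 * (i2 / 100.0)))
    scored.sort(key=lambda row: (-row[5], row[0]))

    counts: dict[float, int] = {}
    for row in scored:
        counts[row[5]] = counts.get(row[5], 0) + 1

    ranked = [
        RankedGene(
            gene=g,
            degree=d,
            index_one=i1,
            pathway_hits=h,
            index_two=i2,
            integrated_index=ii,
            rank=r,
            tied=counts[ii] > 1,
        )
        for r, (g, d, i1, h, i2, ii) in enumerate(scored, 1)
    ]
    if any(m.tied for m in ranked):
        log.info("ties in integrated index broken lexicographically by gene id")
    return ranked
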