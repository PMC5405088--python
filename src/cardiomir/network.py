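"""Bipartite miRNA-disease network construction and hub detection.

A miRNA that dysregulates many diseases, or a disease that attracts many
miRNAs, is a *hub*. Hub criteria follow the convention of ">5 disease links"
for miRNA hubs (degree >= 6) and ">10 miRNA links" for disease hubs
(degree >= 11); both thresholds are configurable.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .records import AssociationDataset

__all__ = [
    "BipartiteNetwork",
    "HubCriteria",
    "HubReport",
    "build_network",
    "degree",
    "mirna_frequency_table",
    "find_hubs",
]


@dataclass(frozen=True)
class BipartiteNetwork:
    """Undirected bipartite graph between miRNA and disease nodes.

    Edges are direction-agnostic: multiple directed incidences of the same
    (miRNA, disease) pair collapse to one edge. Dysregulation direction
    lives in the statistics and mining layers, not here.
    """

    mirna_nodes: frozenset[str]
    disease_nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.mirna_nodes & self.disease_nodes:
            raise ValueError(
                f"node sets overlap: {sorted(self.mirna_nodes & self.disease_nodes)}"
            )
        for mirna, disease in self.edges:
            if mirna not in self.mirna_nodes:
                raise ValueError(f"edge endpoint {mirna!r} not a miRNA node")
            if disease not in self.disease_nodes:
                raise ValueError(f"edge endpoint {disease!r} not a disease node")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> dict[str, int]:
        """Degree of every node (isolated nodes included with degree 0)."""
        counts: Counter[str] = Counter()
        for mirna, disease in self.edges:
            counts[mirna] += 1
            counts[disease] += 1
        return {n: counts.get(n, 0) for n in self.mirna_nodes | self.disease_nodes}


@dataclass(frozen=True)
class HubCriteria:
    """Minimum degree for a node to count as a hub, per partition.

    Defaults encode "more than 5 disease edges" for miRNAs (>=6) and "more
    than 10 miRNAs" for diseases (>=11).
    """

    mirna_min_links: int = 6
    disease_min_links: int = 11

    def __post_init__(self) -> None:
        if self.mirna_min_links < 1 or self.disease_min_links < 1:
            raise ValueError("hub thresholds must be >= 1")


@dataclass(frozen=True)
class HubReport:
    mirna_hubs: dict[str, int] = field(default_factory=dict)
    disease_hubs: dict[str, int] = field(default_factory=dict)
    criteria: HubCriteria = HubCriteria()

    def hub_nodes(self) -> frozenset[str]:
        return frozenset(self.mirna_hubs) | frozenset(self.disease_hubs)

    def to_frame(self, net: BipartiteNetwork) -> pd.DataFrame:
        """Full node table: ``node  partition  degree  is_hub``."""
        degs = net.degrees()
        rows = [
            (n, "mirna", degs[n], n in self.mirna_hubs)
            for n in sorted(net.mirna_nodes)
        ] + [
            (n, "disease", degs[n], n in self.disease_hubs)
            for n in sorted(net.disease_nodes)
        ]
        frame = pd.DataFrame(rows, columns=["node", "partition", "degree", "is_hub"])
        return frame.sort_values(
            ["degree", "node"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)


def build_network(ds: AssociationDataset) -> BipartiteNetwork:
    """Collapse a dataset to its bipartite topology.

    Node sets are exactly the distinct ids in the dataset; edges are the
    distinct (miRNA, disease) pairs regardless of direction.
    """
    return BipartiteNetwork(
        mirna_nodes=frozenset(ds.mirna_ids()),
        disease_nodes=frozenset(ds.disease_ids()),
        edges=frozenset((r.mirna_id, r.disease_id) for r in ds.records),
    )


def degree(net: BipartiteNetwork, node_id: str) -> int:
    """Number of edges incident to ``node_id`` (error if the node is unknown)."""
    if node_id not in net.mirna_nodes and node_id not in net.disease_nodes:
        raise KeyError(f"unknown node: {node_id!r}")
    return net.degrees()[node_id]


def mirna_frequency_table(net: BipartiteNetwork) -> dict[str, int]:
    """Disease-incidence frequency per miRNA: degree, sorted by descending
    degree then id. This is the profile behind a frequency bar chart of
    miRNA-disease incidence."""
    degs = net.degrees()
    ordered = sorted(net.mirna_nodes, key=lambda m: (-degs[m], m))
    return {m: degs[m] for m in ordered}


def find_hubs(net: BipartiteNetwork, criteria: HubCriteria | None = None) -> HubReport:
    """Identify hub miRNAs and hub diseases under the given degree criteria."""
    criteria = criteria or HubCriteria()
    degs = net.degrees()
    mirna_hubs = {
        m: degs[m]
        for m in sorted(net.mirna_nodes, key=lambda n: (-degs[n], n))
        if degs[m] >= criteria.mirna_min_links
    }
    disease_hubs = {
        d: degs[d]
        for d in sorted(net.disease_nodes, key=lambda n: (-degs[n], n))
        if degs[d] >= criteria.disease_min_links
    }
    return HubReport(mirna_hubs=mirna_hubs, disease_hubs=disease_hubs, criteria=criteria)
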