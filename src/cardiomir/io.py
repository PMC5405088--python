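"""Reading and writing external formats.

Association tables are tab-separated text with a header row; network
interchange files are SIF (Cytoscape simple interaction format) or GraphML
(via networkx). All emitted tables are lexicographically ordered so that
repeated runs are byte-stable.
"""
from __future__ import annotations

import csv
import io as _io
import os
from typing import IO, Iterable, Union

import networkx as nx

from .records import AssociationDataset, AssociationRecord, parse_direction

__all__ = [
    "parse_associations",
    "write_associations",
    "write_network_interchange",
    "read_network_interchange",
    "ParseError",
]

_MIRNA_COLUMNS = {"mirna", "mirna_id", "microrna"}
_DISEASE_COLUMNS = {"disease", "disease_id"}
_DIRECTION_COLUMNS = {"direction", "dysregulation", "regulation"}

Source = Union[str, os.PathLike, IO[str]]


class ParseError(ValueError):
    """Raised for malformed association tables, with a 1-based line number."""

    def __init__(self, line: int, message: str) -> None:
        super().__init__(f"line {line}: {message}")
        self.line = line


def _open_source(source: Source) -> tuple[IO[str], bool]:
    if hasattr(source, "read"):
        return source, False  # caller-owned stream
    return open(os.fspath(source), "r", encoding="utf-8", newline=""), True


def parse_associations(source: Source, provenance: str | None = None) -> AssociationDataset:
    """Parse a tab-separated association table into an :class:`AssociationDataset`.

    The header must name a miRNA column, a disease column and a direction
    column (extra columns, e.g. evidence notes, are ignored). Direction
    tokens {UP, U, DOWN, D} are accepted case-insensitively. Exact duplicate
    rows are collapsed with a logged warning.
    """
    stream, owned = _open_source(source)
    try:
        reader = csv.reader(stream, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(1, "empty input: missing header row") from None
        columns = [h.strip().lower() for h in header]

        def _locate(names: set[str], what: str) -> int:
            for idx, col in enumerate(columns):
                if col in names:
                    return idx
            raise ParseError(1, f"header does not name a {what} column (got {columns})")

        i_mirna = _locate(_MIRNA_COLUMNS, "miRNA")
        i_disease = _locate(_DISEASE_COLUMNS, "disease")
        i_direction = _locate(_DIRECTION_COLUMNS, "direction")
        needed = max(i_mirna, i_disease, i_direction) + 1

        records: list[AssociationRecord] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue  # blank line
            if len(row) < needed:
                raise ParseError(lineno, f"expected at least {needed} fields, got {len(row)}")
            try:
                records.append(
                    AssociationRecord(
                        mirna_id=row[i_mirna],
                        disease_id=row[i_disease],
                        direction=parse_direction(row[i_direction]),
                    )
                )
            except ValueError as exc:
                raise ParseError(lineno, str(exc)) from None
        if provenance is None:
            provenance = getattr(stream, "name", "<stream>")
        return AssociationDataset.from_records(records, provenance=str(provenance))
    finally:
        if owned:
            stream.close()


def write_associations(ds: AssociationDataset, target: Source) -> None:
    """Write a dataset as the canonical three-column association TSV."""
    stream, owned = (
        (target, False) if hasattr(target, "write")
        else (open(os.fspath(target), "w", encoding="utf-8", newline=""), True)
    )
    try:
        stream.write("mirna\tdisease\tdirection\n")
        for rec in ds.records:
            stream.write(f"{rec.mirna_id}\t{rec.disease_id}\t{rec.direction.value}\n")
    finally:
        if owned:
            stream.close()


def _as_graphml_graph(net, hub_nodes: Iterable[str]) -> nx.Graph:
    hubs = set(hub_nodes)
    graph = nx.Graph()
    for node in sorted(net.mirna_nodes):
        graph.add_node(node, partition="mirna", hub=node in hubs)
    for node in sorted(net.disease_nodes):
        graph.add_node(node, partition="disease", hub=node in hubs)
    for mirna, disease in sorted(net.edges):
        graph.add_edge(mirna, disease)
    return graph


def write_network_interchange(
    net, dialect: str = "SIF", hub_nodes: Iterable[str] = ()
) -> str:
    """Serialize a bipartite network as SIF or GraphML text.

    SIF emits one ``mirna<TAB>associates<TAB>disease`` line per edge in
    lexicographic order, plus bare-name lines for isolated nodes. GraphML
    carries a ``partition`` attribute (``mirna``/``disease``) and a boolean
    ``hub`` attribute per node (hub membership is supplied by the caller,
    typically from :func:`cardiomir.network.find_hubs`).
    """
    dialect = dialect.upper()
    if dialect == "SIF":
        lines = [f"{m}\tassociates\t{d}" for m, d in sorted(net.edges)]
        linked = {m for m, _ in net.edges} | {d for _, d in net.edges}
        lines.extend(sorted(net.mirna_nodes - linked))
        lines.extend(sorted(net.disease_nodes - linked))
        return "\n".join(lines) + ("\n" if lines else "")
    if dialect == "GRAPHML":
        graph = _as_graphml_graph(net, hub_nodes)
        return "\n".join(nx.generate_graphml(graph)) + "\n"
    raise ValueError(f"unknown network dialect: {dialect!r} (expected SIF or GraphML)")


def read_network_interchange(text: str, dialect: str = "SIF"):
    """Parse SIF or GraphML text back into a :class:`BipartiteNetwork`.

    SIF carries no partition metadata, so isolated (bare-name) nodes are
    dropped on read; the edge set round-trips exactly. GraphML round-trips
    node sets, partitions and edges.
    """
    from .network import BipartiteNetwork

    dialect = dialect.upper()
    if dialect == "SIF":
        edges = set()
        for lineno, line in enumerate(text.splitlines(), start=1):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                continue  # isolated node; partition unknowable in SIF
            if len(parts) != 3 or parts[1] != "associates":
                raise ParseError(lineno, f"malformed SIF line: {line!r}")
            edges.add((parts[0], parts[2]))
        return BipartiteNetwork(
            mirna_nodes=frozenset(m for m, _ in edges),
            disease_nodes=frozenset(d for _, d in edges),
            edges=frozenset(edges),
        )
    if dialect == "GRAPHML":
        graph = nx.parse_graphml(text)
        mirnas = {n for n, d in graph.nodes(data=True) if d.get("partition") == "mirna"}
        diseases = {n for n, d in graph.nodes(data=True) if d.get("partition") == "disease"}
        edges = set()
        for u, v in graph.edges():
            if u in mirnas:
                edges.add((u, v))
            else:
                edges.add((v, u))
        return BipartiteNetwork(
            mirna_nodes=frozenset(mirnas),
            disease_nodes=frozenset(diseases),
            edges=frozenset(edges),
        )
    raise ValueError(f"unknown network dialect: {dialect!r} (expected SIF or GraphML)")


def dataset_to_tsv(ds: AssociationDataset) -> str:
    """Canonical TSV serialization of a dataset (used for checksumming)."""
    buf = _io.StringIO()
    write_associations(ds, buf)
    return buf.getvalue()
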