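"""Protein–protein interaction network ingestion.

Reads BioGRID-style tab-delimited interaction tables into a clean undirected
:class:`networkx.Graph` keyed by uppercased gene symbols, which is the graph
every neighborhood sum in :mod:`gibbsnet.energy` runs over.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from typing import IO, Iterable, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

#: Column headers of the BioGRID TAB format carrying the two interactor symbols.
DEFAULT_SYMBOL_COLUMNS: tuple[str, str] = (
    "Official Symbol Interactor A",
    "Official Symbol Interactor B",
)

#: Column headers of the BioGRID TAB format carrying the two interactor taxa.
DEFAULT_ORGANISM_COLUMNS: tuple[str, str] = (
    "Organism Interactor A",
    "Organism Interactor B",
)

#: NCBI taxon id for Homo sapiens — the default organism filter.
HUMAN_TAXON = 9606


class NetworkFormatError(ValueError):
    """Raised when an interaction table does not match the expected layout."""


@dataclass(frozen=True)
class InteractionRecord:
    """One raw interaction row: two gene symbols plus optional taxon ids.

    Symbols are whitespace-stripped and uppercased on construction so the
    network shares a namespace with the expression matrix.
    """

    symbol_a: str
    symbol_b: str
    organism_a: int | None = None
    organism_b: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "symbol_a", self.symbol_a.strip().upper())
        object.__setattr__(self, "symbol_b", self.symbol_b.strip().upper())
        if not self.symbol_a or not self.symbol_b:
            raise ValueError("interaction symbols must be non-empty")


def parse_interactions(
    stream: IO[str] | str,
    organism_filter: int | None | str = "default",
    symbol_columns: Sequence[str] = DEFAULT_SYMBOL_COLUMNS,
    organism_columns: Sequence[str] = DEFAULT_ORGANISM_COLUMNS,
) -> list[InteractionRecord]:
    """Parse a tab-delimited interaction table into interaction records.

    Parameters
    ----------
    stream:
        Text stream (or literal string) with a header row naming the two
        interactor-symbol columns; organism columns are optional.
    organism_filter:
        Taxon id that *both* interactors must match, ``None`` for no
        filtering, or the string ``"default"``: filter to human (9606) when
        organism columns are present, no filter when they are not.
    symbol_columns, organism_columns:
        Header names to look for; defaults match the BioGRID TAB dialect.

    Returns
    -------
    list of :class:`InteractionRecord`, one per retained data row. Rows with
    empty symbols are dropped and counted in the log.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    try:
        table = pd.read_csv(stream, sep="\t", dtype=str, comment=None)
    except pd.errors.EmptyDataError:
        raise NetworkFormatError("empty interaction stream: no header row") from None

    col_a, col_b = symbol_columns
    missing = [c for c in (col_a, col_b) if c not in table.columns]
    if missing:
        raise NetworkFormatError(
            f"missing symbol column(s) {missing}; expected headers "
            f"{col_a!r} and {col_b!r}"
        )
    if table.empty:
        raise NetworkFormatError("no data rows in interaction stream")

    org_a, org_b = (
        organism_columns if all(c in table.columns for c in organism_columns) else (None, None)
    )
    if organism_filter == "default":
        organism_filter = HUMAN_TAXON if org_a is not None else None
    if organism_filter is not None and org_a is None:
        logger.warning(
            "organism filter %s requested but no organism columns present; not filtering",
            organism_filter,
        )
        organism_filter = None

    records: list[InteractionRecord] = []
    n_empty = 0
    n_filtered = 0
    for i in range(len(table)):
        a = table[col_a].iat[i]
        b = table[col_b].iat[i]
        a = "" if pd.isna(a) else str(a).strip()
        b = "" if pd.isna(b) else str(b).strip()
        if not a or not b:
            n_empty += 1
            continue
        ta = tb = None
        if org_a is not None:
            ta = _parse_taxon(table[org_a].iat[i])
            tb = _parse_taxon(table[org_b].iat[i])
            if organism_filter is not None and (ta != organism_filter or tb != organism_filter):
                n_filtered += 1
                continue
        records.append(InteractionRecord(a, b, ta, tb))

    if n_empty:
        logger.info("dropped %d interaction rows with empty symbols", n_empty)
    if n_filtered:
        logger.info(
            "dropped %d interaction rows failing organism filter %s", n_filtered, organism_filter
        )
    return records


def _parse_taxon(value: object) -> int | None:
    if value is None or pd.isna(value):
        return None
    try:
        return int(str(value).strip())
    except ValueError:
        return None


def build_network(records: Iterable[InteractionRecord]) -> nx.Graph:
    """Assemble an undirected simple graph from interaction records.

    Self-loops are dropped (the chemical-potential denominator already unions
    a node into its own neighborhood, so a self-edge would double-count its
    concentration) and duplicate edges — including reversed pairs — collapse
    to one. Counts of dropped rows are logged. An empty record list yields a
    valid empty network.
    """
    graph = nx.Graph()
    n_self = 0
    n_dup = 0
    for rec in records:
        a, b = rec.symbol_a, rec.symbol_b
        if a == b:
            n_self += 1
            continue
        if graph.has_edge(a, b):
            n_dup += 1
            continue
        graph.add_edge(a, b)
    if n_self:
        logger.info("dropped %d self-loop interaction rows", n_self)
    if n_dup:
        logger.info("collapsed %d duplicate interaction rows", n_dup)
    return graph


def neighbors(network: nx.Graph, node: str) -> set[str]:
    """Return the neighbor set Adj(node), excluding the node itself.

    The union with the node itself that appears in the chemical-potential
    denominator is applied by the scorer, not here. A node with no edges
    returns the empty set; an absent node raises ``KeyError`` naming it.
    """
    if node not in network:
        raise KeyError(f"node {node!r} not in network")
    return set(network.adj[node])


def write_edge_list(network: nx.Graph, stream: IO[str]) -> None:
    """Write the canonical 2-column TSV edge list.

    Each edge is written with its endpoints sorted, rows sorted
    lexicographically, under a ``symbol_a\\tsymbol_b`` header — the dialect
    :func:`read_edge_list` accepts, so write→read round-trips exactly.
    Isolated nodes are appended as single-column ``#node`` comment lines so
    the node set round-trips too.
    """
    stream.write("symbol_a\tsymbol_b\n")
    for a, b in sorted(tuple(sorted(e)) for e in network.edges):
        stream.write(f"{a}\t{b}\n")
    for node in sorted(n for n in network.nodes if network.degree[n] == 0):
        stream.write(f"#node\t{node}\n")


def read_edge_list(stream: IO[str] | str) -> nx.Graph:
    """Read a canonical edge-list TSV written by :func:`write_edge_list`."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    text = stream.read()
    isolated = []
    lines = []
    for line in text.splitlines():
        if line.startswith("#node\t"):
            isolated.append(line.split("\t", 1)[1].strip().upper())
        elif line.strip():
            lines.append(line)
    if len(lines) <= 1:  # header only
        graph = nx.Graph()
    else:
        records = parse_interactions(
            "\n".join(lines), organism_filter=None, symbol_columns=("symbol_a", "symbol_b")
        )
        graph = build_network(records)
    graph.add_nodes_from(isolated)
    return graph
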