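"""Network data model, edge-list / reaction-table I/O and currency filtering.

The in-memory model is deliberately minimal: an ordered node list, a set of
undirected edges stored as sorted string pairs, and two optional per-node
annotation maps — ``node_class`` distinguishing metabolite from reaction
nodes of a bipartite metabolic graph, and ``node_module`` carrying functional
module (subsystem) labels used for weight boosting and drawing styles.
"""

from __future__ import annotations

import logging
from contextlib import contextmanager
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

#: Label given to nodes with no entry in a class/module annotation file.
UNASSIGNED = "unassigned"

Edge = tuple[str, str]


def _edge(a: str, b: str) -> Edge:
    """Canonical unordered-pair representation of an edge."""
    return (a, b) if a <= b else (b, a)


@contextmanager
def _open_text(source: str | Path | IO[str], mode: str = "r") -> Iterator[IO[str]]:
    if hasattr(source, "read") or hasattr(source, "write"):
        yield source  # type: ignore[misc]
    else:
        with open(source, mode, encoding="utf-8") as handle:
            yield handle


@dataclass
class Network:
    """An undirected network with optional node class and module annotations.

    Parameters
    ----------
    nodes
        Unique node identifiers, in a stable order that downstream matrices
        and layouts follow.
    edges
        Unordered pairs of distinct node identifiers; both endpoints must be
        listed in ``nodes``.
    node_class
        Optional map ``node -> {"metabolite", "reaction"}`` for bipartite
        metabolic graphs.
    node_module
        Optional map ``node -> module label`` (functional subsystem).
    """

    nodes: list[str]
    edges: set[Edge] = field(default_factory=set)
    node_class: dict[str, str] | None = None
    node_module: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.nodes = list(self.nodes)
        if not self.nodes:
            raise ValueError("a network needs at least one node")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("node identifiers must be unique")
        known = set(self.nodes)
        normalized: set[Edge] = set()
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on node {a!r} is not allowed")
            if a not in known or b not in known:
                raise ValueError(f"edge ({a!r}, {b!r}) references an unlisted node")
            normalized.add(_edge(a, b))
        self.edges = normalized

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index(self) -> dict[str, int]:
        """Node identifier -> row index in matrix representations."""
        return {v: i for i, v in enumerate(self.nodes)}

    def degree(self, node: str) -> int:
        return sum(1 for e in self.edges if node in e)

    def module_labels(self) -> list[str]:
        """Per-node module labels in node order (``UNASSIGNED`` when absent)."""
        mods = self.node_module or {}
        return [mods.get(v, UNASSIGNED) for v in self.nodes]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        if self.node_class:
            nx.set_node_attributes(g, self.node_class, "node_class")
        if self.node_module:
            nx.set_node_attributes(g, self.node_module, "module")
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "Network":
        nodes = [str(v) for v in g.nodes]
        edges = {_edge(str(a), str(b)) for a, b in g.edges if str(a) != str(b)}
        ncls = nx.get_node_attributes(g, "node_class")
        nmod = nx.get_node_attributes(g, "module")
        return cls(
            nodes,
            edges,
            {str(k): v for k, v in ncls.items()} or None,
            {str(k): v for k, v in nmod.items()} or None,
        )


@dataclass(frozen=True)
class ReactionRecord:
    """One metabolic reaction: an identifier plus substrate/product metabolites."""

    reaction_id: str
    substrates: tuple[str, ...]
    products: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.reaction_id:
            raise ValueError("reaction_id must be nonempty")
        if not (self.substrates or self.products):
            raise ValueError(
                f"reaction {self.reaction_id!r} has neither substrates nor products"
            )


def read_edge_list(
    source: str | Path | IO[str],
    class_source: str | Path | IO[str] | None = None,
) -> Network:
    """Read a two-column edge list, optionally paired with a node-label file.

    The edge list is plain text, one edge per line, whitespace- or
    tab-separated, ``#`` starts a comment. Duplicate edges are collapsed and
    self-loops dropped with a warning. The optional label file has lines
    ``node<TAB>label``; its labels become module labels, with unlabeled nodes
    assigned :data:`UNASSIGNED`.
    """
    nodes: list[str] = []
    seen: set[str] = set()
    edges: set[Edge] = set()
    with _open_text(source) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"line {lineno}: expected two node identifiers, got {line!r}")
            a, b = fields[0], fields[1]
            for v in (a, b):
                if v not in seen:
                    seen.add(v)
                    nodes.append(v)
            if a == b:
                logger.warning("line %d: dropping self-loop on node %r", lineno, a)
                continue
            edges.add(_edge(a, b))
    if not edges:
        raise ValueError("no edges")
    net = Network(nodes, edges)
    if class_source is not None:
        net.node_module = _read_labels(class_source, set(nodes))
    return net


def _read_labels(source: str | Path | IO[str], known: set[str]) -> dict[str, str]:
    labels: dict[str, str] = {}
    with _open_text(source) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.split("#", 1)[0].rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise ValueError(f"label file line {lineno}: expected 'node<TAB>label'")
            node, label = fields[0].strip(), fields[1].strip()
            if node not in known:
                raise ValueError(f"label file names unknown node {node!r}")
            labels[node] = label
    for v in known - set(labels):
        labels[v] = UNASSIGNED
    return labels


def write_edge_list(net: Network, sink: str | Path | IO[str]) -> None:
    """Write the edge list in the dialect :func:`read_edge_list` reads."""
    with _open_text(sink, "w") as handle:
        for a, b in sorted(net.edges):
            handle.write(f"{a}\t{b}\n")


def write_class_file(net: Network, sink: str | Path | IO[str]) -> None:
    """Write the node -> module label table (``node<TAB>label``)."""
    mods = net.node_module or {}
    with _open_text(sink, "w") as handle:
        for v in net.nodes:
            handle.write(f"{v}\t{mods.get(v, UNASSIGNED)}\n")


def read_reaction_table(source: str | Path | IO[str]) -> list[ReactionRecord]:
    """Read a reaction TSV: ``reaction_id<TAB>substrates<TAB>products``.

    Substrates and products are ``;``-separated metabolite lists; a header
    row starting with ``reaction_id`` is skipped.
    """
    records: list[ReactionRecord] = []
    with _open_text(source) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0].strip() == "reaction_id":
                continue
            if len(fields) < 3:
                raise ValueError(
                    f"reaction table line {lineno}: expected 3 tab-separated columns"
                )
            split = lambda s: tuple(m.strip() for m in s.split(";") if m.strip())
            records.append(
                ReactionRecord(fields[0].strip(), split(fields[1]), split(fields[2]))
            )
    if not records:
        raise ValueError("no reactions")
    return records


def build_bipartite(reactions: Sequence[ReactionRecord]) -> Network:
    """Build the bipartite metabolite–reaction graph from a reaction set.

    Each reaction becomes one node of class ``reaction``; every substrate or
    product metabolite becomes a node of class ``metabolite`` connected to
    the reactions it participates in. Reaction direction is discarded, so a
    metabolite appearing on either side yields the same undirected edge.
    """
    nodes: list[str] = []
    node_class: dict[str, str] = {}
    edges: set[Edge] = set()
    for rec in reactions:
        if node_class.get(rec.reaction_id) == "metabolite":
            raise ValueError(
                f"identifier {rec.reaction_id!r} used for both a reaction and a metabolite"
            )
        if rec.reaction_id in node_class:
            raise ValueError(f"duplicate reaction identifier {rec.reaction_id!r}")
        node_class[rec.reaction_id] = "reaction"
        nodes.append(rec.reaction_id)
        for met in rec.substrates + rec.products:
            if node_class.get(met) == "reaction":
                raise ValueError(
                    f"identifier {met!r} used for both a reaction and a metabolite"
                )
            if met not in node_class:
                node_class[met] = "metabolite"
                nodes.append(met)
            edges.add(_edge(rec.reaction_id, met))
    return Network(nodes, edges, node_class=node_class)


def remove_currency(net: Network, stoplist: Iterable[str]) -> Network:
    """Drop currency metabolites (and their incident edges) from a network.

    Ubiquitous small molecules such as H2O and CO2 connect to very many
    reactions and would dominate graph distances; excluding them avoids
    spurious hub connectivity. Nodes left isolated by the removal are kept —
    the layout still places them. Stoplisted identifiers absent from the
    network are ignored.
    """
    drop = set(stoplist)
    keep = [v for v in net.nodes if v not in drop]
    if not keep:
        raise ValueError("stoplist removes every node")
    edges = {e for e in net.edges if e[0] not in drop and e[1] not in drop}
    subset = lambda m: {k: v for k, v in m.items() if k not in drop} if m else None
    return Network(keep, edges, subset(net.node_class), subset(net.node_module))


def default_stoplist() -> set[str]:
    """The shipped currency-metabolite stoplist (editable text resource)."""
    text = resources.files("netgrid.data").joinpath("currency_metabolites.txt").read_text()
    return {
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    }
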