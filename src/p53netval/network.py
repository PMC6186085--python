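"""Signed directed interaction networks.

The central object is :class:`InteractionNetwork`: a signed directed graph
whose nodes are genes, stimuli (the DNA-damage input) or output phenotypes,
and whose edges carry an activation (+1) or inhibition (-1) sign.  Networks
of this kind — the p53 interactome model PKT206 is the motivating example —
are exchanged as small SIF-like text files with ``activates``/``inhibits``
relation tokens.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

NodeKind = Literal["gene", "stimulus", "phenotype"]

#: Default identifiers for the designated nodes.
DEFAULT_INPUT_NODE = "DNA_damage"
DEFAULT_P53_NODE = "TP53"

_RELATION_TOKENS = {"activates": +1, "inhibits": -1}
_SIGN_TOKENS = {+1: "activates", -1: "inhibits"}


class NetworkFormatError(ValueError):
    """Raised for malformed network files or invalid network structure."""


@dataclass(frozen=True)
class Node:
    """A network node: a gene/protein, a stimulus, or an output phenotype."""

    id: str
    kind: NodeKind = "gene"
    label: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("node id must be non-empty")


@dataclass(frozen=True)
class Edge:
    """A signed directed interaction: +1 activation, -1 inhibition."""

    source: str
    target: str
    sign: int

    def __post_init__(self) -> None:
        if self.sign not in (+1, -1):
            raise ValueError(f"edge sign must be +1 or -1, got {self.sign}")


@dataclass
class InteractionNetwork:
    """Signed directed graph with designated input (stimulus) and p53 nodes.

    Parallel edges with opposite signs are allowed (a regulator may both
    activate and inhibit a target in curated networks); exact duplicate
    edges are collapsed on construction with a logged warning.
    """

    nodes: dict[str, Node] = field(default_factory=dict)
    edges: list[Edge] = field(default_factory=list)
    input_node: str = DEFAULT_INPUT_NODE
    p53_node: str = DEFAULT_P53_NODE

    def __post_init__(self) -> None:
        self.validate()

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, int]],
        input_node: str = DEFAULT_INPUT_NODE,
        p53_node: str = DEFAULT_P53_NODE,
        kinds: dict[str, NodeKind] | None = None,
    ) -> "InteractionNetwork":
        """Build a network from ``(source, target, sign)`` triples.

        Every referenced node is materialized; the input node defaults to
        kind ``stimulus`` and everything else to ``gene`` unless overridden
        through *kinds*.
        """
        kinds = dict(kinds or {})
        nodes: dict[str, Node] = {}
        edge_list: list[Edge] = []
        seen: set[tuple[str, str, int]] = set()
        for source, target, sign in edges:
            for name in (source, target):
                if name not in nodes:
                    kind = kinds.get(name, "stimulus" if name == input_node else "gene")
                    nodes[name] = Node(name, kind)
            triple = (source, target, sign)
            if triple in seen:
                logger.warning("duplicate edge %s -> %s (sign %+d) collapsed", *triple)
                continue
            seen.add(triple)
            edge_list.append(Edge(source, target, sign))
        for name, kind in kinds.items():
            if name not in nodes:
                nodes[name] = Node(name, kind)
        return cls(nodes=nodes, edges=edge_list, input_node=input_node, p53_node=p53_node)

    # -- invariants -----------------------------------------------------------

    def validate(self) -> None:
        if self.input_node not in self.nodes:
            raise NetworkFormatError(
                f"designated input node {self.input_node!r} absent from network"
            )
        if self.p53_node not in self.nodes:
            raise NetworkFormatError(
                f"designated p53 node {self.p53_node!r} absent from network"
            )
        triples = [(e.source, e.target, e.sign) for e in self.edges]
        if len(triples) != len(set(triples)):
            raise NetworkFormatError("duplicate (source, target, sign) triples")
        for e in self.edges:
            if e.source not in self.nodes or e.target not in self.nodes:
                raise NetworkFormatError(
                    f"edge {e.source}->{e.target} references an undeclared node"
                )

    # -- queries --------------------------------------------------------------

    @property
    def node_ids(self) -> list[str]:
        return list(self.nodes)

    def genes(self) -> list[str]:
        """Node ids of kind ``gene`` (model genes mappable to expression)."""
        return [n.id for n in self.nodes.values() if n.kind == "gene"]

    def regulators(self, node: str) -> list[tuple[str, int]]:
        """``(source, sign)`` pairs of incoming edges of *node*."""
        return [(e.source, e.sign) for e in self.edges if e.target == node]

    def out_degree(self, node: str) -> int:
        return sum(1 for e in self.edges if e.source == node)

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        for n in self.nodes.values():
            g.add_node(n.id, kind=n.kind, label=n.label)
        for e in self.edges:
            g.add_edge(e.source, e.target, sign=e.sign)
        return g

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.to_networkx())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and set((e.source, e.target, e.sign) for e in self.edges)
            == set((e.source, e.target, e.sign) for e in other.edges)
            and self.input_node == other.input_node
            and self.p53_node == other.p53_node
        )


# -- I/O ----------------------------------------------------------------------


def read_network(
    path: str | Path,
    format: str = "sif",
    input_node: str | None = None,
    p53_node: str | None = None,
) -> InteractionNetwork:
    """Read a SIF-like network file.

    Each record is ``source relation target`` with relation token
    ``activates`` or ``inhibits``; fields are separated by tabs or
    whitespace and ``#`` starts a comment.  An optional JSON sidecar
    ``<path>.json`` may name ``input_node`` and ``p53_node``; explicit
    arguments take precedence over the sidecar, which takes precedence
    over the defaults ``DNA_damage``/``TP53``.
    """
    if format != "sif":
        raise ValueError(f"unsupported network format {format!r}")
    path = Path(path)
    sidecar = path.with_name(path.name + ".json")
    meta: dict[str, str] = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    resolved_input = input_node or meta.get("input_node", DEFAULT_INPUT_NODE)
    resolved_p53 = p53_node or meta.get("p53_node", DEFAULT_P53_NODE)

    triples: list[tuple[str, str, int]] = []
    declared: dict[str, NodeKind] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        fields = [f.strip() for f in fields if f.strip()]
        if len(fields) == 1:
            # bare node declaration (needed for edge-less networks)
            declared.setdefault(fields[0], "gene")
            continue
        if len(fields) != 3:
            raise NetworkFormatError(f"{path}:{lineno}: expected 3 fields, got {len(fields)}")
        source, relation, target = fields
        if relation not in _RELATION_TOKENS:
            raise NetworkFormatError(
                f"{path}:{lineno}: unknown relation token {relation!r} "
                f"(expected one of {sorted(_RELATION_TOKENS)})"
            )
        triples.append((source, target, _RELATION_TOKENS[relation]))

    kinds: dict[str, NodeKind] = dict(declared)
    kinds.update(meta.get("kinds", {}))
    kinds.setdefault(resolved_input, "stimulus")
    if not triples and not declared:
        raise NetworkFormatError(f"{path}: empty network file (no input node)")
    net = InteractionNetwork.from_edges(
        triples, input_node=resolved_input, p53_node=resolved_p53, kinds=kinds
    )
    return net


def write_network(net: InteractionNetwork, path: str | Path) -> None:
    """Write *net* as SIF plus a JSON sidecar naming the designated nodes.

    ``read_network(write_network(net))`` round-trips up to node/edge order.
    """
    path = Path(path)
    lines = [f"{e.source}\t{_SIGN_TOKENS[e.sign]}\t{e.target}" for e in net.edges]
    referenced = {e.source for e in net.edges} | {e.target for e in net.edges}
    lines.extend(n for n in net.nodes if n not in referenced)
    path.write_text("\n".join(lines) + "\n")
    sidecar = path.with_name(path.name + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "input_node": net.input_node,
                "p53_node": net.p53_node,
                "kinds": {n.id: n.kind for n in net.nodes.values() if n.kind != "gene"},
            },
            indent=2,
        )
        + "\n"
    )


# -- fixtures and generators ---------------------------------------------------


def toy_p53_network() -> InteractionNetwork:
    """A small documented p53 DNA-damage-response fixture network.

    Twenty nodes around the DNA-damage -> ATM -> TP53 axis with the
    TP53-MDM2 negative feedback (the only cycle), the ATM-mediated relief
    of MDM2 inhibition, a TP53-dependent apoptosis arm
    (APAF1/BAX/CASP9 -> apoptosis) and an E2F1/FOXM1 proliferation arm
    carrying survival-relevant genes (FEN1, MMP2, SIAH1, AURKA, ...).
    Signs encode textbook regulatory logic; the fixture is a plausible
    stand-in for a p53 interactome model, not a reconstruction of any
    published edge list.  Removing TP53 disconnects DNA_damage from the
    apoptosis-side nodes (APAF1, BAX, CASP9, apoptosis), which are reachable
    only through TP53.
    """
    edges = [
        ("DNA_damage", "ATM", +1),
        ("ATM", "TP53", +1),
        ("ATM", "MDM2", -1),       # damage destabilizes MDM2
        ("TP53", "MDM2", +1),      # negative feedback loop (the only cycle)
        ("MDM2", "TP53", -1),
        ("TP53", "CDKN1A", +1),
        ("TP53", "BAX", +1),
        ("TP53", "APAF1", +1),
        ("TP53", "SIAH1", +1),
        ("TP53", "RRM2B", +1),
        ("TP53", "GADD45A", +1),
        ("TP53", "PDRG1", +1),
        ("TP53", "FOXM1", -1),
        ("BAX", "APAF1", +1),
        ("APAF1", "CASP9", +1),
        ("CASP9", "apoptosis", +1),
        ("ATM", "E2F1", +1),
        ("CDKN1A", "E2F1", -1),
        ("CDKN1A", "CCNE1", -1),
        ("E2F1", "FEN1", +1),
        ("E2F1", "CCNE1", +1),
        ("E2F1", "FOXM1", +1),
        ("FOXM1", "AURKA", +1),
        ("FOXM1", "MMP2", +1),
        ("CCNE1", "proliferation", +1),
    ]
    kinds: dict[str, NodeKind] = {
        "DNA_damage": "stimulus",
        "apoptosis": "phenotype",
        "proliferation": "phenotype",
    }
    return InteractionNetwork.from_edges(edges, kinds=kinds)


def random_network(
    n_nodes: int,
    edge_density: float,
    inhibition_fraction: float,
    seed: int,
    acyclic: bool = False,
) -> InteractionNetwork:
    """Generate a reproducible random signed network.

    The input node ``DNA_damage`` has out-edges only; every node is
    guaranteed reachable from it (unreachable nodes are re-wired to a
    reachable parent).  Node ``G001`` doubles as the designated p53 node.
    With ``acyclic=True`` edges only run from lower to higher node index,
    yielding a DAG (useful for comparing solvers against single-pass
    topological evaluation).
    """
    if n_nodes < 3:
        raise ValueError("n_nodes must be >= 3")
    if not (0 < edge_density <= 1):
        raise ValueError("edge_density must be in (0, 1]")
    if not (0 <= inhibition_fraction <= 1):
        raise ValueError("inhibition_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    input_node = DEFAULT_INPUT_NODE
    gene_names = [f"G{i:03d}" for i in range(1, n_nodes)]
    p53 = gene_names[0]

    triples: set[tuple[str, str, int]] = set()

    def draw_sign() -> int:
        return -1 if rng.random() < inhibition_fraction else +1

    # candidate gene-gene edges
    for i, u in enumerate(gene_names):
        for j, v in enumerate(gene_names):
            if i == j or (acyclic and j <= i):
                continue
            if rng.random() < edge_density:
                triples.add((u, v, draw_sign()))
    # input out-edges: seed a handful of direct targets
    n_roots = max(1, int(round(edge_density * (n_nodes - 1))))
    roots = rng.choice(gene_names, size=min(n_roots, len(gene_names)), replace=False)
    for v in roots:
        triples.add((input_node, v, +1))

    # enforce reachability from the input by re-wiring orphans
    def reachable(trs: set[tuple[str, str, int]]) -> set[str]:
        g = nx.DiGraph()
        g.add_nodes_from([input_node, *gene_names])
        g.add_edges_from([(s, t) for s, t, _ in trs])
        return set(nx.descendants(g, input_node)) | {input_node}

    order = {name: i for i, name in enumerate(gene_names)}
    reach = reachable(triples)
    for v in gene_names:
        if v in reach:
            continue
        if acyclic:
            pool = [u for u in reach if u == input_node or order.get(u, -1) < order[v]]
        else:
            pool = sorted(reach)
        parent = pool[int(rng.integers(len(pool)))] if pool else input_node
        sign = +1 if parent == input_node else draw_sign()
        triples.add((parent, v, sign))
        reach = reachable(triples)

    return InteractionNetwork.from_edges(
        sorted(triples), input_node=input_node, p53_node=p53,
        kinds={input_node: "stimulus"},
    )
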