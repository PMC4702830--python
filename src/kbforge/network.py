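"""Incremental concept-network sessions and graph export.

An exploration session starts from a single seed concept and grows by
expanding nodes against chosen dictionaries: each expansion adds the node's
significant association partners from that dictionary, then closes the graph
over the association list (every association whose two endpoints are now
both present becomes an edge). Nodes can be trimmed at any point. Every step
is recorded in a history that is sufficient to replay the session
deterministically.

Node identity is ``(concept_id, dictionary)``; the same concept indexed by
two dictionaries renders as two nodes. Edge attributes are the association's
co-occurring document count (``n_ab``), PMI and FDR; the dictionary of each
node is exported as a categorical attribute (styling is the viewer's job).

Exports: SIF plus an edge-attribute sidecar TSV (Cytoscape-loadable),
GraphML (lossless for nodes/edges; reload with :func:`load_graphml`), and a
plain edge TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .errors import UsageError
from .index import ConceptRef
from .stats import Association, EnrichedConcept

EXPORT_FORMATS = ("sif", "graphml", "edge_tsv")


@dataclass
class ConceptNetwork:
    nodes: dict[ConceptRef, str] = field(default_factory=dict)  # ref -> preferred_name
    edges: dict[frozenset, dict] = field(default_factory=dict)  # {a,b} -> attrs
    history: list[dict] = field(default_factory=list)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ConceptNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_pairs(self) -> set[tuple[ConceptRef, ConceptRef]]:
        return {tuple(sorted(e)) for e in self.edges}


def _names_from(enriched: list[EnrichedConcept]) -> dict[ConceptRef, str]:
    return {e.ref: e.preferred_name for e in enriched}


def seed_network(concept: ConceptRef, enriched: list[EnrichedConcept]) -> ConceptNetwork:
    """Single-node network rooted at an enriched concept."""
    names = _names_from(enriched)
    if concept not in names:
        raise UsageError(
            f"concept {concept} is not in this knowledgebase's enriched set")
    net = ConceptNetwork()
    net.nodes[concept] = names[concept]
    net.history.append({"op": "seed", "concept": list(concept)})
    return net


def _close_over_associations(net: ConceptNetwork, associations: list[Association]) -> int:
    added = 0
    for x in associations:
        if x.concept_a in net.nodes and x.concept_b in net.nodes:
            key = frozenset((x.concept_a, x.concept_b))
            if key not in net.edges:
                net.edges[key] = {"n_ab": x.n_ab, "pmi": x.pmi, "fdr": x.fdr}
                added += 1
    return added


def expand_node(net: ConceptNetwork, node: ConceptRef, dictionary: str,
                associations: list[Association],
                enriched: list[EnrichedConcept],
                top_k: int | None = None) -> ConceptNetwork:
    """Add the node's significant partners from one dictionary (all, or the
    ``top_k`` by FDR), then close the graph over the association list.

    In place; returns ``net``. Idempotent for fixed inputs.
    """
    if node not in net.nodes:
        raise UsageError(f"node {node} is not in the network")
    names = _names_from(enriched)
    partners = []
    for x in associations:
        other = None
        if x.concept_a == node:
            other = x.concept_b
        elif x.concept_b == node:
            other = x.concept_a
        if other is not None and other.dictionary == dictionary:
            partners.append((x.fdr, other))
    partners.sort(key=lambda t: (t[0], t[1]))
    if top_k is not None:
        partners = partners[:top_k]
    for _, other in partners:
        net.nodes.setdefault(other, names.get(other, other.concept_id))
    n_edges = _close_over_associations(net, associations)
    net.history.append({"op": "expand", "node": list(node), "dictionary": dictionary,
                        "top_k": top_k, "added_nodes": len(partners),
                        "added_edges": n_edges})
    return net


def remove_nodes(net: ConceptNetwork, concepts) -> ConceptNetwork:
    """Drop nodes and their incident edges; absent nodes are logged no-ops."""
    concepts = {ConceptRef(*c) if not isinstance(c, ConceptRef) else c
                for c in concepts}
    present = concepts & set(net.nodes)
    for ref in present:
        del net.nodes[ref]
    net.edges = {e: a for e, a in net.edges.items() if not (e & present)}
    net.history.append({"op": "remove",
                        "concepts": sorted([list(c) for c in present]),
                        "ignored": sorted([list(c) for c in concepts - present])})
    return net


def replay(history: list[dict], associations: list[Association],
           enriched: list[EnrichedConcept]) -> ConceptNetwork:
    """Reconstruct a network from its recorded history."""
    net = None
    for step in history:
        op = step["op"]
        if op == "seed":
            net = seed_network(ConceptRef(*step["concept"]), enriched)
        elif op == "expand":
            expand_node(net, ConceptRef(*step["node"]), step["dictionary"],
                        associations, enriched, top_k=step.get("top_k"))
        elif op == "remove":
            remove_nodes(net, [ConceptRef(*c) for c in step["concepts"]
                               + step.get("ignored", [])])
        else:
            raise UsageError(f"unknown history op {op!r}")
    if net is None:
        raise UsageError("history contains no seed step")
    return net


# --- export -----------------------------------------------------------------

def _node_id(ref: ConceptRef) -> str:
    return f"{ref.dictionary}::{ref.concept_id}"


def _parse_node_id(s: str) -> ConceptRef:
    dictionary, concept_id = s.split("::", 1)
    return ConceptRef(concept_id, dictionary)


def to_networkx(net: ConceptNetwork) -> nx.Graph:
    g = nx.Graph()
    for ref in sorted(net.nodes):
        g.add_node(_node_id(ref), concept_id=ref.concept_id,
                   dictionary=ref.dictionary, preferred_name=net.nodes[ref])
    for key in sorted(net.edges, key=lambda e: tuple(sorted(e))):
        a, b = sorted(key)
        attrs = net.edges[key]
        g.add_edge(_node_id(a), _node_id(b), n_ab=int(attrs["n_ab"]),
                   pmi=float(attrs["pmi"]), fdr=float(attrs["fdr"]))
    return g


def from_networkx(g: nx.Graph) -> ConceptNetwork:
    net = ConceptNetwork()
    for node, data in g.nodes(data=True):
        ref = ConceptRef(data.get("concept_id"), data.get("dictionary")) \
            if "concept_id" in data else _parse_node_id(node)
        net.nodes[ref] = data.get("preferred_name", ref.concept_id)
    for u, v, data in g.edges(data=True):
        key = frozenset((_parse_node_id(u), _parse_node_id(v)))
        net.edges[key] = {"n_ab": int(data["n_ab"]), "pmi": float(data["pmi"]),
                          "fdr": float(data["fdr"])}
    return net


def export_network(net: ConceptNetwork, fmt: str, path) -> None:
    """Write the network as ``sif`` (+ ``<path>.edges.tsv`` sidecar),
    ``graphml`` or ``edge_tsv``. SIF/GraphML require a non-empty network."""
    if fmt not in EXPORT_FORMATS:
        raise UsageError(f"unknown export format {fmt!r}; choose from {EXPORT_FORMATS}")
    if fmt in ("sif", "graphml") and not net.nodes:
        raise UsageError(f"cannot export an empty network as {fmt}")
    if fmt == "graphml":
        nx.write_graphml(to_networkx(net), path)
        return
    edges = sorted(net.edges, key=lambda e: tuple(sorted(e)))
    if fmt == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            connected = set()
            for key in edges:
                a, b = sorted(key)
                connected |= {a, b}
                fh.write(f"{_node_id(a)}\tco_occurs\t{_node_id(b)}\n")
            for ref in sorted(set(net.nodes) - connected):
                fh.write(f"{_node_id(ref)}\n")
        _write_edge_tsv(net, edges, str(path) + ".edges.tsv")
        return
    _write_edge_tsv(net, edges, path)


def _write_edge_tsv(net: ConceptNetwork, edges, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("concept_a\tdictionary_a\tconcept_b\tdictionary_b\tn_ab\tpmi\tfdr\n")
        for key in edges:
            a, b = sorted(key)
            attrs = net.edges[key]
            fh.write(f"{a.concept_id}\t{a.dictionary}\t{b.concept_id}\t{b.dictionary}\t"
                     f"{attrs['n_ab']}\t{attrs['pmi']:.6g}\t{attrs['fdr']:.6g}\n")


def load_graphml(path) -> ConceptNetwork:
    return from_networkx(nx.read_graphml(path))
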