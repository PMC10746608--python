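"""Regulatory and protein-interaction networks over a candidate-TF set.

Regulatory edges are directed regulator -> target and come from TF-target
library membership (u -> v when v belongs to one of u's experiment sets);
parallel edges from multiple experiments are collapsed with the experiment
count retained.  Protein-interaction edges are undirected and overlaid from
an interaction table, restricted to pairs touching the network's nodes.
Hubs are ranked by distinct-partner counts against named reference lists
(e.g. the two candidate-TF lists), with regulatory out-degree as the
tie-break; both raw counts are always reported so users can re-rank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import networkx as nx

from .io import GeneSetLibrary, InteractionTable, normalize_symbol

logger = logging.getLogger("coretf")

__all__ = [
    "TFNetwork",
    "build_regulatory_network",
    "add_ppi_overlay",
    "rank_hubs",
    "remove_node",
    "to_networkx",
    "write_edge_list",
    "write_node_stats",
    "write_graphml",
]


@dataclass(frozen=True)
class TFNetwork:
    """Directed regulatory edges plus undirected PPI edges over TF nodes.

    ``regulatory_edges`` maps (regulator, target) to the supporting
    experiment set names; ``ppi_edges`` maps canonical unordered pairs to a
    source tag tuple.  ``node_stats`` carries, per node, the regulatory
    out-degree within the node set and distinct-partner counts against each
    named reference list; it is always recomputable from the edges.
    """

    nodes: tuple[str, ...]
    regulatory_edges: Mapping[tuple[str, str], tuple[str, ...]] = field(default_factory=dict)
    ppi_edges: Mapping[tuple[str, str], tuple[str, ...]] = field(default_factory=dict)
    node_stats: Mapping[str, dict] = field(default_factory=dict)
    reference_lists: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for u, v in self.regulatory_edges:
            if u not in node_set or v not in node_set:
                raise ValueError(f"regulatory edge {(u, v)} leaves the node set")
        for a, b in self.ppi_edges:
            if a not in node_set and b not in node_set:
                raise ValueError(f"ppi edge {(a, b)} touches no node")

    def out_degree(self, node: str) -> int:
        return sum(1 for (u, _v) in self.regulatory_edges if u == node)

    def partners(self, node: str) -> set[str]:
        out: set[str] = set()
        for a, b in self.ppi_edges:
            if a == node:
                out.add(b)
            elif b == node:
                out.add(a)
        return out


def _compute_stats(
    nodes: Sequence[str],
    regulatory_edges: Mapping[tuple[str, str], tuple[str, ...]],
    ppi_edges: Mapping[tuple[str, str], tuple[str, ...]],
    reference_lists: Mapping[str, frozenset[str]],
) -> dict[str, dict]:
    stats: dict[str, dict] = {}
    for node in nodes:
        partners: set[str] = set()
        for a, b in ppi_edges:
            if a == node:
                partners.add(b)
            elif b == node:
                partners.add(a)
        per_ref = {
            ref: len(partners & members) for ref, members in reference_lists.items()
        }
        stats[node] = {
            "regulatory_out_degree": sum(1 for (u, _v) in regulatory_edges if u == node),
            "partners": per_ref,
            "partner_total": sum(per_ref.values()),
        }
    return stats


def build_regulatory_network(
    tfs: Sequence[str],
    tf_library: GeneSetLibrary,
) -> TFNetwork:
    """Directed TF -> TF regulation network from target-set membership.

    Edge u -> v exists iff v is a member of at least one of u's experiment
    sets, for u, v both in ``tfs`` (self-loops included when a TF targets
    itself).  Each edge records the supporting set names.
    """
    nodes = tuple(sorted({normalize_symbol(t) for t in tfs if normalize_symbol(t)}))
    if not nodes:
        raise ValueError("empty TF list")
    node_set = set(nodes)
    edges: dict[tuple[str, str], list[str]] = {}
    for tf, sets in tf_library.sets_by_tf().items():
        if tf not in node_set:
            continue
        for s in sets:
            for v in node_set & s.members:
                edges.setdefault((tf, v), []).append(s.name)
    reg = {e: tuple(sorted(names)) for e, names in sorted(edges.items())}
    if not reg:
        logger.info("build_regulatory_network: no library sets for %d nodes", len(nodes))
    return TFNetwork(
        nodes=nodes,
        regulatory_edges=reg,
        node_stats=_compute_stats(nodes, reg, {}, {}),
    )


def add_ppi_overlay(
    network: TFNetwork,
    interactions: InteractionTable,
    reference_lists: Mapping[str, Sequence[str]],
) -> TFNetwork:
    """Overlay undirected interaction edges and per-reference partner counts.

    Kept edges have at least one endpoint among the network nodes and the
    other endpoint in the nodes or any reference list.  For each node and
    each reference list, the count of *distinct* partner symbols in that
    list is recorded (a self-pair contributes the node itself as one
    partner).  Idempotent for a fixed interaction table: the overlay is
    recomputed from scratch, never accumulated.
    """
    refs = {
        name: frozenset(normalize_symbol(s) for s in members)
        for name, members in reference_lists.items()
    }
    node_set = set(network.nodes)
    allowed = node_set | set().union(*refs.values()) if refs else node_set
    ppi: dict[tuple[str, str], tuple[str, ...]] = {}
    for (a, b) in interactions.pairs():
        if (a in node_set and b in allowed) or (b in node_set and a in allowed):
            ppi[(a, b)] = interactions.sources.get((a, b), ())
    return replace(
        network,
        ppi_edges=ppi,
        reference_lists=refs,
        node_stats=_compute_stats(network.nodes, network.regulatory_edges, ppi, refs),
    )


def rank_hubs(network: TFNetwork) -> list[tuple[str, dict]]:
    """Nodes ordered by hub score, with their raw counts.

    Primary key: total distinct-partner count across reference lists
    (descending); tie-break: regulatory out-degree (descending), then name
    (ascending).  Returns (node, stats) pairs.
    """
    stats = network.node_stats
    ordered = sorted(
        network.nodes,
        key=lambda t: (
            -stats[t]["partner_total"],
            -stats[t]["regulatory_out_degree"],
            t,
        ),
    )
    return [(t, dict(stats[t])) for t in ordered]


def remove_node(network: TFNetwork, node: str) -> TFNetwork:
    """A copy of the network without ``node`` and its incident edges."""
    sym = normalize_symbol(node)
    nodes = tuple(t for t in network.nodes if t != sym)
    reg = {e: s for e, s in network.regulatory_edges.items() if sym not in e}
    ppi = {
        e: s for e, s in network.ppi_edges.items()
        if sym not in e and (e[0] in nodes or e[1] in nodes)
    }
    return TFNetwork(
        nodes=nodes,
        regulatory_edges=reg,
        ppi_edges=ppi,
        reference_lists=network.reference_lists,
        node_stats=_compute_stats(nodes, reg, ppi, network.reference_lists),
    )


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def to_networkx(network: TFNetwork) -> nx.MultiDiGraph:
    """Export as a MultiDiGraph: regulatory edges directed with experiment
    counts; PPI edges stored once with ``undirected=True``."""
    g = nx.MultiDiGraph()
    for node in network.nodes:
        stats = network.node_stats.get(node, {})
        g.add_node(
            node,
            regulatory_out_degree=stats.get("regulatory_out_degree", 0),
            partner_total=stats.get("partner_total", 0),
        )
    for (u, v), names in network.regulatory_edges.items():
        g.add_edge(u, v, type="regulatory", n_experiments=len(names))
    for (a, b), sources in network.ppi_edges.items():
        g.add_node(a)
        g.add_node(b)
        g.add_edge(a, b, type="ppi", undirected=True, source=";".join(sources))
    return g


def write_edge_list(network: TFNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\ttype\tn_experiments\tsources\n")
        for (u, v), names in sorted(network.regulatory_edges.items()):
            fh.write(f"{u}\t{v}\tregulatory\t{len(names)}\t{';'.join(names)}\n")
        for (a, b), sources in sorted(network.ppi_edges.items()):
            fh.write(f"{a}\t{b}\tppi\t\t{';'.join(sources)}\n")


def write_node_stats(network: TFNetwork, path: str | Path) -> None:
    ref_names = sorted(network.reference_lists)
    with open(path, "w") as fh:
        cols = ["tf", "regulatory_out_degree", *(f"partners_{r}" for r in ref_names), "partner_total"]
        fh.write("\t".join(cols) + "\n")
        for node in network.nodes:
            s = network.node_stats[node]
            row = [node, str(s["regulatory_out_degree"])]
            row += [str(s["partners"].get(r, 0)) for r in ref_names]
            row.append(str(s["partner_total"]))
            fh.write("\t".join(row) + "\n")


def write_graphml(network: TFNetwork, path: str | Path) -> None:
    nx.write_graphml(to_networkx(network), path)
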