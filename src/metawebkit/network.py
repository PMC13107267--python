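"""Weighted, directed, multilayer seasonal metaweb assembly and queries.

The metaweb is the regional pool of potential interactions: a directed
unipartite graph whose edges run resource -> consumer (the direction of
energy flow) and carry the interaction layer (Pr, Sc, He, Po, Kl, ...),
season, scaled strength and provenance. Layers live side by side as parallel
edge sets in one ``networkx.MultiDiGraph``; pollination edges stay in the
same unipartite graph (plant -> pollinator, energy via nectar and pollen)
and kleptoparasitism edges run from the robbed victim to the kleptoparasite.

Layers backed by too few measured links to be resolved reliably can be
dropped wholesale, and subwebs (induced consumer-set x resource-set x layer
restrictions) extracted for focused analysis. Per-consumer profiles split a
consumer's incoming strength by the realm of its resources, quantifying
marine-terrestrial energy crossover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .records import NodeInfo, Season
from .scaling import (
    PROVENANCE_MEASURED,
    ScaledLink,
    read_links,
    write_links,
)

SEASON_FILTERS = ("summer", "winter", "both")


@dataclass
class Metaweb:
    """A multilayer seasonal metaweb.

    ``graph`` is a MultiDiGraph with node attributes (label, guild, realm,
    n_species, flagship) and one edge per (consumer, resource, layer, season)
    key, directed resource -> consumer with the strength as weight.
    """

    graph: nx.MultiDiGraph
    included_layers: frozenset[str] = field(default_factory=frozenset)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def links(self) -> list[ScaledLink]:
        out = []
        for resource, consumer, data in self.graph.edges(data=True):
            out.append(ScaledLink(
                consumer=consumer,
                resource=resource,
                layer=data["layer"],
                season=Season(data["season"]),
                strength=data["strength"],
                n_studies=data["n_studies"],
                provenance=data["provenance"],
            ))
        out.sort(key=lambda ln: (ln.consumer, ln.resource, ln.layer, ln.season.value))
        return out

    def node_info(self, node_id: str) -> NodeInfo:
        d = self.graph.nodes[node_id]
        return NodeInfo(node_id=node_id, **{
            k: d[k] for k in ("label", "guild", "realm", "n_species", "flagship")
        })


@dataclass
class ConsumerProfile:
    """A consumer's seasonal resource spectrum and realm split.

    ``realm_split`` maps realm -> fraction of the consumer's total incoming
    strength; it is ``None`` (undefined) when the consumer receives no
    energy edges under the requested filter.
    """

    consumer: str
    season: str
    entries: list[tuple[str, str, float]]  # (resource, layer, strength)
    total_strength: float
    realm_split: dict[str, float] | None


def _edge_key(layer: str, season: Season) -> str:
    return f"{layer}:{season.value}"


def build_metaweb(
    links: Sequence[ScaledLink],
    nodes: Mapping[str, NodeInfo],
    season: str = "both",
) -> Metaweb:
    """Assemble a metaweb from scaled links and a node table.

    ``season`` selects 'summer', 'winter' or 'both'. Zero-strength links are
    dropped (an absent interaction is no edge); duplicate
    (consumer, resource, layer, season) keys and endpoints missing from the
    node table raise ``ValueError``.
    """
    if season not in SEASON_FILTERS:
        raise ValueError(f"season filter {season!r} not in {SEASON_FILTERS}")
    g = nx.MultiDiGraph()
    for node in nodes.values():
        g.add_node(
            node.node_id,
            label=node.label,
            guild=node.guild,
            realm=node.realm,
            n_species=node.n_species,
            flagship=node.flagship,
        )
    layers: set[str] = set()
    seen: set[tuple] = set()
    for ln in links:
        if season != "both" and ln.season.value != season:
            continue
        if ln.strength == 0:
            continue
        for endpoint in (ln.consumer, ln.resource):
            if endpoint not in nodes:
                raise ValueError(f"link endpoint {endpoint!r} absent from node table")
        if ln.key in seen:
            raise ValueError(
                f"duplicate link key {ln.consumer}<-{ln.resource} "
                f"[{ln.layer}, {ln.season.value}]"
            )
        seen.add(ln.key)
        g.add_edge(
            ln.resource, ln.consumer,
            key=_edge_key(ln.layer, ln.season),
            layer=ln.layer,
            season=ln.season.value,
            strength=ln.strength,
            n_studies=ln.n_studies,
            provenance=ln.provenance,
        )
        layers.add(ln.layer)
    return Metaweb(graph=g, included_layers=frozenset(layers))


def exclude_sparse_layers(
    metaweb: Metaweb, min_links: int = 3
) -> tuple[Metaweb, dict[str, dict]]:
    """Drop layers with fewer than ``min_links`` measured links.

    Case-only and extrapolated links do not count toward a layer's support;
    a layer kept alive only by anecdotes is considered unresolved and all of
    its edges (whatever their provenance) are removed. Returns the reduced
    metaweb and a per-layer report of measured-link counts.
    """
    if min_links < 1:
        raise ValueError("min_links must be >= 1")
    measured_counts: dict[str, int] = {layer: 0 for layer in metaweb.included_layers}
    for _, _, data in metaweb.graph.edges(data=True):
        if data["provenance"] == PROVENANCE_MEASURED:
            measured_counts[data["layer"]] += 1
    dropped = {
        layer for layer, n in measured_counts.items() if n < min_links
    }
    g = metaweb.graph.copy()
    g.remove_edges_from([
        (u, v, k) for u, v, k, data in g.edges(keys=True, data=True)
        if data["layer"] in dropped
    ])
    report = {
        layer: {
            "measured_links": measured_counts[layer],
            "dropped": layer in dropped,
        }
        for layer in sorted(measured_counts)
    }
    kept = frozenset(metaweb.included_layers - dropped)
    return Metaweb(graph=g, included_layers=kept), report


def extract_subweb(
    metaweb: Metaweb,
    consumers: Iterable[str],
    resources: Iterable[str],
    layers: Iterable[str],
) -> Metaweb:
    """Induced subweb: edges from the resource set to the consumer set in the
    named layers, over the union of both node sets."""
    consumers = set(consumers)
    resources = set(resources)
    layers = set(layers)
    unknown = (consumers | resources) - set(metaweb.graph.nodes)
    if unknown:
        raise ValueError(f"unknown node ids in subweb request: {sorted(unknown)}")
    g = nx.MultiDiGraph()
    for node in consumers | resources:
        g.add_node(node, **metaweb.graph.nodes[node])
    present: set[str] = set()
    for u, v, k, data in metaweb.graph.edges(keys=True, data=True):
        if u in resources and v in consumers and data["layer"] in layers:
            g.add_edge(u, v, key=k, **data)
            present.add(data["layer"])
    return Metaweb(graph=g, included_layers=frozenset(present))


def crossover_summary(
    metaweb: Metaweb, consumer: str, season: str = "both"
) -> ConsumerProfile:
    """Split a consumer's incoming interaction strength by resource realm.

    Quantifies marine-terrestrial energy crossover: a terrestrial predator
    drawing half its scaled intake from marine resources has marine
    fraction 0.5.
    """
    if consumer not in metaweb.graph.nodes:
        raise ValueError(f"consumer {consumer!r} not in metaweb")
    if season not in SEASON_FILTERS:
        raise ValueError(f"season filter {season!r} not in {SEASON_FILTERS}")
    entries: list[tuple[str, str, float]] = []
    buckets: dict[str, float] = {}
    total = 0.0
    for resource, _, data in metaweb.graph.in_edges(consumer, data=True):
        if season != "both" and data["season"] != season:
            continue
        entries.append((resource, data["layer"], data["strength"]))
        realm = metaweb.graph.nodes[resource]["realm"]
        buckets[realm] = buckets.get(realm, 0.0) + data["strength"]
        total += data["strength"]
    entries.sort(key=lambda e: (-e[2], e[0], e[1]))
    if total > 0:
        split = {realm: s / total for realm, s in sorted(buckets.items())}
    else:
        split = None
    return ConsumerProfile(
        consumer=consumer, season=season, entries=entries,
        total_strength=total, realm_split=split,
    )


def network_summary(metaweb: Metaweb) -> pd.DataFrame:
    """Per layer and season: link count, nodes touched, strength stats."""
    rows = []
    groups: dict[tuple[str, str], list[tuple[str, str, float]]] = {}
    for u, v, data in metaweb.graph.edges(data=True):
        groups.setdefault((data["layer"], data["season"]), []).append(
            (u, v, data["strength"])
        )
    for (layer, season), edges in sorted(groups.items()):
        strengths = [s for _, _, s in edges]
        touched = {u for u, _, _ in edges} | {v for _, v, _ in edges}
        rows.append({
            "layer": layer,
            "season": season,
            "n_links": len(edges),
            "n_nodes": len(touched),
            "strength_min": min(strengths),
            "strength_mean": sum(strengths) / len(strengths),
            "strength_max": max(strengths),
            "strength_total": sum(strengths),
        })
    return pd.DataFrame(
        rows,
        columns=["layer", "season", "n_links", "n_nodes", "strength_min",
                 "strength_mean", "strength_max", "strength_total"],
    )


# ---------------------------------------------------------------------------
# export / import


def write_edge_csv(metaweb: Metaweb, path: str | Path) -> None:
    write_links(metaweb.links(), path)


def read_edge_csv(
    path: str | Path, nodes: Mapping[str, NodeInfo], season: str = "both"
) -> Metaweb:
    return build_metaweb(read_links(path), nodes, season=season)


def write_graphml(metaweb: Metaweb, path: str | Path) -> None:
    """GraphML export with strengths serialized as one-decimal strings so a
    round-trip reproduces weights bit-exactly."""
    g = nx.MultiDiGraph()
    for node, data in metaweb.graph.nodes(data=True):
        attrs = dict(data)
        attrs["flagship"] = str(attrs.get("flagship", False)).lower()
        g.add_node(node, **attrs)
    for u, v, k, data in metaweb.graph.edges(keys=True, data=True):
        attrs = dict(data)
        attrs["strength"] = f"{data['strength']:.1f}"
        g.add_edge(u, v, key=k, **attrs)
    g.graph["included_layers"] = ";".join(sorted(metaweb.included_layers))
    nx.write_graphml(g, path)


def read_graphml(path: str | Path) -> Metaweb:
    g_raw = nx.read_graphml(path, force_multigraph=True)
    g = nx.MultiDiGraph()
    for node, data in g_raw.nodes(data=True):
        attrs = dict(data)
        attrs["n_species"] = int(attrs["n_species"])
        attrs["flagship"] = str(attrs["flagship"]).lower() == "true"
        g.add_node(node, **attrs)
    for u, v, k, data in g_raw.edges(keys=True, data=True):
        attrs = dict(data)
        attrs["strength"] = float(attrs["strength"])
        attrs["n_studies"] = int(attrs["n_studies"])
        g.add_edge(u, v, key=k, **attrs)
    layers_attr = g_raw.graph.get("included_layers", "")
    layers = frozenset(l for l in layers_attr.split(";") if l)
    return Metaweb(graph=g, included_layers=layers)
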