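"""Completeness and accuracy evaluation of a knowledge graph.

Completeness: topology statistics (node/edge counts, degree distribution,
density, log-log degree slope).  Accuracy: contradiction count, agreement of
closeness-centrality rankings and maximum-k-core membership with prior
knowledge.

Conventions: all metrics use the undirected view; by default M counts
triples (each parallel relation between the same endpoints counts), with a
deduplicated distinct-endpoint-pair mode behind ``edge_mode="pairs"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import numpy as np

from ._util import round4
from .completion_implicit import detect_contradictions
from .errors import EntityLookupError, UsageError
from .kg_model import KnowledgeGraph

logger = logging.getLogger(__name__)


@dataclass
class PriorKnowledge:
    """Domain prior: core prescription labels and exterior-pattern symptom
    labels used in accuracy checks."""

    core_prescriptions: set[str] = field(default_factory=set)
    exterior_symptoms: set[str] = field(default_factory=set)


@dataclass
class CompletenessReport:
    node_count: int
    relation_count: int
    largest_degree: int
    average_degree: float
    density: float
    degree_slope: float

    def to_dict(self) -> dict:
        return {
            "node_count": self.node_count,
            "relation_count": self.relation_count,
            "largest_degree": self.largest_degree,
            "average_degree": self.average_degree,
            "density": self.density,
            "degree_slope": self.degree_slope,
        }


@dataclass
class AccuracyReport:
    contradiction_count: int
    top_k_closeness_nodes: list[str]
    core_prescription_proportion: float
    max_kcore: int
    max_kcore_nodes: set[str]
    prior_proportion: float

    def to_dict(self) -> dict:
        return {
            "contradiction_count": self.contradiction_count,
            "top_k_closeness_nodes": list(self.top_k_closeness_nodes),
            "core_prescription_proportion": self.core_prescription_proportion,
            "max_kcore": self.max_kcore,
            "max_kcore_nodes": sorted(self.max_kcore_nodes),
            "prior_proportion": self.prior_proportion,
        }


# ----------------------------------------------------------- completeness
def average_degree(n_nodes: int, n_edges: int) -> float:
    """<k> = 2M/N on the undirected convention, to 4 decimals."""
    if n_nodes < 1:
        raise UsageError("average_degree needs N >= 1")
    if n_edges < 0:
        raise UsageError("edge count must be >= 0")
    return round4(2.0 * n_edges / n_nodes)


def network_density(n_nodes: int, n_edges: int) -> float:
    """rho = 2M / (N (N-1)), to 4 decimals."""
    if n_nodes < 2:
        raise UsageError("network_density needs N >= 2")
    return round4(2.0 * n_edges / (n_nodes * (n_nodes - 1)))


def degree_slope(degrees: Iterable[int]) -> float:
    """Least-squares slope of log10(count) vs log10(degree) over nonzero
    histogram bins (degree >= 1).  NaN when fewer than 2 bins exist."""
    degs = np.asarray([d for d in degrees if d >= 1], dtype=int)
    if degs.size == 0:
        return float("nan")
    values, counts = np.unique(degs, return_counts=True)
    if values.size < 2:
        return float("nan")
    slope = np.polyfit(np.log10(values), np.log10(counts), 1)[0]
    return float(slope)


def completeness_report(
    kg: KnowledgeGraph, edge_mode: str = "triples"
) -> CompletenessReport:
    """Topology summary of the graph.

    ``edge_mode="triples"`` (default) counts every triple as an edge;
    ``"pairs"`` counts distinct unordered endpoint pairs.  Degrees are taken
    on the matching undirected view so <k> = 2M/N holds exactly.
    """
    n = kg.n_entities()
    if edge_mode == "triples":
        g = kg.undirected_view(multigraph=True)
    elif edge_mode == "pairs":
        g = kg.undirected_view(multigraph=False)
    else:
        raise UsageError(f"unknown edge_mode {edge_mode!r}")
    m = g.number_of_edges()
    degrees = [d for _, d in g.degree()]
    if n >= 2:
        density = network_density(n, m)
    else:
        logger.warning("completeness_report: single-node graph; density "
                       "reported as 0")
        density = 0.0
    return CompletenessReport(
        node_count=n,
        relation_count=m,
        largest_degree=max(degrees) if degrees else 0,
        average_degree=average_degree(n, m),
        density=density,
        degree_slope=degree_slope(degrees),
    )


# --------------------------------------------------------------- accuracy
def closeness_centrality(kg: KnowledgeGraph, node: str) -> float:
    """Component-restricted closeness with size scaling.

    CC(i) = (Nc - 1) / sum_j d_ij within i's component, scaled by
    (Nc - 1)/(N - 1) so values are comparable across components.  Isolated
    nodes score 0.
    """
    if node not in kg.entities:
        raise EntityLookupError(f"unknown node {node!r}")
    g = kg.undirected_view()
    dist = nx.single_source_shortest_path_length(g, node)
    nc = len(dist)
    if nc <= 1 or kg.n_entities() <= 1:
        return 0.0
    total = sum(dist.values())
    return (nc - 1) / total * (nc - 1) / (kg.n_entities() - 1)


def top_closeness_proportion(
    kg: KnowledgeGraph,
    entity_type: str,
    k: int,
    prior: PriorKnowledge,
) -> tuple[list[str], float]:
    """Top-k entities of a type ranked by closeness, and the fraction of
    them found in the prior core-prescription set (matched on labels)."""
    if not prior.core_prescriptions:
        raise UsageError("prior core_prescriptions is empty")
    entities = kg.entities_of_type(entity_type)
    if not entities:
        raise UsageError(f"no entities of type {entity_type!r}")
    if len(entities) < k:
        logger.warning(
            "top_closeness_proportion: only %d %s entities for k=%d",
            len(entities), entity_type, k,
        )
    g = kg.undirected_view()
    n = kg.n_entities()
    cc = {}
    for e in entities:
        dist = nx.single_source_shortest_path_length(g, e.id)
        nc = len(dist)
        cc[e.id] = (
            0.0
            if nc <= 1 or n <= 1
            else (nc - 1) / sum(dist.values()) * (nc - 1) / (n - 1)
        )
    ranked = sorted(entities, key=lambda e: (-cc[e.id], e.label))
    top = ranked[: min(k, len(ranked))]
    hits = sum(1 for e in top if e.label in prior.core_prescriptions)
    return [e.id for e in top], round4(hits / k)


def kcore_analysis(
    kg: KnowledgeGraph, entity_type: str, prior: PriorKnowledge
) -> tuple[int, set[str], float]:
    """Maximum core number, the entities of the type in it, and the fraction
    of those whose label is in the prior exterior-symptom set."""
    g = kg.undirected_view()
    g.remove_edges_from(nx.selfloop_edges(g))
    if g.number_of_edges() == 0:
        raise UsageError("kcore_analysis needs at least one edge")
    core = nx.core_number(g)
    max_core = max(core.values())
    nodes = {
        n for n, c in core.items()
        if c == max_core and kg.entity(n).entity_type == entity_type
    }
    if not nodes:
        return max_core, set(), 0.0
    hits = sum(1 for n in nodes if kg.entity(n).label in prior.exterior_symptoms)
    return max_core, nodes, round4(hits / len(nodes))


def accuracy_report(
    kg: KnowledgeGraph,
    prior: PriorKnowledge,
    closeness_type: str = "Prescription",
    kcore_type: str = "Symptom",
    k: int = 20,
) -> AccuracyReport:
    """Bundle contradiction count, top-k closeness agreement and max-k-core
    agreement with prior knowledge."""
    contradictions = detect_contradictions(kg)
    if prior.core_prescriptions:
        top_nodes, core_prop = top_closeness_proportion(
            kg, closeness_type, k, prior
        )
    else:
        top_nodes, core_prop = [], 0.0
    max_core, core_nodes, prior_prop = kcore_analysis(kg, kcore_type, prior)
    return AccuracyReport(
        contradiction_count=len(contradictions),
        top_k_closeness_nodes=top_nodes,
        core_prescription_proportion=core_prop,
        max_kcore=max_core,
        max_kcore_nodes=core_nodes,
        prior_proportion=prior_prop,
    )
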