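"""Typed knowledge-graph data model, schema validation and TSV/JSON I/O.

A graph is a set of typed entities plus a set of directed, provenance-tagged
triples validated against an :class:`OntologySchema`.  All topology metrics in
the toolkit operate on the undirected view of the graph; triples themselves
remain directed (head -> tail).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx

from .errors import EntityLookupError, ParseError, SchemaViolationError

logger = logging.getLogger(__name__)

#: Provenance tags a triple may carry.
PROVENANCE_TAGS = frozenset(
    {
        "original",
        "outlier_completion",
        "path_reasoning",
        "ontology_reasoning",
        "association_rule",
    }
)

#: Entity type assigned to ids missing from the schema's type map.
UNTYPED = "Other"


@dataclass(frozen=True)
class Entity:
    """A node of the graph: an opaque id, a display label and a type."""

    id: str
    label: str = ""
    entity_type: str = UNTYPED

    def __post_init__(self) -> None:
        if not self.label:
            object.__setattr__(self, "label", self.id)


@dataclass(frozen=True)
class RelationSpec:
    """Schema-level description of one relation.

    ``domain`` / ``range_type`` constrain the entity types of head and tail
    ("any" disables the check).  ``transitive``/``symmetric`` enable ontology
    closure; ``exclusive_with`` names a relation that may not co-occur on the
    same (head, tail) pair.
    """

    name: str
    domain: str = "any"
    range_type: str = "any"
    transitive: bool = False
    symmetric: bool = False
    exclusive_with: str | None = None


@dataclass(frozen=True)
class Triple:
    """A directed (head, relation, tail) assertion.

    Provenance does not participate in equality: a graph holds at most one
    triple per (head, relation, tail) key.
    """

    head: str
    relation: str
    tail: str
    provenance: str = field(default="original", compare=False)

    def key(self) -> tuple[str, str, str]:
        return (self.head, self.relation, self.tail)

    def with_provenance(self, provenance: str) -> "Triple":
        return replace(self, provenance=provenance)


class OntologySchema:
    """Declared entity types, relation specs and an id -> type map."""

    def __init__(
        self,
        entity_types: Iterable[str],
        relations: Iterable[RelationSpec],
        entity_type_map: Mapping[str, str] | None = None,
    ) -> None:
        self.entity_types: set[str] = set(entity_types) | {UNTYPED}
        self.relations: dict[str, RelationSpec] = {}
        for spec in relations:
            if spec.name in self.relations:
                raise SchemaViolationError(f"duplicate relation {spec.name!r}")
            self.relations[spec.name] = spec
        self.entity_type_map: dict[str, str] = dict(entity_type_map or {})
        self._validate()

    def _validate(self) -> None:
        for spec in self.relations.values():
            for t in (spec.domain, spec.range_type):
                if t != "any" and t not in self.entity_types:
                    raise SchemaViolationError(
                        f"relation {spec.name!r}: undeclared type {t!r}"
                    )
            if spec.exclusive_with == spec.name:
                raise SchemaViolationError(
                    f"relation {spec.name!r} cannot exclude itself"
                )
        # Exclusivity is symmetric at schema level: normalize missing halves.
        for spec in list(self.relations.values()):
            other = spec.exclusive_with
            if other is None:
                continue
            if other not in self.relations:
                raise SchemaViolationError(
                    f"relation {spec.name!r} excludes undeclared {other!r}"
                )
            peer = self.relations[other]
            if peer.exclusive_with is None:
                self.relations[other] = replace(peer, exclusive_with=spec.name)
            elif peer.exclusive_with != spec.name:
                raise SchemaViolationError(
                    f"inconsistent exclusivity between {spec.name!r} and {other!r}"
                )
        for ent_id, t in self.entity_type_map.items():
            if t not in self.entity_types:
                raise SchemaViolationError(
                    f"entity {ent_id!r} mapped to undeclared type {t!r}"
                )

    def relation(self, name: str) -> RelationSpec:
        try:
            return self.relations[name]
        except KeyError:
            raise SchemaViolationError(f"undeclared relation {name!r}") from None

    def entity_type_of(self, entity_id: str) -> str:
        return self.entity_type_map.get(entity_id, UNTYPED)

    def exclusivity_pairs(self) -> list[tuple[str, str]]:
        """Unordered exclusivity pairs, each emitted once, sorted."""
        seen = set()
        out = []
        for spec in self.relations.values():
            if spec.exclusive_with is None:
                continue
            pair = tuple(sorted((spec.name, spec.exclusive_with)))
            if pair not in seen:
                seen.add(pair)
                out.append(pair)
        return sorted(out)

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_dict(cls, data: Mapping) -> "OntologySchema":
        relations = [
            RelationSpec(
                name=r["name"],
                domain=r.get("domain", "any"),
                range_type=r.get("range", "any"),
                transitive=bool(r.get("transitive", False)),
                symmetric=bool(r.get("symmetric", False)),
                exclusive_with=r.get("exclusive_with"),
            )
            for r in data.get("relations", [])
        ]
        return cls(
            entity_types=data.get("entity_types", []),
            relations=relations,
            entity_type_map=data.get("entity_type_map", {}),
        )

    def to_dict(self) -> dict:
        return {
            "entity_types": sorted(self.entity_types),
            "relations": [
                {
                    "name": s.name,
                    "domain": s.domain,
                    "range": s.range_type,
                    "transitive": s.transitive,
                    "symmetric": s.symmetric,
                    "exclusive_with": s.exclusive_with,
                }
                for s in sorted(self.relations.values(), key=lambda s: s.name)
            ],
            "entity_type_map": dict(sorted(self.entity_type_map.items())),
        }

    @classmethod
    def load(cls, path: str | Path) -> "OntologySchema":
        with open(path, encoding="utf-8") as fh:
            try:
                data = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ParseError(f"{path}: invalid schema JSON: {exc}") from exc
        return cls.from_dict(data)

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, ensure_ascii=False, indent=2)


class KnowledgeGraph:
    """Entities + triples + schema, with set semantics on triples."""

    def __init__(
        self,
        schema: OntologySchema,
        entities: Iterable[Entity] = (),
        triples: Iterable[Triple] = (),
    ) -> None:
        self.schema = schema
        self._entities: dict[str, Entity] = {}
        self._triples: dict[tuple[str, str, str], Triple] = {}
        for e in entities:
            self.add_entity(e)
        for t in triples:
            self.add_triple(t)

    # ----------------------------------------------------------- accessors
    @property
    def entities(self) -> dict[str, Entity]:
        return self._entities

    @property
    def triples(self) -> set[Triple]:
        return set(self._triples.values())

    def __contains__(self, item) -> bool:
        if isinstance(item, Triple):
            return item.key() in self._triples
        return item in self._entities

    def has_triple(self, head: str, relation: str, tail: str) -> bool:
        return (head, relation, tail) in self._triples

    def __len__(self) -> int:
        return len(self._triples)

    def n_entities(self) -> int:
        return len(self._entities)

    def entity(self, entity_id: str) -> Entity:
        try:
            return self._entities[entity_id]
        except KeyError:
            raise EntityLookupError(f"unknown entity {entity_id!r}") from None

    def entities_of_type(self, entity_type: str) -> list[Entity]:
        return sorted(
            (e for e in self._entities.values() if e.entity_type == entity_type),
            key=lambda e: e.id,
        )

    def triples_of(self, relation: str) -> list[Triple]:
        return sorted(
            (t for t in self._triples.values() if t.relation == relation),
            key=Triple.key,
        )

    def label_to_id(self) -> dict[str, str]:
        """Label -> id map; on label collisions the smallest id wins."""
        out: dict[str, str] = {}
        for e in sorted(self._entities.values(), key=lambda e: e.id, reverse=True):
            out[e.label] = e.id
        return out

    # ----------------------------------------------------------- mutation
    def add_entity(self, entity: Entity) -> None:
        if entity.entity_type not in self.schema.entity_types:
            raise SchemaViolationError(
                f"entity {entity.id!r} has undeclared type {entity.entity_type!r}"
            )
        existing = self._entities.get(entity.id)
        if existing is not None and existing != entity:
            raise SchemaViolationError(f"conflicting redefinition of {entity.id!r}")
        self._entities[entity.id] = entity

    def _auto_register(self, entity_id: str) -> None:
        if entity_id not in self._entities:
            self.add_entity(
                Entity(entity_id, entity_type=self.schema.entity_type_of(entity_id))
            )

    def add_triple(self, triple: Triple, validate_types: bool = True) -> bool:
        """Add a triple (idempotent).  Returns True if it was new."""
        spec = self.schema.relation(triple.relation)
        self._auto_register(triple.head)
        self._auto_register(triple.tail)
        if validate_types:
            self._check_domain_range(triple, spec)
        if triple.key() in self._triples:
            return False
        self._triples[triple.key()] = triple
        return True

    def _check_domain_range(self, triple: Triple, spec: RelationSpec) -> None:
        # Untyped (Other) endpoints are exempt: their true type is unknown.
        head_t = self._entities[triple.head].entity_type
        tail_t = self._entities[triple.tail].entity_type
        if spec.domain != "any" and head_t not in (spec.domain, UNTYPED):
            raise SchemaViolationError(
                f"triple {triple.key()}: head type {head_t!r} "
                f"violates domain {spec.domain!r} of {spec.name!r}"
            )
        if spec.range_type != "any" and tail_t not in (spec.range_type, UNTYPED):
            raise SchemaViolationError(
                f"triple {triple.key()}: tail type {tail_t!r} "
                f"violates range {spec.range_type!r} of {spec.name!r}"
            )

    def remove_triple(self, triple: Triple) -> bool:
        return self._triples.pop(triple.key(), None) is not None

    def copy(self) -> "KnowledgeGraph":
        return KnowledgeGraph(
            self.schema, self._entities.values(), self._triples.values()
        )

    # ----------------------------------------------------------- topology
    def undirected_view(self, multigraph: bool = False) -> nx.Graph:
        """Undirected view; simple graph by default, multigraph on request."""
        g: nx.Graph = nx.MultiGraph() if multigraph else nx.Graph()
        g.add_nodes_from(self._entities)
        for t in self._triples.values():
            g.add_edge(t.head, t.tail, relation=t.relation)
        return g

    def iter_triples(self) -> Iterator[Triple]:
        return iter(sorted(self._triples.values(), key=Triple.key))

    def to_graphml(self, path: str | Path) -> None:
        g = nx.DiGraph()
        for e in self._entities.values():
            g.add_node(e.id, label=e.label, entity_type=e.entity_type)
        for t in self._triples.values():
            g.add_edge(t.head, t.tail, relation=t.relation, provenance=t.provenance)
        nx.write_graphml(g, str(path))


# ---------------------------------------------------------------------- ops
def load_triples(
    triple_path: str | Path, schema_path: str | Path | OntologySchema
) -> KnowledgeGraph:
    """Load a TSV triple file against a schema JSON file (or schema object).

    Each data line is ``head<TAB>relation<TAB>tail[<TAB>provenance]``.
    Entities are auto-registered; types come from the schema's
    ``entity_type_map`` and default to ``Other``.
    """
    schema = (
        schema_path
        if isinstance(schema_path, OntologySchema)
        else OntologySchema.load(schema_path)
    )
    kg = KnowledgeGraph(schema)
    with open(triple_path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{triple_path}: line {lineno}: expected >=3 tab-separated "
                    f"columns, got {len(parts)}"
                )
            head, relation, tail = parts[0], parts[1], parts[2]
            provenance = parts[3] if len(parts) > 3 and parts[3] else "original"
            if provenance not in PROVENANCE_TAGS:
                raise ParseError(
                    f"{triple_path}: line {lineno}: unknown provenance "
                    f"{provenance!r}"
                )
            try:
                kg.add_triple(Triple(head, relation, tail, provenance))
            except SchemaViolationError as exc:
                raise SchemaViolationError(f"line {lineno}: {exc}") from exc
    return kg


def save_triples(kg: KnowledgeGraph, path: str | Path) -> int:
    """Write the graph's triples as TSV (sorted, deterministic). Returns count."""
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for t in kg.iter_triples():
            fh.write(f"{t.head}\t{t.relation}\t{t.tail}\t{t.provenance}\n")
            n += 1
    return n


def merge_triples(
    kg: KnowledgeGraph,
    additions: Iterable[Triple] = (),
    removals: Iterable[Triple] = (),
) -> KnowledgeGraph:
    """Return a new graph = (kg ∪ additions) \\ removals.

    Additions keep their provenance; removing an absent triple only logs a
    warning.  Endpoint entities of additions are auto-registered.
    """
    out = kg.copy()
    for t in additions:
        out.add_triple(t)
    for t in removals:
        if not out.remove_triple(t):
            logger.warning("merge_triples: removal of absent triple %s", t.key())
    return out


def connected_components(kg: KnowledgeGraph) -> list[set[str]]:
    """Components of the undirected view, largest first.

    Ties on size are broken by the lexicographically smallest member id, so
    the ordering (and hence "the largest component") is deterministic.
    """
    comps = [set(c) for c in nx.connected_components(kg.undirected_view())]
    return sorted(comps, key=lambda c: (-len(c), min(c)))
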