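"""Ontology-level completion: transitive/symmetric closure and
mutual-exclusivity contradiction handling."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

from .errors import UsageError
from .kg_model import KnowledgeGraph, Triple, merge_triples

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContradictionPair:
    """Two triples on the same (head, tail) whose relations exclude each other."""

    triple_a: Triple
    triple_b: Triple
    rule: tuple[str, str]

    def __post_init__(self) -> None:
        if (self.triple_a.head, self.triple_a.tail) != (
            self.triple_b.head,
            self.triple_b.tail,
        ):
            raise UsageError("contradiction pair must share head and tail")


def transitive_closure(kg: KnowledgeGraph, relation: str) -> set[Triple]:
    """Triples in the transitive closure of ``relation`` absent from the graph.

    Terminates on cyclic inputs; self-loops produced by cycles are discarded.
    Idempotent: on an already-closed relation the result is empty.
    """
    spec = kg.schema.relation(relation)
    if not spec.transitive:
        raise UsageError(f"relation {relation!r} is not flagged transitive")
    succ: dict[str, set[str]] = {}
    edges: set[tuple[str, str]] = set()
    for t in kg.triples_of(relation):
        succ.setdefault(t.head, set()).add(t.tail)
        edges.add((t.head, t.tail))
    closure = set(edges)
    frontier = set(edges)
    while frontier:
        new = set()
        for h, m in frontier:
            for t in succ.get(m, ()):
                if (h, t) not in closure:
                    closure.add((h, t))
                    new.add((h, t))
        frontier = new
    return {
        Triple(h, relation, t, provenance="ontology_reasoning")
        for h, t in closure - edges
        if h != t
    }


def symmetric_closure(kg: KnowledgeGraph, relation: str) -> set[Triple]:
    """Reversed triples missing for a symmetric relation; idempotent."""
    spec = kg.schema.relation(relation)
    if not spec.symmetric:
        raise UsageError(f"relation {relation!r} is not flagged symmetric")
    return {
        Triple(t.tail, relation, t.head, provenance="ontology_reasoning")
        for t in kg.triples_of(relation)
        if not kg.has_triple(t.tail, relation, t.head) and t.head != t.tail
    }


def ontology_closure(kg: KnowledgeGraph) -> set[Triple]:
    """Closure additions for every transitive or symmetric relation in schema."""
    additions: set[Triple] = set()
    for spec in sorted(kg.schema.relations.values(), key=lambda s: s.name):
        if spec.transitive:
            additions |= transitive_closure(kg, spec.name)
        if spec.symmetric:
            additions |= symmetric_closure(kg, spec.name)
    return additions


def detect_contradictions(kg: KnowledgeGraph) -> list[ContradictionPair]:
    """Every (head, tail) pair carrying both relations of an exclusivity pair.

    Deterministic order: by rule, then head id, then tail id.
    """
    out: list[ContradictionPair] = []
    for rel_p, rel_r in kg.schema.exclusivity_pairs():
        pairs_r = {
            (t.head, t.tail): t for t in kg.triples_of(rel_r)
        }
        for tp in kg.triples_of(rel_p):
            tr = pairs_r.get((tp.head, tp.tail))
            if tr is not None:
                out.append(ContradictionPair(tp, tr, (rel_p, rel_r)))
    out.sort(key=lambda c: (c.rule, c.triple_a.head, c.triple_a.tail))
    return out


def resolve_contradictions(
    kg: KnowledgeGraph,
    pairs: Iterable[ContradictionPair],
    keep_policy: str = "drop_both",
    decisions: Mapping[tuple[str, str], str] | None = None,
) -> KnowledgeGraph:
    """Remove triples of contradiction pairs according to ``keep_policy``.

    Policies: ``drop_both`` removes both triples; ``keep_first_relation``
    keeps the triple whose relation sorts first in the exclusivity rule;
    ``external_decisions_file`` consults ``decisions`` mapping
    (head, tail) -> relation name to keep.  Pairs without a decision are
    reported and left untouched.
    """
    removals: set[Triple] = set()
    unresolved: list[ContradictionPair] = []
    for pair in pairs:
        if keep_policy == "drop_both":
            removals.add(pair.triple_a)
            removals.add(pair.triple_b)
        elif keep_policy == "keep_first_relation":
            keep_rel = pair.rule[0]
            for t in (pair.triple_a, pair.triple_b):
                if t.relation != keep_rel:
                    removals.add(t)
        elif keep_policy == "external_decisions_file":
            if decisions is None:
                raise UsageError("external_decisions_file policy needs decisions")
            key = (pair.triple_a.head, pair.triple_a.tail)
            keep_rel = decisions.get(key)
            if keep_rel is None:
                unresolved.append(pair)
                continue
            for t in (pair.triple_a, pair.triple_b):
                if t.relation != keep_rel:
                    removals.add(t)
        else:
            raise UsageError(f"unknown keep_policy {keep_policy!r}")
    if unresolved:
        logger.warning(
            "resolve_contradictions: %d pairs left unresolved (no decision)",
            len(unresolved),
        )
    return merge_triples(kg, removals=removals)
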