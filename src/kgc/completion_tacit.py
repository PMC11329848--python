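"""Association-rule mining over medical-record transactions.

Level-wise Apriori frequent-itemset search, syndrome -> symptom rule
derivation with support/confidence/lift, and conversion of lift-selected
rules into graph triples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import UsageError
from .kg_model import KnowledgeGraph, Triple

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Transaction:
    """One medical record: exactly one syndrome label plus symptom labels."""

    syndrome: str
    symptoms: frozenset[str]

    @property
    def items(self) -> frozenset[str]:
        return self.symptoms | {self.syndrome}


@dataclass(frozen=True)
class AssociationRule:
    """X -> Y with its support, confidence and lift statistics."""

    antecedent: frozenset[str]
    consequent: frozenset[str]
    support: float
    confidence: float
    lift: float

    def __post_init__(self) -> None:
        if self.antecedent & self.consequent:
            raise UsageError("rule antecedent and consequent must be disjoint")


def _as_itemsets(transactions: Sequence) -> list[frozenset[str]]:
    out = []
    for t in transactions:
        out.append(t.items if isinstance(t, Transaction) else frozenset(t))
    return out


def apriori_frequent_itemsets(
    transactions: Sequence, min_support: float
) -> dict[frozenset[str], float]:
    """All itemsets with support >= min_support, via level-wise Apriori.

    A k-itemset is a candidate only if every (k-1)-subset is frequent.
    Accepts :class:`Transaction` objects or plain item sets.
    """
    if not transactions:
        raise UsageError("transaction list is empty")
    if not 0.0 < min_support <= 1.0:
        raise UsageError(f"min_support must be in (0,1], got {min_support}")
    itemsets = _as_itemsets(transactions)
    n = len(itemsets)

    counts: dict[frozenset[str], int] = {}
    for t in itemsets:
        for item in t:
            key = frozenset([item])
            counts[key] = counts.get(key, 0) + 1
    frequent: dict[frozenset[str], float] = {
        s: c / n for s, c in counts.items() if c / n >= min_support
    }
    level = set(frequent)

    while level:
        # Join step: unite pairs differing in one item, then prune.
        candidates = set()
        level_list = sorted(level, key=sorted)
        for a, b in combinations(level_list, 2):
            union = a | b
            if len(union) == len(next(iter(level))) + 1:
                if all(frozenset(sub) in level
                       for sub in combinations(union, len(union) - 1)):
                    candidates.add(union)
        if not candidates:
            break
        counts = {c: 0 for c in candidates}
        for t in itemsets:
            for c in candidates:
                if c <= t:
                    counts[c] += 1
        level = {c for c, k in counts.items() if k / n >= min_support}
        frequent.update({c: counts[c] / n for c in level})
    return frequent


def derive_rules(
    frequent: Mapping[frozenset[str], float],
    item_types: Mapping[str, str],
    antecedent_type: str = "syndrome",
    consequent_type: str = "symptom",
) -> list[AssociationRule]:
    """Single-antecedent, single-consequent rules from the frequent itemsets.

    ``confidence = support(X ∪ Y) / support(X)`` and
    ``lift = confidence / support(Y)``.  Rules are sorted by lift descending,
    ties broken by (support desc, labels asc) for determinism.
    """
    rules: list[AssociationRule] = []
    for itemset, support_xy in frequent.items():
        if len(itemset) != 2:
            continue
        for x in itemset:
            y = next(iter(itemset - {x}))
            if item_types.get(x) != antecedent_type:
                continue
            if item_types.get(y) != consequent_type:
                continue
            support_x = frequent.get(frozenset([x]), 0.0)
            support_y = frequent.get(frozenset([y]), 0.0)
            if support_x <= 0:
                logger.warning("skipping rule with zero-support antecedent %r", x)
                continue
            confidence = support_xy / support_x
            lift = confidence / support_y if support_y > 0 else 0.0
            rules.append(
                AssociationRule(
                    antecedent=frozenset([x]),
                    consequent=frozenset([y]),
                    support=support_xy,
                    confidence=confidence,
                    lift=lift,
                )
            )
    rules.sort(
        key=lambda r: (
            -r.lift,
            -r.support,
            sorted(r.antecedent),
            sorted(r.consequent),
        )
    )
    return rules


def select_and_convert(
    rules: Iterable[AssociationRule],
    kg: KnowledgeGraph,
    lift_threshold: float = 1.0,
    relation: str = "Manifest",
    label_to_id: Mapping[str, str] | None = None,
) -> set[Triple]:
    """Keep rules with lift > threshold and convert them to triples.

    Labels map to entity ids via ``label_to_id`` (default: the graph's label
    index; unmapped labels keep the label as id).  Triples already in the
    graph are dropped.
    """
    kg.schema.relation(relation)  # raises for undeclared relations
    mapping = dict(kg.label_to_id()) if label_to_id is None else dict(label_to_id)
    out: set[Triple] = set()
    for rule in rules:
        if rule.lift <= lift_threshold:
            continue
        (x,) = rule.antecedent
        (y,) = rule.consequent
        head = mapping.get(x, x)
        tail = mapping.get(y, y)
        t = Triple(head, relation, tail, provenance="association_rule")
        if t not in kg:
            out.add(t)
    return out


# ----------------------------------------------------------------- file I/O
def save_records(records: Sequence[Transaction], path: str | Path) -> int:
    """One record per line, tab-separated, syndrome label first."""
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write("\t".join([r.syndrome, *sorted(r.symptoms)]) + "\n")
    return len(records)


def load_records(
    path: str | Path, syndrome_labels: Iterable[str] | None = None
) -> list[Transaction]:
    """Read a transactions file.

    If ``syndrome_labels`` is given, the syndrome item may appear anywhere on
    the line; otherwise the first item is taken as the syndrome.  Exactly one
    syndrome per record is enforced.
    """
    syndrome_set = set(syndrome_labels) if syndrome_labels is not None else None
    records = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            items = [p for p in raw.rstrip("\n").split("\t") if p]
            if not items:
                continue
            if syndrome_set is None:
                syndrome, symptoms = items[0], items[1:]
            else:
                marked = [i for i in items if i in syndrome_set]
                if len(marked) != 1:
                    raise UsageError(
                        f"{path}: line {lineno}: expected exactly one syndrome "
                        f"item, found {len(marked)}"
                    )
                syndrome = marked[0]
                symptoms = [i for i in items if i != syndrome]
            records.append(Transaction(syndrome, frozenset(symptoms)))
    return records
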