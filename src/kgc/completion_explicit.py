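"""Path-level completion: isolated-subgraph re-linking and path-ranking
relation prediction with ontology-consistency filtering.

The relation predictor follows the classic path-ranking recipe: random walks
enumerate relation-sequence features, each feature's value for a (source,
target) pair is the probability that a uniform random walk constrained to
that relation sequence reaches the target, and a logistic-loss linear
classifier combines the feature values into a score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import EntityLookupError, UsageError
from .kg_model import KnowledgeGraph, Triple, connected_components
from ._util import round4

logger = logging.getLogger(__name__)

FORWARD = "forward"
INVERSE = "inverse"


@dataclass(frozen=True)
class PathFeature:
    """An ordered sequence of (relation, direction) steps."""

    steps: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(self.steps) < 1:
            raise UsageError("a path feature needs at least one step")
        for _, direction in self.steps:
            if direction not in (FORWARD, INVERSE):
                raise UsageError(f"bad step direction {direction!r}")

    def __len__(self) -> int:
        return len(self.steps)


@dataclass
class PRAModel:
    """Trained path-ranking model for one target relation."""

    target_relation: str
    features: list[PathFeature]
    weights: np.ndarray
    intercept: float

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.features):
            raise UsageError("|weights| must equal |features|")


@dataclass(frozen=True)
class CandidateTriple:
    """A predicted triple with its score and path support."""

    triple: Triple
    score: float
    supporting_paths: int
    status: str = "proposed"  # proposed | ontology_accepted | ontology_rejected

    @property
    def head(self) -> str:
        return self.triple.head

    @property
    def relation(self) -> str:
        return self.triple.relation

    @property
    def tail(self) -> str:
        return self.triple.tail


@dataclass
class GoldStandard:
    """Expert-annotated positive and negative triples."""

    positive: set[Triple]
    negative: set[Triple] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.positive & self.negative:
            raise UsageError("gold positive and negative sets overlap")


# ------------------------------------------------------------ outliers
def detect_isolated_subgraphs(
    kg: KnowledgeGraph,
) -> list[tuple[set[str], str]]:
    """Every connected component except the largest, with a category hint.

    Hint is ``"SubSyndrome"`` when the component holds a SubSyndrome-typed
    node (re-linkable), else ``"Other"``.
    """
    comps = connected_components(kg)
    out = []
    for comp in comps[1:]:
        hint = (
            "SubSyndrome"
            if any(kg.entity(e).entity_type == "SubSyndrome" for e in comp)
            else "Other"
        )
        out.append((comp, hint))
    return out


def default_link_map(
    kg: KnowledgeGraph, suffix: str = " Syndrome"
) -> dict[str, str]:
    """Name-pattern resolver: SubSyndrome labeled "X Syndrome" -> prescription
    labeled "X", for SubSyndromes inside isolated components."""
    prescriptions = {e.label: e.id for e in kg.entities_of_type("Prescription")}
    link_map: dict[str, str] = {}
    for comp, hint in detect_isolated_subgraphs(kg):
        if hint != "SubSyndrome":
            continue
        for eid in sorted(comp):
            ent = kg.entity(eid)
            if ent.entity_type != "SubSyndrome":
                continue
            if ent.label.endswith(suffix):
                target = prescriptions.get(ent.label[: -len(suffix)])
                if target is not None:
                    link_map[eid] = target
    return link_map


def link_isolated_subgraphs(
    kg: KnowledgeGraph, link_map: Mapping[str, str]
) -> set[Triple]:
    """(Prescription, Treat, SubSyndrome) triples re-linking isolated
    SubSyndrome components; non-SubSyndrome components are left untouched."""
    for sub, prx in link_map.items():
        if sub not in kg.entities or prx not in kg.entities:
            raise EntityLookupError(f"link_map references unknown entity "
                                    f"{sub if sub not in kg.entities else prx!r}")
    out: set[Triple] = set()
    for comp, hint in detect_isolated_subgraphs(kg):
        if hint != "SubSyndrome":
            continue
        for eid in sorted(comp):
            prx = link_map.get(eid)
            if prx is not None:
                out.add(Triple(prx, "Treat", eid, provenance="outlier_completion"))
    return out


# ------------------------------------------------------------ PRA core
class _Adjacency:
    """Per-relation forward/inverse adjacency lists with sorted neighbors."""

    def __init__(self, kg: KnowledgeGraph) -> None:
        self.fwd: dict[str, dict[str, list[str]]] = {}
        self.inv: dict[str, dict[str, list[str]]] = {}
        for t in kg.iter_triples():
            self.fwd.setdefault(t.relation, {}).setdefault(t.head, []).append(t.tail)
            self.inv.setdefault(t.relation, {}).setdefault(t.tail, []).append(t.head)

    def neighbors(self, node: str, relation: str, direction: str) -> list[str]:
        table = self.fwd if direction == FORWARD else self.inv
        return table.get(relation, {}).get(node, [])

    def all_moves(self, node: str) -> list[tuple[str, str, str]]:
        moves = []
        for rel in self.fwd:
            for nbr in self.fwd[rel].get(node, []):
                moves.append((rel, FORWARD, nbr))
        for rel in self.inv:
            for nbr in self.inv[rel].get(node, []):
                moves.append((rel, INVERSE, nbr))
        moves.sort()
        return moves


def _walk_distribution(
    adj: _Adjacency, source: str, steps: Sequence[tuple[str, str]]
) -> dict[str, float]:
    """Distribution of a uniform random walk constrained to a relation path.

    At each step the walker picks uniformly among conforming edges; mass at
    nodes with no conforming edge is lost (the walk dies), so the returned
    masses sum to <= 1.
    """
    probs = {source: 1.0}
    for relation, direction in steps:
        nxt: dict[str, float] = {}
        for node, p in probs.items():
            nbrs = adj.neighbors(node, relation, direction)
            if not nbrs:
                continue
            share = p / len(nbrs)
            for nbr in nbrs:
                nxt[nbr] = nxt.get(nbr, 0.0) + share
        probs = nxt
        if not probs:
            break
    return probs


def path_feature_value(
    kg: KnowledgeGraph, source: str, feature: PathFeature, target: str
) -> float:
    """P(source -> target ; feature): constrained-random-walk probability."""
    adj = _Adjacency(kg)
    return _walk_distribution(adj, source, feature.steps).get(target, 0.0)


def extract_path_features(
    kg: KnowledgeGraph,
    target_relation: str,
    max_path_length: int = 3,
    n_walks: int = 1000,
    seed: int = 0,
) -> list[PathFeature]:
    """Relation-sequence features found by bounded random walks.

    Walks start at heads of known target-relation triples; a relation
    sequence is kept when the walk stands on the known tail.  The trivial
    length-1 sequence equal to the target relation itself is excluded.
    Deterministic given the seed.
    """
    if max_path_length < 1 or n_walks < 1:
        raise UsageError("max_path_length and n_walks must be >= 1")
    positives = kg.triples_of(target_relation)
    if not positives:
        logger.warning("extract_path_features: no instances of %r", target_relation)
        return []
    adj = _Adjacency(kg)
    rng = np.random.default_rng(seed)
    trivial = ((target_relation, FORWARD),)
    found: set[tuple[tuple[str, str], ...]] = set()
    for _ in range(n_walks):
        t = positives[int(rng.integers(len(positives)))]
        node = t.head
        seq: list[tuple[str, str]] = []
        for _ in range(max_path_length):
            moves = adj.all_moves(node)
            if not moves:
                break
            rel, direction, node = moves[int(rng.integers(len(moves)))]
            seq.append((rel, direction))
            if node == t.tail:
                steps = tuple(seq)
                if steps != trivial:
                    found.add(steps)
                break
    return [PathFeature(s) for s in sorted(found, key=lambda s: (len(s), s))]


def _feature_matrix(
    adj: _Adjacency,
    pairs: Sequence[tuple[str, str]],
    features: Sequence[PathFeature],
) -> np.ndarray:
    """Rows: pairs; columns: feature walk probabilities.  Distributions are
    cached per (source, feature)."""
    cache: dict[tuple[str, int], dict[str, float]] = {}
    x = np.zeros((len(pairs), len(features)))
    for j, feat in enumerate(features):
        for i, (s, t) in enumerate(pairs):
            key = (s, j)
            if key not in cache:
                cache[key] = _walk_distribution(adj, s, feat.steps)
            x[i, j] = cache[key].get(t, 0.0)
    return x


def _negative_tails(
    kg: KnowledgeGraph,
    positives: Sequence[Triple],
    negatives_per_positive: int,
    rng: np.random.Generator,
) -> list[tuple[str, str]]:
    """Corrupted-tail pairs, sampled from type-compatible entities."""
    spec = kg.schema.relation(positives[0].relation)
    if spec.range_type != "any":
        pool = [e.id for e in kg.entities_of_type(spec.range_type)]
    else:
        tail_types = {kg.entity(t.tail).entity_type for t in positives}
        pool = sorted(
            e.id for e in kg.entities.values() if e.entity_type in tail_types
        )
    out: list[tuple[str, str]] = []
    for t in positives:
        drawn = 0
        attempts = 0
        while drawn < negatives_per_positive and attempts < 50 * negatives_per_positive:
            attempts += 1
            cand = pool[int(rng.integers(len(pool)))]
            if cand == t.tail or kg.has_triple(t.head, t.relation, cand):
                continue
            out.append((t.head, cand))
            drawn += 1
    return out


def train_pra(
    kg: KnowledgeGraph,
    features: Sequence[PathFeature],
    target_relation: str,
    negatives_per_positive: int = 1,
    seed: int = 0,
) -> PRAModel:
    """Fit the logistic-loss linear classifier over path-feature values.

    Positives are the existing target-relation triples; negatives corrupt
    each positive's tail with type-compatible entities.
    """
    from sklearn.linear_model import LogisticRegression

    positives = kg.triples_of(target_relation)
    if not positives:
        raise UsageError(f"no positive triples for {target_relation!r}")
    if not features:
        raise UsageError("at least one path feature is required")
    rng = np.random.default_rng(seed)
    pos_pairs = [(t.head, t.tail) for t in positives]
    neg_pairs = _negative_tails(kg, positives, negatives_per_positive, rng)
    adj = _Adjacency(kg)
    x = _feature_matrix(adj, pos_pairs + neg_pairs, features)
    y = np.array([1] * len(pos_pairs) + [0] * len(neg_pairs))
    if len(np.unique(y)) < 2:
        raise UsageError("could not sample any negative examples")
    if np.all(x == x[0]):
        logger.warning("train_pra: all feature rows identical; model will "
                       "predict the base rate")
    clf = LogisticRegression(max_iter=1000)
    clf.fit(x, y)
    return PRAModel(
        target_relation=target_relation,
        features=list(features),
        weights=clf.coef_[0].copy(),
        intercept=float(clf.intercept_[0]),
    )


def candidate_pairs(
    kg: KnowledgeGraph, target_relation: str
) -> list[tuple[str, str]]:
    """All type-compatible (head, tail) pairs not already linked by the
    target relation."""
    spec = kg.schema.relation(target_relation)
    positives = kg.triples_of(target_relation)
    if spec.domain != "any":
        heads = [e.id for e in kg.entities_of_type(spec.domain)]
    else:
        head_types = {kg.entity(t.head).entity_type for t in positives}
        heads = sorted(
            e.id for e in kg.entities.values() if e.entity_type in head_types
        )
    if spec.range_type != "any":
        tails = [e.id for e in kg.entities_of_type(spec.range_type)]
    else:
        tail_types = {kg.entity(t.tail).entity_type for t in positives}
        tails = sorted(
            e.id for e in kg.entities.values() if e.entity_type in tail_types
        )
    return [
        (h, t)
        for h in heads
        for t in tails
        if h != t and not kg.has_triple(h, target_relation, t)
    ]


def predict_relations(
    model: PRAModel,
    kg: KnowledgeGraph,
    pairs: Sequence[tuple[str, str]],
    support_threshold: int = 2,
) -> list[CandidateTriple]:
    """Score candidate pairs; keep those with more supporting paths than the
    threshold, sorted by (supporting paths desc, score desc)."""
    pairs = [
        (h, t) for h, t in pairs if not kg.has_triple(h, model.target_relation, t)
    ]
    if not pairs:
        return []
    adj = _Adjacency(kg)
    x = _feature_matrix(adj, pairs, model.features)
    scores = x @ model.weights + model.intercept
    support = (x != 0).sum(axis=1)
    out = [
        CandidateTriple(
            triple=Triple(h, model.target_relation, t, provenance="path_reasoning"),
            score=float(scores[i]),
            supporting_paths=int(support[i]),
        )
        for i, (h, t) in enumerate(pairs)
        if support[i] > support_threshold
    ]
    out.sort(key=lambda c: (-c.supporting_paths, -c.score, c.head, c.tail))
    return out


# ------------------------------------------------------- ontology filter
def ontology_filter(
    candidates: Sequence[CandidateTriple], kg: KnowledgeGraph
) -> list[CandidateTriple]:
    """Accept candidates consistent with syndrome/pathogenesis containment.

    A (Syndrome, Manifest, Symptom) candidate is accepted iff every
    pathogenesis factor the symptom corresponds to is contained by the
    syndrome.  A (Prescription, Treat, Symptom) candidate maps the
    prescription to its curable syndromes first and accepts if any of them
    passes the same containment test.  Everything else is rejected.
    Idempotent and order-independent.
    """
    corr: dict[str, set[str]] = {}
    for t in kg.triples_of("CorrespondTo"):
        corr.setdefault(t.head, set()).add(t.tail)
    contain: dict[str, set[str]] = {}
    for t in kg.triples_of("Contain"):
        contain.setdefault(t.head, set()).add(t.tail)
    curable: dict[str, set[str]] = {}
    for t in kg.triples_of("Treat"):
        if kg.entity(t.tail).entity_type in ("Syndrome", "SubSyndrome"):
            curable.setdefault(t.head, set()).add(t.tail)

    def consistent(syndrome: str, symptom: str) -> bool:
        factors = corr.get(symptom)
        if not factors:
            return False
        return factors <= contain.get(syndrome, set())

    out: list[CandidateTriple] = []
    for cand in candidates:
        if cand.status != "proposed":
            out.append(cand)
            continue
        head_type = kg.entity(cand.head).entity_type
        tail_type = kg.entity(cand.tail).entity_type
        accepted = False
        if cand.relation == "Manifest" and tail_type == "Symptom":
            accepted = consistent(cand.head, cand.tail)
            if not corr.get(cand.tail):
                logger.info("ontology_filter: %s rejected (unmappable symptom)",
                            cand.triple.key())
        elif (
            cand.relation == "Treat"
            and head_type == "Prescription"
            and tail_type == "Symptom"
        ):
            accepted = any(
                consistent(s, cand.tail) for s in curable.get(cand.head, ())
            )
        status = "ontology_accepted" if accepted else "ontology_rejected"
        out.append(replace(cand, status=status))
    return out


# ------------------------------------------------------------- scoring
def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return round4(2 * precision * recall / (precision + recall))


def evaluate_against_gold(
    predicted: Iterable[Triple], gold: GoldStandard
) -> tuple[float, float, float]:
    """(precision, recall, F1) of predicted triples against the gold standard.

    Predictions outside both gold sets count as false positives (closed
    world on the annotation universe).  Values are rounded to 4 decimals.
    """
    if not gold.positive:
        raise UsageError("gold standard has no positive triples")
    predicted = set(predicted)
    tp = len(predicted & gold.positive)
    fp = len(predicted & gold.negative) + len(
        predicted - gold.positive - gold.negative
    )
    fn = len(gold.positive - predicted)
    if tp + fp == 0:
        logger.warning("evaluate_against_gold: no predictions; precision "
                       "undefined, reported as 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return round4(precision), round4(recall), f1_score(precision, recall)
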