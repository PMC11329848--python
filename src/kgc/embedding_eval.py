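"""Usability evaluation via knowledge-graph embeddings.

Four score functions (TransE, RotatE, DistMult, ComplEx) trained with
tail-corruption negative sampling and a margin ranking loss, evaluated by
tail-entity ranking: MR, MRR and Hits@{1,3,10} on a 7:3 split.

All training is plain numpy gradient descent: one pass per epoch over the
positive triples with freshly sampled corrupted tails.  Complex-valued
models (RotatE, ComplEx) store embeddings as complex arrays of dimension/2
entries; RotatE relations are phase vectors, so their entries have unit
modulus by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._util import round4
from .errors import EntityLookupError, UsageError
from .kg_model import KnowledgeGraph, Triple

logger = logging.getLogger(__name__)

MODELS = ("TransE", "RotatE", "DistMult", "ComplEx")


@dataclass
class EmbeddingConfig:
    model: str = "TransE"
    dimension: int = 100
    margin: float = 1.0
    learning_rate: float = 0.01
    epochs: int = 200
    negatives_per_positive: int = 1
    split_ratio: tuple[float, float] = (0.7, 0.3)
    seed: int = 0

    def validate(self) -> None:
        if self.model not in MODELS:
            raise UsageError(f"unknown model {self.model!r}; pick from {MODELS}")
        if self.dimension < 1 or self.margin <= 0 or self.learning_rate <= 0:
            raise UsageError("dimension, margin and learning_rate must be positive")
        if self.epochs < 0 or self.negatives_per_positive < 1:
            raise UsageError("epochs must be >= 0, negatives_per_positive >= 1")
        if abs(sum(self.split_ratio) - 1.0) > 1e-9:
            raise UsageError("split_ratio fractions must sum to 1")
        if self.model in ("RotatE", "ComplEx") and self.dimension % 2:
            raise UsageError(f"{self.model} needs an even dimension")


@dataclass
class RankingMetrics:
    mr: float
    mrr: float
    hits1: float
    hits3: float
    hits10: float

    def to_dict(self) -> dict:
        return {
            "MR": self.mr,
            "MRR": self.mrr,
            "Hits@1": self.hits1,
            "Hits@3": self.hits3,
            "Hits@10": self.hits10,
        }


@dataclass
class EmbeddingModel:
    """Entity/relation embeddings plus the id -> row indexes."""

    model: str
    dimension: int
    entities: list[str]
    relations: list[str]
    ent: np.ndarray
    rel: np.ndarray
    loss_trajectory: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ent_index = {e: i for i, e in enumerate(self.entities)}
        self.rel_index = {r: i for i, r in enumerate(self.relations)}

    # -------------------------------------------------------------- scores
    def _idx(self, table: dict, key: str, kind: str) -> int:
        try:
            return table[key]
        except KeyError:
            raise EntityLookupError(f"unknown {kind} {key!r}") from None

    def score(self, head: str, relation: str, tail: str) -> float:
        h = self._idx(self.ent_index, head, "entity")
        r = self._idx(self.rel_index, relation, "relation")
        t = self._idx(self.ent_index, tail, "entity")
        return float(self.score_batch(np.array([h]), np.array([r]),
                                      np.array([t]))[0])

    def score_batch(
        self, h: np.ndarray, r: np.ndarray, t: np.ndarray
    ) -> np.ndarray:
        eh, et = self.ent[h], self.ent[t]
        if self.model == "TransE":
            return -np.linalg.norm(eh + self.rel[r] - et, axis=-1)
        if self.model == "DistMult":
            return np.sum(eh * self.rel[r] * et, axis=-1)
        if self.model == "ComplEx":
            return np.real(np.sum(eh * self.rel[r] * np.conj(et), axis=-1))
        if self.model == "RotatE":
            phase = np.exp(1j * self.rel[r])
            return -np.linalg.norm(eh * phase - et, axis=-1)
        raise UsageError(f"unknown model {self.model!r}")

    def score_all_tails(self, head: str, relation: str) -> np.ndarray:
        """Score of every entity as tail of (head, relation, .)."""
        h = self._idx(self.ent_index, head, "entity")
        r = self._idx(self.rel_index, relation, "relation")
        n = len(self.entities)
        return self.score_batch(
            np.full(n, h), np.full(n, r), np.arange(n)
        )


def score_triple(model: EmbeddingModel, head: str, relation: str,
                 tail: str) -> float:
    """Plausibility score of a triple under the model (higher = better)."""
    return model.score(head, relation, tail)


# ----------------------------------------------------------------- split
def split_triples(
    kg: KnowledgeGraph | Iterable[Triple],
    ratio: float = 0.7,
    seed: int = 0,
) -> tuple[list[Triple], list[Triple]]:
    """Seeded 7:3-style shuffle split with train-coverage repair.

    Validation triples whose entities or relation never occur in train are
    moved to train (logged), so every validation item is scoreable.
    """
    if not 0.0 < ratio < 1.0:
        raise UsageError(f"ratio must be in (0,1), got {ratio}")
    triples = sorted(
        kg.triples if isinstance(kg, KnowledgeGraph) else set(kg), key=Triple.key
    )
    if len(triples) < 10:
        raise UsageError("need at least 10 triples to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(triples))
    n_train = int(round(ratio * len(triples)))
    train = [triples[i] for i in order[:n_train]]
    val = [triples[i] for i in order[n_train:]]

    seen_entities = {t.head for t in train} | {t.tail for t in train}
    seen_relations = {t.relation for t in train}
    kept, moved = [], []
    for t in val:
        if (
            t.head in seen_entities
            and t.tail in seen_entities
            and t.relation in seen_relations
        ):
            kept.append(t)
        else:
            moved.append(t)
            seen_entities |= {t.head, t.tail}
            seen_relations.add(t.relation)
    if moved:
        logger.info("split_triples: moved %d validation triples to train "
                    "for coverage", len(moved))
    return train + moved, kept


# ---------------------------------------------------------- negative sampling
def negative_sample(
    triple: Triple,
    entity_pool: Sequence[str],
    rng: np.random.Generator,
    train_keys: set[tuple[str, str, str]] | None = None,
    max_retries: int = 10,
) -> Triple:
    """Corrupt the tail with a uniform draw from the pool (!= original tail).

    Corruptions that reproduce a known training triple are resampled up to
    ``max_retries`` times, then accepted with a warning.
    """
    pool = [e for e in entity_pool if e != triple.tail]
    if not pool:
        raise UsageError("entity pool must contain >= 2 entities")
    cand = pool[int(rng.integers(len(pool)))]
    if train_keys:
        for _ in range(max_retries):
            if (triple.head, triple.relation, cand) not in train_keys:
                break
            cand = pool[int(rng.integers(len(pool)))]
        else:
            logger.warning("negative_sample: retry budget exhausted; "
                           "accepting a known-true corruption")
    return Triple(triple.head, triple.relation, cand)


# ---------------------------------------------------------------- training
def _init_model(
    config: EmbeddingConfig,
    entities: list[str],
    relations: list[str],
    rng: np.random.Generator,
) -> EmbeddingModel:
    n, m, d = len(entities), len(relations), config.dimension
    scale = 1.0 / np.sqrt(d)
    if config.model in ("TransE", "DistMult"):
        ent = rng.uniform(-scale, scale, size=(n, d))
        rel = rng.uniform(-scale, scale, size=(m, d))
    elif config.model == "ComplEx":
        d2 = d // 2
        ent = rng.uniform(-scale, scale, (n, d2)) + 1j * rng.uniform(
            -scale, scale, (n, d2)
        )
        rel = rng.uniform(-scale, scale, (m, d2)) + 1j * rng.uniform(
            -scale, scale, (m, d2)
        )
    else:  # RotatE: complex entities, phase relations (unit modulus)
        d2 = d // 2
        ent = rng.uniform(-scale, scale, (n, d2)) + 1j * rng.uniform(
            -scale, scale, (n, d2)
        )
        rel = rng.uniform(-np.pi, np.pi, size=(m, d2))
    return EmbeddingModel(config.model, d, entities, relations, ent, rel)


def _unit_direction(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """d / ||d|| rowwise with zero-norm guard; works for real and complex."""
    if np.iscomplexobj(d):
        norms = np.sqrt(np.sum(np.abs(d) ** 2, axis=1, keepdims=True))
    else:
        norms = np.linalg.norm(d, axis=1, keepdims=True)
    safe = np.where(norms == 0, 1.0, norms)
    return d / safe, norms[:, 0]


def train_embeddings(
    train: Sequence[Triple],
    config: EmbeddingConfig,
    entities: Sequence[str] | None = None,
) -> EmbeddingModel:
    """Minimize max(0, margin - score(pos) + score(neg)) by gradient descent.

    One gradient pass per epoch over all positives with fresh corrupted
    tails; TransE entities are re-projected to unit L2 norm each epoch
    (DistMult/ComplEx entities are clipped to unit norm for stability);
    RotatE relation phases stay unit-modulus by parameterization.
    Deterministic given the config seed.  ``epochs=0`` returns the seeded
    random initialization unchanged.
    """
    config.validate()
    if not train:
        raise UsageError("training set is empty")
    ent_ids = sorted(
        set(entities or [])
        | {t.head for t in train}
        | {t.tail for t in train}
    )
    rel_ids = sorted({t.relation for t in train})
    rng = np.random.default_rng(config.seed)
    model = _init_model(config, ent_ids, rel_ids, rng)

    npos = len(train)
    k = config.negatives_per_positive
    h_idx = np.array([model.ent_index[t.head] for t in train])
    r_idx = np.array([model.rel_index[t.relation] for t in train])
    t_idx = np.array([model.ent_index[t.tail] for t in train])
    key_set = {(h, r, c) for (h, r, c) in zip(h_idx, r_idx, t_idx)}
    n_ent = len(ent_ids)
    lr = config.learning_rate

    if config.model == "TransE":
        norms = np.linalg.norm(model.ent, axis=1, keepdims=True)
        model.ent /= np.where(norms == 0, 1.0, norms)

    for _ in range(config.epochs):
        hp = np.repeat(h_idx, k)
        rp = np.repeat(r_idx, k)
        tp = np.repeat(t_idx, k)
        tn = rng.integers(n_ent, size=npos * k)
        # resample corruptions equal to the true tail or known triples
        for _ in range(10):
            bad = (tn == tp) | np.fromiter(
                ((h, r, c) in key_set for h, r, c in zip(hp, rp, tn)),
                dtype=bool, count=len(tn),
            )
            if not bad.any():
                break
            tn[bad] = rng.integers(n_ent, size=int(bad.sum()))

        s_pos = model.score_batch(hp, rp, tp)
        s_neg = model.score_batch(hp, rp, tn)
        losses = config.margin - s_pos + s_neg
        active = losses > 0
        model.loss_trajectory.append(float(np.mean(np.maximum(losses, 0.0))))
        if not np.isfinite(model.loss_trajectory[-1]):
            raise UsageError("non-finite training loss; lower the learning rate")
        if not active.any():
            continue
        ha, ra, ta, tna = hp[active], rp[active], tp[active], tn[active]
        _apply_gradients(model, config, ha, ra, ta, tna, lr / max(1, k))

        if config.model == "TransE":
            norms = np.linalg.norm(model.ent, axis=1, keepdims=True)
            model.ent /= np.where(norms == 0, 1.0, norms)
        elif config.model in ("DistMult", "ComplEx"):
            norms = np.sqrt(
                np.sum(np.abs(model.ent) ** 2, axis=1, keepdims=True)
            )
            model.ent /= np.where(norms > 1.0, norms, 1.0)
        elif config.model == "RotatE":
            model.rel = np.mod(model.rel + np.pi, 2 * np.pi) - np.pi

    return model


def _apply_gradients(
    model: EmbeddingModel,
    config: EmbeddingConfig,
    h: np.ndarray,
    r: np.ndarray,
    t: np.ndarray,
    tn: np.ndarray,
    lr: float,
) -> None:
    """One margin-loss gradient step for the active (pos, neg) pairs."""
    ent, rel = model.ent, model.rel
    if model.model == "TransE":
        up, _ = _unit_direction(ent[h] + rel[r] - ent[t])
        un, _ = _unit_direction(ent[h] + rel[r] - ent[tn])
        g = up - un
        _scatter_add(ent, h, -lr * g)
        _scatter_add(rel, r, -lr * g)
        _scatter_add(ent, t, lr * up)
        _scatter_add(ent, tn, -lr * un)
    elif model.model == "DistMult":
        gh = -(rel[r] * ent[t]) + rel[r] * ent[tn]
        gr = -(ent[h] * ent[t]) + ent[h] * ent[tn]
        _scatter_add(ent, h, -lr * gh)
        _scatter_add(rel, r, -lr * gr)
        _scatter_add(ent, t, lr * ent[h] * rel[r])
        _scatter_add(ent, tn, -lr * ent[h] * rel[r])
    elif model.model == "ComplEx":
        # d score/d h = conj(r) t ; d/d r = conj(h) t ; d/d tail = h r
        gh = -np.conj(rel[r]) * ent[t] + np.conj(rel[r]) * ent[tn]
        gr = -np.conj(ent[h]) * ent[t] + np.conj(ent[h]) * ent[tn]
        _scatter_add(ent, h, -lr * gh)
        _scatter_add(rel, r, -lr * gr)
        _scatter_add(ent, t, lr * ent[h] * rel[r])
        _scatter_add(ent, tn, -lr * ent[h] * rel[r])
    elif model.model == "RotatE":
        phase = np.exp(1j * rel[r])
        zp = ent[h] * phase
        ep, _ = _unit_direction(zp - ent[t])
        en, _ = _unit_direction(zp - ent[tn])
        # loss = margin + ||d_pos|| - ||d_neg||
        gh = np.conj(phase) * (ep - en)
        gtheta = np.imag(ep * np.conj(zp)) - np.imag(en * np.conj(zp))
        _scatter_add(ent, h, -lr * gh)
        _scatter_add(rel, r, -lr * gtheta)
        _scatter_add(ent, t, lr * ep)
        _scatter_add(ent, tn, -lr * en)


def _scatter_add(array: np.ndarray, index: np.ndarray, update: np.ndarray) -> None:
    np.add.at(array, index, update.astype(array.dtype, copy=False))


# ----------------------------------------------------------------- ranking
def rank_tail(
    model: EmbeddingModel,
    triple: Triple,
    entities: Sequence[str] | None = None,
    filtered: bool = False,
    known_tails: Iterable[str] = (),
) -> int:
    """Optimistic rank of the true tail among all candidate tails.

    rank = 1 + number of candidates scoring strictly better.  ``filtered``
    excludes other known-true tails from the candidate set.
    """
    scores = model.score_all_tails(triple.head, triple.relation)
    true_idx = model._idx(model.ent_index, triple.tail, "entity")
    mask = np.ones(len(model.entities), dtype=bool)
    if entities is not None:
        mask[:] = False
        for e in entities:
            mask[model._idx(model.ent_index, e, "entity")] = True
        mask[true_idx] = True
    if filtered:
        for e in known_tails:
            if e != triple.tail and e in model.ent_index:
                mask[model.ent_index[e]] = False
    return int(1 + np.sum(scores[mask] > scores[true_idx]))


def ranking_metrics(
    model: EmbeddingModel,
    validation: Sequence[Triple],
    entities: Sequence[str] | None = None,
    filtered: bool = False,
    known_tails_by_query: dict[tuple[str, str], set[str]] | None = None,
) -> RankingMetrics:
    """MR, MRR and Hits@{1,3,10} over tail-entity ranking, to 4 decimals."""
    if not validation:
        raise UsageError("validation set is empty")
    ranks = []
    for t in validation:
        known = (
            known_tails_by_query.get((t.head, t.relation), set())
            if known_tails_by_query
            else ()
        )
        ranks.append(
            rank_tail(model, t, entities, filtered=filtered, known_tails=known)
        )
    ranks_arr = np.asarray(ranks, dtype=float)
    return RankingMetrics(
        mr=round4(float(np.mean(ranks_arr))),
        mrr=round4(float(np.mean(1.0 / ranks_arr))),
        hits1=round4(float(np.mean(ranks_arr <= 1))),
        hits3=round4(float(np.mean(ranks_arr <= 3))),
        hits10=round4(float(np.mean(ranks_arr <= 10))),
    )


def evaluate_usability(
    kg: KnowledgeGraph,
    config: EmbeddingConfig,
) -> RankingMetrics:
    """Split the graph 7:3, train the configured model and rank tails."""
    train, val = split_triples(kg, config.split_ratio[0], config.seed)
    model = train_embeddings(
        train, config, entities=sorted(kg.entities)
    )
    return ranking_metrics(model, val)
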