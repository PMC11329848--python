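"""End-to-end orchestration: explicit -> implicit -> tacit completion on a
cumulative graph, followed by before/after quality comparison."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import completion_explicit as explicit
from . import completion_implicit as implicit
from . import completion_tacit as tacit
from .embedding_eval import EmbeddingConfig, RankingMetrics, evaluate_usability
from .errors import UsageError
from .kg_model import KnowledgeGraph, Triple, merge_triples, save_triples
from .quality_eval import (
    AccuracyReport,
    CompletenessReport,
    PriorKnowledge,
    accuracy_report,
    completeness_report,
)

logger = logging.getLogger(__name__)


@dataclass
class EvaluationSide:
    """Metrics of one graph (before or after completion)."""

    completeness: CompletenessReport
    accuracy: AccuracyReport | None = None
    rankings: dict[str, RankingMetrics] = field(default_factory=dict)
    schema_id: str | None = None

    def to_dict(self) -> dict:
        return {
            "completeness": self.completeness.to_dict(),
            "accuracy": self.accuracy.to_dict() if self.accuracy else None,
            "rankings": {m: r.to_dict() for m, r in self.rankings.items()},
        }


@dataclass
class RunConfig:
    """Inputs and per-stage parameters of one pipeline run."""

    kg: KnowledgeGraph
    records: Sequence[tacit.Transaction] | None = None
    prior: PriorKnowledge | None = None
    gold: explicit.GoldStandard | None = None
    link_map: dict[str, str] | None = None

    run_explicit: bool = True
    run_implicit: bool = True
    run_tacit: bool = True
    run_embedding: bool = False

    pra_targets: tuple[str, ...] = ("Manifest",)
    max_path_length: int = 3
    n_walks: int = 1000
    support_threshold: int = 2
    negatives_per_positive: int = 1
    keep_policy: str = "drop_both"
    min_support: float = 0.10
    lift_threshold: float = 1.0
    embedding_models: tuple[str, ...] = ("TransE", "RotatE", "DistMult", "ComplEx")
    embedding_config: EmbeddingConfig | None = None
    seed: int = 0
    out_dir: str | Path | None = None

    def validate(self) -> None:
        if self.run_tacit and self.records is None:
            raise UsageError("tacit stage enabled but no records provided")


@dataclass
class CompletionSummary:
    """Per-stage bookkeeping plus before/after evaluation sides."""

    added_outlier: int = 0
    added_path: int = 0
    added_ontology: int = 0
    added_association: int = 0
    removed: int = 0
    before: EvaluationSide | None = None
    after: EvaluationSide | None = None
    stage_triples: dict[str, list[Triple]] = field(default_factory=dict)

    @property
    def total_added(self) -> int:
        return (
            self.added_outlier
            + self.added_path
            + self.added_ontology
            + self.added_association
        )

    @property
    def net_delta(self) -> int:
        return self.total_added - self.removed

    def to_dict(self) -> dict:
        return {
            "added_outlier": self.added_outlier,
            "added_path": self.added_path,
            "added_ontology": self.added_ontology,
            "added_association": self.added_association,
            "removed": self.removed,
            "total_added": self.total_added,
            "net_delta": self.net_delta,
            "before": self.before.to_dict() if self.before else None,
            "after": self.after.to_dict() if self.after else None,
        }


def _evaluate_side(kg: KnowledgeGraph, config: RunConfig) -> EvaluationSide:
    side = EvaluationSide(completeness=completeness_report(kg))
    if config.prior is not None:
        side.accuracy = accuracy_report(kg, config.prior)
    if config.run_embedding:
        base = config.embedding_config or EmbeddingConfig(
            dimension=24, epochs=100, seed=config.seed
        )
        for name in config.embedding_models:
            cfg = EmbeddingConfig(
                model=name,
                dimension=base.dimension,
                margin=base.margin,
                learning_rate=base.learning_rate,
                epochs=base.epochs,
                negatives_per_positive=base.negatives_per_positive,
                split_ratio=base.split_ratio,
                seed=config.seed,
            )
            side.rankings[name] = evaluate_usability(kg, cfg)
    return side


def run_pipeline(config: RunConfig) -> tuple[KnowledgeGraph, CompletionSummary]:
    """Run the enabled stages in the fixed explicit -> implicit -> tacit
    order, each on the cumulative graph, and evaluate before/after."""
    config.validate()
    summary = CompletionSummary()
    kg = config.kg
    summary.before = _evaluate_side(kg, config)
    current = kg.copy()

    if config.run_explicit:
        link_map = (
            config.link_map
            if config.link_map is not None
            else explicit.default_link_map(current)
        )
        outlier_additions = explicit.link_isolated_subgraphs(current, link_map)
        current = merge_triples(current, additions=outlier_additions)
        summary.added_outlier = len(outlier_additions)
        summary.stage_triples["outlier"] = sorted(outlier_additions, key=Triple.key)

        path_additions: set[Triple] = set()
        for target in config.pra_targets:
            features = explicit.extract_path_features(
                current,
                target,
                max_path_length=config.max_path_length,
                n_walks=config.n_walks,
                seed=config.seed,
            )
            if not features:
                logger.warning("pipeline: no path features for %r; skipping", target)
                continue
            model = explicit.train_pra(
                current,
                features,
                target,
                negatives_per_positive=config.negatives_per_positive,
                seed=config.seed,
            )
            candidates = explicit.predict_relations(
                model,
                current,
                explicit.candidate_pairs(current, target),
                support_threshold=config.support_threshold,
            )
            accepted = [
                c
                for c in explicit.ontology_filter(candidates, current)
                if c.status == "ontology_accepted"
            ]
            path_additions |= {c.triple for c in accepted}
        current = merge_triples(current, additions=path_additions)
        summary.added_path = len(path_additions)
        summary.stage_triples["path"] = sorted(path_additions, key=Triple.key)

    if config.run_implicit:
        pairs = implicit.detect_contradictions(current)
        n_before = len(current)
        current = implicit.resolve_contradictions(
            current, pairs, keep_policy=config.keep_policy
        )
        summary.removed = n_before - len(current)
        closure_additions = implicit.ontology_closure(current)
        current = merge_triples(current, additions=closure_additions)
        summary.added_ontology = len(closure_additions)
        summary.stage_triples["ontology"] = sorted(
            closure_additions, key=Triple.key
        )

    if config.run_tacit:
        frequent = tacit.apriori_frequent_itemsets(
            config.records, config.min_support
        )
        syndromes = {r.syndrome for r in config.records}
        item_types = {}
        for r in config.records:
            item_types.update({s: "symptom" for s in r.symptoms})
        item_types.update({s: "syndrome" for s in syndromes})
        rules = tacit.derive_rules(frequent, item_types)
        assoc_additions = tacit.select_and_convert(
            rules, current, lift_threshold=config.lift_threshold
        )
        current = merge_triples(current, additions=assoc_additions)
        summary.added_association = len(assoc_additions)
        summary.stage_triples["association"] = sorted(
            assoc_additions, key=Triple.key
        )

    summary.after = _evaluate_side(current, config)

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_triples(current, out / "completed.tsv")
        with open(out / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary.to_dict(), fh, indent=2)
        for stage, triples in summary.stage_triples.items():
            with open(out / f"stage_{stage}.tsv", "w", encoding="utf-8") as fh:
                for t in triples:
                    fh.write(f"{t.head}\t{t.relation}\t{t.tail}\t{t.provenance}\n")
    return current, summary


def compare_reports(before: EvaluationSide, after: EvaluationSide) -> dict:
    """Tabulate deltas between two evaluation sides.

    Raises when the sides carry mismatched schema identifiers.
    """
    if (
        before.schema_id is not None
        and after.schema_id is not None
        and before.schema_id != after.schema_id
    ):
        raise UsageError("cannot compare reports computed on different schemas")
    delta: dict = {
        "node_delta": after.completeness.node_count - before.completeness.node_count,
        "edge_delta": (
            after.completeness.relation_count - before.completeness.relation_count
        ),
        "density_delta": round(
            after.completeness.density - before.completeness.density, 10
        ),
        "average_degree_delta": round(
            after.completeness.average_degree - before.completeness.average_degree,
            10,
        ),
    }
    if before.accuracy is not None and after.accuracy is not None:
        delta["contradiction_delta"] = (
            after.accuracy.contradiction_count - before.accuracy.contradiction_count
        )
        delta["core_prescription_proportion_delta"] = round(
            after.accuracy.core_prescription_proportion
            - before.accuracy.core_prescription_proportion,
            10,
        )
        delta["kcore_prior_proportion_delta"] = round(
            after.accuracy.prior_proportion - before.accuracy.prior_proportion, 10
        )
    models = set(before.rankings) & set(after.rankings)
    if models:
        delta["rankings"] = {
            m: {
                "MR": round(after.rankings[m].mr - before.rankings[m].mr, 10),
                "MRR": round(after.rankings[m].mrr - before.rankings[m].mrr, 10),
                "Hits@1": round(
                    after.rankings[m].hits1 - before.rankings[m].hits1, 10
                ),
                "Hits@3": round(
                    after.rankings[m].hits3 - before.rankings[m].hits3, 10
                ),
                "Hits@10": round(
                    after.rankings[m].hits10 - before.rankings[m].hits10, 10
                ),
            }
            for m in sorted(models)
        }
    return delta
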