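"""Synthetic schema-conformant knowledge graphs and medical-record transactions.

Every completion and evaluation stage of the toolkit is testable against
graphs produced here: the generator plants missing-but-true triples,
contradictions, isolated components and association rules, and returns a
ledger describing exactly what was planted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .completion_tacit import Transaction
from .errors import GenerationError, UsageError
from .kg_model import Entity, KnowledgeGraph, OntologySchema, RelationSpec, Triple

logger = logging.getLogger(__name__)

# Relation names used throughout the toolkit's default domain model.
CONTAIN = "Contain"
MANIFEST = "Manifest"
CORRESPOND_TO = "CorrespondTo"
TREAT = "Treat"
CONTRAINDICATION = "ContraindicationIs"
DIFFERENTIAL_DIAGNOSIS = "DifferentialDiagnosisIs"
TREATMENT_METHOD = "TreatmentMethodIs"


def default_schema(entity_type_map: Mapping[str, str] | None = None) -> OntologySchema:
    """The syndrome/symptom/pathogenesis/prescription schema used by default.

    ``Contain`` is transitive, ``DifferentialDiagnosisIs`` is symmetric and
    ``Treat``/``ContraindicationIs`` are mutually exclusive.
    """
    return OntologySchema(
        entity_types=[
            "Syndrome",
            "SubSyndrome",
            "Symptom",
            "PathogenesisFactor",
            "Prescription",
            "TreatmentMethod",
            "Other",
        ],
        relations=[
            RelationSpec(CONTAIN, domain="any", range_type="any", transitive=True),
            RelationSpec(MANIFEST, domain="any", range_type="Symptom"),
            RelationSpec(
                CORRESPOND_TO, domain="Symptom", range_type="PathogenesisFactor"
            ),
            RelationSpec(TREAT, domain="Prescription", range_type="any",
                         exclusive_with=CONTRAINDICATION),
            RelationSpec(CONTRAINDICATION, domain="Prescription", range_type="any"),
            RelationSpec(
                DIFFERENTIAL_DIAGNOSIS, domain="any", range_type="any", symmetric=True
            ),
            RelationSpec(TREATMENT_METHOD, domain="any", range_type="TreatmentMethod"),
        ],
        entity_type_map=entity_type_map,
    )


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic graph generator.

    ``edge_density`` gives per-relation attachment probabilities; the
    ``rule_table`` (auto-built when None) lists the syndrome -> symptom-set
    rules realized in generated medical records, with a per-symptom
    penetrance.
    """

    n_syndromes: int = 12
    n_subsyndromes: int = 4
    n_symptoms: int = 60
    n_factors: int = 18
    n_prescriptions: int = 14
    edge_density: dict[str, float] = field(
        default_factory=lambda: {CONTAIN: 0.18, MANIFEST: 0.35, TREAT: 0.25}
    )
    n_factor_chains: int = 3
    n_planted_missing: int = 8
    n_planted_contradictions: int = 3
    n_isolated_components: int = 2
    n_dd_pairs: int = 3
    rule_table: list[tuple[str, frozenset[str], float]] | None = None
    syndrome_weights: dict[str, float] | None = None
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_syndromes": self.n_syndromes,
            "n_subsyndromes": self.n_subsyndromes,
            "n_symptoms": self.n_symptoms,
            "n_factors": self.n_factors,
            "n_prescriptions": self.n_prescriptions,
            "n_factor_chains": self.n_factor_chains,
            "n_planted_missing": self.n_planted_missing,
            "n_planted_contradictions": self.n_planted_contradictions,
            "n_isolated_components": self.n_isolated_components,
            "n_dd_pairs": self.n_dd_pairs,
        }
        for name, v in counts.items():
            if v < 0:
                raise UsageError(f"{name} must be >= 0, got {v}")
        for rel, p in self.edge_density.items():
            if not 0.0 <= p <= 1.0:
                raise UsageError(f"edge_density[{rel!r}] must be in [0,1], got {p}")
        if self.rule_table is not None:
            for syndrome, symptoms, pen in self.rule_table:
                if not 0.0 < pen <= 1.0:
                    raise UsageError(
                        f"rule penetrance for {syndrome!r} must be in (0,1], got {pen}"
                    )
        if self.n_isolated_components > self.n_subsyndromes:
            raise UsageError(
                "n_isolated_components cannot exceed n_subsyndromes "
                f"({self.n_isolated_components} > {self.n_subsyndromes})"
            )


@dataclass
class SyntheticLedger:
    """What the generator planted, for exact-match testing downstream."""

    withheld_triples: set[Triple] = field(default_factory=set)
    planted_contradiction_pairs: set[tuple[Triple, Triple]] = field(
        default_factory=set
    )
    planted_isolated_component_ids: list[set[str]] = field(default_factory=list)
    planted_rules: list[tuple[str, frozenset[str], float]] = field(
        default_factory=list
    )

    def withheld_by_relation(self, relation: str) -> set[Triple]:
        return {t for t in self.withheld_triples if t.relation == relation}


def _weighted_sample_without_replacement(
    rng: np.random.Generator, items: Sequence[str], weights: Sequence[float], k: int
) -> list[str]:
    items = list(items)
    weights = list(weights)
    chosen: list[str] = []
    for _ in range(min(k, len(items))):
        w = np.asarray(weights, dtype=float)
        probs = w / w.sum()
        idx = int(rng.choice(len(items), p=probs))
        chosen.append(items.pop(idx))
        weights.pop(idx)
    return chosen


def generate_kg(config: GeneratorConfig) -> tuple[KnowledgeGraph, SyntheticLedger]:
    """Build a synthetic typed graph plus a ledger of everything planted.

    The emitted graph mirrors the syndrome/symptom/pathogenesis/prescription
    structure: syndromes contain pathogenesis factors, manifest symptoms
    (chosen preferentially so degrees are heavy-tailed), symptoms correspond
    to factors, prescriptions treat syndromes/symptoms; transitive Contain
    chains are left unclosed, a subset of true Manifest triples is withheld
    (each with surviving two-step evidence), Treat/ContraindicationIs
    contradictions are planted, and small subsyndrome components are left
    disconnected from the giant component.  Deterministic given the seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    syndromes = [f"SYN{i:03d}" for i in range(config.n_syndromes)]
    symptoms = [f"SYM{i:03d}" for i in range(config.n_symptoms)]
    factors = [f"FAC{i:03d}" for i in range(config.n_factors)]
    prescriptions = [f"PRX{i:03d}" for i in range(config.n_prescriptions)]
    subsyndromes = [f"SUB{i:03d}" for i in range(config.n_subsyndromes)]

    type_map: dict[str, str] = {}
    type_map.update({e: "Syndrome" for e in syndromes})
    type_map.update({e: "Symptom" for e in symptoms})
    type_map.update({e: "PathogenesisFactor" for e in factors})
    type_map.update({e: "Prescription" for e in prescriptions})
    type_map.update({e: "SubSyndrome" for e in subsyndromes})

    labels = {e: f"Syndrome {i}" for i, e in enumerate(syndromes)}
    labels.update({e: f"Symptom {i}" for i, e in enumerate(symptoms)})
    labels.update({e: f"Factor {i}" for i, e in enumerate(factors)})
    labels.update({e: f"Prescription {i}" for i, e in enumerate(prescriptions)})

    triples: set[Triple] = set()
    p_contain = config.edge_density.get(CONTAIN, 0.18)
    p_manifest = config.edge_density.get(MANIFEST, 0.35)
    p_treat = config.edge_density.get(TREAT, 0.25)

    # Syndrome -Contain-> PathogenesisFactor (>=1 per syndrome).
    contain: dict[str, set[str]] = {}
    for s in syndromes:
        chosen = {f for f in factors if rng.random() < p_contain}
        if not chosen:
            chosen = {factors[int(rng.integers(len(factors)))]}
        contain[s] = chosen
        triples.update(Triple(s, CONTAIN, f) for f in chosen)
    # every factor is contained by some syndrome (keeps the giant connected)
    for f in factors:
        if not any(f in c for c in contain.values()):
            s = syndromes[int(rng.integers(config.n_syndromes))]
            contain[s].add(f)
            triples.add(Triple(s, CONTAIN, f))

    # Factor -Contain-> Factor chains whose transitive closure is withheld.
    if config.n_factor_chains > 0 and config.n_factors >= 3:
        for _ in range(config.n_factor_chains):
            chain = rng.choice(config.n_factors, size=3, replace=False)
            f1, f2, f3 = (factors[int(i)] for i in chain)
            triples.add(Triple(f1, CONTAIN, f2))
            triples.add(Triple(f2, CONTAIN, f3))

    # Symptom -CorrespondTo-> exactly one factor.
    sym_factor = {
        x: factors[int(rng.integers(config.n_factors))] for x in symptoms
    }
    triples.update(Triple(x, CORRESPOND_TO, f) for x, f in sym_factor.items())

    # Syndrome -Manifest-> Symptom, preferential attachment on symptoms,
    # restricted to ontology-consistent candidates (symptom factor contained).
    sym_degree = {x: 1.0 for x in symptoms}
    manifest: dict[str, list[str]] = {}
    for s in syndromes:
        candidates = sorted(x for x in symptoms if sym_factor[x] in contain[s])
        if not candidates:
            # Force consistency: adopt one symptom's factor into the syndrome.
            x = symptoms[int(rng.integers(config.n_symptoms))]
            contain[s].add(sym_factor[x])
            triples.add(Triple(s, CONTAIN, sym_factor[x]))
            candidates = [x]
        k = max(1, int(rng.binomial(len(candidates), p_manifest)))
        chosen = _weighted_sample_without_replacement(
            rng, candidates, [sym_degree[x] for x in candidates], k
        )
        manifest[s] = chosen
        for x in chosen:
            sym_degree[x] += 1.0
            triples.add(Triple(s, MANIFEST, x))

    # Prescription -Treat-> Syndrome (every syndrome treated) and -Treat-> Symptom.
    treats: dict[str, list[str]] = {p: [] for p in prescriptions}
    for i, s in enumerate(syndromes):
        p = prescriptions[i % config.n_prescriptions]
        treats[p].append(s)
        triples.add(Triple(p, TREAT, s))
    # spare prescriptions still treat a syndrome (no orphan components)
    for j, p in enumerate(prescriptions):
        if not treats[p]:
            s = syndromes[j % config.n_syndromes]
            treats[p].append(s)
            triples.add(Triple(p, TREAT, s))
    for p in prescriptions:
        for s in treats[p]:
            for x in manifest[s]:
                if rng.random() < p_treat:
                    triples.add(Triple(p, TREAT, x))

    # Symmetric differential-diagnosis pairs; only one direction emitted.
    if config.n_syndromes >= 2:
        for _ in range(config.n_dd_pairs):
            i, j = rng.choice(config.n_syndromes, size=2, replace=False)
            triples.add(Triple(syndromes[int(i)], DIFFERENTIAL_DIAGNOSIS,
                               syndromes[int(j)]))

    # Subsyndromes: isolated components first, the rest linked to the giant.
    ledger = SyntheticLedger()
    iso_symptoms: list[str] = []
    for j, sub in enumerate(subsyndromes):
        p = prescriptions[j % config.n_prescriptions]
        labels[sub] = f"{labels[p]} Syndrome"
        if j < config.n_isolated_components:
            iso_sym = f"ISO{j:03d}"
            type_map[iso_sym] = "Symptom"
            labels[iso_sym] = f"Isolated symptom {j}"
            iso_symptoms.append(iso_sym)
            triples.add(Triple(sub, MANIFEST, iso_sym))
            ledger.planted_isolated_component_ids.append({sub, iso_sym})
        else:
            triples.add(Triple(p, TREAT, sub))
            x = manifest[treats[p][0]][0] if treats[p] else symptoms[0]
            triples.add(Triple(sub, MANIFEST, x))

    # Planted contradictions: Treat + ContraindicationIs on the same pair.
    candidates = [
        (p, x)
        for p in prescriptions
        for x in symptoms
        if Triple(p, TREAT, x) not in triples
    ]
    if config.n_planted_contradictions > len(candidates):
        raise GenerationError("not enough free (prescription, symptom) pairs "
                              "for the requested contradictions")
    idx = rng.choice(len(candidates), size=config.n_planted_contradictions,
                     replace=False)
    for i in sorted(int(k) for k in idx):
        p, x = candidates[i]
        a = Triple(p, TREAT, x)
        b = Triple(p, CONTRAINDICATION, x)
        triples.add(a)
        triples.add(b)
        ledger.planted_contradiction_pairs.add((a, b))

    # Withhold true Manifest triples.  Each withheld (s, x) keeps its
    # two-step evidence path (s -Contain-> factor <-CorrespondTo- x) and is
    # reinforced with alternate path types (prescription co-treatment and a
    # factor-sharing second syndrome manifesting x) so the pair clears the
    # supporting-path threshold of the path-ranking predictor.
    eligible = sorted(
        (s, x)
        for s in syndromes
        for x in manifest[s]
        if len(manifest[s]) >= 2 and sym_factor[x] in contain[s]
    )
    if config.n_planted_missing > len(eligible):
        raise GenerationError(
            f"cannot withhold {config.n_planted_missing} Manifest triples; "
            f"only {len(eligible)} are eligible"
        )
    per_syndrome_left = {s: len(manifest[s]) for s in syndromes}
    withheld_manifest: set[Triple] = set()
    protected: set[Triple] = set()
    order = rng.permutation(len(eligible))
    for i in order:
        if len(withheld_manifest) >= config.n_planted_missing:
            break
        s, x = eligible[int(i)]
        if per_syndrome_left[s] <= 1:
            continue
        t = Triple(s, MANIFEST, x)
        if t in withheld_manifest or t in protected:
            continue
        p_s = prescriptions[syndromes.index(s) % config.n_prescriptions]
        if Triple(p_s, CONTRAINDICATION, x) in triples:
            continue  # would plant an unledgered contradiction
        # Alternate path 1: prescription treating s also treats x.
        triples.add(Triple(p_s, TREAT, x))
        # Alternate path 2: a second syndrome shares x's factor and manifests x.
        others = [
            s2 for s2 in syndromes
            if s2 != s and sym_factor[x] in contain[s2]
        ]
        if others:
            s2 = others[int(rng.integers(len(others)))]
        else:
            pool2 = [s2 for s2 in syndromes if s2 != s]
            s2 = pool2[int(rng.integers(len(pool2)))]
            contain[s2].add(sym_factor[x])
            triples.add(Triple(s2, CONTAIN, sym_factor[x]))
        support = Triple(s2, MANIFEST, x)
        if support in withheld_manifest:
            continue
        if support not in triples:
            triples.add(support)
            manifest[s2].append(x)
            per_syndrome_left[s2] += 1
        protected.add(support)
        withheld_manifest.add(t)
        per_syndrome_left[s] -= 1
        triples.discard(t)
        manifest[s].remove(x)
    if len(withheld_manifest) < config.n_planted_missing:
        raise GenerationError("could not withhold the requested number of "
                              "Manifest triples without emptying a syndrome")
    ledger.withheld_triples |= withheld_manifest

    # Withheld Contain closure triples: transitive closure minus emitted.
    contain_edges = {(t.head, t.tail) for t in triples if t.relation == CONTAIN}
    closure = _transitive_closure_pairs(contain_edges)
    ledger.withheld_triples |= {
        Triple(h, CONTAIN, t) for h, t in closure - contain_edges if h != t
    }

    # Rule table for record generation.  Withheld Manifest symptoms are kept
    # in their syndrome's rule so association mining can re-discover the
    # missing links from records.
    if config.rule_table is not None:
        ledger.planted_rules = list(config.rule_table)
    else:
        withheld_by_s: dict[str, set[str]] = {}
        for t in withheld_manifest:
            withheld_by_s.setdefault(t.head, set()).add(t.tail)
        for s in syndromes:
            rule_ids = set(sorted(manifest[s])[:4]) | withheld_by_s.get(s, set())
            if rule_ids:
                rule_symptoms = frozenset(labels[x] for x in rule_ids)
                ledger.planted_rules.append((labels[s], rule_symptoms, 0.8))

    schema = default_schema(type_map)
    kg = KnowledgeGraph(
        schema,
        entities=[Entity(e, labels.get(e, e), t) for e, t in sorted(type_map.items())],
        triples=triples,
    )
    _verify_ledger(kg, ledger)
    return kg, ledger


def _transitive_closure_pairs(edges: set[tuple[str, str]]) -> set[tuple[str, str]]:
    succ: dict[str, set[str]] = {}
    for h, t in edges:
        succ.setdefault(h, set()).add(t)
    closure = set(edges)
    changed = True
    while changed:
        changed = False
        for h, t in list(closure):
            for t2 in succ.get(t, ()):
                if (h, t2) not in closure:
                    closure.add((h, t2))
                    changed = True
    return closure


def _verify_ledger(kg: KnowledgeGraph, ledger: SyntheticLedger) -> None:
    """Every planted item must be real and every withheld triple recoverable."""
    from .kg_model import connected_components  # local to avoid cycle noise

    for t in ledger.withheld_triples:
        if t in kg:
            raise GenerationError(f"withheld triple {t.key()} still emitted")
        if t.relation == MANIFEST:
            evidence = any(
                kg.has_triple(t.head, CONTAIN, f.tail)
                for f in kg.triples_of(CORRESPOND_TO)
                if f.head == t.tail
            )
            if not evidence:
                raise GenerationError(
                    f"withheld {t.key()} lacks a two-step evidence path"
                )
        elif t.relation == CONTAIN:
            pairs = {(c.head, c.tail) for c in kg.triples_of(CONTAIN)}
            if (t.head, t.tail) not in _transitive_closure_pairs(pairs):
                raise GenerationError(
                    f"withheld {t.key()} is not a Contain closure triple"
                )
    for a, b in ledger.planted_contradiction_pairs:
        if a not in kg or b not in kg:
            raise GenerationError("planted contradiction pair missing from graph")
    comps = connected_components(kg)
    comp_sets = [frozenset(c) for c in comps]
    for planted in ledger.planted_isolated_component_ids:
        if frozenset(planted) not in comp_sets:
            raise GenerationError(
                f"planted isolated component {sorted(planted)} is not isolated"
            )


def expected_symptom_rate(
    symptom: str,
    rules: Sequence[tuple[str, frozenset[str], float]],
    weights: Mapping[str, float],
    noise: float,
) -> float:
    """Marginal P(symptom in record) under the generative record model."""
    total = sum(weights.values())
    rate = 0.0
    for syndrome, rule_symptoms, pen in rules:
        w = weights[syndrome] / total
        p_rule = pen if symptom in rule_symptoms else 0.0
        rate += w * (p_rule + (1.0 - p_rule) * noise)
    return rate


def generate_records(
    kg: KnowledgeGraph,
    n_records: int,
    noise: float = 0.05,
    seed: int = 0,
    rules: Sequence[tuple[str, frozenset[str], float]] | None = None,
    syndrome_weights: Mapping[str, float] | None = None,
) -> list[Transaction]:
    """Sample medical-record transactions carrying planted syndrome rules.

    Each record holds one syndrome label, each of the syndrome's rule
    symptoms independently with its penetrance, and every other symptom in
    the pool independently with probability ``noise``.  The syndrome
    prevalence distribution is configurable to emulate class imbalance.
    """
    if not 0.0 <= noise < 1.0:
        raise UsageError(f"noise must be in [0,1), got {noise}")
    if rules is None:
        rules = _default_rules_from_kg(kg)
    if not rules:
        raise UsageError("kg has no syndrome with Manifest symptoms")
    rng = np.random.default_rng(seed)

    syndrome_labels = [r[0] for r in rules]
    if syndrome_weights is None:
        weights = {s: 1.0 for s in syndrome_labels}
    else:
        weights = {s: float(syndrome_weights.get(s, 0.0)) for s in syndrome_labels}
        if sum(weights.values()) <= 0:
            raise UsageError("syndrome_weights give zero total mass")

    pool = sorted(
        {e.label for e in kg.entities_of_type("Symptom")}
        | {lab for _, symps, _ in rules for lab in symps}
    )
    # Planted rules must be positively associated under this configuration
    # (vacuous in a single-syndrome universe, where lift is 1 by definition).
    if len(rules) > 1:
        for syndrome, rule_symptoms, pen in rules:
            for x in rule_symptoms:
                base = expected_symptom_rate(x, rules, weights, noise)
                if pen <= base:
                    raise GenerationError(
                        f"rule {syndrome!r} -> {x!r}: penetrance {pen} does "
                        f"not exceed the expected base rate {base:.4f}; lift "
                        f"would be <= 1"
                    )

    probs = np.array([weights[s] for s in syndrome_labels], dtype=float)
    probs /= probs.sum()
    rule_map = {s: (symps, pen) for s, symps, pen in rules}

    records: list[Transaction] = []
    for _ in range(n_records):
        s = syndrome_labels[int(rng.choice(len(syndrome_labels), p=probs))]
        rule_symptoms, pen = rule_map[s]
        items = {x for x in sorted(rule_symptoms) if rng.random() < pen}
        if noise > 0:
            items |= {
                x for x in pool
                if x not in rule_symptoms and rng.random() < noise
            }
        records.append(Transaction(syndrome=s, symptoms=frozenset(items)))
    return records


def _default_rules_from_kg(
    kg: KnowledgeGraph,
) -> list[tuple[str, frozenset[str], float]]:
    rules = []
    for s in kg.entities_of_type("Syndrome"):
        tails = sorted(t.tail for t in kg.triples_of(MANIFEST) if t.head == s.id)
        if tails:
            labels = frozenset(kg.entity(x).label for x in tails[:4])
            rules.append((s.label, labels, 0.8))
    return rules
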