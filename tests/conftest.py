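import pytest

from kgc.kg_model import Entity, KnowledgeGraph, OntologySchema, RelationSpec, Triple
from kgc.synthetic_data import GeneratorConfig, generate_kg


@pytest.fixture(scope="session")
def synth():
    """Default synthetic graph + ledger, shared read-only across tests."""
    return generate_kg(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def synth_kg(synth):
    return synth[0]


@pytest.fixture(scope="session")
def synth_ledger(synth):
    return synth[1]


@pytest.fixture
def kg_factory():
    """Build a small graph from (head, relation, tail) tuples.

    Relations are auto-declared (with optional flags); entity types come
    from an optional type map.
    """

    def make(
        triples,
        type_map=None,
        relation_flags=None,
        entity_types=("Syndrome", "SubSyndrome", "Symptom", "PathogenesisFactor",
                      "Prescription", "TreatmentMethod"),
    ):
        relation_flags = relation_flags or {}
        names = {t[1] for t in triples} | set(relation_flags)
        relations = [
            RelationSpec(name, **relation_flags.get(name, {})) for name in sorted(names)
        ]
        schema = OntologySchema(entity_types, relations, type_map or {})
        kg = KnowledgeGraph(schema)
        for ent_id, etype in (type_map or {}).items():
            kg.add_entity(Entity(ent_id, entity_type=etype))
        for t in triples:
            kg.add_triple(Triple(*t))
        return kg

    return make
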