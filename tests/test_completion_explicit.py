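import numpy as np
import pytest

from kgc import completion_explicit as ex
from kgc.errors import EntityLookupError, UsageError
from kgc.kg_model import Triple, connected_components, merge_triples
from kgc.completion_explicit import (
    FORWARD,
    INVERSE,
    GoldStandard,
    PathFeature,
    detect_isolated_subgraphs,
    evaluate_against_gold,
    extract_path_features,
    f1_score,
    link_isolated_subgraphs,
    ontology_filter,
    path_feature_value,
    predict_relations,
    train_pra,
)


# --------------------------------------------------------------- outliers
class TestIsolatedSubgraphs:
    def test_two_small_components_reported(self, kg_factory):
        kg = kg_factory(
            [("a", "R", "b"), ("b", "R", "c"), ("d", "R", "e"), ("f", "R", "g")]
        )
        results = detect_isolated_subgraphs(kg)
        assert [c for c, _ in results] == [{"d", "e"}, {"f", "g"}]
        assert all(hint == "Other" for _, hint in results)

    def test_connected_graph_gives_empty(self, kg_factory):
        kg = kg_factory([("a", "R", "b"), ("b", "R", "c")])
        assert detect_isolated_subgraphs(kg) == []

    def test_subsyndrome_hint(self, kg_factory):
        kg = kg_factory(
            [("a", "R", "b"), ("a", "R", "c"), ("sub1", "R", "x")],
            type_map={"sub1": "SubSyndrome"},
        )
        results = detect_isolated_subgraphs(kg)
        assert results == [({"sub1", "x"}, "SubSyndrome")]

    def test_planted_components_match_ledger(self, synth_kg, synth_ledger):
        found = [set(c) for c, hint in detect_isolated_subgraphs(synth_kg)
                 if hint == "SubSyndrome"]
        for planted in synth_ledger.planted_isolated_component_ids:
            assert planted in found


class TestLinkIsolatedSubgraphs:
    def test_single_mapping_merges_component(self, kg_factory):
        kg = kg_factory(
            [("p1", "Treat", "s1"), ("sub1", "Manifest", "x1")],
            type_map={"sub1": "SubSyndrome", "p1": "Prescription"},
        )
        added = link_isolated_subgraphs(kg, {"sub1": "p1"})
        assert added == {Triple("p1", "Treat", "sub1")}
        assert all(t.provenance == "outlier_completion" for t in added)
        merged = merge_triples(kg, additions=added)
        assert len(connected_components(merged)) == 1

    def test_empty_map_gives_empty(self, synth_kg):
        assert link_isolated_subgraphs(synth_kg, {}) == set()

    def test_unknown_entity_raises(self, synth_kg):
        with pytest.raises(EntityLookupError):
            link_isolated_subgraphs(synth_kg, {"ghost": "alsoghost"})

    def test_default_resolver_relinks_all_planted(self, synth_kg, synth_ledger):
        link_map = ex.default_link_map(synth_kg)
        added = link_isolated_subgraphs(synth_kg, link_map)
        assert len(added) == len(synth_ledger.planted_isolated_component_ids)
        merged = merge_triples(synth_kg, additions=added)
        remaining = [c for c, hint in detect_isolated_subgraphs(merged)
                     if hint == "SubSyndrome"]
        assert remaining == []


# --------------------------------------------------------------- PRA core
def brute_force_path_value(kg, source, steps, target):
    """Exhaustive enumeration of conforming paths, product of 1/out-degree."""
    adj = ex._Adjacency(kg)

    def recurse(node, remaining):
        if not remaining:
            return 1.0 if node == target else 0.0
        rel, direction = remaining[0]
        nbrs = adj.neighbors(node, rel, direction)
        if not nbrs:
            return 0.0
        return sum(recurse(n, remaining[1:]) for n in nbrs) / len(nbrs)

    return recurse(source, list(steps))


class TestPathFeatureValue:
    def test_uniform_split(self, kg_factory):
        kg = kg_factory([("s", "R", "t1"), ("s", "R", "t2")])
        f = PathFeature(((("R"), FORWARD),))
        assert path_feature_value(kg, "s", f, "t1") == 0.5

    def test_no_edge_gives_zero(self, kg_factory):
        kg = kg_factory([("a", "R", "b")])
        f = PathFeature((("Q", FORWARD),), ) if False else PathFeature((("R", FORWARD),))
        assert path_feature_value(kg, "b", f, "a") == 0.0

    def test_inverse_step(self, kg_factory):
        kg = kg_factory([("a", "R", "b")])
        f = PathFeature((("R", INVERSE),))
        assert path_feature_value(kg, "b", f, "a") == 1.0

    def test_two_step_lattice_equals_enumeration(self, kg_factory):
        kg = kg_factory(
            [("a", "R", "b"), ("a", "R", "c"), ("b", "S", "d"), ("c", "S", "d"),
             ("c", "S", "e")]
        )
        f = PathFeature((("R", FORWARD), ("S", FORWARD)))
        got = path_feature_value(kg, "a", f, "d")
        assert got == pytest.approx(0.5 * 1.0 + 0.5 * 0.5)
        assert got == pytest.approx(brute_force_path_value(kg, "a", f.steps, "d"))

    def test_matches_brute_force_on_random_graph(self, kg_factory):
        rng = np.random.default_rng(0)
        nodes = [f"n{i}" for i in range(30)]
        triples = []
        for rel in ("R", "S", "T"):
            for _ in range(60):
                h, t = rng.choice(30, size=2, replace=False)
                triples.append((nodes[h], rel, nodes[t]))
        kg = kg_factory(triples)
        features = [
            PathFeature((("R", FORWARD), ("S", FORWARD))),
            PathFeature((("R", FORWARD), ("S", INVERSE), ("T", FORWARD))),
            PathFeature((("T", INVERSE), ("R", FORWARD))),
        ]
        for f in features:
            for src, dst in [("n0", "n5"), ("n3", "n12"), ("n7", "n1")]:
                assert path_feature_value(kg, src, f, dst) == pytest.approx(
                    brute_force_path_value(kg, src, f.steps, dst)
                )

    def test_probability_conservation(self, kg_factory, synth_kg):
        f = PathFeature((("Contain", FORWARD), ("CorrespondTo", INVERSE)))
        adj = ex._Adjacency(synth_kg)
        for src in ["SYN000", "SYN001", "SYN002"]:
            dist = ex._walk_distribution(adj, src, f.steps)
            assert sum(dist.values()) <= 1.0 + 1e-12

    def test_conservation_equality_when_no_dead_ends(self, kg_factory):
        kg = kg_factory([("a", "R", "b"), ("a", "R", "c"), ("b", "S", "d"),
                         ("c", "S", "d")])
        f = PathFeature((("R", FORWARD), ("S", FORWARD)))
        adj = ex._Adjacency(kg)
        dist = ex._walk_distribution(adj, "a", f.steps)
        assert sum(dist.values()) == pytest.approx(1.0)


class TestExtractPathFeatures:
    def test_unique_connecting_path_found(self, kg_factory):
        # Manifest(s, x) is explained only by Contain;CorrespondTo^-1
        kg = kg_factory(
            [("s", "Manifest", "x"), ("s", "Contain", "f"), ("x", "CorrespondTo", "f")]
        )
        feats = extract_path_features(kg, "Manifest", max_path_length=2,
                                      n_walks=500, seed=0)
        assert PathFeature((("Contain", FORWARD), ("CorrespondTo", INVERSE))) in feats

    def test_max_length_one_only_single_steps(self, synth_kg):
        feats = extract_path_features(synth_kg, "Manifest", max_path_length=1,
                                      n_walks=300, seed=0)
        assert all(len(f) == 1 for f in feats)
        assert PathFeature((("Manifest", FORWARD),)) not in feats

    def test_deterministic(self, synth_kg):
        a = extract_path_features(synth_kg, "Manifest", 3, 400, seed=9)
        b = extract_path_features(synth_kg, "Manifest", 3, 400, seed=9)
        assert a == b

    def test_missing_relation_warns_empty(self, kg_factory, caplog):
        kg = kg_factory([("a", "R", "b")], relation_flags={"Manifest": {}})
        assert extract_path_features(kg, "Manifest", 2, 10, seed=0) == []


class TestTrainPredict:
    def separable_kg(self, kg_factory):
        # Manifest holds iff Contain;CorrespondTo^-1 connects the pair.
        triples = []
        for i in range(8):
            s, x, f = f"s{i}", f"x{i}", f"f{i}"
            triples += [(s, "Contain", f), (x, "CorrespondTo", f),
                        (s, "Manifest", x)]
        type_map = {f"s{i}": "Syndrome" for i in range(8)}
        type_map.update({f"x{i}": "Symptom" for i in range(8)})
        type_map.update({f"f{i}": "PathogenesisFactor" for i in range(8)})
        return kg_factory(triples, type_map=type_map)

    def test_separable_fixture_perfect_classification(self, kg_factory):
        kg = self.separable_kg(kg_factory)
        feature = PathFeature((("Contain", FORWARD), ("CorrespondTo", INVERSE)))
        model = train_pra(kg, [feature], "Manifest", negatives_per_positive=2,
                          seed=0)
        adj = ex._Adjacency(kg)
        pos = [(t.head, t.tail) for t in kg.triples_of("Manifest")]
        neg = [("s0", "x1"), ("s2", "x5"), ("s3", "x7")]
        x = ex._feature_matrix(adj, pos + neg, [feature])
        scores = x @ model.weights + model.intercept
        predictions = scores > 0
        assert predictions[: len(pos)].all()
        assert not predictions[len(pos):].any()

    def test_zero_features_scores_intercept(self, kg_factory):
        kg = self.separable_kg(kg_factory)
        dead = PathFeature((("Treat", FORWARD),))
        model = train_pra(kg, [dead], "Manifest", seed=0)
        adj = ex._Adjacency(kg)
        x = ex._feature_matrix(adj, [("s0", "x1")], [dead])
        assert (x == 0).all()
        score = (x @ model.weights + model.intercept).item()
        assert score == pytest.approx(model.intercept)

    def test_deterministic_weights(self, synth_kg):
        feats = extract_path_features(synth_kg, "Manifest", 3, 400, seed=1)
        m1 = train_pra(synth_kg, feats, "Manifest", seed=3)
        m2 = train_pra(synth_kg, feats, "Manifest", seed=3)
        np.testing.assert_array_equal(m1.weights, m2.weights)

    def test_predict_drops_zero_support_and_existing(self, kg_factory):
        kg = self.separable_kg(kg_factory)
        feature = PathFeature((("Contain", FORWARD), ("CorrespondTo", INVERSE)))
        model = train_pra(kg, [feature], "Manifest", seed=0)
        # (s0, x1): no path -> zero support -> dropped even at threshold 0
        out = predict_relations(model, kg, [("s0", "x1")], support_threshold=0)
        assert out == []
        # existing triple is never re-emitted
        out = predict_relations(model, kg, [("s0", "x0")], support_threshold=0)
        assert out == []

    def test_support_threshold_semantics(self, kg_factory):
        # pair connected by exactly 3 distinct feature paths passes "> 2"
        kg = kg_factory(
            [("s", "A", "m1"), ("m1", "B", "x"),
             ("s", "C", "m2"), ("m2", "D", "x"),
             ("s", "E", "m3"), ("m3", "F", "x"),
             ("s", "Manifest", "y")],
        )
        feats = [
            PathFeature((("A", FORWARD), ("B", FORWARD))),
            PathFeature((("C", FORWARD), ("D", FORWARD))),
            PathFeature((("E", FORWARD), ("F", FORWARD))),
        ]
        model = ex.PRAModel("Manifest", feats, np.ones(3), 0.0)
        out = predict_relations(model, kg, [("s", "x")], support_threshold=2)
        assert len(out) == 1 and out[0].supporting_paths == 3
        assert predict_relations(model, kg, [("s", "x")], support_threshold=3) == []

    def test_ranking_matches_hand_oracle(self, synth_kg):
        feats = extract_path_features(synth_kg, "Manifest", 3, 800, seed=1)
        model = train_pra(synth_kg, feats, "Manifest", seed=1)
        pairs = ex.candidate_pairs(synth_kg, "Manifest")[:10]
        out = predict_relations(model, synth_kg, pairs, support_threshold=0)
        # oracle: score every pair via the public per-pair function and sort
        oracle = []
        for h, t in pairs:
            values = [path_feature_value(synth_kg, h, f, t) for f in feats]
            support = sum(v != 0 for v in values)
            score = float(np.dot(values, model.weights) + model.intercept)
            if support > 0:
                oracle.append((-support, -score, h, t))
        oracle.sort()
        assert [(c.head, c.tail) for c in out] == [(h, t) for _, _, h, t in oracle]


class TestOntologyFilter:
    def fixture_kg(self, kg_factory):
        return kg_factory(
            [
                ("syn1", "Contain", "f1"),
                ("x1", "CorrespondTo", "f1"),
                ("x2", "CorrespondTo", "f2"),
                ("p1", "Treat", "syn1"),
            ],
            type_map={"syn1": "Syndrome", "x1": "Symptom", "x2": "Symptom",
                      "x3": "Symptom", "p1": "Prescription",
                      "f1": "PathogenesisFactor", "f2": "PathogenesisFactor"},
        )

    def make_candidate(self, h, r, t):
        return ex.CandidateTriple(Triple(h, r, t), score=1.0, supporting_paths=3)

    def test_consistent_manifest_accepted(self, kg_factory):
        kg = self.fixture_kg(kg_factory)
        (c,) = ontology_filter([self.make_candidate("syn1", "Manifest", "x1")], kg)
        assert c.status == "ontology_accepted"

    def test_inconsistent_manifest_rejected(self, kg_factory):
        kg = self.fixture_kg(kg_factory)
        (c,) = ontology_filter([self.make_candidate("syn1", "Manifest", "x2")], kg)
        assert c.status == "ontology_rejected"

    def test_unmappable_symptom_rejected(self, kg_factory):
        kg = self.fixture_kg(kg_factory)
        (c,) = ontology_filter([self.make_candidate("syn1", "Manifest", "x3")], kg)
        assert c.status == "ontology_rejected"

    def test_treat_candidate_via_curable_syndrome(self, kg_factory):
        kg = self.fixture_kg(kg_factory)
        (good,) = ontology_filter([self.make_candidate("p1", "Treat", "x1")], kg)
        (bad,) = ontology_filter([self.make_candidate("p1", "Treat", "x2")], kg)
        assert good.status == "ontology_accepted"
        assert bad.status == "ontology_rejected"

    def test_idempotent_and_order_independent(self, kg_factory):
        kg = self.fixture_kg(kg_factory)
        cands = [
            self.make_candidate("syn1", "Manifest", "x1"),
            self.make_candidate("syn1", "Manifest", "x2"),
        ]
        once = ontology_filter(cands, kg)
        twice = ontology_filter(once, kg)
        assert once == twice
        reordered = ontology_filter(list(reversed(cands)), kg)
        assert sorted(c.triple.key() + (c.status,) for c in once) == sorted(
            c.triple.key() + (c.status,) for c in reordered
        )

    def test_acceptance_proportion_matches_construction(self, kg_factory):
        # 40 candidates built with known accept labels: 12 consistent, 28 not
        triples = [("p0", "Treat", "syn0")]
        type_map = {"p0": "Prescription"}
        cands = []
        expected = {}
        for i in range(40):
            s, x, f = f"s{i}", f"x{i}", f"f{i}"
            type_map.update({s: "Syndrome", x: "Symptom",
                             f: "PathogenesisFactor"})
            triples.append((x, "CorrespondTo", f))
            if i < 12:
                triples.append((s, "Contain", f))
                expected[(s, x)] = "ontology_accepted"
            else:
                triples.append((s, "Contain", "f0"))
                expected[(s, x)] = "ontology_rejected"
            cands.append(self.make_candidate(s, "Manifest", x))
        kg = kg_factory(triples, type_map=type_map)
        out = ontology_filter(cands, kg)
        assert {(c.head, c.tail): c.status for c in out} == expected


class TestGoldEvaluation:
    def test_paper_f1_value(self):
        assert f1_score(0.6124, 0.4906) == 0.5448

    def test_exact_match(self):
        pos = {Triple("a", "R", "b"), Triple("c", "R", "d")}
        gold = GoldStandard(positive=set(pos))
        assert evaluate_against_gold(pos, gold) == (1.0, 1.0, 1.0)

    def test_disjoint_predictions(self):
        gold = GoldStandard(positive={Triple("a", "R", "b")})
        p, r, f1 = evaluate_against_gold({Triple("x", "R", "y")}, gold)
        assert (r, f1) == (0.0, 0.0)

    def test_mixed_counts(self):
        gold = GoldStandard(
            positive={Triple("a", "R", "b"), Triple("c", "R", "d")},
            negative={Triple("e", "R", "f")},
        )
        predicted = {Triple("a", "R", "b"), Triple("e", "R", "f"),
                     Triple("g", "R", "h")}
        p, r, f1 = evaluate_against_gold(predicted, gold)
        assert p == pytest.approx(1 / 3, abs=1e-4)
        assert r == 0.5
        assert f1 == f1_score(1 / 3, 0.5)

    def test_empty_positive_raises(self):
        with pytest.raises(UsageError):
            evaluate_against_gold(set(), GoldStandard(positive=set()))

    def test_overlapping_gold_rejected(self):
        t = Triple("a", "R", "b")
        with pytest.raises(UsageError):
            GoldStandard(positive={t}, negative={t})


class TestPlantedRecovery:
    def test_withheld_manifest_recall(self, synth_kg, synth_ledger):
        feats = extract_path_features(synth_kg, "Manifest", 3, 2000, seed=1)
        model = train_pra(synth_kg, feats, "Manifest", seed=1)
        cands = predict_relations(
            model, synth_kg, ex.candidate_pairs(synth_kg, "Manifest"),
            support_threshold=2,
        )
        accepted = {
            c.triple for c in ontology_filter(cands, synth_kg)
            if c.status == "ontology_accepted"
        }
        withheld = synth_ledger.withheld_by_relation("Manifest")
        recall = len(accepted & withheld) / len(withheld)
        assert recall >= 0.8
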