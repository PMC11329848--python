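# kgc-toolkit

Knowledge-graph completion and quality evaluation for typed biomedical
knowledge graphs of the syndrome / symptom / pathogenesis-factor /
prescription kind.

The toolkit implements a three-stage completion pipeline —

1. **explicit (path level)** — isolated-subgraph detection and re-linking,
   plus path-ranking relation prediction (random-walk relation-sequence
   features + a logistic linear classifier) filtered for ontology
   consistency (`kgc.completion_explicit`);
2. **implicit (ontology level)** — transitive/symmetric closure and
   mutual-exclusivity contradiction detection and resolution
   (`kgc.completion_implicit`);
3. **tacit (entity level)** — Apriori association-rule mining over medical
   records with syndrome antecedents and symptom consequents, selected by
   lift and converted to triples (`kgc.completion_tacit`);

— and a three-dimension evaluation framework:

* **completeness** — node/edge counts, degree distribution, network density,
  log-log degree slope (`kgc.quality_eval`);
* **accuracy** — contradiction count, closeness-centrality and max-k-core
  agreement with prior knowledge (`kgc.quality_eval`);
* **usability** — TransE / RotatE / DistMult / ComplEx embeddings trained
  with tail-corruption negative sampling and margin ranking loss, scored by
  MR / MRR / Hits@{1,3,10} on a 7:3 split (`kgc.embedding_eval`).

`kgc.synthetic_data` generates schema-conformant synthetic graphs with a
planted-truth ledger (withheld triples, contradictions, isolated components,
association rules), so every stage is testable end-to-end without external
data. `kgc.pipeline` orchestrates the stages in the fixed
explicit → implicit → tacit order and compares before/after reports.

## File formats

* **Triples**: TSV, `head<TAB>relation<TAB>tail[<TAB>provenance]`, UTF-8.
* **Schema**: JSON with `entity_types`, `relations` (name, domain, range,
  transitive, symmetric, exclusive_with) and an `entity_type_map`
  (id → type; unmapped ids become `Other`).
* **Records**: one transaction per line, tab-separated labels, syndrome
  first.
* **Prior knowledge**: JSON `{"core_prescriptions": [...],
  "exterior_symptoms": [...]}`.

## CLI

```bash
# generate a synthetic benchmark (graph, schema, records, planted ledger)
kgc simulate --seed 1 --n-records 470 --out fixtures/

# individual stages
kgc complete-explicit --kg graph.tsv --schema schema.json \
    --target-relation Manifest --support-threshold 2 --out candidates.tsv
kgc complete-implicit --kg graph.tsv --schema schema.json \
    --resolve drop_both --out graph2.tsv --report contradictions.tsv
kgc complete-tacit --records records.tsv --min-support 0.10 \
    --lift-threshold 1.0 --out rules.tsv

# evaluation
kgc evaluate --kg graph.tsv --schema schema.json --prior prior.json \
    --report report.json
kgc evaluate-usability --kg graph.tsv --schema schema.json --model RotatE \
    --dim 100 --margin 1.0 --epochs 200 --seed 42 --report metrics.json

# full pipeline
kgc run --kg graph.tsv --schema schema.json --records records.tsv \
    --seed 1 --out out/
```

## Conventions

* Triples are stored directed; all topology metrics (components, degree,
  density, closeness, k-core) use the undirected view.
* By default the edge count M equals the triple count (parallel relations
  between the same endpoints each count); a deduplicated
  distinct-endpoint-pair mode is available via `edge_mode="pairs"`.
* Reported fractions are rounded half-up to 4 decimals.
* Candidate triples need strictly more supporting path types than the
  support threshold (default 2) to be proposed.
* Ranking is raw (unfiltered) and optimistic on ties; filtered mode is
  available behind a flag.
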