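# tcmaid

Assistive diagnosis for traditional Chinese medicine (TCM) from freestyle
electronic-health-record (EHR) notes.

In TCM a treatment decision needs two judgements at once: the **disease**
diagnosis and the **syndrome** (证) — a pathological summary of the
disease's stage, location and etiology inferred from signs such as the
chief complaint, tongue quality and pulse. The disease↔syndrome relation
is many-to-many, which is what makes machine syndrome prediction hard.
`tcmaid` implements the full pipeline for clinicians' notes:

1. **NLP** — a bidirectional recurrent encoder with a linear-chain
   conditional random field (CRF) extracts named entities (symptom,
   duration, tongue quality, pulse, history) from sectioned notes and
   assembles structured records, pairing each duration with its nearest
   preceding symptom.
2. **Feature extraction** — entity surfaces are standardized against a
   synonym dictionary, mentions are merged across sections
   (split-and-join), duration-qualified symptoms expand into bare plus
   compound terms ("coughing", "coughing|3days"), and each term gets a
   recency weight: with a horizon of N time units, an occurrence n units
   in the past weighs (N − n)/N. Per-term weighted sums become a
   fixed-length feature vector.
3. **Disease diagnosis** — a text-convolution network over the entity
   token sequence: L-token input, d-dimensional embeddings, banks of
   kernels of width d at heights L−1, L−2, L−3 (feature surfaces of 2, 3
   and 4 rows), max-pooling, softmax; output is the ranked top-k disease
   list.
4. **Syndrome prediction** — one integrated model per disease: a
   back-propagation MLP, a support-vector classifier, a random forest and
   an extreme-gradient-boosting classifier vote by majority rule (ties:
   highest mean confidence, then lexicographic). The disease prediction
   gates which model is consulted.

Because real hospital notes cannot be shipped, `tcmaid.synthetic_corpus`
generates seeded, fully annotated corpora with the same statistical
structure — sectioned notes, gold entity spans, severe class imbalance,
full-width/half-width character mixing, synonym variants and planted
quality-control violations — so every stage trains and evaluates offline.

## Worked example

```python
from tcmaid import synthetic_corpus as sc, features as ft, pipeline_eval as pe

# a small synthetic hospital: 4 diseases, 8 syndromes, imbalanced classes
onto = sc.build_ontology(n_diseases=4, n_syndromes=8, mean_syndromes_per_disease=2.5, seed=2)
counts = dict(zip(onto.disease_ids, (120, 90, 40, 60)))
gen = sc.GenConfig(onto, counts, seed=3, synonym_noise=0.1, fullwidth_prob=0.2,
                   qc_violations={"missing_page": 3, "inconsistent": 2, "nonstandard_complaint": 2})
notes = sc.generate_corpus(gen)

lexicon = ft.StandardLexicon(gen.lexicon.surface_to_canonical())
system, splits = pe.train_system(notes, pe.TrainConfig(seed=5, lexicon=lexicon))

test = [n for n in notes if n.note_id in set(splits["test"])]
_, report = pe.run_pipeline(test, system)
print("kept after QC:", len(splits["qc"].kept), "of", len(notes))
print("disease top-k:", report.disease_topk)
print("system  top-k:", report.system_topk)
```

prints

```
kept after QC: 303 of 310
disease top-k: {1: 1.0, 3: 1.0, 5: 1.0}
system  top-k: {1: 1.0, 3: 1.0, 5: 1.0}
```

Quality control discarded the 7 planted violations (missing admission or
discharge page, pages that disagree on a checked field, non-standard chief
complaint). `disease top-k` is the fraction of held-out notes whose gold
disease appears among the k highest-ranked predictions; `system top-k`
additionally requires the predicted syndrome to be correct, so it can
never exceed the disease score. On this cleanly separable synthetic
corpus both reach 1.0; on real notes they would not (see
`docs/methods.md` for what the generator does and does not emulate).

The same pipeline is scriptable from the shell:

```sh
tcmaid generate --config config.yaml --seed 3 --out corpus/
tcmaid preprocess --corpus corpus/ --out work/ --seed 1
tcmaid train-ner      --corpus corpus/ --work work/ --models models/ --seed 1
tcmaid train-disease  --corpus corpus/ --work work/ --models models/ --seed 1
tcmaid train-syndrome --corpus corpus/ --work work/ --models models/ --seed 1
tcmaid evaluate --corpus corpus/ --work work/ --models models/ --out eval/ --split test
```

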