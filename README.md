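# prser — prescription recommendation for plant electronic medical records

Plant doctors at agricultural extension stations record consultations as
plant electronic medical records (PEMRs): free-text descriptions of the
environment (onset date, location, field distribution), the host plant
(species, growth stage, affected part) and the symptoms (severity, main
symptoms, detail), together with the pesticide prescription that was
issued. Classifying such records into a fixed prescription inventory fits
poorly in practice — pesticide catalogues change constantly, labeled data
are scarce, and the same pathogen may need different treatment depending
on crop and season. `prser` instead treats prescription recommendation as
*semantic retrieval*: a bi-encoder maps each record's text to a vector,
historical records form an embedded reference set, and a new case is
answered with the prescriptions of its most cosine-similar references.
New prescriptions are added by inserting reference records — no
retraining, no fixed label space.

## Model

A shared (siamese) transformer encoder `f` maps text to per-token
representations; a pooling operator (CLS, mean, first–last average,
pooler, or max) reduces them to one sentence vector. Attention follows

    Attention(Q, K, V) = softmax(QKᵀ / √d_k) V

with multi-head projections, residual connections, layer norm and a
feed-forward sublayer per block. Training is contrastive over record
pairs labeled `y = 1` iff the two records share a prescription. The
default objective is the CoSENT ranking loss over pair cosines,

    L = log(1 + Σ_{(i,j)∈Ω⁺, (k,l)∈Ω⁻} exp(λ·(cos(u_k, u_l) − cos(u_i, u_j))))

which directly orders positive-pair cosines above negative-pair cosines —
the same quantity used at inference — with scale λ = 20. The SBERT
softmax-classification objective over `(u, v, |u−v|)` and the supervised
SimCSE InfoNCE loss are implemented for comparison; inference is always
cosine retrieval. Recommendation ranks *distinct* prescriptions: reference
rows are sorted by cosine and each prescription keeps its best-scoring
supporting record; Top-N accuracy counts a query as a hit when its true
prescription is among the first N distinct recommendations.

Because real PEMR corpora are not redistributable, the package ships a
seeded generator of PEMR-like corpora with known latent disease classes
(class-specific core vocabularies, a shared noise pool, one prescription
per class), so every claim the test suite makes is checkable end to end.
The trainable encoder is implemented on NumPy with a small reverse-mode
autodiff included in the package; any external pretrained encoder can be
plugged in as a `texts -> matrix` callable instead.

## Worked example

```
prser synth --classes 5 --per-class 20 --seed 7 -o corpus.jsonl
prser pairs corpus.jsonl --seed 7 --max-positives 120 -o pairs.tsv
prser train pairs.tsv --held-out pairs.tsv --seed 7 --epochs 15 -o model/
prser index corpus.jsonl --model model/ -o index.zip
prser recommend --index index.zip --model model/ \
    --text "disease02_sym_t12 disease02_sym_t9 disease02_sym_t11 \
disease02_sym_t1 disease02_sym_t2 disease02_sym_t5" -n 3
```

The query is the symptom text of a class-2 record; the last command
prints

```json
{
  "query_id": "query",
  "ranked": [
    {
      "prescription": "rx02",
      "score": 0.9998445451864129,
      "supporting_record_id": "syn-00047"
    },
    {
      "prescription": "rx00",
      "score": 0.44228135799052387,
      "supporting_record_id": "syn-00014"
    },
    {
      "prescription": "rx03",
      "score": 0.4391860877349595,
      "supporting_record_id": "syn-00062"
    }
  ]
}
```

i.e. the prescription attached to the latent class whose vocabulary the
query shares is ranked first by a wide cosine margin, with the reference
record supporting it; the remaining slots are filled by the next-nearest
(shared-vocabulary) classes. `prser eval-rec queries.jsonl reference.jsonl
--model model/` reports Top-1/3/5 accuracy of a query set against a
reference set, and `prser eval-matching` reports Pearson/Spearman between
pair cosines and the 0/1 same-prescription labels.

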