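# herblabel

Structured data extraction from herbarium specimen label text.

Natural-history collections hold hundreds of millions of specimens whose
labels — taxon name, collecting locality, date, collector and field number,
sometimes coordinates and altitude — exist only as text on paper.  Imaging
pipelines produce OCR text per specimen, but that text is an unstructured
mix of Japanese, English and Latin in a layout that varies by collector.
`herblabel` turns it into a database: it recognizes typed entity spans in
label text and normalizes them into Darwin-Core-style occurrence records
ready for aggregators such as GBIF.  It is aimed at herbarium curators and
biodiversity-informatics developers digitizing specimen backlogs.

## What it does

* **Gazetteer matching** — exact leftmost-longest lookup of label text
  against plant-name and address tables (`surface,label[,source]` CSVs),
  with a per-label coverage report.  Precise for verbatim names, blind to
  dates, numbers, coordinates and altitudes — which is what motivates the
  trained tagger.
* **Artificial-label generation** — rule-based synthesis of annotated
  training labels: field values drawn from the same gazetteers, dates in
  ten messy label formats, collector numbers uniform in [1, 999999],
  altitudes in [0, 8000] m (single value or range), coordinate fragments in
  ten degenerate shapes, randomized layout with cue prefixes.  Every
  inserted value is delimited exactly by a gold span and generation is
  byte-reproducible per seed.
* **Trainable span NER** — an 18-label BIO tagger (averaged perceptron over
  window features, greedy decoding) that trains in seconds on a CPU,
  serializes to one JSON archive, and predicts deterministically.  Heavier
  backends plug into the same `train(docs) -> predictor.predict(text)` seam.
* **Evaluation** — strict entity-level precision / recall / F
  (F = 2C/(P+E)) under seeded k-fold cross-validation, including the
  three-regime comparison: train on manual folds, manual + artificial pool,
  or artificial pool only, always testing on manually annotated documents.
* **Record building** — span-to-field mapping with per-field provenance,
  template-driven date/altitude normalization, Darwin-Core-style CSV plus
  lossless JSON export.

The shipped dictionaries and collector-name pool under `herblabel/data/`
are small synthetic fixtures that mirror the shape of institutional tables;
point the tools at your own CSVs for production use.

## Worked example

Generate labels, train the tagger, and structure a held-out label:

```python
from herblabel.augmentor import AugmentationConfig, ResourcePack, generate_dataset
from herblabel.ner_engine import TrainConfig, train
from herblabel.record_builder import spans_to_record

resources = ResourcePack.builtin()
corpus = generate_dataset(AugmentationConfig(n_records=200, seed=42), resources)
model = train(corpus, TrainConfig(epochs=10, seed=0))

held_out = generate_dataset(AugmentationConfig(n_records=5, seed=43), resources)
doc = held_out[3]
print(doc.text)
for span in model.predict(doc.text):
    print(f"{span.label.value:>9}  {doc.text[span.start:span.end]!r}")
```

```
倉敷市
Arisaema serratum
兵庫県
# 981428
Date: 21. Mar. 1993
コナラ
Coll. N. Fukuoka
藍本字山田
4665–5475 m
Okayama Pref.
  ja_city  '倉敷市'
  en_name  'Arisaema serratum'
  ja_pref  '兵庫県'
   number  '981428'
     date  '21. Mar. 1993'
  jp_name  'コナラ'
   person  'N. Fukuoka'
  ja_addr  '藍本字山田'
      alt  '4665–5475 m'
  en_pref  'Okayama Pref.'
```

Each line is a typed span the model recovered from the never-seen label:
the cue prefixes (`# `, `Date: `, `Coll. `) are correctly left outside the
spans.  Structuring those spans:

```python
record = spans_to_record(doc.with_spans(model.predict(doc.text), source="predicted"))
print(record.scientific_name)   # 'Arisaema serratum'
print(record.event_date_iso)    # '1993-03-21'  (from '21. Mar. 1993')
print(record.collector_number)  # 981428
print(record.prefecture)        # 'Okayama Pref.' (English wins; 兵庫県 kept in provenance)
```

The same flow from a shell:

```sh
herblabel generate --n 10000 --seed 42 --out artificial.jsonl
herblabel train --corpus artificial.jsonl --epochs 10 --seed 42 --out model.json
herblabel evaluate --corpus manual.jsonl --artificial artificial.jsonl \
    --k 5 --k 10 --regimes all --seed 42 --out regimes.csv
herblabel extract --model model.json --in ocr_texts.jsonl --out spans.jsonl
herblabel build-db --spans spans.jsonl --out occurrences.csv
```

`evaluate` prints one Mean and one S.D. row per (regime, k) with the six
columns num_entities, num_predictions, num_correct, precision, recall,
f_value — counts to 1 decimal, ratios to 3.  Every command writes a
`*.manifest.json` (inputs, seed, version) beside its output so any artifact
can be regenerated.

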