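# Methods

## Problem and pipeline

Herbarium specimen labels record, in free layout and mixed scripts
(Japanese, English, Latin), a small set of recurring fields: taxon names
(scientific name, Japanese name, family in both languages), the collecting
locality (prefecture / city / street, in Japanese and/or English), the
collection date, the collector(s), the collector's field number, sometimes
coordinates and altitude, and free-form memos. Given OCR text per specimen
image, `herblabel` locates and types these fields as character-offset entity
spans and normalizes them into occurrence records.

The pipeline has five stages, each usable on its own:

1. **Gazetteer matching** (`dict_matcher`) — exact longest-match lookup
   against a botanical-name table and an address table. Cheap and precise
   for names that appear verbatim, but structurally blind to dates,
   numbers, coordinates, altitudes, and sub-city addresses; its per-label
   coverage report quantifies that gap and motivates the trained tagger.
2. **Artificial-label generation** (`augmentor`) — rule-based synthesis of
   annotated labels to supplement a small hand-annotated corpus.
3. **Trainable span tagging** (`ner_engine`) — per-token BIO classification
   with an averaged perceptron; heavier backends plug into the same seam.
4. **Evaluation** (`evaluator`) — strict entity-level precision / recall /
   F under k-fold cross-validation, including the three-regime comparison
   (manual folds only / manual + artificial pool / artificial pool only).
5. **Record building** (`record_builder`) — span-to-field mapping, date and
   altitude normalization, Darwin-Core-style CSV export plus lossless JSON.

## Data model

Spans are 0-based, half-open, counted in Unicode code points; byte offsets
are fragile for Japanese text and half-open intervals keep span arithmetic
simple. Spans within a document never overlap. The label vocabulary is
closed at 18 members; seven of them (`ja_pref`, `ja_city`, `ja_addr`,
`lat`, `long`, `alt`, `memo`) are only ever produced by the trained tagger,
never by the gazetteer. An older reporting scheme that pooled Japanese and
English locality fields (`collect_pref`, `collect_city`, ...) is kept as an
explicit alias table so coverage reports can be printed under either set of
names; the alias map is total over the legacy names and rejects anything
else.

Every document carries a provenance tag (`manual`, `artificial`,
`predicted`) because the regime comparison partitions on it, and an
optional collector key. Training-candidate selection groups documents by
collector, ranks each group randomly (seeded), and keeps the top 1–3 per
group: collectors reuse one label format, so a few labels per collector
cover most layout variation at a fraction of the annotation cost.
Documents without a collector are pooled into a single "unknown" group
rather than dropped.

## Gazetteer matching

Text and surfaces are normalized per code point with NFKC + casefold, which
unifies full-width/half-width forms and Latin case — both common OCR
artifacts — while a position map keeps returned offsets in the original
text. Matching is greedy leftmost-longest non-overlapping scan, the
standard gazetteer convention, and is property-tested against a brute-force
enumerate-all-substrings oracle. Surfaces shorter than 2 code points are
dropped by default: single-character surfaces (frequent in Japanese) flood
the matcher with false positives. When the same surface occurs in several
source tables, a configurable priority list breaks the tie, plant names
first by default (the rarer, higher-precision class). Coverage is counted
as *documents with at least one match per label*, not match instances.

## Artificial-label generation

Defaults encode the generation conditions the package is designed around:

| parameter | default | meaning |
|---|---|---|
| `n_records` | 10,000 | corpus size for augmentation experiments |
| `collector_number_range` | [1, 999999] | uniform integer draw |
| `altitude_range` | [0, 8000] m | single value or low–high range |
| `altitude_range_prob` | 0.35 | probability of a range vs a single value |
| `place_source_mix` | 0.5 | address-table vs corpus-gazetteer place names |
| `date_formats` | 10 templates | see below |
| `latlong_formats` | 10 templates | see below |
| `date_year_range` | 1950–2020 | plausible collecting era |

The ten date templates render exactly the observed label shapes
(`March. 13.1988`, `10. Oct. 2003`, `16. March, 1997`, `May. 16.1972`,
`1979/4/1`, `1. Aug. 2005`, `24. May, 2013`, `12. January, 1975`,
`Mar. 28. 2009`, `December 30, 1988`); several share an abstract pattern
and differ only in month spelling, and all are kept so template frequency
matches usage. The ten coordinate templates reproduce the degenerate
degree/minute/second fragments found on labels (`− 15° 03′ 1.6`,
`− 131′ 21`, ...), using U+2212 minus and U+2032 prime; each template
induces a validation regex mechanically, and the `lat` and `long` fields
both draw from the same axis-agnostic sampler, since the fragment shapes
carry no axis information.

Field inclusion is independent per label with documented default
probabilities (e.g. scientific name 0.9, date 0.9, person 0.9, number 0.8,
prefecture 0.8 Japanese / 0.4 English, coordinates 0.2); these are package
choices — no empirical per-field frequencies were available — and the
distribution test checks generation against whatever is configured, not
against fixed constants. Memo fields are never generated (probability
pinned to 0): free-form habitat remarks are too diverse to synthesize
honestly, and a generator that faked them would teach the tagger nonsense.

Label layout is likewise a documented package choice: per document a layout
template fixes a separator pool (newline, comma, double-space) and field
order (random by default), and number/altitude/person/date/coordinate
fields occasionally receive a cue prefix ("No. ", "alt. ", "leg. ",
"Date: ", probability 0.4) *outside* the gold span, emulating real labels.
Collector names come from a shipped synthetic pool (the files under
`herblabel/data/` are synthetic fixtures emulating the shape of curated
institutional tables, as their filenames state). When no corpus-derived
place gazetteer is supplied, place names fall back to the address table
alone and the mix probability is ignored.

Two invariants are enforced corpus-wide by tests: **gold-span fidelity**
(`text[start:end]` equals the sampled value exactly, for every span of
every document) and **normalizer closure** (every generated date and
altitude surface parses back to its sampled value through
`record_builder`'s normalizers). Generation is byte-identical for a fixed
(config, resources, seed).

## Tagger

Tokenization splits Latin and digit runs on whitespace/punctuation,
Japanese text at script-class boundaries (kanji / hiragana / katakana), and
emits punctuation one character per token. It is a documented package
choice, not a reconstruction of any third-party tokenizer. Generator
output always places span boundaries on token boundaries (fields are
separated); hand annotations that do not are snapped *outward* to the
enclosing tokens and logged — conservative for recall, never silently
dropped.

The built-in model is an averaged perceptron over per-token BIO tags with
sparse window features (±2 surfaces; shape, script class and affixes of the
focus and immediate neighbours; optional gazetteer-membership flags reusing
the matcher). Decoding is greedy per token with lenient BIO repair (a
dangling `I-x` opens a span). Training shuffles documents each epoch with the
configured seed (default 10 epochs) and is exactly reproducible; the model
serializes to a single JSON archive that embeds any gazetteer used for
features, so a reloaded model predicts identically. A transformer-based
backend would plug into the same `train(docs) -> predictor` seam; the
perceptron is the deterministic desk-scale default, not a stub.

## Evaluation

`Num_correct` uses strict matching — exact (start, end, label) equality,
each gold span consumed at most once; a partial-overlap criterion was
deliberately not made the default because strict matching is conventional
and oracle-checkable. Per fold, precision = C/P, recall = C/E and
F = 2C/(P+E) are computed from that fold's pooled counts (micro);
zero-denominator folds score 0 and are flagged. Summary rows are the mean
and sample (n−1) standard deviation of the per-fold values; note
mean-of-ratios and ratio-of-mean-counts can disagree in the third decimal,
and the report treats the per-fold mean as primary while `CVReport.micro()`
exposes the pooled alternative. Folds split by document with sizes
differing by at most one, seeded.

In the three-regime comparison the held-out test fold always consists of
manually annotated documents — evaluating on artificial text would measure
recall of the generator's own rules — and the harness refuses non-manual
test documents whenever an artificial pool is supplied. Rendered tables
print counts to 1 decimal and ratios to 3.

## Record building

Span-to-field mapping: first occurrence wins for single-valued fields;
every `person` span joins the collectors list in reading order; the
collector number keeps its digits only. When a locality level carries both
Japanese and English spans, the English value fills the exported
Darwin-Core column (aggregators index it) and both variants are retained in
the per-field provenance map, which guarantees that no exported value is
untraceable to a span. Dates and altitudes are parsed by the bounded
template grammars above plus bare ISO; unparseable input stays verbatim
with the normalized field absent. Coordinates are exported verbatim only —
the observed fragments are too degenerate for a safe decimal conversion.

## Problem sizes

The test suite and `scripts/acceptance.py` run the pipeline at sizes the
package treats as its reference desk scale: generator contract checks at
10,000 records and 100,000 scalar draws; synthetic recovery with 200
training and 50 held-out generated labels; the three-regime comparison on a
250-document corpus with a 600-document artificial pool at k = 5; the
end-to-end database build on 300 documents. These sizes give stable
statistics while keeping any single run under a minute or two on one CPU.

## Limitations

* The generator emulates field content and layout variation, not OCR noise
  (character substitutions, line-break corruption) or memo text. Scores on
  generated data therefore bound what the architecture can learn from
  clean, regular labels; they do not estimate accuracy on real scanned
  specimens, and the artificial-only regime in particular looks strong at
  desk scale precisely because train and test then share the generator's
  rules — on real labels it is the weakest regime.
* The shipped dictionaries and name pool are small synthetic fixtures;
  production use expects institutional plant-name and address tables in the
  same `surface,label[,source]` CSV shape.
* The perceptron has no transition model; greedy decoding with BIO repair
  is contract-tested but can fragment long entities in pathological
  layouts.
* Kanji runs tokenize as single tokens, so adjacent Japanese locality
  fields written without separators cannot be split; the generator always
  separates fields, and real labels usually do too.
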