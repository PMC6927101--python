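# adrminer

Extraction of adverse-drug-reaction (ADR) and related entity mentions from
structured drug-label XML, and normalization of ADRs to MedDRA-style
Preferred Terms (PTs). Two recognition arms share one normalizer:

* **ml** — a char-CNN + word/case-embedding, stacked Bi-LSTM, CRF sequence
  tagger trained on BIO2-encoded sentences (implemented from scratch on
  numpy, including a small reverse-mode autodiff engine, CRF
  forward/Viterbi, variational dropout and a NADAM optimizer with global
  gradient-norm clipping).
* **dict** — dictionary longest-match recognition against a two-level
  PT/LLT terminology with plural/singular term expansion and an optional
  exclusion list.

Supporting modules: TAC-style label XML and 6-column CoNLL I/O
(`label_io`), sentence splitting with table detection plus
offset-preserving tokenization and BIO2 encode/decode
(`preprocess`), LLT→PT normalization (`normalizer`), mention-level and
micro/macro PT-level P/R/F1 scoring (`evaluation`), and a seeded
synthetic corpus generator (`synthetic_fixtures`) so everything is
testable with no external data.

## CLI

```bash
adrminer synth    --out data --seed 7 --n-labels 10 --mention-rate 0.6
adrminer convert  --labels data/labels --out data/conll
adrminer train    --conll data/conll --out model.npz --seed 7
adrminer predict  --model model.npz --labels data/labels --out pred/
adrminer dictner  --labels data/labels --pt data/pt.tsv --llt data/llt.tsv --out pred/
adrminer normalize --labels pred/ --pt data/pt.tsv --llt data/llt.tsv --out norm/
adrminer evaluate --gold data/labels --pred norm/ --report json
adrminer run      --config pipeline.yaml
```

`adrminer run` executes a whole arm from a YAML config:

```yaml
arm: dict            # or: ml
labels: data/labels  # input label XML directory
dictionary:
  pt: data/pt.tsv
  llt: data/llt.tsv
  # exclusions: excl.txt   # optional, one surface form per line
gold: true           # inputs are annotated -> write report.json
seed: 7
out: run1/
# ml arm only:
# model:
#   path: model.npz            # use a checkpoint, or:
#   train_labels: data/labels  # train first (extra keys override TaggerConfig)
```

Every run writes predictions (`*.pred.xml`), `normalizations.tsv`, a
`manifest.json` (seed, config hash, input checksums, counts) and, with
gold inputs, `report.json` with identification and micro/macro
normalization precision/recall/F1 in percent. Exit codes: 0 success,
2 config error, 3 data validation error.

## File formats

* **Label XML** — `Label[drug]` root; `Text/Section[id]` raw text;
  `Mentions/Mention[id,section,type,start,len,str]` with comma-separated
  `start`/`len` for discontinuous mentions; `Reactions/Reaction[str]/
  Normalization[meddra_pt,meddra_pt_id,meddra_llt,meddra_llt_id]`.
* **CoNLL** — tab-separated `token  bio_tag  section_id  start  length  _`,
  blank line between sentences. Offsets are 0-based characters from the
  start of the section text.
* **Dictionary** — `pt.tsv` (`pt_id  pt_name`) and `llt.tsv`
  (`llt_id  llt_name  parent_pt_id`).
* **Word vectors** — standard text format (`word v1 v2 ...`, optional
  count/dim header) via `adrminer train --embeddings`; without it, word
  embeddings are seeded uniform(−0.25, 0.25).

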