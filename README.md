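# treeddi

Extraction of drug–drug interactions (DDI) from sentence-level candidate
drug pairs with a binary tree-LSTM over constituency parses.

Each candidate instance is one (sentence, drug pair). Preprocessing
anonymizes annotated drugs to `Ddrug{k}` placeholders, masks independent
numbers, generates one instance per pair, and filters negatives
(same-drug pairs; pairs inside coordination runs of three or more drugs).
Every node of a binarized parse tree receives a 230-dimensional input —
10 (subtree-containment flag) + 2×10 (thermometer-encoded signed
distances to the two targets) + 200 (static word embedding) — and the
tree-LSTM's root hidden state feeds an affine classifier. Detection uses
a 3× loss weight on positive instances; one-stage (5-class) and
two-stage (binary detection, then 4-class typing of predicted positives)
pipelines are supported, as is a logit-sum ensemble of independently
seeded members. Evaluation is micro-averaged P/R/F1 over the positive
classes, charging gold positives filtered from the test split as false
negatives.

The model (forward pass, analytic backpropagation, Adam) is implemented
in numpy; no deep-learning framework is required.

## Layout

| module | role |
| --- | --- |
| `treeddi.corpus_io` | DDI-style XML corpora, instance TSVs, data model |
| `treeddi.preprocessing` | tokenization, anonymization, number masking, candidate generation, negative filtering, deduplication |
| `treeddi.parse_trees` | bracketed-tree reading, binarization, containment/distance annotation |
| `treeddi.features` | distance codec, containment vector, embedding table, input assembly |
| `treeddi.model` | tree-LSTM forward/backward, loss, training loop, checkpoints, ensembling |
| `treeddi.pipeline_eval` | one-/two-stage orchestration, micro-F1 with ledger accounting |
| `treeddi.synthetic_fixtures` | seeded toy corpus generator with aligned parse trees |

## CLI

The pipeline runs end to end on generated data:

```sh
treeddi simulate --n 500 --seed 7 --out corpus.xml --trees corpus.trees
treeddi preprocess --in corpus.xml --split test --out instances.tsv --report filter.json
treeddi train --task detection --corpus corpus.xml --trees corpus.trees --seed 1 --out det.npz
treeddi train --task type4     --corpus corpus.xml --trees corpus.trees --seed 2 --out typ.npz
treeddi predict --task two-stage --corpus corpus.xml --trees corpus.trees \
    --model det.npz --model typ.npz --out pred.tsv
treeddi evaluate --pred pred.tsv --gold instances.tsv --ledger filter.json --out eval.json
```

Real corpora in the SemEval DDIExtraction XML dialect are read the same
way; supply parses of the preprocessed token strings (one bracketed tree
per sentence, aligned by line) and optionally an embedding text file via
`--embedding` (token + 200 floats per line). Training hyperparameters
can be overridden with `--config cfg.yaml` (keys mirror
`treeddi.model.TrainConfig`).

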