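# ddievent

Multiclass drug–drug interaction (DDI) **event** prediction from fused
per-modality similarity features.

Given several binary drug feature matrices (e.g. mono side effects, targets,
enzymes, chemical substructures, pathways), the pipeline:

1. computes one **Jaccard similarity matrix** per modality (drugs × drugs),
2. **concatenates** the matrices into a drug feature table (m × p·m),
3. encodes a drug pair as the **elementwise sum** of the two drugs' rows
   (concatenation and elementwise product are available for comparison), and
4. classifies the pair into one of *n* event types with a small fully
   connected network (512→256→128, ReLU then sigmoid hidden activations,
   dropout 0.3, softmax output, Adam, 100 epochs, batch 128), implemented
   directly on NumPy for full seed-level determinism.

The package also ships the full evaluation apparatus: stratified and nested
cross-validation, six metrics (ACC, AUPR, AUROC, F, precision, recall) with
FP/FN accounting, per-event reports, ranked false-positive tables,
leave-one-feature-out ablation, feature-subset sweeps, PCA reduction
scenarios, pair-encoding comparison, per-modality model fusion, and a
synthetic data generator with planted latent-group structure so everything is
testable without external downloads.

## Command line

```bash
# generate a synthetic bundle shaped like a published benchmark (scaled down)
ddievent simulate --ds-shape DS1 --scale 0.2 --seed 7 --out bundles/ds1s

# or a small custom bundle
ddievent simulate --m 60 --pairs 400 --events 4 --seed 7 --out bundles/small

# 5-fold cross-validation; writes metrics.tsv, per_event.tsv, top_fp.tsv
ddievent train-eval --bundle bundles/small --seed 7 --out runs/cv

# nested CV over a hyperparameter grid
ddievent train-eval --bundle bundles/small --nested --grid-size 4 --out runs/nested

# studies: ablation | combos | pca | encodings | fusion
ddievent experiment ablation --bundle bundles/small --out runs/ablation
```

Bundles are plain TSV files plus a YAML manifest; every command is
reproducible byte-for-byte from its inputs and `--seed`.

## Layout

```
src/ddievent/
  data_io.py        TSV/manifest readers & writers, validation
  similarity.py     Jaccard similarity matrices
  pair_features.py  similarity concatenation + pair encodings
  ddi_net.py        the NumPy dense-network classifier
  evaluation.py     folds, metrics, (nested) cross-validation, FP ranking
  experiments.py    ablation, subsets, PCA scenarios, encodings, fusion
  synthetic_data.py latent-group synthetic bundle generator
  cli.py            simulate / train-eval / experiment commands
tests/              unit, property and acceptance suites
scripts/acceptance.py
```
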