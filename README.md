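# rscdnet

A residual image-classification network for fine-grained grain/seed images,
implemented in pure numpy with reverse-mode autodiff (HIPS `autograd`) —
no GPU framework required. The building blocks:

- **SRU** (spatial reconstruction): group normalization, per-channel
  informativeness weights derived from the GN scale factors, a
  sigmoid-threshold gate splitting the map into binary informative /
  non-informative parts, and cross-reconstruction across channel halves.
- **CRU** (channel reconstruction): channel split by ratio α, strided 1×1
  squeeze, group-wise (GWC) + point-wise (PWC) context transforms, and
  selective-kernel softmax fusion `Y = β1·Y1 + β2·Y2`.
- **SCR-Block**: a residual bottleneck with the SRU→CRU pair in the middle.
- **Double attention**: bilinear gathering of global descriptors
  (`G = A·Bᵀ`) followed by per-position soft distribution (`Z = G·V`),
  inserted after the last stage.
- **RSCD-Net**: 7×7/2 stem + max pool, four stages of SCR-Blocks
  (3, 4, 6, 3 — 16 blocks total), double attention, global average
  pooling, linear head (default 36 classes, 224×224 inputs).

Also included: a confusion-matrix/metrics module (precision, recall, F1,
average accuracy, CSV reports), a deterministic synthetic fine-grained
seed-image generator, and a seeded training/evaluation CLI with AdamW
defaults (batch 32, lr 5e-4, weight decay 0.05, 200 epochs).

## CLI

```bash
# write a synthetic dataset: root/{train,val,test}/{class}/NNNN.png + manifest
rscdnet generate --classes 4 --per-class 40,10,10 --image-size 64 --seed 3 --out data/

# train (defaults follow the reference hyperparameters; override for small runs)
rscdnet train --data data/ --out run/ --epochs 60 --batch-size 16 \
    --learning-rate 3e-3 --input-size 64 \
    --stage-sizes 1,1,1,1 --stage-widths 8,16,32,64 --stem-channels 8 --seed 1

# ablations: --ablation no-a2 (drop double attention), --ablation plain-blocks
# (standard bottlenecks instead of SCR-Blocks)

# evaluate a checkpoint: writes confusion_matrix.csv + metrics.csv
rscdnet evaluate --checkpoint run/checkpoint.npz --data data/ --split test --out eval/

# structural summary (block census, parameter count)
rscdnet summarize --classes 36
```

`--config file.yaml` overrides training defaults with keys
`batch_size`, `epochs`, `optimizer`, `learning_rate`,
`l2_regularization`, `input_size`, `seed`.

## Layout

```
src/rscdnet/
  nn/               numpy/autograd layer: conv, norms, pooling, AdamW
  core_blocks.py    SRU, CRU, SCR-Block (+ equation-level free functions)
  double_attention.py
  network.py        model assembly, summary, checkpoints
  metrics.py        confusion matrix, P/R/F1, CSV tables
  synthetic_data.py deterministic fine-grained seed-image generator
  training.py       seeded train/evaluate pipeline
  cli.py            generate / train / evaluate / summarize
```
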