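# somnofuse

Automatic sleep-stage classification for multi-channel polysomnography,
implemented end to end in NumPy:

- **Multi-branch CNN feature extraction** — one five-block convolutional
  branch (conv → batch norm → ReLU, global average pooling) per signal
  channel, no parameter sharing between channels.
- **Residual-attention channel fusion** — softmax attention over per-channel
  scores with the channel-mean feature added back as a floor, so no channel
  can be silently ignored. Ablation modes: `average`, `concat`,
  `attention_only`, `residual_attention`, and `data` (single-branch
  multi-channel input); decision-level fusion (vote / maximum posterior) is
  also provided.
- **Embedded stage refinement** — the previous epoch's stage vector is
  affinely encoded and concatenated with the fused features; logits decompose
  additively into a signal term and a refinement term. Ground-truth stages
  are teacher-forced during training; at inference each epoch's output
  probability vector feeds the next epoch's input.
- **Post-hoc refinement baselines** — expert-rule smoothing over stage
  triples and a frequency-count HMM with Viterbi decoding fitted on
  validation (truth, prediction) pairs.
- **Evaluation** — leave-one-subject-out folds, top-10% checkpoint ensembles
  ranked by validation macro-F1, pooled confusion-matrix metrics (accuracy,
  macro-F1, Cohen's kappa, per-stage precision/recall/F1) with
  transition/nontransition stratification.
- **Simulator** — Markov hypnograms with sleep-continuity structure and
  stage-conditioned band-limited signals (EEG/EOG/EMG roles), so the entire
  pipeline runs and is tested without any external data.

Stage coding is fixed everywhere: `W=0, N1=1, N2=2, N3=3, REM=4`. All
tie-breaks (argmax, votes, Viterbi) resolve to the lowest stage index.

The network, including backpropagation, is written directly on NumPy (no
deep-learning framework dependency); gradients are validated against finite
differences in the test suite.

## CLI

All workflows are driven by a YAML config validated against a strict schema
(unknown keys are rejected). See `RunConfig` in `somnofuse/cli.py` for every
field; a minimal simulated experiment:

```yaml
seed: 0
n_folds: 3
dataset:
  n_subjects: 6
  epochs_per_subject: 300
  sampling_rate: 30.0
  channels: [EEG, EOG, EMG]
  channel_roles: [EEG, EOG, EMG]
  noise_sigma: 0.3
model:
  blocks: [[5, 3, 8], [5, 3, 8], [3, 2, 16], [3, 1, 16], [3, 1, 32]]
  fusion: residual_attention
training:
  batch_size: 32
  n_epochs: 5
  learning_rate: 0.001
inference:
  ensemble: true
  refinement_method: none   # none | rules | hmm
```

```sh
somnofuse simulate --config cfg.yaml --outdir data/       # write recordings
somnofuse train    --config cfg.yaml --fold 0 --outdir ck # one LOSO fold
somnofuse infer    --config cfg.yaml --checkpoints ck \
                   --recording-dir data --subject S000 --out hyp.txt
somnofuse refine   --method rules --pred hyp.txt --out hyp_smooth.txt
somnofuse report   --truth data/S000_1_hypnogram.txt --pred hyp.txt \
                   --transition-split
somnofuse run      --config cfg.yaml --outdir out/        # full pipeline
```

`run` writes the resolved config, per-fold training logs (CSV), predicted
hypnograms, attention-weight CSVs and a pooled `pooled_report.json`.
Recordings are stored as plain text: a samples-by-channels CSV, a
one-label-per-line hypnogram file and a JSON metadata sidecar. Model defaults
(`TrainConfig`) follow the full-scale protocol: batch 64, 70 training
epochs, Adam at 1e-4 with elementwise gradient clipping at 0.1, dropout 0.5,
top-10% checkpoint ensembling.

## Real data

EDF-based datasets can be used by converting each night to the plain-text
recording format (samples CSV + hypnogram labels + metadata JSON, see
`somnofuse.dataio`) and pointing `dataset: {kind: directory, path: ...}` at
the folder. Preprocessing helpers cover R&K→AASM stage merging (N4→N3,
unscored epochs dropped), per-channel z-scoring, linear-interpolation
resampling to a common rate and 30-s epoching. Reproducing full-scale
published numbers requires the original PhysioNet recordings and 20–25 fold
training runs, which is outside the scope of the test suite.
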