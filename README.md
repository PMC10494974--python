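# mippi

Sequence-only prediction of how a single missense mutation affects a
specific protein–protein interaction (PPI).

Curated interaction databases annotate experimentally tested mutation
consequences with four labels — **disrupting**, **decreasing**,
**no effect**, **increasing** — but such annotations exist for only a
tiny fraction of known variants. This package implements a
transformer-based classifier that predicts the label from sequence
alone, together with the full surrounding pipeline: record and FASTA
I/O, feature encoding (51-residue mutation windows, 1,024-residue
partner input, PSSM profiles, positional encodings), reverse-mutation
data augmentation, class-weighted focal-loss training, attention-based
interface interpretation, a binding-affinity (ΔΔG) bridge for
affinity-table validation, and a synthetic-data generator so that
everything runs reproducibly at desk scale with no downloads.

It is aimed at computational biologists who want to train, ablate, or
interrogate this family of models on their own curated interaction
data, or to prioritize candidate variants by predicted interaction
impact.

## Model

Each event supplies three sequences: the wild-type protein (a
51-residue window centered on the mutated position), the mutant form
(same window, one residue changed), and the interaction partner (first
1,024 residues). Every position is encoded as a 128-dimensional vector:
20 sigmoid-normalized PSSM values, a learned 44-dimensional token
embedding, and a 64-dimensional sinusoidal positional encoding
`PE(pos, 2i) = sin(pos/10000^{2i/d})`, `PE(pos, 2i+1) = cos(·)`.

The network has two branches: the mutation branch (shared weights for
the reference and mutant windows) applies three masked 4-head
transformer encoder blocks and one residual convolution block; the
partner branch applies its own three encoder blocks and two residual
blocks. The branch outputs r_ref, r_mut are combined into auxiliary
vectors r_mut − r_ref and r_mut/(r_ref + ε), all five representations
are merged along the channel axis, and a 1D convolution with one filter per class
followed by global average pooling and softmax yields the four class
probabilities. Training minimizes the class-weighted focal loss
`−α_c (1−p_c)^γ log p_c` (γ = 2, α = (0.25, 0.25, 0.1, 0.25)) with
Adam (lr 2·10⁻⁴, batch 64) on stratified 8:1:1 splits, augmenting the
training split with hypothetical reverse mutations
(increasing ↔ decreasing, no_effect fixed, disrupting excluded) and
nonmutated no-effect entries.

The network is implemented as a compact numpy engine with hand-written
backpropagation (see `docs/methods.md`); no deep-learning framework is
required.

## Worked example

```bash
# simulate a small labeled dataset with a planted, recoverable signal
mippi --seed 3 simulate --n-events 40 --out events.tsv

# augment it and inspect the counts
mippi augment events.tsv --out augmented.tsv
```

The `augment` command prints the augmentation report:

```json
{
  "n_original": 40,
  "n_reversed": 27,
  "n_nonmutated": 40,
  "n_total": 107
}
```

Thirteen of the forty simulated events are labeled disrupting, which
is excluded from the reverse-mutation rule, so 27 reversed entries are
produced; every event yields one nonmutated no-effect entry; the
augmented set totals 40 + 27 + 40 = 107. Training, prediction and
evaluation follow the same pattern (`mippi train`, `mippi predict`,
`mippi evaluate`, `mippi cv`, `mippi attention`, `mippi skempi-prep`,
`mippi skempi-eval`); every run derives all randomness from the single
`--seed` flag and writes its resolved configuration next to its
outputs.

As a library:

```python
from mippi import (GeneratorConfig, generate_dataset, split_dataset,
                   ModelConfig, MIPPIModel, TrainConfig, train,
                   evaluate)
from mippi.training import predict_events

events, _ = generate_dataset(GeneratorConfig(n_events=1000, seed=0))
tr, va, te = split_dataset(events, seed=0)
model = MIPPIModel(ModelConfig(d_model=32, d_embed=8, ffn_width=64,
                               n_encoder_blocks_per_branch=1,
                               resblock_filters=32, partner_len=128))
model, history = train(model, tr, va, TrainConfig(max_epochs=10))
report = evaluate(predict_events(model, te), [e.label for e in te])
print(report.accuracy, report.two_class_accuracy)
```

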