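# Methods

## Problem and model

Given a protein carrying a single amino-acid substitution and a specific
interaction partner, the classifier predicts the consequence of the
substitution for that interaction as one of four classes — *disrupting*,
*decreasing*, *no effect*, *increasing* — from sequence alone. The class
vocabulary follows the curated interaction-mutation annotation standard
used by the IMEx databases; every class-indexed vector in the package
uses the fixed order (disrupting, decreasing, no_effect, increasing).

Three sequence inputs are encoded per event:

* a 51-residue window of the wild-type protein centered on the mutated
  position (windows at sequence edges are padded with zeros on the
  missing side);
* the same window of the mutant form, differing only at the center;
* the first 1,024 residues of the partner protein, zero-padded on the
  right when shorter.

Each position carries an integer token (0 = padding/unknown, 1–20 = the
standard amino acids in alphabetical one-letter order), a 20-dimensional
evolutionary-profile row squashed into (0, 1) by the logistic sigmoid,
and a boolean mask. Inside the network a position becomes a
d_model-dimensional vector by concatenating the 20 profile values, a
learned 44-dimensional token embedding, and a 64-dimensional sinusoidal
positional encoding (`PE[pos, 2i] = sin(pos / 10000^{2i/d})`,
`PE[pos, 2i+1] = cos(...)`, pos 0-based), giving 128 dimensions by
default. For reduced configurations the additive split is preserved
(e.g. d_model 32 = 20 profile + 8 embedding + 4 positional).

The default configuration has 1,395,772 trainable scalars (re-measure
with `build_model().count_parameters()` after configuration changes).

The network has two branches. The mutation branch embeds the reference
and mutant windows with shared weights and passes each through three
masked transformer encoder blocks (4-head self-attention, two-layer
feedforward of width 256, layer norm, dropout 0.1, residual connections,
post-norm arrangement) and one residual convolution block. The partner
branch has its own embedding, three encoder blocks, and two residual
blocks. A residual block is two subblocks of (conv k=3 → ReLU → conv
k=3) with identity skips, ReLU, and max pooling (pool 2), so each block
divides the length by four while preserving channels. Attention logits
at padded keys are set to −1e9 before the softmax; convolutional stages
do not re-mask.

The two mutation-branch outputs r_ref and r_mut are combined into two
auxiliary difference representations, `aux_sub = r_mut − r_ref` and
`aux_div = r_mut / (r_ref + ε)` with ε = 1e−6 and the quotient clipped
to ±100. The five representations (ref, mut, sub, div, partner) are
merged, passed through a 1D convolution with four filters (one per
class), globally average-pooled, and normalized with softmax. Argmax
ties break to the lowest canonical class index.

**Merge geometry.** The five representations are concatenated along the
*channel* axis (the partner map is first resampled to the
mutation-branch length by adaptive average pooling), so the merged
tensor has shape (L_mut, 5·d_model). The alternative — concatenating
along the length axis with shared channels — is available as
`merge_mode="length"` but is strictly weaker: because the conv + GAP
head is linear in the merged tensor and position-shared, a length-axis
merge reduces the head's view to the *sum of all five segments in the
same channels*, which buries the auxiliary difference vectors under the
context variance of the other segments; on desk-scale data it leaves
the substitution-chemistry component of the planted rule near chance.
Channel merging, which lets the head weight each representation
independently, recovers it (the learnability test in the suite
exercises exactly this), and preserves the layer sequence (merge five
vectors → convolution → GAP → softmax) exactly.

Because no deep-learning framework ships with the scientific stack this
package targets, the network is implemented as a compact numpy engine
with hand-written forward/backward passes for every layer (embedding,
masked multi-head attention, layer norm, feedforward, 1D convolution,
max pooling, LSTM for the encoder-substitution ablation, Adam). The
full-model gradient was verified against float64 central differences
along random parameter directions (relative error ~2e−6).

## Training

Adam with learning rate 2e−4, β = (0.9, 0.999), batch 64, and a
class-weighted focal loss

    FL = −α_c (1 − p_c)^γ log p_c,   γ = 2,
    α = (0.25, 0.25, 0.1, 0.25)  over the canonical class order,

which down-weights the majority no_effect class and shrinks the
contribution of confidently-correct examples. Splits are stratified
8:1:1 (train/validation/test); early stopping monitors validation loss
with patience 10 over at most 100 epochs. Data augmentation, when
enabled, applies to the training split only:

* **hypothetical reverse mutations** — decreasing / no_effect /
  increasing entries re-expressed with the mutant as reference and the
  label direction inverted (increasing ↔ decreasing); disrupting is
  excluded because a broken interaction has no meaningful reverse;
* **nonmutated entries** — one no_effect pseudo-entry per original with
  identical reference and "mutant" sequences.

Three schedule elements beyond the basic loop proved necessary for
stable small-scale training and are always active (each is a no-op when
disabled in `TrainConfig`):

* linear learning-rate warmup over the first 100 steps and global
  gradient-norm clipping at 5.0 — standard stabilizers for post-norm
  transformer stacks;
* a final **readout refit**: after early stopping, encoder outputs for
  the training set are cached once, and only the readout stage (the
  residual convolution blocks and the final conv head) is retrained on
  them (10 epochs, batch 256, lr 3e−3), kept only if validation loss
  improves. Rationale: early joint updates reduce loss fastest by
  suppressing input-dependent logit variance, which leaves the weak
  reference-vs-mutant difference signal unread even though linear
  probes show it survives intact in the encoder outputs; refitting the
  readout on a frozen trunk recovers it. This mirrors the common
  linear-probe-then-readout practice for pretrained encoders.

For reduced desk-scale models the package scales the learning rate up
to 1e−3: the published rate belongs to a full-size model trained for
many more updates, and a smaller model trained for ~1,000 steps needs
proportionally larger steps. All randomness (initialization, dropout,
shuffling, splits) derives from explicit seeds; two runs with the same
seeds are bitwise identical.

## Metrics

Per-class one-vs-rest precision, recall and F1
(`F1 = TP / (TP + (FP + FN)/2)`), overall 4-class accuracy, and 2-class
accuracy / Matthews correlation after grouping predictions into
*effective* (disrupting + decreasing + increasing) vs *noneffective*
(no_effect). Undefined ratios (zero denominators) are reported as 0.
Cross-validation uses stratified k-fold (default k = 5) with
augmentation applied inside each training fold only.

## Profiles

With PSI-BLAST available, profiles are computed per sequence (3
iterations, inclusion E-value 1e−3, UniRef90 recommended) and the first
20-column log-odds block of the ASCII PSSM is parsed. Without a
database, `pseudo_pssm` provides a deterministic stand-in: row *i* is
the BLOSUM62 substitution-score row of residue *i* plus Gaussian noise
(σ = 1) drawn from a seed-keyed table indexed by (position, residue).
Keying the noise this way means two sequences that agree at a position
get identical rows there, so a point mutation perturbs exactly one
profile row — the behavior real alignment profiles exhibit. (An earlier
design that hashed the whole sequence made wild-type and mutant
profiles differ everywhere, which drowned the mutation signal.) Because
BLOSUM62's diagonal is strictly maximal, the true residue's column
scores highest in expectation. Profiles for the mutant window are
computed from the mutant full-length sequence, keeping the two channels
self-consistent.

## Binding-affinity bridge

Affinity tables (SKEMPI v2 layout) are filtered to binary complexes
(exactly two chains) with a single point mutation and both dissociation
constants parsed; duplicates are kept. The binding free-energy change
is ΔΔG = R·T·ln(Kd_mut / Kd_wt) with R = 1.987e−3 kcal K⁻¹ mol⁻¹;
temperatures are parsed from their leading number ("298(assumed)" →
298) and default to 298 K when absent. Entries are bucketed at
−1 kcal/mol, inclusive on the stabilized (≤) side. The
reversal-consistency harness predicts each entry in both directions and
reports per-bucket class distributions plus a flip rate — the fraction
of confident increasing/decreasing calls that invert under role swap.
A model trained with reverse-mutation augmentation should flip far more
often than one trained without.

## Attention interpretation

Attention weights are exported from the last self-attention layer of
the partner branch, one L×L map per head, padded positions removed.
The per-residue weight of residue *j* is the mean attention it receives
over non-padded queries, rescaled so each track's maximum is 100 (the
reduction and scale are package choices; the 0–100 scale matches how
such weights are commonly visualized). Per head, the top-5 residues of
each partner are pooled across proteins, partitioned by interface
membership, and compared with a two-sided Mann–Whitney U test — exact
permutation enumeration when both groups have ≤ 8 members, the
tie-corrected normal approximation otherwise.

## Synthetic data

The generator emulates the curated training data at desk scale:
uniform-random sequences over the 20 amino acids, one planted 6-residue
partner motif (whose location doubles as a pseudo-interface for the
interpretation pipeline), and a label rule tying mutation chemistry to
partner context. With Δh the Kyte–Doolittle hydropathy change (alt −
ref) and M motif presence: disrupting if M and Δh < −2; increasing if M
and Δh > +2; decreasing if M and |Δh| ≤ 2; no_effect if not M; the
label is then flipped to a uniformly random other class with
probability η. The rule is partner-conditional by construction, so a
partner-blind model cannot separate no_effect from the effect classes —
the property the partner-ablation comparison exercises.

What the generator does not emulate: real protein composition and
family structure, correlated evolutionary profiles, length
distributions of curated interactomes, or label noise that correlates
with annotation provenance. Passing desk-scale tests therefore
demonstrates that the architecture and pipeline can recover a planted
partner-conditional signal — not that the model reaches published
performance on curated data.

## Problem sizes used by the test suite

Desk-scale runs use mutated-protein and partner lengths of 60–120
residues with a matching partner input length of 128, a reduced model
(d_model 32, one encoder block per branch, ffn width 64), and datasets
of 60–4,000 events. These sizes keep the full suite's training runs in
the minutes range on one CPU while leaving the planted signal
recoverable. The paper-count fixture (16,451 events, 5,452 disrupting)
reproduces the augmentation arithmetic exactly and is label-structure
only.

## Reversal-consistency experimental design

The reversal harness compares, with paired seeds, a model trained with
augmentation against one trained without, measuring the fraction of
confident increasing/decreasing calls that invert when the input roles
are swapped. On a balanced 4-class synthetic mixture this comparison is
confounded: the planted rule assigns the swapped form of an increasing
event (Δh < −2 with motif) to the *disrupting* class, directly
conflicting with the label the reverse-mutation rule teaches
(*decreasing*), so flips become coin flips regardless of augmentation.
The harness therefore uses a no_effect/increasing mixture in which the
swapped pattern occurs only through augmentation, making the expected
direction unambiguous — the synthetic analogue of validating reversal
behavior on externally labeled affinity data, where the reversal truth
is physical rather than planted. Under this design the augmented model
inverts the majority of its confident directional calls while the
non-augmented model largely keeps its original predictions under role
swap (both asserted by the suite).

## Known limitations

* The conv + GAP head is linear in the merged representation;
  position-resolved information reaches the logits only insofar as the
  residual blocks route it into channels. The channel-axis merge gives
  each of the five representations its own channels, which removes the
  dominant failure mode, but within-segment position information is
  still readable only through content.
* Checkpoints store the numpy engine's arrays (.npz) plus a JSON config
  snapshot; they are not interchangeable with any other framework.
* The PSI-BLAST path shells out to the external executable and is
  exercised in tests only through its ASCII-parser and error contracts.
* Nonstandard residues (B, J, O, U, X, Z, *) are retained in records
  but enter the model as padding/unknown (token 0, mask false).
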