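# Methods

## Task and data model

The package classifies small molecules as BACE-1 inhibitors (active) or
not. Activity is defined from the half-maximal inhibitory concentration:
a compound with log₁₀ IC50[nM] strictly below 2 (IC50 < 100 nM) is
labeled 1, otherwise 0. A value of exactly 2.0 maps to inactive: the
definition uses strict inequalities, and the conservative choice avoids
over-calling actives on the boundary. Curation drops multi-component
(salt) SMILES outright rather than stripping to the largest fragment,
removes records without a conclusive numeric IC50, and collapses
duplicate structures by canonical SMILES (first occurrence kept), which
makes curation idempotent.

Splitting is stratified: validation and test receive exactly
⌊ratio·N⌋ records each (largest-remainder allocation across the two
label classes), and all remainder molecules go to the training split, a
deterministic rule that maximizes training data.

## Graph featurization

Atom and bond feature vectors follow the 133/14 layout that is standard
for message-passing networks on molecules: every categorical property
is one-hot encoded with a trailing "other" slot so exotic atoms never
crash the featurizer —

* atom (133): atomic number over the first 100 elements (+other),
  total degree 0–5 (+other), formal charge in {−1,−2,+1,+2,0} (+other),
  chiral tag (4, +other), total H count 0–4 (+other), hybridization
  SP/SP2/SP3/SP3D/SP3D2 (+other), aromatic flag, atomic mass / 100;
* bond (14): null-bond flag, bond type (single/double/triple/aromatic),
  conjugation, ring membership, stereo code (6, +other).

Edges are stored directed (two per bond) for message passing, while the
bond feature matrix keeps one row per undirected bond, so the worked
16-atom example produces matrices of shape [16,133] and [18,14].

## Graph encoder

Hidden width d (default 64), L message-passing layers (default 3).
Initialization projects raw features through linear maps with ReLU.
Per iteration:

1. *Aggregate*: the message for atom v is the element-wise product of
   the **sum** and the **max** of the hidden states of v's incoming
   directed edges. (The product-of-sum-and-max reading reconciles the
   three operations named for the aggregation step; an atom with no
   incoming edges receives a zero message.)
2. *Communicate*: a per-layer MLP (2d→d→d, ReLU between, dropout after
   the hidden layer) applied to the concatenation of message and
   previous atom state.
3. *Edge update*: `h_e ← ReLU(h_e⁰ + W·(h_v[src] − h_e))`, where the
   source-atom convention follows standard directed-edge updates.

Readout re-aggregates the final edge states and communicates them with
the final atom state *and* the raw atom features (2d+133 → d → d).

Feature attention (FA) is applied once after readout (configurable):
sum- and max-pooling per molecule give two d-vectors, a shared
bottleneck W₂: d→d/r, W₁: d/r→d with ReLU and reduction ratio r = 4
produces sigmoid gates in (0,1)^d that rescale every atom row of the
molecule. r = 4 balances capacity against parameter count; any divisor
of d works.

## Sequence tokenization and encoder

Tokenization is purely textual, greedy, left-to-right, with priority:

1. functional-group patterns, longest first (ties: higher corpus count,
   then lexicographic). The default vocabulary covers amide, ether,
   nitro, benzene, sulfonyl, carbonyl variants; mining counts substring
   occurrences over a corpus and keeps candidates above `min_count`.
   The benzene pattern is spelled `c1ccccc1` (valid aromatic-ring
   notation).
2. bracketed units `[...]` as single *ion-group* tokens;
3. two-letter halogens `Cl`/`Br` and `%NN` ring closures whole; every
   remaining character (including digits and parentheses) is one
   *atom-level* token.

Concatenating tokens always reproduces the input string, and
functional-group tokenization provably never yields more tokens than
character-level splitting — on the fixture corpus it is about half as
long on average, which shortens the recurrent computation.

The encoder embeds token indices (width = sequence hidden width,
default 128) and adds a learned 3-way embedding of the token level, the
minimal mechanism that makes level identity visible to the flat
position attention. Hierarchical attention computes
`Z = tanh(W₁X + b)`, scores `S = softmax(W₂Z)` over positions (pads
masked), the weighted input `X_atten = X ⊙ S`, its pooled sum, and the
pooled vector broadcast back over positions. Feeding the broadcast
vector alone to a recurrent network would erase order information, so
the BiLSTM consumes `X_atten + broadcast`, preserving both the
per-token weighting and the global context. The BiLSTM (default 3
stacked bidirectional layers, forget-gate bias 1) concatenates forward
and backward states (output width 2H); one Transformer encoder block
(4 heads, feed-forward 4× width, no positional encoding since order is
already injected by the recurrence) refines the sequence. Pad positions
carry zero state everywhere: the recurrence carries the previous state
through masked steps, so padding a batch never changes real outputs.

## Fusion, head, and losses

Global-attention pooling (a learned scalar gate per item,
softmax-normalized within each molecule) maps atom vectors and token
vectors to per-molecule vectors H_g and H_s. Both are linearly
projected to a common fusion width (default 128; the branches' native
widths differ), combined as `H = W_s·H_s + W_g·H_g + b`, and classified
by the head fusion_dim→256 (ReLU, dropout) →64 (ReLU) →1.

The training loss is `L = Σ_i BCE(logit_i, y_i) + α·L_contrast` (BCE
summed over the batch, not averaged). The contrastive term uses the
L2-normalized projected vectors Z_s, Z_g:

    L_contrast = Σ_{anchor∈{s,g}} −(1/N) Σ_i log
        exp(cos(Z_si, Z_gi)/T) / Σ_{j≠i} exp(cos(anchor_i, other_j)/T)

As written the denominator excludes the positive pair, so the loss is
unbounded below (the orthonormal two-sample construction evaluates to
exactly −2 at T = 1); this form is the default, and
`contrastive_variant="ntxent"` adds the positive pair back for users
who want the standard bounded form. Defaults α = 0.1, T = 0.5 keep the
contrastive term an order of magnitude below the label loss at
initialization.

## Training protocol

Adam (β = 0.9/0.999), batch size 32, learning rate 1e-4, dropout 0.5 —
the selected configuration from the tuning grid (batch {32,64}, lr
{1e-3,1e-4,1e-5}, layers {3,5}, graph hidden {32,64,128}, sequence
hidden {64,128,256}, dropout {0.3,0.5,0.7}). Checkpoint selection is by
validation accuracy with ties broken by MCC then F1; early stopping
patience is 20 epochs (max 300). The decision threshold on the sigmoid
output is 0.5. Every random choice (init, batch order, dropout) derives
from `ModelConfig.seed`, making runs bitwise reproducible on one
device.

Metrics: ACC, SE, SP, MCC, F1 from the 0.5-threshold confusion matrix;
AUC is the trapezoidal area under the ROC curve and PRC the trapezoidal
area under the precision–recall curve (both via scikit-learn,
cross-checked in the tests against explicit threshold sweeps to 1e-9).
Undefined MCC (a zero denominator) and single-class AUC/PRC are
reported as 0.0 with an `*_undefined` flag rather than NaN.
Cross-validation uses stratified k-fold (default k = 10); the
multi-seed runner repeats split+train+test over 10 seeds and reports
mean ± SD per metric.

Ablations switch off one component at a time under a shared split and
seed: FA, HA, functional-group splitting (falling back to pure
character tokenization), or the whole sequence branch (graph-only).

## Synthetic fixture data

The generator assembles 3–9 chainable SMILES fragments (alkyl, benzene,
ether/alcohol, thioether, halogenated and nitrile carbons, nitro,
stereocenters) into parseable drug-like strings covering every token
family the tokenizer handles. The label is substructure-determined —
active iff the amide `C(=O)N` occurs, a string only the dedicated amide
fragment can produce — at a target active fraction of 0.4, emulating
the curated BACE-1 set's ≈2:3 class ratio. log IC50 values are drawn
from N(1.0, 0.3) for actives and N(3.0, 0.3) for inactives, truncated
away from the threshold at 2 so binarization is never ambiguous, and an
optional `noise_rate` flips labels (with log IC50 kept consistent with
the flipped label).

Because the labels follow a clean substructure rule, a trained model
can reach perfect held-out metrics on fixtures; passing these tests
demonstrates that the pipeline can extract a functional-group signal
through both branches, **not** that the model attains any particular
accuracy on real bioactivity data, which is noisier, more diverse, and
not determined by a single substructure. Real-data headline numbers
additionally depend on an external curated dataset and a best-of-seeds
partition selection that is not reproducible from the description, so
they are out of scope for the machine-checked suite.

## Problem sizes for routine runs

The default `ModelConfig` mirrors the selected full-scale
configuration. For CPU-only NumPy execution (tests and the acceptance
script) the package uses `smoke_config()`: hidden widths 32/32, 2 graph
layers, 1 BiLSTM layer, fusion width 64, dropout 0, batch 16, learning
rate 1e-3 — the same architecture at smaller width, chosen once as a
realistic scale for fixture-sized datasets (64–200 molecules). The
overfit capacity check trains on 64 noise-free molecules and typically
memorizes them in 10–20 epochs.

## Numerical notes and limitations

* Softmax masking happens **before** the max-shift stabilization so
  that extreme scores at padded positions cannot underflow real ones.
* `segment_max` routes gradients to the first argmax row on ties;
  empty segments pool to zero.
* BCE uses the `max(z,0) − z·y + log(1+exp(−|z|))` form; sigmoid inputs
  are clipped at ±500.
* The contrastive loss requires N ≥ 2; batches of one fall back to the
  plain BCE term during training.
* The tokenizer is textual, not substructure-aware: it does not
  canonicalize, and a functional-group string split across branch
  parentheses (e.g. `C(=O)` … `N` separated by a branch) is not
  recognized as a group.
* The NumPy implementation is single-threaded per operation and not
  meant for datasets beyond a few thousand molecules at full widths.
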