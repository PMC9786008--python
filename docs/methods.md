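# Methods

## Problem

Predicting which adverse drug reactions (ADRs) a small molecule can cause
is a multi-label classification problem: a drug `d_i` maps to a binary
vector over `N_l` ADR classes (27 system-organ classes in the large-scale
setting, 4 classes in the OMOP-style drug-safety setting). At the
preclinical stage the only input available is the chemical structure, so
every feature here derives from the SMILES string alone.

## Model

Each molecule is represented twice and the two views are fused.

**Graph channel.** The heavy-atom molecular graph carries four attributes:
atomic number and chirality on nodes, bond type and bond direction on
edges (hydrogens are implicit; attribute categories outside the enumerated
sets collapse to `other`/`none`/single). A graph isomorphism network runs
`T` sum-aggregation message-passing iterations,

    m_u^{t+1} = Σ_{v∈N(u)} W_t (h_v^t + e_uv)
    h_u^{t+1} = W_t (h_u^t + m_u^{t+1}),

where the aggregation and update maps at iteration `t` share one square
matrix `W_t` of width `dim` and are purely linear (no activation between
iterations — a deliberate, faithful-to-definition choice). Initial node
states are the sum of the atomic-number and chirality embeddings; edge
features the sum of the bond-type and bond-direction embeddings. The
graph-level embedding is the element-wise maximum over final node states
(max-pool readout), which together with sum aggregation makes the
embedding invariant under node relabeling (tested to 1e-6). Three
independently parameterized encoders, tagged `m`/`e`/`c` after the
mutual-information, edge-prediction and context-prediction pretraining
objectives of the graph-pretraining literature, give embeddings X^m, X^e,
X^c. By default each is a seeded random initialization fine-tuned during
supervised training; weights can be loaded from file, and desk-scale
warm-starts exist for the edge and infomax objectives (`toy_pretrain`).
The context objective is not implemented and says so explicitly.

**Sequence channel.** The FP2 path fingerprint (Open Babel) indexes linear
fragments of 2–7 atoms into 1024 bits; packing four bits per digit gives a
256-token string over the 16-symbol hexadecimal alphabet — the
"substructure sequence". The channel embeds each token (16 × dim′ table),
layer-normalizes across the embedding dimension per position, applies
H-head scaled dot-product self-attention

    α_{s,j} = softmax_j(Q_s·K_j / √d_v),   O_s = Σ_j α_{s,j} V_j,

with `d_v = dim′/H` enforced exactly, concatenates heads, projects by
`W_o`, adds the block input (residual), layer-normalizes again, then
compresses: flatten to 256·dim′, linear to `dim_ff`, batch normalization,
linear to `dim`, LeakyReLU outermost — exactly that nesting. There is no
positional encoding; consequently the attention block is permutation
equivariant in token positions (verified by test), and token identity is
carried only by token values. Dropout (rate ε) acts on the attention
weights and on the feedforward hidden layer, in training mode only.

**Fusion and head.** The drug representation is the width-4·dim
concatenation X = [X^m, X^e, X^c, X^f]; probabilities are
`P = sigmoid(X W_pred)` with `W_pred ∈ R^{4·dim × N_l}`. Binarization uses
threshold τ with a ≥ tie rule.

**Training.** Mean per-label binary cross-entropy, minimized with Adam —
the standard optimizer for this kind of architecture — at learning rate ξ
with L2 weight decay δ added to the gradient. Determinism: every random element (initialization,
shuffling, dropout, the synthetic generator) is driven by generators
derived from a single seed, so identical config + seed reproduces loss
trajectories and evaluation reports bit for bit.

## Parameters

| name | default | meaning |
|------|---------|---------|
| H (`n_heads`) | 2 | attention heads (tuned value) |
| ε (`dropout`) | 0.5 | dropout rate (tuned value) |
| ξ (`lr`) | 0.001 | Adam learning rate (tuned value) |
| δ (`weight_decay`) | 0.001 | L2 coefficient (tuned value) |
| `dim` | 300 | graph/sequence feature width; fused width 4·dim |
| `T` | 5 | message-passing iterations |
| `dim′` | 64 | token embedding width |
| `dim_ff` | 1024 | feedforward hidden width |
| τ (`threshold`) | 0.5 | label binarization threshold |
| `epochs`, `batch_size` | 100, 32 | training run size (open choices, exposed in config) |

`dim`, `T`, `dim′`, `dim_ff`, epochs and batch size are free dimensions
of the architecture; the defaults above follow the conventions of the
pretrained-GIN and transformer literature and are recorded in every run
manifest.

## FP2 dialect

The fingerprint is 1024 bits packed four per digit into 256 hexadecimal
digits; the bit-to-digit order is a convention that must be fixed
somewhere. We define the sequence as Open Babel's
native fpt hex rendering of the 1024-bit vector (32 × 32-bit words in
printed order), lowercased. This is reproducible and matches the reference
FP2 implementation byte for byte; a single molecule always yields the same
string. A single heavy atom (e.g. methane) sets no bits and yields the
all-`0` string, because FP2 indexes only fragments of two or more atoms.

## Synthetic data

The generator emulates a multi-label drug dataset with known ground
truth. Molecules are concatenations of 2–4 chain-extendable SMILES
fragments from a fixed 37-fragment pool (every fragment ends in an atom
with free valence and closes its own rings, so any concatenation parses).
One substructure rule is planted per label — aromatic ring, nitrogen,
carbonyl, halogen for the default four labels — and label j is 1 exactly
when marker j matches; each label then flips independently with
probability ρ (`label_noise`, default 0). Structure and noise use
independent RNG streams, so the molecules drawn for a seed do not depend
on the noise level. Under the default pool the marker prevalences are
roughly 0.23 / 0.55 / 0.35 / 0.35 with natural co-occurrence (fragments
carry several markers at once).

What this does and does not show: planted labels are a deterministic
function of substructure presence, which is exactly the information FP2
bits and short message-passing ranges can carry; recovering them
(held-out macro AUC ≥ 0.95 at n = 200) demonstrates that featurization,
both channels, fusion, training and evaluation are wired correctly. Real
ADR labels are far noisier, depend on targets and dosing outside the
structure, and exhibit much higher label cardinality (the 27-class
benchmark has base 16.5, density 0.6111), so passing these tests says
nothing about clinical performance.

## Numerical choices

* All learnable tensors are float32 by default; oracle tests run the same
  code in float64. Gradients come from a small reverse-mode tape engine
  validated by central finite differences.
* GIN weight matrices initialize at std 0.5/√dim so that T purely linear
  iterations neither explode nor vanish on molecular graphs; embeddings at
  std 0.3; the sequence channel uses Glorot initialization.
* Max-pool readout breaks gradient ties by first row index, the usual
  max-pool convention.
* Batch normalization uses batch statistics while training (falling back
  to running statistics for a single-sample batch) and running statistics
  in evaluation, so single-molecule inference is well defined and
  evaluation is deterministic.
* The binary cross-entropy used for training acts on logits in the
  numerically stable max(z,0) − z·y + log(1+exp(−|z|)) form; the public
  `loss` on probabilities clips away from exact 0/1.
* Undefined per-label metrics (zero denominators, single-class labels in
  a fold) are excluded from macro averages and listed in the report,
  never silently counted as zero. AUC ties follow the Mann–Whitney 0.5
  convention.
* Adam's bias correction is folded into the step size
  (lr_t = lr·√(1−β₂ᵗ)/(1−β₁ᵗ), eps_t = eps·√(1−β₂ᵗ)), which is
  algebraically identical to the m̂/v̂ formulation.
* The 90/10 holdout uses floor rounding on the train side (2248 → 2023/225);
  k-fold sizes differ by at most one; no stratification by default (an
  unstratified random split is the plain reading of the protocol).

## Open design points, resolved

* The attention output is the standard weighted sum over positions `j`
  of value vectors `V_j` (the alternative of weighting each position's
  own value vector would make the sum over positions degenerate).
* Macro precision/recall pool per-label counts over samples and then take
  an unweighted mean over labels; accuracy is sample-wise label (Hamming)
  accuracy averaged over samples rather than all-or-nothing subset
  accuracy.
* Whether the GIN encoders are frozen or fine-tuned during supervised
  training is open; both are supported (`finetune_gin`, default on).
* Layer normalization is applied directly to the embedding lookup; no
  embedding dropout precedes it.

## Run sizes

The parameter-recovery study trains the full-width model (dim 300, T 5,
dim′ 64, dim_ff 1024) on 160 of 200 generated molecules for 12 epochs at
batch size 64 — enough for the planted rules to be recovered essentially
perfectly (held-out macro AUC ≥ 0.99 across seeds) while keeping a
single-CPU run in the minutes range. Unit and oracle tests use reduced
widths (8–24) because the contracts they check are width independent.

## Known limitations

* The purely linear message passing means the three GIN encoders differ
  only by initialization unless warm-started or loaded from file; with
  fine-tuning on, their embeddings specialize during training.
* The context pretraining objective is not provided; `toy_pretrain`
  implements desk-scale edge and infomax objectives only.
* FP2 computation shells out to the `obabel` executable; it must be on
  PATH (it is part of the supported environment).
* Molecules Open Babel cannot fingerprint but RDKit can parse (or vice
  versa) count as featurization failures for both representations, keeping
  the two channels aligned on the same molecule set.
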