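# Methods

## The model

`secmap` predicts per-residue protein secondary structure (the eight-state
DSSP alphabet G, H, I, T, B, E, S, C, or its three-state reduction H, E, C)
from per-residue protein language-model embeddings, without evolutionary
profiles. The design follows the observation that DSSP states are assigned
from *local patterns of pairwise hydrogen bonds*: the architecture therefore
converts the sequential embedding into an explicitly pairwise feature and
then looks for local patterns in it.

Given an embedding matrix `E ∈ R^{p×d}` (default `d = 1024`, the
ProtT5-XL-U50 per-token contract; the language model itself is never run
here), the pipeline is:

1. **Pairwise encoder.** A stack of `N` pre-norm transformer encoder layers
   with `H` heads each (defaults `N = 3`, `H = 8`). The product is not the
   hidden states but the *post-softmax attention maps* of every layer and
   head, stacked into a `p × p × (N·H)` tensor — 24 channels at the
   defaults. Row `i` of each map is a distribution over partners `j` and is
   treated as a pairwise residue feature.
2. **Relative position bias.** Attention logits receive a learnable bias
   `b[bucket(i−j), h]` with `bucket(i, j) = min(|i−j|, B−1)` (default
   `B = 16`). The bucket is symmetric (a bond between `i` and `j` is the
   same bond from either end) and grows linearly before clamping, so small
   distances — where an `i,i+3` bond (3-helix, G) must be distinguished
   from an `i,i+4` bond (alpha-helix, H) — each get their own bucket. The
   table is shared across layers, giving exactly `B·H = 128` learnable
   parameters over a position-free encoder. Absolute sinusoidal encoding
   (APE) exists as an ablation mode only; it is added to the input
   embedding, carries zero learnable parameters, and rejects sequences
   longer than `ape_max_len` (default 1024) since it cannot extrapolate.
3. **2D segment detector.** Three parallel branches scan the stack with
   different kernel geometry: 3×3 (padding 1), 5×5 (padding 2), and 3×3
   dilated ×2 (padding 2). Each branch is a 1×1 projection from `N·H` to
   `C` channels (default `C = 64`) followed by three residual base blocks
   `x + PA(CA(conv(relu(conv(x))) + x))`, where CA is squeeze-and-excite
   channel attention (reduction ratio 8) and PA is a single-channel
   per-position sigmoid gate. All convolutions preserve the `P × P`
   spatial shape — the printed dilated configuration would shrink the map,
   so its padding is 2 by construction. Branch outputs are concatenated to
   `P × P × 3C`.
4. **Head.** Residue `i`'s descriptor is the diagonal entry `(i, i, ·)` of
   the detector output (the stacked receptive fields supply the off-diagonal
   context); two fully connected layers (hidden width 128, ReLU) and a
   softmax give the class probabilities.

Two ablation variants reuse the same parts: `transformer_only` feeds the
encoder's hidden states straight to the head (no pairwise stage);
`external_attention` feeds an externally supplied attention stack to the
detector (no encoder). For desk-scale work the external stack is
row-softmaxed scaled similarity `softmax(E Eᵀ/√d)` of the input embedding,
one channel per temperature.

## Numerical implementation

The network, its gradients, and the optimizer are implemented directly on
NumPy in `secmap._nn`: a small reverse-mode autodiff engine (broadcasting
arithmetic, batched matmul, softmax/log-softmax, erf-based GELU, im2col 2D
convolution with dilation, bucket-table lookup with scatter-add gradients,
diagonal extraction) plus Adam with decoupled weight decay and a
cosine-annealed step size. Everything runs in float32; the test suite
switches the engine to float64 and checks every operation's gradient
against central finite differences. Training is single-threaded and fully
deterministic given the seed: repeated runs reproduce the loss curve
bitwise.

Training minimizes mean per-residue cross-entropy. Batches (default size
2) are averaged per sequence, not per residue, so short sequences are not
down-weighted within a batch. Each epoch every sequence longer than
`crop_len` (default 256) is re-cropped to a uniformly placed window —
bounding the quadratic `P × P` memory of the pairwise feature and acting
as augmentation. The learning rate anneals cosine-wise from
`learning_rate` (default 1e-3) to 0 over the full run; the default epoch
count is 10 and batch size 2. The optimizer family and learning rate are
this package's choice; only the schedule family, batch size and epoch
count are inherited constraints of the reproduced training recipe.

Degenerate inputs: a single-residue protein yields an all-ones 1×1
attention map per channel (softmax over one key); `n_buckets = 1` puts
every pair in bucket 0; ties in strand pairing (below) break toward the
leftmost candidate run.

## Evaluation statistics

* **Dataset accuracy** is the *mean over sequences* of per-sequence residue
  accuracy (not residue-pooled); the two coincide only when all sequences
  have equal length.
* **Precision/recall/F1** are residue-pooled over the evaluation set and
  macro-averaged over all K classes with zero-division treated as 0, so a
  class absent from a dataset still counts. Macro averaging was chosen
  because micro-averaged single numbers over eight imbalanced classes are
  dominated by C and H.
* **MCC** is the multiclass Matthews correlation (covariance form over the
  K×K confusion matrix, via scikit-learn); a degenerate single-class
  comparison is defined as 0.
* **Mean-difference intervals** over paired per-dataset accuracies use a
  two-sided 95% t interval with n−1 degrees of freedom. A t interval was
  chosen over a normal or bootstrap interval because the number of paired
  datasets is small (4–5 in the intended use).

## The synthetic bond grammar

Real training corpora need language-model inference and GPU training, so
the package ships a generator whose *labels are a deterministic function of
local pairwise structure* — the exact inductive bias the architecture
claims to exploit — at desk scale.

1. **Labels.** A DSSP8 string is a concatenation of segments whose states
   are drawn from `state_weights` (defaults H .30, E .20, C .25, T .12,
   G .06, S .05, B .02 — helix/strand/coil-heavy, as in real proteins) and
   whose lengths are the state's minimum (H ≥ 4, G ≥ 3, E ≥ 2, others ≥ 1)
   plus a geometric tail with mean 2. A final run truncated below its
   minimum is relabeled C.
2. **Bonds.** Alpha-helix runs bond `(i, i+4)` within the run; 3-helix
   runs bond `(i, i+3)`; each maximal strand run pairs with its nearest
   other strand run and bonds antiparallel residue-to-residue (lone
   strands stay unbonded); turns bond `(i, i+3)`; isolated bridges bond
   the nearest E/B residue at least 3 apart; S and C contribute nothing.
   The map is symmetric with a zero diagonal. This is a deliberate
   simplification of DSSP's hydrogen-bond energetics, not a
   reimplementation.
3. **Embeddings.** Residue `i` gets its amino acid's codebook vector plus
   `β` times the sum over bonded partners `j` of a positive bond-tag vector
   elementwise-modulated by partner `j`'s codebook vector, plus
   `N(0, σ²)` noise (defaults `d = 32`, `β = 2`, `σ = 0.5`). Bonded pairs
   then have systematically larger inner products than non-bonded pairs,
   with a margin growing in `β`. The codebook and tag are deterministic in
   `d` alone — they stand in for the language model's *fixed* embedding
   space, so datasets generated with different seeds (train vs held-out)
   share them.

What the generator does *not* emulate: amino-acid structural propensities
(labels are independent of the sequence), long-range beta-sheet topology
beyond nearest-run pairing, chain-length variation, and the anisotropic
geometry of real LM embedding spaces. Passing the learnability check
therefore shows the architecture can recover labels from pairwise signal
under noise — not that it reaches any particular accuracy on real
proteins.

Some synthetic labels are information-theoretically ambiguous by design:
S and C are both bond-free, as are minimum-length helix runs (an H-run of
exactly 4 has no `i,i+4` pair inside it), so the Bayes accuracy of the
task is well below 1. The learnability bar is therefore *relative*: a
small full-variant model (2 layers, 4 heads, 16 detector channels,
trained 10 epochs at learning rate 6e-3) must beat the majority-class
baseline by ≥ 10 accuracy points on held-out data.

Two initialization choices matter for optimization here: the channel and
pixel attention gates start mostly open (bias 2, gate ≈ 0.88) so the nine
stacked blocks do not attenuate the signal path at initialization, and
the relative-position bias table starts near zero (N(0, 0.02²)) so
position information is learned rather than imposed.

## Problem sizes used in the checks

The shipped checks run on one CPU: the overfit sanity check uses 8
proteins of length 32 for 200 epochs; the learnability check uses the
generator defaults (200 training proteins, 50 held-out, length 64); the
ablation machinery check trains 1 epoch on a handful of proteins. These
sizes were chosen so the full suite completes in minutes while each check
still exercises the full training path.

## Known limitations

* The engine is CPU-bound and quadratic in sequence length; it is a
  desk-scale research implementation, not a production trainer.
* `d_model` defaults to the embedding dimension with no input projection;
  a projection is inserted only when the two differ.
* Strand pairing in the grammar is nearest-run only; real beta sheets
  with three or more partners per ladder are out of scope.
* The hidden width (128) and activation (ReLU) of the head, the encoder's
  feed-forward width (4·d_model) and GELU, and the cross-layer sharing of
  the bias table are this package's choices where the reproduced design
  left them open.
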