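# secmap

Protein secondary-structure prediction from stacked self-attention maps.

## The problem

A protein's secondary structure — which residues sit in helices, strands
or loops — is assigned by DSSP from the *local pattern of hydrogen bonds*
between residue pairs: an `i → i+4` bonding pattern makes an alpha-helix
(H), `i → i+3` a 3-helix (G), ladders of bonds between two stretches make
strands (E), and so on, over the eight-state alphabet
{G, H, I, T, B, E, S, C} with the standard three-state reduction
G/H/I → H, E/B → E, S/T/C → C.

Most sequence-based predictors extract features *sequentially* (LSTMs, 1D
CNNs over profiles or language-model embeddings). `secmap` instead mirrors
how the labels are defined: it turns per-residue language-model embeddings
(the 1024-dim ProtT5-XL-U50 per-token contract; precomputed, never run
here) into an explicitly **pairwise** feature and detects local patterns in
it:

1. a transformer encoder (3 layers × 8 heads) whose **post-softmax
   attention maps** are stacked into a `p × p × 24` pairwise feature;
2. a learnable **relative position bias** `b[min(|i−j|, 15), h]` on the
   attention logits — symmetric and linearly bucketed so that the
   distance-3 vs distance-4 bond distinction (G vs H) is resolvable; it
   adds exactly 128 parameters;
3. a **2D segment detector**: three parallel convolutional branches
   (3×3, 5×5, and 3×3 dilated ×2; 64 channels; residual blocks with
   channel and pixel attention) that scan the map without shrinking it;
4. per-residue classification from the **diagonal** of the resulting
   `p × p × 192` feature through two fully connected layers.

Because training on real corpora needs GPU-scale resources and
language-model inference, the package ships a synthetic **bond-grammar
generator**: labels are sampled from a segment grammar, a hydrogen-bond
map is derived from the labels, and embeddings are synthesized so their
pairwise inner products encode the bond map plus noise. Every stage of the
pipeline is thereby testable on a laptop. See `docs/methods.md` for the
model, the grammar, and all defaults.

The whole network — autodiff, Adam, cosine annealing, 2D convolution —
is implemented on NumPy in `secmap._nn`; there is no deep-learning
framework dependency.

## Worked example

```sh
# a 40-protein synthetic dataset (CSV + HDF5 embeddings + FASTA + manifest)
secmap synth --n 40 --length 48 --embed-dim 32 --seed 1 --out data/

# train a small full-variant model for 10 epochs
secmap train --data data/dataset.csv --embeddings data/embeddings.h5 \
             --config examples/small_model.yaml \
             --epochs 10 --learning-rate 0.006 --seed 1 --out model/

# predict and score (here: back on the training set itself)
secmap predict --fasta data/sequences.fasta --embeddings data/embeddings.h5 \
               --model model/ --out pred.tsv
secmap evaluate --pred pred.tsv --ref data/dataset.csv --n-classes 8 \
                --report report.json
```

The training run ends at loss 0.547 and the evaluation report prints

```json
{
  "per_dataset_accuracy": {
    "all": 0.8260416666666666
  },
  "precision": 0.5750392503330617,
  "recall": 0.5001328835940688,
  "f1": 0.5081231218206759,
  "mcc": 0.7616229484424533
}
```

i.e. 82.6% of residues correct averaged per sequence — on the data the
model was trained on, so this shows the pipeline fitting, not
generalization (the held-out experiment lives in
`scripts/acceptance.py`). Macro precision/recall/F1 run over all eight
classes, so rare states (B, S) pull them below the accuracy.
`secmap inspect --embed-dim 32` prints the architectural bookkeeping:
24 attention-map channels and a 128-parameter relative position bias
(`"rpe": 128`, `"ape": 0`).

The library surface mirrors the pipeline: `secmap.encode` (embeddings →
attention stack), `secmap.detect` (stack → pairwise feature),
`secmap.extract_diagonal` / `secmap.classify`, `secmap.train` /
`secmap.predict_sequence`, and `secmap.synthetic_data` for the generator.

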