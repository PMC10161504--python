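# A desk-scale full-variant model: same architecture family as the default
# (3-detector conv stack, RPE transformer encoder), scaled down for CPU use.
embed_dim: 32
n_layers: 2
n_heads: 4
detector_channels: 16
head_hidden: 64
n_classes: 8
pe_mode: rpe
variant: full
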