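# Registry of named trait-direction presets. Add new crops here; the
# version field guards downstream caching.
version: 1
presets:
  warm-barley:
    DHE: cost
    DMA: cost
    GFP: benefit
    PLH: cost
    TKW: benefit
    YLD: benefit
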