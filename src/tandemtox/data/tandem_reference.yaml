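# Reference tandem chain: three pathway models coupled by fold-changes.
# Omitted params entries fall back to the packaged reference parameter files.
models:
  glycogen: null   # path to a YAML parameter file, or null for the reference set
  ppp: null
  gsh: null
interfaces:
  - upstream: glycogen
    downstream: ppp
    map: {g6p: g6p_initial}
    mode: fold-change
  - upstream: ppp
    downstream: gsh
    map: {nadph_ratio: k_nadph_supply}
    mode: fold-change
drug_grid_uM: [0.0, 0.01, 0.0316, 0.1, 0.316, 1.0, 3.16, 10.0, 31.6, 100.0]
vite_pool_uM: 0.0
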