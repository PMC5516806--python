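# Reference parameter set for the ppp model (uM, min).
vmax_g6pd: 10.0
km_g6pd_g6p: 50.0
km_g6pd_nadp: 10.0
vmax_6pgd: 10.0
km_6pgd_6pg: 20.0
km_6pgd_nadp: 10.0
k_nadph_drain: 0.2
k_g6p_refresh: 1.0
nadp_total: 50.0
g6p_initial: 100.0
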