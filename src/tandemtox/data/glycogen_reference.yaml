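# Reference parameter set for the glycogen model (uM, min).
vmax_phk: 1.0
km_phk: 5.0
ki_drug: 5.5
vmax_pp1: 2.0
km_pp1: 5.0
k_gs_inact: 1.0
vmax_gp: 2.55
km_gp_gly: 2000.0
vmax_gs: 15.0
km_gs_g6p: 100.0
k_g6p_in: 10.0
k_g6p_out: 0.1
k_gly_loss: 0.001
gp_total: 10.0
gs_total: 10.0
gly_cap: 50000.0
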