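# Reference parameter set for the gsh model (uM, min).
k_h2o2_prod: 2.0
vmax_gpx: 50.0
km_gpx_gsh: 1000.0
km_gpx_h2o2: 1.0
vmax_gr: 10.0
km_gr_gssg: 500.0
km_gr_nadph: 50.0
k_nadph_supply: 10.0
k_synth: 0.0
k_efflux: 0.0
k_vite_quench: 1.0
vite_pool: 0.0
nadp_total: 50.0
gsh_total_init: 3000.0
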