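# Best-fit kinetic rates for B cell-depleted mice (per 6-h unit).
gamma: 0.38
delta_oe: 0.25
delta_r: 0.0
mu_i: 0.53
delta_i_t: 0.20
delta_i_re: 0.158
mu_re: 0.040
phi_BM: 0.95
mu_t: 0.06
delta_t: 0.005
phi_s: 0.019
eps_spl: 0.018
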