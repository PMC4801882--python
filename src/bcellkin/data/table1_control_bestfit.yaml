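# Best-fit kinetic rates for control mice (per 6-h unit). The source S and
# carrying capacity K are not part of the published table; they are
# calibrated from the steady-state anchor in defaults.yaml.
gamma: 0.3
delta_oe: 0.5
delta_r: 0.0
mu_i: 0.10
delta_i_t: 0.60
delta_i_re: 0.19
mu_re: 0.008
phi_BM: 0.94
mu_t: 0.03
delta_t: 0.03
phi_s: 0.03
eps_spl: 0.008
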