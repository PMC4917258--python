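g_na: 21.0
g_cal: 15.3
g_cat: 0.15
g_to: 0.015
g_kur: 0.045
g_kr: 0.4
g_ks: 0.004
k_ksus: 0.16
g_k1: 0.048925
g_kleak: 0.01
g_kach: 1.9
g_f: 0.003
g_nab: 0.0009
g_cab: 0.0003
i_nak_max: 0.95
k_ncx: 2.6e-05
d_ncx: 0.0001
gamma_ncx: 0.5
km_nai: 10.0
km_ko: 1.5
na_o: 140.0
na_i: 8.0
k_o: 5.4
k_i: 140.0
ca_o: 1.8
ach: 1.0
temperature: 295.0
cm: 1.0
c_cell: 1.0
ca_conv: 5.0e-05
r_nsr: 0.03
r_jsr: 0.003333333333333333
vmax_up: 0.000135
kmf_up: 0.00025
kmr_up: 1.7
h_up: 1.787
tau_tr: 8.0
k_leak_sr: 2.0e-05
ko_ca: 450.0
kom: 0.2
ki_ca: 0.5
kim: 0.005
ec50_sr: 0.45
max_sr: 15.0
min_sr: 1.0
ks_rel: 16.0
k_local: 0.02
trpn_tot: 0.035
kd_trpn: 0.0005
kon_trpn: 40.0
cmdn_tot: 0.05
kd_cmdn: 0.00238
kon_cmdn: 34.0
csqn_tot: 24.0
kd_csqn: 0.63
kon_csqn: 1.0
k_temp_na: 1.4
tau_d_shift: 10.0
block: {}
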