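[component:ritonavir]
M = 721.0
m_seg_per_M = 0.022
sigma = 3.9
u_over_kB = 305.787
eps_assoc_over_kB = 1041.0
kappa_assoc = 0.02
n_sites = 4/4
rho = 1151.0
Tg = 323.5
T_SL = 398.15
dh_SL = 63.15
dcp_SL = 224.0

[component:PVPVA64]
M = 65000.0
m_seg_per_M = 0.0372
sigma = 2.947
u_over_kB = 205.271
eps_assoc_over_kB = 0.0
kappa_assoc = 0.02
n_sites = 653/653
rho = 1190.0
Tg = 384.15

[component:water]
M = 18.015
m_seg_per_M = 0.0669
sigma_coeffs = 2.7927 10.11 -0.01755 -1.417 -0.01146
u_over_kB = 353.95
eps_assoc_over_kB = 2425.7
kappa_assoc = 0.0451
n_sites = 1/1
rho = 1000.0
Tg = 138.0

[binary:PVPVA64/ritonavir]
k_m = 0.0
k_b = 0.019
q = -18.83

[binary:ritonavir/water]
k_m = 6e-05
k_b = -0.059
q = -304.87

[binary:PVPVA64/water]
k_m = 0.0
k_b = -0.156
q = 34.82

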