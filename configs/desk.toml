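# Reduced run for desk-scale checks: same agent density (~0.6 / px^2) and
# identical per-unit dynamics as the control set, smaller domain and a
# shorter horizon (10^4 steps).
n_agents = 10000
grid_size = 128
dt = 0.005
t_final = 50.0
D_agent = 0.3
D_chem = 5.0
secretion_rate = 1.0
decay_rate = 0.2
chi0 = 12.0
c_half = 4.0
c_star = 10.0
t_refractory = 0.6
p_reactivate = 8.333333333333333e-4
t_blind = 3.0
r_agent = 0.3
snapshot_every = 100
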