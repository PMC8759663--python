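# Control parameter set: full-scale run.
# One internal time-unit corresponds to 5 wall-clock minutes under the
# shipped motility-switch calibration (t_blind = 3 tu = 15 min,
# t_refractory = 0.6 tu = 3 min, expected stochastic wait dt/p_reactivate
# = 6 tu = 30 min).
n_agents = 100000
grid_size = 384
dt = 0.005
t_final = 2000.0
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
snapshot_every = 200
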