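# pilT2-deletion tug-of-war parameters: slower retraction/extension,
# more and longer filaments; mechanical fields shared with the WT preset.
n_pili_mean: 13.4
v_ext: 0.65
v_ret: 1.27
pilus_length_mean_um: 4.5
kappa_p: 50.0
F_rmax: 100.0
attach_prob: 0.5
rot_mobility: 0.3     # rad/(pN·μm·s), calibrated to WT flapping amplitude
tau_dwell_s: 1.0
dt: 0.01
out_dt: 0.1
duration: 100.0
cell_a: 1.25
cell_b: 0.5
kappa_tilt: 20.0
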