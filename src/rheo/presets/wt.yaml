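# Wild-type vertical-cell tug-of-war parameters.
# Measured fields: filament number/length and bead-assay speeds.
# Mechanical fields are shared package defaults (see docs/methods.md).
n_pili_mean: 7.6
v_ext: 1.01            # μm/s, away-from-pole bead speed
v_ret: 3.04            # μm/s, toward-pole bead speed (magnitude)
pilus_length_mean_um: 2.8
kappa_p: 50.0          # pN/μm
F_rmax: 100.0          # pN
attach_prob: 0.5
rot_mobility: 0.3     # rad/(pN·μm·s), calibrated to WT flapping amplitude
tau_dwell_s: 1.0
dt: 0.01
out_dt: 0.1
duration: 100.0
cell_a: 1.25           # μm
cell_b: 0.5            # μm
kappa_tilt: 20.0       # pN·μm/rad per attached filament (polar adhesion web)
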