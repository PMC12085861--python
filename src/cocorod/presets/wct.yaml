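# West Coast Tall (WCT) coconut palm preset.
# Physical and growth constants follow the published experimental set;
# the taper anchor radii (x_base, x_dbh) are SYNTHETIC representative
# cultivar values, not field measurements.
rho_prime: 600.0      # kg/m^3
g: 9.8                # N/kg
Y: 1.14e10            # Pa
a_v: 0.46             # m/y
V_r: 0.01             # m/y
alpha: 0.001          # m/m
s0: 0.01              # m
s: 0.01               # m
theta_0: 0.0          # rad
theta_p: 1.5707963267948966       # pi/2 rad
theta_p_f: 1.916371519387791      # 0.61*pi rad
beta_max: 0.0         # 1/m
F_wind: 0.0           # N
x_base: 0.16          # m  (synthetic anchor)
x_dbh: 0.14           # m  (synthetic anchor)
breast_height: 1.4    # m
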