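# Chowghat Green Dwarf (CGD) coconut palm preset.
# Shares the published physical constants with the WCT preset; the dwarf
# cultivar's apical velocity and taper anchors are SYNTHETIC representative
# values (slower, slimmer trunk), not field measurements.
rho_prime: 600.0      # kg/m^3
g: 9.8                # N/kg
Y: 1.14e10            # Pa
a_v: 0.30             # m/y  (synthetic: dwarf cultivar grows slower)
V_r: 0.01             # m/y
alpha: 0.001          # m/m
s0: 0.01              # m
s: 0.01               # m
theta_0: 0.0          # rad
theta_p: 1.5707963267948966       # pi/2 rad
theta_p_f: 1.916371519387791      # 0.61*pi rad
beta_max: 0.0         # 1/m
F_wind: 0.0           # N
x_base: 0.13          # m  (synthetic anchor)
x_dbh: 0.115          # m  (synthetic anchor)
breast_height: 1.4    # m
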