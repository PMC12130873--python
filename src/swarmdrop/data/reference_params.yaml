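# Calibrated reference parameter set (effective material properties of the
# swarm as an active droplet), in micrometre / hour / (Pa s) units with an
# arbitrary viscosity normalization eta = 100 Pa s: only the dimensionless
# groups formed from these values enter the dynamics.  See the parameter
# table in docs/methods.md and swarmdrop.params.reference_params().
kind: PhysicalParams
kappa: 3127.934816109534
eta: 100.0
xi: 119321.24390066277
slip_length: 15.0
growth_rate: 0.4733813997523852
consumption_rate: 29.13116306168524
chemo_production: 262.1804675551672
chemo_diffusivity: 171822.5912169544
chemo_decay: 262.1804675551672
sensing_threshold: 0.001953125
saturation_const: 0.0078125
precursor_height: 5.0
height_scale: 100.0
length_scale: 25.6
time_scale: 0.13731
bacteria_scale: 1.0
conc_scale: 1.0
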