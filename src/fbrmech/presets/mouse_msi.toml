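# Murine mechanically stimulating implant (MSI): same disc as the standard
# mouse model with an embedded coin motor, driven at 1.38 g / 203 Hz.
# The vibration is applied as its quasi-static peak: a body force of
# 1.38 * 9.8 ~= 13.5 N/kg acting on the implant mass (PDMS + motor).
# Geometry/material provenance as in mouse_standard.toml; motor mass ~0.9 g
# (10 mm coin vibration motor).
name = "mouse_msi"
lateral_extent_mm = 28.0
implant_layer = "subcutis"

[[layers]]
name = "muscle"
thickness_mm = 2.0
[layers.material]
name = "muscle"
youngs_modulus_pa = 50e3
poisson_ratio = 0.45
density_kg_m3 = 1060.0

[[layers]]
name = "subcutis"
thickness_mm = 8.0
[layers.material]
name = "fat"
youngs_modulus_pa = 3e3
poisson_ratio = 0.45
density_kg_m3 = 920.0

[[layers]]
name = "skin"
thickness_mm = 1.5
[layers.material]
name = "skin"
youngs_modulus_pa = 100e3
poisson_ratio = 0.45
density_kg_m3 = 1100.0

[implant]
radius_mm = 7.75
height_mm = 6.7
motor_mass_kg = 0.0009
[implant.material]
name = "silicone_pdms"
youngs_modulus_pa = 2.0e6
poisson_ratio = 0.48
density_kg_m3 = 970.0

[load]
kind = "vibration"
amplitude_g = 1.38
frequency_hz = 203.0
direction = [1.0, 0.0, 0.0]
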