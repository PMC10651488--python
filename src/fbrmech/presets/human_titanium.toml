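# Human titanium implant variant: identical to human_breast except the
# implant material record (titanium alloy, E ~110 GPa), probing the
# insensitivity of interface stress to implant stiffness once the implant
# is much stiffer than the surrounding tissue.
name = "human_titanium"
lateral_extent_mm = 112.0
implant_layer = "fat"

[[layers]]
name = "muscle"
thickness_mm = 20.0
[layers.material]
name = "muscle"
youngs_modulus_pa = 100e3
poisson_ratio = 0.45
density_kg_m3 = 1060.0

[[layers]]
name = "fat"
thickness_mm = 30.0
[layers.material]
name = "fat"
youngs_modulus_pa = 3e3
poisson_ratio = 0.45
density_kg_m3 = 920.0

[[layers]]
name = "skin"
thickness_mm = 4.0
[layers.material]
name = "skin"
youngs_modulus_pa = 150e3
poisson_ratio = 0.45
density_kg_m3 = 1100.0

[implant]
radius_mm = 40.0
height_mm = 20.0
[implant.material]
name = "titanium"
youngs_modulus_pa = 110e9
poisson_ratio = 0.34
density_kg_m3 = 4500.0

[load]
kind = "static_force"
magnitude = 40.0
direction = [1.0, 0.0, 0.0]
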