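# Human silicone breast implant in a layered chest-wall domain.
#
# Provenance of defaults (all overridable):
# - Implant: silicone-gel disc approximation of a breast implant, 8 cm
#   diameter x 2 cm height; effective gel modulus ~100 kPa.
# - Layers: pectoral muscle base ~2 cm, subcutaneous/breast fat ~3 cm
#   hosting the implant, skin ~4 mm.  Literature-order placeholders (the
#   source supplementary geometry tables were not available).
# - Moduli: fat ~3 kPa, muscle ~100 kPa, human skin ~150 kPa, nu = 0.45.
# - Load: horizontal static force from human soft-tissue dynamic resting
#   tension, order 10^1 N (human wound-closure/skin tension measurements);
#   configuration input with this provenance, not a derived quantity.
name = "human_breast"
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
name = "silicone_gel"
youngs_modulus_pa = 100e3
poisson_ratio = 0.48
density_kg_m3 = 970.0

[load]
kind = "static_force"
magnitude = 40.0
direction = [1.0, 0.0, 0.0]
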