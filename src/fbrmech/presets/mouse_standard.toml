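# Standard murine subcutaneous silicone disc implant (static resting load).
#
# Provenance of defaults (all overridable):
# - Implant: PDMS disc, 1.55 cm diameter x 0.67 cm height, matching the
#   fabricated devices; 5:1 PDMS modulus ~2 MPa from compression testing of
#   Sylgard 184 formulations.
# - Layer thicknesses: dorsal mouse anatomy around a subcutaneous pocket;
#   skin (epidermis+dermis+panniculus) ~1.5 mm, subcutaneous pocket sized to
#   host the implant, thin muscle sheet above the fixed support.  These are
#   literature-order placeholders: the source supplementary geometry tables
#   were not available, so absolute stress values depend on this config.
# - Moduli: indentation-scale soft-tissue values: fat ~3 kPa, muscle
#   ~50 kPa, rodent skin ~100 kPa, Poisson ratio 0.45 (nearly
#   incompressible soft tissue).
# - Load: horizontal static force from murine dynamic resting skin tension,
#   order 10^-2 N (murine wound/skin tension measurements); configuration
#   input, not a derived quantity.
name = "mouse_standard"
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
[implant.material]
name = "silicone_pdms"
youngs_modulus_pa = 2.0e6
poisson_ratio = 0.48
density_kg_m3 = 970.0

[load]
kind = "static_force"
magnitude = 0.025
direction = [1.0, 0.0, 0.0]
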