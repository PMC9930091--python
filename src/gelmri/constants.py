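"""Physical constants and default experimental parameters.

Concentration bookkeeping is per albumin molecule (the contrast agent is
gadolinium-labeled albumin, ~74 kDa with ~10-15 Gd per molecule); all
relaxivities in this package are therefore per-molecule relaxivities.
"""

GAS_CONSTANT = 8.314  # J mol^-1 K^-1
AVOGADRO = 6.022e23  # mol^-1

#: Molecular weight of gadolinium-labeled albumin (kDa = kg/mol = mg/mL per mM)
MW_GALBUMIN_KDA = 74.0

#: Hydrodynamic diameter of albumin (nm), used for the release-regime verdict
ALBUMIN_DIAMETER_NM = 7.2

#: Body temperature (K), the default for rubber-elasticity mesh-size estimates
BODY_TEMPERATURE_K = 310.15

#: Gel slab thickness at the bottom of the in vitro release tube (m)
SLAB_THICKNESS_M = 5.5e-3
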