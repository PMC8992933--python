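"""Physical constants and bundled shielding-design parameters.

The shielding constants (fitting parameters ``k``, concrete tenth-value
layers) are module-level dictionaries so a user can override them for a
site-specific calculation.
"""
from __future__ import annotations

# --- fundamental ---------------------------------------------------------
MEC2_MEV = 0.51099895          # electron rest energy
JOULE_PER_MEV = 1.602176634e-13
CLASSICAL_ELECTRON_RADIUS_CM = 2.8179403262e-13
AVOGADRO = 6.02214076e23

# --- unit conversions ----------------------------------------------------
# 1 R = 2.58e-4 C/kg and W/e = 33.97 J/C  =>  8.76e-3 Gy of air kerma per R.
AIR_KERMA_PER_ROENTGEN_GY = 2.58e-4 * 33.97
PHOTONS_PER_CI_PER_S_CO60 = 2.0 * 3.7e10   # two photons per decay

# --- default densities (g/cm^3) ------------------------------------------
AIR_DENSITY_SEA_LEVEL = 1.225e-3           # dry air, 15 C
CONCRETE_DENSITY = 2.3

# --- analytic-model constants --------------------------------------------
# Energy-dependent fitting parameter k of the skyshine air-kerma-rate formula,
# by nominal accelerating potential (MV).  Conservative fits to Monte Carlo
# ring tallies; linear interpolation is used between the tabulated points.
K_TABLE = {4: 150.0, 6: 140.0, 10: 100.0, 15: 95.0, 18: 85.0}

# NCRP-151 primary-beam tenth-value layers for ordinary concrete, cm.
# Overridable: assign site-specific values before building a scenario.
TVL_CONCRETE_CM = {
    4:  {"TVL1": 35.0, "TVLe": 30.0},
    6:  {"TVL1": 37.0, "TVLe": 33.0},
    10: {"TVL1": 41.0, "TVLe": 37.0},
    15: {"TVL1": 44.0, "TVLe": 41.0},
    18: {"TVL1": 45.0, "TVLe": 43.0},
}

SUPPORTED_MV = (4, 6, 10, 15, 18)

# Mean photon energies (MeV) anchoring the parametric bremsstrahlung spectra.
PARAMETRIC_MEAN_ENERGY_MEV = {4: 1.3, 6: 2.0, 10: 3.2, 15: 4.9, 18: 6.0}
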