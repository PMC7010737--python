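"""Physical constants, element data and reference material definitions.

All lengths are cm, energies keV, densities g/cm^3, mass fractions per-unit
unless stated otherwise.
"""

from __future__ import annotations

from pathlib import Path

DATA_DIR = Path(__file__).parent / "data"

# physical constants
KEV_TO_J = 1.602176634e-16
KEV_PER_G_TO_MGY = KEV_TO_J * 1e6          # keV/g -> mGy
MEC2_KEV = 510.99895                        # electron rest energy
RE2_CM2 = 7.940787e-26                      # classical electron radius squared
AVOGADRO = 6.02214076e23
HC_KEV_ANGSTROM = 12.398420                 # photon E*lambda

# transport conventions
CUTOFF_KEV = 5.0
ENERGY_MIN_KEV = 1.0
ENERGY_MAX_KEV = 50.0
SURFACE_EPS = 1e-7                          # surface-crossing epsilon, cm
DEFAULT_BATCHES = 20

# element registry: symbol -> (Z, atomic mass)
ELEMENTS = {
    "H": (1, 1.008), "C": (6, 12.011), "N": (7, 14.007), "O": (8, 15.999),
    "Al": (13, 26.982), "Ar": (18, 39.948), "Rh": (45, 102.906),
    "Ag": (47, 107.868),
}

# breast-tissue mixtures (printed compositions, weight percent -> per-unit)
# and densities; rows for 25/50/75% glandular fraction plus skin
TABLE_BREAST = {
    0.25: {"density": 0.955,
           "composition": {"H": 0.110, "C": 0.510, "N": 0.021, "O": 0.357}},
    0.50: {"density": 0.982,
           "composition": {"H": 0.107, "C": 0.401, "N": 0.025, "O": 0.464}},
    0.75: {"density": 1.010,
           "composition": {"H": 0.105, "C": 0.293, "N": 0.029, "O": 0.570}},
}
SKIN_DEF = {"density": 1.090,
            "composition": {"H": 0.098, "C": 0.178, "N": 0.050, "O": 0.667}}

# ICRU-44 adult soft tissue, renormalized to the four transport elements
# (1.3% trace Na/P/S/Cl/K folded into O); torso scatter medium only
ICRU44_SOFT_TISSUE_DEF = {
    "density": 1.06,
    "composition": {"H": 0.102, "C": 0.143, "N": 0.034, "O": 0.721},
}

# dry air near sea level
DRY_AIR_DEF = {
    "density": 1.205e-3,
    "composition": {"C": 0.000124, "N": 0.755268, "O": 0.231781,
                    "Ar": 0.012827},
}

# PMMA (C5H8O2) for the reference-geometry compression/support paddles
PMMA_DEF = {
    "density": 1.19,
    "composition": {"H": 0.080538, "C": 0.599848, "O": 0.319614},
}

# beam-filter densities
FILTER_DENSITY = {"Al": 2.699, "Rh": 12.41, "Ag": 10.50}

# tungsten L-fluorescence lines (keV, relative strength) for the
# semi-empirical anode model
W_L_LINES = ((8.397, 1.00), (9.672, 0.85), (9.961, 0.30), (11.285, 0.25))

# tungsten-anode provider shape, fitted once to the published 26/30/36 kVp
# W/Al filter-thickness vs HVL grid (rms 0.009 mm Al over the 12 pairs):
# fluence(E) ~ (kVp/E - 1)^WSPEC_ENDPOINT_EXP * E^-WSPEC_SOFTENING_EXP,
# with L lines WSPEC_LINE_STRENGTH x the 10 keV continuum level.
# Inherent filtration and target self-absorption are absorbed in the shape.
WSPEC_ENDPOINT_EXP = 0.64
WSPEC_SOFTENING_EXP = 0.15
WSPEC_LINE_STRENGTH = 3.0
INHERENT_AL_UM = 0.0

# mammography geometry conventions
SOURCE_TO_RECEPTOR_CM = 65.0
PHANTOM_LIFT_CM = 1.2                       # phantom bottom above the receptor
DEFAULT_FIELD_CM = (18.0, 10.0)             # (lateral width, chest-wall depth)
CHAMBER_RADIUS_CM = 1.45
CHAMBER_HEIGHT_CM = 0.2
CHAMBER_OFFSET_Y_CM = 2.0                   # chamber axis from chest-wall edge
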