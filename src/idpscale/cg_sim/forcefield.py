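"""Residue-level HPS-Urry force-field parameters.

One bead per residue, implicit solvent.  Short-range pair interactions use
the Ashbaugh-Hatch form — a Lennard-Jones potential whose attractive part is
scaled by the mean hydrophobicity lambda of the pair — and electrostatics use
a screened-Coulomb (Yukawa) potential with Debye length 10 A (approximately
100 mM monovalent salt) and relative dielectric 80.

Provenance: lambda values are the Urry-scale hydropathies with the optimal
(mu = 1, Delta = 0.08) shift of Regy, Thompson, Kim & Mittal, Protein Sci.
30:1371 (2021); bead diameters sigma, charges and the pair energy scale
epsilon = 0.8368 kJ/mol follow the HPS parameterisation of Dignon et al.,
PLoS Comput. Biol. 14:e1005941 (2018).  Masses are standard residue masses.
Histidine is neutral by default (force-field convention); a protonated
fraction can be assigned at topology build time.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "AMINO_ACIDS",
    "LAMBDA",
    "SIGMA",
    "CHARGE",
    "MASS",
    "EPSILON_KJ_MOL",
    "DEBYE_LENGTH_A",
    "DIELECTRIC",
    "YUKAWA_PREFACTOR_KJ_A_MOL",
    "KB_KJ_MOL_K",
    "residue_params",
]

# Boltzmann constant (kJ/mol/K)
KB_KJ_MOL_K = 0.008314462618

# Ashbaugh-Hatch pair energy scale (kJ/mol) = 0.2 kcal/mol
EPSILON_KJ_MOL = 0.8368

DEBYE_LENGTH_A = 10.0
DIELECTRIC = 80.0
# e^2 N_A / (4 pi eps0 * eps_r) in kJ * A / mol
YUKAWA_PREFACTOR_KJ_A_MOL = 1389.35457 / DIELECTRIC

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Urry-scale hydrophobicity, shifted by Delta = 0.08 (dimensionless)
LAMBDA = {
    "A": 0.522942, "R": 0.478824, "N": 0.508236, "D": 0.214119, "C": 0.567059,
    "Q": 0.478824, "E": -0.080000, "G": 0.493529, "H": 0.684707, "I": 0.625883,
    "L": 0.641176, "K": 0.302354, "M": 0.596471, "F": 0.743530, "P": 0.678824,
    "S": 0.508236, "T": 0.508236, "W": 0.920000, "Y": 0.817059, "V": 0.584707,
}

# Bead diameter sigma (A)
SIGMA = {
    "A": 5.04, "R": 6.56, "N": 5.68, "D": 5.58, "C": 5.48,
    "Q": 6.02, "E": 5.92, "G": 4.50, "H": 6.08, "I": 6.18,
    "L": 6.18, "K": 6.36, "M": 6.18, "F": 6.36, "P": 5.56,
    "S": 5.18, "T": 5.62, "W": 6.78, "Y": 6.46, "V": 5.86,
}

# Net charge (e) at neutral pH; histidine neutral by convention
CHARGE = {
    "A": 0.0, "R": 1.0, "N": 0.0, "D": -1.0, "C": 0.0,
    "Q": 0.0, "E": -1.0, "G": 0.0, "H": 0.0, "I": 0.0,
    "L": 0.0, "K": 1.0, "M": 0.0, "F": 0.0, "P": 0.0,
    "S": 0.0, "T": 0.0, "W": 0.0, "Y": 0.0, "V": 0.0,
}

# Residue mass (u)
MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "Q": 128.1307, "E": 129.1155, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}


def residue_params(sequence: str, his_charge: float = 0.0):
    """Per-bead (lambda, sigma, charge, mass) arrays for an amino-acid sequence.

    Raises ``KeyError`` naming the offending letter for unknown residues.
    """
    seq = str(sequence).upper()
    for aa in seq:
        if aa not in LAMBDA:
            raise KeyError(f"unknown residue letter {aa!r}")
    lam = np.array([LAMBDA[a] for a in seq])
    sig = np.array([SIGMA[a] for a in seq])
    q = np.array([his_charge if a == "H" else CHARGE[a] for a in seq])
    mass = np.array([MASS[a] for a in seq])
    return lam, sig, q, mass
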