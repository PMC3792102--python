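"""Physical constants and unit conventions.

All energies are kJ/mol internally; distances are Å; charges are elementary
charges. Inputs expressed in kcal/mol are converted at the I/O layer.
"""

#: Gas constant, kJ/(mol·K).
R_GAS = 8.3145e-3

#: Coulomb prefactor K_e in kJ·Å/(mol·e²): E = K_e * q_i * q_j / r.
K_COULOMB = 1389.354

#: kcal -> kJ conversion used at the I/O layer.
KCAL_TO_KJ = 4.184

#: Boltzmann constant, J/K.
K_BOLTZMANN = 1.380649e-23

#: Planck constant, J·s.
H_PLANCK = 6.62607015e-34

#: Interior / exterior dielectric constants for the generalized-Born term.
EPS_INTERIOR = 1.0
EPS_EXTERIOR = 80.0

#: Water-probe radius for solvent-accessible surface area, Å.
SASA_PROBE_RADIUS = 1.4

#: Default nonpolar surface-tension coefficient, kJ/(mol·Å²).
DEFAULT_SASA_COEFFICIENT = 0.0226

#: One-letter <-> three-letter amino acid code maps (20 standard residues).
AA3_TO_AA1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_AA3 = {v: k for k, v in AA3_TO_AA1.items()}
STANDARD_AA1 = frozenset(AA1_TO_AA3)
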