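"""Physical constants, unit bridges, and reference metadata for the GlpG construct.

Unit system: energies in kcal/mol, distances in Å, time in fs, mass in Da,
temperature in K.  The membrane normal is the z-axis with the bilayer midplane
at z = 0 and the interfaces near z = ±15 Å.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

#: Boltzmann constant, kcal/mol/K.
K_B = 0.0019872041

#: 1 pN acting over 1 Å, expressed in kcal/mol.
PN_ANGSTROM_TO_KCAL_MOL = 0.0143932

#: 1 kcal/mol expressed in Da·Å²/fs² (exact: 4184 J/mol / 1e7 J/mol).
KCAL_MOL_TO_DA_A2_FS2 = 4.184e-4

#: Default replica-exchange temperature ladder, K.
DEFAULT_TEMPERATURE_LADDER = (
    300.0, 335.0, 373.0, 417.0, 465.0, 519.0,
    579.0, 645.0, 720.0, 803.0, 896.0, 1000.0,
)

#: GlpG transmembrane-domain construct: author residue numbering.
GLPG_FIRST_RESIDUE = 91
GLPG_LAST_RESIDUE = 271

#: Transmembrane helix ranges for GlpG (inclusive author numbering).  The two
#: interfacial helices in loop L1 are deliberately absent: they do not
#: participate in the orientation or helix-pair terms.
GLPG_TM_HELICES = (
    (94, 114),    # TM1
    (147, 168),   # TM2
    (171, 192),   # TM3
    (200, 217),   # TM4
    (226, 241),   # TM5
    (250, 269),   # TM6
)

#: Residue window whose mutual contacts are strengthened in the perturbed
#: landscape analysis (TM1-4 region).
GLPG_BOOST_RANGE = (91, 217)

#: TM5-6 sub-construct used for the hairpin order parameters.
GLPG_TM56_RANGE = (226, 269)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


def construct_length(first_residue: int, last_residue: int) -> int:
    """Number of residues in an inclusive author-numbered range.

    For the GlpG transmembrane domain (residues 91-271) this is 181.
    """
    if last_residue < first_residue:
        raise ValueError("last_residue must be >= first_residue")
    return last_residue - first_residue + 1


def load_burial_scale() -> dict[str, float]:
    """Water-octanol transfer free energies (kcal/mol) per amino acid.

    Returns a mapping keyed by both three-letter and one-letter codes;
    negative values mark residues that prefer the membrane interior.
    """
    ref = importlib.resources.files("memfold.data").joinpath("burial_scale.csv")
    with importlib.resources.as_file(ref) as path:
        table = pd.read_csv(path)
    scale: dict[str, float] = {}
    for row in table.itertuples(index=False):
        scale[row.residue.upper()] = float(row.delta_g_water_octanol_kcal_mol)
        scale[row.one_letter] = float(row.delta_g_water_octanol_kcal_mol)
    return scale


def force_pn_to_kcal_mol_per_angstrom(force_pn: float) -> float:
    """Convert a pulling force in pN to the k_force slope in kcal/mol/Å."""
    return force_pn * PN_ANGSTROM_TO_KCAL_MOL
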