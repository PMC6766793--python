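"""Physical constants and default analysis parameters.

All energies are kcal/mol, distances Å, times ps, temperatures K.
"""

#: Boltzmann constant in kcal mol^-1 K^-1.
KB_KCAL: float = 0.0019872041

#: Default simulation temperature (K).
DEFAULT_TEMPERATURE_K: float = 300.0

#: Bulk number density of TIP3P water oxygens (molecules / Å^3), the
#: reference for g(O).
BULK_WATER_DENSITY_PER_A3: float = 0.0329

#: Pairwise water-water interaction energy of bulk TIP3P (kcal/mol); the
#: reference subtracted per voxel, scaled by occupancy.
EWW_BULK_KCAL: float = -9.533

#: Default GIST voxel edge length (Å).
DEFAULT_GRID_SPACING_A: float = 0.5

#: Hydration-site occupancy gate: g(O) must reach this many multiples of the
#: bulk density before a voxel is considered a retained-water site.
SITE_G_O_MIN: float = 10.0

#: Hydration-site energy gate (kcal/mol): |ΔG_solv| at or beyond this value
#: classifies the site as favorable (negative) or unfavorable (positive).
SITE_DG_ABS_MIN: float = 3.0

#: Hydrogen-bond geometric cutoffs (Å): maximum hydrogen-acceptor distance
#: and maximum donor-acceptor distance.
HBOND_MAX_HA_A: float = 2.7
HBOND_MAX_DA_A: float = 3.35

#: Hydrophobic (non-bonded apolar) contact window (Å).
HYDROPHOBIC_MIN_A: float = 2.90
HYDROPHOBIC_MAX_A: float = 3.90

#: Covalent D-H search radius used to attach hydrogens to donor heavy atoms.
DONOR_H_ATTACH_A: float = 1.25

#: Water residue names recognized by default.
WATER_RESNAMES = ("HOH", "WAT", "TIP3", "SOL", "H2O")

#: The 20 standard amino-acid residue names (used for backbone flagging).
AMINO_ACIDS = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    # common protonation-state variants
    "HID", "HIE", "HIP", "ASH", "GLH", "LYN", "CYX", "CYM",
)
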