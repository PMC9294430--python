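"""Physical and statistical constants used across the package.

All tables live here so that every threshold or reference value is auditable
in one place.  Radii are in Angstrom, areas in Angstrom^2, frequencies are
unitless and sum to 1.
"""

from __future__ import annotations

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

# Van der Waals radii (A) for the heavy elements found in standard residues.
# Unknown elements fall back to carbon (with a warning at the call site).
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
}
FALLBACK_ELEMENT = "C"

# Theoretical maximum accessible surface areas (A^2) per residue type,
# from the Tien et al. (2013) theoretical set.  Used to normalize absolute
# SASA into relative solvent accessibility (percent).  The table is
# swappable through RunConfig.
MAX_ASA_THEORETICAL = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

# Background amino-acid composition of UniProtKB/Swiss-Prot (release
# statistics), the default null model for mutant-residue composition
# enrichment.  Values are percentages renormalized to sum to 1.
SWISSPROT_FREQUENCIES = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0137,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}
_total = sum(SWISSPROT_FREQUENCIES.values())
SWISSPROT_FREQUENCIES = {k: v / _total for k, v in SWISSPROT_FREQUENCIES.items()}
del _total
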