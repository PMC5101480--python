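"""Reference tables: van der Waals radii and maximum accessible surface areas.

The max-ASA values are the theoretical Gly-X-Gly maxima of Tien et al. (2013),
PLoS ONE 8:e80635, the table most commonly used for relative-accessibility
cutoffs.  Both tables are plain dicts so callers can pass alternatives.
"""

from __future__ import annotations

# Element -> van der Waals radius (A).  Bondi radii for the elements that occur
# in protein heavy atoms; unknown elements fall back to carbon.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
}
VDW_DEFAULT = 1.70


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper().strip(), VDW_DEFAULT)


# Residue type (three-letter) -> theoretical maximum ASA (A^2).
MAX_ASA_TIEN_THEORETICAL: dict[str, float] = {
    "ALA": 129.0,
    "ARG": 274.0,
    "ASN": 195.0,
    "ASP": 193.0,
    "CYS": 167.0,
    "GLN": 225.0,
    "GLU": 223.0,
    "GLY": 104.0,
    "HIS": 224.0,
    "ILE": 197.0,
    "LEU": 201.0,
    "LYS": 236.0,
    "MET": 224.0,
    "PHE": 240.0,
    "PRO": 159.0,
    "SER": 155.0,
    "THR": 172.0,
    "TRP": 285.0,
    "TYR": 263.0,
    "VAL": 174.0,
}

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

# Backbone heavy-atom names (used when picking a side-chain representative).
BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}
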