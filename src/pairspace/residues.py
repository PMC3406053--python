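"""Amino-acid codes, functional atoms and secondary-structure categories.

The "functional atom" of a residue type is the side-chain atom (or pair of
atoms) taken to represent its chemically active tip; inter-residue distances
are measured between functional atoms.  Glycine, having no side chain, uses
its own Cα.
"""

from __future__ import annotations

# 20 standard types, alphabetical by 3-letter code.  This ordering defines the
# AA1/AA2 axes of the pair-count tensor.
AA3: tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

AA3_TO_1: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3: dict[str, str] = {v: k for k, v in AA3_TO_1.items()}

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AA3)}

# Functional atoms per residue type (PDB atom nomenclature), 1 or 2 per type.
FUNCTIONAL_ATOMS: dict[str, tuple[str, ...]] = {
    "ALA": ("CB",),
    "ARG": ("NH1", "NH2"),
    "ASN": ("ND2", "OD1"),
    "ASP": ("OD1", "OD2"),
    "CYS": ("SG",),
    "GLN": ("NE2", "OE1"),
    "GLU": ("OE1", "OE2"),
    "GLY": ("CA",),
    "HIS": ("ND1",),
    "ILE": ("CG1", "CG2"),
    "LEU": ("CG",),
    "LYS": ("NZ",),
    "MET": ("SD",),
    "PHE": ("CZ",),
    "PRO": ("CG",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TRP": ("CE2",),
    "TYR": ("OH",),
    "VAL": ("CG1", "CG2"),
}

# The four secondary-structure categories used for the SS1/SS2 axes.
SS_CATEGORIES: tuple[str, ...] = ("helix", "strand", "turn", "coil")
SS_INDEX: dict[str, int] = {c: i for i, c in enumerate(SS_CATEGORIES)}

# Mapping from DSSP/HSSP single-letter codes to the four categories.  H maps
# to helix, E to strand, T to turn; every other code (3-10 helix G, pi helix I,
# bridge B, bend S, blank) falls into coil.  The four categories do not
# uniquely partition the DSSP alphabet, so the map is a configurable table.
DEFAULT_SS_MAP: dict[str, str] = {
    "H": "helix",
    "E": "strand",
    "T": "turn",
}


def map_ss_code(code: str, ss_map: dict[str, str] | None = None) -> str:
    """Map a raw secondary-structure code to one of the four categories."""
    table = DEFAULT_SS_MAP if ss_map is None else ss_map
    return table.get(code.strip().upper() if code else "", "coil")
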