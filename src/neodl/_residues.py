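"""Residue-level constants shared across the featurization code.

Only the 20 standard amino acids are supported; descriptor scales are not
defined for ambiguity codes (X, B, Z, U), so those are rejected at parse time.
"""

from __future__ import annotations

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(STANDARD_AA)

PEPTIDE_LENGTH = 9

# Average residue (monomer) masses in Da; a free peptide adds one water.
WATER_MASS = 18.0153
RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

# Eisenberg consensus hydrophobicity, used for the helical hydrophobic moment.
EISENBERG = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
    "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
    "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
    "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
}

# Per-residue free energies of transfer (kcal/mol) for the Boman
# protein-binding index; the index is the sequence mean.
BOMAN = {
    "L": -4.92, "I": -4.92, "V": -4.04, "F": -2.98, "M": -2.35,
    "W": -2.33, "A": -1.81, "C": -1.28, "G": -0.94, "Y": 0.14,
    "P": 0.00, "T": 2.57, "S": 3.40, "H": 4.66, "Q": 5.54,
    "K": 5.55, "N": 6.64, "E": 6.81, "D": 8.72, "R": 14.92,
}

CLASS_NAMES = (
    "Tiny", "Small", "Aliphatic", "Aromatic", "NonPolar",
    "Polar", "Charged", "Basic", "Acidic",
)


def validate_sequence(seq: str, *, length: int | None = None) -> str:
    """Check residues are standard; return the sequence uppercased."""
    s = seq.upper()
    bad = set(s) - AA_SET
    if bad:
        raise ValueError(
            f"non-standard residue(s) {sorted(bad)} in sequence {seq!r}; "
            "only the 20 standard amino acids are supported"
        )
    if length is not None and len(s) != length:
        raise ValueError(f"expected a {length}-mer, got {len(s)} residues: {seq!r}")
    return s
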