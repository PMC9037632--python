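"""Nucleotide geometry templates.

Base heavy atoms are given in the standard base reference frame that is
shared by the common base-pair analysis tools: the frame origin sits in the
pair plane, +x points toward the major-groove edge, +y toward the strand-I
sugar, +z along the 5'->3' helix direction for strand I.  In this frame a
Watson-Crick partner is generated simply by negating y and z of its own
template ("flipping" the base).

The sugar/phosphate stub (``SUGAR_LOCAL``) was designed once for this
package: a C3'-endo ribose with an anti glycosidic torsion and A-form
backbone torsions, refined by least squares against standard bond
lengths/angles, the inter-residue O3'-P linkage of a 32 deg / 2.81 A helix,
and the package's calibrated A-form major-groove anchor.  It is expressed in
a local frame attached to each base (origin C1', x along N->C1', z = base
normal) so a single stub serves all four bases.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "BASE_ATOMS",
    "RING_ATOMS",
    "GLYCOSIDIC_N",
    "CHI_REF_ATOM",
    "PURINES",
    "PYRIMIDINES",
    "BACKBONE_ORDER",
    "SUGAR_LOCAL",
    "nucleotide_template",
    "base_template",
    "residue_atom_order",
    "element_of",
]

PURINES = frozenset({"A", "G"})
PYRIMIDINES = frozenset({"C", "U"})

#: Standard-reference-frame coordinates of the base heavy atoms (Angstrom).
BASE_ATOMS: dict[str, dict[str, tuple[float, float, float]]] = {
    "A": {
        "C1'": (-2.479, 5.346, 0.000),
        "N9": (-1.291, 4.498, 0.000),
        "C8": (0.024, 4.897, 0.000),
        "N7": (0.877, 3.902, 0.000),
        "C5": (0.071, 2.771, 0.000),
        "C6": (0.369, 1.398, 0.000),
        "N6": (1.611, 0.909, 0.000),
        "N1": (-0.668, 0.532, 0.000),
        "C2": (-1.912, 1.023, 0.000),
        "N3": (-2.320, 2.290, 0.000),
        "C4": (-1.267, 3.124, 0.000),
    },
    "G": {
        "C1'": (-2.477, 5.399, 0.000),
        "N9": (-1.289, 4.551, 0.000),
        "C8": (0.023, 4.962, 0.000),
        "N7": (0.870, 3.969, 0.000),
        "C5": (0.071, 2.833, 0.000),
        "C6": (0.424, 1.460, 0.000),
        "O6": (1.554, 0.955, 0.000),
        "N1": (-0.700, 0.641, 0.000),
        "C2": (-1.999, 1.087, 0.000),
        "N2": (-2.949, 0.139, -0.001),
        "N3": (-2.342, 2.364, 0.001),
        "C4": (-1.265, 3.177, 0.000),
    },
    "C": {
        "C1'": (-2.477, 5.402, 0.000),
        "N1": (-1.285, 4.542, 0.000),
        "C2": (-1.472, 3.158, 0.000),
        "O2": (-2.628, 2.709, 0.001),
        "N3": (-0.391, 2.344, 0.000),
        "C4": (0.837, 2.868, 0.000),
        "N4": (1.875, 2.027, 0.001),
        "C5": (1.056, 4.275, 0.000),
        "C6": (-0.023, 5.068, 0.000),
    },
    "U": {
        "C1'": (-2.481, 5.354, 0.000),
        "N1": (-1.284, 4.500, 0.000),
        "C2": (-1.462, 3.131, 0.000),
        "O2": (-2.563, 2.608, 0.000),
        "N3": (-0.302, 2.397, 0.000),
        "C4": (0.989, 2.884, 0.000),
        "O4": (1.935, 2.094, -0.001),
        "C5": (1.089, 4.311, 0.000),
        "C6": (-0.024, 5.053, 0.000),
    },
}

#: Ring atoms used for rigid base-frame fitting (exocyclic substituents are
#: deliberately excluded for robustness to propeller/buckle distortion).
RING_ATOMS: dict[str, tuple[str, ...]] = {
    "A": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "G": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "C": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "U": ("N1", "C2", "N3", "C4", "C5", "C6"),
}

GLYCOSIDIC_N = {"A": "N9", "G": "N9", "C": "N1", "U": "N1"}
#: Fourth atom of the chi torsion O4'-C1'-N1-C2 (pyrimidines) / O4'-C1'-N9-C4.
CHI_REF_ATOM = {"A": "C4", "G": "C4", "C": "C2", "U": "C2"}

BACKBONE_ORDER = ("P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "O2'", "C1'")

#: Sugar/backbone stub coordinates in the local C1'-anchored frame.
SUGAR_LOCAL: dict[str, tuple[float, float, float]] = {
    "O4'": (0.1897, -1.3051, 0.5081),
    "C2'": (1.0901, 0.9089, 0.5973),
    "C3'": (1.8203, -0.0797, 1.5222),
    "C4'": (1.5122, -1.4849, 1.0514),
    "C5'": (1.4918, -2.5251, 2.1443),
    "O5'": (0.3754, -3.4046, 1.9221),
    "O3'": (3.1428, 0.0608, 2.0674),
    "O2'": (1.9407, 1.3380, -0.4462),
    "P": (0.4698, -4.5151, 0.7704),
}


def _local_frame(base: str) -> tuple[np.ndarray, np.ndarray]:
    atoms = BASE_ATOMS[base]
    c1 = np.array(atoms["C1'"])
    n = np.array(atoms[GLYCOSIDIC_N[base]])
    ex = (c1 - n) / np.linalg.norm(c1 - n)
    ez = np.array([0.0, 0.0, 1.0])
    ey = np.cross(ez, ex)
    ey /= np.linalg.norm(ey)
    R = np.column_stack([ex, ey, np.cross(ex, ey)])
    return c1, R


def base_template(base: str) -> dict[str, np.ndarray]:
    """Base heavy atoms (incl. C1') in the standard base frame."""
    if base not in BASE_ATOMS:
        raise KeyError(f"unknown base {base!r}")
    return {k: np.array(v) for k, v in BASE_ATOMS[base].items()}


def nucleotide_template(base: str) -> dict[str, np.ndarray]:
    """Full heavy-atom nucleotide template in the standard base frame."""
    tpl = base_template(base)
    if SUGAR_LOCAL:
        c1, R = _local_frame(base)
        for name, loc in SUGAR_LOCAL.items():
            tpl[name] = c1 + R @ np.asarray(loc, dtype=float)
    return tpl


def residue_atom_order(base: str) -> list[str]:
    """Canonical atom ordering used for generated residues."""
    tpl = nucleotide_template(base)
    order = [a for a in BACKBONE_ORDER if a in tpl]
    order += [a for a in BASE_ATOMS[base] if a != "C1'"]
    return order


def element_of(atom_name: str) -> str:
    """Element symbol from a PDB heavy-atom name (nucleic acids)."""
    name = atom_name.strip()
    if name[:1] in ("'", '"'):
        name = name[1:]
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")
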