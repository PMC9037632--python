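"""Base reference frames, base-pair frames and the six step parameters.

A base frame is the least-squares rigid superposition of the standard base
template onto the observed ring atoms; a pair frame is the half-rotation
average of the strand-I frame and the (y,z-negated) strand-II frame; and the
six rigid-body step parameters (tilt, roll, twist / shift, slide, rise)
relate consecutive pair frames through the mid-step-frame decomposition:
the bend angle between the two z-axes is symmetrically removed about the
hinge axis, twist is measured between the unbent x-axes, the bend is split
into roll/tilt by its phase relative to the mid-frame y-axis, and the origin
displacement is expressed in the mid-frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import (
    angle_between,
    dihedral,
    kabsch,
    rotation_about_axis,
    signed_angle,
    unit,
)
from .io import Conformation, StructureError
from .templates import CHI_REF_ATOM, GLYCOSIDIC_N, RING_ATOMS, base_template

__all__ = [
    "Frame",
    "StepParameters",
    "GlycosidicState",
    "PairingMap",
    "fit_base_frame",
    "pair_frame",
    "step_parameters",
    "chi_torsion",
    "infer_pairing",
    "duplex_pair_frames",
    "step_table",
]

#: Pair types treated as Watson-Crick (G.U wobble included).
WC_PAIRS = frozenset({"AU", "UA", "GC", "CG", "GU", "UG"})

_FLIP = np.diag([1.0, -1.0, -1.0])


@dataclass(frozen=True)
class Frame:
    """Orthonormal right-handed frame: columns of ``rotation`` are x, y, z."""

    origin: np.ndarray
    rotation: np.ndarray
    fit_rmsd: float = 0.0

    def __post_init__(self):
        R = self.rotation
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation is improper (det < 0)")

    @property
    def x(self) -> np.ndarray:
        return self.rotation[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.rotation[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.rotation[:, 2]


@dataclass(frozen=True)
class StepParameters:
    tilt: float
    roll: float
    twist: float
    shift: float
    slide: float
    rise: float

    def as_tuple(self) -> tuple[float, ...]:
        return (self.tilt, self.roll, self.twist, self.shift, self.slide, self.rise)


@dataclass(frozen=True)
class GlycosidicState:
    chi: float
    classification: str  # anti | syn | intermediate


@dataclass(frozen=True)
class PairingMap:
    """In-register antiparallel pairing: strand-I residue i with strand-II N+1-i."""

    pairs: tuple[tuple[int, int, str], ...]  # (res_i, res_j, "WC" | "mismatch")
    chain_i: str
    chain_ii: str

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def pair_type(self, i: int) -> str:
        return self.pairs[i - 1][2]

    @property
    def mismatch_indices(self) -> tuple[int, ...]:
        return tuple(i for i, _, t in self.pairs if t == "mismatch")

    def internal_loops(self) -> list[tuple[int, ...]]:
        """Contiguous mismatch runs flanked by WC pairs on both sides."""
        loops, run = [], []
        for i, _, t in self.pairs:
            if t == "mismatch":
                run.append(i)
            else:
                if run and run[0] > 1:
                    loops.append(tuple(run))
                run = []
        # a run touching the 3' terminus is not an internal loop
        return loops


def fit_base_frame(residue_atoms: dict[str, np.ndarray], base: str) -> Frame:
    """Fit the standard base frame to a residue's observed ring atoms."""
    tpl = base_template(base)
    ring = RING_ATOMS[base]
    missing = [a for a in ring if a not in residue_atoms]
    if missing:
        raise StructureError(f"residue lacks ring atoms {missing}")
    P = np.array([tpl[a] for a in ring])
    Q = np.array([residue_atoms[a] for a in ring])
    R, t, rmsd = kabsch(P, Q)
    return Frame(origin=t, rotation=R, fit_rmsd=rmsd)


def _half_rotation(Ra: np.ndarray, Rb: np.ndarray) -> np.ndarray:
    """Rotation halfway from Ra to Rb (geodesic midpoint on SO(3))."""
    Rel = Rb @ Ra.T
    c = np.clip((np.trace(Rel) - 1.0) / 2.0, -1.0, 1.0)
    ang = np.degrees(np.arccos(c))
    if ang < 1e-10:
        return Ra
    axis = np.array(
        [Rel[2, 1] - Rel[1, 2], Rel[0, 2] - Rel[2, 0], Rel[1, 0] - Rel[0, 1]]
    )
    if np.linalg.norm(axis) < 1e-12:  # 180 deg: midpoint ill-defined; pick any
        w, v = np.linalg.eigh(Rel + Rel.T)
        axis = v[:, -1]
    return rotation_about_axis(axis, ang / 2.0) @ Ra


def pair_frame(f1: Frame, f2: Frame) -> Frame:
    """Base-pair frame: flip the strand-II frame, average by half-rotation."""
    R2f = f2.rotation @ _FLIP
    Rm = _half_rotation(f1.rotation, R2f)
    return Frame(origin=0.5 * (f1.origin + f2.origin), rotation=Rm)


def is_flipped(f1: Frame, f2: Frame) -> bool:
    """True when the (flipped) partner z-axis opposes strand I's by > 90 deg."""
    return float(np.dot(f1.z, (f2.rotation @ _FLIP)[:, 2])) < 0.0


def step_parameters(p1: Frame, p2: Frame) -> StepParameters:
    """Six step parameters relating consecutive pair frames (mid-frame)."""
    R1, R2 = p1.rotation, p2.rotation
    z1, z2 = R1[:, 2], R2[:, 2]
    cz = float(np.dot(z1, z2))
    if cz < 0.0:
        raise StructureError("degenerate step: pair z-axes antiparallel")
    gamma = angle_between(z1, z2)
    if gamma > 1e-10:
        hinge = unit(np.cross(z1, z2))
        R1p = rotation_about_axis(hinge, +gamma / 2.0) @ R1
        R2p = rotation_about_axis(hinge, -gamma / 2.0) @ R2
    else:
        hinge = None
        R1p, R2p = R1, R2
    zm = unit(R1p[:, 2] + R2p[:, 2])
    twist = signed_angle(R1p[:, 0], R2p[:, 0], zm)
    xm = unit(R1p[:, 0] + R2p[:, 0])
    xm = unit(xm - np.dot(xm, zm) * zm)
    ym = np.cross(zm, xm)
    Rm = np.column_stack([xm, ym, zm])
    if hinge is not None:
        phi = signed_angle(hinge, ym, zm)
        roll = gamma * np.cos(np.radians(phi))
        tilt = gamma * np.sin(np.radians(phi))
    else:
        roll = tilt = 0.0
    disp = Rm.T @ (p2.origin - p1.origin)
    return StepParameters(
        tilt=float(tilt),
        roll=float(roll),
        twist=float(twist),
        shift=float(disp[0]),
        slide=float(disp[1]),
        rise=float(disp[2]),
    )


def chi_torsion(residue_atoms: dict[str, np.ndarray], base: str) -> GlycosidicState:
    """Glycosidic torsion O4'-C1'-N1/N9-C2/C4 and its anti/syn window."""
    n = GLYCOSIDIC_N[base]
    ref = CHI_REF_ATOM[base]
    needed = ["O4'", "C1'", n, ref]
    missing = [a for a in needed if a not in residue_atoms]
    if missing:
        raise StructureError(f"chi torsion needs atoms {missing}")
    chi = dihedral(*(residue_atoms[a] for a in needed))
    if -180.0 < chi < -90.0 or 150.0 < chi <= 180.0:
        cls = "anti"
    elif 0.0 < chi < 90.0:
        cls = "syn"
    else:
        cls = "intermediate"
    return GlycosidicState(chi=float(chi), classification=cls)


def infer_pairing(c: Conformation) -> PairingMap:
    """Pair strand-I residue i with strand-II residue N+1-i (in register)."""
    ch1, ch2 = c.chain_ids
    s1, s2 = c.sequence(ch1), c.sequence(ch2)
    if len(s1) != len(s2):
        raise StructureError("unequal strand lengths")
    n = len(s1)
    pairs = []
    for i in range(1, n + 1):
        j = n + 1 - i
        kind = "WC" if s1[i - 1] + s2[j - 1] in WC_PAIRS else "mismatch"
        pairs.append((i, j, kind))
    return PairingMap(pairs=tuple(pairs), chain_i=ch1, chain_ii=ch2)


def duplex_pair_frames(
    c: Conformation, pm: PairingMap | None = None
) -> tuple[list[Frame], list[bool]]:
    """Pair frames for every base pair, plus per-pair 'flipped' flags."""
    if pm is None:
        pm = infer_pairing(c)
    frames, flipped = [], []
    for i, j, _ in pm.pairs:
        f1 = fit_base_frame(c.residue(pm.chain_i, i), c.residue_name(pm.chain_i, i))
        f2 = fit_base_frame(c.residue(pm.chain_ii, j), c.residue_name(pm.chain_ii, j))
        frames.append(pair_frame(f1, f2))
        flipped.append(is_flipped(f1, f2))
    return frames, flipped


def step_table(c: Conformation, pm: PairingMap | None = None):
    """Per-step parameter table (pandas DataFrame; flipped pairs excluded)."""
    import pandas as pd

    frames, flipped = duplex_pair_frames(c, pm)
    rows = []
    for s in range(len(frames) - 1):
        if flipped[s] or flipped[s + 1]:
            continue
        p = step_parameters(frames[s], frames[s + 1])
        rows.append(
            {
                "step_index": s + 1,
                "tilt": p.tilt,
                "roll": p.roll,
                "twist": p.twist,
                "shift": p.shift,
                "slide": p.slide,
                "rise": p.rise,
            }
        )
    return pd.DataFrame(rows)
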