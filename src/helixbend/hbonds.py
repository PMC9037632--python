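"""Hydrogen-bond detection and non-canonical pair-state classification.

All criteria are heavy-atom only (generated structures carry no hydrogens):
a donor-acceptor contact counts as a hydrogen bond when the heavy-atom
distance is at most 3.5 A and every heavy-atom neighbor of the donor makes
an antecedent-donor-acceptor angle of at least 110 deg (a proxy for the
donor proton pointing at the acceptor).  Each atom serves in at most one
bond; matching is greedy by ascending distance with lexical tie-breaks.

``max_simultaneous_hbonds`` performs an exhaustive planar rigid-body grid
search over relative base placements constrained to duplex embedding
(C1'-C1' distance 10.4 +/- 0.4 A, both glycosidic vectors in the anti
arrangement, bases coplanar and antiparallel) and reports the maximum
number of simultaneous non-clashing bonds.  The same search supplies the
canonical mismatch-pair geometries used by the synthetic-structure builder.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .geometry import angle_between
from .io import Conformation, StructureError
from .templates import GLYCOSIDIC_N, base_template, nucleotide_template

__all__ = [
    "HBondCriteria",
    "HBond",
    "PairHBondState",
    "ClosingPairStatus",
    "LoopState",
    "detect_hbonds",
    "classify_pair_state",
    "closing_pair_status",
    "max_simultaneous_hbonds",
    "pair_placement",
    "loop_states",
]

#: Base-edge donors with their bonded heavy-atom antecedents.
BASE_DONORS: dict[str, dict[str, tuple[str, ...]]] = {
    "A": {"N6": ("C6",)},
    "G": {"N1": ("C2", "C6"), "N2": ("C2",)},
    "C": {"N4": ("C4",)},
    "U": {"N3": ("C2", "C4")},
}
#: Base-edge acceptors.
BASE_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "A": ("N1", "N3", "N7"),
    "G": ("O6", "N3", "N7"),
    "C": ("O2", "N3"),
    "U": ("O2", "O4"),
}
#: The 2'-hydroxyl acts as both donor and acceptor.
SUGAR_DONORS = {"O2'": ("C2'",)}
SUGAR_ACCEPTORS = ("O2'",)

#: Canonical Watson-Crick bond counts (closing-pair distortion reference).
CANONICAL_COUNTS = {"AU": 2, "UA": 2, "GC": 3, "CG": 3, "GU": 2, "UG": 2}

# search constants (duplex-embedding constraints; see docs/methods.md)
# The C1'-C1' window brackets the Watson-Crick span (10.4 A) but extends
# down to the narrowed span of pyrimidine-pyrimidine pairs (~9.2 A) and up
# to slightly widened purine-purine placements -- both occur in repeat
# duplexes and are required for the two-bond UU/CU states to be embeddable.
_C1C1_RANGE = (8.8, 11.2)
_LAMBDA_RANGE = (20.0, 80.0)  # glycosidic-vector angle window ("anti arrangement")
_THETA_STEP = 5.0  # deg, in-plane rotation grid
_ARC_STEP = 0.2  # A, translation grid along/across the C1'-C1' annulus
_CLASH = 2.5  # A, non-bonded heavy-atom floor


@dataclass(frozen=True)
class HBondCriteria:
    max_distance: float = 3.5
    min_donor_angle: float = 110.0


DEFAULT_CRITERIA = HBondCriteria()


@dataclass(frozen=True)
class HBond:
    donor_res: int  # 0 = first residue argument, 1 = second
    donor_atom: str
    acceptor_res: int
    acceptor_atom: str
    distance: float


@dataclass(frozen=True)
class PairHBondState:
    pair_id: tuple[int, int]
    bonds: tuple[HBond, ...]
    count: int


@dataclass(frozen=True)
class ClosingPairStatus:
    pair_type: str
    count: int
    distorted: bool


@dataclass(frozen=True)
class LoopState:
    loop_id: int
    pair_states: tuple[PairHBondState, ...]
    closing: tuple[ClosingPairStatus, ...]


def _donor_map(base: str, atoms: dict[str, np.ndarray], include_sugar: bool = True):
    donors = dict(BASE_DONORS[base])
    if include_sugar:
        donors = {**donors, **SUGAR_DONORS}
    return {d: ants for d, ants in donors.items() if d in atoms}


def _acceptors(base: str, atoms: dict[str, np.ndarray], include_sugar: bool = True):
    acc = list(BASE_ACCEPTORS[base])
    if include_sugar:
        acc += list(SUGAR_ACCEPTORS)
    return [a for a in acc if a in atoms]


def _candidate_bonds(res1, base1, res2, base2, criteria, include_sugar=True):
    cands = []
    for (da, db, di, ai) in (
        ((res1, base1), (res2, base2), 0, 1),
        ((res2, base2), (res1, base1), 1, 0),
    ):
        datoms, dbase = da
        aatoms, abase = db
        for donor, ants in _donor_map(dbase, datoms, include_sugar).items():
            for acc in _acceptors(abase, aatoms, include_sugar):
                d = float(np.linalg.norm(datoms[donor] - aatoms[acc]))
                if d > criteria.max_distance:
                    continue
                ok = True
                for ant in ants:
                    if ant not in datoms:
                        continue
                    ang = angle_between(
                        datoms[ant] - datoms[donor], aatoms[acc] - datoms[donor]
                    )
                    if ang < criteria.min_donor_angle:
                        ok = False
                        break
                if ok:
                    cands.append(HBond(di, donor, ai, acc, d))
    return cands


def _greedy_match(cands: list[HBond]) -> list[HBond]:
    cands = sorted(cands, key=lambda b: (b.distance, b.donor_atom, b.acceptor_atom))
    used: set[tuple[int, str]] = set()
    out = []
    for b in cands:
        dkey, akey = (b.donor_res, b.donor_atom), (b.acceptor_res, b.acceptor_atom)
        if dkey in used or akey in used:
            continue
        used.add(dkey)
        used.add(akey)
        out.append(b)
    return out


def detect_hbonds(
    res1: dict[str, np.ndarray],
    base1: str,
    res2: dict[str, np.ndarray],
    base2: str,
    criteria: HBondCriteria = DEFAULT_CRITERIA,
) -> list[HBond]:
    """Hydrogen bonds between two residues (greedy one-bond-per-atom)."""
    return _greedy_match(_candidate_bonds(res1, base1, res2, base2, criteria))


def classify_pair_state(
    c: Conformation,
    pair: tuple[int, int],
    criteria: HBondCriteria = DEFAULT_CRITERIA,
) -> PairHBondState:
    """Hydrogen-bond state (0/1/2/... bonds) of one base pair."""
    ch1, ch2 = c.chain_ids
    i, j = pair
    b1, b2 = c.residue_name(ch1, i), c.residue_name(ch2, j)
    bonds = detect_hbonds(c.residue(ch1, i), b1, c.residue(ch2, j), b2, criteria)
    cap = max_simultaneous_hbonds(b1 + b2)
    bonds = tuple(bonds[:cap])
    return PairHBondState(pair_id=(i, j), bonds=bonds, count=len(bonds))


def closing_pair_status(
    c: Conformation,
    pair: tuple[int, int],
    criteria: HBondCriteria = DEFAULT_CRITERIA,
) -> ClosingPairStatus:
    """Whether a Watson-Crick closing pair has lost hydrogen bonds."""
    ch1, ch2 = c.chain_ids
    i, j = pair
    ptype = c.residue_name(ch1, i) + c.residue_name(ch2, j)
    if ptype not in CANONICAL_COUNTS:
        raise StructureError(f"closing_pair_status called on mismatch pair {ptype}")
    bonds = detect_hbonds(
        c.residue(ch1, i), ptype[0], c.residue(ch2, j), ptype[1], criteria
    )
    count = min(len(bonds), CANONICAL_COUNTS[ptype])
    return ClosingPairStatus(
        pair_type=ptype, count=count, distorted=count < CANONICAL_COUNTS[ptype]
    )


# ---------------------------------------------------------------------------
# duplex-constrained planar placement search
# ---------------------------------------------------------------------------

_FLIP = np.diag([1.0, -1.0, -1.0])


def _search_atoms(base: str):
    """Base heavy atoms + C1' (sugar excluded: its conformation is unresolved
    at the level of a planar base-placement search)."""
    tpl = base_template(base)
    names = list(tpl)
    coords = np.array([tpl[n] for n in names])
    return names, coords


def _placement_scan(pair_type: str):
    """Enumerate anti/anti coplanar placements of base B relative to base A.

    Yields per-placement greedy bond counts together with the rigid transform
    (theta, translation) applied to the flipped base-B template.
    """
    if len(pair_type) != 2 or any(b not in "AUGC" for b in pair_type):
        raise ValueError(f"unknown pair type {pair_type!r}")
    base_a, base_b = pair_type[0], pair_type[1]
    names_a, xa = _search_atoms(base_a)
    names_b, xb0 = _search_atoms(base_b)
    atoms_a = dict(zip(names_a, xa))
    c1a = atoms_a["C1'"]
    na = atoms_a[GLYCOSIDIC_N[base_a]]
    ga = na - c1a  # glycosidic vector of base A

    lam_lo, lam_hi = np.radians(_LAMBDA_RANGE)
    results = []
    thetas = np.arange(0.0, 360.0, _THETA_STEP)
    radii = np.arange(_C1C1_RANGE[0], _C1C1_RANGE[1] + 1e-9, _ARC_STEP)
    ga_az = np.arctan2(ga[1], ga[0])
    for theta in thetas:
        t = np.radians(theta)
        R = np.array(
            [[np.cos(t), -np.sin(t), 0], [np.sin(t), np.cos(t), 0], [0, 0, 1.0]]
        )
        xb_rot = (R @ (_FLIP @ xb0.T)).T
        atoms_b_rot = dict(zip(names_b, xb_rot))
        c1b0 = atoms_b_rot["C1'"]
        gb = atoms_b_rot[GLYCOSIDIC_N[base_b]] - c1b0
        gb_az = np.arctan2(gb[1], gb[0])
        for r in radii:
            alphas = np.arange(0.0, 2 * np.pi, _ARC_STEP / r)
            # lambda_A: angle between g_A and the C1'A -> C1'B direction
            dev_a = np.abs((alphas - ga_az + np.pi) % (2 * np.pi) - np.pi)
            ok_a = (dev_a >= lam_lo) & (dev_a <= lam_hi)
            # lambda_B: angle between g_B and the C1'B -> C1'A direction
            dev_b = np.abs((alphas + np.pi - gb_az + np.pi) % (2 * np.pi) - np.pi)
            ok = ok_a & (dev_b >= lam_lo) & (dev_b <= lam_hi)
            for alpha in alphas[ok]:
                shift = c1a + r * np.array([np.cos(alpha), np.sin(alpha), 0.0]) - c1b0
                xb = xb_rot + shift
                dmat = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=2)
                if dmat.min() < _CLASH:
                    continue
                if dmat.min() > DEFAULT_CRITERIA.max_distance:
                    bonds = []
                else:
                    atoms_b = dict(zip(names_b, xb))
                    bonds = _greedy_match(
                        _candidate_bonds(
                            atoms_a, base_a, atoms_b, base_b,
                            DEFAULT_CRITERIA, include_sugar=False,
                        )
                    )
                results.append(
                    (
                        len(bonds),
                        float(sum(b.distance for b in bonds)),
                        float(dmat.min()),
                        float(theta),
                        np.array(shift),
                    )
                )
    return results


@lru_cache(maxsize=None)
def _scan_cached(pair_type: str):
    return _placement_scan(pair_type)


def max_simultaneous_hbonds(pair_type: str, orientation: str = "anti") -> int:
    """Maximum simultaneous hydrogen bonds for a pair type in a duplex.

    Exhaustive coplanar rigid-body grid search under the duplex-embedding
    constraints; ``orientation`` other than anti is out of scope.
    """
    if orientation != "anti":
        raise ValueError("only the anti/anti orientation search is supported")
    return max(r[0] for r in _scan_cached(pair_type))


@lru_cache(maxsize=None)
def pair_placement(pair_type: str, n_bonds: int) -> tuple[float, np.ndarray]:
    """Rigid transform (theta_deg, translation) realizing exactly ``n_bonds``.

    The transform applies to the flipped base-B template; among all grid
    placements with the requested greedy bond count the one closest to the
    Watson-Crick partner position is chosen (keeps duplex embedding tidy).
    """
    results = _scan_cached(pair_type)
    best = None
    c1b_wc = _FLIP @ np.asarray(base_template(pair_type[1])["C1'"])
    for count, dist_sum, dmin, theta, shift in results:
        if count != n_bonds:
            continue
        c1b = _FLIP @ np.asarray(base_template(pair_type[1])["C1'"])
        R = _rotz(theta)
        c1b_here = R @ c1b + shift
        dev = float(np.linalg.norm(c1b_here - c1b_wc)) + 0.02 * abs(
            (theta + 180.0) % 360.0 - 180.0
        )
        if n_bonds == 0:
            # prefer placements that are robustly bond-free
            dev += max(0.0, 4.2 - dmin) * 5.0
        key = (dev, dist_sum, theta)
        if best is None or key < best[0]:
            best = (key, theta, shift)
    if best is None:
        raise ValueError(
            f"{pair_type}: {n_bonds} simultaneous bonds not achievable under "
            "the duplex-embedding constraints"
        )
    return best[1], best[2]


def _rotz(theta_deg: float) -> np.ndarray:
    t = np.radians(theta_deg)
    return np.array(
        [[np.cos(t), -np.sin(t), 0], [np.sin(t), np.cos(t), 0], [0, 0, 1.0]]
    )


def placement_transform(pair_type: str, n_bonds: int) -> tuple[np.ndarray, np.ndarray]:
    """(R, t) such that base-B template atoms map as ``R @ x + t`` (flip included)."""
    theta, shift = pair_placement(pair_type, n_bonds)
    return _rotz(theta) @ _FLIP, shift


# ---------------------------------------------------------------------------
# loop pooling
# ---------------------------------------------------------------------------


def loop_states(
    c: Conformation,
    pm,
    criteria: HBondCriteria = DEFAULT_CRITERIA,
) -> list[LoopState]:
    """Classify every retained internal loop of a construct.

    All internal loops are pooled except the first and the last; when a
    construct has exactly two loops, both are retained.
    """
    loops = pm.internal_loops()
    if len(loops) > 2:
        loops = loops[1:-1]
    out = []
    n = pm.n_pairs
    for k, loop in enumerate(loops, start=1):
        states = tuple(
            classify_pair_state(c, (i, n + 1 - i), criteria) for i in loop
        )
        closing = []
        for i in (loop[0] - 1, loop[-1] + 1):
            closing.append(closing_pair_status(c, (i, n + 1 - i), criteria))
        out.append(LoopState(loop_id=k, pair_states=states, closing=tuple(closing)))
    return out
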