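"""Synthetic duplex generator: ideal A-form helices and perturbed ensembles.

This module stands in for MD trajectories: it builds ideal A-form duplexes
for arbitrary sequences (including the CAG/CUG/CCUG/AUUCU repeat constructs
and their fully Watson-Crick controls) and derives ensembles with known
ground truth — smooth arc bends, single-hinge kinks, twist/rise
overextension, per-step groove modulation and isotropic coordinate noise —
so that every downstream measurement can be validated by parameter
recovery.

Geometry convention: base-pair frames of the ideal build lie exactly on the
global helix axis, related by the fiber (twist, rise) screw; the A-form
character (deep-major-groove phosphate positions, anti glycosidic torsions)
is carried by the frozen nucleotide template.  Mismatched positions embed
the canonical pair geometry found by the duplex-constrained hydrogen-bond
placement search.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .frames import duplex_pair_frames, infer_pairing
from .geometry import rotation_about_axis, unit
from .hbonds import max_simultaneous_hbonds, pair_placement, placement_transform
from .io import Conformation, Ensemble
from .templates import element_of, nucleotide_template, residue_atom_order

__all__ = [
    "FiberParameters",
    "PerturbationSpec",
    "MismatchGeometrySpec",
    "COMPLEMENT",
    "TABLE_CONSTRUCTS",
    "build_ideal_duplex",
    "build_duplex",
    "build_repeat_construct",
    "build_mismatch_pair",
    "apply_bend",
    "apply_kink",
    "apply_overextension",
    "apply_groove_modulation",
    "generate_ensemble",
]

COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: The twelve repeat constructs (short name -> full strand sequence).
TABLE_CONSTRUCTS = {
    f"{n}x{rep}": pre + rep * n + post
    for rep, pre, post, sizes in (
        ("AUUCU", "C", "AUC", (2, 4, 10)),
        ("CCUG", "", "", (4, 10, 15)),
        ("CAG", "GG", "CC", (2, 10, 20)),
        ("CUG", "GG", "CC", (2, 10, 20)),
    )
    for n in sizes
}

_FLIP = np.diag([1.0, -1.0, -1.0])


@dataclass(frozen=True)
class FiberParameters:
    """Helical repeat of the generated duplex.

    Defaults reproduce the standard A-form anchors used throughout the
    analysis modules (32 deg twist, 2.81 A rise).  ``x_displacement`` and
    ``inclination`` displace/tilt the base pair relative to its frame and
    default to zero so that ideal builds recover pure (twist, rise) steps.
    """

    twist: float = 32.0
    rise: float = 2.81
    x_displacement: float = 0.0
    inclination: float = 0.0

    def __post_init__(self):
        if not 0.0 < self.twist < 60.0:
            raise ValueError("twist must lie in (0, 60) degrees")
        if not 2.0 < self.rise < 4.0:
            raise ValueError("rise must lie in (2, 4) Angstrom")


DEFAULT_FIBER = FiberParameters()


@dataclass(frozen=True)
class PerturbationSpec:
    """Ground-truth perturbations applied per model of a generated ensemble."""

    bend_total: float = 0.0
    bend_min: float = 0.0
    kink_step: int | None = None
    kink_angle: float = 0.0
    twist_override: float | None = None
    rise_override: float | None = None
    groove_modulation: np.ndarray | None = None
    noise_sigma: float = 0.0
    n_models: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.bend_total < 0 or self.bend_min < 0 or self.bend_min > self.bend_total:
            raise ValueError("bend range must satisfy 0 <= bend_min <= bend_total")
        if not 0.0 <= self.kink_angle <= 120.0:
            raise ValueError("kink_angle must lie in [0, 120] degrees")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")


@dataclass(frozen=True)
class MismatchGeometrySpec:
    pair_type: str
    target_hbond_count: int
    orientation: str = "anti"

    def __post_init__(self):
        if self.orientation != "anti":
            raise ValueError("only anti/anti mismatch geometries are supported")
        if self.target_hbond_count < 0:
            raise ValueError("target_hbond_count must be >= 0")


# ---------------------------------------------------------------------------
# ideal builds
# ---------------------------------------------------------------------------


def _pair_transform(fiber: FiberParameters, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Placement (R, t) of pair k (0-based) along the global helix axis."""
    Rz = rotation_about_axis([0, 0, 1], k * fiber.twist)
    R = Rz
    t = np.array([0.0, 0.0, k * fiber.rise])
    if fiber.inclination != 0.0:
        R = Rz @ rotation_about_axis([1, 0, 0], fiber.inclination)
    if fiber.x_displacement != 0.0:
        t = t + Rz @ np.array([fiber.x_displacement, 0.0, 0.0])
    return R, t


def _mismatch_embedding(pair_type: str) -> tuple[np.ndarray, np.ndarray]:
    """Canonical (maximum-bond) partner placement for a mismatch pair."""
    return placement_transform(pair_type, max_simultaneous_hbonds(pair_type))


def build_duplex(
    seq_i: str,
    seq_ii: str,
    fiber: FiberParameters | None = None,
    chain_ids: tuple[str, str] = ("A", "B"),
) -> Conformation:
    """Duplex from two explicit strands (both 5'->3', paired in register).

    Watson-Crick positions place the partner base by the exact y/z flip;
    mismatch positions embed the canonical geometry from the hydrogen-bond
    placement search.
    """
    fiber = fiber or DEFAULT_FIBER
    seq_i, seq_ii = seq_i.upper(), seq_ii.upper()
    for s in (seq_i, seq_ii):
        if len(s) < 2:
            raise ValueError("sequence length must be >= 2")
        bad = set(s) - set("AUGC")
        if bad:
            raise ValueError(f"sequence contains non-AUGC characters {sorted(bad)}")
    if len(seq_i) != len(seq_ii):
        raise ValueError("strands must have equal length")
    n = len(seq_i)

    wc = {"AU", "UA", "GC", "CG", "GU", "UG"}
    names, res_names, res_ids, chains, coords = [], [], [], [], []

    def emit(base: str, chain: str, rid: int, R: np.ndarray, t: np.ndarray):
        tpl = nucleotide_template(base)
        for atom in residue_atom_order(base):
            names.append(atom)
            res_names.append(base)
            res_ids.append(rid)
            chains.append(chain)
            coords.append(R @ tpl[atom] + t)

    for i in range(1, n + 1):  # strand I, 5'->3'
        R, t = _pair_transform(fiber, i - 1)
        emit(seq_i[i - 1], chain_ids[0], i, R, t)
    for j in range(1, n + 1):  # strand II, 5'->3' in its own chain
        i = n + 1 - j  # paired strand-I residue
        R, t = _pair_transform(fiber, i - 1)
        pair = seq_i[i - 1] + seq_ii[j - 1]
        if pair in wc:
            Rb, tb = _FLIP, np.zeros(3)
        else:
            Rb, tb = _mismatch_embedding(pair)
        emit(seq_ii[j - 1], chain_ids[1], j, R @ Rb, R @ tb + t)

    elements = [element_of(a) for a in names]
    return Conformation.from_arrays(
        np.array(names), np.array(res_names), np.array(res_ids),
        np.array(chains), np.array(coords), np.array(elements),
    )


def build_ideal_duplex(
    sequence: str, fiber: FiberParameters | None = None
) -> Conformation:
    """Ideal A-form duplex; the complementary strand is auto-generated."""
    sequence = sequence.upper()
    bad = set(sequence) - set("AUGC")
    if bad:
        raise ValueError(f"sequence contains non-AUGC characters {sorted(bad)}")
    comp = "".join(COMPLEMENT[b] for b in reversed(sequence))
    return build_duplex(sequence, comp, fiber)


_CONSTRUCT_RE = re.compile(r"^(\d+)x(AUUCU|CCUG|CAG|CUG)(-WC)?$", re.IGNORECASE)


def build_repeat_construct(
    name: str, fiber: FiberParameters | None = None
) -> Conformation:
    """One of the repeat-expansion model duplexes (or its '-WC' control).

    The canonical labels are the twelve in :data:`TABLE_CONSTRUCTS`
    (e.g. ``20xCAG`` for GG(CAG)20CC paired against an identical strand,
    giving 1x1 A/A internal loops); ``20xCAG-WC`` substitutes the fully
    Watson-Crick complementary strand.
    """
    m = _CONSTRUCT_RE.match(name.strip())
    if not m:
        raise KeyError(f"unknown construct label {name!r}")
    n, rep, wc = int(m.group(1)), m.group(2).upper(), bool(m.group(3))
    pre, post = {"AUUCU": ("C", "AUC"), "CCUG": ("", ""), "CAG": ("GG", "CC"), "CUG": ("GG", "CC")}[rep]
    seq = pre + rep * n + post
    if wc:
        other = "".join(COMPLEMENT[b] for b in reversed(seq))
    else:
        other = seq  # the construct pairs against an identical strand
    return build_duplex(seq, other, fiber)


def build_mismatch_pair(spec: MismatchGeometrySpec) -> Conformation:
    """Two-residue 'pair' conformation with exactly the requested bond count.

    Only base atoms + C1' are emitted: the pair geometry is defined at the
    base level and the sugar conformation is not part of the search.
    """
    pair_type = spec.pair_type.upper()
    theta, shift = pair_placement(pair_type, spec.target_hbond_count)
    Rb = rotation_about_axis([0, 0, 1], theta) @ _FLIP
    names, res_names, res_ids, chains, coords = [], [], [], [], []
    from .templates import base_template

    for chain, base, R, t in (
        ("A", pair_type[0], np.eye(3), np.zeros(3)),
        ("B", pair_type[1], Rb, shift),
    ):
        tpl = base_template(base)
        for atom, v in tpl.items():
            names.append(atom)
            res_names.append(base)
            res_ids.append(1)
            chains.append(chain)
            coords.append(R @ np.asarray(v) + t)
    elements = [element_of(a) for a in names]
    return Conformation.from_arrays(
        np.array(names), np.array(res_names), np.array(res_ids),
        np.array(chains), np.array(coords), np.array(elements),
    )


# ---------------------------------------------------------------------------
# perturbations
# ---------------------------------------------------------------------------


def _pair_atom_groups(c: Conformation) -> list[np.ndarray]:
    """Atom-index array per base pair (strand-I residue i + partner)."""
    arr = c.atoms
    ch1, ch2 = c.chain_ids
    n = c.n_pairs
    groups = []
    idx = np.arange(arr.array_length())
    for i in range(1, n + 1):
        m = ((arr.chain_id == ch1) & (arr.res_id == i)) | (
            (arr.chain_id == ch2) & (arr.res_id == n + 1 - i)
        )
        groups.append(idx[m])
    return groups


def apply_bend(
    c: Conformation,
    bend_total: float,
    azimuth: float = 0.0,
    terminal_margin: int | None = None,
    frames: list | None = None,
    groups: list | None = None,
) -> Conformation:
    """Impose a smooth circular-arc bend of ``bend_total`` degrees.

    The bend is distributed as equal hinge rotations about a fixed lab axis
    perpendicular to the initial helix axis (direction set by ``azimuth``),
    applied at every interior step; ``terminal_margin`` steps at each end
    stay straight so the imposed angle equals the end-to-end axis direction
    change of the analyzed interior region (default 12 = terminal
    exclusion 5 + the bending estimator's 7-step end windows, reduced for
    short duplexes).  Base pairs move rigidly.
    """
    if bend_total < 0:
        raise ValueError("bend_total must be >= 0")
    if bend_total > 120.0:
        raise ValueError("bend_total > 120 degrees is outside the validated range")
    if bend_total == 0.0:
        return c
    if frames is None:
        frames, _ = duplex_pair_frames(c)
    n = len(frames)
    if terminal_margin is None:
        terminal_margin = min(12, (n - 4) // 2)
    hinges = list(range(terminal_margin + 1, n - terminal_margin))  # 1-based steps
    if not hinges:
        raise ValueError("duplex too short for the requested terminal margin")
    z0 = unit(np.mean([f.z for f in frames], axis=0))
    x0 = frames[0].x - np.dot(frames[0].x, z0) * z0
    a_hat = rotation_about_axis(z0, azimuth) @ unit(x0)
    delta = bend_total / len(hinges)
    R = rotation_about_axis(a_hat, delta)

    if groups is None:
        groups = _pair_atom_groups(c)
    coords = c.coords.copy()
    origins = np.array([f.origin for f in frames])
    for s in hinges:  # hinge between pairs s and s+1 (1-based)
        pivot = 0.5 * (origins[s - 1] + origins[s])
        down = np.concatenate(groups[s:])
        coords[down] = (coords[down] - pivot) @ R.T + pivot
        origins[s:] = (origins[s:] - pivot) @ R.T + pivot
    return c.with_coords(coords)


def apply_kink(
    c: Conformation,
    kink_step: int,
    kink_angle: float,
    azimuth: float = 0.0,
    frames: list | None = None,
    groups: list | None = None,
) -> Conformation:
    """Rigid single-hinge kink at a step: all downstream pairs rotate by
    ``kink_angle`` about an axis through the mid-step origin perpendicular
    to the local helix axis."""
    frames, _ = duplex_pair_frames(c)
    n = len(frames)
    if not 5 < kink_step < n - 5:
        raise ValueError(f"kink_step must lie in (5, {n - 5}) for a {n}-pair duplex")
    if not 0.0 <= kink_angle <= 120.0:
        raise ValueError("kink_angle must lie in [0, 120] degrees")
    if kink_angle == 0.0:
        return c
    f1, f2 = frames[kink_step - 1], frames[kink_step]
    zm = unit(f1.z + f2.z)
    xm = unit((f1.x + f2.x) - np.dot(f1.x + f2.x, zm) * zm)
    ym = np.cross(zm, xm)
    axis = rotation_about_axis(zm, azimuth) @ ym
    pivot = 0.5 * (f1.origin + f2.origin)
    R = rotation_about_axis(axis, kink_angle)
    if groups is None:
        groups = _pair_atom_groups(c)
    coords = c.coords.copy()
    down = np.concatenate(groups[kink_step:])
    coords[down] = (coords[down] - pivot) @ R.T + pivot
    return c.with_coords(coords)


def apply_overextension(
    c: Conformation,
    twist: float,
    rise: float,
    fiber: FiberParameters | None = None,
) -> Conformation:
    """Rebuild the helical placement with overridden (twist, rise).

    Overextension means undertwisting at increased rise (twist <= fiber
    default, rise >= fiber default); base-pair internal geometry is kept.
    """
    fiber = fiber or DEFAULT_FIBER
    if twist > fiber.twist + 1e-9:
        raise ValueError("overextension requires twist <= the fiber default")
    if rise < fiber.rise - 1e-9:
        raise ValueError("overextension requires rise >= the fiber default")
    frames, _ = duplex_pair_frames(c)
    groups = _pair_atom_groups(c)
    coords = c.coords.copy()
    R1, o1 = frames[0].rotation, frames[0].origin
    z1 = frames[0].z
    for i, (f, g) in enumerate(zip(frames, groups)):
        Rnew = rotation_about_axis(z1, i * twist) @ R1
        onew = o1 + i * rise * z1
        local = (coords[g] - f.origin) @ f.rotation  # coordinates in pair frame
        coords[g] = local @ Rnew.T + onew
    return c.with_coords(coords)


def apply_groove_modulation(c: Conformation, profile: np.ndarray) -> Conformation:
    """Scale phosphate positions radially about the local helix axis.

    ``profile`` holds one scale factor per step (length N-1); each residue's
    P atom uses the mean factor of its flanking steps, so a factor < 1 at a
    step narrows the grooves measured there.
    """
    pm = infer_pairing(c)
    n = pm.n_pairs
    profile = np.asarray(profile, dtype=float)
    if profile.shape != (n - 1,):
        raise ValueError(f"groove modulation profile must have length {n - 1}")
    frames, _ = duplex_pair_frames(c)
    arr = c.atoms
    coords = c.coords.copy()
    ch1, ch2 = c.chain_ids
    for chain in (ch1, ch2):
        for rid in range(1, n + 1):
            pair_i = rid if chain == ch1 else n + 1 - rid  # pair index of residue
            steps = [s for s in (pair_i - 1, pair_i) if 1 <= s <= n - 1]
            f = float(np.mean(profile[[s - 1 for s in steps]]))
            m = (arr.chain_id == chain) & (arr.res_id == rid) & (arr.atom_name == "P")
            if not np.any(m):
                continue
            fr = frames[pair_i - 1]
            v = coords[m] - fr.origin
            axial = v @ fr.z
            radial = v - np.outer(axial, fr.z)
            coords[m] = fr.origin + np.outer(axial, fr.z) + f * radial
    return c.with_coords(coords)


# ---------------------------------------------------------------------------
# ensemble generation
# ---------------------------------------------------------------------------


def generate_ensemble(
    c: Conformation, spec: PerturbationSpec, label: str = ""
) -> tuple[Ensemble, pd.DataFrame]:
    """Generate a perturbed ensemble plus its ground-truth manifest.

    Per model the imposed bend is drawn uniformly from
    [bend_min, bend_total] with a uniform random bend-plane azimuth; the
    kink (if any) and twist/rise overrides are applied as given; isotropic
    Gaussian noise of sigma ``noise_sigma`` is added last.  Fully
    reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    base = c
    if spec.twist_override is not None or spec.rise_override is not None:
        fiber = DEFAULT_FIBER
        base = apply_overextension(
            base,
            spec.twist_override if spec.twist_override is not None else fiber.twist,
            spec.rise_override if spec.rise_override is not None else fiber.rise,
        )
    if spec.groove_modulation is not None:
        base = apply_groove_modulation(base, spec.groove_modulation)

    base_frames, _ = duplex_pair_frames(base)
    base_groups = _pair_atom_groups(base)
    models, rows = [], []
    for m in range(spec.n_models):
        work = base
        bend = 0.0
        az = 0.0
        if spec.bend_total > 0:
            bend = float(rng.uniform(spec.bend_min, spec.bend_total))
            az = float(rng.uniform(0.0, 360.0))
            work = apply_bend(work, bend, azimuth=az,
                              frames=base_frames, groups=base_groups)
        if spec.kink_step is not None and spec.kink_angle > 0:
            # frames are only reusable while the geometry is unchanged
            work = apply_kink(
                work, spec.kink_step, spec.kink_angle,
                frames=base_frames if bend == 0.0 else None,
                groups=base_groups,
            )
        if spec.noise_sigma > 0:
            noise = rng.normal(0.0, spec.noise_sigma, size=work.coords.shape)
            work = work.with_coords(work.coords + noise)
        models.append(work)
        rows.append(
            {
                "model": m + 1,
                "bend_imposed": bend,
                "bend_azimuth": az,
                "kink_step": spec.kink_step if spec.kink_step is not None else -1,
                "kink_angle": spec.kink_angle if spec.kink_step is not None else 0.0,
                "noise_sigma": spec.noise_sigma,
            }
        )
    return Ensemble(models, label=label), pd.DataFrame(rows)
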