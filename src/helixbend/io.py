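"""Multi-model PDB ensemble I/O and the validated atomic data model.

A :class:`Conformation` is one all-atom duplex model (exactly two chains of
equal length, contiguous 1-based residue numbering, A/U/G/C residues with at
least the base ring atoms and C1' present).  An :class:`Ensemble` is an
ordered list of conformations sharing chains, sequences and atom ordering —
the package's stand-in for an MD trajectory.

Structures are stored as :class:`biotite.structure.AtomArray` under the
hood; waters, ions and ligands are silently dropped on read.  Hydrogens are
accepted but never required (all downstream criteria are heavy-atom only).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from os import PathLike
from pathlib import Path

import biotite.structure as struc
import numpy as np
from biotite.structure.io.pdb import PDBFile

from .templates import GLYCOSIDIC_N, RING_ATOMS

__all__ = ["StructureError", "Conformation", "Ensemble", "read_pdb", "write_pdb"]

_RNA_NAMES = {
    "A": "A", "U": "U", "G": "G", "C": "C",
    "RA": "A", "RU": "U", "RG": "G", "RC": "C",
    "ADE": "A", "URA": "U", "GUA": "G", "CYT": "C",
}


class StructureError(ValueError):
    """Raised for inputs violating the duplex-ensemble data model."""


@dataclass(frozen=True, eq=False)
class Conformation:
    """One duplex model: a validated heavy-atom :class:`AtomArray`.

    PDB-bound coordinates are float32; generated structures additionally
    carry full-precision coordinates so that exact geometric round trips
    (e.g. step-parameter recovery on ideal builds) are not limited by
    storage precision.
    """

    atoms: struc.AtomArray
    coords64: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self._validate()
        if self.coords64 is not None and self.coords64.shape != (
            self.atoms.array_length(),
            3,
        ):
            raise StructureError("full-precision coordinate shape mismatch")

    # -- construction ------------------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        atom_names: np.ndarray,
        res_names: np.ndarray,
        res_ids: np.ndarray,
        chain_ids: np.ndarray,
        coords: np.ndarray,
        elements: np.ndarray,
    ) -> "Conformation":
        n = len(atom_names)
        arr = struc.AtomArray(n)
        arr.atom_name = np.asarray(atom_names, dtype="U6")
        arr.res_name = np.asarray(res_names, dtype="U5")
        arr.res_id = np.asarray(res_ids, dtype=int)
        arr.chain_id = np.asarray(chain_ids, dtype="U4")
        arr.element = np.asarray(elements, dtype="U2")
        arr.hetero = np.zeros(n, dtype=bool)
        coords = np.asarray(coords, dtype=float)
        arr.coord = coords.astype(np.float32)
        return cls(arr, coords64=coords)

    # -- validation --------------------------------------------------------
    def _validate(self) -> None:
        arr = self.atoms
        if not isinstance(arr, struc.AtomArray) or arr.array_length() == 0:
            raise StructureError("empty conformation")
        if not np.all(np.isfinite(arr.coord)):
            raise StructureError("non-finite coordinates")
        chains = list(dict.fromkeys(arr.chain_id))
        if len(chains) != 2:
            raise StructureError(f"duplex requires exactly 2 chains, found {len(chains)}")
        counts = []
        for ch in chains:
            sub = arr[arr.chain_id == ch]
            ids = np.unique(sub.res_id)
            n = len(ids)
            if not np.array_equal(np.sort(ids), np.arange(1, n + 1)):
                raise StructureError(f"chain {ch}: residues not contiguous 1..N")
            counts.append(n)
            for rid in ids:
                res = sub[sub.res_id == rid]
                name = res.res_name[0]
                if name not in RING_ATOMS:
                    raise StructureError(f"chain {ch} residue {rid}: non-AUGC residue {name!r}")
                present = set(res.atom_name)
                missing = ({"C1'", GLYCOSIDIC_N[name]} | set(RING_ATOMS[name])) - present
                if missing:
                    raise StructureError(
                        f"chain {ch} residue {rid} ({name}): missing atoms {sorted(missing)}"
                    )
        if counts[0] != counts[1]:
            raise StructureError(
                f"strand lengths differ ({counts[0]} vs {counts[1]}): not a duplex"
            )

    # -- accessors ---------------------------------------------------------
    @property
    def chain_ids(self) -> tuple[str, str]:
        return tuple(dict.fromkeys(self.atoms.chain_id))  # type: ignore[return-value]

    @property
    def n_pairs(self) -> int:
        ch = self.chain_ids[0]
        return int(np.max(self.atoms.res_id[self.atoms.chain_id == ch]))

    def sequence(self, chain: str) -> str:
        arr = self.atoms
        sub = arr[arr.chain_id == chain]
        seq = []
        for rid in range(1, int(np.max(sub.res_id)) + 1):
            seq.append(sub.res_name[sub.res_id == rid][0])
        return "".join(seq)

    @property
    def sequences(self) -> dict[str, str]:
        return {ch: self.sequence(ch) for ch in self.chain_ids}

    def residue(self, chain: str, res_id: int) -> dict[str, np.ndarray]:
        """Atom name -> coordinate map for one residue."""
        arr = self.atoms
        m = (arr.chain_id == chain) & (arr.res_id == res_id)
        if not np.any(m):
            raise StructureError(f"no residue {res_id} in chain {chain}")
        return dict(zip(arr.atom_name[m], self.coords[m]))

    def residue_name(self, chain: str, res_id: int) -> str:
        arr = self.atoms
        m = (arr.chain_id == chain) & (arr.res_id == res_id)
        return str(arr.res_name[m][0])

    @property
    def coords(self) -> np.ndarray:
        if self.coords64 is not None:
            return self.coords64
        return np.asarray(self.atoms.coord, dtype=float)

    def with_coords(self, coords: np.ndarray) -> "Conformation":
        arr = self.atoms.copy()
        coords = np.asarray(coords, dtype=float)
        arr.coord = coords.astype(np.float32)
        return Conformation(arr, coords64=coords)


@dataclass(frozen=True)
class Ensemble:
    """Ordered set of duplex models sharing chains, sequences, atom order."""

    models: tuple[Conformation, ...]
    label: str = ""

    def __init__(self, models, label: str = ""):
        object.__setattr__(self, "models", tuple(models))
        object.__setattr__(self, "label", label)
        if len(self.models) == 0:
            raise StructureError("ensemble must contain at least one model")
        ref = self.models[0].atoms
        for i, c in enumerate(self.models[1:], start=2):
            a = c.atoms
            if a.array_length() != ref.array_length() or not (
                np.array_equal(a.atom_name, ref.atom_name)
                and np.array_equal(a.res_id, ref.res_id)
                and np.array_equal(a.chain_id, ref.chain_id)
                and np.array_equal(a.res_name, ref.res_name)
            ):
                raise StructureError(f"inconsistent ensemble: model {i} differs in atom layout")

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)

    def __getitem__(self, i):
        return self.models[i]

    def coords(self) -> np.ndarray:
        """Stacked coordinates, shape (n_models, n_atoms, 3)."""
        return np.stack([c.coords for c in self.models])


def read_pdb(path: str | PathLike) -> Ensemble:
    """Read a (multi-model) PDB file into an :class:`Ensemble`.

    Each MODEL becomes one conformation (a single unmarked model is accepted);
    waters, ions and ligands are ignored.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pdb = PDBFile.read(str(path))
    try:
        stack = pdb.get_structure()
    except Exception as exc:  # biotite signals per-model atom-count mismatch
        raise StructureError(f"inconsistent ensemble: {exc}") from exc
    if stack.stack_depth() == 0:
        raise StructureError("file contains no models")
    keep = np.array([name in _RNA_NAMES for name in stack.res_name])
    keep &= ~np.char.startswith(np.char.upper(stack.element.astype("U2")), "H")
    stack = stack[..., keep]
    if stack.array_length() == 0:
        raise StructureError("no RNA residues in file")
    stack.res_name = np.array([_RNA_NAMES[n] for n in stack.res_name], dtype="U5")
    # renumber each chain contiguously from 1, preserving order of appearance
    new_ids = np.empty(stack.array_length(), dtype=int)
    for ch in dict.fromkeys(stack.chain_id):
        m = stack.chain_id == ch
        ids = stack.res_id[m]
        uniq = list(dict.fromkeys(ids))
        remap = {old: i + 1 for i, old in enumerate(uniq)}
        new_ids[m] = [remap[i] for i in ids]
    stack.res_id = new_ids
    models = [Conformation(stack[i]) for i in range(stack.stack_depth())]
    return Ensemble(models, label=path.stem)


def write_pdb(ensemble: Ensemble, path: str | PathLike) -> None:
    """Write an ensemble as a standards-conforming multi-model PDB file."""
    if not isinstance(ensemble, Ensemble):
        if isinstance(ensemble, Conformation):
            ensemble = Ensemble([ensemble])
        else:
            raise StructureError("write_pdb expects an Ensemble or Conformation")
    stack = struc.stack([c.atoms for c in ensemble.models])
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))
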