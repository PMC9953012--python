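"""Domain types and readers/writers for protein structures and trajectories.

Coordinates are always in Angstroms. Internal residue indexing is 0-based and
contiguous in file order; the original PDB ``resSeq`` is retained as metadata.
Hydrogens are kept at read time and flagged ``is_heavy=False``; each analysis
stage declares its own heavy-atom behaviour.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile


class ParseError(ValueError):
    """Raised when a structure or trajectory file cannot be parsed."""


@dataclass(frozen=True)
class Atom:
    """A single atom (PDB naming conventions)."""

    serial: int
    name: str
    element: str
    coords: tuple[float, float, float]
    residue_index: int
    residue_name: str
    chain: str
    is_heavy: bool

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError("element must be non-empty")
        if not all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")


class Structure:
    """An ordered collection of atoms with contiguous 0-based residue indices.

    Atom attributes are stored as parallel numpy arrays for efficiency; the
    ``atoms`` property materialises :class:`Atom` objects on demand.
    """

    def __init__(
        self,
        serial: np.ndarray,
        name: np.ndarray,
        element: np.ndarray,
        coords: np.ndarray,
        residue_index: np.ndarray,
        residue_name: np.ndarray,
        chain: np.ndarray,
        res_seq: np.ndarray | None = None,
        source_id: str = "",
    ) -> None:
        n = len(name)
        self.serial = np.asarray(serial, dtype=int)
        self.name = np.asarray(name, dtype="U6")
        self.element = np.asarray(element, dtype="U2")
        self.coords = np.asarray(coords, dtype=float).reshape(n, 3)
        self.residue_index = np.asarray(residue_index, dtype=int)
        self.residue_name = np.asarray(residue_name, dtype="U3")
        self.chain = np.asarray(chain, dtype="U4")
        self.res_seq = (
            np.asarray(res_seq, dtype=int) if res_seq is not None else self.residue_index + 1
        )
        self.source_id = source_id
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if np.any(self.element == ""):
            raise ValueError("every atom needs an element symbol")

    # -- basic protocol ------------------------------------------------
    def __len__(self) -> int:
        return len(self.name)

    @property
    def n_atoms(self) -> int:
        return len(self.name)

    @property
    def is_heavy(self) -> np.ndarray:
        return self.element != "H"

    @property
    def n_residues(self) -> int:
        return len(np.unique(self.residue_index))

    @property
    def residues(self) -> list[tuple[int, str, str]]:
        """Ordered (residue_index, residue_name, chain) triples."""
        out = []
        seen = set()
        for idx, rname, ch in zip(self.residue_index, self.residue_name, self.chain):
            if idx not in seen:
                seen.add(idx)
                out.append((int(idx), str(rname), str(ch)))
        return out

    @property
    def residue_names(self) -> np.ndarray:
        """3-letter code per residue, in residue-index order."""
        _, first = np.unique(self.residue_index, return_index=True)
        return self.residue_name[np.sort(first)]

    @property
    def atoms(self) -> list[Atom]:
        heavy = self.is_heavy
        return [
            Atom(
                serial=int(self.serial[i]),
                name=str(self.name[i]),
                element=str(self.element[i]),
                coords=tuple(float(x) for x in self.coords[i]),
                residue_index=int(self.residue_index[i]),
                residue_name=str(self.residue_name[i]),
                chain=str(self.chain[i]),
                is_heavy=bool(heavy[i]),
            )
            for i in range(len(self))
        ]

    def select(self, mask: np.ndarray, renumber: bool = False) -> "Structure":
        mask = np.asarray(mask, dtype=bool)
        ridx = self.residue_index[mask]
        if renumber:
            _, ridx = np.unique(ridx, return_inverse=True)
        return Structure(
            self.serial[mask],
            self.name[mask],
            self.element[mask],
            self.coords[mask],
            ridx,
            self.residue_name[mask],
            self.chain[mask],
            self.res_seq[mask],
            self.source_id,
        )

    def heavy(self) -> "Structure":
        return self.select(self.is_heavy)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        return Structure(
            self.serial,
            self.name,
            self.element,
            coords,
            self.residue_index,
            self.residue_name,
            self.chain,
            self.res_seq,
            self.source_id,
        )

    @classmethod
    def from_atom_records(
        cls,
        records: Iterable[tuple[str, str, tuple[float, float, float], int, str]],
        chain: str = "A",
        source_id: str = "",
    ) -> "Structure":
        """Build a structure from (atom_name, element, xyz, residue_index, residue_name)."""
        recs = list(records)
        return cls(
            serial=np.arange(1, len(recs) + 1),
            name=np.array([r[0] for r in recs]),
            element=np.array([r[1] for r in recs]),
            coords=np.array([r[2] for r in recs], dtype=float),
            residue_index=np.array([r[3] for r in recs]),
            residue_name=np.array([r[4] for r in recs]),
            chain=np.full(len(recs), chain),
            source_id=source_id,
        )

    # -- biotite interop ----------------------------------------------
    def to_atom_array(self) -> bst.AtomArray:
        arr = bst.AtomArray(len(self))
        arr.coord = self.coords.astype(np.float32)
        arr.atom_name = self.name
        arr.element = np.char.upper(self.element)
        arr.res_id = self.res_seq
        arr.res_name = self.residue_name
        arr.chain_id = self.chain
        arr.hetero = np.zeros(len(self), dtype=bool)
        return arr


@dataclass
class Trajectory:
    """Ordered frames over a fixed atom set; ``frame_interval`` in ps."""

    topology: Structure
    coords: np.ndarray  # (n_frames, n_atoms, 3) in Angstroms
    frame_interval: float = 20.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frames have {self.coords.shape[1] if self.coords.ndim == 3 else '?'} atoms, "
                f"topology has {self.topology.n_atoms}"
            )
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Frame times in ps."""
        return np.arange(self.n_frames) * self.frame_interval

    def frame(self, i: int) -> Structure:
        return self.topology.with_coords(self.coords[i])


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def _validate_pdb_lines(path: str) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise ParseError(f"{path}:{lineno}: truncated coordinate record")
                try:
                    float(line[30:38]), float(line[38:46]), float(line[46:54])
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: unparsable coordinates in record"
                    ) from None


def _atom_array_to_structure(arr: bst.AtomArray, source_id: str) -> Structure:
    aa_mask = np.isin(arr.res_name, list(_AA3))
    if not np.any(aa_mask):
        raise ParseError(f"{source_id}: no protein atoms")
    arr = arr[aa_mask]
    # contiguous 0-based residue index in file order
    starts = bst.get_residue_starts(arr)
    ridx = np.zeros(arr.array_length(), dtype=int)
    for i, s in enumerate(starts):
        e = starts[i + 1] if i + 1 < len(starts) else arr.array_length()
        ridx[s:e] = i
    element = np.array([e.capitalize() if e else "" for e in arr.element], dtype="U2")
    return Structure(
        serial=np.arange(1, arr.array_length() + 1),
        name=arr.atom_name,
        element=element,
        coords=np.asarray(arr.coord, dtype=float),
        residue_index=ridx,
        residue_name=arr.res_name,
        chain=arr.chain_id,
        res_seq=arr.res_id,
        source_id=source_id,
    )


def read_structure(path: str) -> Structure:
    """Read the first model of a PDB file; amino-acid atoms only.

    Hydrogens are retained (``is_heavy`` False). Altloc resolution keeps the
    highest-occupancy variant (ties broken toward 'A').
    """
    if os.path.getsize(path) == 0:
        raise ParseError(f"{path}: empty file")
    _validate_pdb_lines(path)
    try:
        pdb = PDBFile.read(path)
        arr = pdb.get_structure(model=1, altloc="occupancy")
    except ParseError:
        raise
    except Exception as exc:  # biotite errors -> uniform parse error
        raise ParseError(f"{path}: {exc}") from exc
    source_id = os.path.splitext(os.path.basename(path))[0]
    return _atom_array_to_structure(arr, source_id)


def write_structure(structure: Structure, path: str, bfactors: np.ndarray | None = None) -> None:
    arr = structure.to_atom_array()
    if bfactors is not None:
        arr.set_annotation("b_factor", np.asarray(bfactors, dtype=float))
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(path)


def read_trajectory(
    topology_path: str, frames_path: str, frame_interval: float = 20.0
) -> Trajectory:
    """Read a trajectory from a multi-model PDB or a DCD file (assumed Angstroms)."""
    top = read_structure(topology_path)
    if frames_path.lower().endswith(".dcd"):
        import mdtraj as md

        t = md.load_dcd(frames_path, top=topology_path)
        coords = np.asarray(t.xyz, dtype=float) * 10.0  # nm -> Angstrom
        n = coords.shape[1]
        if n != top.n_atoms:
            # mdtraj topology may include non-protein atoms; align on count
            raise ParseError(
                f"frame atom count {n} != topology atom count {top.n_atoms}"
            )
    else:
        _validate_pdb_lines(frames_path)
        pdb = PDBFile.read(frames_path)
        stack = pdb.get_structure(altloc="occupancy")
        aa_mask = np.isin(stack.res_name, list(_AA3))
        stack = stack[..., aa_mask]
        coords = np.asarray(stack.coord, dtype=float)
        if coords.ndim == 2:
            coords = coords[None]
        if coords.shape[1] != top.n_atoms:
            raise ParseError(
                f"frame atom count {coords.shape[1]} != topology atom count {top.n_atoms}"
            )
    return Trajectory(topology=top, coords=coords, frame_interval=frame_interval)


def write_trajectory(traj: Trajectory, path: str) -> None:
    """Write a trajectory as a multi-model PDB."""
    n_frames, n_atoms = traj.coords.shape[:2]
    base = traj.topology.to_atom_array()
    stack = bst.AtomArrayStack(n_frames, n_atoms)
    for key in ("atom_name", "element", "res_id", "res_name", "chain_id", "hetero"):
        stack.set_annotation(key, base.get_annotation(key))
    stack.coord = traj.coords.astype(np.float32)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(path)
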