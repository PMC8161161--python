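"""Structures, conformational ensembles and the Kelch blade scheme.

PDB reading and writing is delegated to gemmi; this module defines the
in-memory containers used by every analysis stage (:class:`Structure`,
:class:`Ensemble`), backbone atom selections, and the six-blade residue
decomposition of the KEAP1 Kelch beta-propeller.

Residue numbering is always author (PDB) numbering with inclusive closed
intervals.  Coordinates are in Angstrom.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from ._peptide import virtual_cb

__all__ = [
    "Atom", "Structure", "Ensemble", "BladeScheme", "BackboneSelection",
    "PDBError", "read_structure", "read_ensemble", "write_structure",
    "write_ensemble", "backbone_selection", "kelch_blade_scheme",
]

FIT_BACKBONE_ATOMS = ("N", "CA", "C", "O")
SHEET_BACKBONE_ATOMS = ("N", "CA", "CB", "C", "O")


class PDBError(ValueError):
    """Raised for malformed or unsupported PDB input."""


@dataclass
class Atom:
    """A single atom with author numbering and Cartesian position (A)."""
    name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    position: np.ndarray

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        if not self.residue_name:
            raise ValueError(f"atom {self.name}: empty residue name")


class Structure:
    """An ordered collection of atoms grouped into residues.

    ``residues`` lists unique ``(chain_id, residue_index)`` keys in file
    order.  Atom names are unique within a residue.
    """

    def __init__(self, atoms: list[Atom]):
        self.atoms = list(atoms)
        self.residues: list[tuple[str, int]] = []
        self._residue_atoms: dict[tuple[str, int], dict[str, int]] = {}
        for i, atom in enumerate(self.atoms):
            key = (atom.chain_id, atom.residue_index)
            if key not in self._residue_atoms:
                self._residue_atoms[key] = {}
                self.residues.append(key)
            names = self._residue_atoms[key]
            if atom.name in names:
                raise PDBError(
                    f"duplicate atom name {atom.name!r} in residue "
                    f"{atom.residue_name} {atom.chain_id}{atom.residue_index}")
            names[atom.name] = i

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def residue_name(self, chain_id: str, residue_index: int) -> str:
        idx = next(iter(self._residue_atoms[(chain_id, residue_index)].values()))
        return self.atoms[idx].residue_name

    def atom_index(self, chain_id: str, residue_index: int, name: str) -> int:
        try:
            return self._residue_atoms[(chain_id, residue_index)][name]
        except KeyError:
            raise KeyError(
                f"no atom {name!r} in residue {chain_id}{residue_index}") from None

    def residue_atom_indices(self, chain_id: str, residue_index: int) -> list[int]:
        return list(self._residue_atoms[(chain_id, residue_index)].values())

    def has_atom(self, chain_id: str, residue_index: int, name: str) -> bool:
        return name in self._residue_atoms.get((chain_id, residue_index), {})

    def with_coords(self, coords: np.ndarray) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [Atom(a.name, a.element, a.residue_index, a.residue_name,
                      a.chain_id, c) for a, c in zip(self.atoms, coords)]
        return Structure(atoms)


@dataclass
class Ensemble:
    """Ordered conformations sharing a single topology."""
    topology: Structure
    frames: list[np.ndarray]
    frame_interval: float | None = None

    def __post_init__(self):
        if len(self.frames) < 1:
            raise ValueError("an ensemble needs at least one frame")
        n = self.topology.n_atoms
        self.frames = [np.asarray(f, dtype=float) for f in self.frames]
        for k, f in enumerate(self.frames):
            if f.shape != (n, 3):
                raise ValueError(
                    f"frame {k} has shape {f.shape}, expected ({n}, 3)")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class BladeScheme:
    """Named, non-overlapping inclusive residue-index intervals.

    A blade may span several disjoint intervals (the propeller's junction
    blade closes the ring with residues from both chain termini).
    """
    names: list[str]
    ranges: dict[str, list[tuple[int, int]]]

    def __post_init__(self):
        seen: set[int] = set()
        for name in self.names:
            for lo, hi in self.ranges[name]:
                if hi < lo:
                    raise ValueError(f"blade {name}: inverted interval ({lo}, {hi})")
                members = set(range(lo, hi + 1))
                if members & seen:
                    raise ValueError(f"blade {name}: overlapping intervals")
                seen |= members

    def blade_of(self, residue_index: int) -> str | None:
        for name in self.names:
            for lo, hi in self.ranges[name]:
                if lo <= residue_index <= hi:
                    return name
        return None

    def residues(self, name: str) -> list[int]:
        out: list[int] = []
        for lo, hi in self.ranges[name]:
            out.extend(range(lo, hi + 1))
        return out

    def size(self, name: str) -> int:
        return sum(hi - lo + 1 for lo, hi in self.ranges[name])


def kelch_blade_scheme() -> BladeScheme:
    """The six-blade decomposition of the KEAP1 Kelch domain.

    Blade I is the sequence-discontinuous junction blade joining the N- and
    C-terminal strands of the propeller.
    """
    return BladeScheme(
        names=["I", "II", "III", "IV", "V", "VI"],
        ranges={
            "I": [(325, 358), (598, 609)],
            "II": [(359, 409)],
            "III": [(410, 456)],
            "IV": [(457, 503)],
            "V": [(504, 550)],
            "VI": [(551, 597)],
        },
    )


# ---------------------------------------------------------------------------
# PDB input

def _as_text(source) -> str:
    if isinstance(source, Path):
        return source.read_text()
    if isinstance(source, str):
        if "\n" in source:
            return source
        if os.path.exists(source):
            return Path(source).read_text()
        raise PDBError(f"no such file: {source}")
    raise TypeError("source must be PDB text or a path")


def _convert_model(model: gemmi.Model, model_label: str) -> list[Atom]:
    atoms: list[Atom] = []
    for chain in model:
        for res in chain:
            if res.het_flag != "A":
                continue
            if res.seqid.icode not in (" ", ""):
                raise PDBError(
                    f"insertion code {res.seqid.icode!r} at residue "
                    f"{res.name} {chain.name}{res.seqid.num} is not supported")
            # altloc: keep highest occupancy, tie broken toward 'A'
            by_name: dict[str, gemmi.Atom] = {}
            plain: set[str] = set()
            for atom in res:
                prev = by_name.get(atom.name)
                if prev is None:
                    by_name[atom.name] = atom
                    if atom.altloc in ("", "\0"):
                        plain.add(atom.name)
                    continue
                if atom.altloc in ("", "\0") and atom.name in plain:
                    raise PDBError(
                        f"duplicate atom name {atom.name!r} in residue "
                        f"{res.name} {chain.name}{res.seqid.num}"
                        f" ({model_label})")
                if (atom.occ, atom.altloc in ("A",)) > (prev.occ, prev.altloc in ("A",)):
                    by_name[atom.name] = atom
            for atom in by_name.values():
                atoms.append(Atom(
                    name=atom.name,
                    element=atom.element.name,
                    residue_index=res.seqid.num,
                    residue_name=res.name,
                    chain_id=chain.name,
                    position=(atom.pos.x, atom.pos.y, atom.pos.z),
                ))
    return atoms


def read_structure(source) -> Structure:
    """Parse the first model of a PDB file or text into a :class:`Structure`."""
    text = _as_text(source)
    st = gemmi.read_pdb_string(text)
    n_lines = len(text.splitlines())
    if len(st) == 0:
        raise PDBError(f"no ATOM records found in {n_lines} lines scanned")
    atoms = _convert_model(st[0], "model 1")
    if not atoms:
        raise PDBError(f"no ATOM records found in {n_lines} lines scanned")
    return Structure(atoms)


def read_ensemble(source) -> Ensemble:
    """Parse a multi-model PDB into an :class:`Ensemble` (one frame per MODEL)."""
    text = _as_text(source)
    st = gemmi.read_pdb_string(text)
    n_lines = len(text.splitlines())
    if len(st) == 0:
        raise PDBError(f"no ATOM records found in {n_lines} lines scanned")
    topology: Structure | None = None
    signature: list[tuple[str, int, str]] = []
    frames: list[np.ndarray] = []
    for k, model in enumerate(st, start=1):
        atoms = _convert_model(model, f"model {k}")
        if topology is None:
            if not atoms:
                raise PDBError(f"no ATOM records found in {n_lines} lines scanned")
            topology = Structure(atoms)
            signature = [(a.chain_id, a.residue_index, a.name) for a in atoms]
        else:
            if len(atoms) != len(signature):
                raise PDBError(
                    f"model {k} has {len(atoms)} atoms, expected "
                    f"{len(signature)} (atom count mismatch)")
            sig = [(a.chain_id, a.residue_index, a.name) for a in atoms]
            if sig != signature:
                raise PDBError(f"model {k}: atom ordering differs from model 1")
        frames.append(np.array([a.position for a in atoms]))
    assert topology is not None
    return Ensemble(topology=topology, frames=frames)


# ---------------------------------------------------------------------------
# PDB output

def _gemmi_structure(topology: Structure, frames: list[np.ndarray]) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = "kelchdyn"
    # group atom rows per (chain, residue) preserving file order
    groups: list[tuple[tuple[str, int], list[int]]] = []
    last_key = None
    for i, atom in enumerate(topology.atoms):
        key = (atom.chain_id, atom.residue_index)
        if key != last_key:
            groups.append((key, []))
            last_key = key
        groups[-1][1].append(i)
    for k, frame in enumerate(frames, start=1):
        model = gemmi.Model(k)
        chain: gemmi.Chain | None = None
        for (chain_id, resi), rows in groups:
            if chain is None or chain.name != chain_id:
                if chain is not None:
                    model.add_chain(chain)
                chain = gemmi.Chain(chain_id)
            residue = gemmi.Residue()
            residue.name = topology.atoms[rows[0]].residue_name
            residue.seqid = gemmi.SeqId(resi, " ")
            residue.het_flag = "A"
            for i in rows:
                g = gemmi.Atom()
                g.name = topology.atoms[i].name
                g.element = gemmi.Element(topology.atoms[i].element)
                g.pos = gemmi.Position(*frame[i])
                g.occ = 1.0
                g.b_iso = 0.0
                residue.add_atom(g)
            chain.add_residue(residue)
        if chain is not None:
            model.add_chain(chain)
        st.add_model(model)
    return st


def write_structure(structure: Structure, path=None) -> str:
    """Serialize a structure as PDB text; optionally also write to ``path``."""
    st = _gemmi_structure(structure, [structure.coords])
    text = st.make_pdb_string()
    if path is not None:
        Path(path).write_text(text)
    return text


def write_ensemble(ensemble: Ensemble, path=None) -> str:
    """Serialize an ensemble as multi-model PDB text."""
    st = _gemmi_structure(ensemble.topology, ensemble.frames)
    text = st.make_pdb_string()
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# backbone selections

@dataclass
class BackboneSelection:
    """An ordered backbone atom selection over a structure.

    ``indices`` holds one entry per selected atom position; ``-1`` marks a
    glycine C-beta that does not exist in the structure and is synthesised
    at the ideal tetrahedral position from that residue's N/CA/C whenever
    coordinates are extracted.  Ordering is residue order, then the fixed
    per-residue atom order of the scheme.
    """
    structure: Structure
    scheme: str
    residues: list[tuple[str, int]]
    indices: np.ndarray
    atom_order: tuple[str, ...]
    _virtual: list[tuple[int, int, int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.indices)

    def extract(self, coords: np.ndarray) -> np.ndarray:
        """Gather selected coordinates from a full-structure frame."""
        coords = np.asarray(coords, dtype=float)
        out = np.empty((len(self.indices), 3))
        real = self.indices >= 0
        out[real] = coords[self.indices[real]]
        for pos, i_n, i_ca, i_c in self._virtual:
            out[pos] = virtual_cb(coords[i_n], coords[i_ca], coords[i_c])
        return out

    def residue_slices(self) -> list[slice]:
        w = len(self.atom_order)
        return [slice(i * w, (i + 1) * w) for i in range(len(self.residues))]


def backbone_selection(structure: Structure, scheme: str = "fit-backbone",
                       residues: list[tuple[str, int]] | None = None
                       ) -> BackboneSelection:
    """Build a backbone selection.

    ``fit-backbone`` selects N, CA, C, O per residue (the least-squares fit
    and deviation-metric selection).  ``sheet-backbone`` selects
    N, CA, CB, C, O per residue, synthesising a virtual CB for glycine so
    that every residue contributes the same five atoms to beta-sheet
    fragment comparisons.
    """
    if scheme == "fit-backbone":
        order = FIT_BACKBONE_ATOMS
    elif scheme == "sheet-backbone":
        order = SHEET_BACKBONE_ATOMS
    else:
        raise ValueError(f"unknown backbone scheme {scheme!r}")
    res_list = structure.residues if residues is None else residues
    indices: list[int] = []
    virtual: list[tuple[int, int, int, int]] = []
    for chain_id, resi in res_list:
        for name in order:
            if structure.has_atom(chain_id, resi, name):
                indices.append(structure.atom_index(chain_id, resi, name))
            elif (name == "CB" and scheme == "sheet-backbone"
                  and structure.residue_name(chain_id, resi) == "GLY"):
                pos = len(indices)
                virtual.append((pos,
                                structure.atom_index(chain_id, resi, "N"),
                                structure.atom_index(chain_id, resi, "CA"),
                                structure.atom_index(chain_id, resi, "C")))
                indices.append(-1)
            else:
                raise PDBError(
                    f"residue {structure.residue_name(chain_id, resi)} "
                    f"{chain_id}{resi} is missing backbone atom {name!r}")
    return BackboneSelection(structure=structure, scheme=scheme,
                             residues=list(res_list),
                             indices=np.asarray(indices, dtype=int),
                             atom_order=order, _virtual=virtual)
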