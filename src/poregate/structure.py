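"""Structures, trajectories and numbering-aware selections.

The in-memory containers are deliberately light: a :class:`Structure` is a set
of parallel NumPy arrays (one entry per atom) plus coordinates, and a
:class:`Trajectory` is a topology plus a ``(n_frames, n_atoms, 3)`` coordinate
stack.  Reading uses Bio.PDB; writing is fixed-column PDB with one MODEL per
frame for trajectories.  Species tagging follows the conventions of the
simulation analysis: water oxygens are tagged ``"water"``, Na+/Cl- ions by
element, everything else ``"protein"``/``"other"``.

Residue numbering is kept verbatim from the file (the Drosophila Orai crystal
structure uses author numbers, e.g. the pore helix spans residues 141-174).
:class:`ResidueMap` converts between human Orai1 and Drosophila Orai numbering
(offset +72: hOrai1 F99 <-> dOrai F171).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    AlignmentError,
    ParseError,
    SelectionError,
    UnsupportedFormatError,
)

WATER_RESNAMES = {"HOH", "WAT", "TIP", "TIP3", "TIP4", "SOL", "H2O"}
ION_RESNAMES = {"NA": "Na", "SOD": "Na", "CL": "Cl", "CLA": "Cl"}

# canonical atom ordering inside a residue, for stable selection order
_BACKBONE_RANK = {"N": 0, "CA": 1, "C": 2, "O": 3, "CB": 4}


def atom_name_rank(name: str) -> tuple[int, str]:
    return (_BACKBONE_RANK.get(name, 5), name)


def species_of(resname: str, element: str, atom_name: str) -> str:
    """Classify an atom as 'water', 'Na', 'Cl', 'protein' or 'other'."""
    resname = resname.strip().upper()
    element = element.strip().upper()
    if resname in WATER_RESNAMES:
        return "water" if element == "O" or atom_name.startswith("O") else "other"
    if element == "NA" or (not element and resname == "NA"):
        return "Na"
    if element == "CL" or (not element and resname == "CL"):
        return "Cl"
    if resname in ION_RESNAMES and element in ("", resname):
        return ION_RESNAMES[resname]
    return "protein"


@dataclass
class Structure:
    """A single-model structure as parallel per-atom arrays."""

    chain_ids: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    coords: np.ndarray
    model_index: int = 0
    is_hetero: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chain_ids = np.asarray(self.chain_ids, dtype=object)
        self.resids = np.asarray(self.resids, dtype=int)
        self.resnames = np.asarray(self.resnames, dtype=object)
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = self.coords.shape[0]
        if not all(
            len(a) == n
            for a in (self.chain_ids, self.resids, self.resnames, self.atom_names, self.elements)
        ):
            raise ParseError("per-atom arrays have inconsistent lengths")
        if not np.all(np.isfinite(self.coords)):
            raise ParseError("non-finite coordinates")
        if self.is_hetero is None:
            self.is_hetero = np.array(
                [s != "protein" for s in self.species], dtype=bool
            )

    # -- derived views ----------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def species(self) -> np.ndarray:
        return np.array(
            [
                species_of(rn, el, an)
                for rn, el, an in zip(self.resnames, self.elements, self.atom_names)
            ],
            dtype=object,
        )

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(c)
        return list(seen)

    def validate_unique(self) -> None:
        keys = set(zip(self.chain_ids, self.resids, self.atom_names))
        if len(keys) != self.n_atoms:
            raise ParseError("(chain, residue, atom name) not unique within model")

    # -- selection ---------------------------------------------------------
    def mask(
        self,
        chains: str | Iterable[str] | None = None,
        residues: int | tuple[int, int] | Iterable[int] | None = None,
        atom_names: str | Iterable[str] | None = None,
    ) -> np.ndarray:
        m = np.ones(self.n_atoms, dtype=bool)
        if chains is not None:
            cs = {chains} if isinstance(chains, str) else set(chains)
            m &= np.isin(self.chain_ids, list(cs))
        if residues is not None:
            if isinstance(residues, tuple) and len(residues) == 2:
                lo, hi = residues
                m &= (self.resids >= lo) & (self.resids <= hi)
            elif isinstance(residues, (int, np.integer)):
                m &= self.resids == int(residues)
            else:
                m &= np.isin(self.resids, list(residues))
        if atom_names is not None:
            ns = {atom_names} if isinstance(atom_names, str) else set(atom_names)
            m &= np.isin(self.atom_names, list(ns))
        return m

    def select(
        self,
        chains: str | Iterable[str] | None = None,
        residues: int | tuple[int, int] | Iterable[int] | None = None,
        atom_names: str | Iterable[str] | None = None,
    ) -> "Structure":
        """Subset atoms; stable order (chain, residue, atom-name rank).

        Raises :class:`SelectionError` naming the first unmatched criterion
        when the result is empty.
        """
        m = self.mask(chains, residues, atom_names)
        if not m.any():
            for name, kwargs, value in (
                ("chain", {"chains": chains}, chains),
                ("residue", {"residues": residues}, residues),
                ("atom name", {"atom_names": atom_names}, atom_names),
            ):
                if value is not None and not self.mask(**kwargs).any():
                    raise SelectionError(
                        f"selection matched no atoms: unmatched {name} = {value!r}"
                    )
            raise SelectionError("selection matched no atoms (criteria jointly empty)")
        idx = np.flatnonzero(m)
        order = sorted(
            idx,
            key=lambda i: (
                self.chain_ids[i],
                self.resids[i],
                atom_name_rank(self.atom_names[i]),
            ),
        )
        order = np.asarray(order, dtype=int)
        return Structure(
            chain_ids=self.chain_ids[order],
            resids=self.resids[order],
            resnames=self.resnames[order],
            atom_names=self.atom_names[order],
            elements=self.elements[order],
            coords=self.coords[order],
            model_index=self.model_index,
            is_hetero=self.is_hetero[order],
        )

    def atom_coord(self, chain: str, residue: int, atom_name: str) -> np.ndarray:
        m = self.mask(chain, residue, atom_name)
        if not m.any():
            raise SelectionError(
                f"atom {atom_name!r} of residue {residue} chain {chain!r} not found"
            )
        return self.coords[np.flatnonzero(m)[0]]

    def with_coords(self, coords: np.ndarray) -> "Structure":
        return replace(self, coords=np.asarray(coords, dtype=float))


@dataclass
class Trajectory:
    """Topology plus an ordered stack of coordinate frames."""

    topology: Structure
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    frame_spacing_ns: float | None = None
    repeat_id: str = "repeat-0"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1] != self.topology.n_atoms:
            raise AlignmentError(
                f"frame atom count {self.frames.shape} does not match topology "
                f"({self.topology.n_atoms} atoms)"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame(self, i: int) -> Structure:
        return self.topology.with_coords(self.frames[i])

    def __iter__(self):
        for i in range(self.n_frames):
            yield self.frame(i)


@dataclass(frozen=True)
class ResidueMap:
    """Offset map between two residue-numbering schemes.

    Default maps human Orai1 numbers to Drosophila Orai numbers (+72), e.g.
    F99 -> F171, V102 -> V174, G98 -> G170, E106 -> E178.
    """

    offset: int = 72

    def forward(self, number: int) -> int:
        return int(number) + self.offset

    def backward(self, number: int) -> int:
        return int(number) - self.offset


def map_residue(rmap: ResidueMap, number: int, direction: str = "forward") -> int:
    """Map a residue number across schemes; direction 'forward' or 'backward'."""
    if direction in ("forward", "h_to_d"):
        return rmap.forward(number)
    if direction in ("backward", "d_to_h"):
        return rmap.backward(number)
    raise ValueError(f"unknown direction {direction!r}")


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _from_biopdb_model(model) -> Structure:
    chain_ids, resids, resnames, atom_names, elements, coords, het = (
        [], [], [], [], [], [], []
    )
    for chain in model:
        for residue in chain:
            hetflag, resseq, icode = residue.id
            if icode.strip():
                raise UnsupportedFormatError(
                    f"insertion code {icode!r} at residue {resseq} is not supported"
                )
            for atom in residue:
                if atom.is_disordered():
                    children = {a.get_altloc(): a for a in atom}
                    chosen = children.get(" ") or children.get("A")
                    if chosen is None:  # fall back to first altloc, flagged
                        chosen = sorted(children.items())[0][1]
                        warnings.warn(
                            f"altloc 'A' absent for {atom.get_id()} res {resseq}; "
                            f"kept {chosen.get_altloc()!r}"
                        )
                    atom = chosen
                chain_ids.append(chain.id)
                resids.append(int(resseq))
                resnames.append(residue.resname.strip())
                atom_names.append(atom.get_name().strip())
                elements.append((atom.element or "").strip())
                coords.append(atom.coord)
                het.append(bool(hetflag.strip()))
    if not coords:
        raise ParseError("model contains no atoms")
    return Structure(
        chain_ids=chain_ids,
        resids=resids,
        resnames=resnames,
        atom_names=atom_names,
        elements=elements,
        coords=np.asarray(coords, dtype=float),
        is_hetero=np.asarray(het, dtype=bool),
    )


def read_pdb(path: str | Path) -> Structure | Trajectory:
    """Read a fixed-column PDB file.

    Single-MODEL files return a :class:`Structure`; multi-MODEL files return a
    :class:`Trajectory` (frames in file MODEL order).  Altlocs are resolved by
    keeping ' ' or 'A'; insertion codes raise
    :class:`~poregate.errors.UnsupportedFormatError`.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    if path.stat().st_size == 0:
        raise ParseError(f"empty PDB file: {path}")
    parser = PDBParser(QUIET=True)
    biostructure = parser.get_structure(path.stem, str(path))
    models = list(biostructure)
    if not models:
        raise ParseError(f"no MODEL/ATOM records found in {path}")
    structures = [_from_biopdb_model(m) for m in models]
    if len(structures) == 1:
        return structures[0]
    n0 = structures[0].n_atoms
    for i, s in enumerate(structures):
        if s.n_atoms != n0:
            raise AlignmentError(
                f"MODEL {i + 1} has {s.n_atoms} atoms, expected {n0}"
            )
    frames = np.stack([s.coords for s in structures])
    return Trajectory(topology=structures[0], frames=frames)


def _format_atom_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resid: int,
    xyz: np.ndarray,
    element: str,
    hetero: bool,
) -> str:
    record = "HETATM" if hetero else "ATOM  "
    if len(name) < 4 and len(element) <= 1:
        name_f = f" {name:<3s}"
    else:
        name_f = f"{name:<4s}"
    return (
        f"{record}{serial:5d} {name_f} {resname:<3s} {chain:1s}{resid:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2s}\n"
    )


def _write_model(fh, structure: Structure) -> None:
    serial = 0
    for i in range(structure.n_atoms):
        serial += 1
        fh.write(
            _format_atom_line(
                serial % 100000,
                structure.atom_names[i],
                structure.resnames[i],
                structure.chain_ids[i],
                int(structure.resids[i]),
                structure.coords[i],
                structure.elements[i],
                bool(structure.is_hetero[i]),
            )
        )


def write_pdb(path: str | Path, obj: Structure | Trajectory) -> None:
    """Write a Structure (single model) or Trajectory (one MODEL per frame)."""
    path = Path(path)
    with open(path, "w") as fh:
        if isinstance(obj, Trajectory):
            for i in range(obj.n_frames):
                fh.write(f"MODEL {i + 1:8d}\n")
                _write_model(fh, obj.frame(i))
                fh.write("ENDMDL\n")
        else:
            _write_model(fh, obj)
        fh.write("END\n")


def read_binary_trajectory(
    topology_path: str | Path, trajectory_path: str | Path, **kwargs
) -> Trajectory:
    """Adapter for binary trajectory formats (DCD/XTC) via MDAnalysis.

    Returns the same :class:`Trajectory` contract as multi-model PDB reading.
    Requires the optional ``MDAnalysis`` dependency.
    """
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise UnsupportedFormatError(
            "binary trajectory support requires MDAnalysis (pip install poregate[traj])"
        ) from exc
    u = mda.Universe(str(topology_path), str(trajectory_path), **kwargs)
    atoms = u.atoms
    topo = Structure(
        chain_ids=[str(s) for s in atoms.segids],
        resids=atoms.resids,
        resnames=[str(r) for r in atoms.resnames],
        atom_names=[str(n) for n in atoms.names],
        elements=[str(getattr(a, "element", "")) for a in atoms],
        coords=atoms.positions,
    )
    frames = np.stack([atoms.positions.copy() for _ in u.trajectory])
    dt_ns = getattr(u.trajectory, "dt", None)
    return Trajectory(
        topology=topo,
        frames=frames,
        frame_spacing_ns=None if dt_ns is None else dt_ns / 1000.0,
    )


def select(
    structure: Structure,
    chains: str | Iterable[str] | None = None,
    residues: int | tuple[int, int] | Iterable[int] | None = None,
    atom_names: str | Iterable[str] | None = None,
) -> Structure:
    """Module-level alias for :meth:`Structure.select`."""
    return structure.select(chains=chains, residues=residues, atom_names=atom_names)
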