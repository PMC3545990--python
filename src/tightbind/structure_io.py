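"""Coordinate-file reading and validated atom selection.

A thin, explicit layer over gemmi: files are parsed into a flat, ordered
list of atom records (one conformer per atom after the altloc policy is
applied) that the geometry operations consume directly.  Residue numbering
is taken verbatim from the file — plasmin(ogen) numbering for microplasmin
chains (catalytic triad S741/H603/D646), chymotrypsinogen numbering for
trypsin (S195/H57/D102) — with no renumbering layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "StructureModel",
    "ResidueSelector",
    "StructureError",
    "SelectionError",
    "read_structure",
    "write_pdb",
    "select",
    "select_chain",
    "ca_atoms",
    "parse_selector",
]


class StructureError(ValueError):
    """Unreadable or empty coordinate file."""


class SelectionError(KeyError):
    """A selector resolved to no atoms."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a structure (coordinates in Angstrom)."""

    chain: str
    resnum: int
    icode: str
    resname: str
    name: str
    element: str
    x: float
    y: float
    z: float
    occupancy: float = 1.0
    altloc: str = ""
    b_factor: float = 0.0
    is_water: bool = False
    is_het: bool = False

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class StructureModel:
    """Ordered atoms plus a label; supports subsetting and coordinate access."""

    atoms: list[AtomRecord]
    label: str = ""

    def __post_init__(self) -> None:
        seen = set()
        for a in self.atoms:
            key = (a.chain, a.resnum, a.icode, a.name, a.altloc)
            if key in seen:
                raise StructureError(f"duplicate atom {key} in {self.label!r}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in file order."""
        return np.array([[a.x, a.y, a.z] for a in self.atoms])

    @property
    def chains(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain not in out:
                out.append(a.chain)
        return out

    def residue_index(self) -> dict[str, list[tuple[int, str, str]]]:
        """Per-chain ordered list of (resnum, icode, resname)."""
        index: dict[str, list[tuple[int, str, str]]] = {}
        for a in self.atoms:
            entry = (a.resnum, a.icode, a.resname)
            index.setdefault(a.chain, [])
            if not index[a.chain] or index[a.chain][-1] != entry:
                index[a.chain].append(entry)
        return index

    def filter(self, predicate: Callable[[AtomRecord], bool],
               label: str | None = None) -> "StructureModel":
        return StructureModel(
            [a for a in self.atoms if predicate(a)],
            label if label is not None else self.label,
        )

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        """Copy of the model with replaced coordinates (same atom order)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise StructureError(
                f"coordinate array shape {coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        atoms = [
            replace(a, x=float(c[0]), y=float(c[1]), z=float(c[2]))
            for a, c in zip(self.atoms, coords)
        ]
        return StructureModel(atoms, self.label)


@dataclass(frozen=True)
class ResidueSelector:
    """Addresses atoms of one residue, optionally one named atom."""

    resnum: int
    chain: str | None = None
    atom_name: str | None = None
    icode: str = ""

    def matches(self, a: AtomRecord) -> bool:
        if self.chain is not None and a.chain != self.chain:
            return False
        if a.resnum != self.resnum or a.icode != self.icode:
            return False
        if self.atom_name is not None and a.name != self.atom_name:
            return False
        return True

    def __str__(self) -> str:
        parts = [self.chain or "*", f"{self.resnum}{self.icode}"]
        if self.atom_name:
            parts.append(self.atom_name)
        return ":".join(parts)


def parse_selector(text: str) -> ResidueSelector:
    """Parse ``chain:resnum[:atom]`` (chain ``*`` or empty = any chain)."""
    parts = text.split(":")
    if len(parts) < 2 or len(parts) > 3:
        raise SelectionError(f"cannot parse selector {text!r}; expected chain:resnum[:atom]")
    chain = parts[0] if parts[0] not in ("", "*") else None
    num = parts[1]
    icode = ""
    if num and num[-1].isalpha():
        num, icode = num[:-1], num[-1]
    try:
        resnum = int(num)
    except ValueError:
        raise SelectionError(f"bad residue number in selector {text!r}") from None
    atom = parts[2] if len(parts) == 3 else None
    return ResidueSelector(resnum=resnum, chain=chain, atom_name=atom, icode=icode)


def _apply_altloc_policy(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one conformer per atom site: highest occupancy, ties -> 'A'
    (or the alphabetically first altloc present)."""
    best: dict[tuple, AtomRecord] = {}
    order: list[tuple] = []
    for a in atoms:
        key = (a.chain, a.resnum, a.icode, a.name)
        if key not in best:
            best[key] = a
            order.append(key)
        else:
            b = best[key]
            if (a.occupancy, -ord(a.altloc or "z")) > (b.occupancy, -ord(b.altloc or "z")):
                best[key] = a
    return [best[k] for k in order]


def read_structure(
    path: str | Path,
    fmt: str | None = None,
    keep_waters: bool = True,
    model_index: int = 0,
) -> StructureModel:
    """Read a PDB (or mmCIF) file into a :class:`StructureModel`.

    One conformer per atom is retained (highest occupancy, ties broken
    toward altloc 'A').  Waters and heteroatoms are kept but flagged so
    downstream selections can exclude them.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such coordinate file: {path}")
    fmt = fmt or ("mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb")
    try:
        if fmt == "mmcif":
            structure = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            structure = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    if len(structure) == 0:
        raise StructureError(f"{path} contains no models")
    model = structure[model_index]

    atoms: list[AtomRecord] = []
    for chain in model:
        for residue in chain:
            is_water = residue.is_water()
            is_het = residue.het_flag == "H"
            if is_water and not keep_waters:
                continue
            for atom in residue:
                atoms.append(
                    AtomRecord(
                        chain=chain.name,
                        resnum=residue.seqid.num,
                        icode=(residue.seqid.icode or "").strip(),
                        resname=residue.name,
                        name=atom.name,
                        element=atom.element.name,
                        x=atom.pos.x,
                        y=atom.pos.y,
                        z=atom.pos.z,
                        occupancy=atom.occ,
                        altloc=(atom.altloc or "").strip(),
                        b_factor=atom.b_iso,
                        is_water=is_water,
                        is_het=is_het,
                    )
                )
    if not atoms:
        raise StructureError(f"{path} contains no atoms")
    atoms = _apply_altloc_policy(atoms)
    label = structure.name or path.stem
    return StructureModel(atoms, label=label)


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write the model as a single-model PDB file (via gemmi)."""
    st = gemmi.Structure()
    st.name = model.label
    md = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    residues: dict[tuple, gemmi.Residue] = {}
    for a in model.atoms:
        if a.chain not in chains:
            chains[a.chain] = gemmi.Chain(a.chain)
        rkey = (a.chain, a.resnum, a.icode)
        if rkey not in residues:
            res = gemmi.Residue()
            res.name = a.resname
            res.seqid = gemmi.SeqId(a.resnum, a.icode or " ")
            res.het_flag = "H" if (a.is_het or a.is_water) else "A"
            chains[a.chain].add_residue(res)
            residues[rkey] = chains[a.chain][-1]
        atom = gemmi.Atom()
        atom.name = a.name
        atom.element = gemmi.Element(a.element)
        atom.pos = gemmi.Position(a.x, a.y, a.z)
        atom.occ = a.occupancy
        atom.b_iso = a.b_factor
        atom.altloc = a.altloc[:1] if a.altloc else "\0"
        residues[rkey].add_atom(atom)
    for chain in chains.values():
        md.add_chain(chain)
    st.add_model(md)
    st.setup_entities()
    st.write_pdb(str(path))


def select(model: StructureModel, selector: ResidueSelector | str) -> StructureModel:
    """Atoms matching *selector*, in file order; empty selection is an error."""
    if isinstance(selector, str):
        selector = parse_selector(selector)
    out = [a for a in model.atoms if selector.matches(a)]
    if not out:
        raise SelectionError(f"selector {selector} matches no atoms in {model.label!r}")
    return StructureModel(out, label=f"{model.label}[{selector}]")


def select_chain(
    model: StructureModel,
    chain: str,
    atom_names: Sequence[str] | None = None,
    heavy_only: bool = False,
    include_waters: bool = False,
) -> StructureModel:
    """Atoms of one chain, optionally restricted by atom name/element."""
    wanted = set(atom_names) if atom_names is not None else None

    def keep(a: AtomRecord) -> bool:
        if a.chain != chain:
            return False
        if a.is_water and not include_waters:
            return False
        if wanted is not None and a.name not in wanted:
            return False
        if heavy_only and a.element == "H":
            return False
        return True

    out = model.filter(keep, label=f"{model.label}[{chain}]")
    if len(out) == 0:
        raise SelectionError(f"chain {chain!r} matches no atoms in {model.label!r}")
    return out


def ca_atoms(model: StructureModel, chain: str | None = None) -> StructureModel:
    """C-alpha atoms (of one chain if given), excluding waters/het."""
    out = model.filter(
        lambda a: a.name == "CA"
        and a.element == "C"
        and not a.is_water
        and not a.is_het
        and (chain is None or a.chain == chain),
        label=f"{model.label}[CA]",
    )
    if len(out) == 0:
        raise SelectionError(f"no C-alpha atoms found in {model.label!r}")
    return out
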