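"""Read and represent macromolecular structures; generate crystal-symmetry neighbors.

Parsing of PDB and mmCIF files is delegated to gemmi; this module converts
the gemmi hierarchy into a small immutable-ish model tailored to the
activity criteria: author residue numbering, heavy atoms only, one altloc
conformer per atom (highest occupancy, ties broken toward altloc 'A'), and
the first model only for multi-model (NMR) entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "SymmetryCopy",
    "ParseError",
    "CapabilityError",
    "read_structure",
    "expand_crystal_neighbors",
]


class ParseError(ValueError):
    """A structure file could not be read or has an unknown format."""


class CapabilityError(ValueError):
    """An operation needs records (e.g. crystal cell) the structure lacks."""


@dataclass
class Atom:
    """One heavy atom.  ``bfactor`` doubles as pLDDT in predicted models."""

    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.name}")


@dataclass
class Residue:
    chain_id: str
    seqnum: int
    icode: str
    name: str
    atoms: list[Atom] = field(default_factory=list)
    hetero: bool = False

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def positions(self, names) -> list[np.ndarray]:
        """Positions of the named atoms that are present (order preserved)."""
        out = []
        for nm in names:
            a = self.atom(nm)
            if a is not None:
                out.append(a.position)
        return out

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seqnum, self.icode)


@dataclass
class StructureModel:
    entry_id: str
    chains: dict[str, list[Residue]]
    cell: tuple[float, float, float, float, float, float] | None = None
    spacegroup: str | None = None
    symmetry_ops: list[gemmi.Op] = field(default_factory=list)

    def residue(self, chain_id: str, seqnum: int, icode: str = "") -> Residue | None:
        for r in self.chains.get(chain_id, []):
            if r.seqnum == seqnum and r.icode == (icode or ""):
                return r
        return None

    def polymer_residues(self, chain_id: str) -> list[Residue]:
        return [r for r in self.chains.get(chain_id, []) if not r.hetero]


@dataclass
class SymmetryCopy:
    """One placed symmetry/translation image of a chain."""

    chain_id: str
    op_index: int
    lattice_offset: tuple[int, int, int]
    residues: list[Residue]


# Hydroxyl-bearing modified residues mapped to their parent type.
MODIFIED_PARENT = {"SEP": "SER", "TPO": "THR", "PTR": "TYR"}


def _pick_altloc(res: gemmi.Residue) -> list[gemmi.Atom]:
    """One conformer per atom name: highest occupancy, ties -> lowest altloc letter."""
    by_name: dict[str, gemmi.Atom] = {}
    for at in res:
        prev = by_name.get(at.name)
        if prev is None:
            by_name[at.name] = at
            continue
        if at.occ > prev.occ or (at.occ == prev.occ and (at.altloc or "A") < (prev.altloc or "A")):
            by_name[at.name] = at
    return list(by_name.values())


def read_structure(path, fmt: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Heavy atoms of all residues (polymer, ligand, water) are retained;
    hydrogens are dropped; ligands and waters carry ``hetero=True``.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    fmt = fmt.lower()
    if fmt not in {"pdb", "mmcif", "cif", "auto"}:
        raise ParseError(f"unknown format {fmt!r}; expected pdb, mmcif or auto")
    try:
        if fmt == "pdb":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
        elif fmt in {"mmcif", "cif"}:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise ParseError(f"no models in {path}")
    model = st[0]  # first model only (NMR ensembles collapse to one conformer)

    chains: dict[str, list[Residue]] = {}
    for ch in model:
        residues: list[Residue] = []
        for res in ch:
            het = res.het_flag == "H"
            atoms = []
            for at in _pick_altloc(res):
                if at.element == gemmi.Element("H") or at.element == gemmi.Element("D"):
                    continue
                atoms.append(
                    Atom(
                        name=at.name,
                        element=at.element.name,
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        occupancy=at.occ,
                        bfactor=at.b_iso,
                    )
                )
            if atoms:
                residues.append(
                    Residue(
                        chain_id=ch.name,
                        seqnum=res.seqid.num,
                        icode=(res.seqid.icode or "").strip(),
                        name=res.name,
                        atoms=atoms,
                        hetero=het,
                    )
                )
        if residues:
            chains.setdefault(ch.name, []).extend(residues)

    cell = None
    sg_name = None
    ops: list[gemmi.Op] = []
    if st.cell and st.cell.a > 1.0:
        cell = (st.cell.a, st.cell.b, st.cell.c, st.cell.alpha, st.cell.beta, st.cell.gamma)
    hm = (st.spacegroup_hm or "").strip()
    if hm and cell is not None:
        sg = gemmi.find_spacegroup_by_name(hm)
        if sg is not None:
            sg_name = sg.hm
            ops = list(sg.operations())
            # make sure the identity comes first
            ident = gemmi.Op("x,y,z")
            ops.sort(key=lambda op: 0 if op == ident else 1)

    return StructureModel(
        entry_id=st.name or path.stem,
        chains=chains,
        cell=cell,
        spacegroup=sg_name,
        symmetry_ops=ops,
    )


def _fractionalization(cell) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonalization and fractionalization matrices for a unit cell."""
    gc = gemmi.UnitCell(*cell)
    orth = np.array(gc.orth.mat.tolist())
    frac = np.array(gc.frac.mat.tolist())
    return orth, frac


def transform_position(pos, op: gemmi.Op, offset, cell) -> np.ndarray:
    """Apply a symmetry operator plus lattice translation to a Cartesian position."""
    orth, frac = _fractionalization(cell)
    f = frac @ np.asarray(pos, dtype=float)
    rot = np.array(op.rot, dtype=float) / op.DEN
    tran = np.array(op.tran, dtype=float) / op.DEN
    f2 = rot @ f + tran + np.asarray(offset, dtype=float)
    return orth @ f2


def expand_crystal_neighbors(model: StructureModel, shell: int = 1) -> list[SymmetryCopy]:
    """All symmetry/translation images of every chain in a (2*shell+1)^3 lattice block.

    The identity image at zero lattice translation is excluded.  shell=1
    builds the 3x3x3 block of unit cells around the deposited one.
    """
    if model.cell is None or model.spacegroup is None or not model.symmetry_ops:
        raise CapabilityError("structure has no crystal cell / space group records")
    if shell < 0:
        raise ValueError("shell must be >= 0")
    orth, frac = _fractionalization(model.cell)
    ident = gemmi.Op("x,y,z")
    copies: list[SymmetryCopy] = []
    offsets = range(-shell, shell + 1)
    for op_idx, op in enumerate(model.symmetry_ops):
        rot = np.array(op.rot, dtype=float) / op.DEN
        tran = np.array(op.tran, dtype=float) / op.DEN
        is_ident = op == ident
        for i in offsets:
            for j in offsets:
                for k in offsets:
                    if is_ident and i == 0 and j == 0 and k == 0:
                        continue
                    off = np.array([i, j, k], dtype=float)
                    for cid, residues in model.chains.items():
                        placed = []
                        for r in residues:
                            new_atoms = []
                            for a in r.atoms:
                                f = frac @ a.position
                                f2 = rot @ f + tran + off
                                new_atoms.append(
                                    Atom(a.name, a.element, orth @ f2, a.occupancy, a.bfactor)
                                )
                            placed.append(
                                Residue(r.chain_id, r.seqnum, r.icode, r.name, new_atoms, r.hetero)
                            )
                        copies.append(SymmetryCopy(cid, op_idx, (i, j, k), placed))
    return copies
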