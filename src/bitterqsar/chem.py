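"""Molecular and receptor data model plus file IO.

The in-memory molecule is a heavy-atom graph (hydrogens are implicit and
carried as per-atom counts); receptor structures keep the PDB's own residue
numbering. SMILES and SDF parsing and 3D embedding are delegated to RDKit;
the PDB subset reader/writer is fixed-column so that malformed records can
be reported with their line number.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit import RDLogger

log = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.warning")

#: Elements the pipeline's descriptor and interaction code understands.
SUPPORTED_ELEMENTS = frozenset(
    {"C", "H", "N", "O", "S", "P", "F", "Cl", "Br", "I", "B", "Se"}
)

AROMATIC_BOND = "ar"


class ParseError(ValueError):
    """A record could not be parsed; carries the offending id/line."""


@dataclass(frozen=True)
class Atom:
    element: str
    formal_charge: int = 0
    aromatic: bool = False
    #: implicit hydrogens attached to this heavy atom (explicit H atoms are
    #: their own Atom entries with element "H" and n_hydrogens 0)
    n_hydrogens: int = 0


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    order: object = 1  # 1, 2, 3 or AROMATIC_BOND

    def __post_init__(self):
        if self.i == self.j:
            raise ValueError(f"self-bond on atom {self.i}")


@dataclass
class Molecule:
    """Heavy-atom molecular graph with optional 3D coordinates (Å)."""

    id: str
    atoms: list[Atom]
    bonds: list[Bond]
    coords: Optional[np.ndarray] = None  # shape (n_atoms, 3)

    def __post_init__(self):
        n = len(self.atoms)
        seen = set()
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise ValueError(f"bond ({b.i},{b.j}) out of range for {n} atoms")
            key = (min(b.i, b.j), max(b.i, b.j))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (n, 3):
                raise ValueError(
                    f"coords shape {self.coords.shape} != ({n}, 3)"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_heavy_atoms(self) -> int:
        return sum(1 for a in self.atoms if a.element != "H")

    def neighbors(self, i: int) -> list[int]:
        out = []
        for b in self.bonds:
            if b.i == i:
                out.append(b.j)
            elif b.j == i:
                out.append(b.i)
        return out

    def heavy_indices(self) -> list[int]:
        return [k for k, a in enumerate(self.atoms) if a.element != "H"]

    def total_hydrogens(self) -> int:
        """Implicit plus explicit hydrogen count."""
        return sum(a.n_hydrogens for a in self.atoms) + sum(
            1 for a in self.atoms if a.element == "H"
        )

    def with_coords(self, coords: np.ndarray) -> "Molecule":
        return Molecule(self.id, self.atoms, self.bonds, np.asarray(coords, float))


# ---------------------------------------------------------------------------
# RDKit bridge

_BOND_FROM_RDKIT = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
    Chem.BondType.AROMATIC: AROMATIC_BOND,
}
_BOND_TO_RDKIT = {v: k for k, v in _BOND_FROM_RDKIT.items()}


def from_rdkit(rdmol: Chem.Mol, mol_id: str = "") -> Molecule:
    atoms = [
        Atom(
            element=a.GetSymbol(),
            formal_charge=a.GetFormalCharge(),
            aromatic=a.GetIsAromatic(),
            n_hydrogens=a.GetTotalNumHs(),
        )
        for a in rdmol.GetAtoms()
    ]
    bonds = [
        Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), _BOND_FROM_RDKIT[b.GetBondType()])
        for b in rdmol.GetBonds()
    ]
    coords = None
    if rdmol.GetNumConformers() > 0:
        coords = np.array(rdmol.GetConformer().GetPositions(), dtype=float)
    return Molecule(mol_id, atoms, bonds, coords)


def to_rdkit(mol: Molecule, sanitize: bool = True) -> Chem.Mol:
    em = Chem.RWMol()
    for a in mol.atoms:
        ra = Chem.Atom(a.element)
        ra.SetFormalCharge(a.formal_charge)
        ra.SetIsAromatic(a.aromatic)
        if a.element != "H":
            ra.SetNumExplicitHs(a.n_hydrogens)
            ra.SetNoImplicit(True)
        em.AddAtom(ra)
    for b in mol.bonds:
        em.AddBond(b.i, b.j, _BOND_TO_RDKIT[b.order])
    out = em.GetMol()
    if sanitize:
        Chem.SanitizeMol(out)
    if mol.coords is not None:
        conf = Chem.Conformer(mol.n_atoms)
        for k, (x, y, z) in enumerate(mol.coords):
            conf.SetAtomPosition(k, (float(x), float(y), float(z)))
        out.AddConformer(conf, assignId=True)
    return out


# ---------------------------------------------------------------------------
# SMILES

def read_smiles(text: str, mol_id: str = "") -> Molecule:
    """Parse one SMILES record into a heavy-atom :class:`Molecule`.

    Multi-fragment inputs (salts) keep the largest fragment; a parse failure
    raises :class:`ParseError` naming the record.
    """
    rdmol = Chem.MolFromSmiles(text)
    if rdmol is None:
        raise ParseError(f"could not parse SMILES for record {mol_id!r}: {text!r}")
    frags = Chem.GetMolFrags(rdmol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        log.warning(
            "record %r has %d fragments; keeping the largest", mol_id, len(frags)
        )
        rdmol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
    return from_rdkit(rdmol, mol_id)


def write_smiles(mol: Molecule) -> str:
    return Chem.MolToSmiles(to_rdkit(mol))


def read_smiles_file(path) -> list[Molecule]:
    """Read a whitespace-separated ``SMILES<TAB>id`` file, '#' comments.

    Unparseable records are skipped and logged; the batch never aborts.
    """
    out: list[Molecule] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            smiles = parts[0]
            mol_id = parts[1] if len(parts) > 1 else f"line{lineno}"
            try:
                out.append(read_smiles(smiles, mol_id))
            except ParseError as exc:
                log.warning("skipping line %d: %s", lineno, exc)
    return out


def read_sdf(path) -> list[Molecule]:
    """Read a V2000 SDF; molecules keep their coordinates and title as id."""
    out = []
    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    for k, rdmol in enumerate(supplier):
        if rdmol is None:
            log.warning("skipping unreadable SDF record %d in %s", k, path)
            continue
        mol_id = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else f"mol{k}"
        out.append(from_rdkit(rdmol, mol_id))
    return out


def write_sdf(mols: Iterable[Molecule], path, scores: Optional[dict] = None) -> None:
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    for m in mols:
        rd = to_rdkit(m)
        rd.SetProp("_Name", m.id)
        if scores and m.id in scores:
            rd.SetProp("score", repr(float(scores[m.id])))
        writer.write(rd)
    writer.close()


# ---------------------------------------------------------------------------
# 3D embedding

def embed_3d(mol: Molecule, seed: int = 1) -> Molecule:
    """Embed a single 3D conformer (ETKDG); deterministic per (graph, seed).

    Hydrogens are added for the embedding and stripped again, so the
    returned molecule keeps the heavy-atom indexing of the input.
    """
    if mol.n_atoms < 1:
        raise ValueError(f"cannot embed empty molecule {mol.id!r}")
    rd = to_rdkit(mol)
    rdh = Chem.AddHs(rd)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    params.useRandomCoords = False
    code = AllChem.EmbedMolecule(rdh, params)
    if code != 0:
        # fall back to random-coordinate initialisation before giving up
        params.useRandomCoords = True
        code = AllChem.EmbedMolecule(rdh, params)
    if code != 0:
        raise RuntimeError(f"3D embedding failed for compound {mol.id!r}")
    AllChem.MMFFOptimizeMolecule(rdh, maxIters=500)
    rdheavy = Chem.RemoveHs(rdh)
    coords = np.array(rdheavy.GetConformer().GetPositions(), dtype=float)
    return mol.with_coords(coords[: mol.n_atoms])


# ---------------------------------------------------------------------------
# Receptor structures (PDB subset)

@dataclass(frozen=True)
class ReceptorAtom:
    serial: int
    name: str
    resname: str
    chain: str
    resnum: int
    element: str
    pos: tuple  # (x, y, z) Å


@dataclass
class ReceptorStructure:
    """Protein atoms grouped by (chain, residue number); PDB numbering kept."""

    atoms: list[ReceptorAtom] = field(default_factory=list)
    #: optional user-supplied generic-numbering labels, e.g. {("A", 265): "7.39"}
    annotations: dict = field(default_factory=dict)

    def __post_init__(self):
        for a in self.atoms:
            if not all(math.isfinite(v) for v in a.pos):
                raise ValueError(f"non-finite coordinates on atom serial {a.serial}")

    def residues(self) -> dict:
        """Map (chain, resnum, resname) -> list of atoms, in file order."""
        out: dict = {}
        for a in self.atoms:
            out.setdefault((a.chain, a.resnum, a.resname), []).append(a)
        return out

    @property
    def n_residues(self) -> int:
        return len(self.residues())


@dataclass
class ComplexPose:
    """One docked ligand pose in a receptor; score in kcal/mol if known."""

    receptor: ReceptorStructure
    ligand: Molecule
    score: Optional[float] = None

    def __post_init__(self):
        if self.ligand.coords is None:
            raise ValueError(f"ligand {self.ligand.id!r} has no coordinates")


def _parse_pdb_float(s: str, what: str, lineno: int) -> float:
    try:
        return float(s)
    except ValueError:
        raise ParseError(f"line {lineno}: malformed {what} field {s.strip()!r}")


def read_pdb(path, include_hetatm: bool = False) -> ReceptorStructure:
    """Read the ATOM/HETATM/TER/END fixed-column subset of PDB v3.3.

    HETATM records are skipped unless ``include_hetatm``; a malformed
    fixed-width field raises :class:`ParseError` naming the line.
    """
    atoms: list[ReceptorAtom] = []
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            n_lines += 1
            rec = line[:6]
            if rec == "HETATM" and not include_hetatm:
                continue
            if rec not in ("ATOM  ", "HETATM"):
                continue
            if len(line.rstrip("\n")) < 54:
                raise ParseError(f"line {lineno}: truncated ATOM record")
            try:
                serial = int(line[6:11])
                resnum = int(line[22:26])
            except ValueError:
                raise ParseError(f"line {lineno}: malformed serial/resSeq field")
            x = _parse_pdb_float(line[30:38], "x", lineno)
            y = _parse_pdb_float(line[38:46], "y", lineno)
            z = _parse_pdb_float(line[46:54], "z", lineno)
            name = line[12:16].strip()
            element = line[76:78].strip() if len(line) >= 78 else ""
            if not element:
                element = name[:1] if name[:1].isalpha() else name[1:2]
            atoms.append(
                ReceptorAtom(
                    serial=serial,
                    name=name,
                    resname=line[17:20].strip(),
                    chain=line[21].strip() or "A",
                    resnum=resnum,
                    element=element.capitalize(),
                    pos=(x, y, z),
                )
            )
    if n_lines == 0 or not atoms:
        log.warning("no atoms read from %s", path)
    return ReceptorStructure(atoms=atoms)


def write_pdb(receptor: ReceptorStructure, path) -> None:
    """Write the receptor in the same fixed-column subset read_pdb accepts."""
    with open(path, "w") as fh:
        for a in receptor.atoms:
            name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
            fh.write(
                f"ATOM  {a.serial:5d} {name}{'':1s}{a.resname:>3s} "
                f"{a.chain:1s}{a.resnum:4d}    "
                f"{a.pos[0]:8.3f}{a.pos[1]:8.3f}{a.pos[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}\n"
            )
        fh.write("TER\nEND\n")
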