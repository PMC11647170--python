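"""Geometric typing of receptor-ligand contacts and population maps.

Contacts are typed purely from geometry — hydrogen-bond donor/acceptor
distances and angles, charge-group separations for salt bridges, ring
centroid distances and plane angles for aromatic stacking, and carrier-to-
centroid elevation for CH-π — with every cutoff configurable. Kinds use the
ligand's perspective: ``H-Donor`` means the ligand donates a hydrogen bond
to the residue; ``pi-H`` means a residue C–H points into a ligand ring.
Per-contact energies are never computed here; an optional pass-through
field carries externally supplied values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .chem import ComplexPose, Molecule, ReceptorAtom
from .topo import aromatic_rings

log = logging.getLogger(__name__)

INTERACTION_KINDS = ("H-Donor", "H-Acceptor", "Ionic", "H-pi", "pi-H", "pi-pi")

#: receptor aromatic ring definitions by residue name (atom-name tuples)
RING_ATOMS = {
    "PHE": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "TYR": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "TRP": (
        ("CG", "CD1", "NE1", "CE2", "CD2"),
        ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    ),
    "HIS": (("CG", "ND1", "CD1", "NE2", "CE2"),),
}

#: anionic side-chain groups (midpoint of the named atoms is the charge center)
ACID_GROUPS = {"GLU": ("OE1", "OE2"), "ASP": ("OD1", "OD2")}
#: cationic side-chain groups at pH 7
BASE_GROUPS = {"LYS": ("NZ",), "ARG": ("NH1", "NH2")}

#: side-chain H-bond donor heavy atoms; backbone N is a donor for every residue
SIDECHAIN_DONORS = {
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "TRP": ("NE1",),
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "HIS": ("ND1", "NE2"),
    "CYS": ("SG",),
}
#: side-chain H-bond acceptor heavy atoms; backbone O accepts for every residue
SIDECHAIN_ACCEPTORS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "HIS": ("ND1", "NE2"),
    "MET": ("SD",),
}


@dataclass
class Thresholds:
    """Geometric cutoffs for contact typing (distances in Å, angles in deg)."""

    hbond_dist: float = 3.5
    hbond_angle: float = 120.0
    ionic_dist: float = 4.0
    pipi_dist: float = 5.5
    pipi_angle: float = 30.0
    chpi_dist: float = 4.5
    chpi_elevation: float = 45.0
    neighborhood: float = 8.0  # residue prefilter around the ligand

    def scaled(self, factor: float) -> "Thresholds":
        return Thresholds(
            hbond_dist=self.hbond_dist * factor,
            hbond_angle=self.hbond_angle,
            ionic_dist=self.ionic_dist * factor,
            pipi_dist=self.pipi_dist * factor,
            pipi_angle=self.pipi_angle,
            chpi_dist=self.chpi_dist * factor,
            chpi_elevation=self.chpi_elevation,
            neighborhood=self.neighborhood,
        )


@dataclass(frozen=True)
class Residue:
    chain: str
    number: int
    name: str
    generic_label: Optional[str] = None

    @property
    def label(self) -> str:
        return f"{self.name}{self.number}"


@dataclass(frozen=True)
class InteractionRecord:
    residue: Residue
    kind: str
    distance: float
    participants: tuple  # (ligand-side id, receptor-side id)
    energy: Optional[float] = None  # pass-through only, never computed here

    def __post_init__(self):
        if self.kind not in INTERACTION_KINDS:
            raise ValueError(f"unknown interaction kind {self.kind!r}")
        if self.distance <= 0:
            raise ValueError(f"non-positive distance {self.distance}")


# ---------------------------------------------------------------------------
# ligand-side chemical perception

def _ligand_coords(mol: Molecule) -> np.ndarray:
    return np.asarray(mol.coords, dtype=float)


def _explicit_h_neighbors(mol: Molecule, i: int) -> list[int]:
    return [j for j in mol.neighbors(i) if mol.atoms[j].element == "H"]


def ligand_donors(mol: Molecule) -> list[int]:
    """Heavy atoms (N/O/S) bearing at least one hydrogen."""
    out = []
    for i, a in enumerate(mol.atoms):
        if a.element in ("N", "O", "S"):
            if a.n_hydrogens > 0 or _explicit_h_neighbors(mol, i):
                out.append(i)
    return out


def ligand_acceptors(mol: Molecule) -> list[int]:
    """N/O atoms with a lone pair (positively charged nitrogens excluded)."""
    return [
        i
        for i, a in enumerate(mol.atoms)
        if a.element in ("N", "O") and not (a.element == "N" and a.formal_charge > 0)
    ]


def _is_amide_nitrogen(mol: Molecule, i: int) -> bool:
    for j in mol.neighbors(i):
        if mol.atoms[j].element == "C":
            for b in mol.bonds:
                if b.order == 2 and {b.i, b.j} >= {j} and (
                    mol.atoms[b.i].element == "O" or mol.atoms[b.j].element == "O"
                ) and j in (b.i, b.j):
                    return True
    return False


def ligand_cation_centers(mol: Molecule) -> list[int]:
    """Nitrogens treated as protonated at pH 7: formal + charge, or neutral
    sp3 amines that are neither aromatic nor amide nitrogens."""
    out = []
    for i, a in enumerate(mol.atoms):
        if a.element != "N":
            continue
        if a.formal_charge > 0:
            out.append(i)
            continue
        if a.aromatic or a.formal_charge < 0:
            continue
        orders = [b.order for b in mol.bonds if i in (b.i, b.j)]
        if all(o == 1 for o in orders) and not _is_amide_nitrogen(mol, i):
            out.append(i)
    return out


def ligand_anion_centers(mol: Molecule) -> list[np.ndarray]:
    """Carboxylate midpoints (COO- or COOH, deprotonated at pH 7)."""
    centers = []
    coords = _ligand_coords(mol)
    for i, a in enumerate(mol.atoms):
        if a.element != "C":
            continue
        oxy = [j for j in mol.neighbors(i) if mol.atoms[j].element == "O"]
        terminal_o = [
            j for j in oxy if len([k for k in mol.neighbors(j) if mol.atoms[k].element != "H"]) == 1
        ]
        if len(terminal_o) == 2:
            centers.append(coords[terminal_o].mean(axis=0))
    return centers


def _ring_geometry(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit normal of a ring by SVD plane fit."""
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid)
    return centroid, vt[2]


def _elevation_deg(vec: np.ndarray, normal: np.ndarray) -> float:
    n = np.linalg.norm(vec)
    if n == 0:
        return 90.0
    return float(np.degrees(np.arcsin(min(1.0, abs(float(vec @ normal)) / n))))


def _plane_angle_deg(n1: np.ndarray, n2: np.ndarray) -> float:
    c = abs(float(n1 @ n2)) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    return float(np.degrees(np.arccos(min(1.0, c))))


# ---------------------------------------------------------------------------
# detection

def _residue_atom(atoms: Sequence[ReceptorAtom], name: str) -> Optional[ReceptorAtom]:
    for a in atoms:
        if a.name == name:
            return a
    return None


def _donor_angle_ok(
    mol: Molecule, donor_idx: int, acceptor_pos: np.ndarray, min_angle: float
) -> bool:
    """Donor-H-acceptor angle check; passes when no explicit H is placeable."""
    hs = _explicit_h_neighbors(mol, donor_idx)
    if not hs:
        return True
    coords = _ligand_coords(mol)
    for h in hs:
        v1 = coords[donor_idx] - coords[h]
        v2 = acceptor_pos - coords[h]
        denom = np.linalg.norm(v1) * np.linalg.norm(v2)
        if denom == 0:
            continue
        ang = np.degrees(np.arccos(np.clip(float(v1 @ v2) / denom, -1.0, 1.0)))
        if ang >= min_angle:
            return True
    return False


def detect_interactions(
    pose: ComplexPose, thresholds: Optional[Thresholds] = None
) -> list[InteractionRecord]:
    """Type all receptor-ligand contacts of one pose.

    Residues with any atom within the neighborhood cutoff of the ligand are
    considered. A residue missing atoms required by a group definition is
    skipped for that group with a warning. A single atom pair may yield both
    an H-Donor and an Ionic record (the salt-bridge signature).
    """
    th = thresholds or Thresholds()
    lig = pose.ligand
    lcoords = _ligand_coords(lig)
    records: list[InteractionRecord] = []
    seen: set = set()

    lig_rings = [r for r in aromatic_rings(lig)]
    lig_ring_geoms = [_ring_geometry(lcoords[r]) for r in lig_rings]

    def emit(residue, kind, dist, participants):
        key = (residue, kind, participants)
        if key in seen:
            return
        seen.add(key)
        records.append(InteractionRecord(residue, kind, float(dist), participants))

    for (chain, resnum, resname), atoms in pose.receptor.residues().items():
        rpos = np.array([a.pos for a in atoms])
        if np.min(
            np.linalg.norm(rpos[:, None, :] - lcoords[None, :, :], axis=2)
        ) > th.neighborhood:
            continue
        residue = Residue(
            chain, resnum, resname,
            pose.receptor.annotations.get((chain, resnum)),
        )

        # --- hydrogen bonds -------------------------------------------------
        acceptor_names = ("O",) + SIDECHAIN_ACCEPTORS.get(resname, ())
        donor_names = ("N",) + SIDECHAIN_DONORS.get(resname, ())
        for ld in ligand_donors(lig):
            for aname in acceptor_names:
                ra = _residue_atom(atoms, aname)
                if ra is None:
                    continue
                d = float(np.linalg.norm(lcoords[ld] - np.array(ra.pos)))
                if d <= th.hbond_dist and _donor_angle_ok(
                    lig, ld, np.array(ra.pos), th.hbond_angle
                ):
                    emit(residue, "H-Donor", d, (f"atom{ld}", aname))
        for la in ligand_acceptors(lig):
            for dname in donor_names:
                ra = _residue_atom(atoms, dname)
                if ra is None:
                    continue
                d = float(np.linalg.norm(lcoords[la] - np.array(ra.pos)))
                if d <= th.hbond_dist:
                    emit(residue, "H-Acceptor", d, (f"atom{la}", dname))

        # --- salt bridges ---------------------------------------------------
        if resname in ACID_GROUPS:
            names = ACID_GROUPS[resname]
            group = [_residue_atom(atoms, n) for n in names]
            if any(g is None for g in group):
                log.warning(
                    "residue %s%d missing %s atoms; skipping charge group",
                    resname, resnum, names,
                )
            else:
                center = np.array([g.pos for g in group]).mean(axis=0)
                for lc in ligand_cation_centers(lig):
                    d = float(np.linalg.norm(lcoords[lc] - center))
                    if d <= th.ionic_dist:
                        emit(residue, "Ionic", d, (f"atom{lc}", "+".join(names)))
        if resname in BASE_GROUPS:
            names = BASE_GROUPS[resname]
            group = [_residue_atom(atoms, n) for n in names]
            if any(g is None for g in group):
                log.warning(
                    "residue %s%d missing %s atoms; skipping charge group",
                    resname, resnum, names,
                )
            else:
                center = np.array([g.pos for g in group]).mean(axis=0)
                for k, lan in enumerate(ligand_anion_centers(lig)):
                    d = float(np.linalg.norm(lan - center))
                    if d <= th.ionic_dist:
                        emit(residue, "Ionic", d, (f"anion{k}", "+".join(names)))

        # --- aromatic stacking ----------------------------------------------
        rec_rings = []
        for ring_names in RING_ATOMS.get(resname, ()):
            ring_atoms = [_residue_atom(atoms, n) for n in ring_names]
            if any(a is None for a in ring_atoms):
                log.warning(
                    "residue %s%d missing ring atoms; skipping ring",
                    resname, resnum,
                )
                continue
            rec_rings.append(
                (ring_names, _ring_geometry(np.array([a.pos for a in ring_atoms])))
            )
        stacked_pairs = set()  # (lig ring idx, receptor ring names)
        for li, (lring, (lcen, lnorm)) in enumerate(zip(lig_rings, lig_ring_geoms)):
            for ring_names, (rcen, rnorm) in rec_rings:
                d = float(np.linalg.norm(lcen - rcen))
                if d <= th.pipi_dist and _plane_angle_deg(lnorm, rnorm) <= th.pipi_angle:
                    stacked_pairs.add((li, ring_names))
                    emit(residue, "pi-pi", d, (f"ring{li}", "ring:" + ring_names[0]))

        # --- CH-pi: ligand C-H into a receptor ring ("H-pi") ------------------
        for i, a in enumerate(lig.atoms):
            if a.element != "C":
                continue
            if a.n_hydrogens == 0 and not _explicit_h_neighbors(lig, i):
                continue
            in_stacked = {
                names
                for (li, names) in stacked_pairs
                if i in lig_rings[li]
            }
            for ring_names, (rcen, rnorm) in rec_rings:
                if ring_names in in_stacked:
                    continue  # the whole ring already counts as pi-pi
                vec = lcoords[i] - rcen
                d = float(np.linalg.norm(vec))
                if d <= th.chpi_dist and _elevation_deg(vec, rnorm) >= th.chpi_elevation:
                    emit(residue, "H-pi", d, (f"atom{i}", "ring:" + ring_names[0]))

        # --- CH-pi: receptor C-H into a ligand ring ("pi-H") ------------------
        rec_ring_atom_names = {
            n for ring_names in RING_ATOMS.get(resname, ()) for n in ring_names
        }
        for ra in atoms:
            if ra.element != "C" or ra.name == "C":
                continue  # backbone carbonyl carbon has no H
            for li, (lring, (lcen, lnorm)) in enumerate(
                zip(lig_rings, lig_ring_geoms)
            ):
                if ra.name in rec_ring_atom_names and any(
                    (li, names) in stacked_pairs
                    for names in (
                        rn for rn in RING_ATOMS.get(resname, ()) if ra.name in rn
                    )
                ):
                    continue
                vec = np.array(ra.pos) - lcen
                d = float(np.linalg.norm(vec))
                if d <= th.chpi_dist and _elevation_deg(vec, lnorm) >= th.chpi_elevation:
                    emit(residue, "pi-H", d, (f"ring{li}", ra.name))

    return records


# ---------------------------------------------------------------------------
# aggregation

def lowest_energy_selection(
    poses_by_compound: Mapping[str, Sequence[ComplexPose]]
) -> dict:
    """Pick the lowest-score pose per compound; ties keep the earliest pose."""
    out = {}
    for cid, poses in poses_by_compound.items():
        scored = [(p.score, k) for k, p in enumerate(poses) if p.score is not None]
        if not scored:
            log.warning("compound %s has no scored pose; excluded", cid)
            continue
        best_score = min(s for s, _ in scored)
        best_idx = next(k for s, k in scored if s == best_score)
        if sum(1 for s, _ in scored if s == best_score) > 1:
            log.info("compound %s: tie at %.4f broken by input order", cid, best_score)
        out[cid] = poses[best_idx]
    return out


@dataclass
class PopulationMap:
    """Per-residue interaction tallies over a compound set."""

    counts: dict  # residue label -> record count
    total: int

    @property
    def percentages(self) -> dict:
        if self.total == 0:
            return {}
        return {k: round(100.0 * v / self.total, 1) for k, v in self.counts.items()}

    def most_common(self) -> list[tuple]:
        return sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))


def population_map(records: Iterable[InteractionRecord]) -> PopulationMap:
    """Count records per residue; percentages are 100·count/total, 1 decimal."""
    counts: dict = {}
    total = 0
    for rec in records:
        counts[rec.residue.label] = counts.get(rec.residue.label, 0) + 1
        total += 1
    return PopulationMap(counts=counts, total=total)


ARENE_KINDS = frozenset({"H-pi", "pi-H", "pi-pi"})
POLAR_KINDS = frozenset({"H-Donor", "H-Acceptor", "Ionic"})


def arene_vs_polar_summary(
    records_by_compound: Mapping[str, Sequence[InteractionRecord]],
    residues: Sequence[str],
) -> pd.DataFrame:
    """Per compound × residue: 'R' for any arene contact, '-' for none.

    Polar contacts are reported separately in ``<residue>_polar`` columns as
    a comma-joined kind list (empty when none).
    """
    rows = {}
    for cid, recs in records_by_compound.items():
        row = {}
        for res in residues:
            here = [r for r in recs if r.residue.label == res]
            row[res] = "R" if any(r.kind in ARENE_KINDS for r in here) else "-"
            polar = sorted({r.kind for r in here if r.kind in POLAR_KINDS})
            row[f"{res}_polar"] = ",".join(polar)
        rows[cid] = row
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# records CSV

RECORD_COLUMNS = [
    "compound_id", "pose_rank", "chain", "resnum", "resname", "kind", "distance_A",
]


def write_records_csv(records_by_compound: Mapping[str, Sequence[InteractionRecord]], path):
    rows = []
    for cid, recs in records_by_compound.items():
        for rec in recs:
            rows.append(
                {
                    "compound_id": cid,
                    "pose_rank": 0,
                    "chain": rec.residue.chain,
                    "resnum": rec.residue.number,
                    "resname": rec.residue.name,
                    "kind": rec.kind,
                    "distance_A": rec.distance,
                }
            )
    pd.DataFrame(rows, columns=RECORD_COLUMNS).to_csv(path, index=False)


def read_records_csv(path) -> dict:
    df = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"records CSV missing columns: {missing}")
    out: dict = {}
    for _, row in df.iterrows():
        rec = InteractionRecord(
            Residue(str(row["chain"]), int(row["resnum"]), str(row["resname"])),
            str(row["kind"]),
            float(row["distance_A"]),
            participants=("external", "external"),
        )
        out.setdefault(str(row["compound_id"]), []).append(rec)
    return out
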