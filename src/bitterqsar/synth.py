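"""Synthetic inputs emulating the study design, for testing every stage.

Three generators: descriptor tables with a planted linear
descriptor-to-score relationship buried among independent decoy columns
(the GA's search problem), random connected molecular graphs (Wiener-index
fixtures), and toy receptor-ligand complexes with prescribed contact
geometries (interaction-typing fixtures). All are pure functions of their
seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .chem import (
    Atom,
    Bond,
    ComplexPose,
    Molecule,
    ReceptorAtom,
    ReceptorStructure,
    write_pdb,
    write_sdf,
)
from .topo import DescriptorTable

log = logging.getLogger(__name__)

DEFAULT_COEFFICIENTS = {"vsurf_S": -0.01161, "wienerPath": 0.00007}
DEFAULT_INTERCEPT = -1.26777


@dataclass
class PlantedModelSpec:
    """Generative truth for a synthetic descriptor table.

    Defaults mirror the published model's constants and the study's scale:
    490 compounds, a 336-column pool, interaction-surface areas of
    150-1500 Å², Wiener numbers log-uniform over 50-60000 (the span implied
    by compounds from phenol to large oligomeric polyphenols), and noise
    calibrated so the population R² of the planted pair is ``target_r2``.
    """

    n: int = 490
    pool_width: int = 336
    intercept: float = DEFAULT_INTERCEPT
    coefficients: dict = field(default_factory=lambda: dict(DEFAULT_COEFFICIENTS))
    vsurf_range: tuple = (150.0, 1500.0)
    wiener_range: tuple = (50, 60000)
    noise_sd: Optional[float] = None  # derived from target_r2 when None
    target_r2: float = 0.93
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        unknown = set(self.coefficients) - {"vsurf_S", "wienerPath"}
        if unknown:
            raise ValueError(f"planted name(s) missing from the pool: {sorted(unknown)}")
        if self.pool_width < len(self.coefficients):
            raise ValueError("pool narrower than the planted descriptor set")

    def signal_variance(self) -> float:
        """Population variance of the planted linear combination."""
        a, b = self.vsurf_range
        var_v = (b - a) ** 2 / 12.0
        lo, hi = self.wiener_range
        lr = math.log(hi / lo)
        mean_w = (hi - lo) / lr
        m2_w = (hi**2 - lo**2) / (2.0 * lr)
        var_w = m2_w - mean_w**2
        cv = self.coefficients.get("vsurf_S", 0.0)
        cw = self.coefficients.get("wienerPath", 0.0)
        return cv**2 * var_v + cw**2 * var_w

    def effective_noise_sd(self) -> float:
        if self.noise_sd is not None:
            return self.noise_sd
        sig = self.signal_variance()
        return math.sqrt(sig * (1.0 - self.target_r2) / self.target_r2)

    def implied_population_r2(self) -> float:
        sig = self.signal_variance()
        return sig / (sig + self.effective_noise_sd() ** 2)


def gen_descriptor_table(spec: PlantedModelSpec) -> DescriptorTable:
    """Descriptor table with planted signal columns and independent decoys.

    The response S (kcal/mol) is the planted linear combination plus
    Gaussian noise; decoy columns are independent of S with heterogeneous
    scales. Deterministic per spec.seed; two seeds give different values but
    an identical column schema.
    """
    rng = np.random.default_rng(spec.seed)
    ids = [f"cmpd{k:04d}" for k in range(spec.n)]
    cols: dict = {}
    cols["vsurf_S"] = rng.uniform(*spec.vsurf_range, size=spec.n)
    lo, hi = spec.wiener_range
    cols["wienerPath"] = np.floor(
        np.exp(rng.uniform(math.log(lo), math.log(hi), size=spec.n))
    )
    n_decoys = spec.pool_width - len(cols)
    # heterogeneous decoy scales so no column is trivially recognisable
    scales = 10.0 ** rng.uniform(-1, 3, size=n_decoys)
    for k in range(n_decoys):
        cols[f"desc_{k:03d}"] = rng.normal(0.0, scales[k], size=spec.n)
    signal = spec.intercept + sum(
        coef * cols[name] for name, coef in spec.coefficients.items()
    )
    noise = rng.normal(0.0, spec.effective_noise_sd(), size=spec.n)
    df = pd.DataFrame(cols, index=pd.Index(ids, name="compound_id"))
    response = pd.Series(signal + noise, index=df.index, name="S")
    return DescriptorTable(df, response)


# ---------------------------------------------------------------------------
# random molecular graphs

def gen_random_molgraph(
    n_atoms: int,
    branch_prob: float = 0.0,
    seed: int = 0,
    ring_closures: int = 0,
) -> Molecule:
    """Random connected carbon skeleton: tree plus optional ring closures.

    ``branch_prob`` 0 gives a path graph; otherwise each new atom attaches
    to a uniformly chosen earlier atom (degree-capped at 4 so the all-carbon
    assignment stays valence-legal).
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    rng = np.random.default_rng(seed)
    edges: list[tuple] = []
    degree = [0] * n_atoms
    for i in range(1, n_atoms):
        if branch_prob > 0 and rng.random() < branch_prob:
            parent = int(rng.integers(0, i))
        else:
            parent = i - 1
        if degree[parent] >= 4:
            candidates = [j for j in range(i) if degree[j] < 4]
            parent = int(candidates[rng.integers(len(candidates))])
        edges.append((parent, i))
        degree[parent] += 1
        degree[i] += 1
    existing = {tuple(sorted(e)) for e in edges}
    attempts = 0
    added = 0
    while added < ring_closures and attempts < 50 * max(1, ring_closures):
        attempts += 1
        i, j = rng.integers(0, n_atoms, size=2)
        key = (min(int(i), int(j)), max(int(i), int(j)))
        if i == j or key in existing or degree[key[0]] >= 4 or degree[key[1]] >= 4:
            continue
        existing.add(key)
        edges.append(key)
        degree[key[0]] += 1
        degree[key[1]] += 1
        added += 1
    atoms = [Atom("C", n_hydrogens=4 - degree[k]) for k in range(n_atoms)]
    bonds = [Bond(i, j, 1) for i, j in edges]
    return Molecule(f"randmol_{seed}", atoms, bonds)


# ---------------------------------------------------------------------------
# toy receptor-ligand complexes

COMPLEX_KINDS = ("salt_bridge", "hbond", "pi_stack", "ch_pi", "none")


def _hexagon(radius: float = 1.39, z: float = 0.0) -> np.ndarray:
    ang = np.radians(np.arange(6) * 60.0)
    return np.stack(
        [radius * np.cos(ang), radius * np.sin(ang), np.full(6, z)], axis=1
    )


def _receptor(resname: str, resnum: int, atom_specs: list) -> ReceptorStructure:
    atoms = [
        ReceptorAtom(
            serial=k + 1,
            name=name,
            resname=resname,
            chain="A",
            resnum=resnum,
            element=name[0] if name[0] != "1" else name[1],
            pos=tuple(float(v) for v in pos),
        )
        for k, (name, pos) in enumerate(atom_specs)
    ]
    return ReceptorStructure(atoms=atoms)


def _glu_residue(resnum: int = 265) -> ReceptorStructure:
    # carboxylate in the z=0 plane: CD at origin, OE1/OE2 symmetric about x
    return _receptor(
        "GLU",
        resnum,
        [
            ("N", (-4.4, 2.4, 0.0)),
            ("CA", (-3.8, 1.2, 0.0)),
            ("C", (-4.5, 0.0, 0.0)),
            ("O", (-5.7, 0.0, 0.0)),
            ("CB", (-2.3, 1.2, 0.0)),
            ("CG", (-1.5, 0.0, 0.0)),
            ("CD", (0.0, 0.0, 0.0)),
            ("OE1", (1.0, 0.77, 0.0)),
            ("OE2", (1.0, -0.77, 0.0)),
        ],
    )


def _gly_residue(resnum: int = 180) -> ReceptorStructure:
    # backbone carbonyl oxygen at the origin, C=O pointing toward +x
    return _receptor(
        "GLY",
        resnum,
        [
            ("N", (-3.4, 1.2, 0.0)),
            ("CA", (-2.0, 1.2, 0.0)),
            ("C", (-1.23, 0.0, 0.0)),
            ("O", (0.0, 0.0, 0.0)),
        ],
    )


def _phe_residue(resnum: int = 252) -> ReceptorStructure:
    # aromatic ring centered on the origin in the z=0 plane
    ring = _hexagon()
    names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    specs = [(n, ring[k]) for k, n in enumerate(names)]
    specs += [
        ("CB", (2.89, 0.0, 0.0)),
        ("CA", (3.6, 1.3, 0.0)),
        ("N", (5.0, 1.3, 0.0)),
        ("C", (3.2, 2.7, 0.0)),
        ("O", (2.0, 3.0, 0.0)),
    ]
    return _receptor("PHE", resnum, specs)


def _methylammonium(origin_oe1: np.ndarray) -> Molecule:
    """CH3-NH3+ with N placed 3.24 Å from OE1 along the CD->OE1 axis."""
    direction = origin_oe1 / np.linalg.norm(origin_oe1)
    n_pos = origin_oe1 + 3.24 * direction
    h_inline = n_pos - 1.02 * direction  # N-H pointing straight at OE1
    perp = np.array([-direction[1], direction[0], 0.0])
    atoms = [
        Atom("N", formal_charge=1),
        Atom("C", n_hydrogens=3),
        Atom("H"),
        Atom("H"),
        Atom("H"),
    ]
    bonds = [Bond(0, 1, 1), Bond(0, 2, 1), Bond(0, 3, 1), Bond(0, 4, 1)]
    coords = np.array(
        [
            n_pos,
            n_pos + 1.5 * direction,
            h_inline,
            n_pos + 1.02 * (perp * 0.9 + np.array([0, 0, 0.44])),
            n_pos + 1.02 * (perp * -0.9 + np.array([0, 0, 0.44])),
        ]
    )
    return Molecule("methylammonium", atoms, bonds, coords)


def _methanol() -> Molecule:
    atoms = [Atom("O"), Atom("C", n_hydrogens=3), Atom("H")]
    bonds = [Bond(0, 1, 1), Bond(0, 2, 1)]
    coords = np.array([[2.9, 0.0, 0.0], [3.8, 1.1, 0.0], [1.9, 0.0, 0.0]])
    return Molecule("methanol", atoms, bonds, coords)


def _benzene(z: float) -> Molecule:
    atoms = [Atom("C", aromatic=True, n_hydrogens=1) for _ in range(6)]
    bonds = [Bond(k, (k + 1) % 6, "ar") for k in range(6)]
    return Molecule("benzene", atoms, bonds, _hexagon(z=z))


def _methane(pos) -> Molecule:
    return Molecule(
        "methane", [Atom("C", n_hydrogens=4)], [], np.array([pos], dtype=float)
    )


def gen_toy_complex(
    kind: str,
    jitter: float = 0.0,
    seed: int = 0,
    out_dir: Optional[Path] = None,
    score: float = -6.0,
) -> ComplexPose:
    """Minimal receptor-ligand complex realising one contact geometry.

    Kinds: ``salt_bridge`` (Glu carboxylate vs. methylammonium, in-line N-H:
    an H-Donor at 3.24 Å plus an Ionic contact), ``hbond`` (methanol O-H to
    a backbone carbonyl at 2.9 Å), ``pi_stack`` (benzene parallel over a
    Phe ring at 3.6 Å), ``ch_pi`` (methane C-H over the Phe ring at 3.8 Å)
    and ``none`` (ligand far outside every cutoff). ``jitter`` adds Gaussian
    positional noise (Å) to the ligand.
    """
    if kind not in COMPLEX_KINDS:
        raise ValueError(f"unknown complex kind {kind!r}; one of {COMPLEX_KINDS}")
    if kind == "salt_bridge":
        receptor = _glu_residue()
        ligand = _methylammonium(np.array([1.0, 0.77, 0.0]))
    elif kind == "hbond":
        receptor = _gly_residue()
        ligand = _methanol()
    elif kind == "pi_stack":
        receptor = _phe_residue()
        ligand = _benzene(z=3.6)
    elif kind == "ch_pi":
        receptor = _phe_residue()
        ligand = _methane((0.0, 0.0, 3.8))
    else:  # none
        receptor = _glu_residue()
        ligand = _methane((0.0, 0.0, 30.0))
    if jitter > 0:
        rng = np.random.default_rng(seed)
        ligand = ligand.with_coords(
            ligand.coords + rng.normal(0.0, jitter, size=ligand.coords.shape)
        )
    pose = ComplexPose(receptor=receptor, ligand=ligand, score=score)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_pdb(receptor, out_dir / f"{kind}_receptor.pdb")
        write_sdf([ligand], out_dir / f"{kind}_ligand.sdf", scores={ligand.id: score})
    return pose
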