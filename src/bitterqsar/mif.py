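"""Grid-based water-probe molecular interaction field and surface area.

The interaction-field surface area descriptor (``vsurf_S``) is the area of
an isoenergy surface of a water-probe field around the molecule. The field
is a sum over atoms of a Lennard-Jones 12-6 term (probe oxygen mixed with
per-element parameters) and a Coulomb term with Gasteiger partial charges
and a distance-dependent dielectric. The isosurface area is estimated by
counting grid-cell faces that straddle the level and calibrating away the
axis-aligned over-count.

This is a documented analogue of the commercial descriptor of the same
role: its absolute values are not comparable to any particular vendor's,
but its semantics — larger, branchier molecules expose a larger interaction
surface — are what the downstream regression model uses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from rdkit.Chem import AllChem

from .chem import Molecule, embed_3d, to_rdkit

log = logging.getLogger(__name__)

#: Face-counting over-counts an isotropically oriented smooth surface by the
#: spherical mean of |nx|+|ny|+|nz|, which is exactly 3/2; dividing raw face
#: area by this constant calibrates the estimator (validated on spheres).
FACE_CALIBRATION = 1.5

COULOMB_CONSTANT = 332.0637  # kcal·Å/(mol·e²)

#: per-element van der Waals radius (Å) and well depth (kcal/mol)
LJ_PARAMS = {
    "H": (1.20, 0.030),
    "C": (1.70, 0.105),
    "N": (1.55, 0.170),
    "O": (1.52, 0.210),
    "F": (1.47, 0.061),
    "P": (1.80, 0.200),
    "S": (1.80, 0.250),
    "Cl": (1.75, 0.265),
    "Br": (1.85, 0.320),
    "I": (1.98, 0.400),
    "B": (1.92, 0.180),
    "Se": (1.90, 0.290),
}


@dataclass
class WaterProbe:
    """OPLS-like water-oxygen probe."""

    radius: float = 1.52  # Å
    epsilon: float = 0.152  # kcal/mol
    charge: float = -0.66  # e, TIP3P-like oxygen partial charge


@dataclass
class GridField:
    """Regular scalar grid: energies in kcal/mol at nodes."""

    origin: np.ndarray  # (3,) Å
    spacing: float  # Å
    dims: tuple  # (nx, ny, nz)
    values: Optional[np.ndarray] = None  # shape dims

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        if self.spacing <= 0:
            raise ValueError(f"grid spacing must be positive, got {self.spacing}")
        if any(d < 2 for d in self.dims):
            raise ValueError(f"grid dims must be >= 2 per axis, got {self.dims}")

    def node_positions(self) -> np.ndarray:
        """All node coordinates, shape (nx*ny*nz, 3), x fastest last axis."""
        ax = [self.origin[k] + self.spacing * np.arange(self.dims[k]) for k in range(3)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        return np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    def save_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "# origin %r spacing %r dims %d %d %d\n"
                % (list(self.origin), self.spacing, *self.dims)
            )
            np.savetxt(fh, self.values.ravel())


def build_grid(mol: Molecule, spacing: float = 0.5, padding: float = 4.0) -> GridField:
    """Axis-aligned bounding-box grid around the molecule plus padding."""
    if mol.coords is None:
        raise ValueError(f"molecule {mol.id!r} has no coordinates")
    lo = mol.coords.min(axis=0) - padding
    hi = mol.coords.max(axis=0) + padding
    if spacing <= 0:
        raise ValueError(f"grid spacing must be positive, got {spacing}")
    dims = tuple(int(np.ceil((hi[k] - lo[k]) / spacing - 1e-9)) + 1 for k in range(3))
    # center the (ceil-expanded) node lattice on the box so a symmetric
    # molecule gets a symmetric grid
    center = (lo + hi) / 2.0
    origin = center - spacing * (np.array(dims) - 1) / 2.0
    return GridField(origin=origin, spacing=spacing, dims=dims)


def gasteiger_charges(mol: Molecule) -> Optional[np.ndarray]:
    """Gasteiger partial charges per atom, or None if they cannot be assigned."""
    try:
        rd = to_rdkit(mol)
        AllChem.ComputeGasteigerCharges(rd)
        # fold implicit-H charges into their heavy atom (united-atom view);
        # otherwise a neutral molecule acquires a spurious net monopole
        q = np.array(
            [
                float(a.GetProp("_GasteigerCharge"))
                + float(a.GetProp("_GasteigerHCharge"))
                for a in rd.GetAtoms()
            ]
        )
        if not np.all(np.isfinite(q)):
            return None
        return q
    except Exception:
        return None


def water_probe_field(
    mol: Molecule,
    grid: GridField,
    probe: Optional[WaterProbe] = None,
    charges: Optional[np.ndarray] = None,
    chunk: int = 200_000,
) -> GridField:
    """Populate the grid with the water-probe interaction energy.

    ``charges``: per-atom partial charges; if None, Gasteiger charges are
    computed, and if that fails the Coulomb term is dropped (pure steric
    field) with a warning.
    """
    if mol.coords is None:
        raise ValueError(f"molecule {mol.id!r} has no coordinates")
    probe = probe or WaterProbe()
    if charges is None:
        charges = gasteiger_charges(mol)
        if charges is None:
            log.warning(
                "no partial charges for %s; using a pure steric field", mol.id
            )
            charges = np.zeros(mol.n_atoms)
    charges = np.asarray(charges, dtype=float)

    rmin = np.empty(mol.n_atoms)
    eps = np.empty(mol.n_atoms)
    for k, a in enumerate(mol.atoms):
        r_a, e_a = LJ_PARAMS.get(a.element, LJ_PARAMS["C"])
        rmin[k] = r_a + probe.radius  # Lorentz combined minimum-energy distance
        eps[k] = np.sqrt(e_a * probe.epsilon)  # Berthelot mixing

    nodes = grid.node_positions()
    values = np.empty(nodes.shape[0])
    for start in range(0, nodes.shape[0], chunk):
        block = nodes[start : start + chunk]
        d = np.linalg.norm(block[:, None, :] - mol.coords[None, :, :], axis=2)
        np.maximum(d, 0.05, out=d)  # finite (huge) repulsion at atomic centers
        s6 = (rmin[None, :] / d) ** 6
        e_lj = eps[None, :] * (s6 * s6 - 2.0 * s6)
        # distance-dependent dielectric eps(r) = 4r -> 1/(4 r^2) screening
        e_coul = COULOMB_CONSTANT * charges[None, :] * probe.charge / (4.0 * d * d)
        values[start : start + chunk] = (e_lj + e_coul).sum(axis=1)
    return GridField(grid.origin, grid.spacing, grid.dims, values.reshape(grid.dims))


def interaction_surface_area(field: GridField, iso_level: float) -> float:
    """Area (Å²) of the iso_level isosurface by calibrated face counting.

    Counts faces between adjacent nodes whose values straddle the level;
    each face contributes spacing²; the total is divided by the 3/2
    axis-aligned over-count. Returns 0 (with a warning) when the level lies
    outside the field's range.
    """
    if field.values is None:
        raise ValueError("field has no values")
    v = field.values
    if iso_level <= v.min() or iso_level >= v.max():
        log.warning(
            "iso level %g outside field range [%g, %g]", iso_level, v.min(), v.max()
        )
        return 0.0
    inside = v > iso_level
    faces = 0
    for axis in range(3):
        a = np.swapaxes(inside, 0, axis)
        faces += int(np.count_nonzero(a[1:] != a[:-1]))
    return faces * field.spacing**2 / FACE_CALIBRATION


def vsurf_s(
    mol: Molecule,
    iso_level: float = 0.2,
    spacing: float = 0.5,
    padding: float = 4.0,
    seed: int = 1,
    probe: Optional[WaterProbe] = None,
) -> float:
    """Interaction-field surface area (Å²) of one molecule.

    Embeds a single conformer when the molecule carries no coordinates
    (fixed seed; no conformational averaging), builds the water-probe field
    and measures the isosurface at ``iso_level`` kcal/mol.
    """
    if mol.coords is None:
        mol = embed_3d(mol, seed=seed)
    grid = build_grid(mol, spacing=spacing, padding=padding)
    field = water_probe_field(mol, grid, probe=probe)
    return interaction_surface_area(field, iso_level)
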