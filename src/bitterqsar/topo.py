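"""Topological and compositional molecular descriptors.

The two descriptors that carry the published structure-activity model are
``wienerPath`` — the Wiener path number, half the sum of all entries of the
heavy-atom topological distance matrix — and molecular weight on a pinned
atomic-weight table that reproduces printed two-decimal values. Around them
sits a configurable descriptor pool that pads a small built-in set with
deterministic derived columns up to a target width, emulating the wide
descriptor tables that feed genetic-algorithm model selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .chem import Molecule

log = logging.getLogger(__name__)

#: Pinned standard atomic weights (g/mol). Versioned: changing these changes
#: every MW output, so they are part of the package's reproducibility contract.
ATOMIC_WEIGHTS = {
    "H": 1.00794,
    "B": 10.811,
    "C": 12.0107,
    "N": 14.0067,
    "O": 15.9994,
    "F": 18.9984032,
    "P": 30.973762,
    "S": 32.065,
    "Cl": 35.453,
    "Se": 78.96,
    "Br": 79.904,
    "I": 126.90447,
}

RESPONSE_COLUMN = "S"


class DisconnectedGraphError(ValueError):
    pass


def _heavy_graph(mol: Molecule) -> nx.Graph:
    g = nx.Graph()
    heavy = mol.heavy_indices()
    g.add_nodes_from(heavy)
    hset = set(heavy)
    for b in mol.bonds:
        if b.i in hset and b.j in hset:
            g.add_edge(b.i, b.j)
    return g


def wiener_path(mol: Molecule, allow_disconnected: bool = False) -> int:
    """Wiener path number: half the sum of the topological distance matrix.

    Distances are shortest-path bond counts on the heavy-atom graph with unit
    edge lengths regardless of bond order. A disconnected graph raises unless
    ``allow_disconnected`` is set, in which case components are summed —
    infinite distances are never silently produced.
    """
    g = _heavy_graph(mol)
    if g.number_of_nodes() <= 1:
        return 0
    if not nx.is_connected(g):
        if not allow_disconnected:
            raise DisconnectedGraphError(
                f"heavy-atom graph of {mol.id!r} is disconnected"
            )
        return sum(
            wiener_path_of_graph(g.subgraph(c)) for c in nx.connected_components(g)
        )
    return wiener_path_of_graph(g)


def wiener_path_of_graph(g: nx.Graph) -> int:
    total = 0
    for _, dists in nx.all_pairs_shortest_path_length(g):
        total += sum(dists.values())
    return total // 2


def molecular_weight(mol: Molecule) -> float:
    """Molecular weight in g/mol, implicit hydrogens included."""
    total = 0.0
    for a in mol.atoms:
        try:
            total += ATOMIC_WEIGHTS[a.element]
        except KeyError:
            raise ValueError(
                f"no atomic weight for element {a.element!r} in {mol.id!r}"
            )
        total += a.n_hydrogens * ATOMIC_WEIGHTS["H"]
    return total


def _ring_count(mol: Molecule) -> int:
    # cycle rank of the heavy-atom graph
    g = _heavy_graph(mol)
    return g.number_of_edges() - g.number_of_nodes() + nx.number_connected_components(g)


def aromatic_rings(mol: Molecule) -> list[list[int]]:
    """Rings (from a cycle basis) whose atoms are all flagged aromatic."""
    g = _heavy_graph(mol)
    rings = []
    for cycle in nx.minimum_cycle_basis(g):
        if all(mol.atoms[i].aromatic for i in cycle):
            rings.append(sorted(cycle))
    return rings


def _hbond_donor_count(mol: Molecule) -> int:
    n = 0
    for k, a in enumerate(mol.atoms):
        if a.element in ("N", "O", "S"):
            nh = a.n_hydrogens + sum(
                1 for j in mol.neighbors(k) if mol.atoms[j].element == "H"
            )
            if nh > 0:
                n += 1
    return n


def _hbond_acceptor_count(mol: Molecule) -> int:
    return sum(1 for a in mol.atoms if a.element in ("N", "O"))


def _zagreb(mol: Molecule) -> tuple[int, int]:
    g = _heavy_graph(mol)
    deg = dict(g.degree())
    m1 = sum(d * d for d in deg.values())
    m2 = sum(deg[u] * deg[v] for u, v in g.edges())
    return m1, m2


#: name -> callable computing one built-in descriptor
BUILTIN_DESCRIPTORS = {
    "heavy_atoms": lambda m: m.n_heavy_atoms,
    "h_count": lambda m: m.total_hydrogens(),
    "ring_count": _ring_count,
    "aromatic_ring_count": lambda m: len(aromatic_rings(m)),
    "hbd_count": _hbond_donor_count,
    "hba_count": _hbond_acceptor_count,
    "zagreb_m1": lambda m: _zagreb(m)[0],
    "zagreb_m2": lambda m: _zagreb(m)[1],
    "wienerPath": wiener_path,
    "MW": molecular_weight,
    "branch_count": lambda m: sum(
        1 for i in m.heavy_indices() if len(m.neighbors(i)) >= 3
    ),
}


@dataclass
class PoolConfig:
    """Configuration of the descriptor pool.

    ``width`` pads the built-in set with deterministic derived columns
    (smooth nonlinear combinations of built-ins, seeded by column index) so
    that descriptor-selection experiments face a realistically wide table.
    """

    width: int = 336
    extra: dict = field(default_factory=dict)  # name -> callable(Molecule)


@dataclass(frozen=True)
class DescriptorVector:
    compound_id: str
    values: dict

    def __post_init__(self):
        for k, v in self.values.items():
            if v is None or (isinstance(v, float) and np.isnan(v)):
                raise ValueError(f"NaN descriptor {k!r} for {self.compound_id!r}")


def descriptor_pool(mol: Molecule, config: Optional[PoolConfig] = None) -> DescriptorVector:
    """Compute the configured descriptor pool for one molecule.

    A descriptor that fails is omitted (and logged); the row survives.
    """
    config = config or PoolConfig()
    values: dict = {}
    calcs = dict(BUILTIN_DESCRIPTORS)
    calcs.update(config.extra)
    for name, fn in calcs.items():
        try:
            values[name] = float(fn(mol))
        except Exception as exc:  # descriptor-level failure only
            log.warning("descriptor %s failed for %s: %s", name, mol.id, exc)
    base_names = sorted(values)
    n_pad = max(0, config.width - len(values))
    base = np.array([values[k] for k in base_names], dtype=float)
    for k in range(n_pad):
        rng = np.random.default_rng(k)
        i, j = rng.integers(0, len(base), size=2)
        a, b = rng.normal(size=2)
        kind = rng.integers(0, 3)
        x = a * base[i] + b * base[j]
        if kind == 1:
            x = np.log1p(abs(x))
        elif kind == 2:
            x = np.sqrt(abs(x))
        values[f"pool_{k:03d}"] = float(x)
    return DescriptorVector(mol.id, values)


@dataclass
class DescriptorTable:
    """Named descriptors per compound, optionally with the response score S.

    Backed by a DataFrame indexed by compound id; the response is the docking
    binding-energy score in kcal/mol when present.
    """

    data: pd.DataFrame
    response: Optional[pd.Series] = None
    response_name: str = RESPONSE_COLUMN

    def __post_init__(self):
        if self.response is not None:
            self.response = self.response.reindex(self.data.index)
            if self.response.isna().any():
                missing = list(self.response.index[self.response.isna()])
                raise ValueError(f"response missing for compounds {missing[:5]}")

    @classmethod
    def from_vectors(
        cls,
        vectors: Sequence[DescriptorVector],
        response: Optional[dict] = None,
    ) -> "DescriptorTable":
        """Assemble rows on the intersection of descriptor names (inner join)."""
        if not vectors:
            raise ValueError("no descriptor vectors")
        common = set(vectors[0].values)
        for v in vectors[1:]:
            common &= set(v.values)
        dropped = set().union(*(set(v.values) for v in vectors)) - common
        if dropped:
            log.warning("dropping %d descriptors absent in some rows", len(dropped))
        cols = sorted(common)
        df = pd.DataFrame(
            [[v.values[c] for c in cols] for v in vectors],
            index=pd.Index([v.compound_id for v in vectors], name="compound_id"),
            columns=cols,
        )
        resp = None
        if response is not None:
            resp = pd.Series(response, name=RESPONSE_COLUMN)
        return cls(df, resp)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.data.columns)

    def restrict(self, names: Sequence[str]) -> pd.DataFrame:
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise KeyError(f"missing descriptor columns: {missing}")
        return self.data[list(names)]

    def to_csv(self, path) -> None:
        out = self.data.copy()
        if self.response is not None:
            out[self.response_name] = self.response
        out.to_csv(path, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, response: Optional[str] = None) -> "DescriptorTable":
        df = pd.read_csv(path, index_col="compound_id", float_precision="round_trip")
        resp = None
        if response is not None:
            if response not in df.columns:
                raise ValueError(
                    f"missing required column(s): [{response!r}] in {path}"
                )
            resp = df.pop(response)
        elif RESPONSE_COLUMN in df.columns:
            resp = df.pop(RESPONSE_COLUMN)
        return cls(df, resp)
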