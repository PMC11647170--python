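"""QSAR model fitting, validation, and genetic-algorithm descriptor selection.

The workflow mirrors evolutionary QSAR tools: a wide descriptor table and a
docking binding-energy score S per compound come in; a genetic algorithm
searches descriptor subsets, each scored by ordinary least squares on a
training split; the winning model is validated on the held-out split and by
leave-one-out cross-validation (q²). The published two-descriptor model

    S = -1.26777 - 0.01161 * vsurf_S + 0.00007 * wienerPath   (kcal/mol)

is also shipped as a frozen predictor whose coefficients are never refit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .topo import DescriptorTable

log = logging.getLogger(__name__)

PUBLISHED_INTERCEPT = -1.26777
PUBLISHED_COEFFICIENTS = {"vsurf_S": -0.01161, "wienerPath": 0.00007}
#: fit statistics reported for the published model (documentation only)
PUBLISHED_STATS = {"r2": 0.9359, "q2": 0.9003}


class RankDeficientError(np.linalg.LinAlgError):
    pass


@dataclass
class QsarModel:
    """Linear QSAR model: intercept plus named descriptor coefficients."""

    intercept: float
    coefficients: dict
    stats: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        for key in ("r2", "q2"):
            v = self.stats.get(key)
            if v is not None and v > 1.0 + 1e-12:
                raise ValueError(f"{key} = {v} exceeds 1")

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.coefficients)

    def predict(self, data) -> pd.Series:
        """Predict S for a DataFrame (or DescriptorTable) of descriptors."""
        if isinstance(data, DescriptorTable):
            data = data.data
        missing = [c for c in self.coefficients if c not in data.columns]
        if missing:
            raise KeyError(f"missing descriptor columns: {missing}")
        yhat = pd.Series(self.intercept, index=data.index, dtype=float)
        for name, coef in self.coefficients.items():
            yhat += coef * data[name].astype(float)
        return yhat

    def to_json(self, path=None) -> str:
        payload = {
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "stats": dict(self.stats),
            "provenance": dict(self.provenance),
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "QsarModel":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                payload = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    payload = json.load(fh)
        return cls(
            intercept=float(payload["intercept"]),
            coefficients={k: float(v) for k, v in payload["coefficients"].items()},
            stats=payload.get("stats", {}),
            provenance=payload.get("provenance", {}),
        )


def published_model() -> QsarModel:
    return QsarModel(
        intercept=PUBLISHED_INTERCEPT,
        coefficients=dict(PUBLISHED_COEFFICIENTS),
        stats=dict(PUBLISHED_STATS),
        provenance={"source": "published two-descriptor model (frozen constants)"},
    )


def published_model_predict(vsurf_s: float, wiener_path: float) -> float:
    """Frozen published predictor; the constants are never refit."""
    if not (np.isfinite(vsurf_s) and np.isfinite(wiener_path)):
        raise ValueError("descriptor inputs must be finite")
    return (
        PUBLISHED_INTERCEPT
        + PUBLISHED_COEFFICIENTS["vsurf_S"] * vsurf_s
        + PUBLISHED_COEFFICIENTS["wienerPath"] * wiener_path
    )


# ---------------------------------------------------------------------------
# splitting

@dataclass(frozen=True)
class SplitSpec:
    seed: int = 0
    train_fraction: float = 0.8

    def __post_init__(self):
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError(f"train_fraction must be in (0,1), got {self.train_fraction}")


def split_train_test(ids: Sequence[str], spec: SplitSpec) -> tuple[list, list]:
    """Random disjoint train/test partition, |train| = round(fraction·n)."""
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValueError("compound ids must be unique")
    n = len(ids)
    if n < 2:
        raise ValueError(f"need at least 2 compounds to split, got {n}")
    n_train = int(np.floor(spec.train_fraction * n + 0.5))
    n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(spec.seed).permutation(n)
    train = [ids[k] for k in perm[:n_train]]
    test = [ids[k] for k in perm[n_train:]]
    return train, test


# ---------------------------------------------------------------------------
# OLS

def _design(table: DescriptorTable, subset: Sequence[str], response) -> tuple:
    X = table.restrict(subset).to_numpy(dtype=float)
    if response is None:
        response = table.response
    if response is None:
        raise ValueError("no response available")
    y = response.reindex(table.data.index).to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing values in descriptor subset")
    if np.isnan(y).any():
        raise ValueError("missing values in response")
    return X, y


def _name_collinear(table: DescriptorTable, subset: Sequence[str]) -> list[str]:
    X = table.restrict(subset).to_numpy(dtype=float)
    Xa = np.column_stack([np.ones(len(X)), X])
    full_rank = np.linalg.matrix_rank(Xa)
    bad = []
    for k, name in enumerate(subset):
        reduced = np.delete(Xa, k + 1, axis=1)
        if np.linalg.matrix_rank(reduced) == full_rank:
            bad.append(name)
    return bad


def fit_ols(
    table: DescriptorTable,
    subset: Sequence[str],
    response: Optional[pd.Series] = None,
) -> QsarModel:
    """Ordinary least squares of the response on a descriptor subset.

    Degenerate conventions: a constant response yields all-zero coefficients
    with R² defined as 0; a rank-deficient design raises, naming the
    redundant columns.
    """
    subset = list(subset)
    X, y = _design(table, subset, response)
    n, k = X.shape
    if n < k + 2:
        raise ValueError(f"need n >= k+2 observations (n={n}, k={k})")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        log.info("constant response: returning the zero model with r2 = 0")
        return QsarModel(
            intercept=float(y.mean()),
            coefficients={name: 0.0 for name in subset},
            stats={"r2": 0.0, "n_train": n},
        )
    Xa = np.column_stack([np.ones(n), X])
    beta, _, rank, _ = np.linalg.lstsq(Xa, y, rcond=None)
    if rank < k + 1:
        bad = _name_collinear(table, subset)
        raise RankDeficientError(f"rank-deficient design; collinear columns: {bad}")
    resid = y - Xa @ beta
    r2 = 1.0 - float(resid @ resid) / sst
    return QsarModel(
        intercept=float(beta[0]),
        coefficients={name: float(b) for name, b in zip(subset, beta[1:])},
        stats={"r2": r2, "n_train": n},
    )


def r_squared(
    model: QsarModel,
    table: DescriptorTable,
    response: Optional[pd.Series] = None,
) -> float:
    """Coefficient of determination of the model on an evaluation set."""
    if response is None:
        response = table.response
    y = response.reindex(table.data.index).to_numpy(dtype=float)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("zero-variance response: R² undefined")
    yhat = model.predict(table).to_numpy()
    return 1.0 - float(np.sum((y - yhat) ** 2)) / sst


def loo_q2(
    table: DescriptorTable,
    response: Optional[pd.Series] = None,
    subset: Optional[Sequence[str]] = None,
) -> float:
    """Leave-one-out cross-validated R² for a fixed descriptor subset.

    Uses the PRESS identity e_i/(1-h_ii), which equals refitting the OLS
    model n times with one observation removed; the descriptor subset itself
    is held fixed across folds (selection is not repeated per fold).
    """
    subset = list(subset) if subset is not None else table.descriptor_names
    X, y = _design(table, subset, response)
    n, k = X.shape
    if n < k + 3:
        raise ValueError(f"need n >= k+3 observations for LOO (n={n}, k={k})")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("zero-variance response: q² undefined")
    Xa = np.column_stack([np.ones(n), X])
    gram = Xa.T @ Xa
    try:
        ginv = np.linalg.inv(gram)
    except np.linalg.LinAlgError:
        bad = _name_collinear(table, subset)
        raise RankDeficientError(f"rank-deficient design; collinear columns: {bad}")
    beta = ginv @ (Xa.T @ y)
    resid = y - Xa @ beta
    h = np.einsum("ij,jk,ik->i", Xa, ginv, Xa)
    denom = 1.0 - h
    if np.any(denom <= 1e-12):
        raise ValueError("leverage 1 observation: LOO prediction undefined")
    press = float(np.sum((resid / denom) ** 2))
    return 1.0 - press / sst


# ---------------------------------------------------------------------------
# genetic algorithm

@dataclass
class GAConfig:
    """Settings of the descriptor-selection genetic algorithm.

    Fitness is the training-set R² minus ``parsimony_penalty`` per selected
    descriptor, so an extra column must explain more variance than the
    penalty to survive.
    """

    population_size: int = 100
    generations: int = 200
    crossover_rate: float = 0.8
    mutation_rate: float = 0.01  # per bit
    max_descriptors: int = 4
    parsimony_penalty: float = 0.01
    elitism: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.max_descriptors < 1:
            raise ValueError("max_descriptors must be >= 1")


class _FastSubsetOLS:
    """Centered-Gram OLS for scoring many small subsets of one big table."""

    def __init__(self, X: np.ndarray, y: np.ndarray):
        self.n = X.shape[0]
        self.xmean = X.mean(axis=0)
        self.ymean = y.mean()
        Xc = X - self.xmean
        yc = y - self.ymean
        self.gram = Xc.T @ Xc
        self.gy = Xc.T @ yc
        self.sst = float(yc @ yc)

    def r2(self, idx: tuple) -> float:
        if self.sst == 0.0:
            return 0.0
        g = self.gram[np.ix_(idx, idx)]
        gy = self.gy[list(idx)]
        try:
            beta = np.linalg.solve(g, gy)
        except np.linalg.LinAlgError:
            return -np.inf
        return float(beta @ gy) / self.sst


def ga_evolve(
    table: DescriptorTable,
    response: Optional[pd.Series] = None,
    ga: Optional[GAConfig] = None,
    split: Optional[SplitSpec] = None,
) -> QsarModel:
    """Evolve a descriptor subset and return its validated OLS model.

    Chromosomes are descriptor subsets (bit vectors capped at
    ``max_descriptors``); fitness is training-set R² with a parsimony
    penalty; tournament selection, one-point crossover, per-bit mutation,
    and elitism drive the search. The returned model is fit on the training
    split and carries train R², held-out test R², all-data R², and LOO q²
    (subset fixed) in its stats. Fully reproducible per seed.
    """
    ga = ga or GAConfig()
    split = split or SplitSpec(seed=ga.seed)
    names = table.descriptor_names
    p = len(names)
    if p < ga.max_descriptors:
        raise ValueError(f"pool width {p} smaller than max_descriptors {ga.max_descriptors}")

    X, y = _design(table, names, response)
    if np.all(X.std(axis=0) == 0):
        raise ValueError("no feasible model: all descriptor columns are constant")

    ids = table.compound_ids
    train_ids, test_ids = split_train_test(ids, split)
    pos = {cid: k for k, cid in enumerate(ids)}
    tr = np.array([pos[c] for c in train_ids])
    te = np.array([pos[c] for c in test_ids])
    solver = _FastSubsetOLS(X[tr], y[tr])

    rng = np.random.default_rng(ga.seed)
    cache: dict = {}

    def fitness(subset: tuple) -> float:
        if subset not in cache:
            cache[subset] = solver.r2(subset) - ga.parsimony_penalty * len(subset)
        return cache[subset]

    def repair(bits: np.ndarray) -> tuple:
        # Per-bit mutation adds far more bits than it removes (most bits are
        # off), so children pile up at the size cap. Re-sampling the target
        # size uniformly in [1, max] keeps small subsets in the population,
        # letting the parsimony penalty actually select for them.
        on = np.flatnonzero(bits)
        if len(on) == 0:
            on = np.array([rng.integers(p)])
        elif len(on) > ga.max_descriptors:
            size = int(rng.integers(1, ga.max_descriptors + 1))
            on = rng.choice(on, size=size, replace=False)
        return tuple(sorted(int(i) for i in on))

    # initial population: random subsets of size 1..max_descriptors
    population = []
    for _ in range(ga.population_size):
        size = int(rng.integers(1, ga.max_descriptors + 1))
        population.append(tuple(sorted(rng.choice(p, size=size, replace=False).tolist())))

    best = max(population, key=fitness)
    for _ in range(ga.generations):
        scores = np.array([fitness(c) for c in population])
        new_pop = [best]  # elitism
        while len(new_pop) < ga.population_size:
            # tournament selection, size 2
            a, b = rng.integers(ga.population_size, size=2)
            p1 = population[a] if scores[a] >= scores[b] else population[b]
            a, b = rng.integers(ga.population_size, size=2)
            p2 = population[a] if scores[a] >= scores[b] else population[b]
            b1 = np.zeros(p, dtype=bool)
            b1[list(p1)] = True
            b2 = np.zeros(p, dtype=bool)
            b2[list(p2)] = True
            if rng.random() < ga.crossover_rate:
                cut = int(rng.integers(1, p))
                child = np.concatenate([b1[:cut], b2[cut:]])
            else:
                child = b1.copy()
            flip = rng.random(p) < ga.mutation_rate
            child ^= flip
            new_pop.append(repair(child))
        population = new_pop
        gen_best = max(population, key=fitness)
        if fitness(gen_best) > fitness(best):
            best = gen_best

    subset_names = [names[i] for i in best]
    resp = response if response is not None else table.response
    train_table = DescriptorTable(
        table.data.loc[train_ids], resp.reindex(train_ids)
    )
    test_table = DescriptorTable(table.data.loc[test_ids], resp.reindex(test_ids))
    model = fit_ols(train_table, subset_names)
    model.stats.update(
        {
            "q2": loo_q2(table, resp, subset_names),
            "n_train": len(train_ids),
            "n_test": len(test_ids),
            "test_r2": r_squared(model, test_table),
            "r2_all": r_squared(model, table, resp),
        }
    )
    model.provenance.update(
        {
            "method": "ga_evolve",
            "seed": ga.seed,
            "generations": ga.generations,
            "population_size": ga.population_size,
        }
    )
    return model
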