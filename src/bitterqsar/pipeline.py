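"""Orchestration of the descriptor → split → GA → validation workflow."""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .chem import read_smiles_file
from .mif import vsurf_s
from .qsar import GAConfig, SplitSpec, ga_evolve, split_train_test
from .synth import PlantedModelSpec, gen_descriptor_table
from .topo import DescriptorTable, PoolConfig, descriptor_pool

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the one global seed (stable hash)."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


@dataclass
class PipelineConfig:
    """One config object drives the whole run; one global seed derives all
    stage seeds deterministically."""

    seed: int = 0
    out_dir: str = "bitterqsar_out"
    # inputs: either synthetic (default) or SMILES + response CSV
    synthetic: bool = True
    n_compounds: int = 490
    smiles_path: Optional[str] = None
    response_path: Optional[str] = None
    response_column: str = "S"
    # descriptors
    pool_width: int = 336
    compute_mif: bool = False
    mif_iso: float = 0.2
    mif_spacing: float = 0.5
    # model selection
    train_fraction: float = 0.8
    ga: GAConfig = field(default_factory=GAConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        ga = GAConfig(**raw.pop("ga", {}))
        return cls(ga=ga, **raw)


def _build_table(config: PipelineConfig) -> DescriptorTable:
    if config.synthetic:
        spec = PlantedModelSpec(
            n=config.n_compounds,
            pool_width=config.pool_width,
            seed=stage_seed(config.seed, "table"),
        )
        return gen_descriptor_table(spec)
    if not config.smiles_path or not config.response_path:
        raise ValueError("file mode needs smiles_path and response_path")
    mols = read_smiles_file(config.smiles_path)
    resp_df = pd.read_csv(config.response_path, index_col="compound_id")
    if config.response_column not in resp_df.columns:
        raise ValueError(
            f"missing response column {config.response_column!r} in {config.response_path}"
        )
    vectors = [descriptor_pool(m, PoolConfig(width=config.pool_width)) for m in mols]
    from .topo import DescriptorVector  # local to avoid unused at module level

    if config.compute_mif:
        embed_seed = stage_seed(config.seed, "embed")
        vectors = [
            DescriptorVector(
                v.compound_id,
                {**v.values, "vsurf_S": vsurf_s(
                    m, iso_level=config.mif_iso, spacing=config.mif_spacing,
                    seed=embed_seed,
                )},
            )
            for v, m in zip(vectors, mols)
        ]
    response = resp_df[config.response_column].to_dict()
    missing = [v.compound_id for v in vectors if v.compound_id not in response]
    if missing:
        raise ValueError(f"no response for compounds {missing[:5]}")
    return DescriptorTable.from_vectors(
        vectors, {v.compound_id: response[v.compound_id] for v in vectors}
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run descriptors → split → GA → validation; write model and reports.

    Returns a report dict with the fit statistics; artifacts (model JSON,
    prediction CSV with train/test labels, run log) land in out_dir. A
    stage failure raises :class:`PipelineError` naming the stage; partial
    outputs are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    table = stage("descriptors", _build_table, config)

    ga = GAConfig(**{**config.ga.__dict__, "seed": stage_seed(config.seed, "ga")})
    split = SplitSpec(
        seed=stage_seed(config.seed, "split"), train_fraction=config.train_fraction
    )
    model = stage("ga", ga_evolve, table, None, ga, split)

    yhat = model.predict(table)
    train_ids, _ = stage("split", split_train_test, table.compound_ids, split)
    pred = pd.DataFrame(
        {
            "S": table.response,
            "S_pred": yhat,
            "set": ["train" if c in set(train_ids) else "test" for c in table.compound_ids],
        }
    )
    model_path = out / "model.json"
    model.to_json(model_path)
    pred.to_csv(out / "predictions.csv", float_format="%.17g")
    table.to_csv(out / "table.csv")

    report = {
        "r2_all": model.stats["r2_all"],
        "r2_train": model.stats["r2"],
        "r2_test": model.stats["test_r2"],
        "q2": model.stats["q2"],
        "n_train": model.stats["n_train"],
        "n_test": model.stats["n_test"],
        "descriptors": model.descriptor_names,
        "model_path": str(model_path),
    }
    with open(out / "run.log", "w") as fh:
        fh.write(f"bitterqsar {__version__}\n")
        fh.write(f"started {time.strftime('%Y-%m-%dT%H:%M:%S')}\n")
        fh.write(f"elapsed_s {time.time() - t0:.2f}\n")
        fh.write(f"global_seed {config.seed}\n")
        for name in ("table", "split", "ga", "embed"):
            fh.write(f"seed[{name}] {stage_seed(config.seed, name)}\n")
        for k, v in report.items():
            fh.write(f"{k} {v}\n")
    return report


def rank_report(scores, k: int = 10, mw: Optional[dict] = None) -> pd.DataFrame:
    """Top-k and bottom-k compounds by binding-energy score.

    Ascending order: the most negative score ranks first (strongest
    predicted binder). Ties break lexicographically by compound id; k larger
    than the compound count is clamped with a warning.
    """
    s = pd.Series(scores, dtype=float)
    if k > len(s):
        log.warning("k=%d clamped to %d compounds", k, len(s))
        k = len(s)
    order = s.reset_index()
    order.columns = ["compound_id", "S"]
    order = order.sort_values(["S", "compound_id"]).reset_index(drop=True)
    top = order.head(k).assign(group="top")
    bottom = order.tail(k).assign(group="bottom")
    result = pd.concat([top, bottom], ignore_index=True)
    if mw is not None:
        result.insert(1, "MW", result["compound_id"].map(mw))
    return result
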