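"""End-to-end orchestration of the modelling workflow.

One config drives the sequence: load/curate (or synthesize) the dataset,
compute descriptors, prune them (OFS), split train/external, optionally
scan the subset size, run the GA-MLR search, fit and validate the best
model, and persist every stage's inputs, outputs and seeds into an
append-only run directory.  Re-running the same config reproduces the
artifacts byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import curation, descriptors, selection, synthetic, validation
from .chem import parse_molecule

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """The pipeline configuration is inconsistent or incomplete."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Everything one run needs; seeds are recorded in every output."""

    output_dir: str = "run"
    input_csv: str | None = None          # columns: mol_id, smiles, ki_nM
    charge_source: str = "auto"
    synthetic_spec: synthetic.SyntheticSpec | None = None
    ofs: selection.OFSConfig = field(default_factory=selection.OFSConfig)
    ga: selection.GAConfig = field(default_factory=selection.GAConfig)
    split_seed: int = 0
    train_fraction: float = 0.8
    split_sizes: tuple[int, int] | None = None
    scan_k_max: int = 0                   # 0 = skip the size scan
    elevation_min_gain: float = 0.01
    lmo_fraction: float = 0.2
    lmo_repeats: int = 500
    n_scrambles: int = 500

    def validate(self) -> None:
        if (self.input_csv is None) == (self.synthetic_spec is None):
            raise ConfigError("exactly one of input_csv / synthetic_spec required")
        if self.input_csv is not None and not Path(self.input_csv).exists():
            raise ConfigError(f"input file not found: {self.input_csv}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "ofs" in raw:
            raw["ofs"] = selection.OFSConfig(**raw["ofs"])
        if "ga" in raw:
            raw["ga"] = selection.GAConfig(**raw["ga"])
        if "synthetic_spec" in raw and raw["synthetic_spec"] is not None:
            spec = dict(raw["synthetic_spec"])
            if "y_range" in spec:
                spec["y_range"] = tuple(spec["y_range"])
            raw["synthetic_spec"] = synthetic.SyntheticSpec(**spec)
        if "split_sizes" in raw and raw["split_sizes"] is not None:
            raw["split_sizes"] = tuple(raw["split_sizes"])
        return cls(**raw)


def _write_once(path: Path, text: str) -> None:
    """Append-only discipline: a stage never rewrites an existing artifact
    with different content."""
    if path.exists() and path.read_text() != text:
        raise StageError(f"refusing to overwrite existing artifact {path}")
    path.write_text(text)


def _load_descriptors(cfg: PipelineConfig, outdir: Path
                      ) -> tuple[pd.DataFrame, pd.Series]:
    if cfg.synthetic_spec is not None:
        X, y, truth = synthetic.make_feature_matrix(cfg.synthetic_spec)
        _write_once(outdir / "truth.json", json.dumps(
            {k: list(v) if isinstance(v, tuple) else v for k, v in truth.items()},
            indent=2, default=str))
        _write_once(outdir / "descriptors.csv", X.to_csv())
        _write_once(outdir / "activity.csv", y.to_frame().to_csv())
        return X, y

    table = pd.read_csv(cfg.input_csv)
    missing = {"mol_id", "smiles", "ki_nM"} - set(table.columns)
    if missing:
        raise StageError(f"curate: input lacks columns {sorted(missing)}")
    records = []
    for row in table.itertuples(index=False):
        ki = None if pd.isna(row.ki_nM) else float(row.ki_nM)
        try:
            records.append(parse_molecule(row.smiles, charge_source=cfg.charge_source,
                                          mol_id=str(row.mol_id), ki_nM=ki))
        except Exception as exc:
            raise StageError(f"curate: record {row.mol_id}: {exc}") from exc
    curated, report = curation.curate(records)
    _write_once(outdir / "curation_report.json", report.to_json())
    _write_once(outdir / "curated.csv", pd.DataFrame(
        {"mol_id": [r.mol_id for r in curated],
         "smiles": [r.smiles for r in curated],
         "ki_nM": [r.ki_nM for r in curated],
         "pki": [r.pki for r in curated]}).to_csv(index=False))
    if any(r.charge_origin != "file" for r in curated):
        logger.warning("internally generated charges in use; descriptor values "
                       "are not comparable to externally charged runs")
    X = descriptors.compute_descriptor_table(curated)
    y = pd.Series({r.mol_id: r.pki for r in curated}, name="pki").loc[X.index]
    _write_once(outdir / "descriptors.csv", X.to_csv())
    _write_once(outdir / "activity.csv", y.rename_axis("mol_id").to_frame().to_csv())
    return X, y


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute every stage; returns the run directory."""
    cfg.validate()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    X, y = _load_descriptors(cfg, outdir)

    try:
        X_kept = selection.objective_feature_selection(X, y, cfg.ofs)
    except selection.AllPrunedError as exc:
        raise StageError(f"ofs: {exc}") from exc
    _write_once(outdir / "ofs_kept.json", json.dumps(list(X_kept.columns), indent=2))

    split = validation.random_split(list(X_kept.index), cfg.train_fraction,
                                    seed=cfg.split_seed, sizes=cfg.split_sizes)
    _write_once(outdir / "split.json", json.dumps(
        {"train_ids": list(split.train_ids), "test_ids": list(split.test_ids),
         "seed": split.seed}, indent=2))
    X_tr, y_tr = X_kept.loc[list(split.train_ids)], y.loc[list(split.train_ids)]
    X_ex, y_ex = X_kept.loc[list(split.test_ids)], y.loc[list(split.test_ids)]

    ga = cfg.ga
    if cfg.scan_k_max:
        curve = selection.q2_vs_k_scan(X_tr, y_tr, cfg.scan_k_max, ga)
        k_opt = selection.elevation_point(curve, cfg.elevation_min_gain)
        _write_once(outdir / "q2_vs_k.csv", pd.DataFrame(
            curve, columns=["k", "best_q2_loo"]).to_csv(index=False))
        ga = dataclasses.replace(ga, model_size_k=k_opt)

    ranked = selection.ga_mlr_search(X_tr, y_tr, ga)
    _write_once(outdir / "ranked_models.csv", pd.DataFrame(
        [{"rank": i + 1, "descriptors": "|".join(s), "q2_loo": q}
         for i, (s, q) in enumerate(ranked[:100])]).to_csv(index=False))

    best = list(ranked[0][0])
    model, report, ad = validation.validate_model(
        X_tr[best], y_tr, X_ex[best], y_ex, seed=cfg.split_seed,
        lmo_fraction=cfg.lmo_fraction, lmo_repeats=cfg.lmo_repeats,
        n_scrambles=cfg.n_scrambles)

    _write_once(outdir / "model.json", json.dumps({
        "intercept": model.intercept,
        "coefficients": model.coefficients,
        "std_errors": model.coefficient_std_errors,
        "n_train": model.n_train,
        "ga_seed": ga.seed, "split_seed": cfg.split_seed,
    }, indent=2, sort_keys=True))
    _write_once(outdir / "validation.json", report.to_json())
    _write_once(outdir / "validation.txt", report.to_table() + "\n")
    _write_once(outdir / "williams.csv", ad.to_frame().to_csv(index=False))
    logger.info("run complete: %s (overall criteria pass: %s)",
                outdir, report.criteria_pass.get("overall"))
    return outdir
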