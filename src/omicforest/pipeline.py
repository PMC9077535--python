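"""End-to-end orchestration: simulate -> assemble -> preprocess ->
evaluate (-> impute), with a run manifest recording the feature-attrition
ledger (raw -> post-NZV -> post-correlation) and every seed used."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assemble import DesignMatrix, assemble
from .modeling import ModelSpec, SplitSpec, evaluate, group_holdout, train
from .preprocess import Preprocessor
from .simulate import MultiomicsBundle, SynthConfig, simulate

logger = logging.getLogger("omicforest")

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "stage_seeds"]


@dataclass
class RunConfig:
    """A full pipeline run: data source, thresholds, model, outputs."""

    outdir: str = "omicforest_run"
    bundle_dir: str | None = None          # None -> simulate
    synth: SynthConfig = field(default_factory=SynthConfig)
    strategy: str = "by_sample"
    train_fraction: float = 0.8
    algorithm: str = "rf"
    hyperparameters: dict = field(default_factory=lambda: {"mtry": "sqrt"})
    k: int = 10
    freq_cut: float = 95 / 5
    unique_cut: float = 10.0
    corr_cutoff: float = 0.75
    rfe_sizes: list[int] | None = None     # None -> skip RFE
    seed: int = 7

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth = SynthConfig(**raw.pop("synth", {}))
        return cls(synth=synth, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def holdout_evaluate(design: DesignMatrix, strategy: str, spec: ModelSpec,
                     split_seed: int, train_fraction: float = 0.8,
                     freq_cut: float = 95 / 5, unique_cut: float = 10.0,
                     corr_cutoff: float = 0.75):
    """Group hold-out evaluation with leakage-free preprocessing.

    Splits rows with an observed target by the given strategy, fits the
    preprocessing pipeline on the training side only, trains the model on
    every surviving feature, and returns (model, test EvalMetrics).
    """
    usable = design.table[design.table[design.target].notna()]
    sub = lambda t: DesignMatrix(table=t, manifest=design.manifest,  # noqa: E731
                                 categorical=design.categorical,
                                 target=design.target)
    keys = list(usable.index)
    tr, te = group_holdout(keys, SplitSpec(strategy=strategy,
                                           train_fraction=train_fraction,
                                           seed=split_seed))
    prep = Preprocessor(freq_cut, unique_cut, corr_cutoff)
    clean_tr = prep.fit_transform(sub(usable.iloc[tr]))
    clean_te = prep.transform(sub(usable.iloc[te]))
    model = train(spec, clean_tr.table, clean_tr.table[design.target],
                  clean_tr.feature_columns)
    metrics = evaluate(model, clean_te.table, clean_te.table[design.target])
    return model, metrics


class PipelineError(RuntimeError):
    def __init__(self, stage: str, error: Exception, manifest: dict):
        super().__init__(f"pipeline failed in stage '{stage}': {error}")
        self.stage = stage
        self.manifest = manifest


def stage_seeds(seed: int) -> dict[str, int]:
    """Fan a single run seed out into per-stage seeds (all < 2^31)."""
    rng = np.random.default_rng(seed)
    names = ("simulate", "split", "model", "rfe", "impute")
    return {name: int(s) for name, s in
            zip(names, rng.integers(0, 2 ** 31, size=len(names)))}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the fixed stage order and write all artifacts to ``outdir``.

    Returns the run manifest (also written as manifest.json)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    manifest: dict = {
        "software": {"name": "omicforest", "version": __version__},
        "config": config.to_dict(),
        "seeds": seeds,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }
    stage = "simulate"
    try:
        if config.bundle_dir is not None:
            bundle = MultiomicsBundle.read(config.bundle_dir)
        else:
            synth = dataclasses.replace(config.synth, seed=seeds["simulate"])
            bundle, truth = simulate(synth)
            bundle.write(outdir / "bundle")
            truth.write(outdir / "bundle")
        manifest["stages"]["simulate"] = {
            "n_proteins": int(bundle.protein_expr.shape[0]),
            "n_samples": int(bundle.protein_expr.shape[1]),
            "missing_fraction":
                float(bundle.protein_expr.isna().to_numpy().mean()),
        }
        logger.info("simulate: %s", manifest["stages"]["simulate"])

        stage = "assemble"
        design = assemble(bundle)
        design.write(outdir / "design.tsv")
        n_raw = len(design.feature_columns)
        manifest["stages"]["assemble"] = {
            "rows": int(design.table.shape[0]),
            "raw_features": n_raw,
            "category_counts": design.category_counts(),
        }
        logger.info("assemble: %d rows, %d raw features",
                    design.table.shape[0], n_raw)

        stage = "split"
        usable = design.table[design.table[design.target].notna()]
        design_usable = DesignMatrix(table=usable, manifest=design.manifest,
                                     categorical=design.categorical,
                                     target=design.target)
        keys = list(usable.index)
        split = SplitSpec(strategy=config.strategy,
                          train_fraction=config.train_fraction,
                          seed=seeds["split"])
        train_idx, test_idx = group_holdout(keys, split)
        manifest["stages"]["split"] = {
            "strategy": config.strategy,
            "train_rows": int(len(train_idx)), "test_rows": int(len(test_idx)),
        }

        stage = "preprocess"
        prep = Preprocessor(config.freq_cut, config.unique_cut, config.corr_cutoff)
        dm_train = DesignMatrix(table=usable.iloc[train_idx],
                                manifest=design.manifest,
                                categorical=design.categorical,
                                target=design.target)
        dm_test = DesignMatrix(table=usable.iloc[test_idx],
                               manifest=design.manifest,
                               categorical=design.categorical,
                               target=design.target)
        clean_train = prep.fit_transform(dm_train)
        clean_test = prep.transform(dm_test)
        state = prep.state
        n_post_dummy = n_raw + len(state.dummy_columns) - len(design.categorical)
        n_post_nzv = n_post_dummy - len(state.dropped_nzv)
        n_post_corr = n_post_nzv - len(state.dropped_correlated)
        manifest["stages"]["preprocess"] = {
            "raw_features": n_raw,
            "features_after_dummy_encoding": n_post_dummy,
            "features_after_nzv_filter": n_post_nzv,
            "features_after_correlation_filter": n_post_corr,
            "n_removed_nzv": len(state.dropped_nzv),
            "n_removed_correlated": len(state.dropped_correlated),
            "train_rows_after_complete_case": int(clean_train.table.shape[0]),
            "test_rows_after_complete_case": int(clean_test.table.shape[0]),
        }
        state.write(outdir / "preprocess_state.json")
        clean_train.write(outdir / "train.tsv")
        clean_test.write(outdir / "test.tsv")
        logger.info("preprocess: %s", manifest["stages"]["preprocess"])

        stage = "evaluate"
        spec = ModelSpec(algorithm=config.algorithm,
                         hyperparameters=config.hyperparameters,
                         seed=seeds["model"])
        features = clean_train.feature_columns
        model = train(spec, clean_train.table, clean_train.table[design.target],
                      features)
        metrics = evaluate(model, clean_test.table, clean_test.table[design.target])
        manifest["stages"]["evaluate"] = {
            "algorithm": config.algorithm,
            "train_rmse": model.train_rmse,
            "train_r_squared": model.train_r_squared,
            "test": metrics.as_dict(),
        }
        (outdir / "metrics.json").write_text(
            json.dumps(manifest["stages"]["evaluate"], indent=1))
        logger.info("evaluate: test %s", metrics.as_dict())

        if config.rfe_sizes:
            stage = "rfe"
            from .modeling import group_kfold, rfe as run_rfe
            tr_keys = list(clean_train.table.index)
            folds = group_kfold(tr_keys, config.strategy, k=config.k,
                                seed=seeds["rfe"])
            rfe_spec = ModelSpec(algorithm=config.algorithm,
                                 hyperparameters=config.hyperparameters,
                                 seed=seeds["rfe"])
            result = run_rfe(clean_train.table[features],
                             clean_train.table[design.target], tr_keys,
                             rfe_spec, folds, config.rfe_sizes)
            result.per_size.to_csv(outdir / "rfe_per_size.tsv", sep="\t")
            pd.Series(result.mean_rank, name="mean_rank").to_csv(
                outdir / "rfe_ranking.tsv", sep="\t", index_label="feature")
            manifest["stages"]["rfe"] = {
                "optimal_size": result.optimal_size,
                "top10": result.selected_features(10),
            }

        manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        counts = [n_post_dummy, n_post_nzv, n_post_corr]
        if not all(a >= b for a, b in zip(counts, counts[1:])):
            raise RuntimeError(f"feature attrition not monotone: {counts}")
    except Exception as err:  # noqa: BLE001 - abort with stage context
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise PipelineError(stage, err, manifest) from err
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
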