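"""End-to-end orchestration: simulate -> preprocess -> train -> explain ->
cluster -> correlate, with file artifacts per stage and reproducible seeds.

Every stage reads/writes a conventional layout under one output directory:

    cubes/      raw phantom cubes + manifest.csv
    pre/        preprocessed cubes (one HDF5 per image)
    model/      checkpoint.npz, history.csv, metrics.json
    explain/    attention maps + top-attended spectra + attributions.csv
    cluster/    embedding.csv, nmi_results.csv
    correlate/  correlations_<group>.csv
    run_manifest.json   artifact index with the config hash and seed

Re-running with an identical config reproduces identical metric files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .axis import WavenumberAxis
from .cube import HyperCube
from .errors import InvalidArgumentError
from .interpret import attend_bag, gradient_attributions, rank_report, save_attention_overlay
from .mil import MilAttentionModel, ModelConfig, bag_from_cube
from .preprocess import PreprocessedCube, auc_image, preprocess_cube
from .synthetic import Cohort, PhantomSpec, generate_cohort
from .training import TrainConfig, evaluate, split_by_animal, train
from .downstream import (
    UmapGrid,
    band_metrics,
    pearson_correlate,
    standard_scale,
    umap_grid_search,
)

ALL_STAGES = ("simulate", "preprocess", "train", "explain", "cluster", "correlate")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run (loadable from YAML)."""

    out_dir: str
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    phantom: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    train: dict = field(default_factory=dict)
    umap: dict = field(default_factory=dict)
    top_fraction: float = 0.05
    threshold: float = 0.1
    peak: float = 1654.0
    split_fraction: float = 0.5

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise InvalidArgumentError(f"unknown stages {sorted(unknown)}")

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


# --------------------------------------------------------------------- stages


def stage_simulate(spec: PhantomSpec, out_dir: str | Path) -> Cohort:
    return generate_cohort(spec, Path(out_dir) / "cubes")


def load_cohort(cube_dir: str | Path) -> tuple[dict[str, HyperCube], pd.DataFrame]:
    cube_dir = Path(cube_dir)
    manifest = dio.read_manifest(cube_dir / "manifest.csv")
    cubes = {row.image_id: dio.read_cube(row.path) for row in manifest.itertuples()}
    return cubes, manifest


def stage_preprocess(
    cubes: dict[str, HyperCube],
    out_dir: str | Path | None = None,
    threshold: float = 0.1,
    peak: float = 1654.0,
) -> dict[str, PreprocessedCube]:
    pre = {}
    for image_id, cube in cubes.items():
        pre[image_id] = preprocess_cube(cube, threshold=threshold, peak=peak)
    if out_dir is not None:
        pre_dir = Path(out_dir) / "pre"
        pre_dir.mkdir(parents=True, exist_ok=True)
        for image_id, p in pre.items():
            dio.write_preprocessed(pre_dir / f"{image_id}.h5", p)
    return pre


def make_bags(pre: dict[str, PreprocessedCube], manifest: pd.DataFrame):
    # note: "class" is a Python keyword, so label access goes through getitem
    return [
        bag_from_cube(pre[row["image_id"]], label=int(row["class"]), source_id=row["image_id"])
        for _, row in manifest.iterrows()
    ]


def stage_train(
    pre: dict[str, PreprocessedCube],
    manifest: pd.DataFrame,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    out_dir: str | Path | None = None,
    split_fraction: float = 0.5,
    meta: dict | None = None,
):
    train_manifest, val_manifest = split_by_animal(
        manifest, fraction=split_fraction, seed=train_cfg.seed
    )
    train_bags = make_bags(pre, train_manifest)
    val_bags = make_bags(pre, val_manifest)
    model, history = train(model_cfg, train_cfg, train_bags, val_bags)
    metrics = {
        "train": evaluate(model, train_bags),
        "validation": evaluate(model, val_bags),
        "best_epoch": history.best_epoch,
        "best_val_f1": history.best_val_f1,
    }
    if meta:
        metrics.update(meta)
    if out_dir is not None:
        model_dir = Path(out_dir) / "model"
        model_dir.mkdir(parents=True, exist_ok=True)
        model.save(model_dir / "checkpoint.npz")
        history.to_frame().to_csv(model_dir / "history.csv", index=False)
        with open(model_dir / "metrics.json", "w") as f:
            json.dump(metrics, f, indent=2, sort_keys=True)
    return model, history, metrics, train_manifest, val_manifest


def stage_explain(
    model: MilAttentionModel,
    pre: dict[str, PreprocessedCube],
    cubes: dict[str, HyperCube],
    val_manifest: pd.DataFrame,
    out_dir: str | Path | None = None,
    top_fraction: float = 0.05,
    seed: int = 0,
    attribution_samples: int = 32,
    instances_per_bag: int = 2000,
):
    """Attention maps, top-attended spectra and gradient attributions."""
    import h5py

    results = {}
    val_bags = make_bags(pre, val_manifest)
    for row, bag in zip(val_manifest.itertuples(), val_bags):
        p = pre[row.image_id]
        H, W, _ = p.shape
        results[row.image_id] = attend_bag(model, bag, H, W, fraction=top_fraction)

    # attribution background: instances subsampled from the validation bags
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 41]))
    pool = np.concatenate([b.instances for b in val_bags], axis=0)
    nz = np.flatnonzero(np.any(pool != 0.0, axis=1))
    take = rng.choice(nz, size=min(512, nz.size), replace=False)
    background = pool[take]
    axis = next(iter(pre.values())).axis
    summary = gradient_attributions(
        model, val_bags, background,
        n_samples=attribution_samples, instances_per_bag=instances_per_bag,
        axis=axis, seed=seed,
    )
    report = rank_report(
        summary,
        band_annotations={
            "phosphate_965": 965.0, "rna_uracil_996": 996.0, "amide_iii_1240": 1240.0,
            "paraffin_1373": 1373.0, "paraffin_1464": 1464.0, "amide_ii_1544": 1544.0,
            "amide_i_1654": 1654.0, "carbonyl_1727": 1727.0,
        },
    )

    if out_dir is not None:
        exp_dir = Path(out_dir) / "explain"
        exp_dir.mkdir(parents=True, exist_ok=True)
        for row in val_manifest.itertuples():
            res = results[row.image_id]
            with h5py.File(exp_dir / f"attention_{row.image_id}.h5", "w") as f:
                f.create_dataset("raw", data=res.raw)
                f.create_dataset("map", data=res.map)
                f.create_dataset("top_indices", data=res.top_indices)
                f.create_dataset("top_spectra", data=res.top_spectra)
            save_attention_overlay(
                exp_dir / f"attention_{row.image_id}.png",
                res.map,
                auc_image(cubes[row.image_id]),
            )
        report.to_csv(exp_dir / "attributions.csv", index=False)
    return results, summary, report


def stage_cluster(
    attention_results: dict,
    val_manifest: pd.DataFrame,
    grid: UmapGrid,
    out_dir: str | Path | None = None,
):
    """UMAP + k-means grid search of pooled top-attended spectra vs treatment."""
    from .downstream import umap_kmeans

    spectra, treatments, classes = [], [], []
    for _, row in val_manifest.iterrows():
        res = attention_results[row["image_id"]]
        spectra.append(res.top_spectra)
        treatments.extend([row["treatment"]] * len(res.top_spectra))
        classes.extend([row["class"]] * len(res.top_spectra))
    X = standard_scale(np.concatenate(spectra, axis=0))
    params, best_nmi, results = umap_grid_search(X, treatments, grid)
    embedding, labels = umap_kmeans(X, k=grid.k, random_state=grid.random_state, **params)
    table = pd.DataFrame(
        {
            "x": embedding[:, 0], "y": embedding[:, 1],
            "treatment": treatments, "class": classes, "cluster": labels,
        }
    )
    if out_dir is not None:
        cl_dir = Path(out_dir) / "cluster"
        cl_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(cl_dir / "embedding.csv", index=False)
        results.to_csv(cl_dir / "nmi_results.csv", index=False)
        with open(cl_dir / "best.json", "w") as f:
            json.dump({"params": params, "nmi": best_nmi}, f, indent=2, sort_keys=True)
    return params, best_nmi, results, table


def stage_correlate(
    attention_results: dict,
    manifest: pd.DataFrame,
    axis: WavenumberAxis,
    out_dir: str | Path | None = None,
    protein_cols: tuple[str, ...] = ("bim", "puma"),
):
    """Band metrics of per-image top-spectra means, correlated with proteins."""
    means = {
        image_id: res.top_spectra.mean(axis=0) for image_id, res in attention_results.items()
    }
    metrics = band_metrics(means, axis)
    sub = manifest[manifest["image_id"].isin(means)].set_index("image_id")
    proteins = sub[["class", *protein_cols]]
    tables = pearson_correlate(metrics, proteins, group_key="class")
    if out_dir is not None:
        co_dir = Path(out_dir) / "correlate"
        co_dir.mkdir(parents=True, exist_ok=True)
        metrics.to_csv(co_dir / "band_metrics.csv")
        for group, table in tables.items():
            table.to_csv(co_dir / f"correlations_class{group}.csv")
    return metrics, tables


# ------------------------------------------------------------------ pipeline


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in order; returns the artifact manifest.

    A stage failure leaves earlier artifacts in place and a ``failure`` entry
    in the run manifest before the exception propagates.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    artifacts: dict = {"config_hash": chash, "seed": config.seed, "stages": {}}
    manifest_path = out / "run_manifest.json"

    def record(stage: str, entry) -> None:
        artifacts["stages"][stage] = entry
        with open(manifest_path, "w") as f:
            json.dump(artifacts, f, indent=2, sort_keys=True)

    try:
        cubes = manifest = pre = None
        if "simulate" in config.stages:
            spec = PhantomSpec(seed=config.seed, **config.phantom)
            cohort = stage_simulate(spec, out)
            cubes = {c.meta["image_id"]: c for c in cohort.cubes}
            manifest = cohort.manifest
            record("simulate", {"n_images": len(cohort.cubes), "dir": str(out / "cubes")})
        if set(config.stages) - {"simulate"}:
            if cubes is None:
                cubes, manifest = load_cohort(out / "cubes")
        if "preprocess" in config.stages:
            pre = stage_preprocess(cubes, out, threshold=config.threshold, peak=config.peak)
            record("preprocess", {"dir": str(out / "pre")})
        needs_pre = set(config.stages) & {"train", "explain", "cluster", "correlate"}
        if needs_pre and pre is None:
            pre = stage_preprocess(cubes, None, threshold=config.threshold, peak=config.peak)

        model = val_manifest = None
        if "train" in config.stages:
            input_dim = len(next(iter(pre.values())).axis)
            model_cfg = ModelConfig(input_dim=input_dim, **config.model)
            train_cfg = TrainConfig(seed=config.seed, **config.train)
            model, history, metrics, _, val_manifest = stage_train(
                pre, manifest, model_cfg, train_cfg, out,
                split_fraction=config.split_fraction,
                meta={"config_hash": chash, "seed": config.seed},
            )
            record("train", {"metrics": metrics, "dir": str(out / "model")})

        needs_explain = set(config.stages) & {"explain", "cluster", "correlate"}
        if needs_explain:
            if model is None:
                model = MilAttentionModel.load(out / "model" / "checkpoint.npz")
            if val_manifest is None:
                _, val_manifest = split_by_animal(
                    manifest, fraction=config.split_fraction, seed=config.seed
                )
            results, summary, report = stage_explain(
                model, pre, cubes, val_manifest,
                out if "explain" in config.stages else None,
                top_fraction=config.top_fraction, seed=config.seed,
            )
            if "explain" in config.stages:
                record("explain", {"dir": str(out / "explain")})
        if "cluster" in config.stages:
            grid = UmapGrid(**config.umap)
            params, best_nmi, _, _ = stage_cluster(results, val_manifest, grid, out)
            record("cluster", {"best_params": params, "best_nmi": best_nmi})
        if "correlate" in config.stages:
            axis = next(iter(pre.values())).axis
            stage_correlate(results, manifest, axis, out)
            record("correlate", {"dir": str(out / "correlate")})
    except Exception as e:
        record("failure", {"error": str(e)})
        raise
    return artifacts
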