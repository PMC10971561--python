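"""End-to-end runs: scene -> features -> screening/SPA -> models -> reports.

A run is configured by :class:`RunConfig` and is fully reproducible from
its root seed: scene synthesis, the train/test split, SPA's internal
validation split, the random forest and the CNN each draw from a named
substream derived from the root.

For each requested feature set the pipeline

1. extracts raw canopy-mean features (vegetation indices and/or texture);
2. splits trees 75/25 (stratified), then min-max normalises with bounds
   fitted on the training trees and applied to all;
3. screens features by one-way ANOVA against damage level on the
   training trees and keeps the sensitive ones (F above the 0.01-tail
   critical value);
4. runs SPA over the sensitive features and keeps the
   validation-optimal subset, in selection order;
5. trains the requested models on the selected features and evaluates
   OA, Kappa, UA/PA and feature importances on the held-out trees.

``run_experiment`` additionally runs the sample-size sweep over the
Tables-style grid of sizes x feature sets x models and an
all-features-vs-SPA comparison, writing every table to the run
directory together with a replay manifest.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .classify import (ModelSpec, SplitPlan, evaluate_on_test, make_split,
                       sample_size_sweep, train_model)
from .evaluate import EvaluationReport
from .selection import SelectionResult, screen_features, spa_select
from .synthetic import Scene, SceneConfig, generate_scene, write_scene
from .texture import texture_feature_table
from .vegindex import (FeatureTable, MS_INDEX_NAMES, RGB_INDEX_NAMES,
                       apply_normalisation, extract_canopy_means, normalise)

__all__ = [
    "FEATURE_SETS",
    "RunConfig",
    "derive_seed",
    "compute_feature_table",
    "split_normalise",
    "run_feature_set",
    "run_experiment",
]

FEATURE_SETS = ("MS_VI", "RGB_VI", "RGB_TF", "RGB_VI&TF")
DEFAULT_SWEEP_SIZES = (140, 240, 340, 440, 540, 640, 740, 840)


def derive_seed(root: int, stream: str) -> int:
    """A stable, named sub-seed below 2**31."""
    ss = np.random.SeedSequence([int(root), zlib.crc32(stream.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class RunConfig:
    scene: SceneConfig = field(default_factory=lambda: SceneConfig(ms_enabled=True))
    feature_sets: tuple[str, ...] = ("MS_VI", "RGB_VI", "RGB_VI&TF")
    models: tuple[str, ...] = ("RF", "CNN")
    k_min: int = 1
    k_max: int = 15
    sweep_sizes: tuple[int, ...] = DEFAULT_SWEEP_SIZES
    stratify: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = [f for f in self.feature_sets if f not in FEATURE_SETS]
        if unknown:
            raise ValueError(f"unknown feature sets: {unknown}")
        if "MS_VI" in self.feature_sets and not self.scene.ms_enabled:
            raise ValueError("feature set MS_VI requires scene.ms_enabled")
        if any(m not in ("RF", "CNN") for m in self.models):
            raise ValueError("models must be among RF, CNN")


def compute_feature_table(scene: Scene, feature_set: str) -> FeatureTable:
    """Raw (un-normalised) canopy-mean features for one feature set."""
    if feature_set == "MS_VI":
        return extract_canopy_means(scene, MS_INDEX_NAMES)
    if feature_set == "RGB_VI":
        return extract_canopy_means(scene, RGB_INDEX_NAMES)
    if feature_set == "RGB_TF":
        return texture_feature_table(scene)
    if feature_set == "RGB_VI&TF":
        return extract_canopy_means(scene, RGB_INDEX_NAMES).join(
            texture_feature_table(scene))
    raise ValueError(f"unknown feature set {feature_set!r}")


def split_normalise(table: FeatureTable, labels: pd.Series, seed: int,
                    stratify: bool = True) -> tuple[FeatureTable, SplitPlan]:
    """75/25 split, then min-max bounds fitted on train, applied to all."""
    plan = make_split(table.tree_ids, labels.loc[table.tree_ids].to_numpy(),
                      seed=seed, stratify=stratify)
    train = FeatureTable(table.values.loc[list(plan.train_ids)])
    bounds = normalise(train).bounds
    return apply_normalisation(table, bounds), plan


@dataclass
class FeatureSetRun:
    feature_set: str
    sensitivity: pd.DataFrame
    selection: SelectionResult
    reports: dict[str, EvaluationReport]  # model kind -> report
    table_norm: FeatureTable
    plan: SplitPlan


def run_feature_set(scene: Scene, feature_set: str,
                    models: Sequence[str] = ("RF", "CNN"),
                    seed: int = 0, k_min: int = 1, k_max: int = 15,
                    stratify: bool = True,
                    select: bool = True) -> FeatureSetRun:
    """Full pipeline for one feature set on one scene.

    ``select=False`` skips SPA and trains on every sensitive feature
    (the all-features comparison arm).
    """
    labels = pd.Series(scene.labels, index=scene.tree_ids)
    raw = compute_feature_table(scene, feature_set)
    table, plan = split_normalise(raw, labels, seed=derive_seed(seed, "split"),
                                  stratify=stratify)

    train_ids = list(plan.train_ids)
    train_table = FeatureTable(table.values.loc[train_ids],
                               normalised=True, bounds=table.bounds)
    sens = screen_features(train_table, labels.loc[train_ids].to_numpy())
    sensitive = [f for f in sens.index[sens["sensitive"]]]
    if len(sensitive) < max(2, k_min):
        sensitive = list(sens.index)  # degenerate screen: keep everything

    if "CNN" in models:
        k_min = max(k_min, 2)  # the 1-D convolution needs >= 2 features
    if select:
        sel = spa_select(train_table.select(sensitive),
                         labels.loc[train_ids].to_numpy(),
                         k_min=min(k_min, len(sensitive)),
                         k_max=min(k_max, len(sensitive)),
                         seed=derive_seed(seed, "spa"))
        chosen = sel.selected
    else:
        sel = SelectionResult(chains={}, norm_traces={}, errors={},
                              selected=list(sensitive),
                              validation_error=float("nan"))
        chosen = list(sensitive)

    sub = table.select(chosen)
    reports: dict[str, EvaluationReport] = {}
    for kind in models:
        spec = ModelSpec(kind=kind, seed=derive_seed(seed, kind.lower()))
        fitted = train_model(sub, labels, plan, spec)
        reports[kind] = evaluate_on_test(
            fitted, sub, labels, plan,
            metadata={"feature_set": feature_set, "n_features": len(chosen),
                      "features": list(chosen), "spa": select})
    return FeatureSetRun(feature_set=feature_set, sensitivity=sens,
                         selection=sel, reports=reports,
                         table_norm=table, plan=plan)


def _selection_to_dict(sel: SelectionResult) -> dict:
    return {
        "selected": sel.selected,
        "validation_error": sel.validation_error,
        "chains": sel.chains,
        "norm_traces": sel.norm_traces,
        "errors": {f"{s}|k={k}": v for (s, k), v in sel.errors.items()},
    }


def run_experiment(config: RunConfig, out_dir: str | Path,
                   sweep_seeds: Sequence[int] | None = None,
                   save_scene: bool = False) -> Path:
    """Execute the configured experiment and write all reports.

    Emits per-feature-set feature/sensitivity/selection files, per-model
    evaluation reports, the sizes x feature-sets x models sweep CSV, the
    all-features-vs-SPA comparison CSV and a replay manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scene_cfg = replace(config.scene, seed=derive_seed(config.seed, "scene"))
    scene = generate_scene(scene_cfg)
    if save_scene:
        write_scene(scene, out / "scene")
    labels = pd.Series(scene.labels, index=scene.tree_ids)
    if sweep_seeds is None:
        sweep_seeds = [derive_seed(config.seed, "sweep")]

    sweep_rows = []
    comparison_rows = []
    for fs in config.feature_sets:
        run = run_feature_set(scene, fs, models=config.models,
                              seed=config.seed, k_min=config.k_min,
                              k_max=config.k_max, stratify=config.stratify)
        tag = fs.replace("&", "_")
        compute_feature_table(scene, fs).to_csv(out / f"features_{tag}.csv")
        run.sensitivity.to_csv(out / f"sensitivity_{tag}.csv")
        (out / f"selection_{tag}.json").write_text(
            json.dumps(_selection_to_dict(run.selection), indent=2))
        for kind, rep in run.reports.items():
            rep.to_json(out / f"report_{tag}_{kind}.json")
            rep.cm.to_frame().to_csv(out / f"confusion_{tag}_{kind}.csv")
            pd.Series(rep.importances).sort_values(ascending=False).rename(
                "importance").to_csv(out / f"importances_{tag}_{kind}.csv")

        # all-features arm for the SPA-vs-all comparison
        run_all = run_feature_set(scene, fs, models=config.models,
                                  seed=config.seed, k_min=config.k_min,
                                  k_max=config.k_max,
                                  stratify=config.stratify, select=False)
        for kind in config.models:
            comparison_rows.append({
                "feature_set": fs, "model": kind,
                "OA_spa": run.reports[kind].OA,
                "Kappa_spa": run.reports[kind].Kappa,
                "n_features_spa": len(run.selection.selected),
                "OA_all": run_all.reports[kind].OA,
                "Kappa_all": run_all.reports[kind].Kappa,
                "n_features_all": len(run_all.selection.selected),
            })

        # sweep on the SPA-selected normalised features
        sub = run.table_norm.select(run.selection.selected)
        specs = [ModelSpec(kind=k, seed=derive_seed(config.seed, k.lower()))
                 for k in config.models]
        sw = sample_size_sweep(sub, labels, config.sweep_sizes, specs,
                               seeds=sweep_seeds, stratify=config.stratify)
        sw.insert(1, "feature_set", fs)
        sweep_rows.append(sw)

    sweep = pd.concat(sweep_rows, ignore_index=True)
    sweep.to_csv(out / "sweep.csv", index=False)
    pd.DataFrame(comparison_rows).to_csv(out / "comparison_all_vs_spa.csv",
                                         index=False)
    manifest = {
        "package": "needlegrade",
        "version": __version__,
        "seed": config.seed,
        "sweep_seeds": list(map(int, sweep_seeds)),
        "feature_sets": list(config.feature_sets),
        "models": list(config.models),
        "sweep_sizes": list(config.sweep_sizes),
        "scene": {k: (list(v) if isinstance(v, tuple) else
                      ({int(kk): vv for kk, vv in v.items()}
                       if isinstance(v, dict) else v))
                  for k, v in asdict(scene_cfg).items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    return out
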