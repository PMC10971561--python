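"""Synthetic UAV canopy scenes with damage-dependent colour and texture.

Real acquisitions of pest-damaged larch stands are not publicly deposited,
so the pipeline is exercised on generated scenes that carry the statistical
structure the analysis assumes:

* four damage classes whose canopy colour progresses green -> yellow ->
  red -> grey as defoliation worsens;
* class-dependent local pixel noise (texture grain), so grey-level
  co-occurrence statistics carry class signal;
* per-tree needle counts whose leaf-loss rate falls inside the class band,
  so survey grading round-trips exactly;
* optional multispectral planes (b, g, r, RE, NIR) in which NIR reflectance
  decreases with damage, the canonical stress response;
* shadow pixels (a darkened fraction of each canopy) and a soil-like
  background, the main noise sources named for real orthomosaics.

Canopies are filled ellipses with jittered radii placed on a
non-overlapping grid; masks are exact pixel sets, and the scene can be
persisted as a multi-page TIFF + GeoJSON canopy polygons + a survey CSV.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile
from shapely.geometry import Point, mapping, shape
from shapely.affinity import scale as shapely_scale

from .survey import SurveyRecord, write_survey_csv, read_survey_csv

__all__ = [
    "SceneConfig",
    "Scene",
    "SceneLayoutError",
    "generate_survey",
    "generate_scene",
    "write_scene",
    "read_scene",
]

RGB_CHANNELS = ("R", "G", "B")
MS_CHANNELS = ("b", "g", "r", "RE", "NIR")

#: DR bands per level, (low, high); low exclusive except level 1, high inclusive.
_DR_BANDS = {1: (0.0, 5.0), 2: (5.0, 30.0), 3: (30.0, 70.0), 4: (70.0, 100.0)}


class SceneLayoutError(RuntimeError):
    """Canopies cannot be placed without overlap in the requested image."""


@dataclass(frozen=True)
class SceneConfig:
    """Generator settings; defaults are the study conditions.

    ``class_color_means`` encodes the green/yellow/red/grey canopy
    progression; ``texture_grain`` is the within-canopy pixel noise sd per
    class (drives GLCM contrast); ``class_color_sd`` is the between-tree
    jitter of the canopy mean colour within a class.
    """

    n_trees_per_class: int = 210
    classes: tuple[int, ...] = (1, 2, 3, 4)
    image_size: tuple[int, int] | None = None  # (rows, cols); derived if None
    canopy_radius_range: tuple[float, float] = (4.0, 6.0)
    class_color_means: Mapping[int, tuple[float, float, float]] = field(
        default_factory=lambda: {
            1: (0.20, 0.45, 0.18),  # healthy: green
            2: (0.45, 0.48, 0.20),  # mild: yellowing
            3: (0.55, 0.35, 0.18),  # moderate: reddish
            4: (0.40, 0.40, 0.40),  # severe: grey
        }
    )
    class_color_sd: float = 0.04
    texture_grain: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.020, 2: 0.035, 3: 0.050, 4: 0.065}
    )
    ms_enabled: bool = False
    class_nir_means: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.75, 2: 0.62, 3: 0.50, 4: 0.38}
    )
    class_re_means: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.48, 2: 0.44, 3: 0.40, 4: 0.36}
    )
    background_reflectance: tuple[float, float, float] = (0.32, 0.26, 0.20)
    background_noise_sd: float = 0.015
    shadow_fraction: float = 0.15
    needle_total_range: tuple[int, int] = (200, 1200)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees_per_class < 1:
            raise ValueError("n_trees_per_class must be >= 1")
        if not self.classes:
            raise ValueError("classes must be non-empty")
        if any(c not in _DR_BANDS for c in self.classes):
            raise ValueError(f"classes must be among {sorted(_DR_BANDS)}")
        if self.canopy_radius_range[0] < 2.0:
            raise ValueError("minimum canopy radius must be >= 2 px "
                             "(masks need >= 9 pixels)")
        means = [self.class_color_means[c] for c in self.classes]
        for m in means:
            if any(not (0.0 <= v <= 1.0) for v in m):
                raise ValueError("class colour means must lie in [0, 1]")
        for a in range(len(means)):
            for b in range(a + 1, len(means)):
                if math.dist(means[a], means[b]) <= 0.0:
                    raise ValueError("class colour means must be pairwise distinct")
        if not (0.0 <= self.shadow_fraction < 1.0):
            raise ValueError("shadow_fraction must lie in [0, 1)")
        lo, hi = self.needle_total_range
        if lo < 100:
            raise ValueError("needle totals below 100 make integer DR bands "
                             "unreliable; use needle_total_range[0] >= 100")

    @property
    def n_trees(self) -> int:
        return self.n_trees_per_class * len(self.classes)

    @property
    def channel_names(self) -> tuple[str, ...]:
        return RGB_CHANNELS + MS_CHANNELS if self.ms_enabled else RGB_CHANNELS


@dataclass
class Scene:
    """A generated (or loaded) labelled scene.

    ``raster`` is channels x rows x cols reflectance in [0, 1];
    ``canopies`` maps tree id -> (row_indices, col_indices) pixel arrays;
    ``truth`` maps tree id -> its survey record.
    """

    raster: np.ndarray
    channel_names: tuple[str, ...]
    canopies: dict[int, tuple[np.ndarray, np.ndarray]]
    truth: dict[int, SurveyRecord]
    canopy_geoms: dict[int, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.canopies) != set(self.truth):
            raise ValueError("every canopy must have exactly one truth record")
        if not np.all(np.isfinite(self.raster)):
            raise ValueError("raster must be finite")
        if self.raster.min() < 0 or self.raster.max() > 1:
            raise ValueError("raster reflectances must lie in [0, 1]")

    @property
    def tree_ids(self) -> list[int]:
        return sorted(self.canopies)

    @property
    def labels(self) -> np.ndarray:
        return np.array([self.truth[t].level for t in self.tree_ids])

    def channel(self, name: str) -> np.ndarray:
        return self.raster[self.channel_names.index(name)]


def _needle_counts_for_level(level: int, rng: np.random.Generator,
                             total_range: tuple[int, int]) -> tuple[int, int]:
    """Draw (L_h, L_d) whose DR lies inside the level's band."""
    lo, hi = _DR_BANDS[level]
    total = int(rng.integers(total_range[0], total_range[1] + 1))
    d_lo = 0 if level == 1 else math.floor(total * lo / 100.0) + 1
    d_hi = math.floor(total * hi / 100.0)
    if d_hi < d_lo:
        raise ValueError(f"empty needle-count band for level {level} at "
                         f"total={total}")
    L_d = int(rng.integers(d_lo, d_hi + 1))
    return total - L_d, L_d


def generate_survey(config: SceneConfig) -> list[SurveyRecord]:
    """Per-tree needle counts with class-consistent leaf-loss rates.

    Tree ids run 0..n_trees-1, grouped by class in ``config.classes`` order;
    the derived record level always equals the generating class.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    records: list[SurveyRecord] = []
    tree_id = 0
    for level in config.classes:
        for _ in range(config.n_trees_per_class):
            L_h, L_d = _needle_counts_for_level(level, rng,
                                                config.needle_total_range)
            rec = SurveyRecord.from_counts(tree_id, L_h, L_d)
            assert rec.level == level
            records.append(rec)
            tree_id += 1
    return records


def _grid_layout(config: SceneConfig) -> tuple[tuple[int, int], int]:
    """Cell size and image shape for a non-overlapping canopy grid."""
    r_max = config.canopy_radius_range[1]
    cell = int(math.ceil(2 * r_max)) + 4
    n = config.n_trees
    ncols = int(math.ceil(math.sqrt(n)))
    nrows = int(math.ceil(n / ncols))
    shape_auto = (nrows * cell, ncols * cell)
    if config.image_size is None:
        return shape_auto, cell
    rows, cols = config.image_size
    # honour a user-fixed image size: recompute the cell that fits
    ncols_fit = cols // cell
    nrows_fit = rows // cell
    if ncols_fit * nrows_fit < n:
        raise SceneLayoutError(
            f"cannot place {n} non-overlapping canopies of radius <= {r_max} "
            f"in a {rows}x{cols} image (fits {ncols_fit * nrows_fit})"
        )
    return (rows, cols), cell


def generate_scene(config: SceneConfig) -> Scene:
    """Render a labelled scene: raster + canopy masks + truth survey.

    Identical config (including seed) yields a bit-identical scene.
    """
    records = generate_survey(config)
    (rows, cols), cell = _grid_layout(config)
    ncols = cols // cell
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))

    n_channels = len(config.channel_names)
    raster = np.empty((n_channels, rows, cols))
    bg_rgb = np.asarray(config.background_reflectance)
    for k in range(3):
        raster[k] = bg_rgb[k]
    if config.ms_enabled:
        # b,g,r planes mirror the camera channels; RE/NIR have soil levels
        raster[3] = bg_rgb[2]
        raster[4] = bg_rgb[1]
        raster[5] = bg_rgb[0]
        raster[6] = 0.28
        raster[7] = 0.32
    raster += rng.normal(0.0, config.background_noise_sd, raster.shape)

    # scatter trees over grid cells so classes are spatially mixed
    cell_order = rng.permutation(ncols * (rows // cell))[: config.n_trees]
    rr, cc = np.mgrid[0:rows, 0:cols]

    canopies: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    geoms: dict[int, object] = {}
    truth: dict[int, SurveyRecord] = {}
    r_lo, r_hi = config.canopy_radius_range
    for rec, cell_idx in zip(records, cell_order):
        gy, gx = divmod(int(cell_idx), ncols)
        cy = gy * cell + cell / 2 + rng.uniform(-1, 1)
        cx = gx * cell + cell / 2 + rng.uniform(-1, 1)
        ry = rng.uniform(r_lo, r_hi)
        rx = rng.uniform(r_lo, r_hi)
        y0, y1 = max(0, int(cy - ry) - 1), min(rows, int(cy + ry) + 2)
        x0, x1 = max(0, int(cx - rx) - 1), min(cols, int(cx + rx) + 2)
        sub = (((rr[y0:y1, x0:x1] - cy) / ry) ** 2
               + ((cc[y0:y1, x0:x1] - cx) / rx) ** 2) <= 1.0
        ys, xs = np.nonzero(sub)
        ys, xs = ys + y0, xs + x0
        if ys.size < 9:
            raise SceneLayoutError(f"canopy of tree {rec.tree_id} has "
                                   f"{ys.size} pixels (< 9)")

        level = rec.level
        grain = config.texture_grain[level]
        tree_rgb = (np.asarray(config.class_color_means[level])
                    + rng.normal(0.0, config.class_color_sd, 3))
        for k in range(3):
            raster[k, ys, xs] = tree_rgb[k] + rng.normal(0, grain, ys.size)
        if config.ms_enabled:
            raster[3, ys, xs] = tree_rgb[2] + rng.normal(0, grain, ys.size)
            raster[4, ys, xs] = tree_rgb[1] + rng.normal(0, grain, ys.size)
            raster[5, ys, xs] = tree_rgb[0] + rng.normal(0, grain, ys.size)
            re_mean = config.class_re_means[level] + rng.normal(0, config.class_color_sd)
            nir_mean = config.class_nir_means[level] + rng.normal(0, config.class_color_sd)
            raster[6, ys, xs] = re_mean + rng.normal(0, grain, ys.size)
            raster[7, ys, xs] = nir_mean + rng.normal(0, grain, ys.size)

        if config.shadow_fraction > 0:
            n_shadow = int(round(config.shadow_fraction * ys.size))
            if n_shadow:
                pick = rng.choice(ys.size, size=n_shadow, replace=False)
                raster[:, ys[pick], xs[pick]] *= 0.5

        canopies[rec.tree_id] = (ys, xs)
        truth[rec.tree_id] = rec
        geoms[rec.tree_id] = shapely_scale(
            Point(cx, cy).buffer(1.0, quad_segs=16), xfact=rx, yfact=ry,
            origin=(cx, cy),
        )

    # strictly positive floor: real sensors never record exactly zero
    # radiance, and log-based indices (SCCI) are defined on the output
    np.clip(raster, 1e-4, 1.0, out=raster)
    return Scene(raster=raster, channel_names=config.channel_names,
                 canopies=canopies, truth=truth, canopy_geoms=geoms)


def write_scene(scene: Scene, out_dir: str | Path) -> None:
    """Persist raster (multi-page TIFF), canopies (GeoJSON) and survey CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "raster.tif", scene.raster.astype(np.float32),
                     photometric="minisblack",
                     metadata={"channels": list(scene.channel_names)})
    features = []
    for tid in scene.tree_ids:
        geom = scene.canopy_geoms.get(tid)
        if geom is None:  # fall back to the mask's bounding pixels
            ys, xs = scene.canopies[tid]
            geom = Point(float(xs.mean()), float(ys.mean())).buffer(
                max(1.0, (np.ptp(ys) + np.ptp(xs)) / 4), quad_segs=8)
        features.append({
            "type": "Feature",
            "geometry": mapping(geom),
            "properties": {"tree_id": tid, "level": scene.truth[tid].level},
        })
    (out / "canopies.geojson").write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}))
    write_survey_csv([scene.truth[t] for t in scene.tree_ids],
                     out / "survey.csv")


def read_scene(in_dir: str | Path,
               channel_names: Sequence[str] | None = None) -> Scene:
    """Load a persisted scene; masks are rasterised from the polygons."""
    src = Path(in_dir)
    raster = tifffile.imread(src / "raster.tif").astype(float)
    if channel_names is None:
        channel_names = (RGB_CHANNELS + MS_CHANNELS if raster.shape[0] == 8
                         else RGB_CHANNELS)
    records = {r.tree_id: r for r in read_survey_csv(src / "survey.csv")}
    collection = json.loads((src / "canopies.geojson").read_text())
    canopies: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    geoms: dict[int, object] = {}
    for feat in collection["features"]:
        tid = int(feat["properties"]["tree_id"])
        geom = shape(feat["geometry"])
        minx, miny, maxx, maxy = geom.bounds
        y0, y1 = max(0, int(miny)), min(raster.shape[1], int(maxy) + 2)
        x0, x1 = max(0, int(minx)), min(raster.shape[2], int(maxx) + 2)
        ys, xs = [], []
        for y in range(y0, y1):
            for x in range(x0, x1):
                if geom.covers(Point(x, y)):
                    ys.append(y)
                    xs.append(x)
        canopies[tid] = (np.asarray(ys, dtype=int), np.asarray(xs, dtype=int))
        geoms[tid] = geom
    return Scene(raster=np.clip(raster, 0, 1),
                 channel_names=tuple(channel_names),
                 canopies=canopies,
                 truth={t: records[t] for t in canopies},
                 canopy_geoms=geoms)
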