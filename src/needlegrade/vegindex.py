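"""Vegetation indices from RGB channels and multispectral bands.

Two index families are registered:

* ``RGB_VI`` — computed from camera channel reflectances R, G, B
  (e.g. ExG = 2G - R - B, RGRI = R/G, CIVE = 0.441R - 0.881G + 0.3856B
  + 18.78745);
* ``MS_VI`` — computed from multispectral band reflectances b, g, r, RE,
  NIR (e.g. NDVIreg = (NIR - RE)/(NIR + RE), TCARI, MTVI2).

Lower-case r, g, b appearing in some published RGB formulas are treated as
the channel reflectances themselves (no chromatic normalisation).
Indices carried over from the wider literature rather than from printed
formulas are flagged ``literature-sourced`` in the registry.

Per-tree features are the mean of the per-pixel index over each canopy
mask, optionally min-max normalised to [0, 1] with the bounds retained for
re-use on held-out data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .synthetic import Scene

__all__ = [
    "SpectralSample",
    "FeatureTable",
    "RGB_INDEX_NAMES",
    "MS_INDEX_NAMES",
    "TEXTURE_FEATURE_PREFIX",
    "rgb_index",
    "ms_index",
    "list_indices",
    "extract_canopy_means",
    "normalise",
    "apply_normalisation",
]

_EPS = 1e-9  # zero-denominator guard for ratio indices


def _safe_div(num, den):
    den = np.asarray(den, dtype=float)
    return np.asarray(num, dtype=float) / np.where(den == 0.0, _EPS, den)


@dataclass(frozen=True)
class SpectralSample:
    """Reflectances of one pixel (or one array of pixels)."""

    R: float | np.ndarray
    G: float | np.ndarray
    B: float | np.ndarray
    b: float | np.ndarray | None = None
    g: float | np.ndarray | None = None
    r: float | np.ndarray | None = None
    RE: float | np.ndarray | None = None
    NIR: float | np.ndarray | None = None

    def channels(self) -> dict[str, np.ndarray]:
        out = {}
        for name in ("R", "G", "B", "b", "g", "r", "RE", "NIR"):
            v = getattr(self, name)
            if v is not None:
                out[name] = np.asarray(v, dtype=float)
        return out


@dataclass(frozen=True)
class _IndexDef:
    name: str
    namespace: str  # "RGB_VI" or "MS_VI"
    requires: tuple[str, ...]
    fn: Callable[..., np.ndarray]
    source: str = "printed"  # "printed" or "literature-sourced"


def _ln(x):
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("logarithm of non-positive reflectance")
    return np.log(x)


_RGB_DEFS = [
    _IndexDef("R", "RGB_VI", ("R",), lambda R: np.asarray(R, float)),
    _IndexDef("G", "RGB_VI", ("G",), lambda G: np.asarray(G, float),
              source="literature-sourced"),
    _IndexDef("B", "RGB_VI", ("B",), lambda B: np.asarray(B, float)),
    _IndexDef("ExG", "RGB_VI", ("R", "G", "B"),
              lambda R, G, B: 2 * G - R - B),
    _IndexDef("ExR", "RGB_VI", ("R", "G"), lambda R, G: 1.4 * R - G),
    _IndexDef("GBRI", "RGB_VI", ("G", "B"), lambda G, B: _safe_div(G, B)),
    _IndexDef("GCC", "RGB_VI", ("R", "G", "B"),
              lambda R, G, B: _safe_div(G, R + G + B)),
    _IndexDef("RBRI", "RGB_VI", ("R", "B"), lambda R, B: _safe_div(R, B)),
    _IndexDef("RGRI", "RGB_VI", ("R", "G"), lambda R, G: _safe_div(R, G)),
    _IndexDef("VDVI", "RGB_VI", ("R", "G", "B"),
              lambda R, G, B: _safe_div(G - B - R, G + B + R)),
    _IndexDef("GLA", "RGB_VI", ("R", "G", "B"),
              lambda R, G, B: _safe_div(2 * G - R - B, 2 * G + R + B)),
    _IndexDef("CIVE", "RGB_VI", ("R", "G", "B"),
              lambda R, G, B: 0.441 * R - 0.881 * G + 0.3856 * B + 18.78745),
    _IndexDef("GB", "RGB_VI", ("G", "B"), lambda G, B: G - B),
    # indices named without printed formulas; standard literature definitions
    _IndexDef("VARI", "RGB_VI", ("R", "G", "B"),
              lambda R, G, B: _safe_div(G - R, G + R - B),
              source="literature-sourced"),
    _IndexDef("GRVI", "RGB_VI", ("R", "G"),
              lambda R, G: _safe_div(G - R, G + R),
              source="literature-sourced"),
    _IndexDef("NGRVI", "RGB_VI", ("R", "G"),
              lambda R, G: _safe_div(G**2 - R**2, G**2 + R**2),
              source="literature-sourced"),
    _IndexDef("PPR", "RGB_VI", ("G", "B"),
              lambda G, B: _safe_div(G - B, G + B),
              source="literature-sourced"),
    _IndexDef("WI", "RGB_VI", ("R", "G", "B"),
              lambda R, G, B: _safe_div(G - B, R - G),
              source="literature-sourced"),
    _IndexDef("ExGR", "RGB_VI", ("R", "G", "B"),
              lambda R, G, B: (2 * G - R - B) - (1.4 * R - G),
              source="literature-sourced"),
    _IndexDef("RGBVI", "RGB_VI", ("R", "G", "B"),
              lambda R, G, B: _safe_div(G**2 - B * R, G**2 + B * R),
              source="literature-sourced"),
]

_MS_DEFS = [
    _IndexDef("2NLI", "MS_VI", ("NIR", "g"),
              lambda NIR, g: _safe_div(NIR**2 - g, NIR**2 + g)),
    _IndexDef("GDVI", "MS_VI", ("NIR", "g"), lambda NIR, g: NIR - g),
    _IndexDef("GMNLI", "MS_VI", ("NIR", "g"),
              lambda NIR, g: 1.5 * _safe_div(np.sqrt(NIR) - g,
                                             np.sqrt(NIR) + g + 0.5)),
    _IndexDef("NDVIreg", "MS_VI", ("NIR", "RE"),
              lambda NIR, RE: _safe_div(NIR - RE, NIR + RE)),
    _IndexDef("SI1reg", "MS_VI", ("g", "RE"),
              lambda g, RE: np.sqrt(g * RE)),
    _IndexDef("SI1reg*", "MS_VI", ("r", "RE"),
              lambda r, RE: np.sqrt(r * RE)),
    _IndexDef("TCARI", "MS_VI", ("r", "g", "RE"),
              lambda r, g, RE: 3 * ((RE - r) - 0.2 * (RE - g) * _safe_div(RE, r))),
    _IndexDef("MTVI2", "MS_VI", ("NIR", "r", "g"),
              lambda NIR, r, g: _safe_div(
                  1.5 * (1.2 * (NIR - g) - 2.5 * (r - g)),
                  np.sqrt((2 * NIR + 1) ** 2
                          - (6 * NIR - 5 * np.sqrt(r)) - 0.5))),
    _IndexDef("Int2reg*", "MS_VI", ("g", "r", "RE"),
              lambda g, r, RE: (g + r + RE) / 2),
    _IndexDef("NDSIreg", "MS_VI", ("RE", "NIR"),
              lambda RE, NIR: _safe_div(RE - NIR, RE + NIR)),
    _IndexDef("RECI", "MS_VI", ("NIR", "RE"),
              lambda NIR, RE: _safe_div(NIR, RE) - 1),
    _IndexDef("SCCI", "MS_VI", ("NIR", "r"),
              lambda NIR, r: 100 * _safe_div(_ln(NIR) - _ln(r),
                                             _safe_div(NIR - r, NIR + r))),
    _IndexDef("SI2reg", "MS_VI", ("g", "RE", "NIR"),
              lambda g, RE, NIR: np.sqrt(g**2 + RE**2 + NIR**2)),
]

_REGISTRY: dict[str, _IndexDef] = {d.name: d for d in _RGB_DEFS + _MS_DEFS}
RGB_INDEX_NAMES: tuple[str, ...] = tuple(d.name for d in _RGB_DEFS)
MS_INDEX_NAMES: tuple[str, ...] = tuple(d.name for d in _MS_DEFS)
TEXTURE_FEATURE_PREFIX = "RGB_TF:"


def list_indices(namespace: str | None = None) -> list[dict]:
    """Registry listing: name, namespace, required channels, source."""
    return [
        {"name": d.name, "namespace": d.namespace,
         "requires": list(d.requires), "source": d.source}
        for d in _REGISTRY.values()
        if namespace is None or d.namespace == namespace
    ]


def _evaluate(name: str, channels: Mapping[str, np.ndarray],
              expect_namespace: str | None = None) -> np.ndarray:
    if name not in _REGISTRY:
        raise KeyError(f"unknown vegetation index {name!r}")
    d = _REGISTRY[name]
    if expect_namespace is not None and d.namespace != expect_namespace:
        raise KeyError(f"{name!r} is a {d.namespace} index, "
                       f"not {expect_namespace}")
    missing = [c for c in d.requires if c not in channels]
    if missing:
        raise ValueError(f"index {name!r} requires channels {missing}")
    return d.fn(*(channels[c] for c in d.requires))


def rgb_index(name: str, s: SpectralSample) -> float | np.ndarray:
    """Evaluate a registered RGB index on one sample (scalar or array)."""
    out = _evaluate(name, s.channels(), expect_namespace="RGB_VI")
    return out.item() if np.ndim(out) == 0 else out


def ms_index(name: str, s: SpectralSample) -> float | np.ndarray:
    """Evaluate a registered multispectral index on one sample."""
    out = _evaluate(name, s.channels(), expect_namespace="MS_VI")
    return out.item() if np.ndim(out) == 0 else out


@dataclass
class FeatureTable:
    """Trees x named features, with optional min-max normalisation state.

    Feature names are namespaced (``RGB_VI:ExG``, ``MS_VI:NDVIreg``,
    ``RGB_TF:con``). ``bounds`` maps feature -> (min, max) once normalised.
    """

    values: pd.DataFrame  # index = tree_id, columns = namespaced features
    normalised: bool = False
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError("feature names must be unique")
        if self.values.isna().any().any():
            raise ValueError("feature table contains missing values")
        if self.normalised:
            v = self.values.to_numpy()
            if v.size and (v.min() < -1e-12 or v.max() > 1 + 1e-12):
                raise ValueError("normalised values must lie in [0, 1]")

    @property
    def tree_ids(self) -> np.ndarray:
        return self.values.index.to_numpy()

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def select(self, features: Sequence[str]) -> "FeatureTable":
        missing = [f for f in features if f not in self.values.columns]
        if missing:
            raise KeyError(f"features not in table: {missing}")
        return FeatureTable(self.values[list(features)].copy(),
                            normalised=self.normalised,
                            bounds={f: self.bounds[f] for f in features
                                    if f in self.bounds})

    def join(self, other: "FeatureTable") -> "FeatureTable":
        if self.normalised != other.normalised:
            raise ValueError("cannot join tables with different "
                             "normalisation states")
        if not np.array_equal(self.tree_ids, other.tree_ids):
            raise ValueError("tables index different trees")
        return FeatureTable(pd.concat([self.values, other.values], axis=1),
                            normalised=self.normalised,
                            bounds={**self.bounds, **other.bounds})

    def to_csv(self, path: str | Path) -> None:
        self.values.rename_axis("tree_id").to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        return cls(pd.read_csv(path, index_col="tree_id"))


def extract_canopy_means(scene: Scene,
                         index_set: Sequence[str]) -> FeatureTable:
    """Per-tree canopy means of per-pixel vegetation indices.

    One row per tree (sorted by id), one column per requested index,
    namespaced by the index family.
    """
    defs = []
    for name in index_set:
        if name not in _REGISTRY:
            raise KeyError(f"unknown vegetation index {name!r}")
        d = _REGISTRY[name]
        missing = [c for c in d.requires if c not in scene.channel_names]
        if missing:
            raise ValueError(f"index {name!r} needs channels {missing} "
                             f"absent from the scene")
        defs.append(d)

    rows = {}
    for tid in scene.tree_ids:
        ys, xs = scene.canopies[tid]
        if ys.size == 0:
            raise ValueError(f"tree {tid} has an empty canopy mask")
        channels = {name: scene.raster[k, ys, xs]
                    for k, name in enumerate(scene.channel_names)}
        rows[tid] = [float(np.mean(d.fn(*(channels[c] for c in d.requires))))
                     for d in defs]
    df = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=[f"{d.namespace}:{d.name}" for d in defs]).sort_index()
    return FeatureTable(df)


def normalise(table: FeatureTable) -> FeatureTable:
    """Min-max scale each feature to [0, 1]; constant features map to 0."""
    if table.normalised:
        raise ValueError("table is already normalised")
    lo = table.values.min(axis=0)
    hi = table.values.max(axis=0)
    span = (hi - lo).replace(0.0, np.nan)
    scaled = ((table.values - lo) / span).fillna(0.0)
    bounds = {c: (float(lo[c]), float(hi[c])) for c in table.values.columns}
    return FeatureTable(scaled, normalised=True, bounds=bounds)


def apply_normalisation(table: FeatureTable,
                        bounds: Mapping[str, tuple[float, float]],
                        clip: bool = True) -> FeatureTable:
    """Scale a raw table with previously stored bounds (held-out data)."""
    if table.normalised:
        raise ValueError("table is already normalised")
    missing = [c for c in table.values.columns if c not in bounds]
    if missing:
        raise KeyError(f"no stored bounds for features: {missing}")
    out = table.values.copy()
    for c in out.columns:
        lo, hi = bounds[c]
        out[c] = 0.0 if hi == lo else (out[c] - lo) / (hi - lo)
    if clip:
        out = out.clip(0.0, 1.0)
    return FeatureTable(out, normalised=True, bounds=dict(bounds))
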