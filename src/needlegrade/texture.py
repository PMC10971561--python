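"""Grey-level co-occurrence texture over the first RGB principal component.

The canopy raster's R, G, B channels are reduced to their leading
principal component; a sliding-window grey-level co-occurrence matrix
(GLCM) is then built around every pixel and summarised by the eight
Haralick-style statistics

    mean = sum_i i * P_ij                 var  = sum (i - mean)^2 * P_ij
    hom  = sum P_ij / (1 + (i - j)^2)     con  = sum (i - j)^2 * P_ij
    dis  = sum |i - j| * P_ij             ent  = -sum P_ij * ln P_ij
    sm   = sum P_ij^2                     corr = sum (i-mu_i)(j-mu_j) P_ij / (s_i s_j)

with 0*ln 0 := 0 and corr := 1 when a window holds a single grey level.
Per-tree texture features (namespace ``RGB_TF``) are canopy means of these
statistic rasters.

Defaults (32 grey levels, 7x7 window, offsets (0,1),(1,0),(1,1),(1,-1)
averaged, symmetric) follow common remote-sensing co-occurrence practice.

Some published tables typeset these sums with an extra leading ``i``
factor inside dis/ent/sm; ``texture_stats(..., paper_literal=True)``
evaluates those literal variants for comparison, but the standard forms
above are the defaults throughout the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter

from .synthetic import Scene
from .vegindex import FeatureTable
import pandas as pd

__all__ = [
    "GLCM",
    "TextureSet",
    "TEXTURE_STAT_NAMES",
    "DEFAULT_OFFSETS",
    "pca_first_component",
    "quantise",
    "glcm",
    "texture_stats",
    "texture_rasters",
    "texture_feature_table",
]

TEXTURE_STAT_NAMES = ("mean", "var", "hom", "con", "dis", "ent", "sm", "corr")
DEFAULT_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))
DEFAULT_LEVELS = 32
DEFAULT_WINDOW = 7


@dataclass(frozen=True)
class GLCM:
    """Normalised co-occurrence probabilities at one spatial offset."""

    P: np.ndarray
    levels: int
    offset: tuple[int, int]
    symmetric: bool

    def __post_init__(self) -> None:
        if self.P.shape != (self.levels, self.levels):
            raise ValueError("P must be levels x levels")
        if np.any(self.P < 0) or abs(self.P.sum() - 1.0) > 1e-9:
            raise ValueError("P must be non-negative and sum to 1")
        if self.symmetric and not np.allclose(self.P, self.P.T, atol=1e-12):
            raise ValueError("symmetric GLCM must equal its transpose")


@dataclass(frozen=True)
class TextureSet:
    mean: float
    var: float
    hom: float
    con: float
    dis: float
    ent: float
    sm: float
    corr: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in TEXTURE_STAT_NAMES}


def pca_first_component(raster: np.ndarray) -> np.ndarray:
    """Project an RGB raster onto its leading channel principal component.

    The eigenvector sign is fixed so the green loading is non-negative and
    the output is linearly rescaled to [0, 1].
    """
    if raster.ndim != 3 or raster.shape[0] < 3:
        raise ValueError("expected a (>=3)-channel raster; uses channels 0..2")
    pixels = raster[:3].reshape(3, -1).T
    cov = np.cov(pixels, rowvar=False)
    if not np.any(cov > 1e-15):
        raise ValueError("constant raster: channel covariance is degenerate")
    eigvals, eigvecs = np.linalg.eigh(cov)
    v = eigvecs[:, -1]
    if v[1] < 0:
        v = -v
    pc1 = (pixels - pixels.mean(axis=0)) @ v
    lo, hi = pc1.min(), pc1.max()
    if hi == lo:
        raise ValueError("degenerate projection: PC1 is constant")
    return ((pc1 - lo) / (hi - lo)).reshape(raster.shape[1:])


def quantise(image: np.ndarray, levels: int) -> np.ndarray:
    """Linear binning of a [0, 1] image into integer grey levels."""
    if levels < 2:
        raise ValueError("levels must be >= 2")
    q = np.floor(np.clip(image, 0.0, 1.0) * levels).astype(np.intp)
    return np.minimum(q, levels - 1)


def glcm(window: np.ndarray, levels: int, offset: tuple[int, int],
         symmetric: bool = True) -> GLCM:
    """Co-occurrence matrix of a quantised patch at one offset."""
    if levels < 2:
        raise ValueError("levels must be >= 2")
    patch = np.asarray(window)
    if patch.min() < 0 or patch.max() >= levels:
        raise ValueError("patch values must lie in [0, levels)")
    dr, dc = offset
    h, w = patch.shape
    if h <= abs(dr) or w <= abs(dc):
        raise ValueError("patch dimensions must exceed the offset span")
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    a = patch[r0:r1, c0:c1].ravel()
    b = patch[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()
    if a.size == 0:
        raise ValueError("no valid pixel pairs at this offset")
    counts = np.zeros((levels, levels))
    np.add.at(counts, (a, b), 1.0)
    if symmetric:
        counts = counts + counts.T
    return GLCM(P=counts / counts.sum(), levels=levels, offset=offset,
                symmetric=symmetric)


def texture_stats(m: GLCM, paper_literal: bool = False) -> TextureSet:
    """The eight co-occurrence statistics of one GLCM.

    ``paper_literal=True`` evaluates the typeset variants that carry an
    extra leading ``i`` factor inside dis, ent and sm.
    """
    P = m.P
    i = np.arange(m.levels)[:, None].astype(float)
    j = np.arange(m.levels)[None, :].astype(float)
    mu_i = float((i * P).sum())
    mu_j = float((j * P).sum())
    var_i = float(((i - mu_i) ** 2 * P).sum())
    var_j = float(((j - mu_j) ** 2 * P).sum())
    lit = i if paper_literal else 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        lnP = np.where(P > 0, np.log(np.where(P > 0, P, 1.0)), 0.0)
    hom = float((P / (1.0 + (i - j) ** 2)).sum())
    con = float(((i - j) ** 2 * P).sum())
    dis = float((lit * np.abs(i - j) * P).sum())
    ent = float((-lit * P * lnP).sum())
    sm = float((lit * P * P).sum())
    if var_i <= 0 or var_j <= 0:
        corr = 1.0  # single-level window: perfectly correlated by convention
    else:
        corr = float((((i - mu_i) * (j - mu_j) * P).sum())
                     / np.sqrt(var_i * var_j))
    return TextureSet(mean=mu_i, var=var_i, hom=hom, con=con, dis=dis,
                      ent=ent, sm=sm, corr=corr)


def _offset_pair_maps(q: np.ndarray, offset: tuple[int, int],
                      pad: int) -> tuple[np.ndarray, np.ndarray]:
    """Origin/neighbour grey values per padded pixel for one offset."""
    dr, dc = offset
    qp = np.pad(q, pad + max(abs(dr), abs(dc)), mode="reflect")
    e = max(abs(dr), abs(dc))
    H, W = q.shape
    a = qp[e:e + H + 2 * pad, e:e + W + 2 * pad]
    b = qp[e + dr:e + dr + H + 2 * pad, e + dc:e + dc + W + 2 * pad]
    return a, b


def texture_rasters(pc1: np.ndarray,
                    window: int = DEFAULT_WINDOW,
                    levels: int = DEFAULT_LEVELS,
                    offsets: Sequence[tuple[int, int]] = DEFAULT_OFFSETS,
                    ) -> dict[str, np.ndarray]:
    """Per-pixel sliding-window texture statistics, averaged over offsets.

    Each pixel's GLCM collects the symmetric co-occurrence pairs whose
    origin falls in the window centred on it; edges use reflective
    padding. The eight statistics are computed per offset and averaged.
    """
    if window < 2 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    span = max(max(abs(dr), abs(dc)) for dr, dc in offsets)
    if window <= span:
        raise ValueError("window must exceed the offset span")
    q = quantise(pc1, levels)
    pad = window // 2
    H, W = q.shape
    out = {name: np.zeros((H, W)) for name in TEXTURE_STAT_NAMES}

    def uf(x):
        return uniform_filter(x.astype(float), size=window,
                              mode="constant")[pad:pad + H, pad:pad + W]

    for offset in offsets:
        a, b = _offset_pair_maps(q, offset, pad)
        af = a.astype(float)
        bf = b.astype(float)
        mu = uf((af + bf) / 2.0)
        e2 = uf((af**2 + bf**2) / 2.0)
        var = np.maximum(e2 - mu**2, 0.0)
        con = uf((af - bf) ** 2)
        dis = uf(np.abs(af - bf))
        hom = uf(1.0 / (1.0 + (af - bf) ** 2))
        eij = uf(af * bf)
        cov = eij - mu**2
        corr = np.where(var > 1e-12, cov / np.where(var > 1e-12, var, 1.0), 1.0)

        # ent and sm need the per-window joint histogram: accumulate over
        # unordered grey-pair codes that actually occur
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        codes = lo * levels + hi
        ent = np.zeros((H, W))
        sm = np.zeros((H, W))
        for code in np.unique(codes):
            u = uf(codes == code)
            pos = u > 0
            i_lvl, j_lvl = divmod(int(code), levels)
            if i_lvl == j_lvl:
                sm += u * u
                ent[pos] -= u[pos] * np.log(u[pos])
            else:  # symmetric: mass u splits evenly across (i,j) and (j,i)
                sm += u * u / 2.0
                ent[pos] -= u[pos] * np.log(u[pos] / 2.0)

        out["mean"] += mu
        out["var"] += var
        out["hom"] += hom
        out["con"] += con
        out["dis"] += dis
        out["ent"] += ent
        out["sm"] += sm
        out["corr"] += corr

    k = float(len(offsets))
    return {name: arr / k for name, arr in out.items()}


def texture_feature_table(scene: Scene,
                          window: int = DEFAULT_WINDOW,
                          levels: int = DEFAULT_LEVELS,
                          offsets: Sequence[tuple[int, int]] = DEFAULT_OFFSETS,
                          ) -> FeatureTable:
    """Canopy-mean texture features (RGB_TF namespace) for every tree.

    The statistic rasters are cached on the scene per parameter set, so
    feature sets that share a scene do not recompute them.
    """
    key = (window, levels, tuple(offsets))
    cache = getattr(scene, "_texture_cache", None)
    if cache is not None and cache[0] == key:
        return FeatureTable(cache[1].copy())
    pc1 = pca_first_component(scene.raster)
    rasters = texture_rasters(pc1, window=window, levels=levels,
                              offsets=offsets)
    rows = {}
    for tid in scene.tree_ids:
        ys, xs = scene.canopies[tid]
        if ys.size == 0:
            raise ValueError(f"tree {tid} has an empty canopy mask")
        rows[tid] = [float(rasters[name][ys, xs].mean())
                     for name in TEXTURE_STAT_NAMES]
    df = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=[f"RGB_TF:{n}" for n in TEXTURE_STAT_NAMES]).sort_index()
    scene._texture_cache = (key, df.copy())
    return FeatureTable(df)
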