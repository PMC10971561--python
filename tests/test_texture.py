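"""PCA projection, GLCM construction and the eight texture statistics."""

import math

import numpy as np
import pytest

from _oracles import naive_glcm, naive_stats

from needlegrade import SceneConfig, generate_scene
from needlegrade.texture import (GLCM, TEXTURE_STAT_NAMES, glcm,
                                 pca_first_component, quantise,
                                 texture_feature_table, texture_rasters,
                                 texture_stats)


# ---------------------------------------------------------------- PCA

def test_pc1_recovers_greyscale_structure(rng):
    grey = rng.uniform(0, 1, (16, 16))
    raster = np.stack([grey, grey, grey])
    pc1 = pca_first_component(raster)
    flat_g, flat_p = grey.ravel(), pc1.ravel()
    corr = np.corrcoef(flat_g, flat_p)[0, 1]
    assert corr == pytest.approx(1.0, abs=1e-10)


def test_pc1_variance_dominates_single_channels(rng):
    raster = rng.uniform(0, 1, (3, 12, 12))
    pixels = raster.reshape(3, -1)
    cov = np.cov(pixels, rowvar=False)
    top = np.linalg.eigvalsh(cov)[-1]
    assert top >= np.var(pixels, axis=1, ddof=1).max() - 1e-12


def test_pc1_separates_two_colours():
    raster = np.zeros((3, 4, 4))
    raster[:, :, 2:] = np.array([0.8, 0.2, 0.1])[:, None, None]
    raster[:, :, :2] = np.array([0.1, 0.7, 0.2])[:, None, None]
    pc1 = pca_first_component(raster)
    vals = np.unique(np.round(pc1, 9))
    assert vals.size == 2 and {0.0, 1.0} == set(vals.tolist())


def test_pc1_rejects_constant_raster():
    with pytest.raises(ValueError):
        pca_first_component(np.full((3, 5, 5), 0.3))


# ---------------------------------------------------------------- GLCM

def test_constant_patch_single_cell():
    m = glcm(np.full((5, 5), 3), levels=8, offset=(0, 1), symmetric=True)
    assert m.P[3, 3] == pytest.approx(1.0)
    assert m.P.sum() == pytest.approx(1.0)


def test_two_by_two_alternating_patch():
    m = glcm(np.array([[0, 1], [0, 1]]), levels=2, offset=(0, 1),
             symmetric=True)
    assert m.P[0, 1] == pytest.approx(0.5)
    assert m.P[1, 0] == pytest.approx(0.5)


@pytest.mark.parametrize("offset", [(0, 1), (1, 0), (1, 1), (1, -1)])
@pytest.mark.parametrize("symmetric", [True, False])
def test_glcm_matches_naive_oracle(rng, offset, symmetric):
    for _ in range(10):
        patch = rng.integers(0, 6, (7, 9))
        m = glcm(patch, levels=6, offset=offset, symmetric=symmetric)
        assert np.allclose(m.P, naive_glcm(patch, 6, offset, symmetric),
                           atol=1e-12)
        assert m.P.sum() == pytest.approx(1.0, abs=1e-12)


def test_glcm_matches_skimage():
    skimage_feature = pytest.importorskip("skimage.feature")
    rng = np.random.default_rng(5)
    patch = rng.integers(0, 8, (12, 12))
    m = glcm(patch, levels=8, offset=(0, 1), symmetric=True)
    ref = skimage_feature.graycomatrix(patch.astype(np.uint8), [1], [0],
                                       levels=8, symmetric=True, normed=True)
    assert np.allclose(m.P, ref[:, :, 0, 0], atol=1e-12)


def test_glcm_parameter_errors():
    with pytest.raises(ValueError):
        glcm(np.zeros((2, 2), dtype=int), levels=1, offset=(0, 1))
    with pytest.raises(ValueError):
        glcm(np.zeros((2, 2), dtype=int), levels=4, offset=(0, 2))


# ----------------------------------------------------------- statistics

def test_stats_constant_patch():
    s = texture_stats(glcm(np.full((5, 5), 2), levels=4, offset=(0, 1)))
    assert s.con == 0 and s.dis == 0 and s.ent == 0
    assert s.sm == pytest.approx(1.0) and s.hom == pytest.approx(1.0)
    assert s.corr == 1.0  # degenerate single-level convention


def test_stats_two_cell_closed_form():
    P = np.zeros((2, 2))
    P[0, 1] = P[1, 0] = 0.5
    s = texture_stats(GLCM(P=P, levels=2, offset=(0, 1), symmetric=True))
    assert s.con == pytest.approx(1.0)
    assert s.dis == pytest.approx(1.0)
    assert s.sm == pytest.approx(0.5)
    assert s.ent == pytest.approx(math.log(2))


def test_stats_match_naive_oracle_on_random_patches(rng):
    for _ in range(50):
        patch = rng.integers(0, 8, (8, 8))
        m = glcm(patch, levels=8, offset=(1, 0), symmetric=True)
        got = texture_stats(m).as_dict()
        want = naive_stats(m.P)
        for k in TEXTURE_STAT_NAMES:
            assert got[k] == pytest.approx(want[k], abs=1e-10), k


def test_paper_literal_variants_apply_row_weight(rng):
    patch = rng.integers(0, 6, (8, 8))
    m = glcm(patch, levels=6, offset=(0, 1), symmetric=True)
    lit = texture_stats(m, paper_literal=True)
    i = np.arange(6)[:, None].astype(float)
    j = np.arange(6)[None, :].astype(float)
    P = m.P
    assert lit.dis == pytest.approx(float((i * np.abs(i - j) * P).sum()))
    assert lit.sm == pytest.approx(float((i * P * P).sum()))


# --------------------------------------------------------- raster mode

def test_interior_contrast_vanishes_on_noiseless_scene(noiseless_config):
    scene = generate_scene(noiseless_config)
    pc1 = pca_first_component(scene.raster)
    rasters = texture_rasters(pc1, window=5)
    for tid in scene.tree_ids:
        ys, xs = scene.canopies[tid]
        # strict interior: the whole window + offset reach stays in-mask
        pix = set(zip(ys.tolist(), xs.tolist()))
        reach = range(-3, 4)  # window half-width 2 plus offset span 1
        interior = [(y, x) for y, x in pix
                    if all((y + dy, x + dx) in pix
                           for dy in reach for dx in reach)]
        if interior:
            yy = [p[0] for p in interior]
            xx = [p[1] for p in interior]
            assert rasters["con"][yy, xx].max() == pytest.approx(0.0, abs=1e-9)


def test_texture_grain_orders_contrast():
    """Higher texture grain -> larger canopy contrast, averaged over
    10 seeds with shadows and colour jitter off (canopy-edge effects
    dominate any single small scene)."""
    per_seed = []
    for seed in range(10):
        cfg = SceneConfig(n_trees_per_class=12, shadow_fraction=0.0,
                          class_color_sd=0.0, seed=seed)
        scene = generate_scene(cfg)
        table = texture_feature_table(scene, window=5)
        per_seed.append(table.values["RGB_TF:con"].groupby(scene.labels).mean())
    import pandas as pd
    by_level = pd.concat(per_seed, axis=1).mean(axis=1)
    assert by_level[1] < by_level[2] < by_level[3] < by_level[4]


def test_entropy_ordering_is_seed_stable():
    """Canopy entropy orders the classes the same way across seeds."""
    orders = set()
    for seed in (0, 1, 2):
        scene = generate_scene(SceneConfig(n_trees_per_class=10, seed=seed))
        table = texture_feature_table(scene, window=5)
        by_level = table.values["RGB_TF:ent"].groupby(scene.labels).mean()
        orders.add(tuple(by_level.sort_values().index.tolist()))
    assert len(orders) == 1
    (order,) = orders
    assert order[0] == 1  # healthiest canopies have the least texture entropy


def test_texture_rasters_parameter_errors():
    with pytest.raises(ValueError):
        texture_rasters(np.zeros((5, 5)), window=4)
    with pytest.raises(ValueError):
        texture_rasters(np.zeros((5, 5)), window=1)


def test_quantise_bins_unit_interval():
    q = quantise(np.array([0.0, 0.49, 0.51, 1.0]), levels=2)
    assert q.tolist() == [0, 0, 1, 1]
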