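"""Vegetation-index formulas, canopy aggregation and normalisation."""

import numpy as np
import pandas as pd
import pytest

from needlegrade import generate_scene
from needlegrade.vegindex import (FeatureTable, MS_INDEX_NAMES,
                                  RGB_INDEX_NAMES, SpectralSample,
                                  apply_normalisation, extract_canopy_means,
                                  list_indices, ms_index, normalise,
                                  rgb_index)

from _oracles import GOLDEN, POINTS


@pytest.mark.parametrize("name", sorted(GOLDEN))
def test_index_formulas_match_independent_recomputation(name):
    fn = rgb_index if name in RGB_INDEX_NAMES else ms_index
    for sample, expected in zip(POINTS, GOLDEN[name]):
        assert fn(name, sample) == pytest.approx(expected, abs=1e-9)


def test_registry_covers_golden_set():
    assert set(GOLDEN) == set(RGB_INDEX_NAMES) | set(MS_INDEX_NAMES)


@pytest.mark.parametrize("name, sample, expected", [
    ("CIVE", SpectralSample(R=0, G=0, B=0), 18.78745),
    ("ExG", SpectralSample(R=0.3, G=0.3, B=0.3), 0.0),
    ("RGRI", SpectralSample(R=0.3, G=0.3, B=0.1), 1.0),
    ("VDVI", SpectralSample(R=0.1, G=0.4, B=0.1), 1.0 / 3.0),
])
def test_rgb_special_cases(name, sample, expected):
    assert rgb_index(name, sample) == pytest.approx(expected, abs=1e-9)


@pytest.mark.parametrize("name, sample, expected", [
    ("NDVIreg", SpectralSample(R=0, G=0, B=0, RE=0.4, NIR=0.4), 0.0),
    ("GDVI", SpectralSample(R=0, G=0, B=0, g=0.2, NIR=0.5), 0.3),
    ("SI1reg", SpectralSample(R=0, G=0, B=0, g=0.04, RE=0.25), 0.1),
    ("RECI", SpectralSample(R=0, G=0, B=0, RE=0.3, NIR=0.3), 0.0),
])
def test_ms_special_cases(name, sample, expected):
    assert ms_index(name, sample) == pytest.approx(expected, abs=1e-9)


def test_zero_denominator_fallback_is_finite():
    v = rgb_index("RGRI", SpectralSample(R=0.3, G=0.0, B=0.1))
    assert np.isfinite(v)


def test_unknown_or_misplaced_index_name():
    with pytest.raises(KeyError):
        rgb_index("NOPE", POINTS[0])
    with pytest.raises(KeyError):
        ms_index("RGRI", POINTS[0])  # RGB index queried as multispectral
    with pytest.raises(ValueError):
        ms_index("NDVIreg", SpectralSample(R=0.1, G=0.2, B=0.3))


def test_scci_rejects_nonpositive_reflectance():
    with pytest.raises(ValueError):
        ms_index("SCCI", SpectralSample(R=0, G=0, B=0, r=0.0, NIR=0.5))


def test_canopy_means_on_constant_canopies(noiseless_config):
    """Zero-noise canopies: the mean equals the pixel-level formula."""
    scene = generate_scene(noiseless_config)
    table = extract_canopy_means(scene, ["RGRI", "ExG", "CIVE"])
    for tid in scene.tree_ids:
        level = scene.truth[tid].level
        R, G, B = noiseless_config.class_color_means[level]
        s = SpectralSample(R=R, G=G, B=B)
        for name in ("RGRI", "ExG", "CIVE"):
            got = table.values.loc[tid, f"RGB_VI:{name}"]
            assert got == pytest.approx(rgb_index(name, s), abs=1e-9)


def test_canopy_mean_is_arithmetic_mean(small_scene):
    tid = small_scene.tree_ids[0]
    ys, xs = small_scene.canopies[tid]
    table = extract_canopy_means(small_scene, ["ExG"])
    R = small_scene.raster[0, ys, xs]
    G = small_scene.raster[1, ys, xs]
    B = small_scene.raster[2, ys, xs]
    assert table.values.loc[tid, "RGB_VI:ExG"] == pytest.approx(
        np.mean(2 * G - R - B), abs=1e-12)


def test_mask_order_does_not_change_table(small_scene):
    table = extract_canopy_means(small_scene, ["ExG", "RGRI"])
    reordered = dict(reversed(list(small_scene.canopies.items())))
    from needlegrade.synthetic import Scene
    scene2 = Scene(raster=small_scene.raster,
                   channel_names=small_scene.channel_names,
                   canopies=reordered, truth=small_scene.truth)
    table2 = extract_canopy_means(scene2, ["ExG", "RGRI"])
    pd.testing.assert_frame_equal(table.values, table2.values)


def test_rgri_separates_classes_on_noiseless_scene(noiseless_config):
    """Red/green ratio rises monotonically through the green -> yellow ->
    red progression and stays elevated for grey canopies (R = G there, so
    the ratio returns to 1 — above healthy but below the red peak)."""
    scene = generate_scene(noiseless_config)
    table = extract_canopy_means(scene, ["RGRI"])
    by_level = table.values["RGB_VI:RGRI"].groupby(scene.labels).mean()
    assert by_level[1] < by_level[2] < by_level[3]
    assert by_level[1] < by_level[4] < by_level[3]
    assert len(set(np.round(by_level, 9))) == 4


def test_normalise_minmax_and_constant_rule():
    df = pd.DataFrame({"a": [2.0, 4.0, 6.0], "b": [5.0, 5.0, 5.0]},
                      index=[1, 2, 3])
    out = normalise(FeatureTable(df))
    assert out.values["a"].tolist() == [0.0, 0.5, 1.0]
    assert out.values["b"].tolist() == [0.0, 0.0, 0.0]
    assert out.normalised and out.bounds["a"] == (2.0, 6.0)
    with pytest.raises(ValueError):
        normalise(out)  # double normalisation is a usage error


def test_stored_bounds_reproduce_normalisation():
    df = pd.DataFrame({"a": [2.0, 4.0, 6.0]}, index=[1, 2, 3])
    table = FeatureTable(df)
    out = normalise(table)
    again = apply_normalisation(table, out.bounds)
    pd.testing.assert_frame_equal(out.values, again.values)


def test_listing_flags_literature_sourced_indices():
    entries = {e["name"]: e for e in list_indices("RGB_VI")}
    assert entries["CIVE"]["source"] == "printed"
    assert entries["VARI"]["source"] == "literature-sourced"
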