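import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gliotile.synthetic import ROIAnnotation
from gliotile.tiling import (
    ChannelStats,
    D4_TAGS,
    TileDataset,
    apply_d4,
    augment_d4,
    augment_dataset,
    compute_channel_stats,
    count_tiles,
    d4_views,
    denormalize_array,
    extract_roi_tiles,
    grid_tiles,
    normalize_array,
    normalize_tiles,
    tissue_filter,
)
from conftest import make_slide, make_tile


# ---------------------------------------------------------------------- tiling
@pytest.mark.parametrize(
    "w,h,t,s,expected",
    [
        (1024, 1024, 512, 256, 9),
        (512, 512, 512, 256, 1),
        (500, 800, 512, 256, 0),
        (1024, 512, 512, 256, 3),
        (64, 64, 64, 32, 1),
    ],
)
def test_count_tiles_examples(w, h, t, s, expected):
    assert count_tiles(w, h, t, s) == expected


def test_count_tiles_rejects_bad_stride():
    with pytest.raises(ValueError):
        count_tiles(100, 100, 10, 0)
    with pytest.raises(ValueError):
        count_tiles(100, 100, 0, 5)


@given(
    length=st.integers(0, 64),
    tile=st.integers(1, 16),
    stride=st.integers(1, 16),
)
def test_count_tiles_matches_enumeration_1d(length, tile, stride):
    positions = [x for x in range(0, length) if x % stride == 0 and x + tile <= length]
    assert count_tiles(length, length, tile, stride) == len(positions) ** 2


def test_extract_positions_match_brute_force():
    rois = [ROIAnnotation(0, 0, 1024, 512, "gbm")]
    slide = make_slide(1024, 512, "gbm", rois, image=np.zeros((512, 1024, 3), np.uint8))
    ds = extract_roi_tiles(slide, tile_size=512, overlap=0.5)
    assert sorted(t.x for t in ds) == [0, 256, 512]
    assert all(t.label == "gbm" and t.provenance == "ground_truth" for t in ds)


def test_disjoint_rois_union_without_cross_tiles():
    img = np.zeros((128, 256, 3), np.uint8)
    rois = [ROIAnnotation(0, 0, 64, 64, "gbm"), ROIAnnotation(128, 64, 64, 64, "normal")]
    slide = make_slide(256, 128, "gbm", rois, image=img)
    ds = extract_roi_tiles(slide, tile_size=64, overlap=0.5)
    assert ds.class_counts == {"gbm": 1, "normal": 1}
    for t in ds:
        # tile fully inside exactly one ROI
        inside = [
            r
            for r in rois
            if t.x >= r.x and t.y >= r.y and t.x + 64 <= r.x + r.width and t.y + 64 <= r.y + r.height
        ]
        assert len(inside) == 1


def test_conflicting_overlapping_rois_raise():
    img = np.zeros((64, 128, 3), np.uint8)
    rois = [ROIAnnotation(0, 0, 96, 64, "gbm"), ROIAnnotation(0, 0, 64, 64, "necrosis")]
    slide = make_slide(128, 64, "gbm", rois, image=img)
    with pytest.raises(ValueError, match="conflicting"):
        extract_roi_tiles(slide, tile_size=64, overlap=0.5)


def test_roi_outside_slide_names_slide_and_roi():
    slide = make_slide(64, 64, "gbm", [ROIAnnotation(32, 0, 64, 64, "gbm")], slide_id="bad1")
    with pytest.raises(ValueError, match="bad1"):
        extract_roi_tiles(slide, tile_size=32)


def test_extraction_order_is_slide_y_x(small_cohort):
    s = small_cohort.slides[0]
    ds = extract_roi_tiles(s, tile_size=64)
    keys = [(t.slide_id, t.y, t.x) for t in ds]
    assert keys == sorted(keys)


def test_grid_tiles_full_slide_and_exclusion():
    img = np.zeros((1024, 1024, 3), np.uint8)
    slide = make_slide(1024, 1024, "gbm", [], image=img)
    assert len(grid_tiles(slide, 512, 0.5)) == 9
    covered = make_slide(
        1024, 1024, "gbm", [ROIAnnotation(0, 0, 1024, 1024, "gbm")], image=img
    )
    assert len(grid_tiles(covered, 512, 0.5, exclude_rois=True)) == 0


def test_grid_exclusion_matches_rectangle_intersection_oracle():
    img = np.zeros((1024, 1536, 3), np.uint8)
    roi = ROIAnnotation(0, 0, 512, 512, "gbm")
    slide = make_slide(1536, 1024, "gbm", [roi], image=img)
    kept = {(t.x, t.y) for t in grid_tiles(slide, 512, 0.5, exclude_rois=True)}
    expected = set()
    for y in range(0, 1024 - 512 + 1, 256):
        for x in range(0, 1536 - 512 + 1, 256):
            intersects = x < roi.x + roi.width and roi.x < x + 512 and y < roi.y + roi.height and roi.y < y + 512
            if not intersects:
                expected.add((x, y))
    assert kept == expected
    full = len(grid_tiles(slide, 512, 0.5))
    assert full - len(kept) == 4  # the four positions touching the corner ROI


# ---------------------------------------------------------------- tissue filter
def test_tissue_filter_boundary_conventions():
    white = make_tile(value=255, size=20)
    dark = make_tile(value=0, size=20)
    ds = TileDataset([white, dark])
    kept = tissue_filter(ds, 0.05)
    assert kept.tiles == [dark]
    assert tissue_filter(ds, 0.0).tiles == ds.tiles  # pass-through
    # exactly 5% dark pixels is retained (inclusive comparison)
    pix = np.full((20, 20, 3), 255, np.uint8)
    pix[0, :, :] = 0  # 20/400 = 5%
    borderline = make_tile()
    borderline.pixels = pix
    assert len(tissue_filter(TileDataset([borderline]), 0.05)) == 1


# ------------------------------------------------------------------ dihedral D4
def _asym():
    return np.arange(48, dtype=np.uint8).reshape(4, 4, 3)


def test_d4_orbit_has_eight_distinct_views_for_asymmetric_input():
    views = d4_views(_asym())
    assert set(views) == set(D4_TAGS)
    raw = {v.tobytes() for v in views.values()}
    assert len(raw) == 8


def test_d4_orbit_of_constant_tile_is_eight_identical_arrays():
    views = d4_views(np.full((4, 4, 3), 7, np.uint8))
    assert len(views) == 8
    assert len({v.tobytes() for v in views.values()}) == 1


def test_d4_orbit_closure():
    orbit = {v.tobytes() for v in d4_views(_asym()).values()}
    for member in d4_views(_asym()).values():
        assert {v.tobytes() for v in d4_views(member).values()} == orbit


def test_apply_d4_matches_views():
    views = d4_views(_asym())
    for tag, v in views.items():
        assert np.array_equal(apply_d4(_asym(), tag), v)
    with pytest.raises(ValueError):
        apply_d4(_asym(), "r45")


def test_augment_preserves_labels_and_multiplies_counts_by_eight():
    tiles = [make_tile(x=i * 16, label="gbm", split="train") for i in range(3)]
    tiles += [make_tile(x=i * 16, y=99, label="normal", split="test") for i in range(2)]
    ds = augment_dataset(TileDataset(tiles))
    assert ds.class_counts == {"gbm": 24, "normal": 2}
    assert all(t.augmentation_tag == "r0" for t in ds if t.split == "test")


def test_augmenting_a_test_tile_is_an_error():
    with pytest.raises(ValueError, match="test"):
        augment_d4(make_tile(split="test"))


def test_non_square_tile_rejected():
    t = make_tile()
    t.pixels = np.zeros((4, 8, 3), np.uint8)
    with pytest.raises(ValueError, match="square"):
        augment_d4(t)


# -------------------------------------------------------------- channel stats
def test_constant_tiles_give_exact_mean_and_floored_std():
    tiles = [make_tile(value=0) for _ in range(3)]
    for t in tiles:
        t.pixels = np.empty((8, 8, 3), np.uint8)
        t.pixels[..., 0], t.pixels[..., 1], t.pixels[..., 2] = 100, 150, 200
    stats = compute_channel_stats(tiles)
    assert np.allclose(stats.mean, [100, 150, 200])
    assert np.allclose(stats.std, 1e-6)


def test_two_value_channel_mean():
    a, b = make_tile(value=0, size=4), make_tile(value=2, size=4)
    stats = compute_channel_stats([a, b])
    assert np.allclose(stats.mean, 1.0)


def test_stats_match_brute_force_pixel_pool():
    rng = np.random.default_rng(0)
    tiles = []
    for _ in range(50):
        t = make_tile()
        t.pixels = rng.integers(0, 256, size=(12, 12, 3)).astype(np.uint8)
        tiles.append(t)
    stats = compute_channel_stats(tiles)
    pool = np.concatenate([t.pixels.reshape(-1, 3).astype(float) for t in tiles])
    assert np.allclose(stats.mean, pool.mean(axis=0))
    assert np.allclose(stats.std, pool.std(axis=0))


def test_empty_tile_set_rejected():
    with pytest.raises(ValueError):
        compute_channel_stats([])


# ---------------------------------------------------------------- normalization
def test_normalizing_with_own_stats_centers_and_scales():
    rng = np.random.default_rng(1)
    tiles = []
    for _ in range(10):
        t = make_tile()
        t.pixels = rng.integers(0, 256, size=(8, 8, 3)).astype(np.uint8)
        tiles.append(t)
    ds = TileDataset(tiles)
    stats = compute_channel_stats(tiles)
    normed = normalize_tiles(ds, stats)
    pool = np.concatenate([t.pixels.reshape(-1, 3) for t in normed])
    assert np.allclose(pool.mean(axis=0), 0.0, atol=1e-9)
    assert np.allclose(pool.std(axis=0), 1.0, atol=1e-9)


def test_identity_stats_and_round_trip():
    x = np.random.default_rng(2).uniform(0, 255, (6, 6, 3))
    ident = ChannelStats(mean=np.zeros(3), std=np.ones(3))
    assert np.allclose(normalize_array(x, ident), x)
    stats = ChannelStats(mean=np.array([10.0, 20.0, 30.0]), std=np.array([2.0, 3.0, 4.0]))
    assert np.allclose(denormalize_array(normalize_array(x, stats), stats), x, atol=1e-6)


def test_channel_mismatch_rejected():
    stats = ChannelStats(mean=np.zeros(4), std=np.ones(4))
    with pytest.raises(ValueError, match="channel"):
        normalize_array(np.zeros((4, 4, 3)), stats)
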