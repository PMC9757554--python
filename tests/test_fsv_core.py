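import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from octafsv import (
    AlgorithmParams,
    EnFaceScan,
    ScanMeta,
    ValidationError,
    apply_clahe,
    compute_metrics,
    filter_components,
    normalize_minmax,
    run_fsv,
    soft_dilate,
    threshold_inverse,
)
from octafsv._clahe import clahe, tile_luts
from octafsv.fsv_core import VoidMask
from octafsv.synthetic_data import SceneTruth, _disc_mask, render_scan_pair

from _oracles import dilate_set, global_hist_eq


def scan_of(meta, arr):
    return EnFaceScan(meta=meta, pixels=np.asarray(arr, dtype=np.uint8))


# ---------------------------------------------------------------- normalize

def test_normalize_linear_scaling_example():
    meta = ScanMeta("e", "CSCR", "inner_CC", 1, grid_px=2)
    out = normalize_minmax(scan_of(meta, [[10, 20], [30, 50]]))
    assert out.pixels.tolist() == [[0, 64], [128, 255]]


def test_normalize_constant_image_warns_and_zeroes(meta64):
    scan = scan_of(meta64, np.full((64, 64), 77))
    with pytest.warns(UserWarning):
        out = normalize_minmax(scan)
    assert not out.pixels.any()


def test_normalize_fixes_range_endpoints(random_scan64):
    px = random_scan64.pixels.copy()
    px[0, 0], px[0, 1] = 0, 255  # image already spans the full range
    out = normalize_minmax(random_scan64.with_pixels(px))
    assert out.pixels.min() == 0 and out.pixels.max() == 255
    assert np.array_equal(out.pixels, px)  # identity when already 0..255


@settings(derandomize=True, max_examples=25)
@given(st.integers(0, 255), st.integers(0, 255))
def test_normalize_output_spans_full_range(lo, hi):
    meta = ScanMeta("e", "CSCR", "inner_CC", 1, grid_px=2)
    if lo == hi:
        return
    out = normalize_minmax(scan_of(meta, [[lo, hi], [lo, hi]]))
    assert out.pixels.min() == 0 and out.pixels.max() == 255


# ------------------------------------------------------------------- CLAHE

def test_clahe_output_is_8bit(random_scan64, default_params):
    out = apply_clahe(random_scan64, default_params)
    assert out.pixels.dtype == np.uint8
    assert out.pixels.shape == random_scan64.pixels.shape


def test_clahe_tile_mappings_are_monotone(random_scan64):
    luts = tile_luts(random_scan64.pixels, (8, 8), 40.0)
    assert (np.diff(luts.astype(int), axis=-1) >= 0).all()


def test_clahe_single_tile_unbounded_equals_global_equalization(rng):
    img = rng.integers(0, 256, (64, 64)).astype(np.uint8)
    assert np.array_equal(clahe(img, (1, 1), None), global_hist_eq(img))


def test_clahe_tile_grid_larger_than_image_rejected(random_scan64):
    with pytest.raises(ValidationError):
        apply_clahe(random_scan64, AlgorithmParams(tile_grid=(65, 65)))


# --------------------------------------------------------------- threshold

def test_threshold_boundary_convention():
    meta = ScanMeta("e", "CSCR", "inner_CC", 1, grid_px=2)
    mask = threshold_inverse(scan_of(meta, [[0, 30], [31, 255]]), AlgorithmParams())
    assert mask.pixels.tolist() == [[True, True], [False, False]]


@pytest.mark.parametrize("value,expected", [(255, 0), (0, 64 * 64)])
def test_threshold_constant_images(meta64, value, expected):
    mask = threshold_inverse(scan_of(meta64, np.full((64, 64), value)), AlgorithmParams())
    assert int(mask.pixels.sum()) == expected


def test_threshold_monotone_in_T(random_scan64):
    prev = None
    for t in (0, 10, 30, 50, 255):
        cur = threshold_inverse(random_scan64, AlgorithmParams(threshold=t)).pixels
        if prev is not None:
            assert (cur | prev == cur).all()  # prev is a subset of cur
        prev = cur


# ---------------------------------------------------------------- dilation

def test_dilation_of_single_pixel_is_kernel_block(meta64):
    px = np.zeros((64, 64), dtype=bool)
    px[32, 32] = True
    out = soft_dilate(VoidMask(pixels=px, meta=meta64), AlgorithmParams())
    expected = np.zeros_like(px)
    expected[31:34, 31:34] = True
    assert np.array_equal(out.pixels, expected)


@pytest.mark.parametrize("fill", [False, True])
def test_dilation_constant_masks_fixed_points(meta64, fill):
    px = np.full((64, 64), fill, dtype=bool)
    out = soft_dilate(VoidMask(pixels=px, meta=meta64), AlgorithmParams())
    assert np.array_equal(out.pixels, px)


def test_dilation_zero_iterations_is_identity(meta64, rng):
    px = rng.random((64, 64)) < 0.2
    out = soft_dilate(VoidMask(pixels=px, meta=meta64), AlgorithmParams(dilation_iters=0))
    assert out.pixels is px or np.array_equal(out.pixels, px)


def test_dilation_matches_set_definition(meta64, rng):
    px = rng.random((64, 64)) < 0.05
    for kernel, iters in [(3, 1), (3, 2), (5, 1)]:
        out = soft_dilate(
            VoidMask(pixels=px, meta=meta64),
            AlgorithmParams(dilation_kernel=kernel, dilation_iters=iters),
        )
        assert np.array_equal(out.pixels, dilate_set(px, kernel, iters))


def test_dilation_never_shrinks(meta64, rng):
    px = rng.random((64, 64)) < 0.1
    out = soft_dilate(VoidMask(pixels=px, meta=meta64), AlgorithmParams())
    assert (out.pixels | px == out.pixels).all()


def test_even_dilation_kernel_rejected():
    with pytest.raises(ValidationError):
        AlgorithmParams(dilation_kernel=4)


# ------------------------------------------------------ component filtering

def _blob_mask(meta, sizes, gap=4):
    """Disjoint horizontal runs of the requested pixel counts (8-separated)."""
    px = np.zeros((meta.grid_px, meta.grid_px), dtype=bool)
    row = 1
    for size in sizes:
        full_rows, rem = divmod(size, meta.grid_px - 2)
        r = row
        for _ in range(full_rows):
            px[r, 1:meta.grid_px - 1] = True
            r += 1
        if rem:
            px[r, 1:1 + rem] = True
        row = r + gap
    return px


def test_area_filter_is_strict_at_the_bound(meta64):
    params = AlgorithmParams(min_area_px=20)
    at_bound = filter_components(VoidMask(pixels=_blob_mask(meta64, [20]), meta=meta64), params)
    assert at_bound.area_px == 0 and len(at_bound.components) == 0
    above = filter_components(VoidMask(pixels=_blob_mask(meta64, [21]), meta=meta64), params)
    assert above.area_px == 21 and len(above.components) == 1


def test_area_filter_four_blob_example(meta64):
    mask = VoidMask(pixels=_blob_mask(meta64, [5, 20, 21, 100]), meta=meta64)
    out = filter_components(mask, AlgorithmParams(min_area_px=20))
    assert len(out.components) == 2
    assert out.area_px == 121
    metrics = compute_metrics(out)
    assert metrics.n_contours == 2 and metrics.area_px == 121


def test_empty_mask_filters_to_empty(meta64):
    out = filter_components(
        VoidMask(pixels=np.zeros((64, 64), dtype=bool), meta=meta64), AlgorithmParams()
    )
    assert out.area_px == 0 and out.components == ()


def test_component_accounting(meta64, rng):
    px = rng.random((64, 64)) < 0.3
    out = filter_components(VoidMask(pixels=px, meta=meta64), AlgorithmParams(min_area_px=3))
    assert sum(c.area_px for c in out.components) == out.area_px
    assert all(c.area_px > 3 for c in out.components)


def test_filtering_monotone_in_min_area(meta64, rng):
    px = rng.random((64, 64)) < 0.3
    areas, counts = [], []
    for min_area in (0, 5, 10, 20, 50):
        out = filter_components(
            VoidMask(pixels=px, meta=meta64), AlgorithmParams(min_area_px=min_area)
        )
        areas.append(out.area_px)
        counts.append(len(out.components))
    assert areas == sorted(areas, reverse=True)
    assert counts == sorted(counts, reverse=True)


# ----------------------------------------------------------------- metrics

def test_metrics_unit_conversion(meta64):
    meta500 = ScanMeta("e", "CSCR", "inner_CC", 1)  # 12 um pitch
    px = np.zeros((500, 500), dtype=bool)
    px[10:20, 10:20] = True  # 100 pixels
    out = filter_components(VoidMask(pixels=px, meta=meta500), AlgorithmParams(min_area_px=20))
    m = compute_metrics(out)
    assert m.area_px == 100
    assert m.area_um2 == pytest.approx(14_400.0)
    assert m.area_mm2 == pytest.approx(0.0144)


def test_metrics_require_filtered_mask(meta64):
    with pytest.raises(ValidationError):
        compute_metrics(VoidMask(pixels=np.zeros((64, 64), dtype=bool), meta=meta64))


def test_metrics_empty_mask(meta64):
    out = filter_components(
        VoidMask(pixels=np.zeros((64, 64), dtype=bool), meta=meta64), AlgorithmParams()
    )
    m = compute_metrics(out)
    assert m.area_px == 0 and m.n_contours == 0 and m.area_um2 == 0.0


# ---------------------------------------------------------------- pipeline

def test_pipeline_bright_constant_image_yields_no_voids(meta64):
    scan = scan_of(meta64, np.full((64, 64), 255))
    with pytest.warns(UserWarning):  # constant-image normalization
        mask, metrics = run_fsv(scan)
    assert metrics.area_px == 0 and metrics.n_contours == 0
    assert not mask.pixels.any()


def test_pipeline_is_deterministic(random_scan64, default_params):
    m1, f1 = run_fsv(random_scan64, default_params)
    m2, f2 = run_fsv(random_scan64, default_params)
    assert np.array_equal(m1.pixels, m2.pixels)
    assert f1.area_px == f2.area_px and f1.n_contours == f2.n_contours


def test_pipeline_recovers_planted_high_contrast_voids(default_meta):
    grid = default_meta.grid_px
    mask = np.zeros((grid, grid), dtype=bool)
    blobs = []
    for i in range(3):
        for j in range(3):
            r, c = 80 + 120 * i, 80 + 120 * j
            mask |= _disc_mask(grid, r, c, 7.0)
            blobs.append((r, c, 7.0))
    scene = SceneTruth(truth_mask=mask, void_blobs=tuple(blobs),
                       speckle_sd=1.0, jitter_sd=0.0, texture_sd=0.0)
    scan1, _, truth = render_scan_pair(scene, default_meta, seed=5)
    detected, metrics = run_fsv(scan1)
    # every planted void intersects a detected component, and counts agree
    assert metrics.n_contours == len(blobs)
    for r, c, rad in blobs:
        blob = _disc_mask(grid, r, c, rad)
        assert (detected.pixels & blob).any()
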