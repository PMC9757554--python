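import numpy as np
import pytest

from octafsv import AlgorithmParams, EnFaceScan, ScanMeta


@pytest.fixture
def meta64() -> ScanMeta:
    return ScanMeta("eye01", "CSCR", "inner_CC", 1, fov_mm=6.0, grid_px=64)


@pytest.fixture
def default_meta() -> ScanMeta:
    return ScanMeta("eye01", "CSCR", "inner_CC", 1)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)


@pytest.fixture
def random_scan64(meta64, rng) -> EnFaceScan:
    return EnFaceScan(meta=meta64, pixels=rng.integers(0, 256, (64, 64)).astype(np.uint8))


@pytest.fixture
def default_params() -> AlgorithmParams:
    return AlgorithmParams()


def make_mask_scan(meta: ScanMeta, coords) -> np.ndarray:
    """Boolean mask of meta.grid_px size with the given (row, col) pixels set."""
    m = np.zeros((meta.grid_px, meta.grid_px), dtype=bool)
    for r, c in coords:
        m[r, c] = True
    return m
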