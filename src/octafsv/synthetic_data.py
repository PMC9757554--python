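"""Synthetic paired en-face scans and paired measurements with known truth.

Real choriocapillaris OCTA slabs show a granular bright/dark speckle texture
with dark flow-void regions whose load differs by slab.  The generator
emulates exactly the structure the analysis relies on, nothing more:

* a scene is a bright background with dark discs (the planted voids) plus a
  granular texture field; the texture models true flow heterogeneity, so it
  is shared by the two repeats of a scene (scans two minutes apart image the
  same perfusion pattern);
* a repeat acquisition shares the scene's true void mask and texture but
  receives its own independent additive Gaussian speckle field plus an
  independent global intensity offset (brightness jitter between
  acquisitions);
* cohorts draw a true per-eye, per-slab void-area fraction from a log-normal
  distribution so eyes differ (between-subject variance) while their two
  repeats differ only through noise (within-subject variance).

All randomness flows from explicit integer seeds through
``numpy.random.default_rng``; identical (spec, seed) reproduces every image
and table bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .image_io import (
    EnFaceScan,
    Group,
    ScanMeta,
    Slab,
    write_manifest,
    write_scan,
)
from .repeatability import PairedCohort

__all__ = [
    "SceneTruth",
    "CohortSpec",
    "make_scene",
    "render_scan_pair",
    "SyntheticCohort",
    "generate_cohort",
    "generate_paired_values",
]

#: default expected void-area fraction per slab; ordering inner_CC > outer_CC
#: > choroid mirrors the relative void loads seen across the three depths
DEFAULT_SLAB_VOID_LOAD: dict[str, float] = {
    Slab.INNER_CC.value: 0.10,
    Slab.OUTER_CC.value: 0.05,
    Slab.CHOROID.value: 0.02,
}


@dataclass(frozen=True)
class SceneTruth:
    """Ground truth for one eye x slab scene shared by both repeats."""

    truth_mask: np.ndarray = field(repr=False)
    void_blobs: tuple[tuple[int, int, float], ...]  # (row, col, radius_px)
    background_level: int = 170
    void_level: int = 10
    speckle_sd: float = 6.0
    jitter_sd: float = 3.0
    texture_sd: float = 15.0  # shared granular texture (true flow heterogeneity)

    def __post_init__(self) -> None:
        mask = np.asarray(self.truth_mask, dtype=bool)
        if mask.ndim != 2 or mask.shape[0] != mask.shape[1]:
            raise ValidationError(f"truth_mask must be square 2-D, got {mask.shape}")
        if not 0 <= self.void_level < self.background_level <= 255:
            raise ValidationError(
                "need 0 <= void_level < background_level <= 255 (voids are dark), "
                f"got {self.void_level}, {self.background_level}"
            )
        if self.speckle_sd < 0 or self.jitter_sd < 0 or self.texture_sd < 0:
            raise ValidationError("noise SDs must be non-negative")
        size = mask.shape[0]
        for r, c, rad in self.void_blobs:
            if r - rad < -0.5 or c - rad < -0.5 or r + rad > size - 0.5 or c + rad > size - 0.5:
                raise ValidationError(f"blob ({r}, {c}, r={rad}) extends outside the image")
        object.__setattr__(self, "truth_mask", mask)


def _disc_mask(size: int, row: float, col: float, radius: float) -> np.ndarray:
    rr, cc = np.ogrid[:size, :size]
    return (rr - row) ** 2 + (cc - col) ** 2 <= radius ** 2


def make_scene(
    grid_px: int,
    target_void_fraction: float,
    rng: np.random.Generator,
    radius_range: tuple[float, float] = (2.0, 12.0),
    background_level: int = 170,
    void_level: int = 10,
    speckle_sd: float = 6.0,
    jitter_sd: float = 3.0,
    texture_sd: float = 15.0,
    max_blobs: int = 100_000,
) -> SceneTruth:
    """Sample dark discs (radius log-uniform over ``radius_range``) at uniform
    random positions until the union of discs covers at least
    ``target_void_fraction`` of the image."""
    if not 0.0 < target_void_fraction < 1.0:
        raise ValidationError(
            f"target_void_fraction must be in (0, 1), got {target_void_fraction}"
        )
    rmin, rmax = radius_range
    if not 0 < rmin <= rmax:
        raise ValidationError(f"invalid radius_range {radius_range}")
    if rmax >= grid_px / 2:
        raise ValidationError("maximum blob radius does not fit in the image")
    mask = np.zeros((grid_px, grid_px), dtype=bool)
    blobs: list[tuple[int, int, float]] = []
    target_px = target_void_fraction * grid_px * grid_px
    while mask.sum() < target_px and len(blobs) < max_blobs:
        radius = float(np.exp(rng.uniform(np.log(rmin), np.log(rmax))))
        margin = int(np.ceil(radius))
        row = int(rng.integers(margin, grid_px - margin))
        col = int(rng.integers(margin, grid_px - margin))
        mask |= _disc_mask(grid_px, row, col, radius)
        blobs.append((row, col, radius))
    return SceneTruth(
        truth_mask=mask,
        void_blobs=tuple(blobs),
        background_level=background_level,
        void_level=void_level,
        speckle_sd=speckle_sd,
        jitter_sd=jitter_sd,
        texture_sd=texture_sd,
    )


def _render_one(base: np.ndarray, truth: SceneTruth, rng: np.random.Generator) -> np.ndarray:
    img = base
    if truth.speckle_sd > 0:
        img = img + rng.normal(0.0, truth.speckle_sd, size=base.shape)
    if truth.jitter_sd > 0:
        img = img + rng.normal(0.0, truth.jitter_sd)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def render_scan_pair(
    truth: SceneTruth, meta: ScanMeta, seed: int
) -> tuple[EnFaceScan, EnFaceScan, np.ndarray]:
    """Render the two repeat acquisitions of one scene.

    Both repeats share ``truth.truth_mask`` and the scene's granular texture
    field; each gets independent speckle and an independent global intensity
    jitter.  A fixed seed reproduces the pair bit-exactly.
    """
    if truth.truth_mask.shape[0] != meta.grid_px:
        raise ValidationError(
            f"scene size {truth.truth_mask.shape[0]} does not match meta.grid_px={meta.grid_px}"
        )
    rng = np.random.default_rng(seed)
    base = np.where(truth.truth_mask, float(truth.void_level), float(truth.background_level))
    if truth.texture_sd > 0:
        base = base + rng.normal(0.0, truth.texture_sd, size=base.shape)
    scan1 = EnFaceScan(meta=replace(meta, repeat_index=1), pixels=_render_one(base, truth, rng))
    scan2 = EnFaceScan(meta=replace(meta, repeat_index=2), pixels=_render_one(base, truth, rng))
    return scan1, scan2, truth.truth_mask.copy()


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic two-group repeatability cohort.

    ``sigma_between`` is the SD (log scale) of the per-eye true void load;
    ``sigma_within`` is the SD in gray levels of the per-repeat speckle
    noise, with the global intensity jitter tied to it
    (jitter SD = ``sigma_within / 2``), so ``sigma_within = 0`` produces
    bit-identical repeat pairs.
    """

    n_eyes: int = 52
    slab_void_load: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SLAB_VOID_LOAD)
    )
    sigma_between: float = 0.25
    sigma_within: float = 6.0
    seed: int = 0
    grid_px: int = 500
    fov_mm: float = 6.0
    background_level: int = 170
    void_level: int = 10
    texture_sd: float = 15.0
    radius_range: tuple[float, float] = (2.0, 12.0)
    fellow_load_scale: float = 0.9
    groups: tuple[str, ...] = (Group.CSCR.value, Group.FELLOW.value)

    def __post_init__(self) -> None:
        if self.n_eyes < 1:
            raise ValidationError(f"n_eyes must be >= 1, got {self.n_eyes}")
        if self.sigma_between < 0 or self.sigma_within < 0:
            raise ValidationError("sigma_between and sigma_within must be >= 0")
        loads = dict(self.slab_void_load)
        for slab, load in loads.items():
            Slab(slab)
            if not 0.0 < load < 1.0:
                raise ValidationError(f"void load for {slab} must be in (0, 1), got {load}")
        object.__setattr__(self, "slab_void_load", loads)
        object.__setattr__(self, "radius_range", tuple(self.radius_range))
        object.__setattr__(self, "groups", tuple(Group(g).value for g in self.groups))

    def to_dict(self) -> dict:
        return {
            "n_eyes": self.n_eyes,
            "slab_void_load": dict(self.slab_void_load),
            "sigma_between": self.sigma_between,
            "sigma_within": self.sigma_within,
            "seed": self.seed,
            "grid_px": self.grid_px,
            "fov_mm": self.fov_mm,
            "background_level": self.background_level,
            "void_level": self.void_level,
            "texture_sd": self.texture_sd,
            "radius_range": list(self.radius_range),
            "fellow_load_scale": self.fellow_load_scale,
            "groups": list(self.groups),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortSpec":
        return cls(**dict(d))


@dataclass(frozen=True)
class SyntheticCohort:
    """In-memory synthetic cohort: scans plus manifest and truth tables."""

    manifest: pd.DataFrame
    truth: pd.DataFrame
    scans: tuple[EnFaceScan, ...]
    spec: CohortSpec

    def write(self, out_dir: str | Path) -> tuple[Path, Path]:
        """Materialise images (PNG), manifest CSV and truth CSV under
        ``out_dir``; returns (manifest_path, truth_path)."""
        out_dir = Path(out_dir)
        img_dir = out_dir / "images"
        img_dir.mkdir(parents=True, exist_ok=True)
        manifest = self.manifest.copy()
        for i, scan in enumerate(self.scans):
            m = scan.meta
            name = f"{m.eye_id}_{m.slab.value}_r{m.repeat_index}.png"
            write_scan(scan, img_dir / name)
            manifest.loc[i, "image_path"] = str(Path("images") / name)
        manifest_path = out_dir / "manifest.csv"
        truth_path = out_dir / "truth.csv"
        write_manifest(manifest, manifest_path)
        self.truth.to_csv(truth_path, index=False)
        return manifest_path, truth_path


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a full paired cohort (all groups x eyes x slabs x 2 repeats).

    Per eye and slab the true void-area fraction is
    ``load * exp(Normal(0, sigma_between^2))`` (log-normal around the slab
    load, capped at 0.5); a scene is built at that fraction and rendered
    twice with per-repeat noise controlled by ``sigma_within``.
    """
    master = np.random.default_rng(spec.seed)
    manifest_rows: list[dict] = []
    truth_rows: list[dict] = []
    scans: list[EnFaceScan] = []
    for group in spec.groups:
        scale = spec.fellow_load_scale if group == Group.FELLOW.value else 1.0
        for eye in range(1, spec.n_eyes + 1):
            eye_id = f"{group}_{eye:03d}"
            for slab, load in spec.slab_void_load.items():
                fraction = min(float(load * scale * np.exp(master.normal(0.0, spec.sigma_between))), 0.5)
                scene_rng = np.random.default_rng(master.integers(2 ** 31))
                scene = make_scene(
                    grid_px=spec.grid_px,
                    target_void_fraction=fraction,
                    rng=scene_rng,
                    radius_range=spec.radius_range,
                    background_level=spec.background_level,
                    void_level=spec.void_level,
                    speckle_sd=spec.sigma_within,
                    jitter_sd=spec.sigma_within / 2.0,
                    texture_sd=spec.texture_sd,
                )
                meta = ScanMeta(
                    eye_id=eye_id, group=group, slab=slab, repeat_index=1,
                    fov_mm=spec.fov_mm, grid_px=spec.grid_px,
                )
                pair_seed = int(master.integers(2 ** 31))
                scan1, scan2, truth_mask = render_scan_pair(scene, meta, pair_seed)
                truth_rows.append({
                    "eye_id": eye_id, "group": group, "slab": slab,
                    "true_area_px": int(truth_mask.sum()),
                    "n_blobs": len(scene.void_blobs),
                })
                for scan in (scan1, scan2):
                    scans.append(scan)
                    manifest_rows.append({
                        "eye_id": eye_id, "group": group, "slab": slab,
                        "repeat_index": scan.meta.repeat_index, "image_path": "",
                        "fov_mm": spec.fov_mm, "grid_px": spec.grid_px,
                    })
    return SyntheticCohort(
        manifest=pd.DataFrame(manifest_rows),
        truth=pd.DataFrame(truth_rows),
        scans=tuple(scans),
        spec=spec,
    )


def generate_paired_values(
    n: int,
    mu: float,
    sigma_between: float,
    sigma_within: float,
    seed: int,
    metric_name: str = "area",
    group: str = Group.CSCR.value,
    slab: str = Slab.INNER_CC.value,
    k: int = 2,
) -> PairedCohort:
    """Direct variance-component simulator (no images).

    Subject truths t_i ~ Normal(mu, sigma_between^2); each of the k repeats
    observes t_i + Normal(0, sigma_within^2) independently.  The expected
    single-measures absolute-agreement ICC is
    sigma_between^2 / (sigma_between^2 + sigma_within^2).
    """
    if n < 2:
        raise ValidationError(f"need n >= 2 subjects, got {n}")
    if sigma_between < 0 or sigma_within < 0:
        raise ValidationError("SDs must be non-negative")
    rng = np.random.default_rng(seed)
    truths = rng.normal(mu, sigma_between, size=n)
    values = truths[:, None] + rng.normal(0.0, sigma_within, size=(n, k))
    return PairedCohort(values=values, metric_name=metric_name, group=group, slab=slab)
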