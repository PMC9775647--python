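"""Synthetic H&E-like cohort generator with exact ground truth.

Each specimen is a near-white background holding a blob-shaped tissue region
split into a "cancer" portion (hematoxylin-dense purple, high-amplitude
texture) and a "noncancer" portion (eosin pink, low-amplitude texture).
Texture is per-channel Gaussian noise smoothed at a configurable scale,
renormalized to unit standard deviation and scaled by the region amplitude,
so local value diversity — and hence local entropy — rises monotonically
with the amplitude. Region geometry comes from thresholded smoothed noise,
giving irregular margins rather than straight edges.

All randomness flows from a single integer seed through
``numpy.random.default_rng``; identical spec + seed reproduce bit-identical
images and masks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from hepix.errors import ConfigError
from hepix.imaging import (
    ANNOTATION_CANCER,
    ANNOTATION_NONCANCER,
    SpecimenImage,
)
from hepix.stats import COHORT_COLUMNS, STAGES, UNKNOWN_STAGE, map_tnm_to_stage

# representative complete TNM triplet per stage (default stage table inverse)
STAGE_TNM: dict[str, tuple[str | None, str | None, str | None]] = {
    "I": ("T1", "N0", "M0"),
    "II": ("T2", "N0", "M0"),
    "III": ("T3", "N0", "M0"),
    "IV-A": ("T4", "N0", "M0"),
    "IV-B": ("T2", "N1", "M1"),
    UNKNOWN_STAGE: (None, None, None),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic specimen."""

    image_size: tuple[int, int] = (256, 256)
    cancer_fraction: float = 0.4
    texture_amplitude_cancer: float = 60.0
    texture_amplitude_noncancer: float = 10.0
    texture_scale_cancer: float = 1.5
    texture_scale_noncancer: float = 1.5
    base_color_cancer: tuple[int, int, int] = (110, 70, 150)
    base_color_noncancer: tuple[int, int, int] = (228, 160, 195)
    background_color: tuple[int, int, int] = (247, 245, 247)
    tissue_fill: float = 0.7
    tnm: tuple[str | None, str | None, str | None] = (None, None, None)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.cancer_fraction <= 1.0):
            raise ConfigError(
                f"cancer_fraction must lie in [0, 1]; got {self.cancer_fraction}"
            )
        if self.texture_amplitude_cancer < 0 or self.texture_amplitude_noncancer < 0:
            raise ConfigError("texture amplitudes must be >= 0")
        if self.texture_scale_cancer < 1 or self.texture_scale_noncancer < 1:
            raise ConfigError("texture scales must be >= 1 pixel")
        if not (0.0 < self.tissue_fill <= 1.0):
            raise ConfigError(f"tissue_fill must lie in (0, 1]; got {self.tissue_fill}")
        h, w = self.image_size
        if h < 8 or w < 8:
            raise ConfigError(f"image_size must be at least 8x8; got {self.image_size}")


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    field_ = ndi.gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    sd = field_.std()
    return field_ / sd if sd > 0 else field_


def _blob_mask(field_: np.ndarray, inside: np.ndarray | None, fraction: float) -> np.ndarray:
    """Threshold a field at the quantile that keeps ``fraction`` of pixels."""
    if fraction <= 0.0:
        return np.zeros(field_.shape, dtype=bool)
    domain = field_ if inside is None else field_[inside]
    if fraction >= 1.0:
        mask = np.ones(field_.shape, dtype=bool)
    else:
        thr = np.quantile(domain, 1.0 - fraction)
        mask = field_ >= thr
    if inside is not None:
        mask &= inside
    return mask


def generate_specimen(spec: SyntheticSpec) -> SpecimenImage:
    """Render one synthetic specimen with exact tissue/annotation masks."""
    h, w = spec.image_size
    rng = np.random.default_rng(spec.seed)

    # tissue blob: smoothed noise with a radial bias, thresholded at the
    # quantile that yields the requested fill
    rr, cc = np.mgrid[0:h, 0:w]
    radial = np.hypot((rr - (h - 1) / 2) / h, (cc - (w - 1) / 2) / w)
    score = _smooth_field(rng, (h, w), min(h, w) / 8.0) - 4.0 * radial
    tissue = _blob_mask(score, None, spec.tissue_fill)
    tissue = ndi.binary_fill_holes(tissue)

    # cancer sub-blob inside the tissue
    cancer_field = _smooth_field(rng, (h, w), min(h, w) / 6.0)
    cancer = _blob_mask(cancer_field, tissue, spec.cancer_fraction)
    noncancer = tissue & ~cancer

    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = np.asarray(spec.background_color, dtype=np.float64)
    img[noncancer] = np.asarray(spec.base_color_noncancer, dtype=np.float64)
    img[cancer] = np.asarray(spec.base_color_cancer, dtype=np.float64)

    regions = (
        (noncancer, spec.texture_amplitude_noncancer, spec.texture_scale_noncancer),
        (cancer, spec.texture_amplitude_cancer, spec.texture_scale_cancer),
    )
    for mask, amplitude, scale in regions:
        for c in range(3):
            noise = _smooth_field(rng, (h, w), scale)
            if mask.any() and amplitude > 0:
                img[:, :, c][mask] += amplitude * noise[mask]

    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    annotation = np.zeros((h, w), dtype=np.uint8)
    annotation[noncancer] = ANNOTATION_NONCANCER
    annotation[cancer] = ANNOTATION_CANCER
    return SpecimenImage(
        pixels=pixels,
        tissue_mask=tissue,
        annotation_mask=annotation,
        specimen_id=f"synthetic-{spec.seed}",
        resolution_um=0.441,
    )


def _apportion(n: int, proportions: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n among the given proportions."""
    keys = [s for s in list(STAGES) + [UNKNOWN_STAGE] if s in proportions]
    extra = [k for k in proportions if k not in keys]
    if extra:
        raise ConfigError(f"unknown stages in distribution: {sorted(extra)}")
    total = sum(proportions.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigError(f"stage proportions sum to {total!r}, not 1")
    quotas = {k: n * proportions[k] for k in keys}
    counts = {k: int(math.floor(q)) for k, q in quotas.items()}
    short = n - sum(counts.values())
    by_remainder = sorted(keys, key=lambda k: (-(quotas[k] - counts[k]), keys.index(k)))
    for k in by_remainder[:short]:
        counts[k] += 1
    return counts


def generate_cohort(
    n_specimens: int,
    stage_distribution: dict[str, float],
    cohort_label: str,
    seed: int,
    unknown_fraction: float = 0.0,
    base_spec: SyntheticSpec | None = None,
    stage_overrides: dict[str, dict] | None = None,
) -> tuple[list[SpecimenImage], pd.DataFrame]:
    """Generate a cohort of specimens realizing a target stage distribution.

    ``round(n_specimens * unknown_fraction)`` specimens get missing TNM
    (stage "Unknown"); the remainder are apportioned across the distribution
    by largest remainder. ``stage_overrides`` maps a stage to SyntheticSpec
    field overrides (e.g. to broaden noncancer texture at late stages).

    Returns the specimens plus a cohort metadata table with columns
    specimen_id, cohort, T, N, M, stage, tissue_area_cancer,
    tissue_area_noncancer.
    """
    if n_specimens < 1:
        raise ConfigError(f"n_specimens must be >= 1; got {n_specimens}")
    if not (0.0 <= unknown_fraction <= 1.0):
        raise ConfigError(f"unknown_fraction must lie in [0, 1]; got {unknown_fraction}")
    base = base_spec or SyntheticSpec()
    overrides = stage_overrides or {}

    n_unknown = int(round(n_specimens * unknown_fraction))
    counts = _apportion(n_specimens - n_unknown, stage_distribution)
    stages: list[str] = [UNKNOWN_STAGE] * n_unknown
    for stage, count in counts.items():
        stages.extend([stage] * count)

    rng = np.random.default_rng(seed)
    rng.shuffle(stages)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_specimens + 1)[1:]

    specimens: list[SpecimenImage] = []
    rows = []
    for i, stage in enumerate(stages):
        tnm = STAGE_TNM[stage]
        spec = replace(
            base,
            seed=int(child_seeds[i]),
            tnm=tnm,
            **overrides.get(stage, {}),
        )
        specimen = generate_specimen(spec)
        specimen.specimen_id = f"{cohort_label}-{i:03d}"
        ann = specimen.annotation_mask
        assert map_tnm_to_stage(*tnm) == stage
        rows.append(
            {
                "specimen_id": specimen.specimen_id,
                "cohort": cohort_label,
                "T": tnm[0],
                "N": tnm[1],
                "M": tnm[2],
                "stage": stage,
                "tissue_area_cancer": int((ann == ANNOTATION_CANCER).sum()),
                "tissue_area_noncancer": int((ann == ANNOTATION_NONCANCER).sum()),
            }
        )
        specimens.append(specimen)
    table = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    return specimens, table
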