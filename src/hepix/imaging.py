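"""Raster I/O, tissue masking and tiling for histology specimens.

Conventions
-----------
* Coordinates are (row, col), 0-based, origin at the top-left; rasters are
  indexed ``[row][col]``.
* Images are 8-bit RGB with channel order red, green, blue.
* Tissue masks are stored as single-channel PNG with 0 = background and
  255 = tissue; in memory they are boolean arrays.
* Annotation masks use 0 = unlabeled, 1 = noncancer, 2 = cancer, and only
  carry labels inside the tissue mask.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage import morphology

from hepix.errors import FormatError

ANNOTATION_UNLABELED = 0
ANNOTATION_NONCANCER = 1
ANNOTATION_CANCER = 2

DEFAULT_WHITE_THRESHOLD = 230
DEFAULT_MIN_OBJECT_SIZE = 64
DEFAULT_RESOLUTION_UM = 0.441


@dataclass
class SpecimenImage:
    """One RGB histology image with its masks and resolution metadata.

    Attributes
    ----------
    pixels : (H, W, 3) uint8 array
    tissue_mask : (H, W) bool array
    annotation_mask : (H, W) uint8 array or None
        0 = unlabeled, 1 = noncancer, 2 = cancer.
    specimen_id : str
    resolution_um : float
        Microns per pixel; metadata only.
    """

    pixels: np.ndarray
    tissue_mask: np.ndarray
    annotation_mask: np.ndarray | None = None
    specimen_id: str = ""
    resolution_um: float = DEFAULT_RESOLUTION_UM

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise FormatError(
                f"pixels must be (H, W, 3); got shape {self.pixels.shape}"
            )
        if self.pixels.dtype != np.uint8:
            raise FormatError(
                f"pixels must be 8-bit (uint8); got {self.pixels.dtype}"
            )
        if self.tissue_mask.shape != self.pixels.shape[:2]:
            raise FormatError(
                "tissue_mask shape "
                f"{self.tissue_mask.shape} does not match image "
                f"{self.pixels.shape[:2]}"
            )
        self.tissue_mask = self.tissue_mask.astype(bool)
        if self.annotation_mask is not None:
            if self.annotation_mask.shape != self.pixels.shape[:2]:
                raise FormatError(
                    "annotation_mask shape "
                    f"{self.annotation_mask.shape} does not match image "
                    f"{self.pixels.shape[:2]}"
                )
            self.annotation_mask = self.annotation_mask.astype(np.uint8)
            if (self.annotation_mask[~self.tissue_mask] != 0).any():
                raise FormatError(
                    "annotation labels occur outside the tissue mask"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class Tile:
    """A grid crop of a specimen, retaining its origin for back-mapping."""

    specimen: SpecimenImage
    origin: tuple[int, int]
    tissue_fraction: float = field(default=0.0)


def _read_raster(path: str | os.PathLike) -> np.ndarray:
    arr = iio.imread(path)
    if arr.dtype != np.uint8:
        raise FormatError(f"{path}: expected 8-bit raster, got {arr.dtype}")
    return arr


def compute_tissue_mask(
    pixels: np.ndarray,
    white_threshold: int = DEFAULT_WHITE_THRESHOLD,
    min_object_size: int = DEFAULT_MIN_OBJECT_SIZE,
) -> np.ndarray:
    """Segment tissue from near-white background.

    A pixel is tissue when its minimum channel value is ``<= white_threshold``
    (H&E background is near-white in every channel). Connected components
    smaller than ``min_object_size`` are removed and holes smaller than
    ``min_object_size`` are filled.
    """
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise FormatError(f"expected (H, W, 3) RGB input, got {pixels.shape}")
    if pixels.dtype != np.uint8:
        raise FormatError(f"expected 8-bit input, got {pixels.dtype}")
    mask = pixels.min(axis=2) <= white_threshold
    if min_object_size > 1:
        # max_size removes components of size <= its value, so components of
        # exactly min_object_size pixels survive
        mask = morphology.remove_small_objects(mask, max_size=min_object_size - 1)
        mask = morphology.remove_small_holes(mask, max_size=min_object_size - 1)
    return mask


def load_specimen(
    image_path: str | os.PathLike,
    tissue_mask_path: str | os.PathLike | None = None,
    annotation_mask_path: str | os.PathLike | None = None,
    specimen_id: str | None = None,
    resolution_um: float = DEFAULT_RESOLUTION_UM,
    white_threshold: int = DEFAULT_WHITE_THRESHOLD,
    min_object_size: int = DEFAULT_MIN_OBJECT_SIZE,
) -> SpecimenImage:
    """Load an RGB specimen image plus optional masks from disk.

    When no tissue mask is supplied, :func:`compute_tissue_mask` is applied.
    Annotation labels falling outside the tissue mask are cleared (they may
    arise when the mask is computed rather than provided).
    """
    pixels = _read_raster(image_path)
    if pixels.ndim == 3 and pixels.shape[2] == 4:  # drop alpha
        pixels = pixels[:, :, :3]
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise FormatError(f"{image_path}: expected RGB image, got {pixels.shape}")

    if tissue_mask_path is not None:
        tissue = _read_raster(tissue_mask_path)
        if tissue.ndim != 2:
            raise FormatError(f"{tissue_mask_path}: mask must be single-channel")
        if tissue.shape != pixels.shape[:2]:
            raise FormatError(
                f"{tissue_mask_path}: mask shape {tissue.shape} does not match "
                f"image {pixels.shape[:2]}"
            )
        tissue = tissue > 0
    else:
        tissue = compute_tissue_mask(pixels, white_threshold, min_object_size)

    annotation = None
    if annotation_mask_path is not None:
        annotation = _read_raster(annotation_mask_path)
        if annotation.ndim != 2:
            raise FormatError(
                f"{annotation_mask_path}: mask must be single-channel"
            )
        if annotation.shape != pixels.shape[:2]:
            raise FormatError(
                f"{annotation_mask_path}: mask shape {annotation.shape} does "
                f"not match image {pixels.shape[:2]}"
            )
        annotation = annotation.astype(np.uint8).copy()
        annotation[~tissue] = ANNOTATION_UNLABELED

    if specimen_id is None:
        specimen_id = Path(image_path).stem
    return SpecimenImage(
        pixels=pixels,
        tissue_mask=tissue,
        annotation_mask=annotation,
        specimen_id=specimen_id,
        resolution_um=resolution_um,
    )


def save_specimen(specimen: SpecimenImage, directory: str | os.PathLike) -> dict:
    """Write image and masks as lossless PNG; returns the written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sid = specimen.specimen_id or "specimen"
    paths = {"image": directory / f"{sid}.image.png"}
    iio.imwrite(paths["image"], specimen.pixels)
    paths["tissue"] = directory / f"{sid}.tissue.png"
    iio.imwrite(
        paths["tissue"], (specimen.tissue_mask.astype(np.uint8) * 255)
    )
    if specimen.annotation_mask is not None:
        paths["annotation"] = directory / f"{sid}.annotation.png"
        iio.imwrite(paths["annotation"], specimen.annotation_mask)
    return {k: str(v) for k, v in paths.items()}


def load_saved_specimen(
    directory: str | os.PathLike, specimen_id: str, **kwargs
) -> SpecimenImage:
    """Inverse of :func:`save_specimen` for a given specimen id."""
    directory = Path(directory)
    ann = directory / f"{specimen_id}.annotation.png"
    return load_specimen(
        directory / f"{specimen_id}.image.png",
        tissue_mask_path=directory / f"{specimen_id}.tissue.png",
        annotation_mask_path=ann if ann.exists() else None,
        specimen_id=specimen_id,
        **kwargs,
    )


def tile_image(
    specimen: SpecimenImage,
    tile_size: int,
    min_tissue_fraction: float = 0.0,
) -> list[Tile]:
    """Split a specimen into non-overlapping grid tiles.

    Edge tiles may be smaller than ``tile_size`` so that the grid covers the
    full raster. Tiles whose tissue fraction is below ``min_tissue_fraction``
    are dropped. A ``tile_size`` larger than the image yields one whole-image
    tile.
    """
    if tile_size < 1:
        raise FormatError("tile_size must be >= 1")
    h, w = specimen.shape
    tiles: list[Tile] = []
    for r0 in range(0, h, tile_size):
        for c0 in range(0, w, tile_size):
            r1, c1 = min(r0 + tile_size, h), min(c0 + tile_size, w)
            tmask = specimen.tissue_mask[r0:r1, c0:c1]
            frac = float(tmask.mean()) if tmask.size else 0.0
            if frac < min_tissue_fraction:
                continue
            ann = specimen.annotation_mask
            sub = SpecimenImage(
                pixels=specimen.pixels[r0:r1, c0:c1].copy(),
                tissue_mask=tmask.copy(),
                annotation_mask=None if ann is None else ann[r0:r1, c0:c1].copy(),
                specimen_id=f"{specimen.specimen_id}:{r0},{c0}",
                resolution_um=specimen.resolution_um,
            )
            tiles.append(Tile(specimen=sub, origin=(r0, c0), tissue_fraction=frac))
    return tiles
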