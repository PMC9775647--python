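"""KMeans pixel clustering with cross-cohort transfer and composition stats.

A model is fitted on the pooled pixel features of one cohort (optionally
subsampled per image) and can then be applied to specimens of any cohort with
the same feature configuration. Cluster IDs are 1-based; 0 marks non-tissue
pixels in cluster maps. Noise clusters (e.g. tissue-edge clusters) are a
configuration list and are excluded from composition ratios.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans

from hepix.errors import ConfigError, DataError
from hepix.features import FeatureMatrix, MBFConfig, extract_mbf
from hepix.imaging import (
    ANNOTATION_CANCER,
    ANNOTATION_NONCANCER,
    SpecimenImage,
)

MODEL_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class ClusterConfig:
    """KMeans parameters plus the list of clusters to treat as noise.

    ``n_clusters`` defaults to 30. ``max_pixels_per_image`` caps the number
    of training pixels drawn (uniformly, seeded) from each image; ``None``
    pools every pixel.
    """

    n_clusters: int = 30
    seed: int = 0
    n_init: int = 3
    max_iter: int = 300
    noise_clusters: tuple[int, ...] = ()
    max_pixels_per_image: int | None = 200_000

    def __post_init__(self) -> None:
        # n_clusters >= 1: the degenerate single-cluster model is allowed for
        # sanity checks even though real analyses use >= 2.
        if self.n_clusters < 1:
            raise ConfigError(f"n_clusters must be >= 1; got {self.n_clusters}")
        bad = [c for c in self.noise_clusters if not (1 <= c <= self.n_clusters)]
        if bad:
            raise ConfigError(
                f"noise_clusters {bad} outside valid range 1..{self.n_clusters}"
            )


@dataclass
class ClusterModel:
    """Fitted centroids together with the configs that produced them."""

    centroids: np.ndarray  # (n_clusters, n_features)
    mbf_config: MBFConfig
    cluster_config: ClusterConfig
    training_cohort: str = ""
    inertia: float = float("nan")

    def __post_init__(self) -> None:
        if self.centroids.shape[1] != self.mbf_config.n_features:
            raise ConfigError(
                f"centroid dimension {self.centroids.shape[1]} does not match "
                f"the feature config ({self.mbf_config.n_features} features)"
            )

    @property
    def n_clusters(self) -> int:
        return self.centroids.shape[0]


@dataclass
class ClusterMap:
    """Integer raster of cluster IDs: 0 outside tissue, 1..n inside."""

    ids: np.ndarray
    specimen_id: str = ""


def fit_cluster_model(
    feature_matrices: list[FeatureMatrix],
    config: ClusterConfig,
    mbf_config: MBFConfig,
    training_cohort: str = "",
) -> ClusterModel:
    """Fit KMeans (k-means++ init, ``n_init`` restarts, best inertia kept)
    on the pooled pixels of the given feature matrices.

    Per-image subsampling (``config.max_pixels_per_image``) is seeded and
    order-preserving, so results are fully determined by ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    pools = []
    for fm in feature_matrices:
        values = fm.values
        cap = config.max_pixels_per_image
        if cap is not None and values.shape[0] > cap:
            idx = np.sort(rng.choice(values.shape[0], size=cap, replace=False))
            values = values[idx]
        pools.append(values)
    pooled = np.concatenate(pools, axis=0) if pools else np.empty((0, 0))
    if pooled.shape[0] < config.n_clusters:
        raise ConfigError(
            f"{pooled.shape[0]} pooled pixels but {config.n_clusters} clusters"
        )
    km = KMeans(
        n_clusters=config.n_clusters,
        init="k-means++",
        n_init=config.n_init,
        max_iter=config.max_iter,
        random_state=config.seed,
    ).fit(pooled)
    return ClusterModel(
        centroids=km.cluster_centers_.astype(np.float64),
        mbf_config=mbf_config,
        cluster_config=config,
        training_cohort=training_cohort,
        inertia=float(km.inertia_),
    )


def assign_nearest(centroids: np.ndarray, values: np.ndarray) -> np.ndarray:
    """1-based nearest-centroid (Euclidean) labels; ties -> lowest cluster ID."""
    if values.shape[1] != centroids.shape[1]:
        raise DataError(
            f"feature dimension {values.shape[1]} does not match model "
            f"dimension {centroids.shape[1]}"
        )
    labels = np.empty(values.shape[0], dtype=np.int32)
    # chunked ||x - c||^2 = ||x||^2 - 2 x.c + ||c||^2; argmin takes the first
    # (lowest-ID) minimum.
    c_sq = (centroids**2).sum(axis=1)
    step = 65536
    for start in range(0, values.shape[0], step):
        chunk = values[start: start + step]
        d2 = chunk @ (-2.0 * centroids.T) + c_sq
        labels[start: start + step] = np.argmin(d2, axis=1) + 1
    return labels


def predict_clusters(model: ClusterModel, specimen: SpecimenImage) -> ClusterMap:
    """Apply a fitted model to a specimen, producing its cluster-ID raster."""
    fm = extract_mbf(specimen, model.mbf_config)
    ids = np.zeros(specimen.shape, dtype=np.int32)
    if fm.n_pixels:
        labels = assign_nearest(model.centroids, fm.values)
        ids[fm.pixel_index[:, 0], fm.pixel_index[:, 1]] = labels
    return ClusterMap(ids=ids, specimen_id=specimen.specimen_id)


def _count_ids(maps: list[ClusterMap], n_clusters: int) -> np.ndarray:
    counts = np.zeros(n_clusters + 1, dtype=np.int64)
    for cmap in maps:
        counts += np.bincount(cmap.ids.ravel(), minlength=n_clusters + 1)[
            : n_clusters + 1
        ]
    return counts


def cluster_composition(
    cluster_map: ClusterMap | list[ClusterMap],
    noise_clusters: tuple[int, ...] | list[int] = (),
) -> dict[int, float]:
    """Fraction of non-noise tissue pixels per cluster.

    Accepts one map or a list (pooled over a cohort). Only clusters with at
    least one pixel appear; ratios sum to 1.
    """
    maps = cluster_map if isinstance(cluster_map, list) else [cluster_map]
    n_clusters = int(max(cmap.ids.max() for cmap in maps))
    counts = _count_ids(maps, n_clusters)
    noise = set(noise_clusters)
    valid = {
        c: int(counts[c])
        for c in range(1, n_clusters + 1)
        if c not in noise and counts[c] > 0
    }
    total = sum(valid.values())
    if total == 0:
        raise DataError("all tissue pixels fall in noise clusters")
    return {c: n / total for c, n in valid.items()}


@dataclass
class RegionFractions:
    """Cancer/noncancer share of a cluster's annotated pixels."""

    cancer: float | None
    noncancer: float | None
    n_labeled: int = 0

    @property
    def defined(self) -> bool:
        return self.n_labeled > 0


def cancer_fraction_per_cluster(
    maps: list[ClusterMap],
    specimens: list[SpecimenImage],
) -> dict[int, RegionFractions]:
    """Per cluster, the fractions of its annotated pixels labeled cancer vs
    noncancer; unlabeled pixels are excluded from the denominator. Clusters
    with no labeled pixels are reported as undefined (fractions ``None``).
    """
    if len(maps) != len(specimens):
        raise DataError("maps and specimens must align 1:1")
    n_clusters = int(max(cmap.ids.max() for cmap in maps))
    cancer = np.zeros(n_clusters + 1, dtype=np.int64)
    labeled = np.zeros(n_clusters + 1, dtype=np.int64)
    seen = np.zeros(n_clusters + 1, dtype=np.int64)
    for cmap, spec in zip(maps, specimens):
        if spec.annotation_mask is None:
            raise DataError(f"specimen {spec.specimen_id!r} has no annotation mask")
        ids = cmap.ids.ravel()
        ann = spec.annotation_mask.ravel()
        seen += np.bincount(ids, minlength=n_clusters + 1)[: n_clusters + 1]
        lab = ann != 0
        labeled += np.bincount(ids[lab], minlength=n_clusters + 1)[: n_clusters + 1]
        cancer += np.bincount(
            ids[ann == ANNOTATION_CANCER], minlength=n_clusters + 1
        )[: n_clusters + 1]
    out: dict[int, RegionFractions] = {}
    for c in range(1, n_clusters + 1):
        if seen[c] == 0:
            continue
        if labeled[c] == 0:
            out[c] = RegionFractions(cancer=None, noncancer=None, n_labeled=0)
        else:
            frac = cancer[c] / labeled[c]
            out[c] = RegionFractions(
                cancer=float(frac),
                noncancer=float(1.0 - frac),
                n_labeled=int(labeled[c]),
            )
    return out


def select_extreme_clusters(
    composition: dict[int, float], top_k: int, bottom_k: int
) -> tuple[list[int], list[int]]:
    """Clusters with the ``top_k`` largest and ``bottom_k`` smallest
    composition ratios. Clusters are sorted by ratio descending, ties broken
    by lower cluster ID first; the top slice comes from the front, the bottom
    slice from the back of that order.
    """
    if len(composition) < top_k + bottom_k:
        raise ConfigError(
            f"need at least {top_k + bottom_k} clusters; have {len(composition)}"
        )
    order = sorted(composition, key=lambda c: (-composition[c], c))
    top = order[:top_k]
    bottom = order[len(order) - bottom_k:]
    return top, bottom


def derive_region_labels(
    cmap: ClusterMap,
    cancer_clusters: list[int] | tuple[int, ...],
    noncancer_clusters: list[int] | tuple[int, ...],
) -> np.ndarray:
    """Annotation-style mask (0/1/2) derived from cluster membership, for
    cohorts without expert annotations."""
    ann = np.zeros(cmap.ids.shape, dtype=np.uint8)
    ann[np.isin(cmap.ids, list(noncancer_clusters))] = ANNOTATION_NONCANCER
    ann[np.isin(cmap.ids, list(cancer_clusters))] = ANNOTATION_CANCER
    return ann


def noise_cluster_heuristic(
    maps: list[ClusterMap],
    specimens: list[SpecimenImage],
    edge_width: int = 3,
    min_edge_fraction: float = 0.6,
) -> list[int]:
    """Flag clusters whose pixels lie mostly within a morphological edge band
    of the tissue mask. Advisory only — the configured noise list is
    authoritative.
    """
    from scipy import ndimage as ndi

    n_clusters = int(max(cmap.ids.max() for cmap in maps))
    edge = np.zeros(n_clusters + 1, dtype=np.int64)
    total = np.zeros(n_clusters + 1, dtype=np.int64)
    for cmap, spec in zip(maps, specimens):
        eroded = ndi.binary_erosion(spec.tissue_mask, iterations=edge_width)
        band = spec.tissue_mask & ~eroded
        ids = cmap.ids
        total += np.bincount(ids.ravel(), minlength=n_clusters + 1)[: n_clusters + 1]
        edge += np.bincount(ids[band].ravel(), minlength=n_clusters + 1)[
            : n_clusters + 1
        ]
    flagged = [
        c
        for c in range(1, n_clusters + 1)
        if total[c] > 0 and edge[c] / total[c] >= min_edge_fraction
    ]
    return flagged


def save_model(model: ClusterModel, path: str | Path) -> None:
    """Persist a model as a single versioned JSON archive."""
    payload = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "training_cohort": model.training_cohort,
        "inertia": None if math.isnan(model.inertia) else model.inertia,
        "mbf_config": asdict(model.mbf_config),
        "cluster_config": asdict(model.cluster_config),
        "centroids": model.centroids.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def load_model(path: str | Path) -> ClusterModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise DataError(
            f"unsupported model schema version {payload.get('schema_version')!r}"
        )
    cc = dict(payload["cluster_config"])
    cc["noise_clusters"] = tuple(cc.get("noise_clusters", ()))
    inertia = payload.get("inertia")
    return ClusterModel(
        centroids=np.asarray(payload["centroids"], dtype=np.float64),
        mbf_config=MBFConfig(**payload["mbf_config"]),
        cluster_config=ClusterConfig(**cc),
        training_cohort=payload.get("training_cohort", ""),
        inertia=float("nan") if inertia is None else float(inertia),
    )
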