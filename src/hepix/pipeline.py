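"""End-to-end orchestration: generate -> mask -> features -> fit -> predict ->
compose -> entropy -> stats.

A run lives in a single directory. Each stage reads only files written by
earlier stages, so deleting downstream outputs and rerunning reproduces
them. Every stage stamps a provenance record (config hash, seed, outputs)
into ``provenance.json``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from hepix import clustering, entropy, stats, synthetic
from hepix.errors import ConfigError, DataError
from hepix.features import MBFConfig, extract_mbf, FeatureMatrix
from hepix.imaging import SpecimenImage, compute_tissue_mask, load_saved_specimen

logger = logging.getLogger(__name__)

STAGE_NAMES = (
    "generate",
    "mask",
    "features",
    "fit",
    "predict",
    "compose",
    "entropy",
    "stats",
)


@dataclass
class CohortSpec:
    """Synthetic-cohort parameters for one arm of a run."""

    label: str
    n_specimens: int
    stage_distribution: dict[str, float] = field(
        default_factory=lambda: {"I": 1.0}
    )
    unknown_fraction: float = 0.0
    spec_overrides: dict = field(default_factory=dict)
    stage_overrides: dict[str, dict] = field(default_factory=dict)


@dataclass
class RunConfig:
    """Everything a pipeline run needs; one global seed drives all stages."""

    out_dir: str
    seed: int = 0
    image_size: tuple[int, int] = (128, 128)
    train_cohort: CohortSpec = field(
        default_factory=lambda: CohortSpec(label="mouse", n_specimens=5)
    )
    transfer_cohort: CohortSpec = field(
        default_factory=lambda: CohortSpec(label="human", n_specimens=20)
    )
    mbf: MBFConfig = field(default_factory=MBFConfig)
    cluster: clustering.ClusterConfig = field(
        default_factory=clustering.ClusterConfig
    )
    entropy: entropy.EntropyConfig = field(default_factory=entropy.EntropyConfig)
    n_draws: int = 10_000
    histogram_bins: int = 64
    top_k: int = 3
    bottom_k: int = 3
    label_source: str = "annotation"  # "annotation" | "clusters"

    def __post_init__(self) -> None:
        if self.label_source not in ("annotation", "clusters"):
            raise ConfigError(
                f"label_source must be 'annotation' or 'clusters'; "
                f"got {self.label_source!r}"
            )

    # deterministic per-stage seeds derived from the one global seed
    def stage_seed(self, stage: str) -> int:
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big")

    def config_hash(self) -> str:
        payload = json.dumps(_as_jsonable(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        try:
            kwargs = dict(raw)
            if "image_size" in kwargs:
                kwargs["image_size"] = tuple(kwargs["image_size"])
            for key in ("train_cohort", "transfer_cohort"):
                if key in kwargs and isinstance(kwargs[key], dict):
                    kwargs[key] = CohortSpec(**kwargs[key])
            if isinstance(kwargs.get("mbf"), dict):
                kwargs["mbf"] = MBFConfig(**kwargs["mbf"])
            if isinstance(kwargs.get("cluster"), dict):
                cc = dict(kwargs["cluster"])
                if "noise_clusters" in cc:
                    cc["noise_clusters"] = tuple(cc["noise_clusters"])
                kwargs["cluster"] = clustering.ClusterConfig(**cc)
            if isinstance(kwargs.get("entropy"), dict):
                kwargs["entropy"] = entropy.EntropyConfig(**kwargs["entropy"])
            return cls(**kwargs)
        except TypeError as exc:
            raise ConfigError(f"invalid run config: {exc}") from exc


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    return obj


class PipelineRun:
    """Stage-by-stage executor over a run directory."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.root = Path(config.out_dir)

    # -- paths -------------------------------------------------------------
    @property
    def cohorts_csv(self) -> Path:
        return self.root / "cohorts.csv"

    def image_dir(self, cohort: str) -> Path:
        return self.root / "images" / cohort

    @property
    def model_path(self) -> Path:
        return self.root / "model" / "model.json"

    def cluster_map_path(self, sid: str) -> Path:
        return self.root / "clusters" / f"{sid}.png"

    def entropy_csv(self, sid: str) -> Path:
        return self.root / "entropy" / f"{sid}.csv"

    # -- provenance --------------------------------------------------------
    def _stamp(self, stage: str, outputs: list[str], t0: float) -> None:
        path = self.root / "provenance.json"
        record = json.loads(path.read_text()) if path.exists() else {}
        record[stage] = {
            "config_hash": self.config.config_hash(),
            "seed": self.config.seed,
            "stage_seed": self.config.stage_seed(stage),
            "elapsed_s": round(time.time() - t0, 3),
            "outputs": outputs,
        }
        path.write_text(json.dumps(record, indent=1, sort_keys=True))

    # -- cohort helpers ----------------------------------------------------
    def cohort_table(self) -> pd.DataFrame:
        if not self.cohorts_csv.exists():
            raise DataError(f"missing {self.cohorts_csv}; run the generate stage")
        return pd.read_csv(self.cohorts_csv, keep_default_na=False).replace(
            {"": None}
        )

    def specimens(self, cohort: str) -> list[SpecimenImage]:
        table = self.cohort_table()
        ids = table.loc[table["cohort"] == cohort, "specimen_id"]
        directory = self.image_dir(cohort)
        return [load_saved_specimen(directory, sid) for sid in ids]

    # -- stages ------------------------------------------------------------
    def stage_generate(self) -> None:
        t0 = time.time()
        self.root.mkdir(parents=True, exist_ok=True)
        (self.root / "config.yaml").write_text(
            yaml.safe_dump(_as_jsonable(self.config))
        )
        tables, outputs = [], []
        for arm, offset in ((self.config.train_cohort, 0), (self.config.transfer_cohort, 1)):
            base = synthetic.SyntheticSpec(
                image_size=self.config.image_size, **arm.spec_overrides
            )
            specimens, table = synthetic.generate_cohort(
                n_specimens=arm.n_specimens,
                stage_distribution=arm.stage_distribution,
                cohort_label=arm.label,
                seed=self.config.stage_seed("generate") + offset,
                unknown_fraction=arm.unknown_fraction,
                base_spec=base,
                stage_overrides=arm.stage_overrides,
            )
            directory = self.image_dir(arm.label)
            for specimen in specimens:
                from hepix.imaging import save_specimen

                paths = save_specimen(specimen, directory)
                outputs.extend(paths.values())
            tables.append(table)
        pd.concat(tables, ignore_index=True).to_csv(self.cohorts_csv, index=False)
        outputs.append(str(self.cohorts_csv))
        logger.info("generate: wrote %d files", len(outputs))
        self._stamp("generate", outputs, t0)

    def stage_mask(self) -> None:
        """Compute tissue masks for any image lacking one (no-op for
        synthetic cohorts, which carry exact masks)."""
        t0 = time.time()
        outputs = []
        for arm in (self.config.train_cohort, self.config.transfer_cohort):
            directory = self.image_dir(arm.label)
            for image_path in sorted(directory.glob("*.image.png")):
                sid = image_path.name[: -len(".image.png")]
                mask_path = directory / f"{sid}.tissue.png"
                if mask_path.exists():
                    continue
                pixels = iio.imread(image_path)
                mask = compute_tissue_mask(pixels)
                iio.imwrite(mask_path, mask.astype(np.uint8) * 255)
                outputs.append(str(mask_path))
        logger.info("mask: wrote %d masks", len(outputs))
        self._stamp("mask", outputs, t0)

    def stage_features(self) -> None:
        t0 = time.time()
        directory = self.root / "features"
        directory.mkdir(parents=True, exist_ok=True)
        outputs = []
        for arm in (self.config.train_cohort, self.config.transfer_cohort):
            for specimen in self.specimens(arm.label):
                fm = extract_mbf(specimen, self.config.mbf)
                path = directory / f"{specimen.specimen_id}.npz"
                np.savez_compressed(
                    path,
                    values=fm.values,
                    pixel_index=fm.pixel_index,
                    feature_names=np.asarray(fm.feature_names),
                )
                outputs.append(str(path))
        logger.info("features: wrote %d matrices", len(outputs))
        self._stamp("features", outputs, t0)

    def _load_features(self, sid: str) -> FeatureMatrix:
        path = self.root / "features" / f"{sid}.npz"
        if not path.exists():
            raise DataError(f"missing feature matrix {path}; run the features stage")
        data = np.load(path, allow_pickle=False)
        return FeatureMatrix(
            values=data["values"],
            pixel_index=data["pixel_index"],
            feature_names=[str(n) for n in data["feature_names"]],
        )

    def stage_fit(self) -> None:
        t0 = time.time()
        table = self.cohort_table()
        label = self.config.train_cohort.label
        ids = table.loc[table["cohort"] == label, "specimen_id"]
        matrices = [self._load_features(sid) for sid in ids]
        config = dataclasses.replace(
            self.config.cluster, seed=self.config.stage_seed("fit")
        )
        model = clustering.fit_cluster_model(
            matrices, config, self.config.mbf, training_cohort=label
        )
        self.model_path.parent.mkdir(parents=True, exist_ok=True)
        clustering.save_model(model, self.model_path)
        logger.info("fit: inertia %.4g on cohort %s", model.inertia, label)
        self._stamp("fit", [str(self.model_path)], t0)

    def stage_predict(self) -> None:
        t0 = time.time()
        model = clustering.load_model(self.model_path)
        (self.root / "clusters").mkdir(parents=True, exist_ok=True)
        outputs = []
        for arm in (self.config.train_cohort, self.config.transfer_cohort):
            for specimen in self.specimens(arm.label):
                cmap = clustering.predict_clusters(model, specimen)
                path = self.cluster_map_path(specimen.specimen_id)
                iio.imwrite(path, cmap.ids.astype(np.uint16))
                outputs.append(str(path))
        logger.info("predict: wrote %d cluster maps", len(outputs))
        self._stamp("predict", outputs, t0)

    def _load_cluster_maps(self, cohort: str) -> list[clustering.ClusterMap]:
        table = self.cohort_table()
        ids = table.loc[table["cohort"] == cohort, "specimen_id"]
        maps = []
        for sid in ids:
            path = self.cluster_map_path(sid)
            if not path.exists():
                raise DataError(f"missing cluster map {path}; run the predict stage")
            maps.append(
                clustering.ClusterMap(
                    ids=iio.imread(path).astype(np.int32), specimen_id=sid
                )
            )
        return maps

    def stage_compose(self) -> None:
        t0 = time.time()
        noise = self.config.cluster.noise_clusters
        train_label = self.config.train_cohort.label
        transfer_label = self.config.transfer_cohort.label
        train_maps = self._load_cluster_maps(train_label)
        transfer_maps = self._load_cluster_maps(transfer_label)

        rows = []
        fractions = clustering.cancer_fraction_per_cluster(
            train_maps, self.specimens(train_label)
        )
        for cohort, maps in ((train_label, train_maps), (transfer_label, transfer_maps)):
            composition = clustering.cluster_composition(maps, noise)
            for cluster, ratio in sorted(composition.items()):
                rf = fractions.get(cluster)
                rows.append(
                    {
                        "cohort": cohort,
                        "cluster": cluster,
                        "ratio": ratio,
                        "cancer_fraction": None if rf is None or not rf.defined else rf.cancer,
                        "noncancer_fraction": None if rf is None or not rf.defined else rf.noncancer,
                    }
                )
        comp_csv = self.root / "clusters" / "composition.csv"
        pd.DataFrame(rows).to_csv(comp_csv, index=False)

        transfer_comp = clustering.cluster_composition(transfer_maps, noise)
        top, bottom = clustering.select_extreme_clusters(
            transfer_comp, self.config.top_k, self.config.bottom_k
        )
        extreme_json = self.root / "clusters" / "extreme_clusters.json"
        extreme_json.write_text(
            json.dumps(
                {"cohort": transfer_label, "top": top, "bottom": bottom},
                indent=1,
            )
        )
        logger.info("compose: top=%s bottom=%s", top, bottom)
        self._stamp("compose", [str(comp_csv), str(extreme_json)], t0)

    def stage_entropy(self) -> None:
        t0 = time.time()
        directory = self.root / "entropy"
        directory.mkdir(parents=True, exist_ok=True)
        extreme_json = self.root / "clusters" / "extreme_clusters.json"
        outputs = []
        label_sources = {}
        for arm in (self.config.train_cohort, self.config.transfer_cohort):
            for specimen in self.specimens(arm.label):
                source = "annotation"
                if self.config.label_source == "clusters" or specimen.annotation_mask is None:
                    if not extreme_json.exists():
                        raise DataError(
                            "cluster-derived region labels requested but "
                            f"{extreme_json} is missing; run the compose stage"
                        )
                    extremes = json.loads(extreme_json.read_text())
                    cmap = clustering.ClusterMap(
                        ids=iio.imread(
                            self.cluster_map_path(specimen.specimen_id)
                        ).astype(np.int32),
                        specimen_id=specimen.specimen_id,
                    )
                    specimen.annotation_mask = clustering.derive_region_labels(
                        cmap, extremes["top"], extremes["bottom"]
                    )
                    source = "clusters"
                label_sources[specimen.specimen_id] = source
                maps = entropy.local_entropy_map(specimen, self.config.entropy)
                for emap in maps:
                    tif = directory / f"{specimen.specimen_id}.ch{emap.channel}.tif"
                    tifffile.imwrite(tif, emap.values.astype(np.float32))
                    outputs.append(str(tif))
                records = entropy.entropy_records(specimen, maps)
                csv = self.entropy_csv(specimen.specimen_id)
                records.to_csv(csv, index=False)
                outputs.append(str(csv))
        (directory / "label_sources.json").write_text(
            json.dumps(label_sources, indent=1, sort_keys=True)
        )
        logger.info("entropy: wrote %d files", len(outputs))
        self._stamp("entropy", outputs, t0)

    def stage_stats(self) -> None:
        t0 = time.time()
        directory = self.root / "stats"
        directory.mkdir(parents=True, exist_ok=True)
        table = stats.validate_cohort_table(self.cohort_table())
        transfer = table[table["cohort"] == self.config.transfer_cohort.label]
        records = pd.concat(
            [pd.read_csv(self.entropy_csv(sid)) for sid in transfer["specimen_id"]],
            ignore_index=True,
        )
        edges = stats.default_bin_edges(
            self.config.histogram_bins, self.config.entropy.max_entropy
        )
        outputs = []
        for group_by, name in ((None, "overall"), ("stage", "by_stage")):
            resampled = stats.area_weighted_resample(
                records,
                transfer,
                n_draws=self.config.n_draws,
                seed=self.config.stage_seed("stats"),
                group_by=group_by,
            )
            resampled_csv = directory / f"resampled_{name}.csv"
            resampled.to_csv(resampled_csv, index=False)
            report = stats.compare_regions(resampled, group_by=group_by, bin_edges=edges)
            report_csv = directory / f"report_{name}.csv"
            report.to_csv(report_csv, index=False)
            hist_rows = []
            group_cols = (["stage"] if group_by else []) + ["channel", "region_class"]
            for key, sub in resampled.groupby(group_cols)[["entropy"]]:
                if group_by:
                    group, channel, region = key
                else:
                    channel, region = key
                    group = None
                probs = stats.entropy_histogram(sub["entropy"], edges)
                for b, p in enumerate(probs):
                    hist_rows.append(
                        {
                            "group": group if group_by else "all",
                            "channel": channel,
                            "region_class": region,
                            "bin_left": edges[b],
                            "bin_right": edges[b + 1],
                            "probability": p,
                        }
                    )
            hist_csv = directory / f"histograms_{name}.csv"
            pd.DataFrame(hist_rows).to_csv(hist_csv, index=False)
            outputs.extend([str(resampled_csv), str(report_csv), str(hist_csv)])
        logger.info("stats: wrote %s", outputs)
        self._stamp("stats", outputs, t0)

    def run(self, stages: tuple[str, ...] = STAGE_NAMES) -> Path:
        for stage in stages:
            if stage not in STAGE_NAMES:
                raise ConfigError(f"unknown stage {stage!r}")
            getattr(self, f"stage_{stage}")()
        return self.root


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage in order; returns the run directory."""
    return PipelineRun(config).run()
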