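# hepix

Pixel-level analysis of H&E histology images: multiscale-feature KMeans
clustering trained on one cohort and transferred to another to assess
tissue-structure homology, plus per-pixel local-entropy statistics
(area-weighted resampling, Welch comparison, per-stage Jensen–Shannon
divergence) that discriminate cancer from noncancer regions.

Because the original slide scans are not distributable, the package ships a
synthetic-cohort generator that emulates two textured region classes
(cancer-like high texture, noncancer-like low texture) under H&E-like color
statistics, with exact ground-truth masks and TNM metadata. Every pipeline
stage is tested against that generator.

## Modules

| module              | purpose |
|---------------------|---------|
| `hepix.synthetic`   | synthetic specimens/cohorts with ground-truth masks and TNM metadata |
| `hepix.imaging`     | PNG/TIFF I/O, tissue masking, grid tiling |
| `hepix.features`    | per-pixel multiscale basic features (Gaussian intensity / gradient / Hessian eigenvalues) |
| `hepix.clustering`  | KMeans fit + cross-cohort transfer, composition ratios, cancer fractions, extreme-cluster selection |
| `hepix.entropy`     | per-pixel, per-channel local Shannon entropy (sliding incremental histogram) |
| `hepix.stats`       | TNM→stage mapping, inverse-area weighted resampling, Welch's t-test, histograms, JSD, comparison reports |
| `hepix.pipeline`    | staged orchestration with provenance stamping |
| `hepix.cli`         | `hepix` command-line interface |

## CLI

A run is configured by one YAML file (see `examples/demo.yaml`) and lives in
a single output directory. Stages can be run individually and are resumable:
each stage reads only files written by earlier stages.

```bash
hepix all --config examples/demo.yaml            # full run
hepix generate --config examples/demo.yaml       # single stage
hepix stats --config examples/demo.yaml          # rebuild statistics only
hepix stage-of T2 N1 M1                          # -> IV-B
```

Stages: `generate mask features fit predict compose entropy stats`.
Exit codes: 0 success, 2 configuration error, 3 data error.

Run-directory layout:

```
run/
  config.yaml  provenance.json  cohorts.csv
  images/<cohort>/<id>.image.png  .tissue.png  .annotation.png
  features/<id>.npz
  model/model.json                 # versioned JSON archive of the centroids
  clusters/<id>.png                # 16-bit cluster-ID rasters
  clusters/composition.csv  extreme_clusters.json
  entropy/<id>.ch{0,1,2}.tif  <id>.csv
  stats/report_{overall,by_stage}.csv  histograms_*.csv  resampled_*.csv
```

## Conventions

* Coordinates are `(row, col)`, 0-based, origin top-left.
* Channels 0, 1, 2 are red, green, blue; images are 8-bit per channel.
* Tissue masks: single-channel PNG, 0 = background, 255 = tissue.
* Annotation masks: single-channel PNG, 0 = unlabeled, 1 = noncancer,
  2 = cancer; labels occur only inside the tissue mask.
* Cluster IDs are 1-based; 0 marks non-tissue pixels in cluster maps.
* Tissue masking (min-channel ≤ 230 plus small-object/hole removal at
  64 px) and the sigma-ladder spacing are this artifact's documented
  defaults; both are configurable.

## Key defaults

* Features: intensity on, edges off, Hessian-eigenvalue texture on,
  sigma 3–7, multichannel (18 features on RGB).
* Clustering: 30 clusters, k-means++ with seeded restarts; optional
  per-image training-pixel cap (200k) for large cohorts; noise clusters are
  an explicit configuration list (an edge-band heuristic is advisory only).
* Entropy: window radius k = 20, log base 2, 256 gray levels, clipped
  border windows (interior-only mode available); a multiplicity-weighted
  summation variant is available for auditability.
* Staging: UICC-7-style default table (M1→IV-B; T4 or N1→IV-A; T3→III;
  T2→II; T1→I; anything missing/unrecognized→Unknown), swappable.
* Resampling: n = 100,000 draws with replacement per stratum, each pixel
  weighted by the inverse area of its specimen's region; "Unknown"-stage
  specimens are excluded from stage-stratified sets.
* JSD histograms: 64 equal-width bins over [0, 8] bits (configurable).

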