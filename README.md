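# laiscape

Wall-to-wall leaf-area-index (LAI) estimation for forest canopies from
simulated spaceborne-LiDAR footprints fused with optical and SAR imagery.
The package re-implements, as a tested and reusable pipeline:

- **Synthetic scene generation** (`laiscape.scene`) — a toy landscape with a
  spatially autocorrelated LAI field of known variogram, terrain, canopy,
  eight optical bands with a saturating vegetation response, VV/VH
  backscatter, quasi-regular laser footprints, 51 noisy circular field plots
  and labelled photon transects. Every downstream stage can be tested
  against this known ground truth.
- **Photon processing** (`laiscape.photons`) — directional-density
  denoising, window-minimum ground seeding, progressive densification of a
  ground line, spline-based ground/canopy classification and 100 m
  footprint-segment metrics (simplified re-implementation).
- **Geostatistics** (`laiscape.geostats`) — empirical variograms, fitting of
  spherical/exponential/gaussian models by count-weighted least squares,
  normal-score transforms, simple kriging, and sequential Gaussian
  conditional simulation (SGCS) with a realization-count sweep.
- **Feature engineering** (`laiscape.features`) — cubic-convolution
  resampling with temporal medians, sliding-window GLCM textures (Mean,
  Variance, Homogeneity, Contrast, Dissimilarity, Entropy, Second Moment,
  Correlation), twelve vegetation indices, and plot-level extraction.
- **Screening** (`laiscape.screening`) — Pearson correlation screening
  against measured LAI with nested 0.01 / 0.05 / 0.1 significance tiers and
  a 4+2+2 modeling-factor selection policy.
- **Optimizers** (`laiscape.optimizers`) — RFR / GBRT / SVR regressors and
  four from-scratch hyperparameter searches (Bayesian optimization,
  particle swarm, genetic algorithm, simulated annealing) minimizing a
  leave-one-out cross-validation RMSE over mixed integer/continuous spaces.
- **Evaluation** (`laiscape.evaluate`, `laiscape.pipeline`) — R²/RMSE/MAE/P1
  metrics, the 15-model × 2-data-source comparison, wall-to-wall LAI map
  prediction and permutation-importance contribution rates.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle
equivalences, parameter recovery, the SGCS contract, optimizer-vs-random
comparisons and a five-seed end-to-end run at reduced tuning budget); the
rest are per-module unit and property tests.

## Command line

Every subcommand reads a JSON config and writes its products plus a
`manifest.json` into `--out`:

```sh
laiscape scene     --config scene.json    --out out/scene
laiscape photons   --config photons.json  --photons out/scene/photons_0.csv --out out/photons
laiscape variogram --points out/scene/footprints.csv --attribute h_te_best_fit --out out/vario
laiscape sgcs      --config sgcs.json     --points out/scene/footprints.csv --attribute h_te_best_fit --out out/sgcs
laiscape features  --config pipeline.json --out out/features
laiscape screen    --features out/features/features.csv --out out/screen
laiscape train     --features out/features/features.csv --config train.json --out out/train
laiscape compare   --features out/features/features.csv --config compare.json --out out/compare
laiscape map       --features out/features/features.csv --config map.json --out out/map
```

A minimal scene config:

```json
{"rows": 120, "cols": 120, "seed": 7, "plot_count": 51}
```

Rasters are written as TIFF with a JSON sidecar carrying the grid geometry
(origin top-left, x east / y south, metres); tables are plain CSV with
`x_m`/`y_m` coordinates and the footprint attribute columns
`h_te_best_fit`, `h_te_interp`, `h_mean_canopy_abs`, `solar_elevation`.

## Notes

- All randomness flows from explicit seeds; a fixed seed reproduces every
  scene, simulation and optimizer trace bit-for-bit.
- The `RDVI`/`IDVI` indices intentionally duplicate `NDVI`/`GNDVI`,
  following the source formula table as printed; a conventional
  square-root-denominator RDVI is available via
  `vegetation_indices(..., conventional_rdvi=True)`.
- SGCS realizations honor conditioning data exactly (data relocated to
  their pixels), reproduce the data histogram through the normal-score
  back-transform, and avoid the smoothing of plain kriging; the ensemble
  mean converges to the simple-kriging surface as realizations grow.
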