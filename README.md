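# cortmap

Analysis pipelines for interareal circuit-mapping experiments in cortex:

- **sCRACM input maps** (`cortmap.scracm`): converts gridded-photostimulation
  voltage-clamp sweeps (8×16 grid, 75 µm pitch, 3–5 repetitions per site)
  into per-cell input maps — repetition-averaged, baseline-subtracted mean
  current over a 75 ms post-stimulus window, thresholded at 4× the baseline
  SD — and derives total input, input per pixel, responsive area, time to
  peak, PV/Pyr fold ratios (geometric-mean cohort slope), laminar profiles,
  smoothed average maps, and nonparametric cross-pathway comparisons.
- **Projection-density hierarchy** (`cortmap.hierarchy`): circular-averaging
  filtered optical-density maps, top-70%-contour band densities, L2-4:L1
  density ratios (DR), the source×target DR matrix, per-source mean DR ± SEM,
  hierarchy ordering with pairwise Mann–Whitney tests, and FF/FB
  classification.
- **Paired recordings** (`cortmap.paired`): spike detection in PV
  current-clamp traces, step-wise IPSC means in Pyr voltage-clamp traces,
  connection classification (largest-step IPSC > k×baseline SD), per-layer
  connection probability, and excitation→inhibition curves with ANOVA.
- **Synthetic data** (`cortmap.synthetic`): generators for all three input
  kinds with planted ground truth (PV:Pyr amplitude folds, laminar density
  ratios, connectivity flags), used by the recovery tests.
- **I/O + CLI** (`cortmap.sweepio`, `cortmap.config`, `cortmap.cli`): HDF5
  sweep container, TIFF/PNG + JSON band annotations, YAML/JSON run
  configuration with a config hash embedded in every output.

## CLI

```bash
cortmap simulate --seed 5 --out sweeps.h5 --ground-truth truth.json \
    --images-dir images --image-drs 2.5,0.7 \
    --paired-connected 11 --paired-unconnected 2
cortmap map       --in sweeps.h5 --out-dir maps
cortmap pairs     --in sweeps.h5 --out-dir pairs
cortmap pathways  --pairs-csv ff=pairs/pairs.csv --pairs-csv fb=other/pairs.csv \
    --out pathways.json
cortmap hierarchy --images-dir images --out-dir hierarchy --filter-radius 3
cortmap fitest    --in sweeps.h5 --out-dir paired
cortmap report    --dir . --out summary.json
```

All commands accept `--config run.yaml` (see `cortmap.config.RunConfig`);
defaults reproduce the experimental protocol (75 ms window, 4× threshold,
100 µm pairing distance, 70% contour). Runs are deterministic under a fixed
seed.

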