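# tepnet

TMS-evoked-potential (TEP) network profiling: a tested, reusable pipeline
that simulates TMS-EEG cohorts with linked white-matter fractional-anisotropy
(FA) tables, extracts four electrophysiological output measures, and runs the
cross-validated classification and FA-prediction analyses.

## What it does

1. **`tepnet.simulate`** — seeded synthetic cohorts: per-electrode TEP epochs
   (sums of Gaussian component peaks P30/N45/P60/N100/P180 plus AR(1)+white
   noise), a single latent injury-severity scalar per subject that distorts
   both the waveforms (proximity-weighted amplitude suppression, latency
   shift, flattened single-vs-1 Hz plasticity contrast) and the per-ROI FA
   values, plus optional large-amplitude artifact epochs.
2. **`tepnet.preprocess`** — peak-to-peak epoch rejection (default 100 µV),
   zero-phase Hamming-windowed-sinc FIR bandpass 0.5–45 Hz, baseline
   correction (−100 to −10 ms), and averaging into eight regional electrode
   hotspots on the 20–300 ms analysis grid.
3. **`tepnet.features`** — the four output measures per subject × hotspot:
   - **EPD** / **LPD**: OLS slope of the single-pulse TEP over 60–100 ms /
     100–180 ms (µV/ms);
   - **WFA**: Pearson correlation with a normative healthy template built
     from held-out reference subjects (leakage-guarded);
   - **STP**: `(MFP_single − MFP_i) / (MFP_single + MFP_i)` where MFP is the
     mean rectified amplitude over 20–300 ms.
   The model feature vector is the 4 proximal hotspots × 4 measures = 16
   values (hotspot-major, measure-minor; median imputation with logging).
4. **`tepnet.fa`** — voxel FA + ROI labels → per-ROI mean FA over voxels
   with FA > 0.2 (strict), with an optional NIfTI adapter.
5. **`tepnet.stats`** — two-sample pooled-variance t-tests per
   (measure, hotspot) cell with Holm step-down correction per measure panel.
6. **`tepnet.classify`** — linear SVM (C=1, balanced class weights), 50
   permutations of stratified 5-fold CV, training-fold-only z-scoring,
   per-permutation pooled confusions and ROC (vertical averaging on a
   101-point FPR grid), aggregated mean ± STDV.
7. **`tepnet.regress`** — per-ROI OLS prediction of FA from the feature
   vector under 50×5-fold CV, reporting Pearson r and RMSE mean ± STDV
   (small fixed ridge penalty on rank-deficient training folds).
8. **`tepnet.pipeline` / `tepnet.cli`** — config-driven orchestration with
   a single global seed deterministically deriving every stage seed;
   identical config + seed yields a byte-identical report bundle.

## CLI

```sh
tepnet run-all --out out/                 # defaults; or --config run.yaml
tepnet simulate --out out/                # epochs.h5, fa.tsv, labels.tsv
tepnet preprocess --epochs out/epochs.h5 --out out/
tepnet features --teps out/teps.tsv --labels out/labels.tsv --out out/
tepnet stats --features out/features.tsv --labels out/labels.tsv --out out/comparison.tsv
tepnet classify --features out/feature_matrix.tsv --labels out/labels.tsv --out out/
tepnet regress --features out/feature_matrix.tsv --fa out/fa.tsv --out out/
```

Stage subcommands chained on the intermediate files reproduce the
`run-all` bundle byte for byte. A YAML configuration (see
`tepnet.pipeline.RunConfig`) controls cohort size, effect sizes,
preprocessing thresholds, CV parameters and the seed.

## Acceptance

The source study's headline numbers come from a clinical cohort that is not
publicly available, so acceptance is property-based and lives in
`tests/test_acceptance.py`: formula exactness against closed-form oracles,
Holm vs. brute-force enumeration, null calibration and signal recovery of
the CV machinery on synthetic cohorts, the proximal-ROI correlation
gradient, preprocessing contracts, leakage guards, and end-to-end
determinism.

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs an end-to-end smoke pipeline and writes the (empty — no recomputable
numeric targets) machine-readable report.
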