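# vima

Case-control association analysis of multi-sample spatial molecular data —
spatial transcriptomics (e.g. MERFISH transcript tables) and multiplexed
imaging (e.g. CODEX / immunofluorescence rasters).

## The problem

Cohort-scale spatial datasets pair each tissue sample with a donor and a
phenotype (disease status, treatment, subtype). The scientific question is
rarely "where are the cells" but "which recurring tissue structures differ
between cases and controls" — and whether any difference exists at all,
with calibration that survives multiple samples per donor.

The pipeline answers both:

1. **Pre-processing.** Samples are rasterized into 10 µm pixels, segmented
   into tissue vs background (10-transcript threshold for transcript data,
   Otsu on a signal summary for imaging data), log-normalized
   (`p̃_m = log(q·p_m / Σ_m' p_m')` with q the dataset-median total pixel
   intensity), reduced to K meta-markers by PCA on 5×5 meta-pixels, and
   batch-corrected at the pixel level (iterative diversity-penalized
   soft-clustering correction, sample id as batch) with dataset-wide
   standardization.
2. **Patch fingerprints.** Overlapping 40×40-pixel patches are encoded by
   an ensemble of E conditional variational autoencoders (loss
   `MSE − (β/2)Σ(1+log σ² − μ² − σ²)`), each conditioned on a learned
   4-dimensional per-sample embedding injected as constant channels at
   every layer so sample-specific signal stays out of the latent code. The
   fingerprint of a patch is the posterior mean μ(p).
3. **Microniches.** Per encoder, a k-NN graph over fingerprints defines a
   microniche at every patch: the arrival distribution of an s-step random
   walk (transition operator = row-normalized A+I; s chosen adaptively by a
   kurtosis-flattening rule). Averaging arrival probabilities per sample
   yields the N×P×E microniche abundance tensor (MAT).
4. **Association testing.** Abundances are standardized per microniche;
   per-encoder correlations with the phenotype are meta-analyzed per patch
   as `ρ_p = Σ_e C³/Σ_e C²`, with the global statistic
   `R = (1/P)Σ_p Σ_e C⁴/Σ_e C²`. Significance comes from donor-preserving
   permutations: a global permutation P-value and per-patch empirical FDR
   (null exceedances over observed exceedances, per tail, isotonized).

A simulation module generates fully synthetic multi-sample cohorts with
planted focal / diffuse / striated case-control structures and implements
the calibration, power, and spatial-accuracy experiments. See
`docs/methods.md` for the full model description and parameter rationale.

## Worked example

```python
from vima import pipeline, simulation

# synthetic 18-sample imaging cohort: cases carry focal aggregates in a
# band of tissue, controls do not
cfg = simulation.SimConfig(n_samples=18, raster_extent_px=(96, 96),
                           signal_type="A_focal_vs_none",
                           focus_density=0.02, amplitude=2500.0, seed=1)
rasters, metadata, truth = simulation.generate_dataset(cfg)

prep = pipeline.prepare_patches(rasters, metadata, seed=1)
emb = pipeline.embed_patches(prep, "cvae", seed=1, n_models=2)
out = pipeline.test_with_embedding(prep, emb, test="microniche",
                                   n_perm=200, seed=1)
print(f"global R = {out['global_R']:.3f}, P = {out['global_p']:.4f}, "
      f"significant patches at FDR 10%: {out['n_significant']}")
classes = truth.patch_classes(prep.analysis_patchset)
print(f"spatial accuracy = "
      f"{simulation.spatial_accuracy(out['patch_scores'], classes):.3f}")
```

Output from this exact script (about two minutes on one CPU):

```
global R = 0.229, P = 0.0050, significant patches at FDR 10%: 193
spatial accuracy = 0.692
```

`R = 0.229` is the average (squared-correlation-weighted) squared
correlation between microniche abundance and case status across the 648
analysis patches; `P = 0.0050` is its donor-preserving permutation P-value,
at the floor of 200 permutations — the planted focal signal is detected.
193 patch-anchored microniches pass 10% empirical FDR (the planted band
contributes 261 truly case-associated patches), and the spatial-accuracy
score of 0.692 says the per-patch coefficients rank truly case- and
control-associated patches well above chance (0.5 is uninformative, 1.0 is
perfect).

The same stages are available as a CLI for on-disk datasets (multichannel
TIFFs + channels manifest + metadata CSV, or transcript tables):

```bash
vima preprocess --input data/ --modality intensity --out run/
vima train      --artifacts run/ --n-models 10
vima microniche --artifacts run/
vima test       --artifacts run/ --n-perm 1000 --fdr 0.1 --out run/results/
vima simulate   --experiment power --signal C_focal_vs_striated --out sims/
```

`vima test` writes a JSON report (global R, P-value, permutation count,
config hash), a per-patch CSV (coefficient ρ, tail, FDR at call,
significance flag) and UMAP coordinates of the consensus patch graph for
plotting.

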