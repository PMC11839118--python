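"""End-to-end orchestration: rasters -> patches -> fingerprints -> MAT -> tests.

This module glues the pipeline stages together for the CLI, the simulation
experiments and programmatic use. Each stage remains usable on its own; the
helpers here only handle the common hand-offs (tissue-density filtering,
per-encoder walk lengths, shared permutation draws).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import association, fingerprint, microniche, preprocess
from .types import MetaMarkerField, PatchSet, SampleMetadata, SampleRaster

logger = logging.getLogger(__name__)


@dataclass
class PreparedPatches:
    """Preprocessed dataset: meta-marker fields plus the analysis patch set."""

    fields: list[MetaMarkerField]
    patchset: PatchSet                 # all patches (used for training)
    analysis_patchset: PatchSet        # tissue fraction > alpha (used for testing)
    analysis_mask: np.ndarray
    metadata: SampleMetadata
    info: dict = field(default_factory=dict)

    @property
    def sample_codes(self) -> np.ndarray:
        index = {s: i for i, s in enumerate(self.metadata.sample_ids)}
        return np.array([index[s] for s in self.analysis_patchset.sample_ids])


def prepare_patches(rasters: list[SampleRaster], metadata: SampleMetadata,
                    modality: str = "intensity",
                    channel_roles: dict[str, str] | None = None,
                    n_metamarkers: int | None = None,
                    side_px: int = preprocess.PATCH_SIDE,
                    stride_px: int = preprocess.PATCH_STRIDE,
                    min_tissue: float = preprocess.MIN_TISSUE_FRACTION,
                    alpha: float = fingerprint.ALPHA_TISSUE,
                    seed: int = 0) -> PreparedPatches:
    """Run preprocessing and split patches into training vs analysis sets.

    All patches passing the generation filter (tissue fraction >= min_tissue)
    are used to train the autoencoders; only sufficiently dense patches
    (tissue fraction > alpha) enter microniche construction and testing.
    """
    raster_samples = {r.sample_id for r in rasters}
    meta_samples = set(metadata.sample_ids)
    if raster_samples != meta_samples:
        raise ValueError(
            f"raster/metadata sample mismatch: only in rasters {sorted(raster_samples - meta_samples)}, "
            f"only in metadata {sorted(meta_samples - raster_samples)}"
        )
    fields, patchset, info = preprocess.preprocess_dataset(
        rasters, modality=modality, channel_roles=channel_roles,
        n_metamarkers=n_metamarkers, side_px=side_px, stride_px=stride_px,
        min_tissue=min_tissue, seed=seed,
    )
    mask = fingerprint.analysis_mask(patchset, alpha)
    analysis = patchset.subset(mask)
    missing = meta_samples - set(analysis.sample_ids)
    if missing:
        logger.warning("samples with no analysis patch dropped: %s", sorted(missing))
        keep = np.isin(metadata.sample_ids, sorted(meta_samples - missing))
        metadata = SampleMetadata(
            sample_ids=metadata.sample_ids[keep],
            donor_ids=metadata.donor_ids[keep],
            phenotype=metadata.phenotype[keep],
            covariates=None if metadata.covariates is None else metadata.covariates[keep],
            covariate_names=metadata.covariate_names,
        )
    info["alpha"] = alpha
    info["n_analysis_patches"] = len(analysis)
    return PreparedPatches(fields=fields, patchset=patchset,
                           analysis_patchset=analysis, analysis_mask=mask,
                           metadata=metadata, info=info)


def sim_scale_config(seed: int = 0, variant: str = "resnet_cvae") -> fingerprint.CvaeConfig:
    """Autoencoder configuration for small simulated cohorts.

    Latent dimension 20 and 10 training epochs (the full-scale defaults of
    100 and 20 target datasets with millions of pixels); narrow residual
    stages keep a CPU training run to seconds on a few hundred patches.
    """
    return fingerprint.CvaeConfig(
        latent_dim=20, epochs=10, seed=seed, variant=variant,
        stage_widths=(8, 16, 32), convnet_widths=(16, 32),
        batch_size=64, lr=3e-3, lr_decay_per_epoch=0.95, extend=False,
    )


def embed_patches(prep: PreparedPatches, method: str = "cvae_single",
                  seed: int = 0, n_models: int = 1,
                  cvae_config: fingerprint.CvaeConfig | None = None,
                  n_pca: int = 20) -> list[np.ndarray]:
    """Featurize the analysis patches; returns one matrix per encoder.

    Methods: ``cvae_single``/``cvae`` (conditional VAE, ``n_models``
    encoders), ``convnet2`` (plain 2-layer conv autoencoder),
    ``patch_mean_embedding`` (per-channel patch means),
    ``flattened_pca_embedding`` (PCA of flattened patches, top ``n_pca``).
    """
    patches = prep.analysis_patchset
    name = method.replace("_embedding", "")
    if name in ("cvae", "cvae_single", "convnet2"):
        if cvae_config is None:
            cvae_config = sim_scale_config(
                seed=seed, variant="convnet2_ae" if name == "convnet2" else "resnet_cvae")
        else:
            from dataclasses import replace as _replace

            cvae_config = _replace(cvae_config, seed=seed)
        ensemble = fingerprint.train_ensemble(
            prep.patchset, prep.metadata, cvae_config, n_models=n_models)
        return ensemble.encode_all(patches)
    if name == "patch_mean":
        return [patches.patches.mean(axis=(1, 2)).astype(np.float64)]
    if name == "flattened_pca":
        from sklearn.decomposition import PCA

        flat = patches.patches.reshape(len(patches), -1)
        k = min(n_pca, *flat.shape)
        return [PCA(n_components=k, svd_solver="randomized",
                    random_state=seed).fit_transform(flat)]
    raise ValueError(f"unknown embedding method {method!r}")


def build_mat(prep: PreparedPatches, embeddings: list[np.ndarray],
              k: int = microniche.DEFAULT_K,
              kurtosis_drop_tol: float = microniche.DEFAULT_KURTOSIS_DROP_TOL,
              s_max: int = microniche.DEFAULT_S_MAX,
              seed: int = 0) -> microniche.MicronicheAbundanceTensor:
    """k-NN graphs, per-encoder adaptive walk lengths, and the MAT."""
    codes = prep.sample_codes
    n_samples = len(prep.metadata)
    graphs, steps = [], []
    for e, emb in enumerate(embeddings):
        g = microniche.build_graph(emb, k=min(k, len(emb) - 1), encoder_index=e, seed=seed)
        s = microniche.choose_steps(g, codes, n_samples,
                                    kurtosis_drop_tol=kurtosis_drop_tol, s_max=s_max)
        graphs.append(g)
        steps.append(s)
    logger.info("walk lengths per encoder: %s", steps)
    return microniche.compute_mat(graphs, steps, codes, prep.metadata.sample_ids)


def test_with_embedding(prep: PreparedPatches, embeddings: list[np.ndarray],
                        metadata: SampleMetadata | None = None,
                        test: str = "microniche", n_perm: int = 1000,
                        fdr_level: float = 0.10, k: int = microniche.DEFAULT_K,
                        seed: int = 0) -> dict:
    """Run the microniche test or the cluster-baseline test on an embedding."""
    metadata = metadata if metadata is not None else prep.metadata
    name = test.replace("_test", "")
    if name == "microniche":
        mat = build_mat(prep, embeddings, k=k, seed=seed)
        if metadata.covariates is not None:
            mat = microniche.project_covariates(mat, metadata.covariates)
        res = association.associate(mat.Q, metadata, n_perm=n_perm,
                                    fdr_level=fdr_level, seed=seed)
        return {
            "global_p": res.global_.p_value,
            "global_R": res.global_.R,
            "n_significant": res.local.n_significant,
            "patch_scores": res.local.rho,
            "result": res,
            "mat": mat,
        }
    if name == "cluster":
        out = association.cluster_baseline_test(
            embeddings[0], prep.sample_codes, metadata, n_perm=n_perm,
            fdr_level=fdr_level, seed=seed, k=k)
        return {
            "global_p": out["global_bonferroni_p"],
            "global_R": float((out["correlations"] ** 2).mean()),
            "n_significant": out["fdr_calls"].n_significant,
            "patch_scores": out["patch_scores"],
            "result": out,
        }
    raise ValueError(f"unknown test {test!r}")


def run_case_control(rasters: list[SampleRaster], metadata: SampleMetadata,
                     modality: str = "intensity", n_models: int = 10,
                     cvae_config: fingerprint.CvaeConfig | None = None,
                     k: int = microniche.DEFAULT_K, n_perm: int = 1000,
                     fdr_level: float = 0.10, alpha: float = fingerprint.ALPHA_TISSUE,
                     n_metamarkers: int | None = None,
                     channel_roles: dict[str, str] | None = None,
                     seed: int = 0) -> dict:
    """Full pipeline: preprocessing, CVAE ensemble, MAT, local + global tests."""
    prep = prepare_patches(rasters, metadata, modality=modality,
                           channel_roles=channel_roles,
                           n_metamarkers=n_metamarkers, alpha=alpha, seed=seed)
    if cvae_config is None:
        cvae_config = fingerprint.CvaeConfig(seed=seed)
    embeddings = embed_patches(prep, "cvae", seed=seed, n_models=n_models,
                               cvae_config=cvae_config)
    out = test_with_embedding(prep, embeddings, test="microniche", n_perm=n_perm,
                              fdr_level=fdr_level, k=k, seed=seed)
    out["prep"] = prep
    out["embeddings"] = embeddings
    return out
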