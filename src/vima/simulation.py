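"""Synthetic multi-sample spatial datasets and the evaluation experiments.

The generator emulates an intensity-based multiplexed-imaging cohort: each
sample is a multichannel pixel raster with a smooth per-channel background
texture inside a tissue mask, and a designated "signal region" (a horizontal
band, standing in for an anatomical layer) in which focal structures are
spiked into one channel according to the case/control status of the sample:

* type A (focal vs none): cases receive a narrow Gaussian blob (diameter 7
  pixels) of added intensity around each focus; controls receive nothing.
* type B (focal vs diffuse): cases receive the narrow blob, controls a wide
  blob (diameter 51 pixels) with the same total added mass per focus.
* type C (focal vs striated): cases receive a filled disc of diameter 7,
  controls a 1 x 33 pixel rectangle, again mass-matched.

Because mass is matched in types B and C, only the *geometry* of the signal
differs between cases and controls — patch-level average intensity carries
little or no information and texture-aware featurization is required.

Label noise re-assigns the analysis label of a fraction h of the samples at
random (the planted signal keeps following the true label). Ground truth is
recorded per patch: signal-region patches of true cases are "case_region",
signal-region patches of true controls are "control_region", the rest "null".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from sklearn.metrics import roc_auc_score
from sklearn.neighbors import NearestNeighbors

from .types import PatchSet, SampleMetadata, SampleRaster

logger = logging.getLogger(__name__)

SIGNAL_TYPES = ("A_focal_vs_none", "B_focal_vs_diffuse", "C_focal_vs_striated", "null")

CASE_REGION, CONTROL_REGION, NULL_REGION = "case_region", "control_region", "null"


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    The defaults describe a small multiplexed-imaging cohort: 8 samples from
    8 donors, 120x120-pixel rasters (1.2 mm at 10 um/px), 5 channels, an
    8-pixel background margin and a central signal band one third of the
    extent tall. ``focus_density`` is the per-pixel Poisson rate of foci in
    the band; ``amplitude`` is the total added intensity mass per focus,
    sized so a focal structure saturates its core pixels well above the
    background texture (intensities clip at ``saturation``, as detectors do).
    """

    n_samples: int = 8
    n_donors: int | None = None
    raster_extent_px: tuple[int, int] = (120, 120)
    n_channels: int = 5
    signal_type: str = "A_focal_vs_none"
    focus_density: float = 0.025
    amplitude: float = 1000.0
    label_noise_h: float = 0.0
    n_reps: int = 50
    seed: int = 0
    background_mean: float = 5.0
    n_texture_types: int = 4
    texture_contrast: float = 0.6
    background_texture_sd: float = 0.25
    background_noise_sd: float = 0.5
    saturation: float = 20.0
    texture_scale_px: float = 20.0
    margin_px: int = 8
    signal_channel: int = 0
    band_fraction: tuple[float, float] = (1 / 3, 2 / 3)

    def __post_init__(self) -> None:
        if self.signal_type not in SIGNAL_TYPES:
            raise ValueError(f"unknown signal_type {self.signal_type!r}")
        if not 0 <= self.label_noise_h <= 0.5:
            raise ValueError("label_noise_h must be in [0, 0.5]")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.n_donors is None:
            self.n_donors = self.n_samples
        if min(self.raster_extent_px) < 40 + 2 * self.margin_px:
            raise ValueError("raster extent too small for patch extraction")


@dataclass
class SimTruth:
    """Ground truth of one simulated cohort."""

    true_labels: np.ndarray              # per sample, 0/1
    region_mask: np.ndarray              # (X, Y) boolean signal region
    sample_ids: np.ndarray

    def patch_classes(self, patchset: PatchSet, min_overlap: float = 0.3) -> np.ndarray:
        """Truth class per patch: signal-region patches of true cases are
        case_region, of true controls control_region, all others null."""
        label_of = {s: l for s, l in zip(self.sample_ids, self.true_labels)}
        side = patchset.side
        classes = np.full(len(patchset), NULL_REGION, dtype=object)
        for i, (sid, (ax, ay)) in enumerate(zip(patchset.sample_ids, patchset.anchors)):
            overlap = self.region_mask[ax : ax + side, ay : ay + side].mean()
            if overlap >= min_overlap:
                classes[i] = CASE_REGION if label_of[sid] == 1 else CONTROL_REGION
        return classes


def _spike_kernels(config: SimConfig) -> tuple[np.ndarray | None, np.ndarray | None]:
    """Unit-mass case/control spike kernels for the configured signal type."""
    def blur(diameter: float) -> np.ndarray:
        sigma = diameter / 4.0
        half = int(np.ceil(3 * sigma))
        img = np.zeros((2 * half + 1, 2 * half + 1))
        img[half, half] = 1.0
        k = gaussian_filter(img, sigma)
        return k / k.sum()

    def disc(diameter: float) -> np.ndarray:
        r = diameter / 2.0
        half = int(np.floor(r))
        xs = np.arange(-half, half + 1)
        m = (xs[:, None] ** 2 + xs[None, :] ** 2) <= r ** 2
        return m / m.sum()

    def rect(h: int, w: int) -> np.ndarray:
        k = np.ones((h, w))
        return k / k.sum()

    t = config.signal_type
    if t == "null":
        return None, None
    if t == "A_focal_vs_none":
        return blur(7), None
    if t == "B_focal_vs_diffuse":
        return blur(7), blur(51)
    return disc(7), rect(1, 33)


def _add_kernel(channel: np.ndarray, kernel: np.ndarray, cx: int, cy: int,
                amplitude: float) -> None:
    """Add amplitude * kernel centered at (cx, cy), clipped at the borders."""
    kh, kw = kernel.shape
    x0, y0 = cx - kh // 2, cy - kw // 2
    xs0, ys0 = max(x0, 0), max(y0, 0)
    xs1 = min(x0 + kh, channel.shape[0])
    ys1 = min(y0 + kw, channel.shape[1])
    if xs1 <= xs0 or ys1 <= ys0:
        return
    channel[xs0:xs1, ys0:ys1] += amplitude * kernel[
        xs0 - x0 : xs1 - x0, ys0 - y0 : ys1 - y0
    ]


def generate_dataset(config: SimConfig) -> tuple[list[SampleRaster], SampleMetadata, SimTruth]:
    """Generate one synthetic cohort with known case-control structure.

    Reproducible: the same config (including seed) yields bit-identical
    rasters. Background = smooth Gaussian random field (texture scale
    ``texture_scale_px``) plus white noise, truncated at zero, inside a
    rectangular tissue mask inset by ``margin_px``; background pixels outside
    the mask are zero, so intensity-mode segmentation recovers the mask.
    """
    rng = np.random.default_rng(config.seed)
    x_ext, y_ext = config.raster_extent_px
    m = config.margin_px
    tissue = np.zeros((x_ext, y_ext), dtype=bool)
    tissue[m : x_ext - m, m : y_ext - m] = True
    lo, hi = (int(config.band_fraction[0] * x_ext), int(config.band_fraction[1] * x_ext))
    region = np.zeros_like(tissue)
    region[lo:hi, m : y_ext - m] = True
    region &= tissue

    n = config.n_samples
    n_donors = config.n_donors
    donor_of_sample = np.arange(n) % n_donors
    # balanced donor-level true labels
    donor_labels = np.zeros(n_donors, dtype=int)
    donor_labels[rng.permutation(n_donors)[: n_donors // 2]] = 1
    true_labels = donor_labels[donor_of_sample]

    case_kernel, control_kernel = _spike_kernels(config)
    region_ix = np.argwhere(region)

    # dataset-level texture vocabulary: every sample's tissue is a smooth
    # mosaic of the same few region types, each with a fixed multichannel
    # intensity profile, so comparable patches recur across samples
    n_types = config.n_texture_types
    profiles = config.background_mean * (
        1.0 + config.texture_contrast * rng.uniform(-1.0, 1.0,
                                                    size=(n_types, config.n_channels))
    )
    type_thresholds = np.quantile(np.linspace(-2.5, 2.5, 1001),
                                  np.linspace(0, 1, n_types + 1)[1:-1])

    rasters = []
    sample_ids = np.array([f"s{i:02d}" for i in range(n)])
    for i in range(n):
        u = gaussian_filter(rng.standard_normal((x_ext, y_ext)),
                            config.texture_scale_px, mode="reflect")
        u = (u - u.mean()) / max(u.std(), 1e-12) * 1.5
        type_map = np.searchsorted(type_thresholds, u)
        values = profiles[type_map].astype(np.float64)
        for ch in range(config.n_channels):
            grf = gaussian_filter(rng.standard_normal((x_ext, y_ext)),
                                  config.texture_scale_px / 2, mode="reflect")
            grf = grf / max(grf.std(), 1e-12) * config.background_texture_sd
            noise = rng.standard_normal((x_ext, y_ext)) * config.background_noise_sd
            values[:, :, ch] = np.clip(values[:, :, ch] + grf + noise, 0.05, None)
        if config.signal_type != "null":
            kernel = case_kernel if true_labels[i] == 1 else control_kernel
            n_foci = rng.poisson(config.focus_density * len(region_ix))
            foci = region_ix[rng.integers(0, len(region_ix), size=n_foci)]
            if kernel is not None:
                for cx, cy in foci:
                    _add_kernel(values[:, :, config.signal_channel], kernel,
                                int(cx), int(cy), config.amplitude)
        # detector saturation: intensities cannot exceed the dynamic range
        np.clip(values, None, config.saturation, out=values)
        values *= tissue[:, :, None]
        rasters.append(SampleRaster(
            sample_id=str(sample_ids[i]), values=values,
            channel_names=[f"ch{c:02d}" for c in range(config.n_channels)],
            foreground=None,
        ))

    # analysis labels: true labels with a fraction h re-assigned at random,
    # applied at the donor level so donor structure stays consistent
    noisy_donor = donor_labels.copy()
    n_flip = int(round(config.label_noise_h * n_donors))
    if n_flip:
        flip_ix = rng.permutation(n_donors)[:n_flip]
        noisy_donor[flip_ix] = rng.integers(0, 2, size=n_flip)
    phenotype = noisy_donor[donor_of_sample].astype(float)

    metadata = SampleMetadata(
        sample_ids=sample_ids,
        donor_ids=np.array([f"d{d:02d}" for d in donor_of_sample]),
        phenotype=phenotype,
    )
    truth = SimTruth(true_labels=true_labels, region_mask=region, sample_ids=sample_ids)
    return rasters, metadata, truth


# ---------------------------------------------------------------------------
# figures of merit
# ---------------------------------------------------------------------------

def spatial_accuracy(scores: np.ndarray, truth_classes: np.ndarray) -> float:
    """Average of two AUROCs measuring spatial localization of the signal.

    AUROC(case-region patches vs rest, ranked by score) is averaged with
    AUROC(control-region patches vs rest, ranked by negated score), with
    midrank tie handling. Perfectly signed scores give 1.0; constant
    (uninformative) scores give 0.5. If one truth class is empty, the other
    AUROC is returned alone with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    truth_classes = np.asarray(truth_classes)
    aucs = []
    for cls, sgn in ((CASE_REGION, 1.0), (CONTROL_REGION, -1.0)):
        is_cls = truth_classes == cls
        if is_cls.sum() == 0 or is_cls.all():
            logger.warning("truth class %s empty or exhaustive; skipping its AUROC", cls)
            continue
        s = sgn * scores
        if np.ptp(s) == 0:
            aucs.append(0.5)  # midrank AUROC of constant scores
        else:
            aucs.append(float(roc_auc_score(is_cls.astype(int), s)))
    if not aucs:
        raise ValueError("no truth class available for the accuracy metric")
    return float(np.mean(aucs))


def relative_perplexity(embedding: np.ndarray, sample_codes: np.ndarray,
                        k: int = 15) -> np.ndarray:
    """Per-patch sample-integration score.

    For each patch, the exp-entropy (perplexity) of the sample composition of
    its k nearest neighbors, divided by the exp-entropy of the global sample
    composition. Values near 1 indicate neighborhoods as sample-diverse as
    the dataset; values near 1/perplexity(global) indicate single-sample
    neighborhoods.
    """
    sample_codes = np.asarray(sample_codes)
    n_samples = int(sample_codes.max()) + 1
    if n_samples < 2:
        raise ValueError("need at least 2 samples")

    def perp(counts: np.ndarray) -> float:
        p = counts / counts.sum()
        p = p[p > 0]
        return float(np.exp(-(p * np.log(p)).sum()))

    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    _, ix = nn.kneighbors(embedding)
    neigh = sample_codes[ix[:, 1:]]  # drop self
    global_perp = perp(np.bincount(sample_codes, minlength=n_samples).astype(float))
    out = np.empty(len(embedding))
    for i in range(len(embedding)):
        out[i] = perp(np.bincount(neigh[i], minlength=n_samples).astype(float)) / global_perp
    return out


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

def type1_experiment(Q_std: np.ndarray, metadata: SampleMetadata,
                     n_simulates: int, alpha: float = 0.05,
                     n_perm: int = 200, seed: int = 0,
                     valid: np.ndarray | None = None) -> dict:
    """Empirical type-I error of the global test under random labels.

    The fingerprints/MAT come from a pipeline trained once on the unlabeled
    data (labels never enter training), so each null simulate only redraws a
    random binary donor-level phenotype (fair coin per donor; degenerate
    constant draws are rejected and redrawn) and reruns the global
    permutation test.
    """
    from .association import global_test

    if n_simulates < 1:
        raise ValueError("n_simulates must be >= 1")
    rng = np.random.default_rng(seed)
    donors, donor_ix = np.unique(metadata.donor_ids, return_inverse=True)
    p_values = np.empty(n_simulates)
    for i in range(n_simulates):
        while True:
            donor_y = rng.integers(0, 2, size=len(donors)).astype(float)
            if donor_y.std() > 0:
                break
        meta_i = SampleMetadata(
            sample_ids=metadata.sample_ids,
            donor_ids=metadata.donor_ids,
            phenotype=donor_y[donor_ix],
        )
        res = global_test(Q_std, meta_i, n_perm=n_perm,
                          seed=int(rng.integers(2 ** 31)), valid=valid)
        p_values[i] = res.p_value
    rejections = p_values < alpha
    rate = float(rejections.mean())
    margin = 1.96 * np.sqrt(max(rate * (1 - rate), 1e-12) / n_simulates)
    return {
        "rejection_rate": rate,
        "n_simulates": n_simulates,
        "alpha": alpha,
        "ci95": (max(0.0, rate - margin), min(1.0, rate + margin)),
        "p_values": p_values,
    }


def apply_label_noise(metadata: SampleMetadata, truth: SimTruth, h: float,
                      rng: np.random.Generator) -> SampleMetadata:
    """Analysis labels with a fraction h of donors re-assigned at random.

    Starts from the true labels, so noise levels are comparable; the planted
    signal keeps following the truth.
    """
    label_of = {s: int(l) for s, l in zip(truth.sample_ids, truth.true_labels)}
    donors, donor_ix = np.unique(metadata.donor_ids, return_inverse=True)
    first = np.array([np.flatnonzero(donor_ix == i)[0] for i in range(len(donors))])
    donor_labels = np.array([label_of[metadata.sample_ids[i]] for i in first])
    n_flip = int(round(h * len(donors)))
    if n_flip:
        ix = rng.permutation(len(donors))[:n_flip]
        donor_labels[ix] = rng.integers(0, 2, size=n_flip)
    return SampleMetadata(
        sample_ids=metadata.sample_ids,
        donor_ids=metadata.donor_ids,
        phenotype=donor_labels[donor_ix].astype(float),
    )


def power_experiment(base_config: SimConfig,
                     h_grid: tuple[float, ...] = (0.0, 0.2, 0.4),
                     methods: tuple[tuple[str, str], ...] = (("cvae_single", "microniche"),),
                     n_reps: int = 10, alpha: float = 0.05, n_perm: int = 200,
                     seed: int = 0, pipeline_kwargs: dict | None = None) -> pd.DataFrame:
    """Power sweep over label-noise levels and method variants.

    ``methods`` pairs an embedding ("cvae_single", "convnet2",
    "patch_mean_embedding", "flattened_pca_embedding") with a test
    ("microniche_test"/"microniche" or "cluster_test"/"cluster"). One cohort
    is generated and featurized per rep (labels never enter featurization);
    each label-noise level then re-assigns labels and reruns the association
    tests, so the h-sweep reuses the per-rep embeddings. Returns a tidy frame
    with one row per (method, h, rep): global P-value, rejection at alpha,
    number of FDR-significant patches, and spatial accuracy.
    """
    from .pipeline import embed_patches, prepare_patches, test_with_embedding

    pipeline_kwargs = dict(pipeline_kwargs or {})
    rows = []
    for rep in range(n_reps):
        rep_seed = base_config.seed + 1009 * rep
        cfg = replace(base_config, label_noise_h=0.0, seed=rep_seed)
        rasters, metadata, truth = generate_dataset(cfg)
        prep = prepare_patches(rasters, metadata, seed=rep_seed,
                               **pipeline_kwargs.get("prepare", {}))
        classes = truth.patch_classes(prep.analysis_patchset)
        embeddings = {
            name: embed_patches(prep, name, seed=rep_seed,
                                **pipeline_kwargs.get("embed", {}))
            for name in {m[0] for m in methods}
        }
        for h in h_grid:
            noise_rng = np.random.default_rng(rep_seed + int(1e6 * h) + 17)
            meta_h = apply_label_noise(prep.metadata, truth, h, noise_rng)
            for emb_name, test_name in methods:
                out = test_with_embedding(
                    prep, embeddings[emb_name], meta_h, test=test_name,
                    n_perm=n_perm, seed=rep_seed, **pipeline_kwargs.get("test", {}))
                rows.append({
                    "method": f"{emb_name}+{test_name}", "embedding": emb_name,
                    "test": test_name, "signal": cfg.signal_type, "h": h,
                    "rep": rep, "global_p": out["global_p"],
                    "reject": out["global_p"] < alpha,
                    "n_significant": out["n_significant"],
                    "accuracy": spatial_accuracy(out["patch_scores"], classes),
                })
        logger.info("power: rep=%d done", rep)
    return pd.DataFrame(rows)
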