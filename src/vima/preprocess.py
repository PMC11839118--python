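"""Raster preprocessing: segmentation, normalization, meta-markers, patches.

The preprocessing stage has three goals: (a) separate tissue from background,
(b) reduce M raw markers/genes to a small number K of "meta-markers" — linear
combinations of the log-normalized markers found by PCA on locally averaged
"meta-pixels" — and (c) remove sample-specific pixel-level batch effects and
standardize each meta-marker dataset-wide. Square overlapping patches are then
cut from the resulting fields for featurization.

Pixel conventions: pixels are half-open bins ``[i*r, (i+1)*r)`` of side
``r`` micrometres, 0-based, with x as the first array axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter
from skimage.filters import threshold_otsu
from sklearn.decomposition import PCA

from .types import MetaMarkerField, PatchSet, SampleRaster

logger = logging.getLogger(__name__)

#: minimum transcripts per pixel for a pixel to count as tissue
TRANSCRIPT_FOREGROUND_MIN = 10

#: meta-pixel averaging window (square side, in pixels)
META_PIXEL_WINDOW = 5

#: default patch geometry (pixels)
PATCH_SIDE = 40
PATCH_STRIDE = 10
MIN_TISSUE_FRACTION = 0.2


class DegenerateHistogramError(ValueError):
    """Raised when the segmentation summary image is constant."""


class UnknownGeneError(KeyError):
    """Raised when a transcript table contains a gene not in the gene order."""


class EmptyPatchSetError(ValueError):
    """Raised when no patch passes the tissue-fraction filter."""


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def rasterize_transcripts(
    transcripts: pd.DataFrame,
    resolution_um: float = 10.0,
    gene_order: list[str] | None = None,
    sample_id: str = "sample",
    x: str = "x",
    y: str = "y",
    gene: str = "gene",
) -> SampleRaster:
    """Bin a transcript table into a pixel grid of per-gene counts.

    A transcript at coordinate ``(x, y)`` (micrometres) lands in pixel
    ``(floor(x/r), floor(y/r))``. Total counts are conserved exactly.
    """
    if resolution_um <= 0:
        raise ValueError("resolution_um must be positive")
    if len(transcripts) == 0:
        raise ValueError("empty transcript table: raster would have zero extent")
    coords = transcripts[[x, y]].to_numpy(dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("transcript coordinates must be finite")
    if np.any(coords < 0):
        raise ValueError("transcript coordinates must be non-negative")

    genes = transcripts[gene].to_numpy()
    if gene_order is None:
        gene_order = sorted(pd.unique(genes))
    gene_index = {g: m for m, g in enumerate(gene_order)}
    unknown = set(genes) - set(gene_index)
    if unknown:
        raise UnknownGeneError(f"unknown gene id(s) not in gene_order: {sorted(unknown)!r}")

    ix = np.floor(coords[:, 0] / resolution_um).astype(np.int64)
    iy = np.floor(coords[:, 1] / resolution_um).astype(np.int64)
    im = np.array([gene_index[g] for g in genes], dtype=np.int64)
    shape = (int(ix.max()) + 1, int(iy.max()) + 1, len(gene_order))
    values = np.zeros(shape, dtype=np.float64)
    np.add.at(values, (ix, iy, im), 1.0)
    return SampleRaster(
        sample_id=sample_id,
        values=values,
        channel_names=list(gene_order),
        resolution_um=resolution_um,
    )


# ---------------------------------------------------------------------------
# foreground segmentation
# ---------------------------------------------------------------------------

def _summary_image(
    raster: SampleRaster,
    modality: str,
    channel_roles: dict[str, str] | None,
) -> np.ndarray:
    if modality == "transcript":
        return raster.values.sum(axis=2)
    roles = channel_roles or {}
    names = raster.channel_names
    marker_ix = [i for i, c in enumerate(names) if roles.get(c, "marker") == "marker"]
    neg_ix = [i for i, c in enumerate(names) if roles.get(c) == "negative_control"]
    signal = raster.values[:, :, marker_ix].sum(axis=2)
    if neg_ix:
        noise = raster.values[:, :, neg_ix].sum(axis=2)
        return signal / np.maximum(noise, np.finfo(float).tiny)
    return signal


def segment_foreground(
    raster: SampleRaster,
    modality: str = "intensity",
    channel_roles: dict[str, str] | None = None,
    inplace: bool = True,
) -> np.ndarray:
    """Segment tissue from background and zero out background pixels.

    Transcript modalities use a hard threshold of ``TRANSCRIPT_FOREGROUND_MIN``
    total transcripts per pixel. Intensity modalities summarize each pixel
    (summed marker intensity, divided by summed negative-control intensity
    when control stains exist) and apply Otsu's threshold on a 256-bin
    histogram of that summary.
    """
    if modality not in ("transcript", "intensity"):
        raise ValueError(f"unknown modality {modality!r}")
    summary = _summary_image(raster, modality, channel_roles)
    if modality == "transcript":
        mask = summary >= TRANSCRIPT_FOREGROUND_MIN
    else:
        if summary.max() == summary.min():
            raise DegenerateHistogramError(
                "summary image is constant; Otsu threshold is undefined"
            )
        thr = threshold_otsu(summary, nbins=256)
        mask = summary > thr
    if inplace:
        raster.foreground = mask
        raster.values = raster.values * mask[:, :, None]
    return mask


# ---------------------------------------------------------------------------
# log-normalization
# ---------------------------------------------------------------------------

def lognormalize_pixels(
    rasters: list[SampleRaster],
    modality: str = "intensity",
    epsilon: float = 1.0,
    marker_names: list[str] | None = None,
) -> tuple[list[np.ndarray], float]:
    """Log-normalize every non-empty foreground pixel of the dataset.

    With ``q`` the dataset-wide median total pixel intensity, each pixel
    ``p`` maps to ``log(q * p_m / sum(p))`` per marker. Zeros inside the log
    are stabilized: intensity data substitutes ``epsilon`` for zero marker
    values in the numerator; transcript counts use ``log1p`` of the scaled
    ratio instead.

    Returns per-sample ``(X, Y, M)`` arrays (zero at background/empty pixels)
    and ``q``.
    """
    sel = None
    if marker_names is not None:
        sel = [rasters[0].channel_names.index(c) for c in marker_names]

    totals = []
    for r in rasters:
        if r.foreground is None:
            raise ValueError("rasters must be segmented before normalization")
        vals = r.values if sel is None else r.values[:, :, sel]
        tot = vals.sum(axis=2)
        totals.append(tot[r.foreground & (tot > 0)])
    q = float(np.median(np.concatenate(totals)))

    out = []
    for r in rasters:
        vals = r.values if sel is None else r.values[:, :, sel]
        tot = vals.sum(axis=2)
        ok = r.foreground & (tot > 0)
        norm = np.zeros_like(vals, dtype=np.float64)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = q * vals / tot[:, :, None]
        if modality == "transcript":
            norm[ok] = np.log1p(ratio[ok])
        else:
            v = ratio[ok]
            zero = vals[ok] == 0
            v[zero] = (q * epsilon / tot[ok][:, None] * np.ones_like(v))[zero]
            norm[ok] = np.log(v)
        out.append(norm)
    return out, q


# ---------------------------------------------------------------------------
# meta-markers
# ---------------------------------------------------------------------------

def _meta_pixel_field(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Average each pixel's 5x5 window over non-empty pixels only."""
    m = mask.astype(np.float64)
    num = uniform_filter(values * m[:, :, None], size=(META_PIXEL_WINDOW, META_PIXEL_WINDOW, 1), mode="constant")
    den = uniform_filter(m, size=META_PIXEL_WINDOW, mode="constant")
    with np.errstate(divide="ignore", invalid="ignore"):
        meta = num / den[:, :, None]
    meta[~mask] = 0.0
    meta[den == 0] = 0.0
    return meta


@dataclass
class MetaMarkerModel:
    """Fitted PCA mapping normalized markers to meta-markers."""

    loadings: np.ndarray        # M x K
    center: np.ndarray          # meta-pixel means, length M
    explained_variance_ratio: np.ndarray

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.center) @ self.loadings


def default_n_metamarkers(n_markers: int) -> int:
    """K = 10 normally, 5 for datasets with fewer than 10 markers."""
    if n_markers >= 10:
        return 10
    return min(5, n_markers)


def compute_metamarkers(
    normalized: list[np.ndarray],
    masks: list[np.ndarray],
    n_metamarkers: int | None = None,
) -> tuple[MetaMarkerModel, list[np.ndarray]]:
    """Fit PCA on 5x5 meta-pixels and project the original pixels.

    The PCA is fit on locally averaged meta-pixels (averaging only non-empty
    pixels in each window), which suppresses single-pixel noise in the
    loadings; each *original* normalized pixel is then centered by the
    meta-pixel means and projected on the top-K loadings.
    """
    n_markers = normalized[0].shape[2]
    if n_metamarkers is None:
        n_metamarkers = default_n_metamarkers(n_markers)
    if n_metamarkers > n_markers:
        raise ValueError(
            f"n_metamarkers={n_metamarkers} exceeds number of markers {n_markers}"
        )

    meta = [
        _meta_pixel_field(vals, mask)[mask]
        for vals, mask in zip(normalized, masks)
    ]
    stacked = np.concatenate(meta, axis=0)
    pca = PCA(n_components=n_metamarkers, svd_solver="full")
    pca.fit(stacked)
    model = MetaMarkerModel(
        loadings=pca.components_.T,
        center=pca.mean_,
        explained_variance_ratio=pca.explained_variance_ratio_,
    )
    fields = []
    for vals, mask in zip(normalized, masks):
        k_field = np.zeros(vals.shape[:2] + (n_metamarkers,), dtype=np.float64)
        k_field[mask] = model.transform(vals[mask])
        fields.append(k_field)
    return model, fields


# ---------------------------------------------------------------------------
# batch correction
# ---------------------------------------------------------------------------

def _soft_kmeans_correct(
    z: np.ndarray,
    batch_codes: np.ndarray,
    n_clusters: int,
    n_batches: int,
    theta: float = 2.0,
    sigma: float = 0.1,
    max_rounds: int = 10,
    tol: float = 1e-4,
    seed: int = 0,
) -> np.ndarray:
    """Iterative diversity-penalized soft clustering with per-cluster linear
    removal of batch offsets (intercept-only design per batch)."""
    rng = np.random.default_rng(seed)
    z = z.copy()
    n = len(z)
    batch_onehot = np.zeros((n, n_batches))
    batch_onehot[np.arange(n), batch_codes] = 1.0
    batch_frac = batch_onehot.mean(axis=0)  # n_b / n

    # initialize centroids from random points
    centroids = z[rng.choice(n, size=n_clusters, replace=False)]
    for _ in range(max_rounds):
        # cosine-style distances on scaled rows stabilize cluster sizes
        d2 = ((z[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        scale = np.median(d2) + 1e-12
        r = np.exp(-d2 / (sigma * scale + 1e-12))
        # diversity penalty: down-weight clusters a batch over-populates
        obs = batch_onehot.T @ r + 1e-12                       # n_batches x k
        exp = batch_frac[:, None] * r.sum(axis=0)[None, :] + 1e-12
        r = r * ((exp / obs) ** theta)[batch_codes, :]
        r = r / r.sum(axis=1, keepdims=True)

        centroids = (r.T @ z) / (r.sum(axis=0)[:, None] + 1e-12)

        # per-cluster batch offsets relative to the cluster mean, vectorized:
        # sums[k,b,:] over points of batch b in cluster k, weighted by r
        rz = r[:, :, None] * z[:, None, :]                      # n x k x d
        sums = np.einsum("nb,nkd->kbd", batch_onehot, rz)
        wsum = np.einsum("nb,nk->kb", batch_onehot, r)          # k x b
        mu_k = sums.sum(axis=1) / (wsum.sum(axis=1)[:, None] + 1e-12)
        mu_kb = sums / np.maximum(wsum[:, :, None], 1e-12)
        delta = np.where(wsum[:, :, None] > 1e-8, mu_kb - mu_k[:, None, :], 0.0)
        # shift_i = sum_k r_ik * delta[k, batch(i), :]
        shift = np.einsum("nk,nkd->nd", r, delta[:, batch_codes, :].transpose(1, 0, 2))
        z = z - shift
        if np.abs(shift).max() < tol:
            break
    return z


def correct_batch(
    pixel_metamarkers: np.ndarray,
    sample_ids: np.ndarray,
    n_clusters: int | None = None,
    theta: float = 2.0,
    max_rounds: int = 10,
    seed: int = 0,
    standardize: bool = True,
) -> np.ndarray:
    """Remove per-sample pixel-level batch effects from meta-markers.

    Runs an iterative soft-clustering linear batch correction (diversity-
    penalized soft k-means; within each cluster, each batch's offset from the
    cluster mean is subtracted) with the sample id as the batch key, then
    standardizes each meta-marker dataset-wide to mean 0, variance 1
    (population convention) — the contract downstream reconstruction
    baselines rely on.
    """
    z = np.asarray(pixel_metamarkers, dtype=np.float64)
    sample_ids = np.asarray(sample_ids)
    uniq, codes = np.unique(sample_ids, return_inverse=True)
    if len(uniq) < 2:
        logger.warning("single sample: skipping batch correction, standardizing only")
        corrected = z.copy()
    else:
        if n_clusters is None:
            n_clusters = int(np.clip(len(z) // 2000, 5, 20))
        corrected = _soft_kmeans_correct(
            z, codes, n_clusters=n_clusters, n_batches=len(uniq),
            theta=theta, max_rounds=max_rounds, seed=seed,
        )
    if standardize:
        mu = corrected.mean(axis=0)
        sd = corrected.std(axis=0)  # population convention
        sd[sd == 0] = 1.0
        corrected = (corrected - mu) / sd
    return corrected


# ---------------------------------------------------------------------------
# patch extraction
# ---------------------------------------------------------------------------

def extract_patches(
    field: MetaMarkerField,
    side_px: int = PATCH_SIDE,
    stride_px: int = PATCH_STRIDE,
    min_tissue: float = MIN_TISSUE_FRACTION,
) -> PatchSet:
    """Cut overlapping square patches from a meta-marker field.

    Anchors lie on the stride grid; patches are fully contained in the field
    (the edge remainder is dropped rather than padded). Patches with tissue
    fraction below ``min_tissue`` are discarded.
    """
    x_ext, y_ext = field.values.shape[:2]
    if side_px > x_ext or side_px > y_ext:
        raise ValueError("patch side exceeds field extent")
    xs = np.arange(0, x_ext - side_px + 1, stride_px)
    ys = np.arange(0, y_ext - side_px + 1, stride_px)
    patches, anchors, fracs = [], [], []
    fg = field.foreground
    for ax in xs:
        for ay in ys:
            frac = fg[ax : ax + side_px, ay : ay + side_px].mean()
            if frac < min_tissue:
                continue
            patches.append(field.values[ax : ax + side_px, ay : ay + side_px, :])
            anchors.append((ax, ay))
            fracs.append(frac)
    if not patches:
        raise EmptyPatchSetError(
            f"no patch of sample {field.sample_id!r} passes min_tissue={min_tissue}"
        )
    n = len(patches)
    return PatchSet(
        patches=np.asarray(patches, dtype=np.float32),
        sample_ids=np.asarray([field.sample_id] * n),
        anchors=np.asarray(anchors, dtype=np.int64),
        tissue_fraction=np.asarray(fracs, dtype=float),
    )


def concat_patchsets(patchsets: list[PatchSet]) -> PatchSet:
    return PatchSet(
        patches=np.concatenate([p.patches for p in patchsets], axis=0),
        sample_ids=np.concatenate([p.sample_ids for p in patchsets]),
        anchors=np.concatenate([p.anchors for p in patchsets], axis=0),
        tissue_fraction=np.concatenate([p.tissue_fraction for p in patchsets]),
    )


# ---------------------------------------------------------------------------
# end-to-end convenience
# ---------------------------------------------------------------------------

def preprocess_dataset(
    rasters: list[SampleRaster],
    modality: str = "intensity",
    channel_roles: dict[str, str] | None = None,
    n_metamarkers: int | None = None,
    side_px: int = PATCH_SIDE,
    stride_px: int = PATCH_STRIDE,
    min_tissue: float = MIN_TISSUE_FRACTION,
    epsilon: float = 1.0,
    seed: int = 0,
) -> tuple[list[MetaMarkerField], PatchSet, dict]:
    """Run segmentation, normalization, meta-marker PCA, batch correction and
    patch extraction over a multi-sample dataset.

    Channels whose role is ``registration`` are excluded before normalization;
    ``negative_control`` channels enter only the segmentation summary.
    """
    roles = channel_roles or {}
    for r in rasters:
        if r.foreground is None:
            segment_foreground(r, modality=modality, channel_roles=roles)
    marker_names = [c for c in rasters[0].channel_names if roles.get(c, "marker") == "marker"]
    normalized, q = lognormalize_pixels(
        rasters, modality=modality, epsilon=epsilon, marker_names=marker_names
    )
    masks = []
    for r, norm in zip(rasters, normalized):
        tot = (r.values[:, :, [r.channel_names.index(c) for c in marker_names]]).sum(axis=2)
        masks.append(r.foreground & (tot > 0))
    model, k_fields = compute_metamarkers(normalized, masks, n_metamarkers)

    flat = np.concatenate([f[m] for f, m in zip(k_fields, masks)], axis=0)
    pix_samples = np.concatenate(
        [np.repeat(r.sample_id, int(m.sum())) for r, m in zip(rasters, masks)]
    )
    corrected = correct_batch(flat, pix_samples, seed=seed)

    fields = []
    offset = 0
    for r, mask in zip(rasters, masks):
        n_pix = int(mask.sum())
        vals = np.zeros(mask.shape + (corrected.shape[1],), dtype=np.float64)
        vals[mask] = corrected[offset : offset + n_pix]
        offset += n_pix
        fields.append(
            MetaMarkerField(
                sample_id=r.sample_id,
                values=vals,
                foreground=mask,
                loadings=model.loadings,
                pixel_median_intensity=q,
            )
        )
    patchset = concat_patchsets(
        [extract_patches(f, side_px, stride_px, min_tissue) for f in fields]
    )
    info = {
        "q": q,
        "n_metamarkers": model.loadings.shape[1],
        "n_pixels_kept": int(sum(m.sum() for m in masks)),
        "n_patches": len(patchset),
        "explained_variance_ratio": model.explained_variance_ratio.tolist(),
    }
    logger.info(
        "preprocess: %d samples, q=%.3g, K=%d, %d pixels, %d patches",
        len(rasters), q, info["n_metamarkers"], info["n_pixels_kept"], info["n_patches"],
    )
    return fields, patchset, info
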