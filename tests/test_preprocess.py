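"""Unit tests for rasterization, segmentation, normalization and patching."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vima import preprocess
from vima.preprocess import (
    DegenerateHistogramError,
    EmptyPatchSetError,
    UnknownGeneError,
    compute_metamarkers,
    correct_batch,
    extract_patches,
    lognormalize_pixels,
    rasterize_transcripts,
    segment_foreground,
)
from vima.types import MetaMarkerField, SampleRaster


def make_raster(values, foreground=None, names=None):
    values = np.asarray(values, dtype=float)
    names = names or [f"c{i}" for i in range(values.shape[2])]
    return SampleRaster(sample_id="s0", values=values, channel_names=names,
                        foreground=foreground)


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

class TestRasterize:
    def test_floor_binning(self):
        df = pd.DataFrame({"x": [1.0, 5.0, 15.0], "y": [1.0, 5.0, 2.0],
                           "gene": ["A", "A", "A"]})
        raster = rasterize_transcripts(df, resolution_um=10, gene_order=["A"])
        assert raster.values[0, 0, 0] == 2
        assert raster.values[1, 0, 0] == 1

    def test_count_conservation_random(self):
        r = np.random.default_rng(1)
        n = 2000
        df = pd.DataFrame({
            "x": r.uniform(0, 300, n), "y": r.uniform(0, 200, n),
            "gene": r.choice(["A", "B", "C"], n),
        })
        raster = rasterize_transcripts(df, 10, ["A", "B", "C"])
        assert raster.values.sum() == n

    def test_matches_bruteforce_loop(self):
        r = np.random.default_rng(7)
        n = 2000
        genes = ["A", "B"]
        df = pd.DataFrame({
            "x": r.uniform(0, 150, n), "y": r.uniform(0, 90, n),
            "gene": r.choice(genes, n),
        })
        raster = rasterize_transcripts(df, 10, genes)
        # independent oracle: naive per-transcript loop
        expected = np.zeros_like(raster.values)
        for _, row in df.iterrows():
            expected[int(row.x // 10), int(row.y // 10), genes.index(row.gene)] += 1
        np.testing.assert_array_equal(raster.values, expected)

    def test_unknown_gene_named_in_error(self):
        df = pd.DataFrame({"x": [1.0], "y": [1.0], "gene": ["Z"]})
        with pytest.raises(UnknownGeneError, match="Z"):
            rasterize_transcripts(df, 10, ["A"])

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="zero extent"):
            rasterize_transcripts(pd.DataFrame({"x": [], "y": [], "gene": []}), 10, ["A"])


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

class TestSegmentation:
    def test_transcript_threshold_at_ten(self):
        vals = np.array([[[3.0], [9.0]], [[10.0], [50.0]]])
        raster = make_raster(vals)
        mask = segment_foreground(raster, modality="transcript", inplace=False)
        np.testing.assert_array_equal(mask, [[False, False], [True, True]])

    def test_otsu_matches_exhaustive_scan(self):
        r = np.random.default_rng(2)
        lo = r.normal(1, 0.3, size=(20, 20))
        hi = r.normal(8, 0.8, size=(20, 20))
        img = np.clip(np.where(r.random((20, 20)) < 0.4, hi, lo), 0.01, None)
        raster = make_raster(img[:, :, None])
        mask = segment_foreground(raster, modality="intensity", inplace=False)

        # oracle: exhaustive between-class-variance maximization over all
        # 256-bin cut points; the threshold is the last class-0 bin center
        counts, edges = np.histogram(img, bins=256)
        centers = (edges[:-1] + edges[1:]) / 2
        best_t, best_v = None, -1.0
        for t in range(255):
            w0, w1 = counts[: t + 1].sum(), counts[t + 1 :].sum()
            if w0 == 0 or w1 == 0:
                continue
            m0 = (counts[: t + 1] * centers[: t + 1]).sum() / w0
            m1 = (counts[t + 1 :] * centers[t + 1 :]).sum() / w1
            v = w0 * w1 * (m0 - m1) ** 2
            if v > best_v:
                best_v, best_t = v, centers[t]
        np.testing.assert_array_equal(mask, img > best_t)

    def test_bimodal_separation(self):
        img = np.array([0.0, 0, 0, 10, 10, 10]).reshape(2, 3)
        raster = make_raster(img[:, :, None])
        mask = segment_foreground(raster, modality="intensity", inplace=False)
        assert mask.sum() == 3
        assert mask[1].all()

    def test_background_zeroed_after_masking(self):
        vals = np.zeros((3, 3, 2))
        vals[0, 0] = [1, 2]  # below transcript threshold
        raster = make_raster(vals)
        segment_foreground(raster, modality="transcript")
        assert np.all(raster.values == 0)

    def test_constant_summary_rejected(self):
        raster = make_raster(np.full((4, 4, 1), 3.0))
        with pytest.raises(DegenerateHistogramError):
            segment_foreground(raster, modality="intensity")

    def test_negative_control_ratio_summary(self):
        vals = np.zeros((1, 2, 2))
        vals[0, 0] = [8.0, 2.0]   # marker / control = 4
        vals[0, 1] = [8.0, 8.0]   # ratio 1
        raster = make_raster(vals, names=["m", "ctrl"])
        summary = preprocess._summary_image(raster, "intensity", {"ctrl": "negative_control"})
        np.testing.assert_allclose(summary, [[4.0, 1.0]])


# ---------------------------------------------------------------------------
# log-normalization
# ---------------------------------------------------------------------------

def _one_pixel_dataset(pixels):
    """Dataset of single-row rasters from a list of pixel vectors."""
    vals = np.array(pixels, dtype=float)[None]  # 1 x n x M
    fg = np.ones(vals.shape[:2], dtype=bool)
    return [make_raster(vals, foreground=fg)]


class TestLogNormalize:
    def test_direct_formula(self):
        rasters = _one_pixel_dataset([[2.0, 2.0], [1.0, 3.0], [3.0, 3.0]])
        out, q = lognormalize_pixels(rasters)
        assert q == 4.0
        np.testing.assert_allclose(out[0][0, 0], [np.log(2), np.log(2)])

    def test_median_total(self):
        rasters = _one_pixel_dataset([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        _, q = lognormalize_pixels(rasters)
        assert q == 4.0

    def test_zero_marker_uses_epsilon(self):
        eps = 0.5
        rasters = _one_pixel_dataset([[4.0, 0.0], [1.0, 3.0], [2.0, 2.0]])
        out, q = lognormalize_pixels(rasters, epsilon=eps)
        assert q == 4.0
        np.testing.assert_allclose(out[0][0, 0], [np.log(4.0), np.log(eps)])

    def test_dataset_rescaling_shifts_uniformly(self):
        # global rescaling only shifts every normalized value by log(c):
        # q and each pixel total scale together, the per-pixel composition
        # is unchanged, and the constant shift is absorbed by PCA centering
        r = np.random.default_rng(3)
        base = r.uniform(0.5, 5, size=(4, 5, 3))
        fg = np.ones((4, 5), dtype=bool)
        out1, q1 = lognormalize_pixels([make_raster(base, foreground=fg)])
        out2, q2 = lognormalize_pixels([make_raster(7.0 * base, foreground=fg)])
        assert q2 == pytest.approx(7.0 * q1)
        np.testing.assert_allclose(out2[0], out1[0] + np.log(7.0), atol=1e-12)

    def test_composition_invariant_per_pixel(self):
        # scaling a single pixel's vector leaves its composition p_m / sum
        # unchanged; with q held fixed the normalized value is unchanged too
        rasters = _one_pixel_dataset([[2.0, 2.0], [6.0, 6.0], [1.0, 3.0]])
        out, q = lognormalize_pixels(rasters)
        np.testing.assert_allclose(out[0][0, 0], out[0][0, 1], atol=1e-12)

    def test_transcript_mode_log1p_of_zero_is_zero(self):
        vals = np.zeros((1, 1, 2))
        vals[0, 0] = [12.0, 0.0]
        fg = np.ones((1, 1), dtype=bool)
        out, q = lognormalize_pixels([make_raster(vals, foreground=fg)],
                                     modality="transcript")
        assert out[0][0, 0, 1] == 0.0
        assert out[0][0, 0, 0] == pytest.approx(np.log1p(q))


# ---------------------------------------------------------------------------
# meta-markers
# ---------------------------------------------------------------------------

class TestMetaMarkers:
    def test_default_k_rule(self):
        assert preprocess.default_n_metamarkers(7) == 5
        assert preprocess.default_n_metamarkers(10) == 10
        assert preprocess.default_n_metamarkers(140) == 10
        assert preprocess.default_n_metamarkers(3) == 3

    def test_k_exceeding_markers_rejected(self):
        r = np.random.default_rng(0)
        vals = r.standard_normal((6, 6, 3))
        mask = np.ones((6, 6), dtype=bool)
        with pytest.raises(ValueError, match="exceeds"):
            compute_metamarkers([vals], [mask], n_metamarkers=5)

    def test_isolated_pixel_meta_equals_itself(self):
        vals = np.zeros((7, 7, 2))
        vals[3, 3] = [1.5, -2.0]
        mask = np.zeros((7, 7), dtype=bool)
        mask[3, 3] = True
        meta = preprocess._meta_pixel_field(vals, mask)
        np.testing.assert_allclose(meta[3, 3], vals[3, 3])

    def test_full_rank_projection_is_exact_rotation(self):
        r = np.random.default_rng(4)
        vals = r.standard_normal((10, 10, 3))
        mask = np.ones((10, 10), dtype=bool)
        model, fields = compute_metamarkers([vals], [mask], n_metamarkers=3)
        # full-rank PCA: reconstruction from all PCs recovers the input
        recon = fields[0][mask] @ model.loadings.T + model.center
        np.testing.assert_allclose(recon, vals[mask], atol=1e-10)
        # loadings are orthonormal
        np.testing.assert_allclose(model.loadings.T @ model.loadings, np.eye(3),
                                   atol=1e-10)

    def test_loadings_ordered_by_explained_variance(self):
        r = np.random.default_rng(5)
        vals = r.standard_normal((20, 20, 4)) * np.array([5, 2, 1, 0.3])
        mask = np.ones((20, 20), dtype=bool)
        model, _ = compute_metamarkers([vals], [mask], n_metamarkers=3)
        evr = model.explained_variance_ratio
        assert np.all(np.diff(evr) <= 0)


# ---------------------------------------------------------------------------
# batch correction
# ---------------------------------------------------------------------------

class TestCorrectBatch:
    def test_offset_batches_aligned(self):
        r = np.random.default_rng(6)
        n = 2000
        base = r.standard_normal((n, 3))
        z = np.concatenate([base, base + np.array([2.0, -1.0, 0.5])])
        sids = np.array(["a"] * n + ["b"] * n)
        out = correct_batch(z, sids, seed=0)
        gap = out[:n].mean(axis=0) - out[n:].mean(axis=0)
        assert np.abs(gap).max() < 0.1

    def test_identical_samples_pass_through(self):
        r = np.random.default_rng(8)
        base = r.standard_normal((800, 2))
        z = np.concatenate([base, base])
        sids = np.array(["a"] * 800 + ["b"] * 800)
        out = correct_batch(z, sids, seed=0)
        expected = (z - z.mean(axis=0)) / z.std(axis=0)
        assert np.abs(out - expected).max() < 0.15

    def test_standardization_contract(self):
        r = np.random.default_rng(9)
        z = r.standard_normal((1500, 4)) + r.standard_normal(4)
        sids = np.repeat(["a", "b", "c"], 500)
        out = correct_batch(z, sids, seed=0)
        np.testing.assert_allclose(out.mean(axis=0), 0, atol=1e-6)
        np.testing.assert_allclose(out.std(axis=0), 1, atol=1e-6)

    def test_single_sample_standardizes_only(self):
        r = np.random.default_rng(10)
        z = 3 * r.standard_normal((300, 2)) + 5
        out = correct_batch(z, np.repeat("a", 300), seed=0)
        np.testing.assert_allclose(out, (z - z.mean(0)) / z.std(0), atol=1e-10)


# ---------------------------------------------------------------------------
# patch extraction
# ---------------------------------------------------------------------------

def make_field(x=120, y=120, k=2, fg=None):
    fg = np.ones((x, y), dtype=bool) if fg is None else fg
    vals = np.random.default_rng(0).standard_normal((x, y, k)) * fg[:, :, None]
    return MetaMarkerField(sample_id="s0", values=vals, foreground=fg,
                           loadings=np.eye(k), pixel_median_intensity=1.0)


class TestExtractPatches:
    def test_grid_count_closed_form(self):
        ps = extract_patches(make_field(120, 120), side_px=40, stride_px=10)
        assert len(ps) == 81  # ((120-40)/10+1)^2

    def test_anchors_on_stride_grid(self):
        ps = extract_patches(make_field(100, 90), side_px=40, stride_px=10)
        assert np.all(ps.anchors % 10 == 0)

    def test_all_foreground_tissue_fraction_one(self):
        ps = extract_patches(make_field(80, 80))
        assert np.all(ps.tissue_fraction == 1.0)

    def test_low_tissue_patch_discarded(self):
        fg = np.zeros((40, 80), dtype=bool)
        fg[:, 46:] = True   # left patch 0% ... right-side patches tissue-rich
        fg[:6, :] = True    # left patch has 6 rows -> 15% tissue
        ps = extract_patches(make_field(40, 80, fg=fg), side_px=40, stride_px=40)
        assert (0, 0) not in {tuple(a) for a in ps.anchors}

    def test_no_patch_passes_raises(self):
        fg = np.zeros((60, 60), dtype=bool)
        with pytest.raises(EmptyPatchSetError):
            extract_patches(make_field(60, 60, fg=fg))

    def test_patch_side_exceeds_extent(self):
        with pytest.raises(ValueError):
            extract_patches(make_field(30, 120), side_px=40)

    @given(st.integers(40, 90), st.integers(40, 90))
    @settings(max_examples=10, deadline=None)
    def test_patch_count_formula_random_extents(self, x, y):
        ps = extract_patches(make_field(x, y), side_px=40, stride_px=10)
        assert len(ps) == ((x - 40) // 10 + 1) * ((y - 40) // 10 + 1)
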