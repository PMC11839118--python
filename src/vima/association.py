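"""Case-control association testing on the microniche abundance tensor.

Given the MAT Q (samples x patches x encoders) and a sample-level phenotype
y, the pipeline standardizes each microniche's abundance across samples,
correlates it with y per encoder (matrix C, E x P), and

* locally meta-analyzes the per-encoder correlations of each patch into a
  single microniche coefficient ``rho_p = sum_e C^3 / sum_e C^2`` — an
  average that weights each encoder by its squared correlation, so encoders
  that learned useful structure for patch p dominate;
* globally summarizes the total signal as
  ``R = (1/P) * sum_p sum_e C^4 / sum_e C^2``.

Significance comes from donor-preserving permutations of y: all samples of a
donor always share a (permuted) phenotype value. The local test converts the
permutation null into an empirical FDR per candidate threshold rho*:
expected null exceedances over observed exceedances, separately for the
positive and negative tails.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .types import SampleMetadata

logger = logging.getLogger(__name__)

DEFAULT_N_PERM = 1000
DEFAULT_FDR_LEVEL = 0.10


# ---------------------------------------------------------------------------
# standardization and correlation
# ---------------------------------------------------------------------------

def standardize_mat(Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Standardize each (patch, encoder) abundance column across samples.

    Returns the standardized tensor and a boolean (P, E) mask of valid
    columns; zero-variance columns are flagged invalid (and zeroed) —
    they carry no case-control information and are excluded from testing.
    """
    Q = np.asarray(Q, dtype=np.float64)
    if Q.ndim != 3:
        raise ValueError("Q must be N x P x E")
    if Q.shape[0] < 3:
        raise ValueError("need at least 3 samples to standardize")
    mu = Q.mean(axis=0)
    sd = Q.std(axis=0)  # population convention
    valid = sd > 0
    if not valid.any():
        raise ValueError("all microniche columns have zero variance")
    out = np.zeros_like(Q)
    np.divide(Q - mu, sd, out=out, where=valid[None, :, :])
    return out, valid


def standardize_phenotype(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=np.float64)
    sd = y.std()
    if sd == 0:
        raise ValueError("phenotype is constant")
    return (y - y.mean()) / sd


def _residualize(x: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Least-squares residuals of x's columns on [1, covariates]."""
    design = np.column_stack([np.ones(len(x)), np.atleast_2d(covariates)])
    q, _ = np.linalg.qr(design)
    x2 = x if x.ndim == 2 else x[:, None]
    res = x2 - q @ (q.T @ x2)
    return res.reshape(x.shape)


def correlate(Q_std: np.ndarray, y: np.ndarray,
              covariates: np.ndarray | None = None,
              valid: np.ndarray | None = None) -> np.ndarray:
    """Correlation matrix C (E x P) between phenotype and microniche abundance.

    If covariates are supplied, both y and the abundance columns are
    residualized on them (then re-standardized) before correlating.
    """
    n, p, e = Q_std.shape
    if covariates is not None:
        Q_flat = _residualize(Q_std.reshape(n, p * e), covariates)
        sd = Q_flat.std(axis=0)
        sd[sd == 0] = 1.0
        Q_std = ((Q_flat - Q_flat.mean(axis=0)) / sd).reshape(n, p, e)
        y = _residualize(np.asarray(y, dtype=float), covariates)
    y_std = standardize_phenotype(y)
    c = np.einsum("n,npe->ep", y_std, Q_std) / n
    if valid is not None:
        c = c * valid.T
    return np.clip(c, -1.0, 1.0)


def meta_local(C: np.ndarray) -> np.ndarray:
    """Moment-ratio meta-analysis across encoders: rho = sum C^3 / sum C^2."""
    C = np.asarray(C, dtype=np.float64)
    num = (C ** 3).sum(axis=0)
    den = (C ** 2).sum(axis=0)
    return np.divide(num, den, out=np.zeros_like(num), where=den > 0)


def global_statistic(C: np.ndarray) -> float:
    """R = (1/P) sum_p sum_e C^4 / sum_e C^2, zero-denominator terms -> 0.

    P counts the patches with at least one non-degenerate correlation, so a
    dataset of all-zero correlations gives R = 0 and R is always in [0, 1].
    """
    C = np.asarray(C, dtype=np.float64)
    num = (C ** 4).sum(axis=0)
    den = (C ** 2).sum(axis=0)
    terms = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    p_eff = int((den > 0).sum())
    if p_eff == 0:
        return 0.0
    return float(terms.sum() / p_eff)


# ---------------------------------------------------------------------------
# permutations
# ---------------------------------------------------------------------------

def permute_phenotype(metadata: SampleMetadata,
                      rng: np.random.Generator) -> np.ndarray:
    """Donor-preserving permutation of the phenotype.

    Phenotype values are permuted at the donor level: every sample of a donor
    receives that donor's permuted value, so within-donor label agreement is
    preserved exactly.
    """
    donors, first_ix = np.unique(metadata.donor_ids, return_index=True)
    donor_values = metadata.phenotype[first_ix]
    for d, v in zip(donors, donor_values):
        vals = metadata.phenotype[metadata.donor_ids == d]
        if not np.all(vals == vals[0]):
            raise ValueError(f"donor {d!r} has inconsistent phenotype values")
    permuted = donor_values[rng.permutation(len(donors))]
    lookup = {d: v for d, v in zip(donors, permuted)}
    return np.array([lookup[d] for d in metadata.donor_ids], dtype=float)


def _null_correlations(Q_std: np.ndarray, metadata: SampleMetadata,
                       n_perm: int, rng: np.random.Generator,
                       valid: np.ndarray | None,
                       covariates: np.ndarray | None) -> np.ndarray:
    """Null correlation matrices, shape (n_perm, E, P)."""
    n, p, e = Q_std.shape
    out = np.empty((n_perm, e, p))
    for i in range(n_perm):
        y0 = permute_phenotype(metadata, rng)
        out[i] = correlate(Q_std, y0, covariates=covariates, valid=valid)
    return out


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------

@dataclass
class LocalResult:
    """Per-patch microniche coefficients with empirical-FDR calls."""

    rho: np.ndarray
    fdr_table: pd.DataFrame
    significant_pos: np.ndarray
    significant_neg: np.ndarray
    qvalue: np.ndarray
    fdr_level: float
    n_permutations: int

    @property
    def n_significant(self) -> int:
        return len(self.significant_pos) + len(self.significant_neg)


@dataclass
class GlobalResult:
    """Global correlation-signal statistic with its permutation P-value."""

    R: float
    p_value: float
    n_permutations: int
    null_R: np.ndarray = field(repr=False, default=None)


@dataclass
class AssociationResult:
    local: LocalResult
    global_: GlobalResult
    C: np.ndarray
    valid: np.ndarray


# ---------------------------------------------------------------------------
# empirical FDR
# ---------------------------------------------------------------------------

def _tail_fdr(rho: np.ndarray, null_rho: np.ndarray,
              thresholds: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Raw and isotonized empirical FDR for the positive tail at each
    threshold: mean null exceedances / observed exceedances."""
    obs = (rho[None, :] >= thresholds[:, None]).sum(axis=1).astype(float)
    null_exc = (null_rho[:, None, :] >= thresholds[None, :, None]).sum(axis=2)
    expected = null_exc.mean(axis=0)
    raw = np.divide(expected, obs, out=np.zeros_like(expected), where=obs > 0)
    # running minimum toward the extreme (largest) threshold: a stricter
    # cutoff can never have a worse estimate than a looser one
    order = np.argsort(thresholds)
    iso = raw.copy()
    iso[order] = np.minimum.accumulate(raw[order])
    return raw, iso


def local_test(Q_std: np.ndarray, metadata: SampleMetadata,
               n_perm: int = DEFAULT_N_PERM,
               fdr_level: float = DEFAULT_FDR_LEVEL,
               seed: int = 0, valid: np.ndarray | None = None,
               covariates: np.ndarray | None = None,
               null_C: np.ndarray | None = None) -> LocalResult:
    """Local association test with permutation-based empirical FDR.

    Observed coefficients rho are computed once; the same donor-preserving
    permutation draws provide null coefficients rho0. For every candidate
    threshold (the observed coefficient values of each tail), the estimated
    FDR is the mean number of null exceedances divided by the number of
    observed exceedances; estimates are isotonized by a running minimum
    toward stricter thresholds. A patch is called significant if its
    coefficient passes the loosest threshold whose estimated FDR is at or
    below ``fdr_level``.
    """
    rng = np.random.default_rng(seed)
    C = correlate(Q_std, metadata.phenotype, covariates=covariates, valid=valid)
    rho = meta_local(C)
    if null_C is None:
        null_C = _null_correlations(Q_std, metadata, n_perm, rng, valid, covariates)
    null_rho = np.stack([meta_local(c0) for c0 in null_C])

    rows = []
    significant = {}
    qvalue = np.ones_like(rho)
    for tail, sign in (("pos", 1.0), ("neg", -1.0)):
        r = sign * rho
        r0 = sign * null_rho
        thr = np.unique(r[r > 0])
        if len(thr) == 0:
            significant[tail] = np.array([], dtype=int)
            continue
        raw, iso = _tail_fdr(r, r0, thr)
        for t, fr, fi in zip(thr, raw, iso):
            rows.append({"tail": tail, "threshold": sign * t,
                         "fdr_raw": min(fr, 1.0), "fdr": min(fi, 1.0)})
        ok = iso <= fdr_level
        if ok.any():
            cutoff = thr[ok].min()
            significant[tail] = np.flatnonzero(r >= cutoff)
        else:
            significant[tail] = np.array([], dtype=int)
        # per-patch q-value: isotonized FDR at the patch's own threshold
        pos_ix = np.flatnonzero(r > 0)
        if len(pos_ix):
            match = np.searchsorted(thr, r[pos_ix])
            qvalue[pos_ix] = np.minimum(qvalue[pos_ix], np.clip(iso[match], 0, 1))
    fdr_table = pd.DataFrame(rows, columns=["tail", "threshold", "fdr_raw", "fdr"])
    return LocalResult(
        rho=rho, fdr_table=fdr_table,
        significant_pos=significant["pos"], significant_neg=significant["neg"],
        qvalue=qvalue, fdr_level=fdr_level, n_permutations=len(null_rho),
    )


def global_test(Q_std: np.ndarray, metadata: SampleMetadata,
                n_perm: int = DEFAULT_N_PERM, seed: int = 0,
                valid: np.ndarray | None = None,
                covariates: np.ndarray | None = None,
                null_C: np.ndarray | None = None) -> GlobalResult:
    """Global association test: permutation P-value for the statistic R."""
    rng = np.random.default_rng(seed)
    C = correlate(Q_std, metadata.phenotype, covariates=covariates, valid=valid)
    r_obs = global_statistic(C)
    if null_C is None:
        null_C = _null_correlations(Q_std, metadata, n_perm, rng, valid, covariates)
    null_r = np.array([global_statistic(c0) for c0 in null_C])
    p = (1.0 + float((null_r >= r_obs).sum())) / (1.0 + len(null_r))
    return GlobalResult(R=r_obs, p_value=p, n_permutations=len(null_r), null_R=null_r)


def associate(Q: np.ndarray, metadata: SampleMetadata,
              n_perm: int = DEFAULT_N_PERM,
              fdr_level: float = DEFAULT_FDR_LEVEL, seed: int = 0,
              covariates: np.ndarray | None = None) -> AssociationResult:
    """Run standardization, the local test and the global test together.

    The two tests share the same permutation draws (one set of null
    correlation matrices), which halves the permutation cost and makes the
    global P-value and local FDRs mutually consistent.
    """
    Q_std, valid = standardize_mat(Q)
    rng = np.random.default_rng(seed)
    null_C = _null_correlations(Q_std, metadata, n_perm, rng, valid, covariates)
    local = local_test(Q_std, metadata, n_perm=n_perm, fdr_level=fdr_level,
                       seed=seed, valid=valid, covariates=covariates, null_C=null_C)
    global_ = global_test(Q_std, metadata, n_perm=n_perm, seed=seed,
                          valid=valid, covariates=covariates, null_C=null_C)
    C = correlate(Q_std, metadata.phenotype, covariates=covariates, valid=valid)
    return AssociationResult(local=local, global_=global_, C=C, valid=valid)


# ---------------------------------------------------------------------------
# auxiliary analyses
# ---------------------------------------------------------------------------

def mat_pca(Q: np.ndarray, n_components: int | None = None):
    """PCA of the flattened MAT (N x P*E): sample scores + explained variance."""
    Q = np.asarray(Q, dtype=np.float64)
    n = Q.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples")
    flat = Q.reshape(n, -1)
    if n_components is None:
        n_components = min(10, n - 1, flat.shape[1])
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(flat)
    return scores, pca.explained_variance_ratio_


def cluster_baseline_test(embedding: np.ndarray, sample_codes: np.ndarray,
                          metadata: SampleMetadata, n_perm: int = DEFAULT_N_PERM,
                          resolution: float = 1.0, seed: int = 0,
                          fdr_level: float = DEFAULT_FDR_LEVEL,
                          k: int = 15) -> dict:
    """Cluster-abundance comparator test.

    Patches are Leiden-clustered on the embedding; each sample is represented
    by its vector of cluster abundance fractions; each cluster's abundance is
    correlated with the phenotype and assigned a donor-preserving permutation
    P-value; the global P-value is the Bonferroni-corrected minimum. A
    sum-of-squared-correlations permutation variant and per-cluster empirical
    FDR calls are also reported.
    """
    import warnings

    import anndata as ad
    import scanpy as sc

    adata = ad.AnnData(X=np.asarray(embedding, dtype=np.float32))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.neighbors(adata, n_neighbors=min(k, len(adata) - 1), use_rep="X",
                        random_state=seed)
        sc.tl.leiden(adata, resolution=resolution, random_state=seed,
                     flavor="igraph", n_iterations=2, directed=False)
    labels = adata.obs["leiden"].astype(int).to_numpy()
    n_clusters = labels.max() + 1
    n_samples = len(metadata)

    abundance = np.zeros((n_samples, n_clusters))
    for s in range(n_samples):
        own = labels[sample_codes == s]
        if len(own):
            abundance[s] = np.bincount(own, minlength=n_clusters) / len(own)
    Q = abundance[:, :, None]  # reuse the microniche machinery with E=1
    Q_std, valid = standardize_mat(Q)
    rng = np.random.default_rng(seed)
    c_obs = correlate(Q_std, metadata.phenotype, valid=valid)[0]
    null_C = _null_correlations(Q_std, metadata, n_perm, rng, valid, None)
    null_c = null_C[:, 0, :]
    per_cluster_p = (1.0 + (np.abs(null_c) >= np.abs(c_obs)[None, :]).sum(axis=0)) / (
        1.0 + n_perm
    )
    global_bonferroni_p = min(1.0, n_clusters * per_cluster_p.min())
    sos_obs = float((c_obs ** 2).sum())
    sos_null = (null_c ** 2).sum(axis=1)
    global_sos_p = (1.0 + float((sos_null >= sos_obs).sum())) / (1.0 + n_perm)
    local = local_test(Q_std, metadata, n_perm=n_perm, fdr_level=fdr_level,
                       seed=seed, valid=valid, null_C=null_C)
    return {
        "labels": labels,
        "n_clusters": int(n_clusters),
        "correlations": c_obs,
        "per_cluster_p": per_cluster_p,
        "global_bonferroni_p": float(global_bonferroni_p),
        "global_sos_p": float(global_sos_p),
        "fdr_calls": local,
        "patch_scores": c_obs[labels],
    }


def contingency_log_odds(a: float, b: float, c: float, d: float) -> dict:
    """Log odds ratio of a 2x2 table with its asymptotic 95% CI.

    Uses the standard large-sample variance 1/a + 1/b + 1/c + 1/d. Zero cells
    are rejected; callers wanting a continuity correction must add it
    explicitly (e.g. 0.5 to every cell).
    """
    if min(a, b, c, d) <= 0:
        raise ValueError(
            "all four cells must be positive; add an explicit continuity "
            "correction (e.g. +0.5 per cell) for tables with zeros"
        )
    log_or = float(np.log((a * d) / (b * c)))
    se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    return {"log_or": log_or, "se": se,
            "ci95": (log_or - 1.96 * se, log_or + 1.96 * se)}
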