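"""Microniches: random-walk neighborhoods on patch-fingerprint k-NN graphs.

A microniche is anchored at one patch p under one encoder e: its membership
weights are the probabilities that an s-step random walk started at each other
patch arrives at p, on the k-nearest-neighbor graph G_e of that encoder's
fingerprints. Averaging arrival probabilities over the patches of each sample
yields the microniche abundance tensor (MAT) Q of shape N x P x E: the
expected fraction of sample n's patches arriving at patch p after s steps in
G_e. The walk's transition operator is the row-normalization of A_e + I
(self-loops keep short walks local); s is chosen adaptively by watching the
across-sample spread of the microniches mix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import scanpy as sc
import scipy.sparse as sp
from scipy.stats import kurtosis

logger = logging.getLogger(__name__)

DEFAULT_K = 15
DEFAULT_S_MAX = 10
DEFAULT_KURTOSIS_DROP_TOL = 0.03
MASS_TRUNCATION = 1e-6


@dataclass
class PatchGraph:
    """Symmetric weighted k-NN graph over patch fingerprints."""

    adjacency: sp.csr_matrix
    k_neighbors: int = DEFAULT_K
    encoder_index: int = 0

    def __post_init__(self) -> None:
        a = sp.csr_matrix(self.adjacency)
        a.setdiag(0.0)
        a.eliminate_zeros()
        self.adjacency = a

    @property
    def n_patches(self) -> int:
        return self.adjacency.shape[0]

    def transition(self) -> sp.csr_matrix:
        """Row-stochastic walk operator: row-normalized (A + I)."""
        a = (self.adjacency + sp.identity(self.n_patches, format="csr")).tocsr()
        rowsum = np.asarray(a.sum(axis=1)).ravel()
        inv = sp.diags(1.0 / rowsum)
        return (inv @ a).tocsr()


@dataclass
class MicronicheAbundanceTensor:
    """N x P x E tensor of expected per-sample arrival fractions."""

    Q: np.ndarray
    sample_order: np.ndarray
    patch_order: np.ndarray
    encoder_order: np.ndarray
    steps: list[int] | None = None
    projected: bool = False

    @property
    def n_samples(self) -> int:
        return self.Q.shape[0]

    @property
    def n_patches(self) -> int:
        return self.Q.shape[1]

    @property
    def n_encoders(self) -> int:
        return self.Q.shape[2]


def build_graph(fingerprints: np.ndarray, k: int = DEFAULT_K,
                encoder_index: int = 0, seed: int = 0) -> PatchGraph:
    """k-NN graph with UMAP-style fuzzy-union connectivity weights.

    Uses the standard single-cell neighbors kernel (exact distances), which
    yields a symmetric, zero-diagonal, non-negative weighted adjacency.
    """
    fingerprints = np.asarray(fingerprints)
    n = fingerprints.shape[0]
    if n <= k:
        raise ValueError(f"need more than k={k} patches, got {n}")
    adata = ad.AnnData(X=fingerprints.astype(np.float32))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.neighbors(adata, n_neighbors=k, use_rep="X", random_state=seed,
                        method="umap", knn=True)
    conn = adata.obsp["connectivities"].tocsr()
    return PatchGraph(adjacency=conn, k_neighbors=k, encoder_index=encoder_index)


def _start_distribution(sample_codes: np.ndarray, n_samples: int) -> sp.csr_matrix:
    """N x P matrix: row n uniform over the patches of sample n."""
    n_patches = len(sample_codes)
    counts = np.bincount(sample_codes, minlength=n_samples).astype(float)
    if np.any(counts == 0):
        raise ValueError("every sample must contribute at least one patch")
    data = 1.0 / counts[sample_codes]
    return sp.csr_matrix(
        (data, (sample_codes, np.arange(n_patches))), shape=(n_samples, n_patches)
    )


def _median_kurtosis(q: np.ndarray) -> float:
    """Median Fisher kurtosis of each microniche's across-sample abundances,
    over columns with non-zero variance."""
    var = q.var(axis=0)
    cols = var > 0
    if not np.any(cols):
        return float("nan")
    k = kurtosis(q[:, cols], axis=0, fisher=True, bias=True)
    return float(np.median(k))


def choose_steps(graph: PatchGraph, sample_codes: np.ndarray, n_samples: int,
                 kurtosis_drop_tol: float = DEFAULT_KURTOSIS_DROP_TOL,
                 s_max: int = DEFAULT_S_MAX) -> int:
    """Adaptive walk length for one graph.

    At each step the across-sample abundance distribution of every microniche
    is summarized by its Fisher (excess) kurtosis; high kurtosis means a
    microniche is dominated by few samples. The walk stops at the first step
    where the relative decrease of the median kurtosis falls below
    ``kurtosis_drop_tol`` — further mixing no longer brings new samples into
    the microniches.
    """
    t = graph.transition()
    q = _start_distribution(sample_codes, n_samples).toarray()
    first = prev = None
    for s in range(1, s_max + 1):
        q = q @ t
        med = _median_kurtosis(np.asarray(q))
        if not np.isfinite(med):
            # no microniche retains across-sample variance: fully mixed
            return s
        if first is None:
            first = med
        elif prev is not None:
            drop = prev - med
            total = first - med
            scale = max(abs(prev), 1e-12)
            # converged once meaningful mixing has happened (the median
            # kurtosis fell from its starting level) and the per-step
            # decrease has flattened out; zero drop without prior mixing
            # (e.g. disconnected samples) is not convergence
            if drop < kurtosis_drop_tol * scale and total > kurtosis_drop_tol * max(abs(first), 1e-12):
                return s
        prev = med
    logger.warning("random walk did not converge by s_max=%d", s_max)
    return s_max


def compute_mat(graphs: list[PatchGraph], s: int | list[int],
                sample_codes: np.ndarray, sample_order: np.ndarray,
                truncate: float = MASS_TRUNCATION) -> MicronicheAbundanceTensor:
    """Assemble the MAT by iterated sparse products (never materializing T^s).

    ``s`` may be a single shared walk length or one per graph. Entries below
    ``truncate`` are zeroed and each row re-normalized, bounding the error
    while keeping the tensor effectively sparse.
    """
    n_samples = len(sample_order)
    steps = [s] * len(graphs) if np.isscalar(s) else list(s)
    if len(steps) != len(graphs):
        raise ValueError("need one step count per graph")
    u = _start_distribution(sample_codes, n_samples)
    mats = []
    for graph, s_e in zip(graphs, steps):
        if graph.n_patches != len(sample_codes):
            raise ValueError("graphs must share the patch order")
        t = graph.transition()
        q = u.toarray()
        for _ in range(int(s_e)):
            q = q @ t
        q = np.asarray(q)
        if truncate:
            q[q < truncate] = 0.0
            q /= q.sum(axis=1, keepdims=True)
        mats.append(q)
    return MicronicheAbundanceTensor(
        Q=np.stack(mats, axis=2),
        sample_order=np.asarray(sample_order),
        patch_order=np.arange(len(sample_codes)),
        encoder_order=np.array([g.encoder_index for g in graphs]),
        steps=[int(x) for x in steps],
    )


def project_covariates(mat: MicronicheAbundanceTensor,
                       covariates: np.ndarray) -> MicronicheAbundanceTensor:
    """Residualize every (patch, encoder) abundance column on the covariates.

    Each column of Q is replaced by its least-squares residual after
    regression on an intercept plus the covariates across samples. Collinear
    covariate columns are dropped with a warning.
    """
    cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov.shape[0] != mat.n_samples:
        raise ValueError("covariate rows must align with samples")
    x = np.column_stack([np.ones(mat.n_samples), cov])
    q, r, piv = _qr_drop_collinear(x)
    n, p, e = mat.Q.shape
    flat = mat.Q.reshape(n, p * e)
    resid = flat - q @ (q.T @ flat)
    return MicronicheAbundanceTensor(
        Q=resid.reshape(n, p, e),
        sample_order=mat.sample_order,
        patch_order=mat.patch_order,
        encoder_order=mat.encoder_order,
        steps=mat.steps,
        projected=True,
    )


def _qr_drop_collinear(x: np.ndarray, tol: float = 1e-10):
    """Orthonormal basis of the column space of x, dropping collinear columns."""
    q, r, piv = _pivoted_qr(x)
    diag = np.abs(np.diag(r))
    rank = int((diag > tol * max(diag[0], 1.0)).sum()) if len(diag) else 0
    if rank < x.shape[1]:
        logger.warning("dropping %d collinear covariate column(s)", x.shape[1] - rank)
    return q[:, :rank], r, piv


def _pivoted_qr(x: np.ndarray):
    from scipy.linalg import qr

    q, r, piv = qr(x, mode="economic", pivoting=True)
    return q, r, piv


def umap_layout(graph: PatchGraph, seed: int = 0) -> np.ndarray:
    """2-D layout of a (consensus) patch graph for plotting.

    Feeds the graph's connectivities directly into the standard UMAP layout
    optimizer, bypassing re-computation of neighbors.
    """
    adata = ad.AnnData(X=np.zeros((graph.n_patches, 1), dtype=np.float32))
    adata.obsp["connectivities"] = graph.adjacency.tocsr()
    adata.obsp["distances"] = graph.adjacency.tocsr()
    adata.uns["neighbors"] = {
        "connectivities_key": "connectivities",
        "distances_key": "distances",
        "params": {"n_neighbors": graph.k_neighbors, "method": "umap"},
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.tl.umap(adata, random_state=seed)
    return np.asarray(adata.obsm["X_umap"])


def build_consensus_graph(graphs: list[PatchGraph]) -> PatchGraph:
    """Mean of per-encoder connectivities; used for visualization layouts."""
    if len(graphs) < 2:
        raise ValueError("need at least two graphs for a consensus")
    acc = graphs[0].adjacency.copy().astype(float)
    for g in graphs[1:]:
        acc = acc + g.adjacency
    return PatchGraph(adjacency=(acc / len(graphs)).tocsr(),
                      k_neighbors=graphs[0].k_neighbors, encoder_index=-1)
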