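"""Core data containers shared across the pipeline stages.

The pipeline's unit of raw data is a rasterized sample: a pixel grid holding
either marker intensities (imaging modalities) or per-gene transcript counts
(transcript modalities), together with a tissue/background mask. Preprocessing
turns rasters into standardized "meta-marker" fields, from which overlapping
square patches are cut for featurization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SampleRaster",
    "MetaMarkerField",
    "PatchSet",
    "SampleMetadata",
]


@dataclass
class SampleRaster:
    """One sample's pixel grid of raw marker counts or intensities.

    Parameters
    ----------
    sample_id
        Identifier of the sample.
    values
        Array of shape ``(X, Y, M)`` with non-negative intensities/counts.
    channel_names
        Length-``M`` list of marker/gene names.
    resolution_um
        Pixel side length in micrometres (default 10).
    foreground
        Boolean ``(X, Y)`` tissue mask. ``None`` until segmentation.
    """

    sample_id: str
    values: np.ndarray
    channel_names: list[str]
    resolution_um: float = 10.0
    foreground: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-axis (X, Y, M) array")
        if self.values.shape[2] != len(self.channel_names):
            raise ValueError("channel_names length must match values' last axis")
        if np.any(self.values < 0):
            raise ValueError("raster values must be non-negative")
        if self.foreground is not None:
            self.foreground = np.asarray(self.foreground, dtype=bool)
            if self.foreground.shape != self.values.shape[:2]:
                raise ValueError("foreground shape must match spatial shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class MetaMarkerField:
    """Batch-corrected, standardized meta-marker pixel field for one sample.

    ``values`` has shape ``(X, Y, K)``; background pixels are all-zero.
    ``loadings`` is the ``M x K`` marker-to-meta-marker projection shared
    across the dataset, with columns ordered by decreasing explained variance.
    ``pixel_median_intensity`` is the dataset-wide median total pixel
    intensity ``q`` used in log-normalization.
    """

    sample_id: str
    values: np.ndarray
    foreground: np.ndarray
    loadings: np.ndarray
    pixel_median_intensity: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.foreground = np.asarray(self.foreground, dtype=bool)
        if self.foreground.shape != self.values.shape[:2]:
            raise ValueError("foreground shape must match spatial shape")


@dataclass
class PatchSet:
    """Square meta-marker patches cut from one or more fields.

    ``patches`` has shape ``(P, side, side, K)``; ``anchors`` holds the
    (x, y) pixel coordinates of each patch's origin on the stride grid;
    ``tissue_fraction`` is the fraction of in-patch pixels that are tissue.
    """

    patches: np.ndarray
    sample_ids: np.ndarray
    anchors: np.ndarray
    tissue_fraction: np.ndarray

    def __post_init__(self) -> None:
        self.patches = np.asarray(self.patches)
        self.sample_ids = np.asarray(self.sample_ids)
        self.anchors = np.asarray(self.anchors)
        self.tissue_fraction = np.asarray(self.tissue_fraction, dtype=float)
        n = len(self.patches)
        if not (len(self.sample_ids) == len(self.anchors) == len(self.tissue_fraction) == n):
            raise ValueError("patch metadata lengths disagree")

    def __len__(self) -> int:
        return len(self.patches)

    @property
    def side(self) -> int:
        return self.patches.shape[1]

    @property
    def n_channels(self) -> int:
        return self.patches.shape[3]

    def subset(self, mask: np.ndarray) -> "PatchSet":
        mask = np.asarray(mask)
        return PatchSet(
            self.patches[mask],
            self.sample_ids[mask],
            self.anchors[mask],
            self.tissue_fraction[mask],
        )


@dataclass
class SampleMetadata:
    """Sample-level metadata: donor structure, phenotype and covariates.

    ``phenotype`` is numeric (a binary phenotype is encoded 0/1).
    ``covariates``, if given, is an ``(N, n_cov)`` numeric matrix aligned to
    ``sample_ids``.
    """

    sample_ids: np.ndarray
    donor_ids: np.ndarray
    phenotype: np.ndarray
    covariates: np.ndarray | None = None
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids)
        self.donor_ids = np.asarray(self.donor_ids)
        self.phenotype = np.asarray(self.phenotype, dtype=float)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids must be unique")
        if not (len(self.sample_ids) == len(self.donor_ids) == len(self.phenotype)):
            raise ValueError("metadata column lengths disagree")
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if self.covariates.shape[0] != len(self.sample_ids):
                raise ValueError("covariate rows must align with samples")

    def __len__(self) -> int:
        return len(self.sample_ids)

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        phenotype: str = "phenotype",
        covariates: list[str] | None = None,
    ) -> "SampleMetadata":
        for col in ("sample_id", "donor_id", phenotype):
            if col not in df.columns:
                raise KeyError(f"metadata is missing required column {col!r}")
        cov = None
        cov_names: list[str] = []
        if covariates:
            missing = [c for c in covariates if c not in df.columns]
            if missing:
                raise KeyError(f"metadata is missing covariate column(s) {missing}")
            cov = df[covariates].to_numpy(dtype=float)
            cov_names = list(covariates)
        pheno = df[phenotype]
        if pheno.dtype == object or str(pheno.dtype) == "category":
            levels = sorted(pheno.unique())
            if len(levels) != 2:
                raise ValueError("non-numeric phenotype must be binary")
            pheno = (pheno == levels[1]).astype(float)
        return cls(
            sample_ids=df["sample_id"].to_numpy(),
            donor_ids=df["donor_id"].to_numpy(),
            phenotype=np.asarray(pheno, dtype=float),
            covariates=cov,
            covariate_names=cov_names,
        )

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "donor_id": self.donor_ids,
                "phenotype": self.phenotype,
            }
        )
        if self.covariates is not None:
            for j, name in enumerate(
                self.covariate_names or [f"cov{j}" for j in range(self.covariates.shape[1])]
            ):
                out[name] = self.covariates[:, j]
        return out
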