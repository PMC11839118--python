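import numpy as np
import pytest

from vima.types import PatchSet, SampleMetadata


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_patchset(n_patches: int, side: int = 16, n_channels: int = 3,
                  n_samples: int = 4, seed: int = 0,
                  tissue_fraction: float = 1.0) -> PatchSet:
    """Random standardized patches spread evenly over samples."""
    r = np.random.default_rng(seed)
    patches = r.standard_normal((n_patches, side, side, n_channels)).astype(np.float32)
    sample_ids = np.array([f"s{i % n_samples}" for i in range(n_patches)])
    anchors = np.stack([10 * np.arange(n_patches), np.zeros(n_patches, int)], axis=1)
    return PatchSet(patches=patches, sample_ids=sample_ids, anchors=anchors,
                    tissue_fraction=np.full(n_patches, tissue_fraction))


def make_metadata(n_samples: int = 4, n_donors: int | None = None,
                  seed: int = 0) -> SampleMetadata:
    r = np.random.default_rng(seed)
    n_donors = n_donors or n_samples
    donors = np.array([f"d{i % n_donors}" for i in range(n_samples)])
    donor_y = {d: float(v) for d, v in zip(np.unique(donors),
                                           r.integers(0, 2, size=n_donors))}
    return SampleMetadata(
        sample_ids=np.array([f"s{i}" for i in range(n_samples)]),
        donor_ids=donors,
        phenotype=np.array([donor_y[d] for d in donors]),
    )


@pytest.fixture
def small_patchset():
    return make_patchset(60)


@pytest.fixture
def small_metadata():
    return make_metadata(4)
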