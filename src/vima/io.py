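"""Reading and writing the pipeline's external formats.

Raw inputs: transcript tables (CSV/TSV/Parquet with sample_id, x, y, gene),
multichannel TIFFs with a channels manifest (name, role), and a sample
metadata CSV. Stage outputs are plain containers: ``.npz`` arrays with a CSV
index for patches, CSV + JSON for results. Every artifact embeds the run's
config hash and seed for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .types import PatchSet, SampleMetadata, SampleRaster

logger = logging.getLogger(__name__)

CHANNEL_ROLES = ("marker", "negative_control", "registration")


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# raw inputs
# ---------------------------------------------------------------------------

def read_transcripts(path: str | Path) -> pd.DataFrame:
    """Read a transcript table; requires sample_id, x, y, gene columns (µm)."""
    path = Path(path)
    if path.suffix == ".parquet":
        df = pd.read_parquet(path)
    elif path.suffix == ".tsv":
        df = pd.read_csv(path, sep="\t")
    else:
        df = pd.read_csv(path)
    missing = [c for c in ("sample_id", "x", "y", "gene") if c not in df.columns]
    if missing:
        raise KeyError(f"transcript table is missing required column(s) {missing}")
    return df


def read_channels_manifest(path: str | Path) -> dict[str, str]:
    """Channels manifest CSV with columns name, role."""
    df = pd.read_csv(path)
    for col in ("name", "role"):
        if col not in df.columns:
            raise KeyError(f"channels manifest is missing required column {col!r}")
    bad = set(df["role"]) - set(CHANNEL_ROLES)
    if bad:
        raise ValueError(f"unknown channel role(s) {sorted(bad)}; expected {CHANNEL_ROLES}")
    return dict(zip(df["name"], df["role"]))


def read_intensity_sample(path: str | Path, channel_names: list[str],
                          sample_id: str | None = None,
                          resolution_um: float = 10.0) -> SampleRaster:
    """Read one sample's multichannel TIFF (channel-first axes)."""
    path = Path(path)
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.shape[0] != len(channel_names):
        raise ValueError(
            f"{path.name}: {arr.shape[0]} image channels but {len(channel_names)} manifest rows"
        )
    values = np.moveaxis(arr, 0, -1).astype(np.float64)
    return SampleRaster(sample_id=sample_id or path.stem, values=values,
                        channel_names=list(channel_names),
                        resolution_um=resolution_um)


def read_metadata(path: str | Path, phenotype: str = "phenotype",
                  covariates: list[str] | None = None) -> SampleMetadata:
    return SampleMetadata.from_frame(pd.read_csv(path), phenotype=phenotype,
                                     covariates=covariates)


# ---------------------------------------------------------------------------
# dataset round-trip (used by the simulator to exercise the full I/O path)
# ---------------------------------------------------------------------------

def write_dataset(rasters: list[SampleRaster], metadata: SampleMetadata,
                  outdir: str | Path,
                  channel_roles: dict[str, str] | None = None) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for r in rasters:
        tifffile.imwrite(outdir / f"{r.sample_id}.tif",
                         np.moveaxis(r.values, -1, 0).astype(np.float32))
    names = rasters[0].channel_names
    roles = channel_roles or {}
    pd.DataFrame({"name": names,
                  "role": [roles.get(c, "marker") for c in names]}
                 ).to_csv(outdir / "channels.csv", index=False)
    metadata.to_frame().to_csv(outdir / "metadata.csv", index=False)
    return outdir


def read_dataset(indir: str | Path, phenotype: str = "phenotype",
                 covariates: list[str] | None = None,
                 resolution_um: float = 10.0
                 ) -> tuple[list[SampleRaster], SampleMetadata, dict[str, str]]:
    indir = Path(indir)
    roles = read_channels_manifest(indir / "channels.csv")
    names = list(roles)
    metadata = read_metadata(indir / "metadata.csv", phenotype=phenotype,
                             covariates=covariates)
    rasters = [
        read_intensity_sample(indir / f"{sid}.tif", names, sample_id=str(sid),
                              resolution_um=resolution_um)
        for sid in metadata.sample_ids
    ]
    return rasters, metadata, roles


# ---------------------------------------------------------------------------
# stage artifacts
# ---------------------------------------------------------------------------

def save_patchset(patchset: PatchSet, outdir: str | Path, info: dict | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(outdir / "patches.npz",
                        patches=patchset.patches.astype(np.float32),
                        sample_ids=patchset.sample_ids.astype(str),
                        anchors=patchset.anchors,
                        tissue_fraction=patchset.tissue_fraction)
    pd.DataFrame({
        "sample_id": patchset.sample_ids,
        "anchor_x": patchset.anchors[:, 0],
        "anchor_y": patchset.anchors[:, 1],
        "tissue_fraction": patchset.tissue_fraction,
    }).to_csv(outdir / "patches_index.csv", index=False)
    if info is not None:
        (outdir / "preprocess_info.json").write_text(json.dumps(info, indent=2, default=str))


def load_patchset(indir: str | Path) -> PatchSet:
    z = np.load(Path(indir) / "patches.npz", allow_pickle=False)
    return PatchSet(patches=z["patches"], sample_ids=z["sample_ids"],
                    anchors=z["anchors"], tissue_fraction=z["tissue_fraction"])


def write_results(outdir: str | Path, result, patchset: PatchSet,
                  run_config: dict, coords: np.ndarray | None = None) -> None:
    """Persist association results: patch-level CSV + JSON report.

    ``result`` is an AssociationResult; ``patchset`` must be the analysis
    patch set whose rows align with the local coefficients.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    local, global_ = result.local, result.global_
    n = len(local.rho)
    tail = np.full(n, "", dtype=object)
    sig = np.zeros(n, dtype=bool)
    tail[local.rho > 0] = "pos"
    tail[local.rho < 0] = "neg"
    sig[local.significant_pos] = True
    sig[local.significant_neg] = True
    df = pd.DataFrame({
        "sample_id": patchset.sample_ids,
        "anchor_x": patchset.anchors[:, 0],
        "anchor_y": patchset.anchors[:, 1],
        "rho": local.rho,
        "tail": tail,
        "fdr_at_call": local.qvalue,
        "significant": sig,
    })
    if coords is not None:
        df["umap_x"], df["umap_y"] = coords[:, 0], coords[:, 1]
    df.to_csv(outdir / "patch_results.csv", index=False)
    report = {
        "global_R": global_.R,
        "global_p_value": global_.p_value,
        "n_permutations": global_.n_permutations,
        "fdr_level": local.fdr_level,
        "n_significant_pos": int(len(local.significant_pos)),
        "n_significant_neg": int(len(local.significant_neg)),
        "config": run_config,
        "config_hash": config_hash(run_config),
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    local.fdr_table.to_csv(outdir / "fdr_table.csv", index=False)
    logger.info("results written to %s (global P=%.3g, R=%.4f)",
                outdir, global_.p_value, global_.R)
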