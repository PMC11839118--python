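"""Patch featurization with an ensemble of conditional variational autoencoders.

Each autoencoder learns a C-dimensional latent code from which it reconstructs
40x40 meta-marker patches. The model is conditioned on a learned 4-dimensional
per-sample embedding (a linear map of the one-hot sample id plus any supplied
covariates), injected as spatially constant channels concatenated to the
representation at every stage of both encoder and decoder. The variational
penalty then incentivizes the encoder to push sample-specific information into
those channels rather than the latent code, integrating samples in latent
space. An ensemble of E models differing only by initialization seed provides
E complementary fingerprint matrices.

The loss minimized is

    mean_pixels (p - D(z))^2  -  (beta/2) * sum_c (1 + log s2_c - mu_c^2 - s2_c)

with z ~ N(mu(p), s2(p)) via the reparameterization trick; the second term is
beta times the KL divergence from the standard-normal prior. beta is small by
default (1e-5), prioritizing reconstruction; if samples integrate poorly it
should be raised one order of magnitude at a time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import _nn
from .types import PatchSet, SampleMetadata

logger = logging.getLogger(__name__)

VARIANTS = ("resnet_cvae", "resnet_ae_no_sid", "convnet2_ae")

#: default tissue-density threshold for inclusion in downstream analysis
ALPHA_TISSUE = 0.5

_LOGVAR_CLIP = 15.0


@dataclass
class CvaeConfig:
    """Hyperparameters of one autoencoder and its training schedule."""

    latent_dim: int = 100
    beta: float = 1e-5
    cond_embed_dim: int = 4
    epochs: int = 20
    kl_warmup_epochs: int = 5
    batch_size: int = 256
    lr: float = 1e-3
    lr_decay_per_epoch: float = 0.9
    train_fraction: float = 0.8
    seed: int = 0
    variant: str = "resnet_cvae"
    stage_widths: tuple[int, ...] = (64, 128, 256)
    convnet_widths: tuple[int, int] = (256, 512)
    extend: bool = False
    extend_step: int = 5
    extend_improve_tol: float = 0.005
    max_epochs: int = 60

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")


class CvaeModel:
    """One (conditional) variational autoencoder over meta-marker patches."""

    def __init__(self, config: CvaeConfig, n_channels: int, side: int,
                 sample_order: np.ndarray, n_covariates: int = 0):
        self.config = config
        self.n_channels = n_channels
        self.side = side
        self.sample_order = np.asarray(sample_order)
        self.n_covariates = n_covariates
        self.variational = config.variant != "convnet2_ae"
        self.conditional = config.variant == "resnet_cvae"
        rng = np.random.default_rng(config.seed)

        cond_dim = config.cond_embed_dim if self.conditional else 0
        n_cond_in = len(sample_order) + n_covariates
        if config.variant == "convnet2_ae":
            if side % 4:
                raise ValueError("convnet2_ae needs a side divisible by 4")
            self.encoder = _nn.ConvNet2Encoder(
                rng, n_channels, config.convnet_widths, config.latent_dim)
            self.decoder = _nn.ConvNet2Decoder(
                rng, n_channels, config.convnet_widths, config.latent_dim, side // 4)
        else:
            n_down = len(config.stage_widths)
            if side % (2 ** n_down):
                raise ValueError("patch side must be divisible by 2^n_stages")
            self.encoder = _nn.ResEncoder(
                rng, n_channels, config.stage_widths, config.latent_dim,
                cond_dim=cond_dim, variational=True)
            self.decoder = _nn.ResDecoder(
                rng, n_channels, config.stage_widths, config.latent_dim,
                base_side=side // (2 ** n_down), cond_dim=cond_dim)
        self.enc_embed = _nn.Linear(rng, n_cond_in, cond_dim) if self.conditional else None
        self.dec_embed = _nn.Linear(rng, n_cond_in, cond_dim) if self.conditional else None
        if self.conditional:
            # start unconditional: the sample embeddings grow during training
            # only insofar as they help reconstruction, so the latent code is
            # not seeded with sample identity at initialization
            self.enc_embed.w.value[...] = 0.0
            self.dec_embed.w.value[...] = 0.0
        self.history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
        self._rng = rng

    # -- parameters ---------------------------------------------------------
    def params(self) -> list[_nn.Param]:
        out = self.encoder.params() + self.decoder.params()
        if self.conditional:
            out += self.enc_embed.params() + self.dec_embed.params()
        return out

    # -- conditioning -------------------------------------------------------
    def _cond_input(self, sample_codes: np.ndarray,
                    covariates: np.ndarray | None) -> np.ndarray:
        onehot = np.zeros((len(sample_codes), len(self.sample_order)), dtype=np.float32)
        onehot[np.arange(len(sample_codes)), sample_codes] = 1.0
        if self.n_covariates:
            cov = covariates[sample_codes].astype(np.float32)
            return np.concatenate([onehot, cov], axis=1)
        return onehot

    def sample_codes(self, sample_ids: np.ndarray) -> np.ndarray:
        index = {s: i for i, s in enumerate(self.sample_order)}
        try:
            return np.array([index[s] for s in sample_ids], dtype=np.int64)
        except KeyError as e:  # pragma: no cover - defensive
            raise KeyError(f"sample {e.args[0]!r} was not seen at training time") from e

    # -- forward passes -----------------------------------------------------
    def encode_mean(self, patches: np.ndarray, sample_codes: np.ndarray,
                    covariates: np.ndarray | None = None) -> np.ndarray:
        """Posterior mean mu(p) for a batch of patches (deterministic)."""
        cond = None
        if self.conditional:
            cond = self.enc_embed.forward(self._cond_input(sample_codes, covariates))
        h = self.encoder.forward(patches.astype(np.float32), cond)
        if self.variational:
            return h[:, : self.config.latent_dim]
        return h

    def reconstruct(self, patches: np.ndarray, sample_codes: np.ndarray,
                    covariates: np.ndarray | None = None) -> np.ndarray:
        """Deterministic reconstruction D(mu(p))."""
        cond_e = cond_d = None
        if self.conditional:
            ci = self._cond_input(sample_codes, covariates)
            cond_e = self.enc_embed.forward(ci)
            cond_d = self.dec_embed.forward(ci)
        h = self.encoder.forward(patches.astype(np.float32), cond_e)
        mu = h[:, : self.config.latent_dim] if self.variational else h
        return self.decoder.forward(mu, cond_d)

    # -- one training step --------------------------------------------------
    def _step(self, x: np.ndarray, sample_codes: np.ndarray,
              covariates: np.ndarray | None, kl_weight: float,
              opt: _nn.Adam, rng: np.random.Generator) -> float:
        b = len(x)
        c_lat = self.config.latent_dim
        npix = x[0].size

        cond_in = cond_e = cond_d = None
        if self.conditional:
            cond_in = self._cond_input(sample_codes, covariates)
            cond_e = self.enc_embed.forward(cond_in)
            cond_d = self.dec_embed.forward(cond_in)

        h = self.encoder.forward(x, cond_e)
        if self.variational:
            mu, logvar = h[:, :c_lat], np.clip(h[:, c_lat:], -_LOGVAR_CLIP, _LOGVAR_CLIP)
            eps = rng.standard_normal(mu.shape).astype(np.float32)
            std = np.exp(0.5 * logvar)
            z = mu + std * eps
        else:
            z = h
        recon = self.decoder.forward(z, cond_d)

        resid = recon - x
        recon_loss = float((resid ** 2).mean(axis=(1, 2, 3)).mean())
        if self.variational:
            var = np.exp(logvar)
            kl_core = -0.5 * (1.0 + logvar - mu ** 2 - var).sum(axis=1)
            loss = recon_loss + kl_weight * float(kl_core.mean())
        else:
            loss = recon_loss
        if not np.isfinite(loss):
            raise FloatingPointError("training loss diverged (non-finite)")

        opt.zero_grad()
        drecon = (2.0 / (npix * b)) * resid.astype(np.float32)
        dz, dwd = self.decoder.backward(drecon)
        if self.variational:
            dmu = dz + (kl_weight / b) * mu
            dlogvar = dz * eps * 0.5 * std + (kl_weight / b) * 0.5 * (var - 1.0)
            dlogvar[np.abs(h[:, c_lat:]) > _LOGVAR_CLIP] = 0.0
            dh = np.concatenate([dmu, dlogvar], axis=1)
        else:
            dh = dz
        _, dwe = self.encoder.backward(dh)
        if self.conditional:
            if dwd is not None:
                self.dec_embed.backward(dwd)
            if dwe is not None:
                self.enc_embed.backward(dwe)
        opt.step()
        return loss

    def _eval_loss(self, x: np.ndarray, sample_codes: np.ndarray,
                   covariates: np.ndarray | None, kl_weight: float) -> float:
        c_lat = self.config.latent_dim
        cond_e = cond_d = None
        if self.conditional:
            ci = self._cond_input(sample_codes, covariates)
            cond_e = self.enc_embed.forward(ci)
            cond_d = self.dec_embed.forward(ci)
        h = self.encoder.forward(x.astype(np.float32), cond_e)
        if self.variational:
            mu, logvar = h[:, :c_lat], np.clip(h[:, c_lat:], -_LOGVAR_CLIP, _LOGVAR_CLIP)
            recon = self.decoder.forward(mu, cond_d)
            kl = -0.5 * (1.0 + logvar - mu ** 2 - np.exp(logvar)).sum(axis=1).mean()
        else:
            recon = self.decoder.forward(h, cond_d)
            kl = 0.0
        mse = float(((recon - x) ** 2).mean(axis=(1, 2, 3)).mean())
        return mse + kl_weight * float(kl)


def build_model(config: CvaeConfig, n_channels: int, n_samples: int,
                sample_order: np.ndarray | None = None,
                n_covariates: int = 0, side: int = 40) -> CvaeModel:
    """Instantiate an autoencoder for ``side x side x n_channels`` patches."""
    if sample_order is None:
        sample_order = np.arange(n_samples)
    return CvaeModel(config, n_channels, side, sample_order, n_covariates)


def kl_weight_at_epoch(epoch: int, beta: float, warmup_epochs: int) -> float:
    """Linear KL warm-up: weight ramps 0 -> beta over the first warm-up epochs.

    ``epoch`` is 1-indexed; at ``epoch == warmup_epochs`` the weight is beta.
    """
    if warmup_epochs <= 0:
        return beta
    return beta * min(1.0, epoch / warmup_epochs)


def cvae_loss(patch: np.ndarray, reconstruction: np.ndarray, mu: np.ndarray,
              log_var: np.ndarray, beta: float) -> float:
    """Total loss for a single patch (or batch, averaged).

    Reconstruction error is the per-pixel-per-channel mean squared error; the
    variational term is ``-(beta/2) * sum_c (1 + log_var - mu^2 - exp(log_var))``,
    i.e. beta times the KL divergence from N(0, I).
    """
    patch = np.asarray(patch, dtype=np.float64)
    reconstruction = np.asarray(reconstruction, dtype=np.float64)
    mu = np.atleast_2d(np.asarray(mu, dtype=np.float64))
    log_var = np.atleast_2d(np.asarray(log_var, dtype=np.float64))
    if patch.shape != reconstruction.shape:
        raise ValueError("patch and reconstruction shapes disagree")
    if not (np.all(np.isfinite(patch)) and np.all(np.isfinite(reconstruction))
            and np.all(np.isfinite(mu)) and np.all(np.isfinite(log_var))):
        raise FloatingPointError("non-finite inputs to loss")
    if patch.ndim == 3:
        patch = patch[None]
        reconstruction = reconstruction[None]
    mse = ((patch - reconstruction) ** 2).mean(axis=(1, 2, 3))
    kl = -0.5 * (1.0 + log_var - mu ** 2 - np.exp(log_var)).sum(axis=1)
    return float((mse + beta * kl).mean())


@dataclass
class CvaeEnsemble:
    """E trained models sharing architecture, differing by seed."""

    models: list[CvaeModel]
    config: CvaeConfig
    sample_order: np.ndarray
    covariates: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.models)

    def encode_all(self, patchset: PatchSet, batch_size: int = 512) -> list[np.ndarray]:
        return [encode(m, patchset, covariates=self.covariates, batch_size=batch_size)
                for m in self.models]


@dataclass
class FingerprintEnsemble:
    """E fingerprint matrices (P x C), row-aligned with one PatchSet."""

    matrices: list[np.ndarray]
    metadata: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.matrices) < 1:
            raise ValueError("need at least one fingerprint matrix")
        p0 = self.matrices[0].shape[0]
        if any(m.shape[0] != p0 for m in self.matrices):
            raise ValueError("fingerprint matrices must share row order/count")


def train_model(patchset: PatchSet, metadata: SampleMetadata,
                config: CvaeConfig) -> CvaeModel:
    """Train a single autoencoder with the configured schedule.

    The patch set is split by patch into training (``train_fraction``) and
    validation parts; the KL weight ramps linearly to beta over the warm-up
    epochs and the learning rate decays by ``lr_decay_per_epoch`` each epoch.
    If ``extend`` is set, training continues in ``extend_step``-epoch
    increments while validation loss keeps improving faster than
    ``extend_improve_tol`` per epoch (up to ``max_epochs``).
    """
    if len(patchset) == 0:
        raise ValueError("empty patch set")
    n_cov = 0 if metadata.covariates is None else metadata.covariates.shape[1]
    model = build_model(config, patchset.n_channels, len(metadata),
                        sample_order=metadata.sample_ids, n_covariates=n_cov,
                        side=patchset.side)
    codes = model.sample_codes(patchset.sample_ids)
    cov = metadata.covariates

    rng = np.random.default_rng(config.seed)
    n = len(patchset)
    perm = rng.permutation(n)
    n_train = max(1, int(round(config.train_fraction * n)))
    train_ix, val_ix = perm[:n_train], perm[n_train:]
    x = patchset.patches.astype(np.float32)

    opt = _nn.Adam(model.params(), lr=config.lr)
    epoch = 0
    budget = config.epochs
    while epoch < budget:
        epoch += 1
        opt.lr = config.lr * config.lr_decay_per_epoch ** (epoch - 1)
        klw = kl_weight_at_epoch(epoch, config.beta, config.kl_warmup_epochs)
        order = rng.permutation(train_ix)
        losses = []
        for start in range(0, len(order), config.batch_size):
            ix = order[start : start + config.batch_size]
            losses.append(model._step(x[ix], codes[ix], cov, klw, opt, rng))
        val = (model._eval_loss(x[val_ix], codes[val_ix], cov, config.beta)
               if len(val_ix) else float("nan"))
        model.history["train_loss"].append(float(np.mean(losses)))
        model.history["val_loss"].append(val)
        logger.debug("seed=%d epoch=%d train=%.4f val=%.4f",
                     config.seed, epoch, model.history["train_loss"][-1], val)
        if config.extend and epoch == budget and budget < config.max_epochs and len(val_ix):
            vals = model.history["val_loss"]
            window = min(config.extend_step, len(vals) - 1)
            if window >= 1 and vals[-1 - window] > 0:
                rate = (vals[-1 - window] - vals[-1]) / (vals[-1 - window] * window)
                if rate > config.extend_improve_tol:
                    budget = min(config.max_epochs, budget + config.extend_step)
    return model


def train_ensemble(patchset: PatchSet, metadata: SampleMetadata,
                   config: CvaeConfig, n_models: int = 10) -> CvaeEnsemble:
    """Train E models with identical architecture and different seeds."""
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    models = []
    for e in range(n_models):
        cfg = replace(config, seed=config.seed + e)
        models.append(train_model(patchset, metadata, cfg))
        logger.info("trained model %d/%d (seed %d)", e + 1, n_models, cfg.seed)
    return CvaeEnsemble(models=models, config=config,
                        sample_order=metadata.sample_ids,
                        covariates=metadata.covariates)


def encode(model: CvaeModel, patchset: PatchSet,
           covariates: np.ndarray | None = None,
           batch_size: int = 512) -> np.ndarray:
    """Fingerprint matrix: posterior mean mu(p) for every patch, row-aligned."""
    if patchset.n_channels != model.n_channels:
        raise ValueError(
            f"patch channels ({patchset.n_channels}) != model channels ({model.n_channels})"
        )
    codes = model.sample_codes(patchset.sample_ids)
    x = patchset.patches.astype(np.float32)
    chunks = []
    for start in range(0, len(x), batch_size):
        sl = slice(start, start + batch_size)
        chunks.append(model.encode_mean(x[sl], codes[sl], covariates))
    return np.concatenate(chunks, axis=0)


def save_model(model: CvaeModel, outdir) -> None:
    """Checkpoint one encoder: parameters, config JSON, training curve CSV."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = {f"p{i:04d}": p.value for i, p in enumerate(model.params())}
    np.savez_compressed(outdir / "params.npz", **params)
    meta = {
        "config": asdict(model.config),
        "n_channels": model.n_channels,
        "side": model.side,
        "n_covariates": model.n_covariates,
        "sample_order": [str(s) for s in model.sample_order],
        "seed": model.config.seed,
    }
    (outdir / "config.json").write_text(json.dumps(meta, indent=2, default=str))
    pd.DataFrame(model.history).to_csv(outdir / "training_curve.csv", index=False)


def load_model(indir) -> CvaeModel:
    import json
    from pathlib import Path

    indir = Path(indir)
    meta = json.loads((indir / "config.json").read_text())
    cfg = meta["config"]
    for key in ("stage_widths", "convnet_widths"):
        cfg[key] = tuple(cfg[key])
    config = CvaeConfig(**cfg)
    model = CvaeModel(config, meta["n_channels"], meta["side"],
                      np.array(meta["sample_order"]), meta["n_covariates"])
    z = np.load(indir / "params.npz")
    for i, p in enumerate(model.params()):
        p.value[...] = z[f"p{i:04d}"]
    return model


def analysis_mask(patchset: PatchSet, alpha: float = ALPHA_TISSUE) -> np.ndarray:
    """Patches dense enough (tissue fraction > alpha) for association analysis."""
    return patchset.tissue_fraction > alpha


def reconstruction_metrics(model: CvaeModel, patchset: PatchSet,
                           covariates: np.ndarray | None = None,
                           batch_size: int = 512) -> dict[str, float]:
    """Reconstruction MSE against two analytic baselines.

    ``dataset_mean_mse`` is the error of always predicting the per-channel
    mean over all in-patch pixels (exactly 1.0 when the meta-markers satisfy
    the standardization contract); ``patch_mean_mse`` predicts each patch's
    own per-channel mean everywhere, a strictly easier baseline.
    """
    x = patchset.patches.astype(np.float64)
    codes = model.sample_codes(patchset.sample_ids)
    sq = 0.0
    n = 0
    for start in range(0, len(x), batch_size):
        sl = slice(start, start + batch_size)
        recon = model.reconstruct(x[sl].astype(np.float32), codes[sl], covariates)
        sq += float(((recon - x[sl]) ** 2).sum())
        n += x[sl].size
    ds_mean = x.mean(axis=(0, 1, 2))
    dataset_mean_mse = float(((x - ds_mean) ** 2).mean())
    patch_mean = x.mean(axis=(1, 2), keepdims=True)
    patch_mean_mse = float(((x - patch_mean) ** 2).mean())
    return {
        "model_mse": sq / n,
        "dataset_mean_mse": dataset_mean_mse,
        "patch_mean_mse": patch_mean_mse,
    }
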