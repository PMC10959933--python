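"""Conditional variational autoencoder for postoperative B-scan prediction.

The generator maps a preoperative 224 x 224 B-scan plus a one-hot condition
vector (the slice's distance band from the fovea) to a predicted 6-month
postoperative B-scan.  Architecture:

* encoder — four 3x3/stride-1/pad-1 convolution blocks with channel doubling
  (C, 2C, 4C, 8C), each followed by batch normalisation, leaky-ReLU, dropout
  and 2x2 max pooling (224 -> 14 spatially), then a five-layer fully
  connected stack whose first layer takes the flattened features
  concatenated with the condition vector and whose final layer is the
  parallel pair of heads emitting the mean and log-variance vectors;
* sampler — the reparameterisation trick, z = mu + exp(logvar/2) * eps;
* decoder — the mirror image: five fully connected layers on [z, condition],
  then four convolution blocks each preceded by nearest-neighbour 2x
  unpooling, ending in a sigmoid output layer;
* loss — binary cross-entropy plus a multiscale structural-similarity
  (MS-SSIM) term for the first ``recon_switch_epoch`` epochs, switching to a
  perceptual feature distance afterwards, plus the Kullback-Leibler
  divergence against the standard-normal prior whose weight beta ramps
  linearly from 0 to 1 over the warm-up epochs.

The perceptual term is a fixed, seeded random-convolution feature distance:
deterministic, self-contained, and requiring no pretrained weights.
Inference is deterministic (z = mu, evaluation mode).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "VAEConfig",
    "VAEState",
    "CVAE",
    "sample",
    "kld",
    "beta_schedule",
    "bce_loss",
    "ms_ssim",
    "PerceptualLoss",
    "vae_loss",
    "train",
    "predict",
]

#: standard five-scale MS-SSIM weights
MSSSIM_WEIGHTS = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)


@dataclass
class VAEConfig:
    """Hyperparameters; the defaults target the full 224-pixel problem and
    smoke runs shrink ``image_size``/``base_channels``/``latent_dim``."""

    image_size: int = 224
    base_channels: int = 32
    conv_layers: int = 4
    fcn_layers: int = 5
    latent_dim: int = 256
    n_conditions: int = 4
    dropout: float = 0.1
    leaky_slope: float = 0.2
    learning_rate: float = 1e-4
    batch_size: int = 16
    max_epochs: int = 600
    recon_switch_epoch: int = 400
    kld_warmup_epochs: int = 50
    ms_ssim_weight: float = 1.0
    perceptual_weight: float = 1.0
    keep_bce_after_switch: bool = False
    patience: int = 30
    grad_clip: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.recon_switch_epoch > self.max_epochs:
            raise ValueError("recon_switch_epoch must be <= max_epochs")
        if self.image_size % (2**self.conv_layers) != 0:
            raise ValueError("image_size must be divisible by 2^conv_layers")

    @property
    def reduced_size(self) -> int:
        """Spatial size after the encoder's pooling stages (224 -> 14)."""
        return self.image_size // (2**self.conv_layers)

    @property
    def flat_dim(self) -> int:
        return self.base_channels * (2 ** (self.conv_layers - 1)) * self.reduced_size**2


@dataclass
class VAEState:
    """A trained (or training) model: weights, history, best epoch."""

    config: VAEConfig
    weights: list
    bn_stats: list
    history: list = field(default_factory=list)
    best_epoch: int = -1
    trained: bool = False

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = {f"w{i}": a for i, a in enumerate(self.weights)}
        arrays.update({f"bn{i}": a for i, a in enumerate(self.bn_stats)})
        np.savez(path.with_suffix(".npz"), **arrays)
        meta = {
            "config": asdict(self.config),
            "history": self.history,
            "best_epoch": self.best_epoch,
            "trained": self.trained,
            "n_weights": len(self.weights),
            "n_bn": len(self.bn_stats),
        }
        path.with_suffix(".json").write_text(json.dumps(meta))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "VAEState":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        data = np.load(path.with_suffix(".npz"))
        return cls(
            config=VAEConfig(**meta["config"]),
            weights=[data[f"w{i}"] for i in range(meta["n_weights"])],
            bn_stats=[data[f"bn{i}"] for i in range(meta["n_bn"])],
            history=meta["history"],
            best_epoch=meta["best_epoch"],
            trained=meta["trained"],
        )


# --------------------------------------------------------------------- model

class CVAE(nn.Module):
    def __init__(self, config: VAEConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self._dropout_rng = np.random.default_rng(config.seed + 1)
        c, d, nc = config.base_channels, config.latent_dim, config.n_conditions

        chans = [1] + [c * 2**i for i in range(config.conv_layers)]
        self.enc_convs = [nn.Conv2d(chans[i], chans[i + 1], rng) for i in range(config.conv_layers)]
        self.enc_bns = [nn.BatchNorm2d(chans[i + 1]) for i in range(config.conv_layers)]
        self.enc_drops = [nn.Dropout(config.dropout, self._dropout_rng) for _ in range(config.conv_layers)]

        flat = config.flat_dim
        h = [4 * d, 2 * d, 2 * d]
        self.enc_fcs = [
            nn.Linear(flat + nc, h[0], rng),
            nn.Linear(h[0], h[1], rng),
            nn.Linear(h[1], h[2], rng),
        ]
        self.fc_mu = nn.Linear(h[2], d, rng)
        self.fc_logvar = nn.Linear(h[2], d, rng)

        self.dec_fcs = [
            nn.Linear(d + nc, 2 * d, rng),
            nn.Linear(2 * d, 2 * d, rng),
            nn.Linear(2 * d, 4 * d, rng),
            nn.Linear(4 * d, 4 * d, rng),
            nn.Linear(4 * d, flat, rng),
        ]
        dec_chans = chans[::-1]  # [8C, 4C, 2C, C, 1]
        self.dec_convs = [
            nn.Conv2d(dec_chans[i], dec_chans[i + 1], rng) for i in range(config.conv_layers)
        ]
        self.dec_bns = [nn.BatchNorm2d(dec_chans[i + 1]) for i in range(config.conv_layers - 1)]

    # state incl. batch-norm running statistics (needed for eval determinism)
    def get_state(self) -> tuple[list, list]:
        bn = []
        for m in self.modules():
            if isinstance(m, nn._BatchNorm):
                bn.append(m.running_mean.copy())
                bn.append(m.running_var.copy())
        return self.state_arrays(), bn

    def set_state(self, weights, bn_stats) -> None:
        self.load_arrays(weights)
        bns = [m for m in self.modules() if isinstance(m, nn._BatchNorm)]
        if len(bn_stats) != 2 * len(bns):
            raise ValueError("batch-norm statistics count mismatch")
        for i, m in enumerate(bns):
            m.running_mean = bn_stats[2 * i].copy()
            m.running_var = bn_stats[2 * i + 1].copy()

    def encode(self, x: Tensor, cond: Tensor) -> tuple[Tensor, Tensor]:
        """Image + one-hot condition -> (mu, logvar), each (N, latent_dim)."""
        if x.shape[-1] != self.config.image_size:
            raise ValueError(
                f"expected {self.config.image_size}-pixel input, got {x.shape[-1]}"
            )
        h = x
        for conv, bn, drop in zip(self.enc_convs, self.enc_bns, self.enc_drops):
            h = nn.maxpool2d(drop(bn(conv(h)).leaky_relu(self.config.leaky_slope)))
        h = h.reshape(h.shape[0], -1)
        h = nn.concat([h, cond], axis=1)
        for fc in self.enc_fcs:
            h = fc(h).leaky_relu(self.config.leaky_slope)
        # clamp the log-variance so exp() cannot overflow early in training
        return self.fc_mu(h), self.fc_logvar(h).clamp(-8.0, 8.0)

    def decode(self, z: Tensor, cond: Tensor) -> Tensor:
        """Latent + condition -> image in (0, 1), sigmoid output."""
        h = nn.concat([z, cond], axis=1)
        for fc in self.dec_fcs:
            h = fc(h).leaky_relu(self.config.leaky_slope)
        s = self.config.reduced_size
        h = h.reshape(h.shape[0], -1, s, s)
        for i, conv in enumerate(self.dec_convs):
            h = conv(nn.upsample_nearest2(h))
            if i < len(self.dec_convs) - 1:
                h = self.dec_bns[i](h).leaky_relu(self.config.leaky_slope)
        return h.sigmoid()

    def forward(self, x: Tensor, cond: Tensor, rng: np.random.Generator) -> tuple[Tensor, Tensor, Tensor]:
        mu, logvar = self.encode(x, cond)
        eps = rng.standard_normal(mu.shape)
        z = mu + (logvar * 0.5).exp() * Tensor(eps)
        return self.decode(z, cond), mu, logvar


# ------------------------------------------------------------------- sampler

def sample(mu: np.ndarray, logvar: np.ndarray, seed: int = 0) -> np.ndarray:
    """Reparameterised draw z = mu + exp(logvar/2) * eps, eps ~ N(0, I)."""
    mu = np.asarray(mu, dtype=float)
    logvar = np.asarray(logvar, dtype=float)
    eps = np.random.default_rng(seed).standard_normal(mu.shape)
    return mu + np.exp(logvar / 2.0) * eps


# --------------------------------------------------------------------- losses

def kld(mu, logvar) -> Tensor:
    """KL divergence of N(mu, diag exp(logvar)) from N(0, I).

    For batched inputs the divergence is summed over latent dimensions and
    averaged over the batch: -1/2 sum_i (1 + logvar_i - mu_i^2 - exp(logvar_i)).
    """
    mu = mu if isinstance(mu, Tensor) else Tensor(mu)
    logvar = logvar if isinstance(logvar, Tensor) else Tensor(logvar)
    per = (1.0 + logvar - mu * mu - logvar.exp()) * (-0.5)
    if per.data.ndim == 1:
        return per.sum()
    return per.sum(axis=1).mean()


def bce_loss(xhat: Tensor, x: Tensor, eps: float = 1e-7) -> Tensor:
    """Mean binary cross-entropy between a predicted and target image."""
    for name, t in (("prediction", xhat), ("target", x)):
        if t.data.min() < 0 or t.data.max() > 1:
            raise ValueError(f"{name} must lie in [0, 1] for binary cross-entropy")
    return -(x * (xhat + eps).log() + (1.0 - x) * (1.0 - xhat + eps).log()).mean()


def ms_ssim(
    x: Tensor,
    y: Tensor,
    win: int = 11,
    sigma: float = 1.5,
    max_levels: int = 5,
) -> Tensor:
    """Differentiable multiscale structural similarity for (N, 1, H, W) images.

    Standard 5-scale definition with the canonical scale weights and an
    11-pixel Gaussian window; images too small for five dyadic scales use as
    many scales as fit (weights renormalised), so the loss stays defined for
    reduced test resolutions.  Data range is 1.
    """
    c1, c2 = 0.01**2, 0.03**2
    g1d = np.exp(-0.5 * ((np.arange(win) - (win - 1) / 2.0) / sigma) ** 2)
    g1d /= g1d.sum()
    size = min(x.shape[-2], x.shape[-1])
    levels = 1
    while levels < max_levels and size // 2 ** (levels) >= win:
        levels += 1
    weights = np.array(MSSSIM_WEIGHTS[:levels])
    weights = weights / weights.sum()

    def blur(t: Tensor) -> Tensor:
        return nn.gauss_blur_valid(t, g1d)

    total = None
    for lv in range(levels):
        mx, my = blur(x), blur(y)
        mxx, myy, mxy = blur(x * x), blur(y * y), blur(x * y)
        sx = mxx - mx * mx
        sy = myy - my * my
        sxy = mxy - mx * my
        cs = ((2.0 * sxy + c2) / (sx + sy + c2)).mean()
        if lv == levels - 1:
            lum = ((2.0 * mx * my + c1) / (mx * mx + my * my + c1)).mean()
            term = (lum * cs).clamp_min(1e-4).pow(float(weights[lv]))
        else:
            term = cs.clamp_min(1e-4).pow(float(weights[lv]))
        total = term if total is None else total * term
        if lv < levels - 1:
            x, y = nn.avgpool2d(x), nn.avgpool2d(y)
    return total


class PerceptualLoss:
    """Fixed seeded random-convolution feature distance.

    Three convolution stages with frozen Gaussian-random kernels (channel
    widths 8/16/16, leaky-ReLU, 2x average pooling) define a deterministic
    multi-layer feature space; the loss is the mean squared feature
    difference summed over stages.  No pretrained weights are involved.
    """

    def __init__(self, seed: int = 7, channels=(8, 16, 16)):
        rng = np.random.default_rng(seed)
        chans = [1] + list(channels)
        self.kernels = [
            Tensor(rng.normal(0.0, np.sqrt(2.0 / (chans[i] * 9)), size=(chans[i + 1], chans[i], 3, 3)))
            for i in range(len(channels))
        ]

    def features(self, x: Tensor) -> list[Tensor]:
        feats = []
        h = x
        for k in self.kernels:
            h = nn.conv2d(h, k, None, pad=1).leaky_relu(0.2)
            feats.append(h)
            h = nn.avgpool2d(h)
        return feats

    def __call__(self, x: Tensor, y: Tensor) -> Tensor:
        total = None
        for fx, fy in zip(self.features(x), self.features(y)):
            d = ((fx - fy) * (fx - fy)).mean()
            total = d if total is None else total + d
        return total


def beta_schedule(epoch: int, warmup_epochs: int) -> float:
    """KLD weight: linear 0 -> 1 over the warm-up, then 1."""
    if warmup_epochs <= 0:
        return 1.0
    return float(min(1.0, epoch / warmup_epochs))


def vae_loss(
    xhat: Tensor,
    x: Tensor,
    mu: Tensor,
    logvar: Tensor,
    epoch: int,
    config: VAEConfig,
    perceptual: PerceptualLoss | None = None,
) -> tuple[Tensor, dict]:
    """Epoch-dependent total loss and its scalar components.

    Up to ``recon_switch_epoch`` the reconstruction term is
    BCE + ms_ssim_weight * (1 - MS-SSIM); afterwards it is
    perceptual_weight * perceptual distance (BCE optionally retained).  The
    KLD term is weighted by the warm-up schedule beta(epoch).
    """
    beta = beta_schedule(epoch, config.kld_warmup_epochs)
    k = kld(mu, logvar)
    components = {"beta": beta, "kld": k.item()}
    if epoch <= config.recon_switch_epoch:
        bce = bce_loss(xhat, x)
        ssim_term = 1.0 - ms_ssim(xhat, x)
        recon = bce + config.ms_ssim_weight * ssim_term
        components.update(
            {"family": "bce+msssim", "bce": bce.item(), "one_minus_msssim": ssim_term.item()}
        )
    else:
        if perceptual is None:
            perceptual = PerceptualLoss()
        recon = config.perceptual_weight * perceptual(xhat, x)
        components["family"] = "perceptual"
        components["perceptual"] = recon.item()
        if config.keep_bce_after_switch:
            bce = bce_loss(xhat, x)
            recon = recon + bce
            components["bce"] = bce.item()
    total = recon + beta * k
    components["recon"] = recon.item()
    components["total"] = total.item()
    return total, components


# -------------------------------------------------------------------- training

def _clip_gradients(model: CVAE, max_norm: float) -> None:
    if max_norm <= 0:
        return
    total = 0.0
    grads = [p.grad for p in model.parameters() if p.grad is not None]
    for g in grads:
        total += float(np.sum(g * g))
    norm = np.sqrt(total)
    if norm > max_norm:
        scale = max_norm / norm
        for g in grads:
            g *= scale


def _one_hot(cond: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros((len(cond), n))
    out[np.arange(len(cond)), cond] = 1.0
    return out


def train(
    train_data: tuple,
    val_data: tuple,
    config: VAEConfig,
    samples_per_epoch: int | None = None,
) -> VAEState:
    """Train the conditional VAE with weighted sampling and early stopping.

    ``train_data`` is ``(pre, post, condition, weight)`` with image arrays of
    shape (N, H, W) in [0, 1]; ``val_data`` is the same without weights
    (``(pre, post, condition)``).  Each epoch draws ``samples_per_epoch``
    pairs (default: the training-set size) with probability proportional to
    the sampling weights, so conditions are drawn uniformly despite the
    43/42/43/72 imbalance.

    Per-epoch history records (train_loss, val_loss, beta); training stops
    at ``max_epochs`` or when the validation loss has not improved for
    ``patience`` epochs, and the returned state carries the weights of the
    epoch with the smallest validation loss.  The training objective uses
    the warm-up weight beta(epoch); the validation loss is evaluated at
    beta = 1 so that warm-up epochs remain comparable when selecting the
    best epoch.
    """
    pre, post, cond, weight = train_data
    if len(pre) == 0:
        raise ValueError("empty training dataset")
    vpre, vpost, vcond = val_data[:3]
    if weight is None:
        weight = np.ones(len(pre))
    prob = np.asarray(weight, dtype=float)
    prob = prob / prob.sum()

    model = CVAE(config)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    perceptual = PerceptualLoss(seed=config.seed + 101)
    sampler_rng = np.random.default_rng(config.seed + 2)
    latent_rng = np.random.default_rng(config.seed + 3)

    n_draw = samples_per_epoch or len(pre)
    cond_1h = _one_hot(np.asarray(cond, dtype=int), config.n_conditions)
    vcond_1h = _one_hot(np.asarray(vcond, dtype=int), config.n_conditions)

    history = []
    best_val = np.inf
    best_epoch = -1
    best_state = None
    stale = 0

    for epoch in range(config.max_epochs):
        model.train()
        order = sampler_rng.choice(len(pre), size=n_draw, replace=True, p=prob)
        epoch_losses = []
        for start in range(0, n_draw, config.batch_size):
            idx = order[start : start + config.batch_size]
            if len(idx) < 2:
                continue  # batch statistics need at least two samples
            x = Tensor(pre[idx][:, None])
            y = Tensor(post[idx][:, None])
            c = Tensor(cond_1h[idx])
            xhat, mu, logvar = model.forward(x, c, latent_rng)
            loss, _ = vae_loss(xhat, y, mu, logvar, epoch, config, perceptual)
            opt.zero_grad()
            loss.backward()
            _clip_gradients(model, config.grad_clip)
            opt.step()
            epoch_losses.append(loss.item())

        model.eval()
        val_losses = []
        for start in range(0, len(vpre), config.batch_size):
            sl = slice(start, start + config.batch_size)
            x = Tensor(vpre[sl][:, None])
            y = Tensor(vpost[sl][:, None])
            c = Tensor(vcond_1h[sl])
            mu, logvar = model.encode(x, c)
            xhat = model.decode(mu, c)  # deterministic validation pass
            _, comps = vae_loss(xhat, y, mu, logvar, epoch, config, perceptual)
            # validation loss at full regularisation weight (beta = 1) so
            # warm-up epochs stay comparable for best-epoch selection
            val_losses.append((comps["recon"] + comps["kld"], len(vpre[sl])))
        val_loss = float(
            sum(l * n for l, n in val_losses) / max(sum(n for _, n in val_losses), 1)
        )
        history.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(epoch_losses)) if epoch_losses else np.nan,
                "val_loss": val_loss,
                "beta": beta_schedule(epoch, config.kld_warmup_epochs),
            }
        )
        if val_loss < best_val:
            best_val = val_loss
            best_epoch = epoch
            best_state = model.get_state()
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break

    weights, bn = best_state if best_state is not None else model.get_state()
    return VAEState(
        config=config,
        weights=weights,
        bn_stats=bn,
        history=history,
        best_epoch=best_epoch,
        trained=True,
    )


def predict(pre_image: np.ndarray, condition: int, state: VAEState) -> np.ndarray:
    """Deterministic inference: z = mu, evaluation mode; returns [0, 1] image."""
    if not state.trained:
        raise ValueError("cannot predict from an untrained state")
    return _predict_with(pre_image, condition, state)


def _predict_with(pre_image: np.ndarray, condition: int, state: VAEState) -> np.ndarray:
    model = CVAE(state.config)
    model.set_state(state.weights, state.bn_stats)
    model.eval()
    x = Tensor(np.asarray(pre_image, dtype=float)[None, None])
    c = Tensor(_one_hot(np.array([condition]), state.config.n_conditions))
    mu, _ = model.encode(x, c)
    out = model.decode(mu, c)
    return out.data[0, 0]


def untrained_state(config: VAEConfig) -> VAEState:
    """Freshly initialised weights, marked trained for baseline comparisons."""
    model = CVAE(config)
    w, bn = model.get_state()
    return VAEState(config=config, weights=w, bn_stats=bn, history=[], best_epoch=-1, trained=True)
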