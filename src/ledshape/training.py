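"""Loss assembly and training loops for LED and vanilla VAE/LSGAN/WGAN flavours.

The local-eigenprojection (LE) terms are gradient-routed: in the VAE the
encoder term ``eta1 * LE(X, mu)`` reaches only the encoder (its other argument
is data) and the generator term ``eta2 * LE(X', mu)`` reaches only the
generator (the latent feeding the decoder and the ``mu`` target are both
detached).  Setting the LE weights to zero reproduces the vanilla training
step exactly, which the tests assert.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict

import numpy as np
import scipy.sparse as sp

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .mesh import ShapePopulation, TemplateStats
from .networks import (ArchitectureConfig, Critic, Discriminator, Encoder,
                       Generator, MeshHierarchy)
from .spectral import SpectralBasis

__all__ = ["TrainConfig", "reconstruction_loss", "kl_loss", "laplacian_loss",
           "le_loss_t", "vae_step", "lsgan_step", "wgan_step", "Trainer",
           "save_checkpoint", "load_checkpoint"]


@dataclass
class TrainConfig:
    """Training hyper-parameters; LE weights zero = vanilla flavour."""

    flavour: str = "vae"            # vae | lsgan | wgan
    alpha: float = 1.0              # Laplacian smoothing weight
    beta: float = 1e-3              # KL weight (linear warm-up)
    eta1: float = 0.5               # encoder LE weight (VAE)
    eta2: float = 0.5               # generator LE weight (VAE)
    eta: float = 0.5                # generator LE weight (GANs)
    clip: float = 0.01              # WGAN critic weight clipping bound
    n_critic: int = 5
    batch_size: int = 32
    epochs: int = 20
    lr: float = 1e-3
    kl_warmup_epochs: int = 5
    sigma_sample: float = 1.0       # truncation-trick sampling std
    seed: int = 0

    def __post_init__(self) -> None:
        if self.flavour not in ("vae", "lsgan", "wgan"):
            raise ValueError(f"unknown flavour {self.flavour!r}")
        for name in ("alpha", "beta", "eta1", "eta2", "eta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.flavour == "wgan" and self.clip <= 0:
            raise ValueError("wgan clipping bound must be > 0")

    @property
    def led(self) -> bool:
        if self.flavour == "vae":
            return self.eta1 > 0 or self.eta2 > 0
        return self.eta > 0


# --------------------------------------------------------------------------
# differentiable losses
# --------------------------------------------------------------------------

def reconstruction_loss(X: Tensor | np.ndarray, Xp: Tensor) -> Tensor:
    """Mean over the batch of ``||X' - X||_F^2 / N``."""
    X = ad.Tensor._wrap(X)
    if X.data.shape != Xp.data.shape:
        raise ValueError("shape mismatch")
    n = X.data.shape[-2]
    batch = 1 if X.data.ndim == 2 else X.data.shape[0]
    d = Xp - X
    return ad.sum_(d * d) * (1.0 / (batch * n))


def kl_loss(mu: Tensor, sigma: Tensor) -> Tensor:
    """Gaussian-prior divergence ``sigma^2 + mu^2 - log(sigma) - 1``, mean-reduced."""
    if (sigma.data <= 0).any():
        raise ValueError("sigma must be positive")
    return ad.mean(sigma * sigma + mu * mu - ad.log(sigma) - 1.0)


def laplacian_loss(Xp: Tensor, T: sp.spmatrix) -> Tensor:
    """Smoothness penalty: mean over the batch of ``||T X'||_F^2 / N``."""
    y = ad.sparse_matmul(T, Xp)
    n = Xp.data.shape[-2]
    batch = 1 if Xp.data.ndim == 2 else Xp.data.shape[0]
    return ad.sum_(y * y) * (1.0 / (batch * n))


def le_loss_t(X_std: Tensor | np.ndarray, z: Tensor, basis: SpectralBasis,
              stats: TemplateStats) -> Tensor:
    """Differentiable LE loss on standardized vertices: mean |z - z*(X)|.

    Matches ``spectral.le_loss`` in value; gradients flow into both arguments
    unless the caller detaches one.
    """
    X_std = ad.Tensor._wrap(X_std)
    sd = ad.signed_distance_op(X_std, stats.std, stats.normals)   # (B, N)
    batch = sd.data.shape[0]
    total = None
    for w in range(basis.n_attributes):
        p = ad.matmul(ad.take_columns(sd, basis.attribute_vertices[w]),
                      Tensor(basis.modes[w]))
        zo = (p - basis.mean[w]) * (1.0 / basis.std[w])
        resid = ad.absolute(z[:, basis.block(w)] - zo)
        s = ad.sum_(resid)
        total = s if total is None else total + s
    return total * (1.0 / (batch * basis.latent_size))


# --------------------------------------------------------------------------
# training steps
# --------------------------------------------------------------------------

def _finite_or_raise(name: str, value: float) -> float:
    if not np.isfinite(value):
        raise RuntimeError(f"{name} became non-finite ({value}); aborting training")
    return float(value)


def vae_step(batch_std: np.ndarray, encoder: Encoder, generator: Generator,
             basis: SpectralBasis, stats: TemplateStats, config: TrainConfig,
             opt_e: Adam, opt_g: Adam, rng: np.random.Generator,
             beta_scale: float = 1.0) -> dict[str, float]:
    """One optimization step of (LED-)VAE on a standardized batch.

    Returns the loss components.  The ``eta1`` LE term backpropagates only into
    the encoder and the ``eta2`` term only into the generator.
    """
    T = _tutte_cache(stats, basis)
    x = Tensor(batch_std.astype(np.float32))
    eps = rng.standard_normal(size=(batch_std.shape[0], encoder.latent_size)
                              ).astype(np.float32)
    encoder.zero_grad()
    generator.zero_grad()

    mu, sigma = encoder.forward(x)
    z = mu + sigma * Tensor(eps)
    xp = generator.forward(z)
    l_rec = reconstruction_loss(x, xp)
    xp_destd = xp * Tensor(stats.std.astype(np.float32)) \
        + Tensor(stats.mean.astype(np.float32))
    l_lap = laplacian_loss(xp_destd, T)
    l_kl = kl_loss(mu, sigma)
    base = l_rec + config.alpha * l_lap + (config.beta * beta_scale) * l_kl
    base.backward()

    out = {"reconstruction": _finite_or_raise("reconstruction", l_rec.data.item()),
           "laplacian": float(l_lap.data), "kl": float(l_kl.data)}
    if config.eta1 > 0:
        l_le1 = le_loss_t(x.data, mu, basis, stats)       # data arg constant -> E only
        (config.eta1 * l_le1).backward()
        out["le_encoder"] = _finite_or_raise("le_encoder", l_le1.data.item())
    if config.eta2 > 0:
        xp2 = generator.forward(z.detach())               # severed from E
        l_le2 = le_loss_t(xp2, mu.detach(), basis, stats)
        (config.eta2 * l_le2).backward()
        out["le_generator"] = _finite_or_raise("le_generator", l_le2.data.item())
    opt_e.step()
    opt_g.step()
    out["total"] = out["reconstruction"] + config.alpha * out["laplacian"] \
        + config.beta * beta_scale * out["kl"] \
        + config.eta1 * out.get("le_encoder", 0.0) \
        + config.eta2 * out.get("le_generator", 0.0)
    return out


def lsgan_step(batch_std: np.ndarray, generator: Generator, disc: Discriminator,
               basis: SpectralBasis, stats: TemplateStats, config: TrainConfig,
               opt_g: Adam, opt_d: Adam, rng: np.random.Generator) -> dict[str, float]:
    """One least-squares GAN step: discriminator update, then generator update."""
    T = _tutte_cache(stats, basis)
    B = batch_std.shape[0]
    x = Tensor(batch_std.astype(np.float32))
    z = Tensor(rng.standard_normal(size=(B, generator.latent_size)).astype(np.float32))

    disc.zero_grad()
    xp_const = Tensor(generator.forward(z).data)     # detached generated batch
    d_real = disc.forward(x)
    d_fake = disc.forward(xp_const)
    l_d = 0.5 * ad.mean((d_real - 1.0) * (d_real - 1.0)) + 0.5 * ad.mean(d_fake * d_fake)
    l_d.backward()
    opt_d.step()

    generator.zero_grad()
    disc.zero_grad()
    xp = generator.forward(z)
    d_fake2 = disc.forward(xp)
    l_adv = 0.5 * ad.mean((d_fake2 - 1.0) * (d_fake2 - 1.0))
    xp_destd = xp * Tensor(stats.std.astype(np.float32)) \
        + Tensor(stats.mean.astype(np.float32))
    l_lap = laplacian_loss(xp_destd, T)
    l_g = l_adv + config.alpha * l_lap
    out = {"d_loss": _finite_or_raise("d_loss", l_d.data.item()),
           "g_adversarial": float(l_adv.data), "laplacian": float(l_lap.data)}
    if config.eta > 0:
        l_le = le_loss_t(xp, z, basis, stats)
        l_g = l_g + config.eta * l_le
        out["le_generator"] = _finite_or_raise("le_generator", l_le.data.item())
    l_g.backward()
    opt_g.step()
    out["g_loss"] = float(l_g.data)
    return out


def wgan_step(batch_std: np.ndarray, generator: Generator, critic: Critic,
              basis: SpectralBasis, stats: TemplateStats, config: TrainConfig,
              opt_g: Adam, opt_c: Adam, rng: np.random.Generator) -> dict[str, float]:
    """``n_critic`` clipped critic updates followed by one generator update."""
    T = _tutte_cache(stats, basis)
    B = batch_std.shape[0]
    x = Tensor(batch_std.astype(np.float32))
    out: dict[str, float] = {}
    for _ in range(config.n_critic):
        z = Tensor(rng.standard_normal(size=(B, generator.latent_size)
                                       ).astype(np.float32))
        critic.zero_grad()
        xp_const = Tensor(generator.forward(z).data)
        l_c = ad.mean(critic.forward(xp_const)) - ad.mean(critic.forward(x))
        l_c.backward()
        opt_c.step()
        critic.clip_(config.clip)
        out["c_loss"] = _finite_or_raise("c_loss", l_c.data.item())

    z = Tensor(rng.standard_normal(size=(B, generator.latent_size)).astype(np.float32))
    generator.zero_grad()
    critic.zero_grad()
    xp = generator.forward(z)
    l_adv = -ad.mean(critic.forward(xp))
    xp_destd = xp * Tensor(stats.std.astype(np.float32)) \
        + Tensor(stats.mean.astype(np.float32))
    l_lap = laplacian_loss(xp_destd, T)
    l_g = l_adv + config.alpha * l_lap
    out["g_adversarial"] = float(l_adv.data)
    out["laplacian"] = float(l_lap.data)
    if config.eta > 0:
        l_le = le_loss_t(xp, z, basis, stats)
        l_g = l_g + config.eta * l_le
        out["le_generator"] = _finite_or_raise("le_generator", l_le.data.item())
    l_g.backward()
    opt_g.step()
    out["g_loss"] = _finite_or_raise("g_loss", l_g.data.item())
    return out


# Tutte Laplacian cache keyed by the stats object (one topology per run)
_TUTTE: dict[int, sp.csr_matrix] = {}


def set_tutte(stats: TemplateStats, T: sp.spmatrix) -> None:
    _TUTTE[id(stats)] = sp.csr_matrix(T, dtype=np.float32)


def _tutte_cache(stats: TemplateStats, basis: SpectralBasis) -> sp.csr_matrix:
    if id(stats) not in _TUTTE:
        raise RuntimeError("call set_tutte(stats, T) before training steps")
    return _TUTTE[id(stats)]


# --------------------------------------------------------------------------
# trainer
# --------------------------------------------------------------------------

class Trainer:
    """Epoch loop over one population; owns the networks and optimizers."""

    def __init__(self, population: ShapePopulation, stats: TemplateStats,
                 basis: SpectralBasis, config: TrainConfig,
                 arch: ArchitectureConfig | None = None,
                 hierarchy: MeshHierarchy | None = None,
                 template_vertices: np.ndarray | None = None):
        from .spectral import tutte_laplacian
        if basis.topology_hash != population.topology.hash():
            raise ValueError("spectral basis was fitted on a different topology")
        self.population = population
        self.stats = stats
        self.basis = basis
        self.config = config
        self.arch = arch or ArchitectureConfig()
        if hierarchy is None:
            tv = stats.mean if template_vertices is None else template_vertices
            hierarchy = MeshHierarchy(population.topology, tv, self.arch)
        self.hierarchy = hierarchy
        set_tutte(stats, tutte_laplacian(population.topology))
        rng = np.random.default_rng(config.seed)
        latent = basis.latent_size
        self.generator = Generator(hierarchy, latent, rng)
        self.encoder = self.discriminator = self.critic = None
        if config.flavour == "vae":
            self.encoder = Encoder(hierarchy, latent, rng)
            self.opt_a = Adam(self.encoder.parameters(), lr=config.lr)
        elif config.flavour == "lsgan":
            self.discriminator = Discriminator(hierarchy, rng)
            self.opt_a = Adam(self.discriminator.parameters(), lr=config.lr)
        else:
            self.critic = Critic(hierarchy, rng)
            self.opt_a = Adam(self.critic.parameters(), lr=config.lr)
        self.opt_g = Adam(self.generator.parameters(), lr=config.lr)
        self.rng = np.random.default_rng(config.seed + 1)
        self.history: list[dict] = []

    # ------------------------------------------------------------------
    def _standardized(self, tag: str) -> np.ndarray:
        from .mesh import standardize
        return standardize(self.population.split(tag), self.stats)

    def fit(self, epochs: int | None = None,
            log_path: str | os.PathLike | None = None,
            progress: bool = False) -> list[dict]:
        """Run ``epochs`` more epochs (default: the configured count).

        The epoch index continues from any restored history, so a run resumed
        from a checkpoint reproduces an uninterrupted one step for step.
        """
        cfg = self.config
        train = self._standardized("train").astype(np.float32)
        val = self._standardized("val").astype(np.float32)
        log_fh = open(log_path, "w") if log_path else None
        iterator = range(epochs if epochs is not None else cfg.epochs)
        if progress:
            from tqdm import tqdm
            iterator = tqdm(iterator, desc=f"{'led-' if cfg.led else ''}{cfg.flavour}")
        for _ in iterator:
            epoch = len(self.history)
            order = self.rng.permutation(len(train))
            warm = min(1.0, (epoch + 1) / max(1, cfg.kl_warmup_epochs))
            records = []
            for start in range(0, len(order) - cfg.batch_size + 1, cfg.batch_size):
                batch = train[order[start:start + cfg.batch_size]]
                if cfg.flavour == "vae":
                    rec = vae_step(batch, self.encoder, self.generator, self.basis,
                                   self.stats, cfg, self.opt_a, self.opt_g,
                                   self.rng, beta_scale=warm)
                elif cfg.flavour == "lsgan":
                    rec = lsgan_step(batch, self.generator, self.discriminator,
                                     self.basis, self.stats, cfg,
                                     self.opt_g, self.opt_a, self.rng)
                else:
                    rec = wgan_step(batch, self.generator, self.critic, self.basis,
                                    self.stats, cfg, self.opt_g, self.opt_a, self.rng)
                records.append(rec)
            epoch_rec = {"epoch": epoch}
            for k in records[0]:
                epoch_rec[k] = float(np.mean([r[k] for r in records]))
            if cfg.flavour == "vae" and len(val):
                epoch_rec["val_reconstruction"] = self._val_reconstruction(val)
            self.history.append(epoch_rec)
            if log_fh:
                log_fh.write(json.dumps(epoch_rec) + "\n")
        if log_fh:
            log_fh.close()
        return self.history

    def _val_reconstruction(self, val_std: np.ndarray) -> float:
        mu, _ = self.encoder.forward(Tensor(val_std))
        xp = self.generator.forward(mu)
        return float(np.mean(np.sum((xp.data - val_std) ** 2, axis=-1)))

    # ------------------------------------------------------------------
    def sample(self, n: int, seed: int = 0, sigma: float | None = None) -> np.ndarray:
        """Generate ``n`` de-standardized shapes from the Gaussian prior."""
        from .mesh import destandardize
        sigma = self.config.sigma_sample if sigma is None else sigma
        rng = np.random.default_rng(seed)
        z = rng.standard_normal(size=(n, self.generator.latent_size)) * sigma
        xp = self.generator.forward(Tensor(z.astype(np.float32)))
        return destandardize(xp.data.astype(np.float64), self.stats)


def save_checkpoint(path: str | os.PathLike, trainer: Trainer) -> None:
    """Parameter archive + architecture/config JSON + topology and basis hashes."""
    arrays: dict[str, np.ndarray] = {}
    nets = {"generator": trainer.generator, "encoder": trainer.encoder,
            "discriminator": trainer.discriminator, "critic": trainer.critic}
    roles = {}
    for role, net in nets.items():
        if net is None:
            continue
        roles[role] = list(net.state_dict())
        for k, v in net.state_dict().items():
            arrays[f"{role}.{k}"] = v
    for tag, opt in (("opt_a", trainer.opt_a), ("opt_g", trainer.opt_g)):
        state = opt.state_dict()
        for i, (m, v) in enumerate(zip(state["m"], state["v"])):
            arrays[f"{tag}.m{i}"] = m
            arrays[f"{tag}.v{i}"] = v
        arrays[f"{tag}.t"] = np.array(state["t"])
    meta = {"roles": roles,
            "architecture": asdict(trainer.arch),
            "train_config": asdict(trainer.config),
            "topology_hash": trainer.population.topology.hash(),
            "basis_kappa": trainer.basis.kappa,
            "history": trainer.history,
            "rng_state": trainer.rng.bit_generator.state}
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str | os.PathLike, trainer: Trainer) -> None:
    """Restore parameters into a freshly built Trainer; refuses topology mismatch."""
    data = np.load(path)
    meta = json.loads(bytes(data["meta"]).decode())
    if meta["topology_hash"] != trainer.population.topology.hash():
        raise ValueError("checkpoint was trained on a different topology")
    if meta["basis_kappa"] != trainer.basis.kappa:
        raise ValueError("checkpoint latent block size differs from fitted basis")
    nets = {"generator": trainer.generator, "encoder": trainer.encoder,
            "discriminator": trainer.discriminator, "critic": trainer.critic}
    for role, keys in meta["roles"].items():
        net = nets[role]
        net.load_state_dict({k: data[f"{role}.{k}"] for k in keys})
    for tag, opt in (("opt_a", trainer.opt_a), ("opt_g", trainer.opt_g)):
        n = len(opt.params)
        opt.load_state_dict({"t": int(data[f"{tag}.t"]),
                             "m": [data[f"{tag}.m{i}"] for i in range(n)],
                             "v": [data[f"{tag}.v{i}"] for i in range(n)]})
    trainer.rng.bit_generator.state = meta["rng_state"]
    trainer.history = meta["history"]
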