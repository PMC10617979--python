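"""Model/Results front-end tying the pipeline together.

:class:`LEDShapeModel` is constructed from a :class:`~ledshape.mesh.ShapePopulation`
(or a population directory) and bundles the preprocessing the method needs —
template statistics, the per-attribute spectral basis, the mesh hierarchy —
with a chosen generative flavour.  ``fit()`` trains the networks and returns a
:class:`LEDShapeResults` carrying the trained generator plus sampling,
evaluation, traversal and editing methods, statsmodels-style.
"""

from __future__ import annotations

import io
from dataclasses import replace

import numpy as np

from .evaluation import (MetricReport, VPConfig, disentanglement_localization_score,
                         evaluate_generator, traversal_distance_map, vp_metric)
from .manipulation import EditRequest, attribute_resample, direct_manipulate
from .mesh import ShapePopulation, compute_template_stats, load_population, standardize
from .networks import ArchitectureConfig, MeshHierarchy
from .spectral import fit_spectral_basis
from .training import TrainConfig, Trainer, load_checkpoint, save_checkpoint

__all__ = ["LEDShapeModel", "LEDShapeResults"]


class LEDShapeModel:
    """A generative shape model with local-eigenprojection disentanglement.

    Parameters
    ----------
    population : ShapePopulation
        Corresponded meshes with attribute segmentation and split tags.
    flavour : str
        "vae", "lsgan" or "wgan".
    led : bool
        With False all local-eigenprojection loss weights are zeroed, giving
        the vanilla counterpart of the chosen flavour.
    kappa : int
        Latent variables per attribute; total latent size is F * kappa.
    n_candidate_modes : int, optional
        Candidate eigenvectors per attribute from which the kappa
        highest-variance projections are selected (default 10 * kappa).
    train_config, architecture : optional
        Overrides for the training and network configuration.
    """

    def __init__(self, population: ShapePopulation, flavour: str = "vae",
                 led: bool = True, kappa: int = 3,
                 n_candidate_modes: int | None = None,
                 train_config: TrainConfig | None = None,
                 architecture: ArchitectureConfig | None = None):
        self.population = population
        self.kappa = kappa
        cfg = train_config or TrainConfig(flavour=flavour)
        cfg = replace(cfg, flavour=flavour)
        if not led:
            cfg = replace(cfg, eta1=0.0, eta2=0.0, eta=0.0)
        self.config = cfg
        self.architecture = architecture or ArchitectureConfig()
        self.stats = compute_template_stats(population)
        self.basis = fit_spectral_basis(population, self.stats, kappa,
                                        n_candidate_modes)
        self.hierarchy = MeshHierarchy(population.topology, self.stats.mean,
                                       self.architecture)

    @classmethod
    def from_directory(cls, path, **kwargs) -> "LEDShapeModel":
        """Build from a population directory written by :func:`mesh.write_population`."""
        return cls(load_population(path), **kwargs)

    @property
    def latent_size(self) -> int:
        return self.basis.latent_size

    def fit(self, progress: bool = False, log_path=None) -> "LEDShapeResults":
        trainer = Trainer(self.population, self.stats, self.basis, self.config,
                          arch=self.architecture, hierarchy=self.hierarchy)
        trainer.fit(log_path=log_path, progress=progress)
        return LEDShapeResults(self, trainer)


class LEDShapeResults:
    """Fitted generative shape model with sampling, metrics and editing."""

    def __init__(self, model: LEDShapeModel, trainer: Trainer):
        self.model = model
        self.trainer = trainer
        self.history = trainer.history

    # -- generation ------------------------------------------------------
    def sample(self, n: int, seed: int = 0, sigma: float | None = None) -> np.ndarray:
        """Generate ``n`` shapes (template units) from the Gaussian prior.

        ``sigma < 1`` applies the truncation trick, avoiding the sparse tails
        of the latent distribution.
        """
        return self.trainer.sample(n, seed=seed, sigma=sigma)

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        """Encode and decode shapes (VAE only), returning template-unit vertices."""
        if self.trainer.encoder is None:
            raise ValueError("reconstruction requires the VAE flavour")
        from .autodiff import Tensor
        from .mesh import destandardize
        Xs = standardize(np.atleast_3d(X.reshape(-1, *self.model.stats.mean.shape)),
                         self.model.stats).astype(np.float32)
        mu, _ = self.trainer.encoder.forward(Tensor(Xs))
        out = self.trainer.generator.forward(mu)
        return destandardize(out.data.astype(np.float64), self.model.stats)

    # -- evaluation ------------------------------------------------------
    def traversal_map(self, endpoints=(-3.0, 3.0)) -> np.ndarray:
        return traversal_distance_map(self.trainer.generator, self.model.stats,
                                      self.model.population.topology.attribute_labels,
                                      endpoints)

    def localization_scores(self) -> np.ndarray:
        return disentanglement_localization_score(self.traversal_map(),
                                                  self.model.kappa)

    def vp(self, config: VPConfig | None = None) -> float:
        return vp_metric(self.trainer.generator, self.model.hierarchy, config)

    def evaluate(self, reference: np.ndarray | None = None, n_generate: int = 100,
                 vp_config: VPConfig | None = None, seed: int = 0,
                 compute_vp: bool = True) -> MetricReport:
        """Metric suite against a reference set (default: the test split)."""
        if reference is None:
            reference = self.model.population.split("test")
        topo = self.model.population.topology
        return evaluate_generator(self.trainer.generator, self.model.hierarchy,
                                  self.model.stats, topo.attribute_labels,
                                  self.model.kappa, reference,
                                  n_generate=n_generate, vp_config=vp_config,
                                  seed=seed, compute_vp=compute_vp)

    # -- editing ---------------------------------------------------------
    def resample_attribute(self, z: np.ndarray, attribute: int, seed: int = 0,
                           sigma: float = 1.0) -> np.ndarray:
        return attribute_resample(z, attribute, self.model.kappa, seed, sigma)

    def edit(self, request: EditRequest, n_iterations: int = 50,
             lr: float = 0.1) -> dict:
        return direct_manipulate(self.trainer.generator, request, self.model.stats,
                                 self.model.basis,
                                 self.model.population.topology.attribute_labels,
                                 n_iterations=n_iterations, lr=lr)

    # -- reporting -------------------------------------------------------
    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        m = self.model
        cfg = self.trainer.config
        last = self.history[-1] if self.history else {}
        loc = self.localization_scores()
        buf = io.StringIO()
        name = ("LED-" if cfg.led else "") + cfg.flavour.upper()
        buf.write(f"{name} shape model\n")
        buf.write("=" * 58 + "\n")
        rows = [
            ("shapes (train/val/test)",
             "/".join(str(int((m.population.split_tags == t).sum()))
                      for t in ("train", "val", "test"))),
            ("vertices / attributes", f"{m.population.topology.n_vertices} / "
                                      f"{m.population.topology.n_attributes}"),
            ("latent size (F x kappa)",
             f"{m.basis.latent_size} ({m.basis.n_attributes} x {m.kappa})"),
            ("epochs / batch / lr", f"{cfg.epochs} / {cfg.batch_size} / {cfg.lr:g}"),
            ("LE weights",
             f"eta1={cfg.eta1:g} eta2={cfg.eta2:g}" if cfg.flavour == "vae"
             else f"eta={cfg.eta:g}"),
        ]
        for k, v in last.items():
            if k != "epoch":
                rows.append((f"final {k}", f"{v:.4f}"))
        rows.append(("median localization score", f"{np.median(loc):.2f}"))
        for k, v in rows:
            buf.write(f"{k:<34}{v:>24}\n")
        buf.write("=" * 58 + "\n")
        return buf.getvalue()

    def save(self, path) -> None:
        save_checkpoint(path, self.trainer)

    def load_params(self, path) -> None:
        load_checkpoint(path, self.trainer)
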