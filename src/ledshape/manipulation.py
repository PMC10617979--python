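"""Latent-space shape editing: per-attribute resampling and direct manipulation.

Direct manipulation drags user-selected handle vertices towards target
positions by optimizing only the latent block of the attribute those vertices
belong to; all other blocks are frozen, so a well-disentangled generator moves
little outside the edited region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .mesh import TemplateStats, destandardize
from .networks import Generator
from .spectral import SpectralBasis

__all__ = ["EditRequest", "attribute_resample", "direct_manipulate"]


@dataclass
class EditRequest:
    """A set of handle vertices and their desired positions (template units)."""

    base_latent: np.ndarray      # (F*kappa,)
    vertex_indices: np.ndarray   # (Y,) int
    targets: np.ndarray          # (Y, 3)

    def __post_init__(self) -> None:
        self.vertex_indices = np.asarray(self.vertex_indices, int)
        self.targets = np.asarray(self.targets, float)
        if self.vertex_indices.shape[0] != self.targets.shape[0]:
            raise ValueError("one target position per selected vertex required")


def attribute_resample(z: np.ndarray, attribute: int, kappa: int, seed: int = 0,
                       sigma: float = 1.0) -> np.ndarray:
    """Redraw one attribute's latent block from N(0, sigma^2 I), others untouched."""
    z = np.asarray(z, float)
    n_attr = z.shape[-1] // kappa
    if not 0 <= attribute < n_attr:
        raise ValueError(f"attribute {attribute} out of range")
    rng = np.random.default_rng(seed)
    out = z.copy()
    sl = slice(attribute * kappa, (attribute + 1) * kappa)
    out[..., sl] = rng.standard_normal(kappa) * sigma
    return out


def direct_manipulate(generator: Generator, request: EditRequest,
                      stats: TemplateStats, basis: SpectralBasis,
                      attribute_labels: np.ndarray, n_iterations: int = 50,
                      lr: float = 0.1) -> dict:
    """Handle-based editing by per-attribute latent optimization.

    Handles are grouped by the attribute of their vertex; for each group (in
    ascending attribute order) the squared handle error ``||S o G(z) - Y||^2``
    in template units is minimized over that attribute's latent block with
    Adam (fixed learning rate), all other blocks frozen.  Returns the final
    latent, the edited de-standardized shape, and the initial/final handle
    losses.
    """
    z = np.asarray(request.base_latent, float).copy()
    kappa = basis.kappa
    groups = {}
    for i, v in enumerate(request.vertex_indices):
        groups.setdefault(int(attribute_labels[v]), []).append(i)

    std32 = stats.std.astype(np.float32)
    mean32 = stats.mean.astype(np.float32)

    def handle_loss_np(zz: np.ndarray, idx: np.ndarray, Y: np.ndarray) -> float:
        X = generator.forward(Tensor(zz[None].astype(np.float32))).data[0]
        Xd = X * stats.std + stats.mean
        return float(np.sum((Xd[idx] - Y) ** 2))

    report = {"attributes": [], "initial_loss": {}, "final_loss": {}}
    for attr in sorted(groups):
        rows = groups[attr]
        idx = request.vertex_indices[rows]
        Y = request.targets[rows]
        sl = slice(attr * kappa, (attr + 1) * kappa)
        report["initial_loss"][attr] = handle_loss_np(z, idx, Y)
        block = Tensor(z[sl].astype(np.float32)[None], requires_grad=True)
        opt = Adam([block], lr=lr)
        last_finite = block.data.copy()
        for _ in range(n_iterations):
            block.grad = None
            zfull = ad.stack_blocks(z.astype(np.float32), block, sl)
            X = generator.forward(zfull)
            Xd = X * Tensor(std32) + Tensor(mean32)
            picked = Xd[:, idx, :]
            d = picked - Tensor(Y.astype(np.float32))
            loss = ad.sum_(d * d)
            if not np.isfinite(loss.data):
                block.data = last_finite    # diverged: keep last finite iterate
                break
            last_finite = block.data.copy()
            loss.backward()
            opt.step()
        z[sl] = block.data[0].astype(float)
        report["final_loss"][attr] = handle_loss_np(z, idx, Y)
        report["attributes"].append(attr)

    edited = destandardize(
        generator.forward(Tensor(z[None].astype(np.float32))).data[0].astype(float),
        stats)
    report["latent"] = z
    report["shape"] = edited
    return report
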