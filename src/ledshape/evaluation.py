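"""Generation-quality metrics, the variation-predictability (VP) score and
latent-traversal localization analysis.

Set-to-set generation metrics (diversity, JSD, MMD, COV, 1-NNA) follow the
point-cloud generation literature with the symmetric squared Chamfer distance;
disentanglement is measured by the VP few-shot classifier and by per-attribute
traversal distance maps.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.spatial import cKDTree

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .mesh import TemplateStats
from .networks import Classifier, Generator, MeshHierarchy

__all__ = ["chamfer_distance", "diversity", "jsd", "mmd_cov", "one_nna_delta",
           "VPConfig", "vp_metric", "traversal_distance_map",
           "disentanglement_localization_score", "MetricReport", "evaluate_generator"]


def chamfer_distance(A: np.ndarray, B: np.ndarray) -> float:
    """Symmetric squared Chamfer distance between two point sets.

    ``mean_a min_b ||a-b||^2 + mean_b min_a ||a-b||^2``.
    """
    A, B = np.asarray(A, float), np.asarray(B, float)
    if len(A) == 0 or len(B) == 0:
        raise ValueError("empty point set")
    da, _ = cKDTree(B).query(A)
    db, _ = cKDTree(A).query(B)
    return float(np.mean(da ** 2) + np.mean(db ** 2))


def diversity(generated: np.ndarray, n_pairs: int | None = None,
              seed: int = 0) -> float:
    """Mean over (sampled) pairs of the mean per-vertex correspondence distance."""
    X = np.asarray(generated, float)
    m = len(X)
    if m < 2:
        raise ValueError("need at least 2 meshes")
    all_pairs = [(i, j) for i in range(m) for j in range(i + 1, m)]
    if n_pairs is None or n_pairs >= len(all_pairs):
        pairs = all_pairs
    else:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(all_pairs), size=n_pairs, replace=False)
        pairs = [all_pairs[i] for i in idx]
    vals = [np.linalg.norm(X[i] - X[j], axis=-1).mean() for i, j in pairs]
    return float(np.mean(vals))


def jsd(generated: np.ndarray, reference: np.ndarray, grid: int = 28) -> float:
    """Jensen-Shannon divergence between pooled-vertex voxel histograms (natural log).

    Both sets are voxelized on the reference set's bounding box extended to
    cover the generated set, so disjoint supports reach the ln(2) maximum.
    """
    gen = np.asarray(generated, float).reshape(-1, 3)
    ref = np.asarray(reference, float).reshape(-1, 3)
    lo = np.minimum(gen.min(axis=0), ref.min(axis=0))
    hi = np.maximum(gen.max(axis=0), ref.max(axis=0))
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    edges = [np.linspace(lo[k] - 1e-9 * span[k], hi[k] + 1e-9 * span[k], grid + 1)
             for k in range(3)]
    hg, _ = np.histogramdd(gen, bins=edges)
    hr, _ = np.histogramdd(ref, bins=edges)
    p = hg.ravel() / hg.sum()
    q = hr.ravel() / hr.sum()
    m = 0.5 * (p + q)

    def kl(a, b):
        mask = a > 0
        return float(np.sum(a[mask] * np.log(a[mask] / b[mask])))
    return 0.5 * kl(p, m) + 0.5 * kl(q, m)


def _chamfer_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    return np.array([[chamfer_distance(a, b) for b in B] for a in A])


def mmd_cov(generated: np.ndarray, reference: np.ndarray) -> tuple[float, float]:
    """Minimum matching distance and coverage of the reference set.

    MMD: mean over reference meshes of the Chamfer distance to their nearest
    generated mesh.  COV: percentage of reference meshes that are the nearest
    reference of at least one generated mesh.
    """
    D = _chamfer_matrix(np.asarray(reference, float), np.asarray(generated, float))
    mmd = float(D.min(axis=1).mean())
    matched = np.unique(D.argmin(axis=0))
    cov = 100.0 * matched.size / D.shape[0]
    return mmd, cov


def one_nna_delta(generated: np.ndarray, reference: np.ndarray) -> float:
    """|accuracy - 50| of a leave-one-out 1-NN two-sample test under Chamfer.

    Values near zero mean the generated and reference distributions are
    indistinguishable to the classifier.
    """
    X = list(np.asarray(generated, float)) + list(np.asarray(reference, float))
    labels = np.array([0] * len(generated) + [1] * len(reference))
    n = len(X)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = chamfer_distance(X[i], X[j])
    np.fill_diagonal(D, np.inf)
    pred = labels[D.argmin(axis=1)]
    acc = 100.0 * float(np.mean(pred == labels))
    return abs(acc - 50.0)


# --------------------------------------------------------------------------
# VP disentanglement metric
# --------------------------------------------------------------------------

@dataclass
class VPConfig:
    """Few-shot classifier protocol of the VP metric."""

    n_pairs: int = 10000        # N_VP generated difference pairs
    train_fraction: float = 0.1  # eta_VP: few-shot training share
    n_repeats: int = 3           # S_VP
    epochs: int = 5
    lr: float = 1e-4
    batch_size: int = 32
    seed: int = 0


def vp_metric(generator: Generator, hierarchy: MeshHierarchy,
              config: VPConfig | None = None) -> float:
    """Variation-predictability score (percent).

    Pairs ``(z, z')`` differ in one uniformly chosen latent dimension whose
    value is redrawn from N(0, 1); a classifier with the encoder trunk is
    trained few-shot on the vertex-difference fields ``G(z') - G(z)`` to
    predict the varied dimension.  Returns the mean test accuracy over
    ``n_repeats`` splits, times 100.
    """
    cfg = config or VPConfig()
    lat = generator.latent_size
    rng = np.random.default_rng(cfg.seed)
    # generate difference fields in batches
    diffs = np.empty((cfg.n_pairs, hierarchy.transforms.level_topologies[0].n_vertices, 3),
                     dtype=np.float32)
    labels = rng.integers(0, lat, size=cfg.n_pairs)
    step = 256
    for s in range(0, cfg.n_pairs, step):
        e = min(s + step, cfg.n_pairs)
        z = rng.standard_normal(size=(e - s, lat)).astype(np.float32)
        z2 = z.copy()
        z2[np.arange(e - s), labels[s:e]] = rng.standard_normal(size=e - s)
        x1 = generator.forward(Tensor(z)).data
        x2 = generator.forward(Tensor(z2)).data
        diffs[s:e] = x2 - x1
    n_train = max(1, int(round(cfg.train_fraction * cfg.n_pairs)))
    accs = []
    for rep in range(cfg.n_repeats):
        rep_rng = np.random.default_rng(cfg.seed + 1000 + rep)
        order = rep_rng.permutation(cfg.n_pairs)
        tr, te = order[:n_train], order[n_train:]
        clf = Classifier(hierarchy, lat, rep_rng)
        opt = Adam(clf.parameters(), lr=cfg.lr)
        for _ in range(cfg.epochs):
            ep_order = rep_rng.permutation(tr)
            for s in range(0, len(ep_order), cfg.batch_size):
                idx = ep_order[s:s + cfg.batch_size]
                clf.zero_grad()
                logits = clf.forward(Tensor(diffs[idx]))
                loss = ad.cross_entropy(logits, labels[idx])
                loss.backward()
                opt.step()
        preds = []
        for s in range(0, len(te), 512):
            idx = te[s:s + 512]
            preds.append(clf.forward(Tensor(diffs[idx])).data.argmax(axis=1))
        accs.append(float(np.mean(np.concatenate(preds) == labels[te])))
    return 100.0 * float(np.mean(accs))


# --------------------------------------------------------------------------
# latent traversal analysis
# --------------------------------------------------------------------------

def traversal_distance_map(generator: Generator, stats: TemplateStats,
                           attribute_labels: np.ndarray,
                           endpoints: tuple[float, float] = (-3.0, 3.0),
                           return_vertex_maps: bool = False):
    """Per-attribute mean traversal distances, one row per latent dimension.

    For each latent dimension the remaining latents sit at their mean (0) and
    the dimension is swept between ``endpoints``; the per-vertex Euclidean
    distance between the two generated meshes (template units) is averaged
    within each attribute.
    """
    lat = generator.latent_size
    F = int(attribute_labels.max()) + 1
    out = np.zeros((lat, F))
    vertex_maps = np.zeros((lat, attribute_labels.size))
    for k in range(lat):
        z = np.zeros((2, lat), np.float32)
        z[0, k], z[1, k] = endpoints
        X = generator.forward(Tensor(z)).data.astype(np.float64)
        d = np.linalg.norm((X[1] - X[0]) * stats.std, axis=-1)
        vertex_maps[k] = d
        for w in range(F):
            out[k, w] = d[attribute_labels == w].mean()
    if return_vertex_maps:
        return out, vertex_maps
    return out


def disentanglement_localization_score(distance_map: np.ndarray, kappa: int
                                       ) -> np.ndarray:
    """Per-latent ratio of designated-attribute distance to the largest other.

    The designated attribute of latent dimension k is its block ``k // kappa``.
    Large ratios mean the dimension moves only its own attribute; an all-zero
    row (unused dimension) reports 1.
    """
    lat, F = distance_map.shape
    scores = np.empty(lat)
    for k in range(lat):
        des = k // kappa
        others = np.delete(distance_map[k], des)
        if distance_map[k].max() == 0:
            scores[k] = 1.0
        else:
            scores[k] = distance_map[k, des] / max(others.max(), 1e-30)
    return scores


def render_vertex_scalar(vertices: np.ndarray, faces: np.ndarray,
                         scalars: np.ndarray, path: str, title: str = "",
                         cmap: str = "coolwarm") -> None:
    """Render a per-vertex scalar field on the mesh to a PNG (diverging map)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig = plt.figure(figsize=(4, 4))
    ax = fig.add_subplot(111, projection="3d")
    face_vals = scalars[faces].mean(axis=1)
    surf = ax.plot_trisurf(vertices[:, 0], vertices[:, 1], vertices[:, 2],
                           triangles=faces, cmap=cmap, linewidth=0)
    surf.set_array(face_vals)
    ax.set_axis_off()
    ax.set_title(title)
    fig.colorbar(surf, shrink=0.6)
    fig.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(fig)


@dataclass
class MetricReport:
    """Bundle of generation-quality and disentanglement metrics."""

    diversity: float
    jsd: float
    mmd: float
    cov_percent: float
    one_nna_delta_percent: float
    vp_percent: float | None
    localization_median: float | None
    settings: dict

    def __post_init__(self) -> None:
        assert 0.0 <= self.cov_percent <= 100.0
        assert 0.0 <= self.one_nna_delta_percent <= 50.0 + 1e-9

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate_generator(generator: Generator, hierarchy: MeshHierarchy,
                       stats: TemplateStats, attribute_labels: np.ndarray,
                       kappa: int, reference: np.ndarray, n_generate: int = 100,
                       vp_config: VPConfig | None = None, seed: int = 0,
                       sigma: float = 1.0, compute_vp: bool = True) -> MetricReport:
    """Full metric suite of one trained generator against a reference mesh set."""
    from .mesh import destandardize
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(size=(n_generate, generator.latent_size)) * sigma
    gen = destandardize(generator.forward(Tensor(z.astype(np.float32))
                                          ).data.astype(np.float64), stats)
    mmd, cov = mmd_cov(gen, reference)
    vp = vp_metric(generator, hierarchy,
                   vp_config or VPConfig(seed=seed)) if compute_vp else None
    dmap = traversal_distance_map(generator, stats, attribute_labels)
    loc = disentanglement_localization_score(dmap, kappa)
    return MetricReport(
        diversity=diversity(gen, n_pairs=500, seed=seed),
        jsd=jsd(gen, reference),
        mmd=mmd,
        cov_percent=cov,
        one_nna_delta_percent=one_nna_delta(
            gen[:len(reference)], reference),
        vp_percent=vp,
        localization_median=float(np.median(loc)),
        settings={"n_generate": n_generate, "sigma": sigma, "seed": seed,
                  "distance": "chamfer", "jsd_grid": 28},
    )
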