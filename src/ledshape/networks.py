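"""Mesh neural building blocks and the encoder/generator/discriminator/critic.

Convolutions are spiral convolutions: every vertex owns a fixed-length ordered
sequence of neighbours (itself, its counter-clockwise 1-ring, then outward
rings); features along the spiral are concatenated and mapped by a shared
linear layer.  Resolution changes are fixed sparse matrix products built once
per topology by quadric-error edge collapse (down) and barycentric embedding
of the removed vertices (up).  All four network roles share these operators;
they differ only in their heads.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import trimesh

from . import autodiff as ad
from .autodiff import Tensor
from .mesh import MeshTopology

__all__ = ["ArchitectureConfig", "SpiralIndexing", "SamplingTransforms",
           "build_spiral_indexing", "spiral_conv_forward",
           "build_sampling_transforms", "MeshHierarchy",
           "Encoder", "Generator", "Discriminator", "Critic", "Classifier"]


# --------------------------------------------------------------------------
# spiral indexing
# --------------------------------------------------------------------------

def _ordered_one_ring(v: int, faces_of: list[list[int]], faces: np.ndarray) -> list[int]:
    """Counter-clockwise 1-ring of ``v`` from face winding, starting at the
    smallest-index neighbour.  Raises on non-manifold vertices."""
    nxt: dict[int, int] = {}
    for fi in faces_of[v]:
        a, b, c = faces[fi]
        if a == v:
            s, t = b, c
        elif b == v:
            s, t = c, a
        else:
            s, t = a, b
        if s in nxt:
            raise ValueError(f"non-manifold vertex {v}")
        nxt[int(s)] = int(t)
    if not nxt:
        raise ValueError(f"isolated vertex {v}")
    start = min(nxt)
    ring = [start]
    cur = nxt[start]
    while cur != start:
        ring.append(cur)
        if cur not in nxt or len(ring) > len(nxt):
            raise ValueError(f"non-manifold vertex {v}")
        cur = nxt[cur]
    if len(ring) != len(nxt):
        raise ValueError(f"non-manifold vertex {v}")
    return ring


@dataclass
class SpiralIndexing:
    """(N, L) neighbour indices per vertex; -1 pads spirals shorter than L."""

    indices: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = ad.gather_matrix(self.indices)

    @property
    def length(self) -> int:
        return self.indices.shape[1]


def build_spiral_indexing(topology: MeshTopology, length: int) -> SpiralIndexing:
    """Spiral per vertex: itself, ordered 1-ring, then outward rings, cut/padded to L."""
    faces = topology.faces
    faces_of: list[list[int]] = [[] for _ in range(topology.n_vertices)]
    for fi, f in enumerate(faces):
        for v in f:
            faces_of[int(v)].append(fi)
    rings = [_ordered_one_ring(v, faces_of, faces) for v in range(topology.n_vertices)]
    out = np.full((topology.n_vertices, length), -1, dtype=np.int64)
    for v in range(topology.n_vertices):
        spiral = [v]
        seen = {v}
        frontier = [u for u in rings[v] if u not in seen]
        while frontier and len(spiral) < length:
            for u in frontier:
                if len(spiral) >= length:
                    break
                spiral.append(u)
                seen.add(u)
            nxt: list[int] = []
            for u in frontier:
                for w in rings[u]:
                    if w not in seen and w not in nxt:
                        nxt.append(w)
            frontier = nxt
        out[v, :len(spiral)] = spiral
    return SpiralIndexing(out)


def spiral_conv_forward(features: Tensor, indexing: SpiralIndexing,
                        weight: Tensor, bias: Tensor,
                        activation: bool = True) -> Tensor:
    """Shared linear map over concatenated spiral features, optional ELU.

    ``features`` is (B, N, C_in); ``weight`` is (L * C_in, C_out).
    """
    if features.data.shape[1] != indexing.indices.shape[0]:
        raise ValueError("indexing does not match feature resolution")
    gathered = ad.gather_padded(features, indexing.matrix, indexing.length)
    out = ad.matmul(gathered, weight) + bias
    return ad.elu(out) if activation else out


# --------------------------------------------------------------------------
# quadric sampling
# --------------------------------------------------------------------------

def _vertex_quadrics(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """4x4 plane quadrics accumulated per vertex."""
    v = vertices
    n = np.cross(v[faces[:, 1]] - v[faces[:, 0]], v[faces[:, 2]] - v[faces[:, 0]])
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    n = n / norm
    d = -np.sum(n * v[faces[:, 0]], axis=1)
    p = np.concatenate([n, d[:, None]], axis=1)      # (G, 4)
    Kf = p[:, :, None] * p[:, None, :]               # (G, 4, 4)
    Q = np.zeros((len(v), 4, 4))
    for k in range(3):
        np.add.at(Q, faces[:, k], Kf)
    return Q


def _collapse_mesh(vertices: np.ndarray, faces: np.ndarray, n_target: int
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Quadric-error edge collapse keeping a subset of the original vertices.

    Collapsing edge (a, b) removes b and reroutes its faces to a; the cost is
    the quadric error of moving b onto a's position.  Ties break on insertion
    order and collapses violating the link condition are skipped, so the
    result is deterministic and manifold.  Returns (kept vertex indices,
    coarse faces in original indexing).
    """
    n = len(vertices)
    Q = _vertex_quadrics(vertices, faces)
    neigh: list[set[int]] = [set() for _ in range(n)]
    for a, b, c in faces:
        neigh[a].update((b, c)); neigh[b].update((a, c)); neigh[c].update((a, b))
    alive = np.ones(n, bool)
    homo = np.concatenate([vertices, np.ones((n, 1))], axis=1)
    target_of = np.arange(n)       # where each removed vertex went

    def cost(keep: int, drop: int) -> float:
        h = homo[keep]
        return float(h @ (Q[keep] + Q[drop]) @ h)

    heap: list[tuple[float, int, int, int]] = []
    counter = 0
    edges = np.unique(np.sort(np.concatenate(
        [faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]), axis=1), axis=0)
    for a, b in edges:
        heapq.heappush(heap, (cost(int(a), int(b)), counter, int(a), int(b))); counter += 1
        heapq.heappush(heap, (cost(int(b), int(a)), counter, int(b), int(a))); counter += 1

    n_alive = n
    while n_alive > n_target and heap:
        _, _, a, b = heapq.heappop(heap)
        if not (alive[a] and alive[b]) or b not in neigh[a]:
            continue
        if len(neigh[a] & neigh[b]) != 2:
            continue
        alive[b] = False
        target_of[b] = a
        n_alive -= 1
        Q[a] = Q[a] + Q[b]
        for w in neigh[b]:
            if w != a:
                neigh[w].discard(b)
                neigh[w].add(a)
                neigh[a].add(w)
        neigh[a].discard(b)
        for w in list(neigh[a]):
            heapq.heappush(heap, (cost(a, int(w)), counter, a, int(w))); counter += 1
            heapq.heappush(heap, (cost(int(w), a), counter, int(w), a)); counter += 1
    if n_alive > n_target:
        raise RuntimeError("edge collapse stalled before reaching target size")

    # resolve chains of merges
    def root(v: int) -> int:
        while target_of[v] != v:
            target_of[v] = target_of[target_of[v]]
            v = target_of[v]
        return v

    mapped = np.array([root(int(v)) for v in range(n)])
    new_faces = mapped[faces]
    keep = ((new_faces[:, 0] != new_faces[:, 1]) & (new_faces[:, 1] != new_faces[:, 2])
            & (new_faces[:, 0] != new_faces[:, 2]))
    new_faces = new_faces[keep]
    kept = np.where(alive)[0]
    return kept, new_faces


def _closest_on_mesh(vertices: np.ndarray, faces: np.ndarray, points: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Exhaustive closest point on a triangle mesh for each query point.

    Brute force over all (point, triangle) pairs — run once per topology on
    meshes of a few hundred faces, so no spatial index is needed.
    """
    T, R = len(faces), len(points)
    tris = np.repeat(vertices[faces], R, axis=0)               # (T*R, 3, 3)
    pts = np.tile(points, (T, 1))                              # (T*R, 3)
    cand = trimesh.triangles.closest_point(tris, pts)
    d2 = np.sum((cand - pts) ** 2, axis=1).reshape(T, R)
    tri_id = np.argmin(d2, axis=0)
    closest = cand.reshape(T, R, 3)[tri_id, np.arange(R)]
    return closest, tri_id


@dataclass
class SamplingTransforms:
    """Fixed per-level topologies and sparse down/up transforms.

    ``down[l]`` maps level-l vertex signals to level l+1 (a row-stochastic
    selection matrix); ``up[l]`` maps them back by barycentric interpolation
    in the nearest coarse face of the template geometry.
    """

    level_topologies: list[MeshTopology]
    level_vertices: list[np.ndarray]          # template geometry per level
    down: list[sp.csr_matrix]
    up: list[sp.csr_matrix]


def build_sampling_transforms(topology: MeshTopology, template_vertices: np.ndarray,
                              factor: float, levels: int) -> SamplingTransforms:
    """``levels`` successive coarsenings by ``factor`` with barycentric up-transforms."""
    if factor <= 1:
        raise ValueError("factor must be > 1")
    topos = [topology]
    verts = [np.asarray(template_vertices, float)]
    down, up = [], []
    for _ in range(levels):
        fine_t, fine_v = topos[-1], verts[-1]
        n_target = max(4, int(round(fine_t.n_vertices / factor)))
        kept, new_faces_orig = _collapse_mesh(fine_v, fine_t.faces, n_target)
        local = -np.ones(fine_t.n_vertices, dtype=int)
        local[kept] = np.arange(kept.size)
        coarse_faces = local[new_faces_orig]
        coarse_v = fine_v[kept]
        coarse_t = MeshTopology.from_faces(kept.size, coarse_faces)
        # down: coarse row i selects fine vertex kept[i]
        D = sp.csr_matrix((np.ones(kept.size, np.float32),
                           (np.arange(kept.size), kept)),
                          shape=(kept.size, fine_t.n_vertices))
        # up: kept vertices map to themselves, removed to barycentric coords
        removed = np.where(local < 0)[0]
        rows, cols, vals = [], [], []
        for i, k in enumerate(kept):
            rows.append(int(k)); cols.append(i); vals.append(1.0)
        if removed.size:
            closest, tri_id = _closest_on_mesh(coarse_v, coarse_faces, fine_v[removed])
            tris = coarse_v[coarse_faces[tri_id]]
            bary = trimesh.triangles.points_to_barycentric(tris, closest)
            bary = np.clip(bary, 0.0, None)
            bary = bary / bary.sum(axis=1, keepdims=True)
            for r, t, bc in zip(removed, tri_id, bary):
                for k in range(3):
                    rows.append(int(r)); cols.append(int(coarse_faces[t][k]))
                    vals.append(float(bc[k]))
        U = sp.csr_matrix((np.asarray(vals, np.float32), (rows, cols)),
                          shape=(fine_t.n_vertices, kept.size))
        topos.append(coarse_t)
        verts.append(coarse_v)
        down.append(D)
        up.append(U)
    return SamplingTransforms(topos, verts, down, up)


# --------------------------------------------------------------------------
# networks
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ArchitectureConfig:
    """Shared architecture of all four network roles."""

    channels: tuple[int, ...] = (16, 32, 64)
    spiral_length: int = 9
    sampling_factor: float = 4.0
    in_channels: int = 3

    @property
    def levels(self) -> int:
        return len(self.channels)


class MeshHierarchy:
    """Topology-derived operators shared by every network on one mesh."""

    def __init__(self, topology: MeshTopology, template_vertices: np.ndarray,
                 config: ArchitectureConfig):
        self.config = config
        self.transforms = build_sampling_transforms(
            topology, template_vertices, config.sampling_factor, config.levels)
        self.spirals = [build_spiral_indexing(t, config.spiral_length)
                        for t in self.transforms.level_topologies]

    @property
    def coarse_size(self) -> int:
        return self.transforms.level_topologies[-1].n_vertices


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=(fan_in, fan_out)).astype(np.float32)


class _Network:
    """Base: parameter registry + (de)serialization."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}

    def _add(self, name: str, array: np.ndarray) -> Tensor:
        t = Tensor(array, requires_grad=True)
        self._params[name] = t
        return t

    def parameters(self) -> list[Tensor]:
        return list(self._params.values())

    def named_parameters(self) -> dict[str, Tensor]:
        return dict(self._params)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self._params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, t in self._params.items():
            t.data = np.array(state[k])

    def zero_grad(self) -> None:
        for p in self._params.values():
            p.grad = None


class _ConvTrunk(_Network):
    """Shared encoder-style trunk: conv, downsample, ... , flatten."""

    def __init__(self, hierarchy: MeshHierarchy, rng: np.random.Generator):
        super().__init__()
        self.h = hierarchy
        cfg = hierarchy.config
        L = cfg.spiral_length
        chans = (cfg.in_channels,) + cfg.channels
        for i in range(cfg.levels):
            self._add(f"conv{i}_w", _xavier(rng, L * chans[i], chans[i + 1]))
            self._add(f"conv{i}_b", np.zeros(chans[i + 1], np.float32))
        self.flat_size = hierarchy.coarse_size * cfg.channels[-1]

    def trunk(self, x: Tensor) -> Tensor:
        cfg = self.h.config
        for i in range(cfg.levels):
            x = spiral_conv_forward(x, self.h.spirals[i],
                                    self._params[f"conv{i}_w"],
                                    self._params[f"conv{i}_b"])
            x = ad.sparse_matmul(self.h.transforms.down[i], x)
        return x.reshape(x.data.shape[0], self.flat_size)


class Encoder(_ConvTrunk):
    """Probabilistic encoder: standardized vertices -> (mu, sigma), sigma > 0."""

    def __init__(self, hierarchy: MeshHierarchy, latent_size: int,
                 rng: np.random.Generator):
        super().__init__(hierarchy, rng)
        self.latent_size = latent_size
        self._add("mu_w", _xavier(rng, self.flat_size, latent_size))
        self._add("mu_b", np.zeros(latent_size, np.float32))
        self._add("logstd_w", _xavier(rng, self.flat_size, latent_size))
        self._add("logstd_b", np.zeros(latent_size, np.float32))

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        h = self.trunk(x)
        mu = ad.matmul(h, self._params["mu_w"]) + self._params["mu_b"]
        logstd = ad.matmul(h, self._params["logstd_w"]) + self._params["logstd_b"]
        return mu, ad.exp(logstd)


class Discriminator(_ConvTrunk):
    """LSGAN discriminator: standardized vertices -> real-valued score."""

    def __init__(self, hierarchy: MeshHierarchy, rng: np.random.Generator):
        super().__init__(hierarchy, rng)
        self._add("out_w", _xavier(rng, self.flat_size, 1))
        self._add("out_b", np.zeros(1, np.float32))

    def forward(self, x: Tensor) -> Tensor:
        h = self.trunk(x)
        return ad.matmul(h, self._params["out_w"]) + self._params["out_b"]


class Critic(Discriminator):
    """WGAN critic; same trunk and scalar head, trained with weight clipping."""

    def clip_(self, bound: float) -> None:
        for p in self._params.values():
            np.clip(p.data, -bound, bound, out=p.data)


class Generator(_Network):
    """Generator: latent vector -> standardized vertices (B, N, 3)."""

    def __init__(self, hierarchy: MeshHierarchy, latent_size: int,
                 rng: np.random.Generator):
        super().__init__()
        self.h = hierarchy
        self.latent_size = latent_size
        cfg = hierarchy.config
        L = cfg.spiral_length
        chans = cfg.channels
        self.flat_size = hierarchy.coarse_size * chans[-1]
        self._add("in_w", _xavier(rng, latent_size, self.flat_size))
        self._add("in_b", np.zeros(self.flat_size, np.float32))
        rev = list(reversed(range(cfg.levels)))     # level indices fine<-coarse
        for j, i in enumerate(rev):
            cin = chans[i]
            cout = chans[i - 1] if i > 0 else chans[0]
            self._add(f"conv{j}_w", _xavier(rng, L * cin, cout))
            self._add(f"conv{j}_b", np.zeros(cout, np.float32))
        self._add("out_w", _xavier(rng, L * chans[0], cfg.in_channels))
        self._add("out_b", np.zeros(cfg.in_channels, np.float32))

    def forward(self, z: Tensor) -> Tensor:
        cfg = self.h.config
        h = ad.matmul(z, self._params["in_w"]) + self._params["in_b"]
        h = ad.elu(h)
        h = h.reshape(h.data.shape[0], self.h.coarse_size, cfg.channels[-1])
        for j, i in enumerate(reversed(range(cfg.levels))):
            h = ad.sparse_matmul(self.h.transforms.up[i], h)
            h = spiral_conv_forward(h, self.h.spirals[i],
                                    self._params[f"conv{j}_w"],
                                    self._params[f"conv{j}_b"])
        return spiral_conv_forward(h, self.h.spirals[0],
                                   self._params["out_w"], self._params["out_b"],
                                   activation=False)


class Classifier(_ConvTrunk):
    """Encoder-trunk classifier over latent dimensions (used by the VP metric)."""

    def __init__(self, hierarchy: MeshHierarchy, n_classes: int,
                 rng: np.random.Generator):
        super().__init__(hierarchy, rng)
        self._add("out_w", _xavier(rng, self.flat_size, n_classes))
        self._add("out_b", np.zeros(n_classes, np.float32))

    def forward(self, x: Tensor) -> Tensor:
        h = self.trunk(x)
        return ad.matmul(h, self._params["out_w"]) + self._params["out_b"]
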