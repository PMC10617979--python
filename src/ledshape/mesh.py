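"""Fixed-topology mesh populations in dense point correspondence.

All shapes in a population share one :class:`MeshTopology` (edges, faces and a
per-vertex attribute segmentation) and differ only in vertex positions.  This
module holds the data model, OBJ/PLY I/O, split bookkeeping and the
training-set standardization statistics used everywhere downstream.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import trimesh

__all__ = [
    "MeshTopology",
    "ShapePopulation",
    "TemplateStats",
    "CorrespondenceError",
    "load_mesh",
    "save_mesh",
    "edges_from_faces",
    "load_labels",
    "save_labels",
    "validate_population",
    "compute_template_stats",
    "standardize",
    "destandardize",
    "area_weighted_vertex_normals",
    "write_population",
    "load_population",
]

SIGMA_FLOOR = 1e-8  # template units; keeps rigid regions from exploding under division


class CorrespondenceError(ValueError):
    """Raised when meshes supposed to be in dense correspondence disagree."""


def edges_from_faces(faces: np.ndarray) -> np.ndarray:
    """Undirected edge list (each edge once, sorted pairs, lexicographic order)."""
    faces = np.asarray(faces)
    e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e = np.sort(e, axis=1)
    e = np.unique(e, axis=0)
    return e


def _connected(n: int, edges: np.ndarray, subset: np.ndarray | None = None) -> bool:
    """BFS connectivity of the (sub)graph induced by ``subset`` (all vertices if None)."""
    if subset is None:
        subset = np.arange(n)
    subset = np.asarray(subset)
    if subset.size == 0:
        return False
    mask = np.zeros(n, bool)
    mask[subset] = True
    adj: dict[int, list[int]] = {int(v): [] for v in subset}
    for a, b in edges:
        if mask[a] and mask[b]:
            adj[int(a)].append(int(b))
            adj[int(b)].append(int(a))
    seen = {int(subset[0])}
    stack = [int(subset[0])]
    while stack:
        v = stack.pop()
        for w in adj[v]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return len(seen) == subset.size


@dataclass(frozen=True)
class MeshTopology:
    """Shared connectivity and attribute segmentation of a corresponded mesh set.

    Parameters
    ----------
    n_vertices : int
        Number of vertices N.
    edges : (e, 2) int array
        Undirected edges, each listed once.
    faces : (g, 3) int array
        Triangle faces.
    attribute_labels : (N,) int array
        Hard partition of vertices into ``n_attributes`` anatomical regions.
    n_attributes : int
        Number of attributes F.
    """

    n_vertices: int
    edges: np.ndarray
    faces: np.ndarray
    attribute_labels: np.ndarray
    n_attributes: int

    def __post_init__(self) -> None:
        n = self.n_vertices
        faces = np.asarray(self.faces)
        labels = np.asarray(self.attribute_labels)
        if faces.ndim != 2 or faces.shape[1] != 3:
            raise ValueError("faces must be (g, 3)")
        if faces.min() < 0 or faces.max() >= n:
            raise ValueError("face index out of range")
        if ((faces[:, 0] == faces[:, 1]) | (faces[:, 1] == faces[:, 2])
                | (faces[:, 0] == faces[:, 2])).any():
            raise ValueError("degenerate face with repeated vertex index")
        induced = edges_from_faces(faces)
        given = np.unique(np.sort(np.asarray(self.edges), axis=1), axis=0)
        if not np.array_equal(induced, given):
            raise ValueError("edge set does not match edges induced by faces")
        object.__setattr__(self, "edges", induced)
        object.__setattr__(self, "faces", faces)
        if labels.shape != (n,):
            raise ValueError("attribute_labels must have one entry per vertex")
        if labels.min() < 0 or labels.max() >= self.n_attributes:
            raise ValueError("attribute label out of range")
        for w in range(self.n_attributes):
            idx = np.where(labels == w)[0]
            if idx.size == 0:
                raise ValueError(f"attribute {w} has no vertices")
            if not _connected(n, induced, idx):
                raise ValueError(f"attribute {w} subgraph is not connected")
        if not _connected(n, induced):
            raise ValueError("mesh graph is not connected")
        object.__setattr__(self, "attribute_labels", labels)

    @classmethod
    def from_faces(cls, n_vertices: int, faces: np.ndarray,
                   attribute_labels: np.ndarray | None = None,
                   n_attributes: int | None = None) -> "MeshTopology":
        if attribute_labels is None:
            attribute_labels = np.zeros(n_vertices, dtype=int)
            n_attributes = 1
        if n_attributes is None:
            n_attributes = int(np.max(attribute_labels)) + 1
        return cls(n_vertices, edges_from_faces(faces), np.asarray(faces),
                   np.asarray(attribute_labels), n_attributes)

    def attribute_vertices(self, w: int) -> np.ndarray:
        """Sorted vertex indices of attribute ``w``."""
        return np.where(self.attribute_labels == w)[0]

    def hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.faces, dtype=np.int64).tobytes())
        h.update(np.ascontiguousarray(self.attribute_labels, dtype=np.int64).tobytes())
        return h.hexdigest()[:16]


def load_mesh(path: str | os.PathLike) -> tuple[np.ndarray, np.ndarray]:
    """Read an OBJ/PLY triangle mesh, returning ``(vertices, faces)`` untouched.

    Vertex order and face indexing are preserved exactly (no merging or
    reprocessing), which the dense-correspondence assumption requires.
    """
    mesh = trimesh.load(str(path), process=False, force="mesh")
    faces = np.asarray(mesh.faces)
    if faces.size and faces.shape[1] != 3:
        raise ValueError(f"{path}: non-triangular faces")
    return np.asarray(mesh.vertices, dtype=float), faces.astype(np.int64)


def save_mesh(path: str | os.PathLike, vertices: np.ndarray, faces: np.ndarray) -> None:
    m = trimesh.Trimesh(vertices, faces, process=False)
    path = str(path)
    if path.endswith(".ply"):
        m.export(path, encoding="ascii")
    else:
        m.export(path)


def load_labels(path: str | os.PathLike) -> np.ndarray:
    """Segmentation file: JSON list or plain text, one integer label per vertex."""
    text = open(path).read()
    if text.lstrip().startswith("["):
        return np.asarray(json.loads(text), dtype=int)
    return np.asarray([int(t) for t in text.split()], dtype=int)


def save_labels(path: str | os.PathLike, labels: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(str(int(v)) for v in labels) + "\n")


@dataclass
class ShapePopulation:
    """Stack of corresponded shapes plus train/val/test split tags."""

    topology: MeshTopology
    vertices: np.ndarray        # (n_shapes, N, 3)
    split_tags: np.ndarray      # (n_shapes,) of {"train","val","test"}

    @property
    def n_shapes(self) -> int:
        return self.vertices.shape[0]

    def split(self, tag: str) -> np.ndarray:
        return self.vertices[self.split_tags == tag]

    def subset(self, tag: str) -> "ShapePopulation":
        m = self.split_tags == tag
        return ShapePopulation(self.topology, self.vertices[m], self.split_tags[m])


def assign_splits(n: int, fractions: tuple[float, float, float] = (0.9, 0.05, 0.05),
                  seed: int = 0) -> np.ndarray:
    """Deterministic seeded shuffle into train/val/test of the given fractions."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    tags = np.empty(n, dtype=object)
    tags[order[:n_train]] = "train"
    tags[order[n_train:n_train + n_val]] = "val"
    tags[order[n_train + n_val:]] = "test"
    return tags.astype(str)


def validate_population(meshes: list[tuple[np.ndarray, np.ndarray]],
                        attribute_labels: np.ndarray | None = None,
                        n_attributes: int | None = None,
                        fractions: tuple[float, float, float] = (0.9, 0.05, 0.05),
                        seed: int = 0) -> ShapePopulation:
    """Check dense correspondence across ``(vertices, faces)`` pairs and stack them.

    Raises :class:`CorrespondenceError` naming the first differing face if any
    mesh disagrees on topology.
    """
    if not meshes:
        raise ValueError("need at least one mesh")
    v0, f0 = meshes[0]
    for i, (v, f) in enumerate(meshes[1:], start=1):
        if f.shape != f0.shape or not np.array_equal(f, f0):
            if f.shape == f0.shape:
                j = int(np.nonzero((f != f0).any(axis=1))[0][0])
                raise CorrespondenceError(
                    f"mesh {i}: face {j} is {f[j].tolist()} but template has {f0[j].tolist()}")
            raise CorrespondenceError(f"mesh {i}: face count {len(f)} != {len(f0)}")
        if v.shape != v0.shape:
            raise CorrespondenceError(f"mesh {i}: vertex count {len(v)} != {len(v0)}")
    topo = MeshTopology.from_faces(len(v0), f0, attribute_labels, n_attributes)
    verts = np.stack([v for v, _ in meshes])
    tags = assign_splits(len(meshes), fractions, seed)
    return ShapePopulation(topo, verts, tags)


def area_weighted_vertex_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Unit vertex normals, each the area-weighted mean of incident face normals."""
    v = np.asarray(vertices, float)
    fn = np.cross(v[faces[:, 1]] - v[faces[:, 0]], v[faces[:, 2]] - v[faces[:, 0]])
    acc = np.zeros_like(v)
    for k in range(3):
        np.add.at(acc, faces[:, k], fn)
    norm = np.linalg.norm(acc, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return acc / norm


@dataclass
class TemplateStats:
    """Per-vertex training-set statistics: mean M, std S (floored) and template normals."""

    mean: np.ndarray      # (N, 3)
    std: np.ndarray       # (N, 3), >= SIGMA_FLOOR
    normals: np.ndarray   # (N, 3), unit rows, frozen normals of the mean shape

    def __post_init__(self) -> None:
        assert (self.std > 0).all()


def compute_template_stats(pop: ShapePopulation) -> TemplateStats:
    """Mean/std over the train split; normals computed once on the mean shape."""
    train = pop.split("train")
    if train.shape[0] < 2:
        raise ValueError("need at least 2 training shapes for a standard deviation")
    mean = train.mean(axis=0)
    std = np.maximum(train.std(axis=0), SIGMA_FLOOR)
    normals = area_weighted_vertex_normals(mean, pop.topology.faces)
    return TemplateStats(mean=mean, std=std, normals=normals)


def standardize(X: np.ndarray, stats: TemplateStats) -> np.ndarray:
    """Elementwise ``(X - M) / S``; accepts a single shape or a stack."""
    X = np.asarray(X, float)
    if X.shape[-2:] != stats.mean.shape:
        raise ValueError(f"shape {X.shape} does not match template {stats.mean.shape}")
    return (X - stats.mean) / stats.std


def destandardize(Xs: np.ndarray, stats: TemplateStats) -> np.ndarray:
    """Inverse of :func:`standardize`: ``Xs * S + M``."""
    Xs = np.asarray(Xs, float)
    if Xs.shape[-2:] != stats.mean.shape:
        raise ValueError(f"shape {Xs.shape} does not match template {stats.mean.shape}")
    return Xs * stats.std + stats.mean


def write_population(directory: str | os.PathLike, pop: ShapePopulation,
                     fmt: str = "ply") -> None:
    """Population directory: one mesh file per shape, a labels file and a manifest."""
    directory = str(directory)
    os.makedirs(directory, exist_ok=True)
    names = []
    for i in range(pop.n_shapes):
        name = f"shape_{i:05d}.{fmt}"
        save_mesh(os.path.join(directory, name), pop.vertices[i], pop.topology.faces)
        names.append(name)
    save_labels(os.path.join(directory, "attribute_labels.txt"),
                pop.topology.attribute_labels)
    manifest = {
        "n_attributes": pop.topology.n_attributes,
        "topology_hash": pop.topology.hash(),
        "shapes": [{"file": n, "split": str(t)} for n, t in zip(names, pop.split_tags)],
    }
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)


def load_population(directory: str | os.PathLike) -> ShapePopulation:
    directory = str(directory)
    manifest = json.load(open(os.path.join(directory, "manifest.json")))
    labels = load_labels(os.path.join(directory, "attribute_labels.txt"))
    meshes = [load_mesh(os.path.join(directory, s["file"])) for s in manifest["shapes"]]
    v0, f0 = meshes[0]
    topo = MeshTopology.from_faces(len(v0), f0, labels, manifest["n_attributes"])
    if topo.hash() != manifest["topology_hash"]:
        raise CorrespondenceError("population files do not match manifest topology hash")
    for i, (v, f) in enumerate(meshes):
        if not np.array_equal(f, f0):
            raise CorrespondenceError(f"mesh {i} has different faces")
    verts = np.stack([v for v, _ in meshes])
    tags = np.asarray([s["split"] for s in manifest["shapes"]], dtype=str)
    return ShapePopulation(topo, verts, tags)
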