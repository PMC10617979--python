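"""A small reverse-mode automatic differentiation core on numpy arrays.

Only the operations the mesh networks need are implemented: broadcasting
arithmetic, dense and sparse matrix products, spiral neighbourhood gathers,
ELU, the signed-distance map, L1/L2 reductions and a softmax cross-entropy.
Gradients accumulate into ``Tensor.grad``; ``detach`` severs the graph, which
is how the training losses route gradients to one network only.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = ["Tensor", "Adam", "matmul", "sparse_matmul", "gather_padded",
           "take_columns", "elu", "exp", "log", "absolute", "mean", "sum_",
           "signed_distance_op", "cross_entropy", "stack_blocks"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """Array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward=None):
        self.data = np.asarray(data)
        if self.data.dtype not in (np.float32, np.float64):
            self.data = self.data.astype(np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- graph -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad needs a scalar output")
            grad = np.ones_like(self.data)
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, self.data.dtype)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is not None:
                for parent, pg in zip(node._parents, node._backward(g)):
                    if pg is None or not parent.requires_grad:
                        continue
                    if id(parent) in grads:
                        grads[id(parent)] += pg
                    else:
                        grads[id(parent)] = pg
            else:  # leaf
                node.grad = (node.grad + g) if node.grad is not None else g.copy()

    # -- arithmetic ------------------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data
        return Tensor(out_data, parents=(self, other),
                      backward=lambda g: (_unbroadcast(g, self.data.shape),
                                          _unbroadcast(g, other.data.shape)))

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, parents=(self,), backward=lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        return Tensor(self.data * other.data, parents=(self, other),
                      backward=lambda g: (_unbroadcast(g * other.data, self.data.shape),
                                          _unbroadcast(g * self.data, other.data.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return Tensor(self.data / other.data, parents=(self, other),
                      backward=lambda g: (
                          _unbroadcast(g / other.data, self.data.shape),
                          _unbroadcast(-g * self.data / other.data ** 2,
                                       other.data.shape)))

    def __pow__(self, p: float):
        return Tensor(self.data ** p, parents=(self,),
                      backward=lambda g: (g * p * self.data ** (p - 1),))

    def reshape(self, *shape):
        old = self.data.shape
        return Tensor(self.data.reshape(*shape), parents=(self,),
                      backward=lambda g: (g.reshape(old),))

    def __getitem__(self, key):
        def back(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            return (full,)
        return Tensor(self.data[key], parents=(self,), backward=back)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """``a @ b`` where ``b`` is 2-D (weights) and ``a`` is 2-D or batched 3-D."""
    a, b = Tensor._wrap(a), Tensor._wrap(b)
    out = a.data @ b.data

    def back(g):
        ga = g @ b.data.T
        m = b.data.shape[0]
        gb = a.data.reshape(-1, m).T @ g.reshape(-1, g.shape[-1])
        return ga, gb
    return Tensor(out, parents=(a, b), backward=back)


def sparse_matmul(S: sp.spmatrix, x: Tensor) -> Tensor:
    """Apply a fixed sparse matrix along the vertex axis of ``x`` (B, N, C) or (N, C)."""
    x = Tensor._wrap(x)
    St = S.T.tocsr()
    S = S.tocsr()

    def apply(mat, arr):
        if arr.ndim == 2:
            return mat @ arr
        B, N, C = arr.shape
        flat = arr.transpose(1, 0, 2).reshape(N, B * C)
        out = mat @ flat
        return out.reshape(mat.shape[0], B, C).transpose(1, 0, 2)

    out = apply(S, x.data)
    return Tensor(out, parents=(x,), backward=lambda g: (apply(St, g),))


def gather_matrix(idx: np.ndarray) -> sp.csr_matrix:
    """Sparse (N*L, N) selection matrix for spiral indices; -1 pads to zero rows."""
    N, L = idx.shape
    flat = idx.ravel()
    valid = flat >= 0
    rows = np.nonzero(valid)[0]
    return sp.csr_matrix((np.ones(rows.size, np.float32), (rows, flat[valid])),
                         shape=(N * L, N))


def gather_padded(x: Tensor, S: sp.csr_matrix, L: int) -> Tensor:
    """Spiral gather as a sparse product: ``x`` (B, N, C) -> (B, N, L*C).

    ``S`` comes from :func:`gather_matrix`; each vertex's spiral features are
    concatenated, padded positions contributing zeros.
    """
    x = Tensor._wrap(x)
    B, N, C = x.data.shape
    St = S.T.tocsr()
    flat = x.data.transpose(1, 0, 2).reshape(N, B * C)
    y = (S @ flat).reshape(N, L, B, C)
    out = np.ascontiguousarray(y.transpose(2, 0, 1, 3)).reshape(B, N, L * C)

    def back(g):
        g_flat = np.ascontiguousarray(
            g.reshape(B, N, L, C).transpose(1, 2, 0, 3)).reshape(N * L, B * C)
        gx = St @ g_flat
        return (np.ascontiguousarray(gx.reshape(N, B, C).transpose(1, 0, 2)),)
    return Tensor(out, parents=(x,), backward=back)


def take_columns(x: Tensor, cols: np.ndarray) -> Tensor:
    """Select columns of a (B, N) array (attribute restriction of a vertex signal)."""
    x = Tensor._wrap(x)

    def back(g):
        full = np.zeros_like(x.data)
        np.add.at(full.T, cols, g.T)
        return (full,)
    return Tensor(x.data[:, cols], parents=(x,), backward=back)


def elu(x: Tensor, alpha: float = 1.0) -> Tensor:
    pos = x.data > 0
    out = np.where(pos, x.data, alpha * np.expm1(np.minimum(x.data, 0.0)))
    return Tensor(out, parents=(x,),
                  backward=lambda g: (g * np.where(pos, 1.0, out + alpha),))


def exp(x: Tensor) -> Tensor:
    out = np.exp(x.data)
    return Tensor(out, parents=(x,), backward=lambda g: (g * out,))


def log(x: Tensor) -> Tensor:
    return Tensor(np.log(x.data), parents=(x,), backward=lambda g: (g / x.data,))


def absolute(x: Tensor) -> Tensor:
    return Tensor(np.abs(x.data), parents=(x,),
                  backward=lambda g: (g * np.sign(x.data),))


def mean(x: Tensor) -> Tensor:
    n = x.data.size
    return Tensor(x.data.mean(), parents=(x,),
                  backward=lambda g: (np.full_like(x.data, float(g) / n),))


def sum_(x: Tensor) -> Tensor:
    return Tensor(x.data.sum(), parents=(x,),
                  backward=lambda g: (np.full_like(x.data, float(g)),))


def signed_distance_op(x_std: Tensor, std: np.ndarray, normals: np.ndarray) -> Tensor:
    """Differentiable signed distance of standardized vertices (B, N, 3) -> (B, N).

    Forward matches the numpy ``spectral.signed_distance(..., standardized=True)``;
    the sign factor is treated as locally constant (it is, almost everywhere)
    and the gradient at a zero-distance vertex is taken as zero (a valid
    subgradient of the Euclidean norm).
    """
    x_std = Tensor._wrap(x_std)
    disp = x_std.data * std                       # (B, N, 3) template-unit displacement
    dist = np.linalg.norm(disp, axis=-1)
    gamma = np.sign(np.sum(disp * normals, axis=-1))
    gamma[gamma == 0] = 1.0
    safe = np.where(dist > 0, dist, 1.0)
    ddisp = np.where(dist[..., None] > 0, disp / safe[..., None], 0.0)

    def back(g):
        return ((g * gamma)[..., None] * ddisp * std,)
    return Tensor(gamma * dist, parents=(x_std,), backward=back)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy of (B, K) logits against integer labels."""
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    logsumexp = zmax + np.log(np.exp(z - zmax).sum(axis=1, keepdims=True))
    probs = np.exp(z - logsumexp)
    B = z.shape[0]
    loss = float(np.mean(logsumexp.ravel() - z[np.arange(B), labels]))

    def back(g):
        grad = probs.copy()
        grad[np.arange(B), labels] -= 1.0
        return (float(g) * grad / B,)
    return Tensor(loss, parents=(logits,), backward=back)


def stack_blocks(base: np.ndarray, block: Tensor, sl: slice) -> Tensor:
    """Latent vector equal to constant ``base`` with ``block`` substituted at ``sl``."""
    block = Tensor._wrap(block)
    out = np.array(base, dtype=np.float64, copy=True)
    out = np.broadcast_to(out, (block.data.shape[0], base.shape[-1])).copy() \
        if out.ndim == 1 else out
    out[:, sl] = block.data

    def back(g):
        return (g[:, sl],)
    return Tensor(out, parents=(block,), backward=back)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def state_dict(self) -> dict:
        return {"t": self.t, "m": [m.copy() for m in self.m],
                "v": [v.copy() for v in self.v]}

    def load_state_dict(self, state: dict) -> None:
        self.t = state["t"]
        self.m = [np.array(m) for m in state["m"]]
        self.v = [np.array(v) for v in state["v"]]
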