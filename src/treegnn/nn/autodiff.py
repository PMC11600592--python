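"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for the tree-sequence network: broadcast-aware
elementwise arithmetic, matmul, activations, reductions, gather/scatter row
ops (for graph message passing and sequence padding), concatenation and
slicing, plus fused losses with analytic gradients.  Gradients are
accumulated through a topologically sorted tape; see the test suite for
central-finite-difference checks of every op.
"""

from __future__ import annotations

import numpy as np


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
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None, name=""):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # ---- graph construction helpers -------------------------------------

    def _accumulate(self, grad: np.ndarray) -> None:
        # never mutate in place: incoming arrays may be shared between ops
        if self.grad is None:
            self.grad = np.asarray(grad)
        else:
            self.grad = self.grad + grad

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ---- operators --------------------------------------------------------

    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __matmul__(self, other):
        return matmul(self, other)

    def __neg__(self):
        return mul(self, -1.0)

    def __getitem__(self, idx):
        return getitem(self, idx)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _coerce(a: Tensor, b: Tensor) -> tuple[Tensor, Tensor]:
    """Cast scalar-like (0-d) operands to the other side's float dtype.

    Keeps python-float constants from silently promoting float32 graphs to
    float64 (numpy wraps them as 0-d float64 arrays).
    """
    if a.data.dtype != b.data.dtype:
        if b.data.ndim == 0 and not b.requires_grad:
            b = Tensor(b.data.astype(a.data.dtype))
        elif a.data.ndim == 0 and not a.requires_grad:
            a = Tensor(a.data.astype(b.data.dtype))
    return a, b


def _make(data, parents, backward) -> Tensor:
    req = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, parents=tuple(p for p in parents if p.requires_grad), backward=backward if req else None)


def add(a, b) -> Tensor:
    a, b = _coerce(as_tensor(a), as_tensor(b))
    out_data = a.data + b.data

    def backward(grad):
        if a.requires_grad:
            a._accumulate(_unbroadcast(grad, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(grad, b.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _coerce(as_tensor(a), as_tensor(b))
    out_data = a.data * b.data

    def backward(grad):
        if a.requires_grad:
            a._accumulate(_unbroadcast(grad * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(grad * a.data, b.shape))

    return _make(out_data, (a, b), backward)


def div(a, b) -> Tensor:
    a, b = _coerce(as_tensor(a), as_tensor(b))
    out_data = a.data / b.data

    def backward(grad):
        if a.requires_grad:
            a._accumulate(_unbroadcast(grad / b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-grad * a.data / b.data**2, b.shape))

    return _make(out_data, (a, b), backward)


def matmul(a, b) -> Tensor:
    """2-D @ 2-D or 2-D @ 1-D matrix product."""
    a, b = as_tensor(a), as_tensor(b)
    if a.ndim != 2 or b.ndim not in (1, 2):
        raise ValueError(f"matmul supports (2D @ 1D/2D); got {a.ndim}D @ {b.ndim}D")
    out_data = a.data @ b.data

    def backward(grad):
        if a.requires_grad:
            a._accumulate(np.outer(grad, b.data) if b.ndim == 1 else grad @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ grad)

    return _make(out_data, (a, b), backward)


def exp(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.exp(a.data)

    def backward(grad):
        a._accumulate(grad * out_data)

    return _make(out_data, (a,), backward)


def log(a) -> Tensor:
    a = as_tensor(a)

    def backward(grad):
        a._accumulate(grad / a.data)

    return _make(np.log(a.data), (a,), backward)


def tanh(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.tanh(a.data)

    def backward(grad):
        a._accumulate(grad * (1.0 - out_data**2))

    return _make(out_data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(grad):
        a._accumulate(grad * out_data * (1.0 - out_data))

    return _make(out_data, (a,), backward)


def relu(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.maximum(a.data, 0)

    def backward(grad):
        a._accumulate(grad * (a.data > 0))

    return _make(out_data, (a,), backward)


def leaky_relu(a, negative_slope: float = 0.2) -> Tensor:
    a = as_tensor(a)
    slope = a.data.dtype.type(negative_slope)
    out_data = np.maximum(a.data, 0) + slope * np.minimum(a.data, 0)

    def backward(grad):
        factor = np.where(a.data > 0, a.data.dtype.type(1.0), slope)
        a._accumulate(grad * factor)

    return _make(out_data, (a,), backward)


def power(a, exponent: float) -> Tensor:
    a = as_tensor(a)
    out_data = a.data**exponent

    def backward(grad):
        a._accumulate(grad * exponent * a.data ** (exponent - 1))

    return _make(out_data, (a,), backward)


def sqrt(a) -> Tensor:
    return power(a, 0.5)


def sum_(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(grad):
        g = np.asarray(grad)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.shape))

    return _make(out_data, (a,), backward)


def mean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        count = a.data.size
    else:
        count = np.prod([a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))])
    return mul(sum_(a, axis=axis, keepdims=keepdims), 1.0 / count)


def getitem(a, idx) -> Tensor:
    a = as_tensor(a)
    out_data = a.data[idx]
    fancy = any(
        isinstance(i, (np.ndarray, list)) for i in (idx if isinstance(idx, tuple) else (idx,))
    )

    def backward(grad):
        g = np.zeros_like(a.data)
        if fancy:
            np.add.at(g, idx, grad)  # duplicate indices accumulate
        else:
            g[idx] += grad
        a._accumulate(g)

    return _make(out_data, (a,), backward)


def _scatter_add_matrix(index: np.ndarray, num_rows: int, dtype):
    """Sparse S with S[index[r], r] = 1: S @ X sums rows of X into buckets."""
    from scipy import sparse

    n = len(index)
    return sparse.csr_matrix(
        (np.ones(n, dtype=dtype), (index, np.arange(n))), shape=(num_rows, n)
    )


def gather_rows(a, index: np.ndarray) -> Tensor:
    """Rows of ``a`` at integer ``index`` (duplicates allowed)."""
    a = as_tensor(a)
    index = np.asarray(index)
    out_data = a.data[index]

    def backward(grad):
        # scatter-add with duplicate accumulation via a sparse product
        S = _scatter_add_matrix(index, a.shape[0], a.data.dtype)
        g = S @ (grad if grad.ndim == 2 else grad.reshape(len(index), -1))
        a._accumulate(g.reshape(a.shape))

    return _make(out_data, (a,), backward)


def segment_sum(a, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``a`` into ``num_segments`` buckets given by segment_ids."""
    a = as_tensor(a)
    segment_ids = np.asarray(segment_ids)
    S = _scatter_add_matrix(segment_ids, num_segments, a.data.dtype)
    a2 = a.data if a.ndim == 2 else a.data.reshape(len(segment_ids), -1)
    out_data = (S @ a2).reshape((num_segments,) + a.shape[1:])

    def backward(grad):
        a._accumulate(grad[segment_ids].reshape(a.shape))

    return _make(out_data, (a,), backward)


def scatter_rows(a, row_index: np.ndarray, num_rows: int) -> Tensor:
    """Place each row of ``a`` at a unique target row (zeros elsewhere)."""
    a = as_tensor(a)
    row_index = np.asarray(row_index)
    out_data = np.zeros((num_rows,) + a.shape[1:], dtype=a.data.dtype)
    out_data[row_index] = a.data

    def backward(grad):
        a._accumulate(grad[row_index])

    return _make(out_data, (a,), backward)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(grad):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * grad.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(grad[tuple(sl)])

    return _make(out_data, tuple(tensors), backward)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)

    def backward(grad):
        a._accumulate(grad.reshape(a.shape))

    return _make(a.data.reshape(shape), (a,), backward)


def softmax_segments(scores, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Softmax of a 1-D score vector within each segment.

    Numerically stabilized by subtracting the (detached) per-segment max,
    which leaves the softmax value and gradient unchanged.
    """
    scores = as_tensor(scores)
    seg_max = np.full(num_segments, -np.inf, dtype=scores.data.dtype)
    np.maximum.at(seg_max, segment_ids, scores.data)
    shifted = add(scores, Tensor(-seg_max[segment_ids]))
    e = exp(shifted)
    denom = segment_sum(reshape(e, (-1, 1)), segment_ids, num_segments)
    denom_per_edge = gather_rows(denom, segment_ids)
    return div(e, reshape(denom_per_edge, (-1,)))


def cross_entropy_logits(logits, targets: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer class targets given logits.

    Fused op with the analytic softmax-minus-onehot gradient.
    """
    logits = as_tensor(logits)
    targets = np.asarray(targets, dtype=np.int64)
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    ez = np.exp(z - zmax)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = z.shape[0]
    nll = -np.log(np.clip(p[np.arange(n), targets], 1e-300, None)).mean()

    def backward(grad):
        g = p.copy()
        g[np.arange(n), targets] -= 1.0
        logits._accumulate(grad * g / n)

    return _make(np.asarray(nll), (logits,), backward)


def smooth_l1(pred, targets: np.ndarray, beta: float = 1.0) -> Tensor:
    """Mean smooth-L1 (Huber-style) loss: quadratic within ``beta`` of zero."""
    pred = as_tensor(pred)
    targets = np.asarray(targets, dtype=pred.data.dtype)
    d = pred.data - targets
    absd = np.abs(d)
    elem = np.where(absd < beta, 0.5 * d**2 / beta, absd - 0.5 * beta)
    n = d.size

    def backward(grad):
        g = np.where(absd < beta, d / beta, np.sign(d))
        pred._accumulate(grad * g / n)

    return _make(np.asarray(elem.mean()), (pred,), backward)


# ---------------------------------------------------------------------------
# fused ops (single tape node, hand-written backward; checked against the
# composed-op versions and finite differences in the test suite)
# ---------------------------------------------------------------------------


def gru_sequence(
    x: "Tensor",
    w_ih: "Tensor",
    w_hh: "Tensor",
    b_ih: "Tensor",
    b_hh: "Tensor",
    lengths: np.ndarray | None = None,
) -> "Tensor":
    """Final hidden state of a GRU run over axis 1 of ``x`` (B, S, I).

    Reset/update/candidate gate layout along the last parameter axis.  With
    ``lengths``, hidden states stop updating after each row's true length,
    making the result invariant to trailing padding.  Implemented as one
    tape node with a backward-through-time pass.
    """
    x, w_ih, w_hh, b_ih, b_hh = (as_tensor(t) for t in (x, w_ih, w_hh, b_ih, b_hh))
    B, S, I = x.shape
    H = w_hh.shape[0]
    dtype = x.data.dtype
    x2d = np.ascontiguousarray(x.data.reshape(B * S, I))
    gi_all = (x2d @ w_ih.data + b_ih.data).reshape(B, S, 3 * H)
    h = np.zeros((B, H), dtype=dtype)
    cache = []
    masks = None
    if lengths is not None:
        steps_idx = np.arange(S)[None, :]
        masks = (steps_idx < np.asarray(lengths)[:, None]).astype(dtype)
    for t in range(S):
        gh = h @ w_hh.data + b_hh.data
        gi = gi_all[:, t, :]
        r = 1.0 / (1.0 + np.exp(-(gi[:, :H] + gh[:, :H])))
        z = 1.0 / (1.0 + np.exp(-(gi[:, H : 2 * H] + gh[:, H : 2 * H])))
        ghn = gh[:, 2 * H :]
        n = np.tanh(gi[:, 2 * H :] + r * ghn)
        h_new = (1.0 - z) * n + z * h
        if masks is not None:
            m = masks[:, t][:, None]
            h_next = m * h_new + (1.0 - m) * h
        else:
            m = None
            h_next = h_new
        cache.append((h, r, z, n, ghn, m))
        h = h_next
    out_data = h

    def backward(grad):
        dh = np.asarray(grad, dtype=dtype)
        dgi_all = np.zeros_like(gi_all)
        dw_hh = np.zeros_like(w_hh.data)
        db_hh = np.zeros_like(b_hh.data)
        for t in range(S - 1, -1, -1):
            h_prev, r, z, n, ghn, m = cache[t]
            if m is not None:
                dh_new = dh * m
                dh_pass = dh * (1.0 - m)
            else:
                dh_new = dh
                dh_pass = 0.0
            dz = dh_new * (h_prev - n)
            dn = dh_new * (1.0 - z)
            dh_prev = dh_new * z + dh_pass
            dn_pre = dn * (1.0 - n * n)
            dr = dn_pre * ghn
            dghn = dn_pre * r
            dz_pre = dz * z * (1.0 - z)
            dr_pre = dr * r * (1.0 - r)
            dgh = np.concatenate([dr_pre, dz_pre, dghn], axis=1)
            dgi_all[:, t, :] = np.concatenate([dr_pre, dz_pre, dn_pre], axis=1)
            dh = dh_prev + dgh @ w_hh.data.T
            dw_hh += h_prev.T @ dgh
            db_hh += dgh.sum(axis=0)
        dgi2d = dgi_all.reshape(B * S, 3 * H)
        if x.requires_grad:
            x._accumulate((dgi2d @ w_ih.data.T).reshape(B, S, I))
        if w_ih.requires_grad:
            w_ih._accumulate(x2d.T @ dgi2d)
        if b_ih.requires_grad:
            b_ih._accumulate(dgi2d.sum(axis=0))
        if w_hh.requires_grad:
            w_hh._accumulate(dw_hh)
        if b_hh.requires_grad:
            b_hh._accumulate(db_hh)

    return _make(out_data, (x, w_ih, w_hh, b_ih, b_hh), backward)


def gat_conv_fused(
    x: "Tensor",
    theta_s: "Tensor",
    theta_t: "Tensor",
    att: "Tensor",
    bias: "Tensor | None",
    child: np.ndarray,
    parent: np.ndarray,
    negative_slope: float = 0.2,
) -> "Tensor":
    """Graph attention convolution as one tape node.

    Scores a . LeakyReLU(Theta_s x_i + Theta_t x_j) are softmax-normalized
    over each node's children plus its self-loop; the self message uses
    Theta_s x_i, child messages Theta_t x_j.
    """
    x, theta_s, theta_t, att = (as_tensor(t) for t in (x, theta_s, theta_t, att))
    bias = as_tensor(bias) if bias is not None else None
    n_nodes = x.shape[0]
    E = len(child)
    dtype = x.data.dtype
    slope = dtype.type(negative_slope)
    src = np.concatenate([child, np.arange(n_nodes)])
    dst = np.concatenate([parent, np.arange(n_nodes)])
    xs = x.data @ theta_s.data
    xt = x.data @ theta_t.data
    pre = xs[dst] + xt[src]
    act = np.maximum(pre, 0) + slope * np.minimum(pre, 0)
    scores = act @ att.data
    seg_max = np.full(n_nodes, -np.inf, dtype=dtype)
    np.maximum.at(seg_max, dst, scores)
    e = np.exp(scores - seg_max[dst])
    S_dst = _scatter_add_matrix(dst, n_nodes, dtype)
    denom = S_dst @ e
    alpha = e / denom[dst]
    messages = np.concatenate([xt[child], xs], axis=0)
    out_data = S_dst @ (alpha[:, None] * messages)
    if bias is not None:
        out_data = out_data + bias.data

    def backward(grad):
        grad = np.asarray(grad, dtype=dtype)
        g_dst = grad[dst]
        d_messages = alpha[:, None] * g_dst
        d_alpha = (messages * g_dst).sum(axis=1)
        # softmax jacobian within each destination segment
        inner = S_dst @ (alpha * d_alpha)
        d_scores = alpha * (d_alpha - inner[dst])
        d_act = np.outer(d_scores, att.data)
        d_pre = d_act * np.where(pre > 0, dtype.type(1.0), slope)
        d_xs = S_dst @ d_pre  # via pre (focal term indexed by dst)
        d_xs += d_messages[E:]  # self-loop messages are xs rows in order
        S_src = _scatter_add_matrix(src, n_nodes, dtype)
        d_xt = S_src @ d_pre
        if E:
            S_child = _scatter_add_matrix(child, n_nodes, dtype)
            d_xt += S_child @ d_messages[:E]
        if att.requires_grad:
            att._accumulate(act.T @ d_scores)
        if theta_s.requires_grad:
            theta_s._accumulate(x.data.T @ d_xs)
        if theta_t.requires_grad:
            theta_t._accumulate(x.data.T @ d_xt)
        if x.requires_grad:
            x._accumulate(d_xs @ theta_s.data.T + d_xt @ theta_t.data.T)
        if bias is not None and bias.requires_grad:
            bias._accumulate(grad.sum(axis=0))

    parents = (x, theta_s, theta_t, att) + ((bias,) if bias is not None else ())
    return _make(out_data, parents, backward)
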