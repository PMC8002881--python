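"""Minimal recurrent neural network engine in numpy.

Implements exactly what the cleavage-site classifier needs: stacked
bidirectional LSTM layers, dense layers, a class-weighted binary
cross-entropy loss on logits, backpropagation through time, and Adam.
Windows are short (8 steps), so a straightforward per-timestep loop with
vectorised batches is fast on a single CPU.

Parameters are stored as a list of per-layer dicts of numpy arrays, which
keeps (de)serialisation, freezing and optimizer state trivial.

Conventions: LSTM gate order is (input, forget, candidate, output); the
forget-gate bias is initialised to 1; recurrent weights use orthogonal
initialisation and input weights Glorot-uniform.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy.special import expit as _sigmoid

__all__ = [
    "init_model",
    "forward",
    "loss_and_grads",
    "predict_logits",
    "Adam",
    "clone_params",
    "params_equal",
]


def _glorot(rng: np.random.Generator, shape: tuple[int, int], dtype) -> np.ndarray:
    limit = math.sqrt(6.0 / sum(shape))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def _orthogonal(rng: np.random.Generator, n_rows: int, n_cols: int, dtype) -> np.ndarray:
    # Stack of square orthogonal blocks (one per gate) along columns.
    blocks = []
    remaining = n_cols
    while remaining > 0:
        k = min(n_rows, remaining)
        a = rng.normal(size=(n_rows, n_rows))
        q, r = np.linalg.qr(a)
        q *= np.sign(np.diag(r))
        blocks.append(q[:, :k])
        remaining -= k
    return np.concatenate(blocks, axis=1).astype(dtype)


def _init_lstm_dir(rng, d_in: int, hidden: int, dtype) -> dict[str, np.ndarray]:
    b = np.zeros(4 * hidden, dtype=dtype)
    b[hidden : 2 * hidden] = 1.0  # forget-gate bias
    return {
        "Wx": _glorot(rng, (d_in, 4 * hidden), dtype),
        "Wh": _orthogonal(rng, hidden, 4 * hidden, dtype),
        "b": b,
    }


def init_model(
    input_dim: int,
    n_bilstm_layers: int,
    hidden_units: int,
    dense_units: int,
    seed: int,
    dtype=np.float32,
) -> list[dict]:
    """Build the parameter tree for the window classifier.

    ``n_bilstm_layers`` stacked bidirectional LSTMs (each direction
    ``hidden_units`` wide, outputs concatenated), then a ReLU dense layer
    of ``dense_units``, then a single-logit output layer.
    """
    rng = np.random.default_rng(seed)
    layers: list[dict] = []
    d = input_dim
    for _ in range(n_bilstm_layers):
        layers.append(
            {
                "type": "bilstm",
                "fwd": _init_lstm_dir(rng, d, hidden_units, dtype),
                "bwd": _init_lstm_dir(rng, d, hidden_units, dtype),
            }
        )
        d = 2 * hidden_units
    layers.append(
        {
            "type": "dense",
            "act": "relu",
            "W": _glorot(rng, (d, dense_units), dtype),
            "b": np.zeros(dense_units, dtype=dtype),
        }
    )
    layers.append(
        {
            "type": "dense",
            "act": "linear",
            "W": _glorot(rng, (dense_units, 1), dtype),
            "b": np.zeros(1, dtype=dtype),
        }
    )
    return layers


# ---------------------------------------------------------------------------
# LSTM forward / backward (one direction)
# ---------------------------------------------------------------------------

def _bilstm_forward(layer: dict, X: np.ndarray):
    """Bidirectional LSTM over time-major (T, B, D); output (T, B, 2H).

    Both directions run in one fused pass: the reversed input is stacked
    under the forward input along the batch axis, so every elementwise
    gate operation covers both directions in a single numpy call (the
    per-direction weights keep their own matmuls).  Gate layout in the
    4H axis is [input, forget, output | candidate]; the three sigmoid
    gates are contiguous and evaluated via tanh (sigmoid(x) =
    0.5*(1 + tanh(x/2))) to share numpy's SIMD tanh kernel.
    """
    pf, pb = layer["fwd"], layer["bwd"]
    T, B, D = X.shape
    H = pf["Wh"].shape[0]
    H3, H4 = 3 * H, 4 * H
    B2 = 2 * B
    # Input projections for all timesteps and both directions.
    Xflat = X.reshape(T * B, D)
    Zx = np.empty((T, B2, H4), dtype=X.dtype)
    Zx[:, :B] = (Xflat @ pf["Wx"] + pf["b"]).reshape(T, B, H4)
    Zx[:, B:] = (Xflat @ pb["Wx"] + pb["b"]).reshape(T, B, H4)[::-1]
    Hs = np.empty((T, B2, H), dtype=X.dtype)
    gates = np.empty((T, B2, H4), dtype=X.dtype)  # post-activation i,f,o,g
    Cs = np.empty((T, B2, H), dtype=X.dtype)
    Ct = np.empty((T, B2, H), dtype=X.dtype)  # tanh(c_t)
    h = np.zeros((B2, H), dtype=X.dtype)
    c_prev = np.zeros((B2, H), dtype=X.dtype)
    for t in range(T):
        z = gates[t]
        np.matmul(h[:B], pf["Wh"], out=z[:B])
        np.matmul(h[B:], pb["Wh"], out=z[B:])
        z += Zx[t]
        zs = z[:, :H3]
        zs *= 0.5
        np.tanh(z, out=z)
        zs *= 0.5
        zs += 0.5
        i = z[:, :H]
        f = z[:, H : 2 * H]
        o = z[:, 2 * H : H3]
        g = z[:, H3:]
        c = Cs[t]
        np.multiply(f, c_prev, out=c)
        c += i * g
        np.tanh(c, out=Ct[t])
        h = Hs[t]
        np.multiply(o, Ct[t], out=h)
        c_prev = c
    out = np.empty((T, B, 2 * H), dtype=X.dtype)
    out[..., :H] = Hs[:, :B]
    out[..., H:] = Hs[::-1, B:]
    cache = {"X": X, "gates": gates, "Cs": Cs, "Ct": Ct, "Hs": Hs}
    return out, cache


def _bilstm_backward(layer: dict, cache: dict, dOut: np.ndarray):
    """Backprop through time for a fused bidirectional layer.

    ``dOut`` is (T, B, 2H); returns (dX, grads) with the same fwd/bwd
    split as the parameter dict.
    """
    pf, pb = layer["fwd"], layer["bwd"]
    X, gates, Cs, Ct, Hs = cache["X"], cache["gates"], cache["Cs"], cache["Ct"], cache["Hs"]
    T, B, D = X.shape
    H = pf["Wh"].shape[0]
    H3, H4 = 3 * H, 4 * H
    B2 = 2 * B
    dHs = np.empty((T, B2, H), dtype=X.dtype)
    dHs[:, :B] = dOut[..., :H]
    dHs[:, B:] = dOut[::-1, :, H:]
    dWh_f = np.zeros_like(pf["Wh"])
    dWh_b = np.zeros_like(pb["Wh"])
    dZ_all = np.empty((T, B2, H4), dtype=X.dtype)
    WhT_f = np.ascontiguousarray(pf["Wh"].T)
    WhT_b = np.ascontiguousarray(pb["Wh"].T)
    dh_next = np.zeros((B2, H), dtype=X.dtype)
    dc_next = np.zeros((B2, H), dtype=X.dtype)
    zeros = np.zeros((B2, H), dtype=X.dtype)
    for t in range(T - 1, -1, -1):
        z = gates[t]
        tc = Ct[t]
        c_prev = Cs[t - 1] if t > 0 else zeros
        h_prev = Hs[t - 1] if t > 0 else zeros
        dz = dZ_all[t]
        i = z[:, :H]
        f = z[:, H : 2 * H]
        o = z[:, 2 * H : H3]
        g = z[:, H3:]
        dh = dHs[t] + dh_next
        dc = 1.0 - tc * tc
        dc *= dh
        dc *= o
        dc += dc_next
        np.multiply(dc, g, out=dz[:, :H])          # d(input gate)
        np.multiply(dc, c_prev, out=dz[:, H : 2 * H])  # d(forget gate)
        np.multiply(dh, tc, out=dz[:, 2 * H : H3])  # d(output gate)
        # sigmoid derivative for the three gate blocks in one pass
        s = z[:, :H3]
        dz[:, :H3] *= s - s * s
        np.multiply(dc, i * (1.0 - g * g), out=dz[:, H3:])  # d(candidate)
        np.multiply(dc, f, out=dc_next)

        dWh_f += h_prev[:B].T @ dz[:B]
        dWh_b += h_prev[B:].T @ dz[B:]
        np.matmul(dz[:B], WhT_f, out=dh_next[:B])
        np.matmul(dz[B:], WhT_b, out=dh_next[B:])
    # Input-side grads batched over all timesteps and directions.
    dZf = dZ_all[:, :B].reshape(T * B, H4)
    dZb = np.ascontiguousarray(dZ_all[::-1, B:]).reshape(T * B, H4)
    Xflat = X.reshape(T * B, D)
    gf = {"Wx": Xflat.T @ dZf, "Wh": dWh_f, "b": dZf.sum(axis=0)}
    gb = {"Wx": Xflat.T @ dZb, "Wh": dWh_b, "b": dZb.sum(axis=0)}
    dX = (dZf @ pf["Wx"].T + dZb @ pb["Wx"].T).reshape(T, B, D)
    return dX, {"fwd": gf, "bwd": gb}


# ---------------------------------------------------------------------------
# Full model
# ---------------------------------------------------------------------------

def forward(params: Sequence[dict], X: np.ndarray, caches: list | None = None) -> np.ndarray:
    """Compute logits (B,) for a batch of (B, T, D) windows.

    The final bidirectional layer is read out through its terminal states
    (forward direction at the last step, backward direction at the first),
    then passed through the dense stack.  Pass a list as ``caches`` to
    collect intermediates for :func:`loss_and_grads`.
    """
    # Recurrent layers run time-major so per-step slices are contiguous.
    h = np.ascontiguousarray(np.transpose(X, (1, 0, 2)))
    bilstm_layers = [l for l in params if l["type"] == "bilstm"]
    last_bilstm = bilstm_layers[-1] if bilstm_layers else None
    for layer in params:
        if layer["type"] == "bilstm":
            out, cache = _bilstm_forward(layer, h)
            if layer is last_bilstm:
                H = layer["fwd"]["Wh"].shape[0]
                pooled = np.concatenate([out[-1, :, :H], out[0, :, H:]], axis=1)
                if caches is not None:
                    caches.append(("bilstm_last", cache, out.shape))
                h = pooled
            else:
                if caches is not None:
                    caches.append(("bilstm", cache, None))
                h = out
        else:
            z = h @ layer["W"] + layer["b"]
            if layer["act"] == "relu":
                a = np.maximum(z, 0.0)
            else:
                a = z
            if caches is not None:
                caches.append(("dense", (h, z), None))
            h = a
    return h[:, 0]


def loss_and_grads(
    params: Sequence[dict],
    X: np.ndarray,
    y: np.ndarray,
    sample_weight: np.ndarray | None = None,
):
    """Weighted binary cross-entropy loss and parameter gradients.

    Loss = mean_i w_i * BCE(sigmoid(logit_i), y_i), computed stably from
    logits.  Returns (loss, grads) with grads mirroring ``params``.
    """
    caches: list = []
    logits = forward(params, X, caches=caches)
    y = y.astype(logits.dtype)
    if sample_weight is None:
        w = np.ones_like(y)
    else:
        w = sample_weight.astype(logits.dtype)
    B = len(y)
    # log(1 + e^z) computed stably
    softplus = np.logaddexp(0.0, logits)
    loss = float(np.mean(w * (softplus - y * logits)))
    p = _sigmoid(logits)
    dlogits = (w * (p - y) / B)[:, None]

    grads: list[dict] = [None] * len(params)
    dh = dlogits
    for li in range(len(params) - 1, -1, -1):
        layer = params[li]
        kind, cache, shape = caches[li]
        if kind == "dense":
            h_in, z = cache
            if layer["act"] == "relu":
                dh = dh * (z > 0)
            grads[li] = {"W": h_in.T @ dh, "b": dh.sum(axis=0)}
            dh = dh @ layer["W"].T
        elif kind == "bilstm_last":
            T, Bb, twoH = shape
            H = twoH // 2
            dOut = np.zeros((T, Bb, twoH), dtype=X.dtype)
            dOut[-1, :, :H] = dh[:, :H]
            dOut[0, :, H:] = dh[:, H:]
            dh, g = _bilstm_backward(layer, cache, dOut)
            grads[li] = g
        else:  # bilstm with sequence output
            dh, g = _bilstm_backward(layer, cache, dh)
            grads[li] = g
    return loss, grads


def apply_bilstm_prefix(
    layers: Sequence[dict], X: np.ndarray, batch_size: int = 4096
) -> np.ndarray:
    """Run X through a prefix of bidirectional layers (sequence outputs).

    Used to cache the activations of frozen layers during transfer
    learning: their parameters never change, so their output for a fixed
    training set is computed once.
    """
    if not layers:
        return X
    chunks = []
    for start in range(0, len(X), batch_size):
        h = np.ascontiguousarray(np.transpose(X[start : start + batch_size], (1, 0, 2)))
        for layer in layers:
            h, _ = _bilstm_forward(layer, h)
        chunks.append(np.transpose(h, (1, 0, 2)))
    return np.ascontiguousarray(np.concatenate(chunks))


def predict_logits(
    params: Sequence[dict], X: np.ndarray, batch_size: int = 4096
) -> np.ndarray:
    """Batched forward pass (memory-bounded)."""
    out = np.empty(len(X), dtype=np.float64)
    for start in range(0, len(X), batch_size):
        out[start : start + batch_size] = forward(params, X[start : start + batch_size])
    return out


def predict_proba(params: Sequence[dict], X: np.ndarray, batch_size: int = 4096) -> np.ndarray:
    return _sigmoid(predict_logits(params, X, batch_size))


# ---------------------------------------------------------------------------
# Parameter-tree utilities and Adam
# ---------------------------------------------------------------------------

def _iter_arrays(tree: Sequence[dict]):
    for li, layer in enumerate(tree):
        for key, val in layer.items():
            if isinstance(val, dict):
                for k2, arr in val.items():
                    yield (li, key, k2), arr
            elif isinstance(val, np.ndarray):
                yield (li, key, None), val


def _get(tree, addr):
    li, key, k2 = addr
    return tree[li][key] if k2 is None else tree[li][key][k2]


def _set(tree, addr, value):
    li, key, k2 = addr
    if k2 is None:
        tree[li][key] = value
    else:
        tree[li][key][k2] = value


def clone_params(params: Sequence[dict]) -> list[dict]:
    out = []
    for layer in params:
        copy = {}
        for key, val in layer.items():
            if isinstance(val, dict):
                copy[key] = {k: v.copy() for k, v in val.items()}
            elif isinstance(val, np.ndarray):
                copy[key] = val.copy()
            else:
                copy[key] = val
        out.append(copy)
    return out


def params_equal(a: Sequence[dict], b: Sequence[dict]) -> bool:
    """Bitwise equality of two parameter trees."""
    addrs_a = list(_iter_arrays(a))
    addrs_b = list(_iter_arrays(b))
    if [x[0] for x in addrs_a] != [x[0] for x in addrs_b]:
        return False
    return all(np.array_equal(x[1], y[1]) for x, y in zip(addrs_a, addrs_b))


class Adam:
    """Adam optimizer over a parameter tree, with layer freezing.

    ``frozen_layers`` are layer indices whose parameters are never
    updated (used by transfer learning to pin the first bidirectional
    layer).
    """

    def __init__(
        self,
        params: Sequence[dict],
        learning_rate: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        frozen_layers: frozenset[int] = frozenset(),
    ):
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.frozen_layers = frozenset(frozen_layers)
        self.t = 0
        self.m = {addr: np.zeros_like(arr) for addr, arr in _iter_arrays(params)}
        self.v = {addr: np.zeros_like(arr) for addr, arr in _iter_arrays(params)}

    def step(self, params: Sequence[dict], grads: Sequence[dict]) -> None:
        self.t += 1
        bc1 = 1.0 - self.beta1**self.t
        bc2 = 1.0 - self.beta2**self.t
        for addr, arr in _iter_arrays(params):
            if addr[0] in self.frozen_layers:
                continue
            g = _get(grads, addr)
            m = self.m[addr]
            v = self.v[addr]
            m += (1.0 - self.beta1) * (g - m)
            v += (1.0 - self.beta2) * (g * g - v)
            arr -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
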