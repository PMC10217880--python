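"""Minimal batched recurrent-network engine in numpy.

No deep-learning framework is assumed: layers implement hand-derived
forward/backward passes (backpropagation through time for the recurrent
cells) over float arrays, and a :class:`Network` chains them.  Input
projections are hoisted out of the time loop into single GEMMs so the
per-step work is one (batch, units) x (units, gates*units) product.

Gate conventions follow the standard formulations:

LSTM   i_t = s(W_i [h_{t-1}, x_t] + b_i)      (input gate)
       f_t = s(W_f [h_{t-1}, x_t] + b_f)      (forget gate)
       g_t = tanh(W_c [h_{t-1}, x_t] + b_c)   (candidate)
       o_t = s(W_o [h_{t-1}, x_t] + b_o)      (output gate)
       c_t = f_t * c_{t-1} + i_t * g_t ;  h_t = o_t * tanh(c_t)

GRU    r_t = s(x_t U_r + h_{t-1} W_r)         (reset gate)
       z_t = s(x_t U_z + h_{t-1} W_z)         (update gate)
       h'_t = tanh((r_t * h_{t-1}) U + x_t W) (candidate)
       h_t = (1 - z_t) * h'_t + z_t * h_{t-1}

The bidirectional LSTM runs two independent LSTM cells over the forward and
the time-reversed input and concatenates their states.

Gradient correctness is established by central-finite-difference checks in
the test suite (run in float64).
"""

from __future__ import annotations

import numpy as np


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, shape, dtype):
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def _orthogonal(rng: np.random.Generator, n: int, dtype):
    """Random square orthogonal matrix (QR of a Gaussian, sign-corrected)."""
    q, r = np.linalg.qr(rng.standard_normal((n, n)))
    d = np.sign(np.diag(r))
    d[d == 0] = 1.0
    return np.ascontiguousarray(q * d, dtype=dtype)


class Layer:
    """Base layer: parameter dict + cached forward state for backward."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def init(self, rng: np.random.Generator):  # pragma: no cover - trivial
        pass

    def zero_grads(self):
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, train: bool, rng: np.random.Generator | None):
        raise NotImplementedError

    def backward(self, dout):
        raise NotImplementedError


class Embedding(Layer):
    """Trainable token lookup: int (B, T) -> (B, T, dim); index 0 = padding."""

    def __init__(self, vocab: int, dim: int, dtype=np.float32):
        super().__init__()
        self.vocab, self.dim, self.dtype = vocab, dim, dtype

    def init(self, rng):
        self.params = {"E": rng.uniform(-0.05, 0.05, (self.vocab, self.dim)).astype(self.dtype)}

    def forward(self, x, train, rng):
        self._tokens = np.asarray(x, dtype=np.int64)
        return self.params["E"][self._tokens]

    def backward(self, dout):
        dE = self.grads["E"]
        np.add.at(dE, self._tokens.ravel(), dout.reshape(-1, self.dim))
        return None  # integer inputs carry no gradient


class LSTMCell(Layer):
    """One-directional LSTM over (B, T, D); optionally returns only h_T."""

    def __init__(self, input_dim: int, units: int, return_sequences: bool = False,
                 dtype=np.float32):
        super().__init__()
        self.input_dim, self.units = input_dim, units
        self.return_sequences = return_sequences
        self.dtype = dtype

    def init(self, rng):
        d, h = self.input_dim, self.units
        self.params = {
            "Wx": _glorot(rng, (d, 4 * h), self.dtype),
            "Wh": np.concatenate(
                [_orthogonal(rng, h, self.dtype) for _ in range(4)], axis=1
            ),
            "b": np.zeros(4 * h, dtype=self.dtype),
        }
        self.params["b"][h : 2 * h] = 1.0  # forget-gate bias: remember by default

    def forward(self, x, train, rng):
        x = np.ascontiguousarray(x, dtype=self.dtype)
        B, T, D = x.shape
        h = self.units
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        xproj = x.reshape(B * T, D) @ Wx
        xproj = xproj.reshape(B, T, 4 * h) + b
        H = np.zeros((B, T + 1, h), dtype=self.dtype)
        C = np.zeros((B, T + 1, h), dtype=self.dtype)
        gates = np.empty((B, T, 4 * h), dtype=self.dtype)
        for t in range(T):
            z = xproj[:, t] + H[:, t] @ Wh
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h : 2 * h])
            g = np.tanh(z[:, 2 * h : 3 * h])
            o = _sigmoid(z[:, 3 * h :])
            C[:, t + 1] = f * C[:, t] + i * g
            H[:, t + 1] = o * np.tanh(C[:, t + 1])
            gates[:, t, :h] = i
            gates[:, t, h : 2 * h] = f
            gates[:, t, 2 * h : 3 * h] = g
            gates[:, t, 3 * h :] = o
        self._cache = (x, H, C, gates)
        return H[:, 1:] if self.return_sequences else H[:, -1]

    def backward(self, dout):
        x, H, C, gates = self._cache
        B, T, D = x.shape
        h = self.units
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dZ = np.empty((B, T, 4 * h), dtype=self.dtype)
        dh_next = np.zeros((B, h), dtype=self.dtype)
        dc_next = np.zeros((B, h), dtype=self.dtype)
        if not self.return_sequences:
            dh_next = dh_next + np.asarray(dout, dtype=self.dtype)
        for t in range(T - 1, -1, -1):
            dh = dh_next
            if self.return_sequences:
                dh = dh + dout[:, t]
            i = gates[:, t, :h]
            f = gates[:, t, h : 2 * h]
            g = gates[:, t, 2 * h : 3 * h]
            o = gates[:, t, 3 * h :]
            tc = np.tanh(C[:, t + 1])
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * C[:, t]
            dg = dc * i
            dc_next = dc * f
            dz = dZ[:, t]
            dz[:, :h] = di * i * (1.0 - i)
            dz[:, h : 2 * h] = df * f * (1.0 - f)
            dz[:, 2 * h : 3 * h] = dg * (1.0 - g * g)
            dz[:, 3 * h :] = do * o * (1.0 - o)
            dh_next = dz @ Wh.T
        flat_dZ = dZ.reshape(B * T, 4 * h)
        self.grads["Wx"] += x.reshape(B * T, D).T @ flat_dZ
        self.grads["Wh"] += H[:, :-1].reshape(B * T, h).T @ flat_dZ
        self.grads["b"] += flat_dZ.sum(axis=0)
        return (flat_dZ @ Wx.T).reshape(B, T, D)


class BiLSTM(Layer):
    """Two independent LSTM cells over forward and reversed time, concatenated."""

    def __init__(self, input_dim: int, units: int, return_sequences: bool = False,
                 dtype=np.float32):
        super().__init__()
        self.units = units
        self.return_sequences = return_sequences
        self.fwd = LSTMCell(input_dim, units, return_sequences, dtype)
        self.bwd = LSTMCell(input_dim, units, return_sequences, dtype)

    @property
    def params(self):
        merged = {f"fwd_{k}": v for k, v in self.fwd.params.items()}
        merged.update({f"bwd_{k}": v for k, v in self.bwd.params.items()})
        return merged

    @params.setter
    def params(self, value):  # Layer.__init__ assigns {}; sub-cells own storage
        if value:
            raise AttributeError("set parameters on .fwd / .bwd directly")

    @property
    def grads(self):
        merged = {f"fwd_{k}": v for k, v in self.fwd.grads.items()}
        merged.update({f"bwd_{k}": v for k, v in self.bwd.grads.items()})
        return merged

    @grads.setter
    def grads(self, value):
        if value:
            raise AttributeError("gradients live on .fwd / .bwd")

    def init(self, rng):
        self.fwd.init(rng)
        self.bwd.init(rng)

    def zero_grads(self):
        self.fwd.zero_grads()
        self.bwd.zero_grads()

    def forward(self, x, train, rng):
        hf = self.fwd.forward(x, train, rng)
        hb = self.bwd.forward(x[:, ::-1], train, rng)
        if self.return_sequences:
            hb = hb[:, ::-1]
        return np.concatenate([hf, hb], axis=-1)

    def backward(self, dout):
        h = self.units
        df, db = dout[..., :h], dout[..., h:]
        if self.return_sequences:
            db = db[:, ::-1]
        dx = self.fwd.backward(np.ascontiguousarray(df))
        dxb = self.bwd.backward(np.ascontiguousarray(db))
        return dx + dxb[:, ::-1]


class GRUCell(Layer):
    """GRU over (B, T, D) using the reset/update-gate formulation above."""

    def __init__(self, input_dim: int, units: int, return_sequences: bool = False,
                 dtype=np.float32):
        super().__init__()
        self.input_dim, self.units = input_dim, units
        self.return_sequences = return_sequences
        self.dtype = dtype

    def init(self, rng):
        d, h = self.input_dim, self.units
        self.params = {
            "Ux": _glorot(rng, (d, 3 * h), self.dtype),  # [r, z, candidate] on x
            "Wh": np.concatenate(
                [_orthogonal(rng, h, self.dtype) for _ in range(3)], axis=1
            ),  # [r, z] on h_prev, [candidate] on r*h_prev
            "b": np.zeros(3 * h, dtype=self.dtype),
        }

    def forward(self, x, train, rng):
        x = np.ascontiguousarray(x, dtype=self.dtype)
        B, T, D = x.shape
        h = self.units
        Ux, Wh, b = self.params["Ux"], self.params["Wh"], self.params["b"]
        xproj = (x.reshape(B * T, D) @ Ux).reshape(B, T, 3 * h) + b
        H = np.zeros((B, T + 1, h), dtype=self.dtype)
        RZ = np.empty((B, T, 2 * h), dtype=self.dtype)
        Cand = np.empty((B, T, h), dtype=self.dtype)
        for t in range(T):
            hp = H[:, t]
            rz = _sigmoid(xproj[:, t, : 2 * h] + hp @ Wh[:, : 2 * h])
            r, z = rz[:, :h], rz[:, h:]
            cand = np.tanh(xproj[:, t, 2 * h :] + (r * hp) @ Wh[:, 2 * h :])
            H[:, t + 1] = (1.0 - z) * cand + z * hp
            RZ[:, t] = rz
            Cand[:, t] = cand
        self._cache = (x, H, RZ, Cand)
        return H[:, 1:] if self.return_sequences else H[:, -1]

    def backward(self, dout):
        x, H, RZ, Cand = self._cache
        B, T, D = x.shape
        h = self.units
        Ux, Wh = self.params["Ux"], self.params["Wh"]
        dZ3 = np.empty((B, T, 3 * h), dtype=self.dtype)  # pre-activation grads
        dRH = np.empty((B, T, h), dtype=self.dtype)  # grad wrt (r * h_prev)
        dh_next = np.zeros((B, h), dtype=self.dtype)
        if not self.return_sequences:
            dh_next = dh_next + np.asarray(dout, dtype=self.dtype)
        for t in range(T - 1, -1, -1):
            dh = dh_next
            if self.return_sequences:
                dh = dh + dout[:, t]
            hp = H[:, t]
            r, z = RZ[:, t, :h], RZ[:, t, h:]
            cand = Cand[:, t]
            dcand = dh * (1.0 - z)
            dz = dh * (hp - cand)
            dh_prev = dh * z
            da_c = dcand * (1.0 - cand * cand)
            drh = da_c @ Wh[:, 2 * h :].T
            dr = drh * hp
            dh_prev = dh_prev + drh * r
            da_r = dr * r * (1.0 - r)
            da_z = dz * z * (1.0 - z)
            dh_prev = dh_prev + da_r @ Wh[:, :h].T + da_z @ Wh[:, h : 2 * h].T
            dZ3[:, t, :h] = da_r
            dZ3[:, t, h : 2 * h] = da_z
            dZ3[:, t, 2 * h :] = da_c
            dRH[:, t] = r * hp  # stash the candidate's hidden input for Wh grad
            dh_next = dh_prev
        flat = dZ3.reshape(B * T, 3 * h)
        self.grads["Ux"] += x.reshape(B * T, D).T @ flat
        self.grads["b"] += flat.sum(axis=0)
        hprev_flat = H[:, :-1].reshape(B * T, h)
        self.grads["Wh"][:, : 2 * h] += hprev_flat.T @ flat[:, : 2 * h]
        self.grads["Wh"][:, 2 * h :] += dRH.reshape(B * T, h).T @ flat[:, 2 * h :]
        return (flat @ Ux.T).reshape(B, T, D)


class SimpleRNNCell(Layer):
    """Elman RNN: h_t = tanh(x_t W + h_{t-1} U + b) over (B, T, D)."""

    def __init__(self, input_dim: int, units: int, return_sequences: bool = False,
                 dtype=np.float32):
        super().__init__()
        self.input_dim, self.units = input_dim, units
        self.return_sequences = return_sequences
        self.dtype = dtype

    def init(self, rng):
        d, h = self.input_dim, self.units
        self.params = {
            "Wx": _glorot(rng, (d, h), self.dtype),
            "Wh": _orthogonal(rng, h, self.dtype),
            "b": np.zeros(h, dtype=self.dtype),
        }

    def forward(self, x, train, rng):
        x = np.ascontiguousarray(x, dtype=self.dtype)
        B, T, D = x.shape
        h = self.units
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        xproj = (x.reshape(B * T, D) @ Wx).reshape(B, T, h) + b
        H = np.zeros((B, T + 1, h), dtype=self.dtype)
        for t in range(T):
            H[:, t + 1] = np.tanh(xproj[:, t] + H[:, t] @ Wh)
        self._cache = (x, H)
        return H[:, 1:] if self.return_sequences else H[:, -1]

    def backward(self, dout):
        x, H = self._cache
        B, T, D = x.shape
        h = self.units
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dZ = np.empty((B, T, h), dtype=self.dtype)
        dh_next = np.zeros((B, h), dtype=self.dtype)
        if not self.return_sequences:
            dh_next = dh_next + np.asarray(dout, dtype=self.dtype)
        for t in range(T - 1, -1, -1):
            dh = dh_next
            if self.return_sequences:
                dh = dh + dout[:, t]
            ht = H[:, t + 1]
            dz = dh * (1.0 - ht * ht)
            dZ[:, t] = dz
            dh_next = dz @ Wh.T
        flat = dZ.reshape(B * T, h)
        self.grads["Wx"] += x.reshape(B * T, D).T @ flat
        self.grads["Wh"] += H[:, :-1].reshape(B * T, h).T @ flat
        self.grads["b"] += flat.sum(axis=0)
        return (flat @ Wx.T).reshape(B, T, D)


class TemporalMeanPool(Layer):
    """Average hidden states over time: (B, T, H) -> (B, H).

    Gives every timestep a direct gradient path to the head, which matters
    for long scalar feature sequences where the informative entries sit far
    from the final state.
    """

    def forward(self, x, train, rng):
        self._T = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dout):
        return np.repeat(dout[:, None, :], self._T, axis=1) / self._T


class Dense(Layer):
    """Affine map with optional sigmoid activation on (B, D) inputs."""

    def __init__(self, input_dim: int, units: int, activation: str = "none",
                 dtype=np.float32):
        super().__init__()
        if activation not in ("none", "sigmoid"):
            raise ValueError(f"unsupported activation {activation!r}")
        self.input_dim, self.units, self.activation = input_dim, units, activation
        self.dtype = dtype

    def init(self, rng):
        self.params = {
            "W": _glorot(rng, (self.input_dim, self.units), self.dtype),
            "b": np.zeros(self.units, dtype=self.dtype),
        }

    def forward(self, x, train, rng):
        x = np.asarray(x, dtype=self.dtype)
        out = x @ self.params["W"] + self.params["b"]
        if self.activation == "sigmoid":
            out = _sigmoid(out)
        self._cache = (x, out)
        return out

    def backward(self, dout):
        x, out = self._cache
        dout = np.asarray(dout, dtype=self.dtype)
        if self.activation == "sigmoid":
            dout = dout * out * (1.0 - out)
        self.grads["W"] += x.T @ dout
        self.grads["b"] += dout.sum(axis=0)
        return dout @ self.params["W"].T


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, dtype=np.float32):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.dtype = dtype

    def forward(self, x, train, rng):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(self.dtype) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


def softmax_xent(logits: np.ndarray, labels: np.ndarray):
    """Mean sparse-categorical cross-entropy and its gradient wrt logits."""
    probs = softmax(np.asarray(logits, dtype=np.float64))
    n = len(labels)
    eps = 1e-12
    loss = -np.log(probs[np.arange(n), labels] + eps).mean()
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, (dlogits / n).astype(logits.dtype), probs


class Network:
    """A plain sequential stack of layers with a softmax classification head."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def init(self, rng: np.random.Generator):
        for layer in self.layers:
            layer.init(rng)
            layer.zero_grads()

    def forward(self, x, train: bool = False, rng: np.random.Generator | None = None):
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def zero_grads(self):
        for layer in self.layers:
            layer.zero_grads()

    def named_params(self):
        for i, layer in enumerate(self.layers):
            for name, value in layer.params.items():
                yield f"layer{i}.{name}", value

    def grad_list(self):
        return [
            (layer, name, layer.grads[name])
            for layer in self.layers
            for name in layer.params
        ]

    def sgd_step(self, lr: float, momentum: float = 0.0, clip_norm: float | None = None,
                 velocity: dict | None = None):
        """One SGD update with optional global-norm clipping and momentum."""
        grads = self.grad_list()
        if clip_norm is not None:
            total = np.sqrt(sum(float((g * g).sum()) for _, _, g in grads))
            if total > clip_norm and total > 0:
                scale = clip_norm / total
                for _, _, g in grads:
                    g *= scale
        for idx, (layer, name, g) in enumerate(grads):
            if momentum > 0.0 and velocity is not None:
                v = velocity.setdefault(idx, np.zeros_like(g))
                v *= momentum
                v -= lr * g
                layer.params[name] += v
            else:
                layer.params[name] -= lr * g
        self.zero_grads()

    def state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.named_params()}

    def load_state(self, state: dict[str, np.ndarray]):
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name][...] = state[f"layer{i}.{name}"]
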