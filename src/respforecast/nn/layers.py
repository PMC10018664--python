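"""Layers with explicit forward/backward passes on NumPy arrays.

The package's predictors are small stacks of recurrent layers (a few layers
of 3-60 units over windows of at most 100 samples), so a compact NumPy engine
with hand-derived backpropagation-through-time is used.  Every layer follows
the same protocol:

``forward(x)``
    consumes a batch and caches whatever the backward pass needs;
``backward(dout)``
    consumes the gradient w.r.t. the forward output, accumulates parameter
    gradients in ``self.grads`` (aligned with ``self.params``) and returns
    the gradient w.r.t. the forward input.

Sequence tensors are ``(batch, time, features)``; flat tensors ``(batch,
features)``.  Recurrent cells follow the Keras conventions: gate
nonlinearities are logistic, the candidate/state nonlinearity is the
configurable hidden activation, and the LSTM forget gate is initialized with
bias 1.  Kernels use Glorot-uniform initialization from a caller-supplied
generator so builds are reproducible.
"""

from __future__ import annotations

import numpy as np

from .activations import Activation, _sigmoid, get_activation


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    def __init__(self):
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def _register(self, *arrays):
        for a in arrays:
            self.params.append(a)
            self.grads.append(np.zeros_like(a))

    def zero_grad(self):
        for g in self.grads:
            g.fill(0.0)

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    """Affine projection with an optional elementwise activation."""

    def __init__(self, n_in, n_out, activation: str | Activation, rng):
        super().__init__()
        self.act = (
            activation
            if isinstance(activation, Activation)
            else get_activation(activation)
        )
        if self.act.name == "softmax":
            raise ValueError(
                "softmax output is inconsistent with scalar amplitude "
                "regression; choose linear, sigmoid, swish or softsign"
            )
        self.W = glorot_uniform(rng, n_in, n_out, (n_in, n_out))
        self.b = np.zeros(n_out)
        self._register(self.W, self.b)

    def forward(self, x):
        self._x = x
        self._z = x @ self.W + self.b
        self._y = self.act(self._z)
        return self._y

    def backward(self, dout):
        dz = dout * self.act.grad(self._z, self._y)
        if dz.ndim == 3:  # time-distributed application
            self.grads[0] += np.einsum("bti,btj->ij", self._x, dz)
            self.grads[1] += dz.sum(axis=(0, 1))
        else:
            self.grads[0] += self._x.T @ dz
            self.grads[1] += dz.sum(axis=0)
        return dz @ self.W.T


class SimpleRNN(Layer):
    """Elman recurrence h_t = act(x_t Wx + h_{t-1} Wh + b)."""

    def __init__(self, n_in, units, activation, rng, return_sequences=False,
                 go_backwards=False):
        super().__init__()
        self.units = units
        self.act = get_activation(activation) if isinstance(activation, str) else activation
        self.return_sequences = return_sequences
        self.go_backwards = go_backwards
        self.Wx = glorot_uniform(rng, n_in, units, (n_in, units))
        self.Wh = glorot_uniform(rng, units, units, (units, units))
        self.b = np.zeros(units)
        self._register(self.Wx, self.Wh, self.b)

    def forward(self, x):
        if self.go_backwards:
            x = x[:, ::-1, :]
        B, T, _ = x.shape
        H = np.zeros((B, T + 1, self.units))
        Z = np.empty((B, T, self.units))
        for t in range(T):
            Z[:, t] = x[:, t] @ self.Wx + H[:, t] @ self.Wh + self.b
            H[:, t + 1] = self.act(Z[:, t])
        self._x, self._H, self._Z = x, H, Z
        if self.return_sequences:
            out = H[:, 1:]
            return out[:, ::-1] if self.go_backwards else out
        return H[:, -1]

    def backward(self, dout):
        x, H, Z = self._x, self._H, self._Z
        B, T, _ = x.shape
        if self.return_sequences:
            dH = dout[:, ::-1] if self.go_backwards else dout
        else:
            dH = None
        dWx, dWh, db = self.grads
        dx = np.empty_like(x)
        dh = dout.copy() if dH is None else np.zeros((B, self.units))
        for t in range(T - 1, -1, -1):
            if dH is not None:
                dh = dh + dH[:, t]
            dz = dh * self.act.grad(Z[:, t], H[:, t + 1])
            dWx += x[:, t].T @ dz
            dWh += H[:, t].T @ dz
            db += dz.sum(axis=0)
            dx[:, t] = dz @ self.Wx.T
            dh = dz @ self.Wh.T
        return dx[:, ::-1] if self.go_backwards else dx


class GRU(Layer):
    """Gated recurrent unit (Cho et al. formulation, reset-before-matmul).

    z_t = sig(x Wz + h Uz + bz);  r_t = sig(x Wr + h Ur + br)
    hh  = act(x Wh + (r*h) Uh + bh);  h_t = z*h_prev + (1-z)*hh
    """

    def __init__(self, n_in, units, activation, rng, return_sequences=False,
                 go_backwards=False):
        super().__init__()
        self.units = units
        self.act = get_activation(activation) if isinstance(activation, str) else activation
        self.return_sequences = return_sequences
        self.go_backwards = go_backwards
        u = units
        self.Wx = glorot_uniform(rng, n_in, 3 * u, (n_in, 3 * u))
        self.Wh = glorot_uniform(rng, u, 3 * u, (u, 3 * u))
        self.b = np.zeros(3 * u)
        self._register(self.Wx, self.Wh, self.b)

    def forward(self, x):
        if self.go_backwards:
            x = x[:, ::-1, :]
        B, T, _ = x.shape
        u = self.units
        H = np.zeros((B, T + 1, u))
        ZR = np.empty((B, T, 2 * u))   # post-sigmoid gates [z, r]
        HH = np.empty((B, T, u))       # candidate output
        AH = np.empty((B, T, u))       # candidate pre-activation
        xw = x @ self.Wx + self.b      # precompute input projections
        for t in range(T):
            h = H[:, t]
            gates = xw[:, t, : 2 * u] + h @ self.Wh[:, : 2 * u]
            zr = _sigmoid(gates)
            z, r = zr[:, :u], zr[:, u:]
            ah = xw[:, t, 2 * u:] + (r * h) @ self.Wh[:, 2 * u:]
            hh = self.act(ah)
            H[:, t + 1] = z * h + (1.0 - z) * hh
            ZR[:, t], HH[:, t], AH[:, t] = zr, hh, ah
        self._x, self._H, self._ZR, self._HH, self._AH = x, H, ZR, HH, AH
        if self.return_sequences:
            out = H[:, 1:]
            return out[:, ::-1] if self.go_backwards else out
        return H[:, -1]

    def backward(self, dout):
        x, H, ZR, HH, AH = self._x, self._H, self._ZR, self._HH, self._AH
        B, T, _ = x.shape
        u = self.units
        if self.return_sequences:
            dH = dout[:, ::-1] if self.go_backwards else dout
            dh = np.zeros((B, u))
        else:
            dH = None
            dh = dout.copy()
        dWx, dWh, db = self.grads
        dx = np.empty_like(x)
        Uz, Ur, Uh = self.Wh[:, :u], self.Wh[:, u:2 * u], self.Wh[:, 2 * u:]
        for t in range(T - 1, -1, -1):
            if dH is not None:
                dh = dh + dH[:, t]
            h_prev = H[:, t]
            z, r = ZR[:, t, :u], ZR[:, t, u:]
            hh = HH[:, t]
            dz_gate = dh * (h_prev - hh) * z * (1.0 - z)
            dhh = dh * (1.0 - z)
            dah = dhh * self.act.grad(AH[:, t], hh)
            drh = dah @ Uh.T                     # grad w.r.t. (r * h_prev)
            dr_gate = drh * h_prev * r * (1.0 - r)
            dgates = np.concatenate([dz_gate, dr_gate, dah], axis=1)
            dWx += x[:, t].T @ dgates
            db += dgates.sum(axis=0)
            dWh[:, :u] += h_prev.T @ dz_gate
            dWh[:, u:2 * u] += h_prev.T @ dr_gate
            dWh[:, 2 * u:] += (r * h_prev).T @ dah
            dx[:, t] = dgates @ self.Wx.T
            dh = (
                dh * z
                + dz_gate @ Uz.T
                + dr_gate @ Ur.T
                + drh * r
            )
        return dx[:, ::-1] if self.go_backwards else dx


class LSTM(Layer):
    """Long short-term memory with forget-bias-1 initialization.

    i, f, o = sig(gates); g = act(candidate); c = f*c_prev + i*g; h = o*act(c)
    """

    def __init__(self, n_in, units, activation, rng, return_sequences=False,
                 go_backwards=False):
        super().__init__()
        self.units = units
        self.act = get_activation(activation) if isinstance(activation, str) else activation
        self.return_sequences = return_sequences
        self.go_backwards = go_backwards
        u = units
        self.Wx = glorot_uniform(rng, n_in, 4 * u, (n_in, 4 * u))
        self.Wh = glorot_uniform(rng, u, 4 * u, (u, 4 * u))
        self.b = np.zeros(4 * u)
        self.b[u:2 * u] = 1.0  # forget gate
        self._register(self.Wx, self.Wh, self.b)

    def forward(self, x):
        if self.go_backwards:
            x = x[:, ::-1, :]
        B, T, _ = x.shape
        u = self.units
        H = np.zeros((B, T + 1, u))
        C = np.zeros((B, T + 1, u))
        G = np.empty((B, T, 4 * u))   # i, f, o post-sigmoid; g post-act
        AG = np.empty((B, T, u))      # candidate pre-activation
        TC = np.empty((B, T, u))      # act(c_t)
        xw = x @ self.Wx + self.b
        for t in range(T):
            s = xw[:, t] + H[:, t] @ self.Wh
            ifo = _sigmoid(s[:, : 3 * u])
            ag = s[:, 3 * u:]
            g = self.act(ag)
            i, f = ifo[:, :u], ifo[:, u:2 * u]
            o = ifo[:, 2 * u:]
            C[:, t + 1] = f * C[:, t] + i * g
            tc = self.act(C[:, t + 1])
            H[:, t + 1] = o * tc
            G[:, t, : 3 * u], G[:, t, 3 * u:] = ifo, g
            AG[:, t], TC[:, t] = ag, tc
        self._x, self._H, self._C, self._G, self._AG, self._TC = x, H, C, G, AG, TC
        if self.return_sequences:
            out = H[:, 1:]
            return out[:, ::-1] if self.go_backwards else out
        return H[:, -1]

    def backward(self, dout):
        x, H, C, G, AG, TC = self._x, self._H, self._C, self._G, self._AG, self._TC
        B, T, _ = x.shape
        u = self.units
        if self.return_sequences:
            dH = dout[:, ::-1] if self.go_backwards else dout
            dh = np.zeros((B, u))
        else:
            dH = None
            dh = dout.copy()
        dc = np.zeros((B, u))
        dWx, dWh, db = self.grads
        dx = np.empty_like(x)
        for t in range(T - 1, -1, -1):
            if dH is not None:
                dh = dh + dH[:, t]
            i, f = G[:, t, :u], G[:, t, u:2 * u]
            o, g = G[:, t, 2 * u:3 * u], G[:, t, 3 * u:]
            tc = TC[:, t]
            do = dh * tc * o * (1.0 - o)
            dc = dc + dh * o * self.act.grad(C[:, t + 1], tc)
            di = dc * g * i * (1.0 - i)
            df = dc * C[:, t] * f * (1.0 - f)
            dag = dc * i * self.act.grad(AG[:, t], g)
            dgates = np.concatenate([di, df, do, dag], axis=1)
            dWx += x[:, t].T @ dgates
            dWh += H[:, t].T @ dgates
            db += dgates.sum(axis=0)
            dx[:, t] = dgates @ self.Wx.T
            dh = dgates @ self.Wh.T
            dc = dc * f
        return dx[:, ::-1] if self.go_backwards else dx


class Bidirectional(Layer):
    """Runs a forward and a time-reversed copy of a cell, concatenating features."""

    def __init__(self, cell_cls, n_in, units, activation, rng,
                 return_sequences=False):
        super().__init__()
        self.fwd = cell_cls(n_in, units, activation, rng,
                            return_sequences=return_sequences)
        self.bwd = cell_cls(n_in, units, activation, rng,
                            return_sequences=return_sequences,
                            go_backwards=True)
        self.units = 2 * units
        self.return_sequences = return_sequences
        self.params = self.fwd.params + self.bwd.params
        self.grads = self.fwd.grads + self.bwd.grads

    def forward(self, x):
        return np.concatenate([self.fwd.forward(x), self.bwd.forward(x)], axis=-1)

    def backward(self, dout):
        u = self.units // 2
        return self.fwd.backward(dout[..., :u]) + self.bwd.backward(dout[..., u:])


class Conv1D(Layer):
    """Temporal convolution (valid padding, stride 1) with activation."""

    def __init__(self, n_in, filters, kernel_size, activation, rng):
        super().__init__()
        self.kernel_size = kernel_size
        self.act = get_activation(activation) if isinstance(activation, str) else activation
        fan_in = n_in * kernel_size
        self.W = glorot_uniform(rng, fan_in, filters, (kernel_size, n_in, filters))
        self.b = np.zeros(filters)
        self._register(self.W, self.b)

    def forward(self, x):
        B, T, F = x.shape
        k = self.kernel_size
        if T < k:
            raise ValueError(f"sequence length {T} shorter than kernel {k}")
        self._x = x
        z = np.zeros((B, T - k + 1, self.W.shape[2]))
        for j in range(k):
            z += x[:, j:T - k + 1 + j, :] @ self.W[j]
        z += self.b
        self._z = z
        self._y = self.act(z)
        return self._y

    def backward(self, dout):
        x, k = self._x, self.kernel_size
        B, T, F = x.shape
        dz = dout * self.act.grad(self._z, self._y)
        dx = np.zeros_like(x)
        for j in range(k):
            self.grads[0][j] += np.einsum("bti,btf->if", x[:, j:T - k + 1 + j, :], dz)
            dx[:, j:T - k + 1 + j, :] += dz @ self.W[j].T
        self.grads[1] += dz.sum(axis=(0, 1))
        return dx


class MaxPool1D(Layer):
    """Temporal max-pool, pool size = stride = 2; odd tail sample dropped."""

    def __init__(self, pool_size=2):
        super().__init__()
        self.pool = pool_size

    def forward(self, x):
        B, T, F = x.shape
        n = T // self.pool
        xr = x[:, : n * self.pool].reshape(B, n, self.pool, F)
        self._argmax = xr.argmax(axis=2)
        self._shape = x.shape
        return xr.max(axis=2)

    def backward(self, dout):
        B, n, F = dout.shape
        dx = np.zeros(self._shape)
        b, t, f = np.ogrid[:B, :n, :F]
        head = dx[:, : n * self.pool].reshape(B, n, self.pool, F)
        head[b, t, self._argmax, f] = dout
        dx[:, : n * self.pool] = head.reshape(B, n * self.pool, F)
        return dx


class RepeatVector(Layer):
    """Tiles a flat feature vector into a length-n sequence."""

    def __init__(self, n):
        super().__init__()
        self.n = n

    def forward(self, x):
        return np.repeat(x[:, None, :], self.n, axis=1)

    def backward(self, dout):
        return dout.sum(axis=1)


CELLS = {"simple_rnn": SimpleRNN, "lstm": LSTM, "gru": GRU}
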