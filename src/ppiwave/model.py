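"""The "Y-type" two-branch bidirectional LSTM classifier.

Architecture
------------
The input layer is 1200 units wide: the first 600 carry protein A's
descriptor, the last 600 protein B's.  Each 600-vector is unstacked
into a 75-step sequence of 8 channels (one channel per physicochemical
property; step t of channel j is feature 75*j + t) and fed through a
stack of bidirectional LSTM layers.  With the default 512 units per
layer per branch (256 per direction) and 2 layers per branch, the
recurrent part totals 512 * 2 * 2 = 2048 units.

*Local weight sharing*: both branches resolve to the same parameter
storage, so the transform applied to protein A is identical to the one
applied to protein B and the recurrent parameter count is half that of
an unshared two-branch network.

Each branch's terminal states (last forward step + first backward
step of the top layer) pass through a shared affine + ReLU projection
to half the buffer width; concatenating the two projections gives the
256-unit buffer layer, followed by a dense stack 32 -> 8 -> 2 with
ReLU on hidden layers and softmax on the 2-unit output.  Output
(1, 0) means interaction, (0, 1) no interaction.

The LSTM cell follows the standard gate equations

    f_t = sigmoid(W_f . [h_{t-1}, x_t] + b_f)
    i_t = sigmoid(W_i . [h_{t-1}, x_t] + b_i)
    C~  = tanh(W_C . [h_{t-1}, x_t] + b_C)
    C_t = f_t * C_{t-1} + i_t * C~
    o_t = sigmoid(W_o . [h_{t-1}, x_t] + b_o)
    h_t = o_t * tanh(C_t)

Training is plain mini-batch SGD on softmax cross-entropy (batch 128,
learning rate 0.05 by default), with all randomness -- initialization
and shuffling -- drawn from one seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from ppiwave.exceptions import (
    ConfigError,
    DivergenceError,
    InvalidInputError,
)
from ppiwave.pairs import PairFeature, pair_matrix
from ppiwave.wavelets import N_FEATURES


def relu(x):
    """Rectified linear unit: max(0, x), elementwise."""
    return np.maximum(0, x)


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the Y-type model.

    ``rnn_units`` counts units per recurrent layer per branch with both
    directions included, so each direction runs ``rnn_units // 2``
    hidden units.  ``steps_per_protein * channels_per_step`` must equal
    the 600-value descriptor length.
    """

    rnn_units: int = 512
    rnn_layers_per_branch: int = 2
    buffer_units: int = 256
    dense_units: tuple[int, ...] = (32, 8, 2)
    batch_size: int = 128
    learning_rate: float = 0.05
    momentum: float = 0.0  # classical momentum; 0 = plain SGD
    epochs: int = 200
    seed: int = 0
    steps_per_protein: int = 75
    channels_per_step: int = 8
    shared: bool = True
    buffer_mode: str = "per_branch"  # or "joint"
    symmetric_inference: bool = True
    standardize_inputs: bool = True

    def __post_init__(self):
        d = tuple(self.dense_units)
        object.__setattr__(self, "dense_units", d)
        if not d or d[-1] != 2:
            raise ConfigError("dense_units must end in the 2-unit output layer")
        if self.steps_per_protein * self.channels_per_step != N_FEATURES:
            raise ConfigError(
                f"steps_per_protein * channels_per_step must be {N_FEATURES}"
            )
        counts = (self.rnn_units, self.rnn_layers_per_branch, self.buffer_units,
                  self.batch_size, self.epochs, *d)
        if any(c <= 0 for c in counts) or self.learning_rate < 0:
            raise ConfigError("all layer/batch/epoch counts must be positive")
        if self.rnn_units % 2:
            raise ConfigError("rnn_units must be even (two directions)")
        if self.buffer_mode not in ("per_branch", "joint"):
            raise ConfigError(f"unknown buffer_mode {self.buffer_mode!r}")
        if self.buffer_mode == "per_branch" and self.buffer_units % 2:
            raise ConfigError("per-branch buffer needs an even buffer_units")

    @property
    def hidden_per_direction(self) -> int:
        return self.rnn_units // 2

    @property
    def recurrent_unit_total(self) -> int:
        """Units across both branches and all layers (2048 by default)."""
        return self.rnn_units * 2 * self.rnn_layers_per_branch


# ---------------------------------------------------------------------------
# LSTM cell and layers


@dataclass
class LSTMCellParams:
    """Gate weights over the concatenation [h_{t-1}, x_t], plus biases."""

    W_f: np.ndarray
    W_i: np.ndarray
    W_C: np.ndarray
    W_o: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_C: np.ndarray
    b_o: np.ndarray

    FIELDS = ("W_f", "W_i", "W_C", "W_o", "b_f", "b_i", "b_C", "b_o")

    @classmethod
    def init(cls, rng: np.random.Generator, input_size: int,
             hidden: int) -> "LSTMCellParams":
        """Glorot-uniform weights, zero biases."""
        fan_in = hidden + input_size
        limit = np.sqrt(6.0 / (fan_in + hidden))
        def w():
            return rng.uniform(-limit, limit, size=(hidden, fan_in))
        def b():
            return np.zeros(hidden)
        return cls(W_f=w(), W_i=w(), W_C=w(), W_o=w(),
                   b_f=b(), b_i=b(), b_C=b(), b_o=b())

    @classmethod
    def zeros_like(cls, p: "LSTMCellParams") -> "LSTMCellParams":
        return cls(**{f: np.zeros_like(getattr(p, f)) for f in cls.FIELDS})

    @property
    def hidden(self) -> int:
        return self.W_f.shape[0]

    def stacked(self) -> tuple[np.ndarray, np.ndarray]:
        """(4H, H+D) weight and (4H,) bias, gate order f, i, C, o."""
        W = np.concatenate([self.W_f, self.W_i, self.W_C, self.W_o])
        b = np.concatenate([self.b_f, self.b_i, self.b_C, self.b_o])
        return W, b


def lstm_step(x_t, h_prev, c_prev, params: LSTMCellParams):
    """One LSTM cell update; returns (h_t, c_t).

    Accepts single vectors or (batch, dim) arrays.
    """
    x_t = np.asarray(x_t, dtype=float)
    h_prev = np.asarray(h_prev, dtype=float)
    c_prev = np.asarray(c_prev, dtype=float)
    H = params.hidden
    D = params.W_f.shape[1] - H
    if x_t.shape[-1] != D or h_prev.shape[-1] != H or c_prev.shape[-1] != H:
        raise InvalidInputError(
            f"shape mismatch: x {x_t.shape}, h {h_prev.shape}, c {c_prev.shape} "
            f"vs cell input {D}, hidden {H}"
        )
    z = np.concatenate([h_prev, x_t], axis=-1)
    f = sigmoid(z @ params.W_f.T + params.b_f)
    i = sigmoid(z @ params.W_i.T + params.b_i)
    g = np.tanh(z @ params.W_C.T + params.b_C)
    c_t = f * c_prev + i * g
    o = sigmoid(z @ params.W_o.T + params.b_o)
    h_t = o * np.tanh(c_t)
    return h_t, c_t


class _Direction:
    """One scan direction of an LSTM layer, with BPTT."""

    def __init__(self, params: LSTMCellParams, reverse: bool):
        self.params = params
        self.reverse = reverse

    def forward(self, X: np.ndarray):
        """X: (B, T, D) -> outputs (B, T, H) in original time order."""
        B, T, D = X.shape
        H = self.params.hidden
        W, b = self.params.stacked()
        Wt = W.T
        order = range(T - 1, -1, -1) if self.reverse else range(T)
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        out = np.empty((B, T, H))
        cache = {"X": X, "steps": {}}
        for t in order:
            z = np.concatenate([h, X[:, t, :]], axis=1)
            a = z @ Wt + b
            f = sigmoid(a[:, :H])
            i = sigmoid(a[:, H:2 * H])
            g = np.tanh(a[:, 2 * H:3 * H])
            o = sigmoid(a[:, 3 * H:])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            cache["steps"][t] = (z, f, i, g, o, c, tanh_c)
            h, c = h_new, c_new
            out[:, t, :] = h
        return out, cache

    def backward(self, dOut: np.ndarray, cache) -> tuple[np.ndarray, LSTMCellParams]:
        """dOut: (B, T, H) gradients w.r.t. outputs (original time order)."""
        X = cache["X"]
        B, T, D = X.shape
        H = self.params.hidden
        W, _ = self.params.stacked()
        dW = np.zeros_like(W)
        db = np.zeros(4 * H)
        dX = np.zeros_like(X)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        # unroll in reverse of the scan order
        order = range(T) if self.reverse else range(T - 1, -1, -1)
        for t in order:
            z, f, i, g, o, c_prev, tanh_c = cache["steps"][t]
            dh = dOut[:, t, :] + dh_next
            do = dh * tanh_c
            dc = dc_next + dh * o * (1.0 - tanh_c ** 2)
            df = dc * c_prev
            di = dc * g
            dg = dc * i
            dc_next = dc * f
            dA = np.concatenate([
                df * f * (1 - f),
                di * i * (1 - i),
                dg * (1 - g ** 2),
                do * o * (1 - o),
            ], axis=1)
            dW += dA.T @ z
            db += dA.sum(axis=0)
            dz = dA @ W
            dh_next = dz[:, :H]
            dX[:, t, :] = dz[:, H:]
        grads = LSTMCellParams(
            W_f=dW[:H], W_i=dW[H:2 * H], W_C=dW[2 * H:3 * H], W_o=dW[3 * H:],
            b_f=db[:H], b_i=db[H:2 * H], b_C=db[2 * H:3 * H], b_o=db[3 * H:],
        )
        return dX, grads


class BiLSTMLayer:
    """Bidirectional LSTM layer: forward + backward scans, concatenated."""

    def __init__(self, rng: np.random.Generator, input_size: int, hidden: int):
        self.hidden = hidden
        self.fwd = _Direction(LSTMCellParams.init(rng, input_size, hidden),
                              reverse=False)
        self.bwd = _Direction(LSTMCellParams.init(rng, input_size, hidden),
                              reverse=True)

    def forward(self, X):
        out_f, cf = self.fwd.forward(X)
        out_b, cb = self.bwd.forward(X)
        return np.concatenate([out_f, out_b], axis=2), (cf, cb)

    def backward(self, dOut, cache):
        cf, cb = cache
        H = self.hidden
        dX_f, gf = self.fwd.backward(dOut[:, :, :H], cf)
        dX_b, gb = self.bwd.backward(dOut[:, :, H:], cb)
        return dX_f + dX_b, (gf, gb)

    def cells(self):
        return (("fwd", self.fwd.params), ("bwd", self.bwd.params))


# ---------------------------------------------------------------------------
# Y-type model


@dataclass
class YTypeModelParams:
    """Parameter storage of the Y-type network.

    ``shared_branch`` is the recurrent stack referenced by BOTH
    branches when weight sharing is on (``branch_b`` is then the very
    same list object, so mutating one mutates the other).
    """

    shared_branch: list
    branch_b: list
    proj_W_a: np.ndarray
    proj_b_a: np.ndarray
    proj_W_b: np.ndarray
    proj_b_b: np.ndarray
    dense: list  # [(W, b), ...]


class YTypeModel:
    """Weight-shared two-branch bidirectional LSTM pair classifier."""

    def __init__(self, config: ModelConfig, seed: int | None = None):
        self.config = config
        seed = config.seed if seed is None else seed
        self.rng = np.random.default_rng(seed)
        H = config.hidden_per_direction
        D = config.channels_per_step

        def make_stack():
            layers, size = [], D
            for _ in range(config.rnn_layers_per_branch):
                layers.append(BiLSTMLayer(self.rng, size, H))
                size = 2 * H
            return layers

        branch_a = make_stack()
        branch_b = branch_a if config.shared else make_stack()

        term_width = 2 * H  # terminal forward state + terminal backward state
        if config.buffer_mode == "per_branch":
            half = config.buffer_units // 2
            W_a = self._glorot(term_width, half)
            b_a = np.zeros(half)
            if config.shared:
                W_b, b_b = W_a, b_a
            else:
                W_b = self._glorot(term_width, half)
                b_b = np.zeros(half)
        else:  # joint: one map from both terminals to the buffer
            W_a = self._glorot(2 * term_width, config.buffer_units)
            b_a = np.zeros(config.buffer_units)
            W_b, b_b = W_a, b_a

        dense = []
        size = config.buffer_units
        for units in config.dense_units:
            dense.append([self._glorot(size, units), np.zeros(units)])
            size = units

        self.params = YTypeModelParams(
            shared_branch=branch_a, branch_b=branch_b,
            proj_W_a=W_a, proj_b_a=b_a, proj_W_b=W_b, proj_b_b=b_b,
            dense=dense,
        )
        # per-feature z-score fitted on the training split; wavelet
        # descriptor columns span several orders of magnitude, which
        # would otherwise saturate the recurrent gates
        self.input_mean: np.ndarray | None = None
        self.input_sd: np.ndarray | None = None

    def _glorot(self, fan_in, fan_out):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return self.rng.uniform(-limit, limit, size=(fan_in, fan_out))

    # -- structure ---------------------------------------------------------

    @property
    def input_units(self) -> int:
        return 2 * N_FEATURES

    def named_parameters(self) -> dict[str, np.ndarray]:
        """Unique parameter arrays by name.  Shared storages appear once."""
        p = self.params
        out: dict[str, np.ndarray] = {}
        seen: set[int] = set()

        def add(name, arr):
            if id(arr) not in seen:
                seen.add(id(arr))
                out[name] = arr

        for bname, stack in (("a", p.shared_branch), ("b", p.branch_b)):
            for li, layer in enumerate(stack):
                for dname, cell in layer.cells():
                    for f in LSTMCellParams.FIELDS:
                        add(f"branch_{bname}.layer{li}.{dname}.{f}",
                            getattr(cell, f))
        add("proj_a.W", p.proj_W_a)
        add("proj_a.b", p.proj_b_a)
        add("proj_b.W", p.proj_W_b)
        add("proj_b.b", p.proj_b_b)
        for i, (W, b) in enumerate(p.dense):
            add(f"dense{i}.W", W)
            add(f"dense{i}.b", b)
        return out

    def n_parameters(self) -> int:
        return sum(a.size for a in self.named_parameters().values())

    # -- forward / backward ------------------------------------------------

    def _reshape_batch(self, X600: np.ndarray) -> np.ndarray:
        c = self.config
        return X600.reshape(-1, c.channels_per_step, c.steps_per_protein) \
                   .transpose(0, 2, 1)

    def _branch_forward(self, stack, X600):
        H = self.config.hidden_per_direction
        seq = self._reshape_batch(X600)
        caches = []
        x = seq
        for layer in stack:
            x, cache = layer.forward(x)
            caches.append(cache)
        # terminal states: forward direction at the last step, backward
        # direction at the first step (its scan terminal)
        term = np.concatenate([x[:, -1, :H], x[:, 0, H:]], axis=1)
        return term, (caches, x.shape)

    def _branch_backward(self, stack, dTerm, cache):
        H = self.config.hidden_per_direction
        caches, out_shape = cache
        dOut = np.zeros(out_shape)
        dOut[:, -1, :H] = dTerm[:, :H]
        dOut[:, 0, H:] = dTerm[:, H:]
        grads = []
        d = dOut
        for layer, lcache in zip(reversed(stack), reversed(caches)):
            d, g = layer.backward(d, lcache)
            grads.append(g)
        return list(reversed(grads))

    def forward(self, X: np.ndarray, return_cache: bool = False):
        """Class probabilities for a (B, 1200) batch of pair features."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.input_units:
            raise InvalidInputError(
                f"expected {self.input_units} input values, got {X.shape[1]}"
            )
        if self.input_mean is not None:
            X = (X - self.input_mean) / self.input_sd
        p = self.params
        term_a, cache_a = self._branch_forward(p.shared_branch, X[:, :N_FEATURES])
        term_b, cache_b = self._branch_forward(p.branch_b, X[:, N_FEATURES:])
        if self.config.buffer_mode == "per_branch":
            za = term_a @ p.proj_W_a + p.proj_b_a
            zb = term_b @ p.proj_W_b + p.proj_b_b
            buf_pre = np.concatenate([za, zb], axis=1)
        else:
            both = np.concatenate([term_a, term_b], axis=1)
            buf_pre = both @ p.proj_W_a + p.proj_b_a
        buf = relu(buf_pre)
        acts = [buf]
        h = buf
        for W, b in p.dense[:-1]:
            h = relu(h @ W + b)
            acts.append(h)
        W_out, b_out = p.dense[-1]
        probs = softmax(h @ W_out + b_out)
        if not return_cache:
            return probs
        cache = dict(X=X, term_a=term_a, term_b=term_b, cache_a=cache_a,
                     cache_b=cache_b, buf_pre=buf_pre, acts=acts, probs=probs)
        return probs, cache

    def _backward(self, Y: np.ndarray, cache) -> dict[str, np.ndarray]:
        """Gradients of mean softmax cross-entropy w.r.t. named parameters."""
        p = self.params
        c = self.config
        B = Y.shape[0]
        grads: dict[str, np.ndarray] = {
            k: np.zeros_like(v) for k, v in self.named_parameters().items()
        }
        names = self.named_parameters()
        id2name = {id(v): k for k, v in names.items()}

        def acc(arr, g):
            grads[id2name[id(arr)]] += g

        dlogits = (cache["probs"] - Y) / B
        h_last = cache["acts"][-1]
        W_out, b_out = p.dense[-1]
        acc(W_out, h_last.T @ dlogits)
        acc(b_out, dlogits.sum(axis=0))
        d = dlogits @ W_out.T
        for li in range(len(p.dense) - 2, -1, -1):
            W, b = p.dense[li]
            # acts[li+1] is the ReLU output of dense layer li
            d = d * (cache["acts"][li + 1] > 0)
            acc(W, cache["acts"][li].T @ d)
            acc(b, d.sum(axis=0))
            d = d @ W.T
        # d is now gradient w.r.t. the buffer ReLU *input*? No: w.r.t. buf.
        dbuf = d * (cache["buf_pre"] > 0)
        if c.buffer_mode == "per_branch":
            half = c.buffer_units // 2
            da, db_ = dbuf[:, :half], dbuf[:, half:]
            acc(p.proj_W_a, cache["term_a"].T @ da)
            acc(p.proj_b_a, da.sum(axis=0))
            acc(p.proj_W_b, cache["term_b"].T @ db_)
            acc(p.proj_b_b, db_.sum(axis=0))
            dterm_a = da @ p.proj_W_a.T
            dterm_b = db_ @ p.proj_W_b.T
        else:
            acc(p.proj_W_a,
                np.concatenate([cache["term_a"], cache["term_b"]], axis=1).T @ dbuf)
            acc(p.proj_b_a, dbuf.sum(axis=0))
            dboth = dbuf @ p.proj_W_a.T
            w = cache["term_a"].shape[1]
            dterm_a, dterm_b = dboth[:, :w], dboth[:, w:]

        for stack, dterm, bc in (
            (p.shared_branch, dterm_a, cache["cache_a"]),
            (p.branch_b, dterm_b, cache["cache_b"]),
        ):
            layer_grads = self._branch_backward(stack, dterm, bc)
            for layer, (gf, gb) in zip(stack, layer_grads):
                for (dname, cell), g in zip(layer.cells(), (gf, gb)):
                    for f in LSTMCellParams.FIELDS:
                        acc(getattr(cell, f), getattr(g, f))
        return grads

    # -- training ----------------------------------------------------------

    @staticmethod
    def _as_arrays(data):
        if isinstance(data, tuple):
            X, Y = data
            return np.asarray(X, dtype=float), np.asarray(Y, dtype=float)
        return pair_matrix(list(data))

    def loss(self, X, Y) -> float:
        probs = self.forward(X)
        eps = 1e-12
        return float(-np.mean(np.sum(Y * np.log(probs + eps), axis=1)))

    def train(self, data, *, epochs: int | None = None,
              learning_rate: float | None = None,
              batch_size: int | None = None) -> list[float]:
        """Mini-batch SGD on softmax cross-entropy.

        ``data`` is either a list of (augmented, training-split)
        :class:`PairFeature` records or an ``(X, Y)`` tuple.  Returns
        the per-epoch mean training loss.
        """
        X, Y = self._as_arrays(data)
        if X.shape[0] == 0:
            raise InvalidInputError("empty training data")
        c = self.config
        if c.standardize_inputs and self.input_mean is None:
            # pool the two 600-column halves so both branches share one
            # per-feature scale; keeps branch symmetry exact
            halves = np.vstack([X[:, :N_FEATURES], X[:, N_FEATURES:]])
            sd = halves.std(axis=0)
            sd[sd < 1e-8] = 1.0
            self.input_mean = np.tile(halves.mean(axis=0), 2)
            self.input_sd = np.tile(sd, 2)
        epochs = c.epochs if epochs is None else epochs
        lr = c.learning_rate if learning_rate is None else learning_rate
        bs = c.batch_size if batch_size is None else batch_size
        n = X.shape[0]
        history: list[float] = []
        params = self.named_parameters()
        velocity = {k: np.zeros_like(v) for k, v in params.items()} \
            if c.momentum else None
        for epoch in range(epochs):
            order = self.rng.permutation(n)
            losses = []
            for start in range(0, n, bs):
                idx = order[start:start + bs]
                xb, yb = X[idx], Y[idx]
                probs, cache = self.forward(xb, return_cache=True)
                eps = 1e-12
                loss = float(-np.mean(np.sum(yb * np.log(probs + eps), axis=1)))
                if not np.isfinite(loss):
                    raise DivergenceError(epoch, loss)
                losses.append(loss)
                if lr == 0:
                    continue
                grads = self._backward(yb, cache)
                for name, arr in params.items():
                    if velocity is None:
                        arr -= lr * grads[name]
                    else:
                        v = velocity[name]
                        v *= c.momentum
                        v -= lr * grads[name]
                        arr += v
            history.append(float(np.mean(losses)) if losses else float("nan"))
        return history

    # -- inference ---------------------------------------------------------

    def predict_proba(self, X) -> np.ndarray:
        """Interaction scores in [0, 1] for (B, 1200) pair features.

        With symmetric inference (default), the reported score is the
        mean of the (A, B)- and (B, A)-ordered passes, making deployed
        predictions exactly order-invariant.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        scores = self.forward(X)[:, 0]
        if self.config.symmetric_inference:
            Xs = np.concatenate([X[:, N_FEATURES:], X[:, :N_FEATURES]], axis=1)
            scores = 0.5 * (scores + self.forward(Xs)[:, 0])
        return scores

    def predict_classes(self, X) -> np.ndarray:
        """1 = interacting, 0 = non-interacting; a tie at exactly 0.5
        resolves to non-interacting (conservative)."""
        return (self.predict_proba(X) > 0.5).astype(int)

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        """Versioned checkpoint: config JSON header + parameter arrays."""
        header = {
            "format": "ppiwave-checkpoint",
            "version": 1,
            "config": {**self.config.__dict__,
                       "dense_units": list(self.config.dense_units)},
        }
        arrays = {k.replace(".", "__"): v
                  for k, v in self.named_parameters().items()}
        if self.input_mean is not None:
            arrays["__input_mean__"] = self.input_mean
            arrays["__input_sd__"] = self.input_sd
        np.savez(path, __header__=np.frombuffer(
            json.dumps(header).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "YTypeModel":
        with np.load(path) as data:
            header = json.loads(bytes(data["__header__"]).decode())
            if header.get("format") != "ppiwave-checkpoint":
                raise InvalidInputError(f"{path} is not a ppiwave checkpoint")
            cfg = header["config"]
            cfg["dense_units"] = tuple(cfg["dense_units"])
            model = cls(ModelConfig(**cfg))
            params = model.named_parameters()
            for name, arr in params.items():
                arr[...] = data[name.replace(".", "__")]
            if "__input_mean__" in data:
                model.input_mean = data["__input_mean__"]
                model.input_sd = data["__input_sd__"]
        return model


def build_model(config: ModelConfig | None = None,
                seed: int | None = None) -> YTypeModel:
    """Construct an initialized Y-type model."""
    return YTypeModel(config or ModelConfig(), seed=seed)


# ---------------------------------------------------------------------------
# reshape plumbing


def reshape_for_rnn(feature_values, config: ModelConfig | None = None) -> np.ndarray:
    """Unstack a 600-value descriptor into (75 steps, 8 channels).

    Step t, channel j carries feature value ``75*j + t`` (block-major:
    the t-th feature of property j's 75-slot block).  Exact inverse:
    :func:`flatten_from_rnn`.
    """
    c = config or ModelConfig()
    v = np.asarray(getattr(feature_values, "values", feature_values), dtype=float)
    if v.shape != (N_FEATURES,):
        raise InvalidInputError(f"expected {N_FEATURES} values, got {v.shape}")
    return v.reshape(c.channels_per_step, c.steps_per_protein).T


def flatten_from_rnn(steps: np.ndarray, config: ModelConfig | None = None) -> np.ndarray:
    """Inverse of :func:`reshape_for_rnn`."""
    c = config or ModelConfig()
    s = np.asarray(steps, dtype=float)
    if s.shape != (c.steps_per_protein, c.channels_per_step):
        raise InvalidInputError(
            f"expected ({c.steps_per_protein}, {c.channels_per_step}), got {s.shape}"
        )
    return s.T.reshape(-1)


def predict(model: YTypeModel, pair: PairFeature) -> tuple[float, str]:
    """Score one pair; returns (interaction probability, class label)."""
    score = float(model.predict_proba(pair.values[None, :])[0])
    label = "interacting" if score > 0.5 else "non-interacting"
    return score, label
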