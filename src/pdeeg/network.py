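"""Declarative model specs, exact parameter counting, and trainable networks.

A :class:`ModelSpec` is an ordered layer list (input, dense, lstm, bilstm,
dropout, batchnorm) with a shape-propagation rule, a parameter-counting
rule per layer type, and named presets reproducing the three published
layer tables.  :func:`build_model` instantiates a trainable network on the
autodiff engine; its recurrent arithmetic follows the same gate equations
as the pure-NumPy reference in :mod:`pdeeg.cells` (the test suite holds
the two routes to agreement).

Parameter counting conventions:
  dense      units * (in + 1)
  lstm       4 * (units * (in + units) + units)
  bilstm     2 * the lstm count
  batchnorm  4 * features   (scale, shift, and the two running moments)
  input/dropout/activation-free layers: 0
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .cells import BiLSTMParams, LSTMParams, StructuralError

LAYER_TYPES = {"input", "dense", "lstm", "bilstm", "dropout", "batchnorm"}


@dataclass
class LayerSpec:
    type: str
    units: int | None = None
    rate: float | None = None
    return_sequences: bool = False
    activation: str | None = None
    steps: int | None = None      # input layers only
    features: int | None = None   # input layers only
    name: str = ""


@dataclass
class ModelSpec:
    layers: list[LayerSpec] = field(default_factory=list)

    def validate(self) -> None:
        if not self.layers:
            raise StructuralError("empty model spec")
        if self.layers[0].type != "input":
            raise StructuralError("first layer must be 'input'")
        for i, ly in enumerate(self.layers):
            if ly.type not in LAYER_TYPES:
                raise StructuralError(f"layer {i}: unknown type {ly.type!r}")
            if ly.type == "dropout" and not (0 <= (ly.rate or 0.0) < 1):
                raise StructuralError(f"layer {i}: dropout rate must be in [0,1)")
            if ly.type in ("dense", "lstm", "bilstm") and not ly.units:
                raise StructuralError(f"layer {i}: {ly.type} needs units")
        self.output_shapes()  # raises on incompatible wiring

    def output_shapes(self) -> list[tuple]:
        """Propagate shapes; (T, F) for sequences, (F,) for vectors."""
        shapes: list[tuple] = []
        cur: tuple = ()
        for i, ly in enumerate(self.layers):
            if ly.type == "input":
                if ly.features is None:
                    raise StructuralError("input layer needs features")
                cur = (ly.steps, ly.features) if ly.steps else (ly.features,)
            elif ly.type == "dense":
                cur = (*cur[:-1], ly.units)
            elif ly.type in ("lstm", "bilstm"):
                if len(cur) != 2:
                    raise StructuralError(
                        f"layer {i} ({ly.name or ly.type}): recurrent layer "
                        f"requires a sequence input, got shape {cur}")
                width = ly.units * (2 if ly.type == "bilstm" else 1)
                cur = (cur[0], width) if ly.return_sequences else (width,)
            # dropout / batchnorm preserve shape
            shapes.append(cur)
        return shapes


@dataclass
class LayerCount:
    name: str
    type: str
    output_shape: tuple
    params: int


def count_parameters(spec: ModelSpec) -> tuple[list[LayerCount], int]:
    """Per-layer and total trainable-parameter counts for a spec."""
    spec.validate()
    shapes = spec.output_shapes()
    rows: list[LayerCount] = []
    prev: tuple = ()
    for i, (ly, shape) in enumerate(zip(spec.layers, shapes)):
        if ly.type == "dense":
            n = ly.units * (prev[-1] + 1)
        elif ly.type == "lstm":
            n = 4 * (ly.units * (prev[-1] + ly.units) + ly.units)
        elif ly.type == "bilstm":
            n = 2 * 4 * (ly.units * (prev[-1] + ly.units) + ly.units)
        elif ly.type == "batchnorm":
            n = 4 * shape[-1]
        else:
            n = 0
        rows.append(LayerCount(ly.name or f"{ly.type}_{i}", ly.type, shape, n))
        prev = shape
    return rows, sum(r.params for r in rows)


# ---------------------------------------------------------------------------
# presets reproducing the published layer tables

def table1_lstm(input_width: int = 2548) -> ModelSpec:
    """Two stacked LSTMs with dropout and a 2-way dense head.

    The published first-layer count is consistent only with an input width
    of 2548 (never stated); it is reproduced here for completeness but the
    published head count (99) does not follow from the printed shapes.
    """
    return ModelSpec([
        LayerSpec("input", steps=1, features=input_width, name="input"),
        LayerSpec("lstm", units=64, return_sequences=True, name="lstm"),
        LayerSpec("dropout", rate=0.4, name="dropout"),
        LayerSpec("lstm", units=32, return_sequences=False, name="lstm_1"),
        LayerSpec("dropout", rate=0.4, name="dropout_1"),
        LayerSpec("dense", units=2, name="dense"),
    ])


def table2_dlblstm() -> ModelSpec:
    """Single wide bidirectional block with batch-normalized dense head."""
    return ModelSpec([
        LayerSpec("input", steps=178, features=1, name="inputs_lstm"),
        LayerSpec("dense", units=32, activation="relu", name="dense"),
        LayerSpec("bilstm", units=128, return_sequences=False, name="bidirectional"),
        LayerSpec("dropout", rate=0.4, name="dropout"),
        LayerSpec("batchnorm", name="batch_normalization"),
        LayerSpec("dense", units=64, activation="relu", name="dense_1"),
        LayerSpec("dropout", rate=0.4, name="dropout_2"),
        LayerSpec("batchnorm", name="batch_normalization_1"),
        LayerSpec("dense", units=2, name="dense_3"),
    ])


def table3_bilstm(units: int = 32, input_width: int = 1,
                  steps: int = 178) -> ModelSpec:
    """Two sequence-returning bidirectional blocks with a per-step head.

    ``units``/``input_width``/``steps`` allow scaled-down variants of the
    same wiring; the defaults reproduce the published table.
    """
    return ModelSpec([
        LayerSpec("input", steps=steps, features=input_width, name="inputs_lstm"),
        LayerSpec("dense", units=units, activation="relu", name="dense"),
        LayerSpec("bilstm", units=units, return_sequences=True, name="bidirectional"),
        LayerSpec("dropout", rate=0.4, name="dropout"),
        LayerSpec("dense", units=units, activation="relu", name="dense_1"),
        LayerSpec("bilstm", units=units, return_sequences=True, name="bidirectional_1"),
        LayerSpec("dropout", rate=0.4, name="dropout_1"),
        LayerSpec("batchnorm", name="batch_normalization"),
        LayerSpec("dense", units=2, name="dense_2"),
    ])


PRESETS = {
    "table1_lstm": table1_lstm,
    "table2_dlblstm": table2_dlblstm,
    "table3_bilstm": table3_bilstm,
}


def get_preset(name: str, **kwargs) -> ModelSpec:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return PRESETS[name](**kwargs)


# ---------------------------------------------------------------------------
# trainable network

_ACTS = {None: lambda t: t, "linear": lambda t: t, "relu": ad.relu,
         "tanh": ad.tanh, "sigmoid": ad.sigmoid}


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class _Dense:
    def __init__(self, in_dim: int, units: int, activation: str | None,
                 rng: np.random.Generator):
        self.W = Tensor(_glorot(rng, in_dim, units, (in_dim, units)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(units), requires_grad=True)
        self.act = _ACTS[activation]

    def params(self):
        return [self.W, self.b]

    def apply_one(self, x: Tensor) -> Tensor:
        return self.act(ad.add(ad.matmul(x, self.W), self.b))

    def apply(self, x, training, rng):
        if isinstance(x, list):
            return [self.apply_one(t) for t in x]
        return self.apply_one(x)


class _LSTMDirection:
    """One direction's gate parameters, column convention (in+units, units)."""

    def __init__(self, in_dim: int, units: int, rng: np.random.Generator):
        self.units = units
        n_in = in_dim + units
        self.W = {g: Tensor(_glorot(rng, n_in, units, (n_in, units)),
                            requires_grad=True) for g in "ifoc"}
        self.b = {g: Tensor(np.ones(units) if g == "f" else np.zeros(units),
                            requires_grad=True) for g in "ifoc"}

    def params(self):
        return [self.W[g] for g in "ifoc"] + [self.b[g] for g in "ifoc"]

    def run(self, xs: list[Tensor]) -> list[Tensor]:
        batch = xs[0].shape[0]
        h = Tensor(np.zeros((batch, self.units)))
        c = Tensor(np.zeros((batch, self.units)))
        out = []
        for x in xs:
            z = ad.concat([h, x], axis=1)
            i = ad.sigmoid(ad.add(ad.matmul(z, self.W["i"]), self.b["i"]))
            f = ad.sigmoid(ad.add(ad.matmul(z, self.W["f"]), self.b["f"]))
            o = ad.sigmoid(ad.add(ad.matmul(z, self.W["o"]), self.b["o"]))
            c_hat = ad.tanh(ad.add(ad.matmul(z, self.W["c"]), self.b["c"]))
            c = ad.add(ad.mul(f, c), ad.mul(i, c_hat))
            h = ad.mul(o, ad.tanh(c))
            out.append(h)
        return out

    def functional(self) -> LSTMParams:
        """Export to the pure-NumPy reference convention (units, units+in)."""
        return LSTMParams(
            W_i=self.W["i"].data.T.copy(), W_f=self.W["f"].data.T.copy(),
            W_o=self.W["o"].data.T.copy(), W_c=self.W["c"].data.T.copy(),
            b_i=self.b["i"].data.copy(), b_f=self.b["f"].data.copy(),
            b_o=self.b["o"].data.copy(), b_c=self.b["c"].data.copy())


class _Recurrent:
    def __init__(self, in_dim: int, units: int, bidirectional: bool,
                 return_sequences: bool, rng: np.random.Generator):
        self.fwd = _LSTMDirection(in_dim, units, rng)
        self.bwd = _LSTMDirection(in_dim, units, rng) if bidirectional else None
        self.return_sequences = return_sequences

    def params(self):
        ps = self.fwd.params()
        if self.bwd:
            ps += self.bwd.params()
        return ps

    def apply(self, x, training, rng):
        if not isinstance(x, list):
            raise StructuralError("recurrent layer requires a sequence input")
        hf = self.fwd.run(x)
        if self.bwd is None:
            return hf if self.return_sequences else hf[-1]
        hb = self.bwd.run(x[::-1])[::-1]
        if self.return_sequences:
            return [ad.concat([f, b], axis=1) for f, b in zip(hf, hb)]
        # final step of each direction: [h_f(T), h_b(1)]
        return ad.concat([hf[-1], hb[0]], axis=1)

    def functional(self):
        if self.bwd is None:
            return self.fwd.functional()
        return BiLSTMParams(forward=self.fwd.functional(),
                            backward=self.bwd.functional())


class _Dropout:
    def __init__(self, rate: float):
        self.rate = rate

    def params(self):
        return []

    def apply(self, x, training, rng):
        if not training or self.rate == 0:
            return x

        def drop(t: Tensor) -> Tensor:
            mask = (rng.random(t.shape) >= self.rate) / (1.0 - self.rate)
            return ad.mul(t, Tensor(mask))

        return [drop(t) for t in x] if isinstance(x, list) else drop(x)


class _BatchNorm:
    def __init__(self, features: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(features), requires_grad=True)
        self.beta = Tensor(np.zeros(features), requires_grad=True)
        self.running_mean = np.zeros(features)
        self.running_var = np.ones(features)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [self.gamma, self.beta]

    def apply(self, x, training, rng):
        # a sequence is flattened step-major into a 2-D tensor; downstream
        # dense/dropout layers act row-wise so per-step semantics survive
        if isinstance(x, list):
            x = ad.concat(x, axis=0)
        if training:
            out, mu, var = ad.batchnorm(x, self.gamma, self.beta, self.eps)
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            return out
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        data = self.gamma.data * (x.data - self.running_mean) * inv + self.beta.data
        return Tensor(data)


class Model:
    """Trainable network instantiated from a :class:`ModelSpec`."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(seed)
        shapes = spec.output_shapes()
        self.steps = spec.layers[0].steps
        self.layers: list = []
        prev: tuple = ()
        for ly, shape in zip(spec.layers, shapes):
            if ly.type == "input":
                self.layers.append(None)
            elif ly.type == "dense":
                self.layers.append(_Dense(prev[-1], ly.units, ly.activation, rng))
            elif ly.type in ("lstm", "bilstm"):
                self.layers.append(_Recurrent(prev[-1], ly.units,
                                              ly.type == "bilstm",
                                              ly.return_sequences, rng))
            elif ly.type == "dropout":
                self.layers.append(_Dropout(ly.rate or 0.0))
            elif ly.type == "batchnorm":
                self.layers.append(_BatchNorm(shape[-1]))
            prev = shape

    def parameters(self) -> list[Tensor]:
        ps: list[Tensor] = []
        for layer in self.layers:
            if layer is not None:
                ps += layer.params()
        return ps

    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.parameters(), weights):
            p.data = w.copy()

    def forward(self, X: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> tuple[Tensor, int]:
        """Returns (logits, steps): logits is (B*steps, C) row-ordered
        step-major for sequence outputs, (B, C) (steps=1) otherwise."""
        X = np.asarray(X, dtype=float)
        rng = rng or np.random.default_rng(0)
        if self.steps:
            if X.ndim != 3:
                raise ValueError("expected a batch of sequences (B, T, F)")
            x = [Tensor(X[:, t, :]) for t in range(X.shape[1])]
        else:
            x = Tensor(X)
        for layer in self.layers[1:]:
            x = layer.apply(x, training, rng)
        if isinstance(x, list):
            x = ad.concat(x, axis=0)
        n_steps = x.shape[0] // X.shape[0]
        return x, n_steps

    def predict_step_scores(self, X: np.ndarray) -> np.ndarray:
        """Per-step class probabilities, (B, steps, C); steps=1 for
        vector-output models."""
        from .losses import softmax

        logits, n_steps = self.forward(X, training=False)
        B = np.asarray(X).shape[0]
        probs = softmax(logits.data, axis=1)
        return probs.reshape(n_steps, B, -1).transpose(1, 0, 2)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Per-item class probabilities (step scores averaged)."""
        return self.predict_step_scores(X).mean(axis=1)


def build_model(spec: ModelSpec, seed: int = 0) -> Model:
    """Instantiate a trainable network from a spec (or preset name)."""
    return Model(spec, seed=seed)
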